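"""Ground-truth-labelled synthetic muscle cross-section generator.

Emulates a four-channel immunofluorescence stain of a transverse muscle
section: AF350 marks slow myosin, AF488 embryonic (regenerating) myosin, AF594
fast myosin, and AF647 collagen VI outlining every fibre. Fibres are a
nearest-seed tessellation of Poisson-disc-sampled seed points; pixels close to
a cell boundary (or beyond a maximum radius from any seed) form the collagen
network. Each fibre draws one mean intensity per channel from its type's
intensity model, a fraction ``bleedthrough_beta`` of the fast channel is added
into the collagen channel (the artefact the analysis pipeline removes by
channel subtraction), and Gaussian background noise is added everywhere.
Generation is pixel-deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .io_core import CHANNEL_ROLES, MultiChannelImage, ValidationError

#: the seven detectable fibre categories (positivity over slow/fast/regen)
CATEGORIES = (
    "slow", "fast", "fast/slow hybrid", "pure regenerative",
    "fast/regenerative", "slow/regenerative", "fast/slow/regenerative",
)

#: channel positivity per category: (slow_350, fast_594, regen_488)
CATEGORY_FLAGS = {
    "slow": (True, False, False),
    "fast": (False, True, False),
    "fast/slow hybrid": (True, True, False),
    "pure regenerative": (False, False, True),
    "fast/regenerative": (False, True, True),
    "slow/regenerative": (True, False, True),
    "fast/slow/regenerative": (True, True, True),
}

DEFAULT_POSITIVE_MEAN = 180.0
DEFAULT_NEGATIVE_MEAN = 20.0
DEFAULT_INTENSITY_SD = 12.0
# background autofluorescence varies less between fibres than specific staining
DEFAULT_NEGATIVE_SD = 5.0


def reporting_composition(type1_pct: float, type2_pct: float, hybrid_pct: float,
                          regen_pct: float,
                          regen_split=(0.6, 0.25, 0.1, 0.05)) -> dict[str, float]:
    """Build a 7-category composition from reporting-class percentages.

    The regenerating share is split over the four regeneration-positive
    categories (pure, fast/regen, slow/regen, triple); the result is
    normalised to sum to 1.
    """
    total = type1_pct + type2_pct + hybrid_pct + regen_pct
    comp = {
        "slow": type1_pct / total,
        "fast": type2_pct / total,
        "fast/slow hybrid": hybrid_pct / total,
    }
    for cat, frac in zip(("pure regenerative", "fast/regenerative",
                          "slow/regenerative", "fast/slow/regenerative"),
                         regen_split):
        comp[cat] = regen_pct / total * frac
    return comp


@dataclass
class SectionParams:
    shape: tuple = (1024, 1024)
    n_fibres: int = 200
    composition: dict = field(
        default_factory=lambda: reporting_composition(41.0, 58.0, 1.0, 0.2))
    boundary_width_px: float = 3.0
    max_cell_radius_px: float = 80.0
    min_seed_spacing_px: float | None = None  # default: 0.65*sqrt(area/n)
    border_margin_px: float | None = None     # default: max cell radius + 12
    positive_mean: float = DEFAULT_POSITIVE_MEAN
    negative_mean: float = DEFAULT_NEGATIVE_MEAN
    intensity_sd: float = DEFAULT_INTENSITY_SD
    negative_sd: float = DEFAULT_NEGATIVE_SD
    collagen_boundary_mean: float = 200.0
    collagen_interior_mean: float = 2.0
    bleedthrough_beta: float = 0.3
    background_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"composition sums to {total}, expected 1")
        unknown = set(self.composition) - set(CATEGORIES) - {"unclassified"}
        if unknown:
            raise ValidationError(f"unknown categories {sorted(unknown)}")
        if self.boundary_width_px < 1:
            raise ValidationError("boundary width must be at least 1 px")
        for m in (self.positive_mean, self.negative_mean):
            if not 0 <= m <= 255:
                raise ValidationError("intensity means must lie in [0, 255]")
        if not 0.0 <= self.bleedthrough_beta < 1.0:
            raise ValidationError("bleedthrough_beta must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Instance labels (0 = background/boundary) plus per-fibre annotations."""

    labels: np.ndarray
    fibres: pd.DataFrame  # columns: label, category, area_px, centroid_r, centroid_c

    @property
    def n_fibres(self) -> int:
        return len(self.fibres)

    def composition_pct(self) -> dict[str, float]:
        """Reporting-class percentages over all generated fibres."""
        from .fibretype import reporting_class
        classes = self.fibres["category"].map(reporting_class)
        counts = classes.value_counts()
        return {cls: 100.0 * counts.get(cls, 0) / len(self.fibres)
                for cls in ("type I", "type II", "hybrid I/II",
                            "regenerating", "unclassified")}


def _poisson_disc(rng: np.random.Generator, shape, n_target: int,
                  spacing: float, margin: float) -> np.ndarray:
    """Dart-throwing Poisson-disc sample of up to ``n_target`` seed points."""
    lo = np.array([margin, margin])
    hi = np.array([shape[0] - margin, shape[1] - margin])
    if np.any(hi <= lo):
        raise ValidationError("margin leaves no room for seeds")
    points: list[np.ndarray] = []
    attempts = 60 * n_target
    for _ in range(attempts):
        if len(points) >= n_target:
            break
        cand = lo + rng.random(2) * (hi - lo)
        if points:
            d2 = np.sum((np.asarray(points) - cand) ** 2, axis=1)
            if d2.min() < spacing ** 2:
                continue
        points.append(cand)
    if len(points) < max(2, n_target // 2):
        raise ValidationError(
            f"could only place {len(points)} of {n_target} fibres: "
            "n_fibres incompatible with image shape / spacing")
    return np.asarray(points)


def generate_section(params: SectionParams):
    """Generate one synthetic section -> (MultiChannelImage, GroundTruth)."""
    p = params
    rng = np.random.default_rng(p.seed)
    area = p.shape[0] * p.shape[1]
    spacing = p.min_seed_spacing_px or 0.65 * np.sqrt(area / p.n_fibres)
    margin = p.border_margin_px if p.border_margin_px is not None \
        else p.max_cell_radius_px + 12.0
    seeds = _poisson_disc(rng, p.shape, p.n_fibres, spacing, margin)

    rr, cc = np.mgrid[0:p.shape[0], 0:p.shape[1]]
    pixels = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    tree = cKDTree(seeds)
    k = min(2, len(seeds))
    dist, idx = tree.query(pixels, k=2)
    d1 = dist[:, 0].reshape(p.shape)
    d2 = dist[:, 1].reshape(p.shape)
    nearest = idx[:, 0].reshape(p.shape)

    interior = (d2 - d1 >= p.boundary_width_px) & (d1 <= p.max_cell_radius_px)
    labels = np.where(interior, nearest + 1, 0).astype(np.int32)
    boundary = (~interior) & (d1 <= p.max_cell_radius_px + p.boundary_width_px)

    # drop fibres that ended up empty or split (possible at extreme packing)
    present = np.unique(labels)
    present = present[present > 0]

    cats = list(p.composition)
    probs = np.array([p.composition[c] for c in cats])
    draw = rng.choice(len(cats), size=len(seeds), p=probs)
    fibre_cat = {i + 1: cats[draw[i]] for i in range(len(seeds))}

    planes = np.zeros((4, *p.shape), dtype=float)
    ch_index = {name: i for i, name in enumerate(CHANNEL_ROLES)}
    rows = []
    com = ndi.center_of_mass(interior, labels, present)
    areas = ndi.sum_labels(interior, labels, present)
    for lab, (cr, ccx), a in zip(present, np.atleast_2d(com), np.atleast_1d(areas)):
        cat = fibre_cat[int(lab)]
        flags = CATEGORY_FLAGS.get(cat, (False, False, False))
        mask = labels == lab
        for ch, positive in zip(("slow_350", "fast_594", "regen_488"), flags):
            mu = p.positive_mean if positive else p.negative_mean
            sd = p.intensity_sd if positive else p.negative_sd
            value = np.clip(rng.normal(mu, sd), 0, 255)
            planes[ch_index[ch]][mask] = value
        planes[ch_index["collagen_647"]][mask] = p.collagen_interior_mean
        rows.append(dict(label=int(lab), category=cat, area_px=float(a),
                         centroid_r=float(cr), centroid_c=float(ccx)))

    planes[ch_index["collagen_647"]][boundary] = p.collagen_boundary_mean
    for ch in ("slow_350", "fast_594", "regen_488"):
        planes[ch_index[ch]][labels == 0] = p.negative_mean

    planes[ch_index["collagen_647"]] += p.bleedthrough_beta * planes[ch_index["fast_594"]]
    if p.background_noise_sd > 0:
        planes += rng.normal(0.0, p.background_noise_sd, size=planes.shape)
    planes = np.clip(planes, 0, 255).round().astype(np.uint8)

    truth = GroundTruth(labels=labels, fibres=pd.DataFrame(rows))
    return MultiChannelImage(planes, CHANNEL_ROLES), truth


def corrupt_section(image: MultiChannelImage, mode: str, truth: GroundTruth | None = None,
                    **kwargs):
    """Apply a named corruption for robustness testing.

    Modes:
      * ``fuse``: erase the collagen boundary between fibre pairs closer than
        ``max_gap_px`` (default: erode the whole boundary by ``iterations``),
        so the watershed must split them;
      * ``darken``: multiply channel ``channel`` by ``factor``;
      * ``crop``: crop ``margin_px`` from every side, pushing peripheral
        fibres onto the image border (returns cropped truth too, when given).
    """
    planes = image.planes.copy()
    idx = {name: i for i, name in enumerate(image.channel_names)}
    if mode == "darken":
        channel = kwargs.get("channel", "slow_350")
        factor = float(kwargs.get("factor", 0.1))
        planes[idx[channel]] = np.clip(
            planes[idx[channel]].astype(float) * factor, 0, 255).astype(np.uint8)
        out_truth = truth
    elif mode == "fuse":
        iterations = int(kwargs.get("iterations", 2))
        coll = planes[idx["collagen_647"]]
        high = coll > 100
        eroded = ndi.binary_erosion(high, iterations=iterations)
        coll = coll.copy()
        coll[high & ~eroded] = 10
        planes[idx["collagen_647"]] = coll
        out_truth = truth
    elif mode == "crop":
        m = int(kwargs.get("margin_px", 64))
        planes = planes[:, m:-m, m:-m]
        if truth is not None:
            labels = truth.labels[m:-m, m:-m]
            kept = np.unique(labels)
            fibres = truth.fibres[truth.fibres["label"].isin(kept)].copy()
            fibres["centroid_r"] -= m
            fibres["centroid_c"] -= m
            out_truth = GroundTruth(labels=labels, fibres=fibres.reset_index(drop=True))
        else:
            out_truth = None
    else:
        raise ValidationError(f"unknown corruption mode {mode!r}")
    corrupted = MultiChannelImage(planes, image.channel_names)
    return (corrupted, out_truth) if truth is not None else corrupted
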