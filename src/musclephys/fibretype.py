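"""Semi-automated immunofluorescence fibre-typing pipeline.

Mirrors the ImageJ-style workflow on four-channel sections: (1) remove the
fast-myosin (AF594) bleed-through from the collagen VI (AF647) outline channel
by integer subtraction; (2) threshold the corrected outline, invert it to
fibre interiors, and split touching fibres with a marker-based watershed on
the interior distance transform; (3) filter candidate particles by area
(>= 300 px), circularity (0.40-1.00, computed as 4*pi*A/P^2 from a chain-code
perimeter and clamped at 1.0) and contact with the image border; (4) measure
mean fluorescence of the three myosin channels inside each region of interest
(ROI); (5) call each ROI as one of seven categories from per-channel
positivity thresholds, grouping every regeneration-positive category into a
single "regenerating" reporting class; (6) summarise per-image percentages and
per-subject means over images.

Thresholds are interactive in the original workflow; here they are either
manual config values or an automatic Otsu-style cutoff on the 1-D distribution
of ROI means, flagged when the channel is not convincingly bimodal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .io_core import MultiChannelImage, RunConfig, ValidationError
from .sim_images import CATEGORY_FLAGS, GroundTruth

REPORTING_CLASSES = ("type I", "type II", "hybrid I/II", "regenerating", "unclassified")

#: (slow, fast, regen) positivity -> category
_FLAGS_TO_CATEGORY = {v: k for k, v in CATEGORY_FLAGS.items()}
_FLAGS_TO_CATEGORY[(False, False, False)] = "unclassified"

#: category -> reporting class (all regeneration-positive categories grouped)
_CATEGORY_TO_CLASS = {
    "slow": "type I",
    "fast": "type II",
    "fast/slow hybrid": "hybrid I/II",
    "pure regenerative": "regenerating",
    "fast/regenerative": "regenerating",
    "slow/regenerative": "regenerating",
    "fast/slow/regenerative": "regenerating",
    "unclassified": "unclassified",
}


def reporting_class(category: str) -> str:
    return _CATEGORY_TO_CLASS[category]


@dataclass
class FibreROI:
    roi_id: int
    label: int
    area_px: float
    perimeter_px: float
    circularity: float
    touches_edge: bool
    mean_slow_350: float = float("nan")
    mean_regen_488: float = float("nan")
    mean_fast_594: float = float("nan")


@dataclass
class ClassifierThresholds:
    t_slow: float
    t_fast: float
    t_regen: float
    source: str = "manual"            # "manual" | "auto"
    low_confidence: tuple = ()        # channels whose auto cutoff is dubious

    def __post_init__(self):
        for t in (self.t_slow, self.t_fast, self.t_regen):
            if not 0 < t < 255:
                raise ValidationError("thresholds must lie in (0, 255)")


@dataclass
class FibreTypeCall:
    roi_id: int
    slow_positive: bool
    fast_positive: bool
    regen_positive: bool
    category: str
    reporting: str


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def bleedthrough_correct(image: MultiChannelImage) -> np.ndarray:
    """Corrected outline plane: clip(collagen_647 - fast_594, 0, 255), integer."""
    coll = image.channel("collagen_647").astype(np.int16)
    fast = image.channel("fast_594").astype(np.int16)
    return np.clip(coll - fast, 0, 255).astype(np.uint8)


def fibre_mask(boundary_plane: np.ndarray, min_level: int = 1,
               config: RunConfig | None = None) -> np.ndarray:
    """Labelled fibre-instance mask from the corrected outline plane.

    Pixels >= ``min_level`` form the boundary network (small specks below
    ``fibre.speckle_min_px`` are treated as noise); the inverted mask gives
    fibre interiors, which a marker-based watershed splits where outlines are
    broken. Markers are local maxima of the Gaussian-smoothed interior
    distance transform.
    """
    config = config or RunConfig()
    boundary = boundary_plane >= min_level
    if boundary.all():
        raise ValidationError("corrected plane is entirely boundary")
    speck = int(config["fibre.speckle_min_px"])
    if speck > 1:
        lab, _ = ndi.label(boundary)
        sizes = np.bincount(lab.ravel())
        boundary &= sizes[lab] >= speck
    interior = ~boundary
    if not boundary.any():
        raise ValidationError("corrected plane contains no boundary pixels")
    dist = ndi.distance_transform_edt(interior)
    sigma = float(config["fibre.marker_smooth_sigma_px"])
    smooth = ndi.gaussian_filter(dist, sigma) if sigma > 0 else dist
    min_dist = int(config["fibre.marker_min_distance_px"])
    coords = peak_local_max(smooth, min_distance=min_dist, labels=interior,
                            exclude_border=False)
    markers = np.zeros(interior.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-smooth, markers, mask=interior)
    return labels


# ---------------------------------------------------------------------------
# particle measurement and filtering
# ---------------------------------------------------------------------------

_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_SQRT2 = float(np.sqrt(2.0))


def chain_perimeter(mask: np.ndarray) -> float:
    """Perimeter of a single connected object by Moore boundary following.

    The outer boundary is traced as an 8-connected pixel chain; cardinal steps
    count 1 and diagonal steps sqrt(2). Isolated pixels and 2-pixel objects
    degenerate to chain lengths of 0/2 and are floored at 1.
    """
    padded = np.pad(mask.astype(bool), 1)
    rows, cols = np.nonzero(padded)
    if rows.size == 0:
        return 0.0
    if rows.size == 1:
        return 1.0
    # start at the first object pixel in raster order; entry direction west
    start = (int(rows[0]), int(cols[0]))
    perim = 0.0
    current = start
    prev_dir = 6  # came from the east means backtrack points west
    first_step = None
    while True:
        found = False
        for turn in range(8):
            d = (prev_dir + 1 + turn) % 8
            nr, nc = current[0] + _MOORE[d][0], current[1] + _MOORE[d][1]
            if padded[nr, nc]:
                step = 1.0 if d % 2 == 0 else _SQRT2
                nxt = (nr, nc)
                found = True
                break
        if not found:
            return 1.0  # isolated pixel (shouldn't reach here for size > 1)
        if first_step is None:
            first_step = (current, nxt)
        elif (current, nxt) == first_step and perim > 0:
            break
        perim += step
        current = nxt
        prev_dir = (d + 4) % 8
        if perim > 8 * mask.size:
            raise RuntimeError("boundary tracing failed to close")
    return max(perim, 1.0)


def measure_particles(labels: np.ndarray) -> list[FibreROI]:
    """Area, chain perimeter, circularity and edge contact for every label."""
    rois = []
    ids = np.unique(labels)
    ids = ids[ids > 0]
    slices = ndi.find_objects(labels)
    for lab in ids:
        sl = slices[int(lab) - 1]
        mask = labels[sl] == lab
        area = float(mask.sum())
        filled = ndi.binary_fill_holes(mask)
        perim = chain_perimeter(filled)
        circ = 4.0 * np.pi * area / perim ** 2 if perim > 0 else 0.0
        circ = min(circ, 1.0)  # digitisation can push a disc slightly past 1
        touches = (sl[0].start == 0 or sl[1].start == 0
                   or sl[0].stop == labels.shape[0] or sl[1].stop == labels.shape[1])
        if touches:
            edge_mask = np.zeros(labels.shape, dtype=bool)
            edge_mask[0, :] = edge_mask[-1, :] = True
            edge_mask[:, 0] = edge_mask[:, -1] = True
            touches = bool((edge_mask[sl] & mask).any())
        rois.append(FibreROI(roi_id=int(lab), label=int(lab), area_px=area,
                             perimeter_px=perim, circularity=float(circ),
                             touches_edge=bool(touches)))
    return rois


def particle_filter(labels: np.ndarray, min_area: float = 300.0,
                    circ_min: float = 0.40, circ_max: float = 1.00) -> list[FibreROI]:
    """Keep ROIs with area >= min_area, circularity in [circ_min, circ_max]
    and no contact with the image border."""
    return [r for r in measure_particles(labels)
            if r.area_px >= min_area
            and circ_min <= r.circularity <= circ_max
            and not r.touches_edge]


def measure_rois(image: MultiChannelImage, labels: np.ndarray,
                 rois: list[FibreROI]) -> list[FibreROI]:
    """Fill per-ROI mean fluorescence of the three myosin channels."""
    if labels.shape != image.shape:
        raise ValidationError("label mask shape does not match image")
    if not rois:
        return rois
    ids = [r.label for r in rois]
    for attr, channel in (("mean_slow_350", "slow_350"),
                          ("mean_regen_488", "regen_488"),
                          ("mean_fast_594", "fast_594")):
        means = ndi.mean(image.channel(channel).astype(float), labels, ids)
        for roi, m in zip(rois, np.atleast_1d(means)):
            if roi.area_px < 1:
                raise ValidationError(f"empty ROI {roi.roi_id}")
            setattr(roi, attr, float(m))
    return rois


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def auto_thresholds(rois: list[FibreROI]) -> ClassifierThresholds:
    """Otsu-style between-class-variance cutoff per channel on ROI means.

    A channel is flagged low-confidence when the two classes it induces are
    separated by less than four times their pooled sd (no convincing
    bimodality: use manual thresholds instead). Four is chosen because an
    Otsu split of a *unimodal* normal yields a separation of ~2.65 pooled
    sds, so any cutoff below that would never flag a structureless channel,
    while genuinely stained-vs-unstained ROI means separate by >> 4.
    """
    if len(rois) < 20:
        raise ValidationError(
            f"only {len(rois)} ROIs; need >= 20 for automatic thresholds - "
            "supply manual thresholds")
    cutoffs = {}
    low_conf = []
    for key, attr in (("slow", "mean_slow_350"), ("fast", "mean_fast_594"),
                      ("regen", "mean_regen_488")):
        values = np.array([getattr(r, attr) for r in rois], dtype=float)
        if np.ptp(values) == 0:
            cutoffs[key] = float(np.clip(values[0] + 1, 1, 254))
            low_conf.append(key)
            continue
        cut = float(threshold_otsu(values, nbins=256))
        lo, hi = values[values <= cut], values[values > cut]
        if lo.size < 2 or hi.size < 2:
            low_conf.append(key)
        else:
            pooled = np.sqrt((lo.var(ddof=1) + hi.var(ddof=1)) / 2.0)
            if pooled > 0 and (hi.mean() - lo.mean()) < 4.0 * pooled:
                low_conf.append(key)
        cutoffs[key] = float(np.clip(cut, 1e-6, 254.999))
    return ClassifierThresholds(t_slow=cutoffs["slow"], t_fast=cutoffs["fast"],
                                t_regen=cutoffs["regen"], source="auto",
                                low_confidence=tuple(low_conf))


def thresholds_from_config(config: RunConfig) -> ClassifierThresholds:
    return ClassifierThresholds(
        t_slow=config["fibre.threshold_slow"],
        t_fast=config["fibre.threshold_fast"],
        t_regen=config["fibre.threshold_regen"],
        source=str(config["fibre.threshold_source"]))


def classify(rois: list[FibreROI],
             thresholds: ClassifierThresholds) -> list[FibreTypeCall]:
    """Per-channel positivity (mean > cutoff) -> 7-way category + reporting class."""
    calls = []
    for r in rois:
        flags = (r.mean_slow_350 > thresholds.t_slow,
                 r.mean_fast_594 > thresholds.t_fast,
                 r.mean_regen_488 > thresholds.t_regen)
        category = _FLAGS_TO_CATEGORY[flags]
        calls.append(FibreTypeCall(
            roi_id=r.roi_id, slow_positive=flags[0], fast_positive=flags[1],
            regen_positive=flags[2], category=category,
            reporting=_CATEGORY_TO_CLASS[category]))
    return calls


# ---------------------------------------------------------------------------
# composition summaries
# ---------------------------------------------------------------------------

def image_composition(calls: list[FibreTypeCall]) -> dict[str, float]:
    """Reporting-class percentages of all accepted ROIs in one image (sum 100)."""
    if not calls:
        raise ValidationError("no accepted ROIs in image")
    n = len(calls)
    return {cls: 100.0 * sum(c.reporting == cls for c in calls) / n
            for cls in REPORTING_CLASSES}


def composition(per_image_calls: dict, group_by_subject: dict) -> pd.DataFrame:
    """Per-subject mean composition over that subject's images.

    ``per_image_calls`` maps image id -> list of FibreTypeCall;
    ``group_by_subject`` maps image id -> subject id. Subject values are
    unweighted means over images; subjects whose images all lack accepted ROIs
    are excluded with a warning.
    """
    import logging
    logger = logging.getLogger("musclephys")
    rows = []
    for image_id, calls in per_image_calls.items():
        if not calls:
            continue
        comp = image_composition(calls)
        comp["image_id"] = image_id
        comp["subject_id"] = group_by_subject[image_id]
        comp["n_fibres"] = len(calls)
        rows.append(comp)
    if not rows:
        raise ValidationError("no image produced accepted ROIs")
    per_image = pd.DataFrame(rows)
    skipped = set(group_by_subject.values()) - set(per_image["subject_id"])
    for s in sorted(skipped):
        logger.warning("subject %s excluded: zero accepted ROIs", s)
    agg = {cls: "mean" for cls in REPORTING_CLASSES}
    agg["n_fibres"] = "sum"
    per_subject = per_image.groupby("subject_id", as_index=False).agg(agg)
    per_subject["n_images"] = per_image.groupby("subject_id").size().values
    return per_subject


def analyze_image(image: MultiChannelImage, config: RunConfig | None = None,
                  thresholds: ClassifierThresholds | None = None):
    """Full single-image pipeline -> (labels, accepted ROIs, calls)."""
    config = config or RunConfig()
    corrected = bleedthrough_correct(image)
    labels = fibre_mask(corrected, min_level=int(config["fibre.mask_min_level"]),
                        config=config)
    rois = particle_filter(labels,
                           min_area=config["fibre.min_area_px"],
                           circ_min=config["fibre.circularity_min"],
                           circ_max=config["fibre.circularity_max"])
    measure_rois(image, labels, rois)
    if thresholds is None:
        thresholds = thresholds_from_config(config)
    calls = classify(rois, thresholds)
    return labels, rois, calls


# ---------------------------------------------------------------------------
# ground-truth evaluation (synthetic sections only)
# ---------------------------------------------------------------------------

def evaluate_detection(labels: np.ndarray, rois: list[FibreROI],
                       calls: list[FibreTypeCall], truth: GroundTruth):
    """Detection fraction and composition error against generator truth.

    An ROI matches the truth fibre owning the majority (> 50%) of its pixels;
    detection fraction = matched distinct true fibres / all true fibres.
    Composition error is the maximum absolute difference between recovered and
    true reporting-class percentages.
    """
    matched = set()
    call_by_roi = {c.roi_id: c for c in calls}
    for roi in rois:
        mask = labels == roi.label
        overlap = truth.labels[mask]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            continue
        counts = np.bincount(overlap)
        best = int(np.argmax(counts))
        if counts[best] > 0.5 * roi.area_px:
            matched.add(best)
    detection = len(matched) / truth.n_fibres if truth.n_fibres else 0.0

    true_comp = truth.composition_pct()
    rec_comp = image_composition(list(call_by_roi.values())) if calls else \
        {cls: 0.0 for cls in REPORTING_CLASSES}
    comp_err = max(abs(rec_comp[cls] - true_comp[cls]) for cls in REPORTING_CLASSES)
    return detection, comp_err
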