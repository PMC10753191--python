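"""Readers/writers for the formats the pipeline touches, plus run configuration.

Torque traces travel as plain CSV with a ``#``-prefixed ``key: value`` header
block followed by ``time_s,torque_Nm`` rows. Section images are multi-channel
TIFFs with four named fluorescence channels. qPCR data are long-format CSV.
All downstream modules consume the validated containers defined here and never
re-parse files themselves.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("musclephys")

GENOTYPES = ("WT", "DE50-MD")
NERVE_TARGETS = ("fibular", "tibial")
TRACE_KINDS = ("twitch", "tetanus", "eccentric")

#: acquisition-order channel roles (AF350 slow myosin, AF488 embryonic myosin,
#: AF594 fast myosin, AF647 collagen VI fibre outline)
CHANNEL_ROLES = ("slow_350", "regen_488", "fast_594", "collagen_647")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Contents parse but violate a domain invariant."""


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

_REQUIRED_TRACE_META = (
    "subject_id", "genotype", "age_months", "bodyweight_kg", "lever_arm_m",
    "nerve_target", "trace_kind", "stim_onset_s", "stim_end_s", "sampling_hz",
)

_FLOAT_META = ("age_months", "bodyweight_kg", "lever_arm_m",
               "stim_onset_s", "stim_end_s", "sampling_hz")


@dataclass
class ForceTrace:
    """Uniformly sampled torque-time record with subject metadata.

    ``time_s`` is strictly increasing with a constant step equal to
    ``1/sampling_hz`` (to within 1 ppm); torque is in newton-metres.
    """

    time_s: np.ndarray
    torque_Nm: np.ndarray
    subject_id: str
    genotype: str
    age_months: float
    bodyweight_kg: float
    lever_arm_m: float
    nerve_target: str
    trace_kind: str
    stim_onset_s: float
    stim_end_s: float
    sampling_hz: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.torque_Nm = np.asarray(self.torque_Nm, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.time_s.ndim != 1 or self.time_s.size == 0:
            raise ValidationError("trace must contain at least one sample")
        if self.time_s.shape != self.torque_Nm.shape:
            raise ValidationError("time and torque lengths differ")
        if np.isnan(self.torque_Nm).any():
            raise ValidationError("torque contains missing values")
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if self.nerve_target not in NERVE_TARGETS:
            raise ValidationError(f"unknown nerve_target {self.nerve_target!r}")
        if self.trace_kind not in TRACE_KINDS:
            raise ValidationError(f"unknown trace_kind {self.trace_kind!r}")
        if self.time_s.size > 1:
            dt = np.diff(self.time_s)
            step = dt[0]
            if step <= 0 or np.any(np.abs(dt - step) > 1e-6 * step):
                raise ValidationError("time grid is not uniform to within 1 ppm")
            if abs(self.sampling_hz * step - 1.0) > 1e-6:
                raise ValidationError(
                    "sampling_hz inconsistent with time step "
                    f"({self.sampling_hz} Hz vs dt={step:.9g} s)")
        if not self.stim_onset_s < self.stim_end_s <= self.time_s[-1] + 1e-12:
            raise ValidationError(
                "stimulus window must satisfy stim_onset_s < stim_end_s <= last time")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_hz

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def copy_with(self, **changes) -> "ForceTrace":
        return dataclasses.replace(self, **changes)


def read_trace(path: str | Path) -> ForceTrace:
    """Parse a trace CSV (``#`` header block + ``time_s,torque_Nm`` rows).

    Units declared in the header as ``mN·m``/``mNm`` (torque) or ``ms`` (time)
    are converted to SI on read.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    data_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
        else:
            data_start = i
            break
    else:
        raise FormatError(f"{path}: no data rows")

    missing = [k for k in _REQUIRED_TRACE_META if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing metadata key(s): {', '.join(missing)}")

    header = lines[data_start].strip().split(",")
    torque_scale = 1.0
    time_scale = 1.0
    if len(header) != 2:
        raise FormatError(f"{path}: expected two data columns, got {header}")
    if header[0] == "time_ms":
        time_scale = 1e-3
    elif header[0] != "time_s":
        raise FormatError(f"{path}: unknown time column {header[0]!r}")
    if header[1] in ("torque_mNm", "torque_mN.m"):
        torque_scale = 1e-3
    elif header[1] != "torque_Nm":
        raise FormatError(f"{path}: unknown torque column {header[1]!r}")

    arr = np.loadtxt(lines[data_start + 1:], delimiter=",", ndmin=2)
    known = set(_REQUIRED_TRACE_META)
    extra = {}
    for k, v in meta.items():
        if k in known:
            continue
        try:
            extra[k] = float(v)
        except ValueError:
            extra[k] = v

    kwargs = {k: meta[k] for k in _REQUIRED_TRACE_META}
    for k in _FLOAT_META:
        try:
            kwargs[k] = float(kwargs[k])
        except ValueError as exc:
            raise FormatError(f"{path}: metadata key {k!r} is not numeric") from exc
    return ForceTrace(
        time_s=arr[:, 0] * time_scale,
        torque_Nm=arr[:, 1] * torque_scale,
        extra=extra,
        **kwargs,
    )


def write_trace(trace: ForceTrace, path: str | Path) -> Path:
    """Write a trace CSV; exact inverse of :func:`read_trace` to 1e-12."""
    trace.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for key in _REQUIRED_TRACE_META:
            fh.write(f"# {key}: {getattr(trace, key)}\n")
        for key, value in trace.extra.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("time_s,torque_Nm\n")
        for t, q in zip(trace.time_s, trace.torque_Nm):
            # Python-float repr round-trips exactly and stays loadtxt-parseable
            fh.write(f"{float(t)!r},{float(q)!r}\n")
    return path


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

@dataclass
class MultiChannelImage:
    """Four-channel 8-bit section image, channel-first array of shape (4, H, W)."""

    planes: np.ndarray
    channel_names: tuple = CHANNEL_ROLES

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or self.planes.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"expected ({len(self.channel_names)}, H, W) planes, got {self.planes.shape}")
        self.channel_names = tuple(self.channel_names)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.planes[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None

    @property
    def shape(self) -> tuple:
        return self.planes.shape[1:]


def _to_uint8(planes: np.ndarray) -> np.ndarray:
    if planes.dtype == np.uint8:
        return planes
    peak = planes.max()
    logger.info("rescaling %s image to 8-bit (max %s -> 255)", planes.dtype, peak)
    if peak == 0:
        return planes.astype(np.uint8)
    return np.clip(planes.astype(float) * (255.0 / float(peak)), 0, 255).round().astype(np.uint8)


def read_image(path: str | Path, channel_names: tuple | None = None) -> MultiChannelImage:
    """Read a 4-plane TIFF; non-8-bit data are rescaled to 0-255 by the maximum.

    Channel names come from the TIFF ImageDescription (JSON written by
    :func:`write_image`) or, failing that, the ``channel_names`` argument or the
    positional acquisition order 350/488/594/647.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        planes = tif.asarray()
        desc = tif.pages[0].description
    if planes.ndim == 2:
        planes = planes[None]
    if planes.shape[0] != 4 and planes.shape[-1] == 4:
        planes = np.moveaxis(planes, -1, 0)
    if planes.shape[0] != 4:
        raise FormatError(
            f"{path}: expected 4 channel planes with roles {CHANNEL_ROLES}, "
            f"got shape {planes.shape}")
    names = channel_names
    if names is None and desc:
        try:
            names = tuple(json.loads(desc)["channel_names"])
        except (json.JSONDecodeError, KeyError, TypeError):
            names = None
    if names is None:
        names = CHANNEL_ROLES
    return MultiChannelImage(_to_uint8(planes), tuple(names))


def write_image(image: MultiChannelImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, image.planes, photometric="minisblack",
        description=json.dumps({"channel_names": list(image.channel_names)}))
    return path


def write_label_mask(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer instance-label mask (0 = background) as TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(labels).astype(np.int32),
                     photometric="minisblack")
    return path


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ("sample_id", "genotype", "gene", "Cq", "replicate")


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read a long-format Cq table (columns sample_id, genotype, gene, Cq, replicate).

    Replicates are stored as-is; collapsing is deferred to the qpcr module.
    """
    table = pd.read_csv(path)
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    return validate_qpcr(table)


def validate_qpcr(table: pd.DataFrame) -> pd.DataFrame:
    bad = table[(table["Cq"] <= 0) | (table["Cq"] > 45)]
    if not bad.empty:
        raise ValidationError(
            f"Cq outside (0, 45]: {bad[['sample_id', 'gene', 'Cq']].to_dict('records')}")
    dup = table.duplicated(subset=["sample_id", "gene", "replicate"])
    if dup.any():
        raise ValidationError(
            f"duplicate (sample, gene, replicate) rows: {table[dup].to_dict('records')}")
    counts = table.groupby(["sample_id", "gene"])["replicate"].count()
    if (counts > 3).any():
        raise ValidationError("more than 3 replicates for some (sample, gene)")
    return table


def write_qpcr(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

#: every downstream tunable with its documented default
CONFIG_DEFAULTS: dict[str, float | int | str] = {
    # io_core
    "io.sampling_hz": 1000.0,
    # kinetics QC
    "kinetics.baseline_window_s": 0.05,
    "kinetics.qc_k_snr": 5.0,          # peak must exceed k_snr x pre-stim noise sd
    "kinetics.qc_f_neg": 0.2,          # negative dips beyond f_neg x peak reject
    "kinetics.qc_m_peaks": 2,          # max prominent maxima >50% of peak in a twitch
    "kinetics.qc_peak_prominence_frac": 0.1,  # min peak prominence, fraction of peak
    "kinetics.qc_f_drop": 0.3,         # max plateau collapse during tetanic stim
    # ecd
    "ecd.plateau_window_s": 0.010,
    "ecd.rotation_delay_s": 0.5,       # rotation begins 0.5 s after stim onset
    "ecd.qc_k_snr": 5.0,
    "ecd.qc_f_jump": 0.5,              # max plausible torque jump between samples
    "ecd.qc_min_frac": 0.8,            # min accepted contractions to keep protocol
    # sim_traces
    "sim.kappa": 5.0,                  # decrement-curve decay constant (contractions)
    # fibretype
    "fibre.min_area_px": 300,
    "fibre.circularity_min": 0.40,
    "fibre.circularity_max": 1.00,
    "fibre.mask_min_level": 1,
    "fibre.speckle_min_px": 20,
    "fibre.marker_min_distance_px": 10,
    "fibre.marker_smooth_sigma_px": 3.0,
    "fibre.threshold_slow": 100.0,
    "fibre.threshold_fast": 100.0,
    "fibre.threshold_regen": 100.0,
    "fibre.threshold_source": "manual",
    # qpcr
    "qpcr.replicate_sd_flag": 0.5,
    # stats
    "power.n_timepoints": 6,
    "power.rho": 0.7,
    "power.alpha": 0.05,
    "power.target_power": 0.8,
    # seeds
    "seed": 0,
}


class RunConfig(dict):
    """Flat namespaced key-value set of all tunables; unknown keys are an error."""

    def __init__(self, overrides: dict | None = None):
        super().__init__(CONFIG_DEFAULTS)
        if overrides:
            unknown = set(overrides) - set(CONFIG_DEFAULTS)
            if unknown:
                raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
            self.update(overrides)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}

        def _flatten(prefix: str, obj) -> None:
            if isinstance(obj, dict):
                for k, v in obj.items():
                    _flatten(f"{prefix}.{k}" if prefix else k, v)
            else:
                flat[prefix] = obj

        _flatten("", raw)
        return cls(flat)

    def log_all(self) -> None:
        for key in sorted(self):
            logger.info("config %s = %s", key, self[key])
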