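"""Parametric torque-trace generators with known ground truth.

The models emulate the statistical structure of in vivo nerve-stimulated
dorsiflexion/plantarflexion recordings: a twitch rises steeply to a peak and
relaxes biexponentially (a slow tail emulates the prolonged terminal relaxation
seen in dystrophic muscle); a tetanus saturates onto a plateau that may creep
upward until the end of the 1 s / 50 Hz stimulation; an eccentric-contraction
protocol applies a pedal rotation 0.5 s into each tetanic contraction and scales
successive plateaus by a geometric-style decrement curve

    a_k = r_inf + (1 - r_inf) * exp(-(k - 1) / kappa),   k = 1..30,

so a_1 = 1 and the series decays monotonically towards r_inf. All generators
are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ForceTrace, ValidationError

DEFAULT_SAMPLING_HZ = 1000.0

_SUBJECT_DEFAULTS = dict(
    subject_id="SIM",
    genotype="WT",
    age_months=12.0,
    bodyweight_kg=12.0,
    lever_arm_m=0.11,
    nerve_target="fibular",
)


@dataclass
class TwitchParams:
    """Single-pulse twitch: normalised exponential rise, biexponential decay."""

    amplitude_Nm: float = 2.0
    t0_s: float = 0.05
    tau_rise_s: float = 0.012
    tau_fast_relax_s: float = 0.05
    tau_slow_relax_s: float = 0.8
    slow_fraction: float = 0.1
    baseline_Nm: float = 0.0
    noise_sd_Nm: float = 0.0
    seed: int = 0
    sampling_hz: float = DEFAULT_SAMPLING_HZ
    post_window_s: float = 0.8
    rise_span: float = 5.0  # rise duration in units of tau_rise; peak = amplitude exactly
    subject: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.amplitude_Nm <= 0:
            raise ValidationError("amplitude must be positive")
        if min(self.tau_rise_s, self.tau_fast_relax_s, self.tau_slow_relax_s) <= 0:
            raise ValidationError("time constants must be positive")
        if not 0.0 <= self.slow_fraction <= 1.0:
            raise ValidationError("slow_fraction must lie in [0, 1]")


@dataclass
class TetanusParams:
    """50 Hz tetanus: saturating rise to plateau with optional linear drift."""

    plateau_Nm: float = 8.0
    tau_rise_s: float = 0.05
    drift_Nm_per_s: float = 0.0
    stim_duration_s: float = 1.0
    post_window_s: float = 0.8
    t0_s: float = 0.05
    tau_fast_relax_s: float = 0.08
    tau_slow_relax_s: float = 0.8
    slow_fraction: float = 0.1
    baseline_Nm: float = 0.0
    noise_sd_Nm: float = 0.0
    seed: int = 0
    sampling_hz: float = DEFAULT_SAMPLING_HZ
    subject: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.plateau_Nm <= 0:
            raise ValidationError("plateau must be positive")
        if self.drift_Nm_per_s < 0:
            raise ValidationError("drift must be non-negative")
        if self.tau_rise_s <= 0:
            raise ValidationError("tau_rise must be positive")


@dataclass
class ECDProtocolParams:
    """Thirty eccentric contractions: three sets of ten, 4 s / 4 min gaps."""

    tetanus: TetanusParams = field(default_factory=lambda: TetanusParams(
        stim_duration_s=0.7, noise_sd_Nm=0.0))
    n_contractions: int = 30
    set_size: int = 10
    intra_gap_s: float = 4.0
    inter_set_gap_s: float = 240.0
    r_inf: float = 0.8
    kappa: float = 5.0
    rotation_delay_s: float = 0.5   # rotation onset after stim start
    rotation_duration_s: float = 0.2
    transient_amplitude_frac: float = 0.6  # eccentric spike height, fraction of plateau
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.r_inf <= 1.0:
            raise ValidationError("r_inf must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValidationError("kappa must be positive")
        end = self.rotation_delay_s + self.rotation_duration_s
        if end > self.tetanus.stim_duration_s + 1e-12:
            raise ValidationError("rotation window must end within stimulation")


@dataclass
class CohortSpec:
    """Per-group distribution of true final decrements, mapped to ECD protocols."""

    genotype: str = "WT"
    age_months: float = 12.0
    decrement_mean_pct: float = 17.0
    decrement_sd_pct: float = 11.0
    n_subjects: int = 53
    traces_per_subject: int = 1  # protocols per subject
    kappa: float = 5.0
    noise_sd_Nm: float = 0.02
    plateau_Nm: float = 8.0
    seed: int = 0
    moment_match: bool = True  # make the truncated mean equal decrement_mean_pct

    def __post_init__(self):
        if self.decrement_sd_pct < 0:
            raise ValidationError("sd must be non-negative")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be at least 1")


def decrement_curve(n: int, r_inf: float, kappa: float) -> np.ndarray:
    """Plateau scale factors a_k = r_inf + (1-r_inf)exp(-(k-1)/kappa), k=1..n."""
    k = np.arange(1, n + 1)
    return r_inf + (1.0 - r_inf) * np.exp(-(k - 1) / kappa)


def _time_grid(duration_s: float, sampling_hz: float) -> np.ndarray:
    n = int(round(duration_s * sampling_hz)) + 1
    return np.arange(n) / sampling_hz


def _biexp(delta_t: np.ndarray, slow_fraction: float,
           tau_fast: float, tau_slow: float) -> np.ndarray:
    return ((1.0 - slow_fraction) * np.exp(-delta_t / tau_fast)
            + slow_fraction * np.exp(-delta_t / tau_slow))


def simulate_twitch(params: TwitchParams) -> ForceTrace:
    """Deterministic-given-seed twitch trace.

    The rise is amplitude-normalised so the noise-free peak equals
    ``amplitude_Nm`` exactly at ``t0 + rise_span * tau_rise``; the decay from
    the peak is the biexponential mixture.
    """
    p = params
    duration = p.t0_s + p.rise_span * p.tau_rise_s + p.post_window_s
    t = _time_grid(duration, p.sampling_hz)
    t_peak = p.t0_s + p.rise_span * p.tau_rise_s
    y = np.full_like(t, p.baseline_Nm)
    rising = (t >= p.t0_s) & (t <= t_peak)
    norm = 1.0 - np.exp(-p.rise_span)
    y[rising] += p.amplitude_Nm * (1.0 - np.exp(-(t[rising] - p.t0_s) / p.tau_rise_s)) / norm
    falling = t > t_peak
    y[falling] += p.amplitude_Nm * _biexp(
        t[falling] - t_peak, p.slow_fraction, p.tau_fast_relax_s, p.tau_slow_relax_s)
    if p.noise_sd_Nm > 0:
        rng = np.random.default_rng(p.seed)
        y = y + rng.normal(0.0, p.noise_sd_Nm, size=t.size)
    meta = {**_SUBJECT_DEFAULTS, **p.subject}
    return ForceTrace(
        time_s=t, torque_Nm=y, trace_kind="twitch",
        stim_onset_s=p.t0_s, stim_end_s=p.t0_s + 1e-4,  # 0.1 ms pulse
        sampling_hz=p.sampling_hz,
        extra={"true_amplitude_Nm": p.amplitude_Nm, "true_baseline_Nm": p.baseline_Nm,
               "true_peak_time_s": t_peak},
        **meta)


def _tetanus_torque(t: np.ndarray, p: TetanusParams, plateau_scale: float = 1.0):
    """Noise-free tetanus torque and the end-of-stimulation reference value."""
    plateau = p.plateau_Nm * plateau_scale
    stim_end = p.t0_s + p.stim_duration_s
    y = np.zeros_like(t)
    during = (t >= p.t0_s) & (t <= stim_end)
    dt_on = t[during] - p.t0_s
    y[during] = plateau * (1.0 - np.exp(-dt_on / p.tau_rise_s)) + p.drift_Nm_per_s * dt_on
    end_val = (plateau * (1.0 - np.exp(-p.stim_duration_s / p.tau_rise_s))
               + p.drift_Nm_per_s * p.stim_duration_s)
    after = t > stim_end
    y[after] = end_val * _biexp(
        t[after] - stim_end, p.slow_fraction, p.tau_fast_relax_s, p.tau_slow_relax_s)
    return y, end_val


def simulate_tetanus(params: TetanusParams) -> ForceTrace:
    """Tetanic trace: saturating rise + linear drift during stimulation,
    biexponential relaxation afterwards, recording extends ``post_window_s``
    beyond the end of stimulation."""
    p = params
    stim_end = p.t0_s + p.stim_duration_s
    t = _time_grid(stim_end + p.post_window_s, p.sampling_hz)
    y, end_val = _tetanus_torque(t, p)
    y += p.baseline_Nm
    if p.noise_sd_Nm > 0:
        rng = np.random.default_rng(p.seed)
        y = y + rng.normal(0.0, p.noise_sd_Nm, size=t.size)
    meta = {**_SUBJECT_DEFAULTS, **p.subject}
    return ForceTrace(
        time_s=t, torque_Nm=y, trace_kind="tetanus",
        stim_onset_s=p.t0_s, stim_end_s=stim_end, sampling_hz=p.sampling_hz,
        extra={"true_plateau_Nm": p.plateau_Nm, "true_baseline_Nm": p.baseline_Nm,
               "true_end_stim_Nm": end_val},
        **meta)


def _raised_cosine(t: np.ndarray, onset: float, duration: float) -> np.ndarray:
    """Unit-height bump confined to [onset, onset + duration]."""
    x = (t - onset) / duration
    bump = np.zeros_like(t)
    inside = (x >= 0) & (x <= 1)
    bump[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * x[inside]))
    return bump


def simulate_ecd_protocol(params: ECDProtocolParams):
    """Generate the full eccentric-contraction protocol.

    Returns ``(traces, scales)``: the ordered contraction traces (each carrying
    its protocol start time and index in ``extra``) and the ground-truth plateau
    scale factors ``a_k``. The lengthening transient is an additive
    raised-cosine bump confined to the rotation window; plateau torque is read
    before rotation onset, so its exact shape is immaterial downstream.
    """
    p = params
    scales = decrement_curve(p.n_contractions, p.r_inf, p.kappa)
    tp = p.tetanus
    stim_end = tp.t0_s + tp.stim_duration_s
    t = _time_grid(stim_end + tp.post_window_s, tp.sampling_hz)
    trace_duration = t[-1]
    rng = np.random.default_rng(p.seed)
    meta = {**_SUBJECT_DEFAULTS, **tp.subject}

    traces = []
    start = 0.0
    for k in range(p.n_contractions):
        y, _ = _tetanus_torque(t, tp, plateau_scale=scales[k])
        rot_onset = tp.t0_s + p.rotation_delay_s
        y += (p.transient_amplitude_frac * tp.plateau_Nm * scales[k]
              * _raised_cosine(t, rot_onset, p.rotation_duration_s))
        y += tp.baseline_Nm
        if tp.noise_sd_Nm > 0:
            y = y + rng.normal(0.0, tp.noise_sd_Nm, size=t.size)
        traces.append(ForceTrace(
            time_s=t, torque_Nm=y, trace_kind="eccentric",
            stim_onset_s=tp.t0_s, stim_end_s=stim_end, sampling_hz=tp.sampling_hz,
            extra={"protocol_index": k + 1, "protocol_start_s": start,
                   "rotation_onset_s": rot_onset,
                   "true_scale": float(scales[k]),
                   "true_plateau_Nm": tp.plateau_Nm * float(scales[k])},
            **meta))
        gap = p.inter_set_gap_s if (k + 1) % p.set_size == 0 else p.intra_gap_s
        start += trace_duration + gap
    return traces, scales


def _truncnorm_loc(target_mean: float, sd: float,
                   lo: float = 0.0, hi: float = 100.0) -> float:
    """Location of a [lo, hi]-truncated normal whose truncated mean is target_mean."""
    if sd == 0:
        return target_mean

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    lo_loc, hi_loc = target_mean - 5 * sd, target_mean + 5 * sd
    for _ in range(200):
        mid = 0.5 * (lo_loc + hi_loc)
        if trunc_mean(mid) < target_mean:
            lo_loc = mid
        else:
            hi_loc = mid
    return 0.5 * (lo_loc + hi_loc)


def simulate_cohort(spec: CohortSpec):
    """Draw per-subject true final decrements and generate their protocols.

    Returns ``(protocols, truth)``: a list of ``(traces, scales)`` per subject
    and a ground-truth DataFrame. Decrements are drawn from a normal truncated
    to [0, 100]%; by default the location is adjusted so the truncated mean
    equals ``decrement_mean_pct`` (the stated group mean is the mean of the
    generated decrements). The decrement maps to the curve via
    ``r_inf = 1 - decrement/100`` with ``kappa`` fixed by the spec.
    """
    s = spec
    rng = np.random.default_rng(s.seed)
    if s.decrement_sd_pct == 0:
        draws = np.full(s.n_subjects, s.decrement_mean_pct)
    else:
        loc = _truncnorm_loc(s.decrement_mean_pct, s.decrement_sd_pct) \
            if s.moment_match else s.decrement_mean_pct
        a = (0.0 - loc) / s.decrement_sd_pct
        b = (100.0 - loc) / s.decrement_sd_pct
        draws = stats.truncnorm.rvs(a, b, loc=loc, scale=s.decrement_sd_pct,
                                    size=s.n_subjects, random_state=rng)

    protocols = []
    rows = []
    for i, dec in enumerate(draws):
        subject_id = f"{s.genotype}-S{i:03d}"
        subject = dict(subject_id=subject_id, genotype=s.genotype,
                       age_months=s.age_months)
        sets = []
        for j in range(s.traces_per_subject):
            params = ECDProtocolParams(
                tetanus=TetanusParams(
                    plateau_Nm=s.plateau_Nm, stim_duration_s=0.7,
                    noise_sd_Nm=s.noise_sd_Nm, subject=subject),
                r_inf=1.0 - dec / 100.0, kappa=s.kappa,
                seed=int(rng.integers(0, 2**31 - 1)))
            sets.append(simulate_ecd_protocol(params))
        protocols.append(sets if s.traces_per_subject > 1 else sets[0])
        rows.append(dict(subject_id=subject_id, genotype=s.genotype,
                         age_months=s.age_months, true_decrement_pct=float(dec)))
    return protocols, pd.DataFrame(rows)


def replace_params(params, **changes):
    """Convenience dataclasses.replace re-export for parameter sweeps."""
    return replace(params, **changes)
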