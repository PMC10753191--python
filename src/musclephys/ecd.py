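"""Eccentric-contraction-decrement pipeline.

Each eccentric contraction is an isometric tetanus whose foot pedal is rotated
0.5 s into stimulation; the tetanic (plateau) torque is read just before the
rotation begins. For a protocol of 30 contractions the series is normalised to
the maximum plateau torque produced during the protocol and the decrement is
the percentage drop of the final contraction from that maximum:

    N_k = 100 * T_k / max_j T_j,    decrement = 100 - N_30.

The maximum is taken over accepted plateau torques (the isometric-phase
reading), never over raw traces, so the eccentric spike cannot inflate it.
Missing or rejected contractions leave gaps at their protocol positions; the
decrement refers to the last protocol position and is flagged if that position
was itself rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_core import ForceTrace, RunConfig, ValidationError
from .kinetics import baseline_correct


@dataclass
class ECDProtocolResult:
    plateau_torques_Nm: np.ndarray          # NaN at rejected/missing positions
    max_torque_Nm: float
    normalised_series_pct: np.ndarray
    final_remaining_pct: float
    final_decrement_pct: float
    max_abs_force_N: float
    n_detected: int
    final_position: int                      # protocol position the decrement refers to
    final_position_flagged: bool             # True if the last position was rejected
    qc_reasons: dict = field(default_factory=dict)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def plateau_torque(trace: ForceTrace, window_s: float = 0.010,
                   rotation_delay_s: float = 0.5,
                   baseline_window_s: float | None = 0.05) -> float:
    """Mean baseline-corrected torque over the ``window_s`` before rotation onset.

    Rotation begins ``rotation_delay_s`` after stimulus onset (or at the
    ``rotation_onset_s`` recorded in the trace metadata, when present).
    ``window_s = 0`` degenerates to a single-sample read at the last
    pre-rotation sample.
    """
    if baseline_window_s:
        trace = baseline_correct(trace, baseline_window_s)
    rot_onset = float(trace.extra.get(
        "rotation_onset_s", trace.stim_onset_s + rotation_delay_s))
    lo = rot_onset - window_s
    if lo < trace.stim_onset_s - 1e-12:
        raise ValidationError(
            f"plateau window [{lo:.4f}, {rot_onset:.4f}) extends before stimulus onset")
    t = trace.time_s
    if window_s == 0:
        idx = int(np.searchsorted(t, rot_onset, side="right")) - 1
        return float(trace.torque_Nm[idx])
    sel = (t >= lo - 1e-12) & (t < rot_onset - 1e-12)
    if not sel.any():
        raise ValidationError("plateau window contains no samples")
    return float(trace.torque_Nm[sel].mean())


def protocol_qc(traces: list[ForceTrace], config: RunConfig | None = None):
    """Per-contraction accept/reject for an ordered protocol.

    A contraction is rejected when its plateau is indistinguishable from noise
    (< k_snr x pre-stimulus noise sd: dislodged electrode), when adjacent
    samples jump implausibly (> f_jump x plateau discontinuity) or when the
    rise fails to settle (torque 10 ms before rotation is < 80% of the plateau
    read). The whole protocol is rejected when fewer than ``min_frac`` of the
    contractions are accepted.

    Returns ``(accepted, reasons, protocol_ok)``.
    """
    config = config or RunConfig()
    k_snr = config["ecd.qc_k_snr"]
    f_jump = config["ecd.qc_f_jump"]
    window = config["ecd.plateau_window_s"]
    rot_delay = config["ecd.rotation_delay_s"]
    accepted = []
    reasons = {}
    for trace in traces:
        why = []
        corrected = baseline_correct(trace, config["kinetics.baseline_window_s"])
        pre = corrected.torque_Nm[corrected.time_s < corrected.stim_onset_s - 1e-12]
        noise_sd = float(pre.std()) if pre.size >= 2 else 0.0
        try:
            plateau = plateau_torque(corrected, window_s=window,
                                     rotation_delay_s=rot_delay,
                                     baseline_window_s=None)
        except ValidationError:
            plateau = float("nan")
            why.append("plateau_window_error")
        if not math.isfinite(plateau) or plateau <= 0:
            why.append("no_plateau")
        elif noise_sd > 0 and plateau < k_snr * noise_sd:
            why.append("low_snr")
        if math.isfinite(plateau) and plateau > 0:
            rot_onset = float(corrected.extra.get(
                "rotation_onset_s", corrected.stim_onset_s + rot_delay))
            during = ((corrected.time_s >= corrected.stim_onset_s)
                      & (corrected.time_s < rot_onset))
            yy = corrected.torque_Nm[during]
            if yy.size >= 2 and float(np.abs(np.diff(yy)).max()) > f_jump * plateau:
                why.append("discontinuity")
            settle = corrected.time_s >= rot_onset - 0.010 - 1e-12
            settle &= corrected.time_s < rot_onset - 1e-12
            if yy.size and corrected.torque_Nm[settle].size:
                if float(corrected.torque_Nm[settle].min()) < 0.8 * plateau:
                    why.append("rise_failure")
        idx = int(trace.extra.get("protocol_index", len(accepted) + 1))
        accepted.append(not why)
        if why:
            reasons[idx] = why
    frac = sum(accepted) / len(accepted) if accepted else 0.0
    return accepted, reasons, frac >= config["ecd.qc_min_frac"]


def ecd_series(traces: list[ForceTrace], config: RunConfig | None = None,
               n_positions: int | None = None,
               apply_qc: bool = True) -> ECDProtocolResult:
    """Normalised plateau-torque series and final decrement for one protocol.

    ``traces`` are protocol-ordered eccentric contractions; each may carry a
    ``protocol_index`` (1-based) in its metadata, otherwise positions are taken
    from list order. Rejected contractions leave NaN gaps without shifting
    indices.
    """
    if not traces:
        raise ValidationError("no traces supplied")
    config = config or RunConfig()
    if apply_qc:
        accepted, reasons, _ = protocol_qc(traces, config)
    else:
        accepted, reasons = [True] * len(traces), {}

    positions = [int(tr.extra.get("protocol_index", i + 1))
                 for i, tr in enumerate(traces)]
    n_pos = n_positions or max(positions)
    plateaus = np.full(n_pos, np.nan)
    for trace, pos, ok in zip(traces, positions, accepted):
        if not ok:
            continue
        plateaus[pos - 1] = plateau_torque(
            trace,
            window_s=config["ecd.plateau_window_s"],
            rotation_delay_s=config["ecd.rotation_delay_s"],
            baseline_window_s=config["kinetics.baseline_window_s"])

    finite = plateaus[np.isfinite(plateaus)]
    if finite.size == 0:
        raise ValidationError("no accepted contractions")
    t_max = float(finite.max())
    if t_max <= 0:
        raise ValidationError("maximum plateau torque is non-positive")
    series = 100.0 * plateaus / t_max

    final_pos = n_pos
    flagged = not np.isfinite(series[-1])
    if flagged:
        final_pos = int(np.nonzero(np.isfinite(series))[0][-1]) + 1
    remaining = float(series[final_pos - 1])
    lever = traces[0].lever_arm_m
    return ECDProtocolResult(
        plateau_torques_Nm=plateaus,
        max_torque_Nm=t_max,
        normalised_series_pct=series,
        final_remaining_pct=remaining,
        final_decrement_pct=100.0 - remaining,
        max_abs_force_N=t_max / lever,
        n_detected=int(np.isfinite(plateaus).sum()),
        final_position=final_pos,
        final_position_flagged=flagged,
        qc_reasons=reasons,
    )


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares with a two-sided t-test on the slope (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need at least 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("x and y must be finite")
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValidationError("zero variance in x")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if ss_res == 0:
        p = 0.0
    else:
        se = math.sqrt(ss_res / (n - 2) / sxx)
        from scipy import stats
        t_stat = slope / se
        p = 2.0 * float(stats.t.sf(abs(t_stat), n - 2))
    return RegressionResult(slope=float(slope), intercept=intercept,
                            r_squared=float(min(max(r2, 0.0), 1.0)),
                            p_value=p, n=int(n))
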