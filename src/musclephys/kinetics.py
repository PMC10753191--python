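"""Per-trace isometric feature extraction.

For a twitch the contraction reference is the maximum baseline-corrected
torque and the reported metric is the time to reach 100% (peak time); for a
tetanus the reference is the torque at the end of stimulation and time to 95%
is reported instead, because real tetanic plateaus fluctuate and creep. Decile
time courses (10%..90%/100%) are measured from stimulus onset via linear
interpolation of the first upward crossing, so the electromechanical delay is
included in every contraction time. Relaxation times are measured from the
reference point (peak for twitch, end of stimulation for tetanus) to the first
downward crossing of reference*(1 - x/100); fractions the record never reaches
are reported as NaN and flagged, not raised.

Force normalisation follows the in vivo convention for dogs: absolute force
(N) = torque / lever arm length (m); relative force (N/kg) = absolute force /
bodyweight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import ForceTrace, RunConfig, ValidationError

TWITCH_FRACTIONS = tuple(np.round(np.arange(1, 11) * 0.1, 2))          # 0.1 .. 1.0
TETANUS_FRACTIONS = tuple(np.round(np.arange(1, 10) * 0.1, 2)) + (0.95,)
RELAX_FRACTIONS = tuple(np.round(np.arange(1, 10) * 0.1, 2)) + (0.95,)


@dataclass
class KineticsResult:
    """Peak/force/time-course features of one baseline-corrected trace."""

    trace_kind: str
    baseline_Nm: float
    peak_torque_Nm: float
    peak_time_s: float
    end_stim_torque_Nm: float | None
    reference_torque_Nm: float
    absolute_force_N: float
    relative_force_N_per_kg: float
    contraction_times_s: dict = field(default_factory=dict)
    relaxation_times_s: dict = field(default_factory=dict)
    relaxation_unreached: tuple = ()
    qc_status: str = "pass"
    qc_reasons: tuple = ()


def baseline_correct(trace: ForceTrace, window_s: float = 0.05) -> ForceTrace:
    """Subtract the mean torque over the pre-stimulus window of ``window_s``.

    The window must fit before stimulus onset and span at least 5 samples.
    The estimated baseline is recorded in ``trace.extra['baseline_Nm']``.
    """
    if window_s > trace.stim_onset_s - trace.time_s[0] + 1e-12:
        raise ValidationError(
            f"baseline window {window_s} s does not fit before stimulus onset "
            f"at {trace.stim_onset_s} s")
    sel = trace.time_s < trace.stim_onset_s - 1e-12
    sel &= trace.time_s >= trace.stim_onset_s - window_s - 1e-12
    if sel.sum() < 5:
        raise ValidationError("baseline window must span at least 5 samples")
    baseline = float(trace.torque_Nm[sel].mean())
    extra = dict(trace.extra)
    extra["baseline_Nm"] = baseline
    return trace.copy_with(torque_Nm=trace.torque_Nm - baseline, extra=extra)


def _first_upward_crossing(t: np.ndarray, y: np.ndarray, level: float,
                           start_idx: int = 0) -> float:
    """Time of the first upward crossing of ``level`` at/after ``start_idx``,
    linearly interpolated between samples. NaN if never crossed."""
    yy = y[start_idx:]
    tt = t[start_idx:]
    if yy[0] >= level:
        return float(tt[0])
    above = np.nonzero(yy >= level)[0]
    if above.size == 0:
        return float("nan")
    i = above[0]
    y0, y1 = yy[i - 1], yy[i]
    frac = (level - y0) / (y1 - y0) if y1 != y0 else 1.0
    return float(tt[i - 1] + frac * (tt[i] - tt[i - 1]))


def _first_downward_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    if y[0] <= level:
        return float(t[0])
    below = np.nonzero(y <= level)[0]
    if below.size == 0:
        return float("nan")
    i = below[0]
    y0, y1 = y[i - 1], y[i]
    frac = (y0 - level) / (y0 - y1) if y0 != y1 else 1.0
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _end_stim_value(trace: ForceTrace) -> float:
    """Torque at the end of stimulation (interpolated onto stim_end_s)."""
    return float(np.interp(trace.stim_end_s, trace.time_s, trace.torque_Nm))


def contraction_features(trace: ForceTrace) -> KineticsResult:
    """Decile contraction time course of a baseline-corrected trace.

    Times are measured from stimulus onset. Twitch: deciles 10%..100% of the
    peak (100% = peak time). Tetanus/eccentric: deciles 10%..90% plus the 95%
    proxy, referenced to the end-of-stimulation torque.
    """
    t, y = trace.time_s, trace.torque_Nm
    i_on = int(np.searchsorted(t, trace.stim_onset_s))
    peak_idx = i_on + int(np.argmax(y[i_on:]))
    peak = float(y[peak_idx])
    peak_time = float(t[peak_idx])
    is_twitch = trace.trace_kind == "twitch"
    end_stim = None if is_twitch else _end_stim_value(trace)
    reference = peak if is_twitch else end_stim
    result = KineticsResult(
        trace_kind=trace.trace_kind,
        baseline_Nm=float(trace.extra.get("baseline_Nm", 0.0)),
        peak_torque_Nm=peak, peak_time_s=peak_time,
        end_stim_torque_Nm=end_stim, reference_torque_Nm=float(reference),
        absolute_force_N=float(reference) / trace.lever_arm_m,
        relative_force_N_per_kg=float(reference) / trace.lever_arm_m / trace.bodyweight_kg,
    )
    if reference <= 0:
        result.qc_status = "reject"
        result.qc_reasons = ("non-positive reference torque",)
        return result

    fractions = TWITCH_FRACTIONS if is_twitch else TETANUS_FRACTIONS
    times = {}
    for f in fractions:
        if is_twitch and f == 1.0:
            times[f] = peak_time - trace.stim_onset_s
            continue
        tc = _first_upward_crossing(t, y, f * reference, start_idx=i_on)
        times[f] = tc - trace.stim_onset_s if np.isfinite(tc) else float("nan")
    result.contraction_times_s = times
    return result


def relaxation_features(trace: ForceTrace,
                        result: KineticsResult | None = None) -> KineticsResult:
    """Decile + 95% relaxation times of a baseline-corrected trace.

    x% relaxation time = first time after the reference point at which torque
    falls to reference*(1 - x/100); entries never reached within the record are
    NaN and listed in ``relaxation_unreached``.
    """
    if result is None:
        result = contraction_features(trace)
    if result.qc_status == "reject":
        return result
    t, y = trace.time_s, trace.torque_Nm
    if trace.trace_kind == "twitch":
        ref_time = result.peak_time_s
    else:
        ref_time = trace.stim_end_s
    reference = result.reference_torque_Nm
    i0 = int(np.searchsorted(t, ref_time))
    times = {}
    unreached = []
    for f in RELAX_FRACTIONS:
        level = reference * (1.0 - f)
        tc = _first_downward_crossing(t[i0:], y[i0:], level)
        if np.isfinite(tc):
            times[f] = tc - ref_time
        else:
            times[f] = float("nan")
            unreached.append(f)
    result.relaxation_times_s = times
    result.relaxation_unreached = tuple(unreached)
    return result


def analyze_trace(trace: ForceTrace, config: RunConfig | None = None) -> KineticsResult:
    """Baseline-correct, QC and extract all kinetics features for one trace."""
    config = config or RunConfig()
    corrected = baseline_correct(trace, config["kinetics.baseline_window_s"])
    status, reasons = qc_trace(corrected, config)
    result = relaxation_features(corrected)
    if status == "reject":
        result.qc_status = "reject"
        result.qc_reasons = tuple(reasons) + tuple(result.qc_reasons)
    return result


def twitch_tetanus_ratio(twitch: KineticsResult, tetanus: KineticsResult) -> float:
    """Twitch peak torque as a fraction of tetanic end-of-stimulation torque."""
    if twitch.qc_status != "pass" or tetanus.qc_status != "pass":
        raise ValidationError("both traces must pass QC")
    if tetanus.reference_torque_Nm <= 0:
        raise ValidationError("tetanic torque must be positive")
    return twitch.peak_torque_Nm / tetanus.reference_torque_Nm


def qc_trace(trace: ForceTrace, rules: RunConfig | None = None):
    """Rule-based trace QC; returns ``(status, reasons)`` and never raises.

    Rules (all thresholds are config defaults, logged per run):
      (a) low SNR: peak < k_snr x pre-stimulus noise sd;
      (b) negative deflection: min torque < -f_neg x peak (antagonist
          co-stimulation produces large opposing torque);
      (c) multi-peaked twitch: > m_peaks local maxima above 50% of peak;
      (d) plateau collapse: during tetanic stimulation the torque falls more
          than f_drop x plateau below the running maximum.
    """
    rules = rules or RunConfig()
    t, y = trace.time_s, trace.torque_Nm
    reasons = []
    pre = y[t < trace.stim_onset_s - 1e-12]
    noise_sd = float(pre.std()) if pre.size >= 2 else 0.0
    i_on = int(np.searchsorted(t, trace.stim_onset_s))
    peak = float(np.max(y[i_on:]))

    if noise_sd > 0 and peak < rules["kinetics.qc_k_snr"] * noise_sd:
        reasons.append("low_snr")
    if peak > 0 and float(np.min(y)) < -rules["kinetics.qc_f_neg"] * peak:
        reasons.append("negative_deflection")
    if trace.trace_kind == "twitch" and peak > 0:
        from scipy.signal import find_peaks
        # prominence keeps noise jitter near the peak from counting as peaks
        peaks, _ = find_peaks(y[i_on:], height=0.5 * peak,
                              prominence=rules["kinetics.qc_peak_prominence_frac"] * peak)
        if peaks.size > rules["kinetics.qc_m_peaks"]:
            reasons.append("multi_peaked")
    # (d) applies to isometric tetani only: eccentric traces legitimately drop
    # back from the lengthening transient and get their own protocol-level QC
    if trace.trace_kind == "tetanus" and peak > 0:
        during = (t >= trace.stim_onset_s) & (t <= trace.stim_end_s)
        yy = y[during]
        if yy.size:
            drop = np.maximum.accumulate(yy) - yy
            if float(drop.max()) > rules["kinetics.qc_f_drop"] * peak:
                reasons.append("plateau_collapse")
    status = "reject" if reasons else "pass"
    return status, reasons
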