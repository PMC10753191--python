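"""Group statistics and repeated-measures sample-size machinery.

Group comparisons use two-tailed unpaired Welch t-tests with step-down
Holm-Sidak adjustment. Sample sizes for detecting a fractional treatment
improvement use a two-group x T-timepoint repeated-measures design with
compound-symmetry covariance (within-subject correlation rho): the group main
effect reduces to a two-sample comparison of subject means over time, whose
variance is

    var(subject mean) = sigma^2 * (1 + (T - 1) * rho) / T,

tested by a noncentral F with (1, 2n - 2) degrees of freedom and noncentrality
lambda = n * delta^2 / (2 * var). The tested effect is the treatment-induced
shift of the affected group towards wild-type levels,

    delta = f * (mu_WT - mu_affected),   f in (0, 1],

i.e. a trial comparing treated versus untreated affected animals. The pooled
sd is sqrt((sd_affected^2 + sd_WT^2) / 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_core import ValidationError


def welch_t(a, b):
    """Two-tailed unpaired t-test with Welch df correction -> (t, df, p).

    Degenerate groups with zero variance in both and equal means return
    t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, \
            float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def holm_sidak(pvals) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values, returned in input order.

    Sorted ascending, adj_(i) = 1 - (1 - p_(i))^(m - i + 1), made monotone
    non-decreasing by a running maximum.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class PowerSpec:
    """Endpoint summary statistics and design for an improvement-detection trial."""

    mu_affected: float
    mu_wildtype: float
    sd_affected: float
    sd_wildtype: float
    improvement_fraction: float = 0.25
    n_timepoints: int = 6
    rho: float = 0.7
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self):
        if self.sd_affected < 0 or self.sd_wildtype < 0:
            raise ValidationError("sds must be non-negative")
        if not 0.0 < self.improvement_fraction <= 1.0:
            raise ValidationError("improvement_fraction must lie in (0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError("rho must lie in [0, 1)")
        if self.n_timepoints < 1:
            raise ValidationError("need at least one timepoint")

    @property
    def effect(self) -> float:
        """Treatment shift: mu_treated - mu_affected = f * (mu_WT - mu_affected)."""
        return self.improvement_fraction * (self.mu_wildtype - self.mu_affected)

    @property
    def pooled_sd(self) -> float:
        return math.sqrt((self.sd_affected ** 2 + self.sd_wildtype ** 2) / 2.0)

    @property
    def subject_mean_var(self) -> float:
        t = self.n_timepoints
        return self.pooled_sd ** 2 * (1.0 + (t - 1) * self.rho) / t


@dataclass
class SampleSizeResult:
    n_per_group: int
    achieved_power: float
    method: str = ("noncentral-F, 2-group x T-timepoint repeated measures, "
                   "compound symmetry, group main effect")


def power_at_n(spec: PowerSpec, n: int) -> float:
    """Power of the group main effect test with ``n`` subjects per group."""
    if n < 2:
        raise ValidationError("n must be at least 2 per group")
    var = spec.subject_mean_var
    if var == 0:
        return 1.0 if spec.effect != 0 else spec.alpha
    lam = n * spec.effect ** 2 / (2.0 * var)
    df2 = 2 * n - 2
    fcrit = stats.f.ppf(1.0 - spec.alpha, 1, df2)
    return float(stats.ncf.sf(fcrit, 1, df2, lam))


def sample_size(spec: PowerSpec, n_max: int = 10_000) -> SampleSizeResult:
    """Smallest integer n >= 2 per group achieving ``target_power``."""
    if spec.effect == 0:
        raise ValidationError("undetectable: affected and wild-type means are equal")
    for n in range(2, n_max + 1):
        pw = power_at_n(spec, n)
        if pw >= spec.target_power:
            return SampleSizeResult(n_per_group=n, achieved_power=pw)
    raise ValidationError(f"target power not reached by n = {n_max}")


def simulate_power(spec: PowerSpec, n: int, n_reps: int = 10_000,
                   seed: int = 0) -> float:
    """Monte-Carlo power of the same design: simulate subject means over time
    under compound symmetry and apply the F(1, 2n-2) group test."""
    rng = np.random.default_rng(seed)
    sd_mean = math.sqrt(spec.subject_mean_var)
    treated = rng.normal(spec.mu_affected + spec.effect, sd_mean, size=(n_reps, n))
    control = rng.normal(spec.mu_affected, sd_mean, size=(n_reps, n))
    # two-sample pooled-variance t is the sqrt of the F(1, 2n-2) group effect
    diff = treated.mean(axis=1) - control.mean(axis=1)
    sp2 = (treated.var(axis=1, ddof=1) + control.var(axis=1, ddof=1)) / 2.0
    tstat = diff / np.sqrt(sp2 * 2.0 / n)
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, 2 * n - 2)
    return float(np.mean(np.abs(tstat) > tcrit))
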