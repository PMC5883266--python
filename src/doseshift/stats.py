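"""Paired nonparametric statistics and bootstrap sample-size estimation.

Dosimetric data from a plan comparison are intrinsically paired (same CT,
same beams, only the dose engine changes), so differences are analyzed with
the Wilcoxon signed-rank test.  The exact null distribution is computed by
enumerating sign assignments (via a dynamic-programming convolution over the
tied-rank values), which stays reliable at the very small sample sizes
typical of beam-by-beam MU comparisons.  The bootstrap procedure estimates
the minimal number of paired cases needed to see significance: for each
sub-sample size n it draws resamples with replacement, computes the Wilcoxon
p-value on each, and records the mean p across resamples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError, ValidationError

#: largest n for which 'auto' mode uses the exact enumeration distribution
EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedSample:
    """Paired reference/test measurements (e.g. per-beam MUs from two plans)."""

    reference: np.ndarray
    test: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        tst = np.asarray(self.test, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "test", tst)
        if ref.ndim != 1 or tst.ndim != 1 or ref.size != tst.size:
            raise ValidationError("reference and test must be 1-D and the same length")
        if ref.size < 2:
            raise ValidationError("paired sample needs at least 2 pairs")

    @property
    def m(self) -> int:
        return int(self.reference.size)

    @property
    def differences(self) -> np.ndarray:
        return self.test - self.reference


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+: sum of ranks of positive differences
    pvalue: float  # two-sided
    n: int  # nonzero differences used
    method: Literal["exact", "approx"]


@dataclass(frozen=True)
class BootstrapCurve:
    """Mean Wilcoxon p-value as a function of resample size n."""

    n_values: np.ndarray
    mean_p: np.ndarray
    B: int
    seed: int | None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_values", np.asarray(self.n_values, dtype=int))
        object.__setattr__(self, "mean_p", np.asarray(self.mean_p, dtype=float))
        if self.n_values.size != self.mean_p.size:
            raise ValidationError("n_values and mean_p must have equal length")
        if np.any((self.mean_p < 0) | (self.mean_p > 1)):
            raise ValidationError("mean p-values must lie in [0, 1]")


def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = sps.rankdata(np.abs(d))  # average ranks for ties
    return float(ranks[d > 0].sum()), ranks


def _exact_counts(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Count sign assignments per doubled W+ value by DP convolution."""
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        counts[r:] = counts[r:] + counts[:-r]
    return counts


_dist_cache: dict[tuple[int, ...], np.ndarray] = {}


def _exact_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
    counts = _dist_cache.get(doubled)
    if counts is None:
        counts = _exact_counts(doubled)
        if len(_dist_cache) < 4096:
            _dist_cache[doubled] = counts
    w2 = int(round(2 * w_plus))
    denom = 2.0 ** len(ranks)
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def _approx_two_sided_p(w_plus: float, d: np.ndarray) -> float:
    n = d.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def wilcoxon_signed_rank(
    sample: PairedSample, mode: Literal["exact", "approx", "auto"] = "auto"
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on the paired differences.

    Zero differences are discarded before ranking; ties in the absolute
    differences receive average ranks.  ``exact`` enumerates the full sign
    distribution (default up to n = 25 in ``auto`` mode); ``approx`` uses the
    normal approximation with tie-corrected variance.
    """
    return wilcoxon_from_differences(sample.differences, mode=mode)


def wilcoxon_from_differences(
    differences: Sequence[float], mode: Literal["exact", "approx", "auto"] = "auto"
) -> WilcoxonResult:
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise DomainError("all paired differences are zero; no test possible")
    w_plus, ranks = _signed_rank_stat(d)
    use_exact = mode == "exact" or (mode == "auto" and d.size <= EXACT_N_MAX)
    if use_exact:
        p = _exact_two_sided_p(w_plus, ranks)
        method: Literal["exact", "approx"] = "exact"
    else:
        p = _approx_two_sided_p(w_plus, d)
        method = "approx"
    return WilcoxonResult(statistic=w_plus, pvalue=p, n=int(d.size), method=method)


def spearman_rho(sample: PairedSample) -> float:
    """Spearman rank correlation between the paired sequences."""
    if sample.m < 3:
        raise DomainError("Spearman correlation needs at least 3 pairs")
    if np.all(sample.reference == sample.reference[0]) or np.all(
        sample.test == sample.test[0]
    ):
        raise DomainError("Spearman correlation is undefined for a constant sequence")
    rho = sps.spearmanr(sample.reference, sample.test).statistic
    return float(rho)


def bootstrap_pcurve(
    sample: PairedSample,
    B: int = 1000,
    n_min: int = 2,
    seed: int | None = None,
    alpha: float = 0.05,
    aggregate: Literal["mean", "median"] = "mean",
) -> BootstrapCurve:
    """Bootstrap p-value curve: aggregate Wilcoxon p over B resamples per n.

    For each n from ``n_min`` to the sample size m (inclusive), draws B
    resamples of size n with replacement from the paired differences and
    computes the two-sided Wilcoxon p on each; resamples whose differences
    are all zero contribute p = 1 (no detectable difference).  Deterministic
    for a given ``seed``.
    """
    if B <= 0:
        raise DomainError("resample count B must be positive")
    if n_min < 2:
        raise DomainError("n_min must be at least 2")
    if sample.m < n_min:
        raise DomainError("sample size m must be at least n_min")
    d = sample.differences
    rng = np.random.default_rng(seed)
    agg = np.mean if aggregate == "mean" else np.median
    p_cache: dict[tuple[float, ...], float] = {}
    n_values = np.arange(n_min, sample.m + 1)
    out = np.empty(n_values.size)
    for j, n in enumerate(n_values):
        idx = rng.integers(0, sample.m, size=(B, int(n)))
        ps = np.empty(B)
        for b in range(B):
            sub = d[idx[b]]
            key = tuple(np.sort(sub))
            p = p_cache.get(key)
            if p is None:
                if np.all(sub == 0):
                    p = 1.0
                else:
                    p = wilcoxon_from_differences(sub).pvalue
                p_cache[key] = p
            ps[b] = p
        out[j] = agg(ps)
    return BootstrapCurve(n_values=n_values, mean_p=out, B=B, seed=seed, alpha=alpha)


def minimal_significant_n(curve: BootstrapCurve) -> int | None:
    """Smallest resample size whose aggregate p falls below alpha, or None."""
    below = np.nonzero(curve.mean_p < curve.alpha)[0]
    if below.size == 0:
        return None
    return int(curve.n_values[below[0]])
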