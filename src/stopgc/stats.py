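"""Inferential layer: correlations, slopes, logistic fits, binning, matching.

All procedures are thin, explicit wrappers over scipy/statsmodels primitives
so that every reported quantity (estimate, SE, p, n) has a single obvious
provenance:

* Spearman rank correlations (two-sided, average ranks for ties) for
  monotone usage-vs-GC trends;
* ordinary least squares for usage-vs-GC slopes, with a normal Z test for
  slope differences, z = (b1 - b2) / sqrt(se1^2 + se2^2);
* per-species logistic regressions of per-gene stop presence/absence on a
  per-gene GC fraction (Wald p on the GC coefficient);
* exact binomial exceedance tests for sign counts across species;
* equal-count GC binning (deciles by default) and nearest-neighbour GC
  matching between panels.

No multiple-testing correction is applied by default; a Benjamini–Hochberg
helper is provided for callers who want one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .site_usage import STOP_CODONS, canonical_usage

__all__ = [
    "CorrelationResult",
    "LinearFit",
    "SlopeComparison",
    "LogisticFit",
    "SignCounts",
    "BinnedUsage",
    "GCMatchPairing",
    "spearman",
    "fit_linear",
    "compare_slopes",
    "logistic_stop_vs_gc",
    "count_coefficient_signs",
    "binomial_exceedance",
    "bin_by_gc",
    "gc_match",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of frequency on GC; slope units follow the x-axis supplied."""

    slope: float
    intercept: float
    slope_se: float
    n: int

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Slope confidence interval from the t distribution (n-2 df)."""
        t = scipy.stats.t.ppf(0.5 + level / 2, self.n - 2)
        return (self.slope - t * self.slope_se, self.slope + t * self.slope_se)


@dataclass(frozen=True)
class SlopeComparison:
    fit_a: LinearFit
    fit_b: LinearFit
    z: float
    p_value: float


@dataclass(frozen=True)
class LogisticFit:
    codon: str
    coefficient: float | None
    p_value: float | None
    converged: bool
    n_genes: int
    coefficient_se: float | None = None


@dataclass(frozen=True)
class SignCounts:
    n_converged: int
    n_excluded: int
    negative: int
    negative_significant: int
    positive: int
    positive_significant: int


@dataclass
class BinnedUsage:
    """Equal-count GC bins with per-bin canonical stop frequencies."""

    n_bins: int
    table: pd.DataFrame  # columns: bin, mean_gc, n_genes, f_TAA, f_TGA, f_TAG


@dataclass
class GCMatchPairing:
    pairs: list[tuple[str, str, float]]  # (query, matched candidate, |dGC|)

    @property
    def matched_candidates(self) -> list[str]:
        return [c for _, c, _ in self.pairs]

    @property
    def mean_abs_delta(self) -> float:
        return float(np.mean([d for _, _, d in self.pairs]))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = scipy.stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(x))


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares of y on x; slope SE from residual variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    res = scipy.stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        n=len(x),
    )


def compare_slopes(a: LinearFit, b: LinearFit) -> SlopeComparison:
    """Z test for a slope difference: (b_a - b_b) / sqrt(se_a^2 + se_b^2)."""
    pooled = float(np.hypot(a.slope_se, b.slope_se))
    if pooled == 0:
        raise ValueError("both slope standard errors are zero")
    z = (a.slope - b.slope) / pooled
    p = 2 * scipy.stats.norm.sf(abs(z))
    return SlopeComparison(fit_a=a, fit_b=b, z=float(z), p_value=float(p))


def logistic_stop_vs_gc(
    records: Iterable,
    codon: str,
    predictor: str = "utr3_gc",
    min_genes: int = 50,
) -> LogisticFit:
    """Logistic regression of per-gene stop presence on a GC fraction.

    The outcome is 1 when the gene's canonical stop equals ``codon``, else 0;
    the predictor is the gene's ``utr3_gc`` or ``gc3`` (a fraction in [0,1]).
    Returns ``converged=False`` (no coefficient) on one-class outcomes,
    too-few genes, perfect separation, or optimiser failure.
    """
    if codon not in STOP_CODONS:
        raise ValueError(f"unknown stop codon {codon!r}")
    xs, ys = [], []
    for rec in records:
        val = getattr(rec, predictor)
        if val is None:
            continue
        xs.append(val)
        ys.append(1.0 if rec.stop_codon == codon else 0.0)
    n = len(xs)
    if n < min_genes or len(set(ys)) < 2 or np.ptp(xs) == 0:
        return LogisticFit(codon, None, None, converged=False, n_genes=n)
    X = sm.add_constant(np.asarray(xs, dtype=float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(np.asarray(ys), X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False):
            return LogisticFit(codon, None, None, converged=False, n_genes=n)
        coef = float(fit.params[1])
        # near-separation blows the coefficient/SE up; report honestly as
        # non-converged rather than as an astronomically uncertain estimate
        if not np.isfinite(coef) or not np.isfinite(fit.bse[1]) or abs(coef) > 1e3:
            return LogisticFit(codon, None, None, converged=False, n_genes=n)
        return LogisticFit(
            codon,
            coef,
            float(fit.pvalues[1]),
            converged=True,
            n_genes=n,
            coefficient_se=float(fit.bse[1]),
        )
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticFit(codon, None, None, converged=False, n_genes=n)


def count_coefficient_signs(
    fits: Iterable[LogisticFit], alpha: float = 0.05
) -> dict[str, SignCounts]:
    """Sign / significance counts of logistic coefficients, per codon.

    Non-converged fits are excluded from all sign counts and tallied in
    ``n_excluded``.
    """
    acc: dict[str, dict[str, int]] = {}
    for fit in fits:
        d = acc.setdefault(
            fit.codon,
            dict(conv=0, excl=0, neg=0, neg_sig=0, pos=0, pos_sig=0),
        )
        if not fit.converged or fit.coefficient is None:
            d["excl"] += 1
            continue
        d["conv"] += 1
        if fit.coefficient < 0:
            d["neg"] += 1
            if fit.p_value is not None and fit.p_value < alpha:
                d["neg_sig"] += 1
        elif fit.coefficient > 0:
            d["pos"] += 1
            if fit.p_value is not None and fit.p_value < alpha:
                d["pos_sig"] += 1
    return {
        codon: SignCounts(
            n_converged=d["conv"],
            n_excluded=d["excl"],
            negative=d["neg"],
            negative_significant=d["neg_sig"],
            positive=d["pos"],
            positive_significant=d["pos_sig"],
        )
        for codon, d in acc.items()
    }


def binomial_exceedance(
    k: int, n: int, p0: float = 0.5, alternative: str = "greater"
) -> float:
    """Exact binomial tail probability of observing k successes in n trials."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    alt = {"greater": "greater", "two_sided": "two-sided"}[alternative]
    return float(scipy.stats.binomtest(k, n, p0, alternative=alt).pvalue)


def bin_by_gc(
    records: Sequence, n_bins: int = 10, predictor: str = "utr3_gc"
) -> BinnedUsage:
    """Sort genes by GC and cut into equal-count bins (deciles by default).

    When the gene count is not divisible by ``n_bins`` the remainder genes go
    one-per-bin to the lowest-GC bins, so bin sizes differ by at most one.
    Each bin reports its mean predictor and pooled canonical stop frequencies.
    """
    recs = [r for r in records if getattr(r, predictor) is not None]
    if len(recs) < n_bins:
        raise ValueError(
            f"need at least {n_bins} genes with {predictor}, got {len(recs)}"
        )
    recs.sort(key=lambda r: getattr(r, predictor))
    base, rem = divmod(len(recs), n_bins)
    rows = []
    pos = 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        chunk = recs[pos : pos + size]
        pos += size
        usage = canonical_usage(chunk)
        freqs = usage.freqs
        rows.append(
            {
                "bin": b,
                "mean_gc": float(
                    np.mean([getattr(r, predictor) for r in chunk])
                ),
                "n_genes": size,
                **{f"f_{c}": freqs.get(c, 0.0) for c in STOP_CODONS},
            }
        )
    return BinnedUsage(n_bins=n_bins, table=pd.DataFrame(rows))


def gc_match(
    queries: Mapping[str, float], candidates: Mapping[str, float]
) -> GCMatchPairing:
    """Nearest-neighbour GC matching with replacement.

    Each query species is paired with the candidate minimising \\|dGC\\|
    (candidates may be reused, so the matched set has exactly the query
    panel's size); ties break by lexicographic candidate id.
    """
    if not queries or not candidates:
        raise ValueError("both panels must be non-empty")
    cand = sorted(candidates.items())
    pairs = []
    for q_id, q_gc in sorted(queries.items()):
        best_id, best_gc = min(cand, key=lambda kv: (abs(kv[1] - q_gc), kv[0]))
        pairs.append((q_id, best_id, abs(best_gc - q_gc)))
    return GCMatchPairing(pairs=pairs)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; off by default)."""
    return multipletests(p_values, method="fdr_bh")[1]
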