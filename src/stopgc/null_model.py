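"""Dinucleotide-controlled Markov null model for stop-codon frequencies.

The null asks: given only the mono- and dinucleotide composition of a
genome's coding sequence, how often would each stop trinucleotide arise by
chance?  A first-order Markov chain is fitted to the CDS set — the initial
distribution from pooled mononucleotide frequencies, the transition matrix
from pooled adjacent-pair (dinucleotide) frequencies — and three-nucleotide
sequences are generated from it (by default 10,000 Monte-Carlo draws;
an exact analytic mode computes P(xyz) = p1(x) T(x,y) T(y,z) in closed form).

Observed canonical stop usage is compared to the null via the deviation
score ``(observed - expected) / expected`` per codon, with both usages
expressed relative to the three stop trinucleotides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

import numpy as np

from .site_usage import STOP_CODONS, SiteClass, StopUsageTable

__all__ = [
    "NUCLEOTIDES",
    "MarkovNullModel",
    "EnrichmentResult",
    "fit_markov",
    "analytic_trinucleotide_probs",
    "simulate_trinucleotides",
    "enrichment",
]

NUCLEOTIDES = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
_TRINUCLEOTIDES = ["".join(t) for t in product(NUCLEOTIDES, repeat=3)]

# byte-code lookup: A/C/G/T -> 0..3, anything else (N) -> 4
_CODE = np.full(256, 4, dtype=np.int8)
for _c, _i in _NUC_INDEX.items():
    _CODE[ord(_c)] = _i


@dataclass
class MarkovNullModel:
    """First-order Markov chain over A/C/G/T fitted from coding sequence.

    ``p1`` is the initial (mononucleotide) distribution; ``T[x][y]`` the
    conditional probability of ``y`` following ``x`` (dinucleotide resolution).
    """

    p1: dict[str, float]
    T: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if abs(sum(self.p1.values()) - 1.0) > 1e-9:
            raise ValueError("initial distribution p1 must sum to 1")
        for x, row in self.T.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"transition row T[{x}] must sum to 1")

    def p1_array(self) -> np.ndarray:
        return np.array([self.p1[c] for c in NUCLEOTIDES])

    def t_matrix(self) -> np.ndarray:
        return np.array(
            [[self.T[x][y] for y in NUCLEOTIDES] for x in NUCLEOTIDES]
        )


@dataclass
class EnrichmentResult:
    """Observed vs null-expected stop usage and per-codon deviation scores.

    ``expected`` is relative among the three stops (matching ``observed``);
    ``expected_absolute`` keeps the raw per-trinucleotide null probabilities
    for transparency.  ``deviation[c] = (observed[c] - expected[c]) /
    expected[c]``; ``most_enriched`` is the argmax deviation (ties broken in
    TAA, TGA, TAG order).
    """

    species_id: str
    observed: dict[str, float]
    expected: dict[str, float]
    deviation: dict[str, float]
    expected_absolute: dict[str, float]
    most_enriched: str
    n_sims: int
    seed: int | None


def fit_markov(cds_seqs: Iterable[str]) -> MarkovNullModel:
    """Fit the null from a CDS set (pooled counts; pairs never span sequences).

    Positions involving ``N`` are skipped: an N contributes to no
    mononucleotide count and a dinucleotide spanning an N is not counted.
    A nucleotide with zero outgoing pairs gets a uniform transition row with
    a warning.
    """
    mono = np.zeros(4, dtype=np.int64)
    pairs = np.zeros((4, 4), dtype=np.int64)
    total_len = 0
    for seq in cds_seqs:
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        total_len += len(codes)
        valid = codes < 4
        mono += np.bincount(codes[valid], minlength=4)
        if len(codes) >= 2:
            a, b = codes[:-1], codes[1:]
            ok = (a < 4) & (b < 4)
            np.add.at(pairs, (a[ok], b[ok]), 1)
    if total_len < 2 or mono.sum() == 0:
        raise ValueError("need at least 2 usable nucleotides to fit the null")

    p1 = mono / mono.sum()
    T = np.empty((4, 4))
    for i in range(4):
        row_sum = pairs[i].sum()
        if row_sum == 0:
            warnings.warn(
                f"nucleotide {NUCLEOTIDES[i]} has no outgoing dinucleotides; "
                "using a uniform transition row",
                stacklevel=2,
            )
            T[i] = 0.25
        else:
            T[i] = pairs[i] / row_sum
    return MarkovNullModel(
        p1={c: float(p1[i]) for i, c in enumerate(NUCLEOTIDES)},
        T={
            x: {y: float(T[i, j]) for j, y in enumerate(NUCLEOTIDES)}
            for i, x in enumerate(NUCLEOTIDES)
        },
    )


def analytic_trinucleotide_probs(model: MarkovNullModel) -> dict[str, float]:
    """Exact null probability of every trinucleotide: p1(x) T(x,y) T(y,z)."""
    p1 = model.p1_array()
    T = model.t_matrix()
    probs = {}
    for tri in _TRINUCLEOTIDES:
        x, y, z = (_NUC_INDEX[c] for c in tri)
        probs[tri] = float(p1[x] * T[x, y] * T[y, z])
    return probs


def simulate_trinucleotides(
    model: MarkovNullModel, n_sims: int, seed: int
) -> dict[str, int]:
    """Draw ``n_sims`` independent 3-nt sequences from the chain (seeded).

    Returns counts per trinucleotide summing to ``n_sims``; identical seeds
    give identical counts.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    p1 = model.p1_array()
    cumT = np.cumsum(model.t_matrix(), axis=1)
    cumT[:, -1] = 1.0  # guard rounding

    first = rng.choice(4, size=n_sims, p=p1)
    second = (rng.random(n_sims)[:, None] > cumT[first]).sum(axis=1)
    third = (rng.random(n_sims)[:, None] > cumT[second]).sum(axis=1)
    idx = first * 16 + second * 4 + third
    counts = np.bincount(idx, minlength=64)
    return {tri: int(counts[i]) for i, tri in enumerate(_TRINUCLEOTIDES)}


def _relative_stop_freqs(tri_weights: Mapping[str, float]) -> dict[str, float]:
    tot = sum(tri_weights[c] for c in STOP_CODONS)
    if tot <= 0:
        raise ValueError(
            "all three stop trinucleotides have zero null frequency"
        )
    return {c: tri_weights[c] / tot for c in STOP_CODONS}


def enrichment(
    observed_usage: StopUsageTable,
    model: MarkovNullModel,
    n_sims: int = 10_000,
    seed: int = 0,
    mode: str = "simulated",
) -> EnrichmentResult:
    """Deviation of canonical stop usage from the dinucleotide null.

    ``mode="simulated"`` derives expected relative stop frequencies from
    seeded Monte-Carlo draws (the default study procedure); ``"analytic"``
    uses the exact chain probabilities and serves as the oracle.
    """
    if observed_usage.site_class is not SiteClass.CANONICAL:
        raise ValueError("enrichment expects canonical-site usage")
    if observed_usage.is_empty:
        raise ValueError("observed usage table is empty")

    tri_abs = analytic_trinucleotide_probs(model)
    if mode == "analytic":
        expected = _relative_stop_freqs(tri_abs)
        used_sims, used_seed = 0, None
    elif mode == "simulated":
        counts = simulate_trinucleotides(model, n_sims, seed)
        expected = _relative_stop_freqs({c: float(counts[c]) for c in STOP_CODONS})
        used_sims, used_seed = n_sims, seed
    else:
        raise ValueError(f"unknown mode {mode!r}")

    observed = observed_usage.freqs
    deviation = {
        c: (observed[c] - expected[c]) / expected[c]
        for c in STOP_CODONS
        if expected[c] > 0
    }
    most = max(STOP_CODONS, key=lambda c: deviation.get(c, float("-inf")))
    return EnrichmentResult(
        species_id=observed_usage.species_id,
        observed=observed,
        expected=expected,
        deviation=deviation,
        expected_absolute={c: tri_abs[c] for c in STOP_CODONS},
        most_enriched=most,
        n_sims=used_sims,
        seed=used_seed,
    )
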