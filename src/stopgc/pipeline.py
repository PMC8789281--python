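"""End-to-end analyses over a panel directory.

Five analyses mirror the comparative study design:

1. **between-species** — stop usage at three site classes (canonical stop,
   any-frame 3'UTR, in-frame post-ASC) against mean 3'UTR GC, with Spearman
   correlations, OLS slopes (per GC percentage point) and a TGA-vs-TAG
   slope-difference Z test per site class;
2. **intragenomic** — per-species logistic regressions of per-gene stop
   presence on per-gene 3'UTR GC (or GC3), with sign/significance counts
   across species and exact binomial exceedance tests;
3. **binned** — single-genome decile analysis: genes split into equal-count
   GC bins, per-bin usage, Spearman over bins and slope comparison;
4. **GC-matched** — nearest-neighbour GC matching of a query panel (e.g.
   archaea) onto a candidate panel (e.g. bacteria) and cross-group
   comparison of the TAG slope;
5. **enrichment** — per-species deviation of canonical stop usage from the
   genome's own dinucleotide-controlled null, the fraction of species where
   TAA is the most enriched stop, and a binomial test against 1/3.

Every run records its configuration; a fixed seed reproduces every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import genome_io, null_model, site_usage, stats
from .genome_io import GeneRecord, SpeciesMeta
from .site_usage import STOP_CODONS, SiteClass

__all__ = [
    "RunConfig",
    "load_panel",
    "species_usage_summary",
    "run_between_species",
    "run_intragenomic",
    "run_binned",
    "run_gc_matched",
    "run_enrichment",
    "run_all",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    utr_len: int = 30
    min_intergenic: Optional[int] = None
    n_bins: int = 10
    n_sims: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    predictor: str = "utr3_gc"
    min_genes_logistic: int = 50
    enrichment_mode: str = "simulated"


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_panel(
    panel_dir: str | Path, config: RunConfig = RunConfig()
) -> tuple[list[SpeciesMeta], dict[str, list[GeneRecord]]]:
    """Load a panel directory (per-species FASTA+GFF3 plus metadata.tsv)."""
    panel_dir = Path(panel_dir)
    metas = genome_io.read_species_metadata(panel_dir / "metadata.tsv")
    records: dict[str, list[GeneRecord]] = {}
    for meta in metas:
        fasta = panel_dir / f"{meta.species_id}.fa"
        gff = panel_dir / f"{meta.species_id}.gff3"
        assembly = genome_io.read_fasta(fasta, species_id=meta.species_id)
        annotations = genome_io.read_annotations(gff)
        records[meta.species_id] = genome_io.extract_gene_records(
            assembly,
            annotations,
            utr_len=config.utr_len,
            min_intergenic=config.min_intergenic,
        )
    return metas, records


# ---------------------------------------------------------------------------
# between-species analysis
# ---------------------------------------------------------------------------

_SITE_CLASS_FUNS = {
    SiteClass.CANONICAL: site_usage.canonical_usage,
    SiteClass.UTR_ANY_FRAME: site_usage.utr_anyframe_usage,
    SiteClass.UTR_POST_ASC_IN_FRAME: site_usage.post_asc_usage,
}


def species_usage_summary(
    records_by_species: Mapping[str, Sequence[GeneRecord]]
) -> pd.DataFrame:
    """Long table: one row per species x site class x codon.

    Columns: species_id, site_class, codon, count, freq, mean_utr3_gc,
    mean_gc3, n_genes.  Site classes with zero counts for a species yield no
    rows (logged).
    """
    rows = []
    for sid, recs in records_by_species.items():
        try:
            gc = site_usage.species_gc_metrics(recs)
        except site_usage.UndefinedMetricError:
            logger.warning("species %s: no GC metrics, skipped", sid)
            continue
        for sclass, fun in _SITE_CLASS_FUNS.items():
            table = fun(recs, species_id=sid)
            if table.is_empty:
                logger.warning(
                    "species %s: no counts at site class %s", sid, sclass
                )
                continue
            freqs = table.freqs
            for codon in STOP_CODONS:
                rows.append(
                    {
                        "species_id": sid,
                        "site_class": str(sclass),
                        "codon": codon,
                        "count": table.counts[codon],
                        "freq": freqs[codon],
                        "mean_utr3_gc": gc.mean_utr3_gc,
                        "mean_gc3": gc.mean_gc3,
                        "n_genes": table.n_genes_contributing,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class BetweenSpeciesResult:
    usage: pd.DataFrame
    correlations: pd.DataFrame
    fits: dict[tuple[str, str], stats.LinearFit]  # (site_class, codon)
    slope_comparisons: dict[str, stats.SlopeComparison]  # TGA vs TAG


def run_between_species(
    records_by_species: Mapping[str, Sequence[GeneRecord]] | pd.DataFrame,
    config: RunConfig = RunConfig(),
) -> BetweenSpeciesResult:
    """Usage-vs-GC trends at the three site classes across a species panel.

    Accepts either raw per-species records or a pre-computed usage summary
    table.  Slopes are fitted against mean 3'UTR GC expressed in percentage
    points; Spearman correlations are scale-free.
    """
    if isinstance(records_by_species, pd.DataFrame):
        usage = records_by_species
    else:
        usage = species_usage_summary(records_by_species)
    if usage["species_id"].nunique() < 10:
        raise ValueError("between-species analysis needs >= 10 species")

    corr_rows = []
    fits: dict[tuple[str, str], stats.LinearFit] = {}
    comparisons: dict[str, stats.SlopeComparison] = {}
    for sclass, sub in usage.groupby("site_class"):
        for codon, cc in sub.groupby("codon"):
            x_pct = cc["mean_utr3_gc"].to_numpy() * 100.0
            y = cc["freq"].to_numpy()
            try:
                corr = stats.spearman(x_pct, y)
            except ValueError:
                logger.warning(
                    "site class %s codon %s: correlation undefined", sclass, codon
                )
                continue
            fit = stats.fit_linear(x_pct, y)
            fits[(sclass, codon)] = fit
            corr_rows.append(
                {
                    "site_class": sclass,
                    "codon": codon,
                    "rho": corr.rho,
                    "p_value": corr.p_value,
                    "n": corr.n,
                    "slope": fit.slope,
                    "slope_se": fit.slope_se,
                    "intercept": fit.intercept,
                }
            )
        if (sclass, "TGA") in fits and (sclass, "TAG") in fits:
            comparisons[sclass] = stats.compare_slopes(
                fits[(sclass, "TGA")], fits[(sclass, "TAG")]
            )
    return BetweenSpeciesResult(
        usage=usage,
        correlations=pd.DataFrame(corr_rows),
        fits=fits,
        slope_comparisons=comparisons,
    )


# ---------------------------------------------------------------------------
# intragenomic logistic analysis
# ---------------------------------------------------------------------------

@dataclass
class IntragenomicResult:
    fits: pd.DataFrame  # species_id, codon, coefficient, p_value, converged, n
    sign_counts: dict[str, stats.SignCounts]
    binomial_p: pd.DataFrame  # codon, test, k, n, p0, p_value
    tga_vs_tag_abs: tuple[int, int]  # (|coef TGA| > |coef TAG| count, n compared)
    tga_vs_tag_p: float


def run_intragenomic(
    records_by_species: Mapping[str, Sequence[GeneRecord]],
    config: RunConfig = RunConfig(),
) -> IntragenomicResult:
    """Per-species logistic regressions and cross-species sign counts."""
    fit_rows = []
    all_fits: list[stats.LogisticFit] = []
    per_species: dict[str, dict[str, stats.LogisticFit]] = {}
    for sid, recs in records_by_species.items():
        per_species[sid] = {}
        for codon in STOP_CODONS:
            fit = stats.logistic_stop_vs_gc(
                recs,
                codon,
                predictor=config.predictor,
                min_genes=config.min_genes_logistic,
            )
            all_fits.append(fit)
            per_species[sid][codon] = fit
            fit_rows.append(
                {
                    "species_id": sid,
                    "codon": codon,
                    "coefficient": fit.coefficient,
                    "p_value": fit.p_value,
                    "converged": fit.converged,
                    "n_genes": fit.n_genes,
                }
            )
    counts = stats.count_coefficient_signs(all_fits, alpha=config.alpha)

    binom_rows = []
    for codon, sc in counts.items():
        n = sc.n_converged
        if n == 0:
            continue
        # direction of interest: negative for TAA, positive for TGA/TAG
        k_dir = sc.negative if codon == "TAA" else sc.positive
        k_sig = (
            sc.negative_significant if codon == "TAA" else sc.positive_significant
        )
        binom_rows.append(
            {
                "codon": codon,
                "test": "direction_vs_half",
                "k": k_dir,
                "n": n,
                "p0": 0.5,
                "p_value": stats.binomial_exceedance(k_dir, n, 0.5, "greater"),
            }
        )
        binom_rows.append(
            {
                "codon": codon,
                "test": "significant_vs_alpha",
                "k": k_sig,
                "n": n,
                "p0": config.alpha,
                "p_value": stats.binomial_exceedance(
                    k_sig, n, config.alpha, "greater"
                ),
            }
        )

    k_abs = n_abs = 0
    for sid, fits in per_species.items():
        ftga, ftag = fits.get("TGA"), fits.get("TAG")
        if (
            ftga is not None
            and ftag is not None
            and ftga.converged
            and ftag.converged
        ):
            n_abs += 1
            if abs(ftga.coefficient) > abs(ftag.coefficient):
                k_abs += 1
    tga_vs_tag_p = (
        stats.binomial_exceedance(k_abs, n_abs, 0.5, "greater")
        if n_abs
        else float("nan")
    )
    return IntragenomicResult(
        fits=pd.DataFrame(fit_rows),
        sign_counts=counts,
        binomial_p=pd.DataFrame(binom_rows),
        tga_vs_tag_abs=(k_abs, n_abs),
        tga_vs_tag_p=tga_vs_tag_p,
    )


# ---------------------------------------------------------------------------
# single-genome binned analysis
# ---------------------------------------------------------------------------

@dataclass
class BinnedResult:
    binned: stats.BinnedUsage
    correlations: pd.DataFrame
    fits: dict[str, stats.LinearFit]
    slope_comparison: stats.SlopeComparison


def run_binned(
    records: Sequence[GeneRecord],
    config: RunConfig = RunConfig(),
) -> BinnedResult:
    """Decile analysis of one genome: per-bin usage, trends, TGA-vs-TAG test."""
    binned = stats.bin_by_gc(
        records, n_bins=config.n_bins, predictor=config.predictor
    )
    tbl = binned.table
    x_pct = tbl["mean_gc"].to_numpy() * 100.0
    corr_rows = []
    fits = {}
    for codon in STOP_CODONS:
        y = tbl[f"f_{codon}"].to_numpy()
        corr = stats.spearman(x_pct, y)
        fit = stats.fit_linear(x_pct, y)
        fits[codon] = fit
        corr_rows.append(
            {
                "codon": codon,
                "rho": corr.rho,
                "p_value": corr.p_value,
                "n": corr.n,
                "slope": fit.slope,
                "slope_se": fit.slope_se,
            }
        )
    comparison = stats.compare_slopes(fits["TGA"], fits["TAG"])
    return BinnedResult(
        binned=binned,
        correlations=pd.DataFrame(corr_rows),
        fits=fits,
        slope_comparison=comparison,
    )


# ---------------------------------------------------------------------------
# GC-matched cross-domain comparison
# ---------------------------------------------------------------------------

@dataclass
class GCMatchedResult:
    pairing: stats.GCMatchPairing
    query_fit: stats.LinearFit
    matched_fit: stats.LinearFit
    query_corr: stats.CorrelationResult
    matched_corr: stats.CorrelationResult
    slope_comparison: stats.SlopeComparison


def run_gc_matched(
    query_usage: pd.DataFrame,
    candidate_usage: pd.DataFrame,
    codon: str = "TAG",
    config: RunConfig = RunConfig(),
) -> GCMatchedResult:
    """Match each query species to its nearest candidate by mean 3'UTR GC.

    Both inputs are usage summary tables (:func:`species_usage_summary`).
    The focal codon's canonical-site usage is regressed on GC (percentage
    points) in the query panel and in the GC-matched candidate multiset, and
    the two slopes are compared by Z test.
    """

    def canon(usage: pd.DataFrame, c: str) -> pd.DataFrame:
        sub = usage[
            (usage["site_class"] == str(SiteClass.CANONICAL))
            & (usage["codon"] == c)
        ]
        return sub.set_index("species_id")

    q = canon(query_usage, codon)
    cand = canon(candidate_usage, codon)
    pairing = stats.gc_match(
        q["mean_utr3_gc"].to_dict(), cand["mean_utr3_gc"].to_dict()
    )
    matched = cand.loc[pairing.matched_candidates]

    qx = q["mean_utr3_gc"].to_numpy() * 100.0
    qy = q["freq"].to_numpy()
    mx = matched["mean_utr3_gc"].to_numpy() * 100.0
    my = matched["freq"].to_numpy()
    query_fit = stats.fit_linear(qx, qy)
    matched_fit = stats.fit_linear(mx, my)
    return GCMatchedResult(
        pairing=pairing,
        query_fit=query_fit,
        matched_fit=matched_fit,
        query_corr=stats.spearman(qx, qy),
        matched_corr=stats.spearman(mx, my),
        slope_comparison=stats.compare_slopes(query_fit, matched_fit),
    )


# ---------------------------------------------------------------------------
# enrichment against the dinucleotide null
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentPanelResult:
    per_species: pd.DataFrame
    taa_most_enriched: int
    n_species: int
    n_excluded: int
    binomial_p: float

    @property
    def taa_fraction(self) -> float:
        return self.taa_most_enriched / self.n_species if self.n_species else float("nan")


def run_enrichment(
    records_by_species: Mapping[str, Sequence[GeneRecord]],
    config: RunConfig = RunConfig(),
) -> EnrichmentPanelResult:
    """Per-species (O-E)/E deviations and the TAA-most-enriched exceedance.

    Each species' null is fitted from its own CDS set; expected stop
    frequencies come from ``n_sims`` seeded Monte-Carlo draws (or the exact
    analytic probabilities).  The count of species whose most enriched stop
    is TAA is tested against the null fraction 1/3 by exact binomial test.
    """
    ss = np.random.SeedSequence(config.seed)
    species_seeds = {
        sid: int(child.generate_state(1)[0] % (2**31))
        for sid, child in zip(
            sorted(records_by_species), ss.spawn(len(records_by_species))
        )
    }
    rows = []
    n_excluded = 0
    for sid in sorted(records_by_species):
        recs = records_by_species[sid]
        usage = site_usage.canonical_usage(recs, species_id=sid)
        cds = [r.cds_seq for r in recs if r.cds_seq]
        try:
            model = null_model.fit_markov(cds)
            result = null_model.enrichment(
                usage,
                model,
                n_sims=config.n_sims,
                seed=species_seeds[sid],
                mode=config.enrichment_mode,
            )
        except ValueError as exc:
            logger.warning("species %s: enrichment skipped (%s)", sid, exc)
            n_excluded += 1
            continue
        row = {"species_id": sid, "most_enriched": result.most_enriched}
        for c in STOP_CODONS:
            row[f"observed_{c}"] = result.observed[c]
            row[f"expected_{c}"] = result.expected[c]
            row[f"deviation_{c}"] = result.deviation.get(c, float("nan"))
        rows.append(row)
    per_species = pd.DataFrame(rows)
    n = len(per_species)
    k = (
        int((per_species["most_enriched"] == "TAA").sum()) if n else 0
    )
    p = stats.binomial_exceedance(k, n, 1 / 3, "greater") if n else float("nan")
    return EnrichmentPanelResult(
        per_species=per_species,
        taa_most_enriched=k,
        n_species=n,
        n_excluded=n_excluded,
        binomial_p=p,
    )


# ---------------------------------------------------------------------------
# run-all orchestration
# ---------------------------------------------------------------------------

def _table_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]


def run_all(
    panel_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig = RunConfig(),
) -> dict:
    """Run every analysis on one panel directory; write tables + summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metas, records = load_panel(panel_dir, config)
    usage = species_usage_summary(records)
    usage.to_csv(out / "usage_by_site_class.tsv", sep="\t", index=False)

    between = run_between_species(usage, config)
    between.correlations.to_csv(
        out / "between_species_trends.tsv", sep="\t", index=False
    )
    intra = run_intragenomic(records, config)
    intra.fits.to_csv(out / "intragenomic_fits.tsv", sep="\t", index=False)
    intra.binomial_p.to_csv(
        out / "intragenomic_binomials.tsv", sep="\t", index=False
    )
    enrich = run_enrichment(records, config)
    enrich.per_species.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    summary = {
        "config": asdict(config),
        "n_species": len(metas),
        "input_hash": _table_hash(usage),
        "between_species": {
            sclass: {
                "z": cmp.z,
                "p_value": cmp.p_value,
                "slope_TGA": cmp.fit_a.slope,
                "slope_TAG": cmp.fit_b.slope,
            }
            for sclass, cmp in between.slope_comparisons.items()
        },
        "intragenomic": {
            codon: asdict(sc) for codon, sc in intra.sign_counts.items()
        },
        "intragenomic_tga_vs_tag_abs": {
            "k": intra.tga_vs_tag_abs[0],
            "n": intra.tga_vs_tag_abs[1],
            "p_value": intra.tga_vs_tag_p,
        },
        "enrichment": {
            "taa_most_enriched": enrich.taa_most_enriched,
            "n_species": enrich.n_species,
            "fraction": enrich.taa_fraction,
            "binomial_p": enrich.binomial_p,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
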