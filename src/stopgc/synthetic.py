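"""Synthetic genome panels with known stop-usage structure.

The generator emulates the statistical structure the comparative analyses
assume, so every pipeline stage is testable without genome downloads:

* a panel of species spans a 3'UTR GC gradient (default 0.2–0.8);
* each species' canonical stop-codon frequencies are a linear function of
  species GC, renormalised onto the simplex, with distinct slopes per codon
  (defaults: TAA −1.2, TGA +1.2, TAG 0.0 per unit GC fraction, i.e. −0.012,
  +0.012 and 0.0 per GC *percentage point* — the scale on which
  between-species usage slopes are conventionally reported, echoing the
  magnitudes observed across real bacterial panels);
* CDS are random codons with an ATG start, no internal in-frame stop
  (rejection sampling at codon draw) and GC3 tracking the species GC;
* 3'UTR windows are drawn i.i.d. from the species composition, optionally
  with the per-gene probability of an in-frame additional stop codon (ASC)
  adjusted toward a target rate;
* every species is emitted as standard FASTA + GFF3 with a truth table
  recording the parameters and per-gene draws for recovery tests.

Identical specs (including the seed) produce byte-identical panels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneRecord, reverse_complement
from .null_model import analytic_trinucleotide_probs, fit_markov
from .site_usage import STOP_CODONS, gc3 as _gc3, gc_content

__all__ = [
    "StopModel",
    "DEFAULT_STOP_MODEL",
    "PanelSpec",
    "SpeciesTruth",
    "stop_freqs_from_gc",
    "generate_species",
    "generate_panel",
    "sample_panel_usage",
    "sample_logistic_genes",
    "generate_null_matched_species",
]

_NUC_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
# codon index = 16*a + 4*b + 4*c over A=0,C=1,G=2,T=3
_STOP_CODON_IDX = {48: "TAA", 56: "TGA", 50: "TAG"}  # TAA, TGA, TAG
_STOP_IDX_SET = np.array(sorted(_STOP_CODON_IDX), dtype=np.int64)
_MARGIN = 12  # unannotated nt after each gene block (plus leading margin)


@dataclass(frozen=True)
class StopModel:
    """Per-codon linear model of stop frequency against species GC.

    ``freq(c) = intercept[c] + slope[c] * gc`` with ``gc`` a fraction in
    (0,1), then renormalised to sum to one.  A slope of 1.2 per unit GC
    fraction equals 0.012 per GC percentage point (the reporting scale of
    the between-species analyses: divide by 100).
    """

    intercepts: Mapping[str, float]
    slopes: Mapping[str, float]

    def feasible_gc_interval(self) -> tuple[float, float]:
        """Open GC interval on which all raw frequencies are positive."""
        lo, hi = 0.0, 1.0
        for c in self.intercepts:
            a, b = self.intercepts[c], self.slopes[c]
            if b > 0:
                lo = max(lo, -a / b)
            elif b < 0:
                hi = min(hi, -a / b)
            elif a <= 0:
                raise ValueError(f"codon {c}: zero slope, non-positive intercept")
        return lo, hi


DEFAULT_STOP_MODEL = StopModel(
    intercepts={"TAA": 0.97, "TGA": 0.01, "TAG": 0.02},
    slopes={"TAA": -1.2, "TGA": 1.2, "TAG": 0.0},
)


@dataclass(frozen=True)
class PanelSpec:
    """Study conditions for one synthetic panel."""

    n_species: int = 200
    gc_grid: tuple[float, float] = (0.2, 0.8)
    genes_per_species: int = 500
    stop_model: StopModel = DEFAULT_STOP_MODEL
    utr_len: int = 30
    #: target per-gene probability of an in-frame UTR stop; ``None`` leaves
    #: the compositional (i.i.d.) rate untouched.
    asc_rate: Optional[float] = None
    cds_len_range: tuple[int, int] = (50, 150)  # codons, incl. start & stop
    #: SD of per-gene GC targets around the species GC.  Zero (default)
    #: gives a compositionally homogeneous genome; positive values emulate
    #: intragenomic GC heterogeneity (isochore-like structure), with each
    #: gene's stop codon drawn at its *own* GC so that local GC pressure
    #: predicts stop usage within the genome.
    gene_gc_sd: float = 0.0
    domain: str = "bacteria"
    seed: int = 0


@dataclass
class SpeciesTruth:
    """Generator ground truth for one species (for recovery tests)."""

    species_id: str
    gc_target: float
    true_stop_freqs: dict[str, float]
    genes: pd.DataFrame  # gene_id, strand, stop_codon, utr3_seq, utr3_gc, gc3
    mean_utr3_gc: float
    mean_gc3: float


def stop_freqs_from_gc(gc: float, stop_model: StopModel = DEFAULT_STOP_MODEL) -> dict[str, float]:
    """Stop-codon frequencies implied by the linear model at a given GC.

    Raw values must all be strictly positive before renormalisation; a
    non-positive raw frequency is a hard error naming the offending GC.
    """
    raw = {
        c: stop_model.intercepts[c] + stop_model.slopes[c] * gc
        for c in STOP_CODONS
    }
    bad = [c for c, v in raw.items() if v <= 0]
    if bad:
        raise ValueError(
            f"stop model infeasible at GC={gc:.3f}: non-positive raw "
            f"frequency for {', '.join(bad)}"
        )
    tot = sum(raw.values())
    return {c: raw[c] / tot for c in STOP_CODONS}


def _base_probs(gc: float) -> np.ndarray:
    """i.i.d. A/C/G/T probabilities with expected GC fraction ``gc``."""
    if not 0 < gc < 1:
        raise ValueError(f"GC target must lie strictly in (0,1), got {gc}")
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _draw_codes(rng: np.random.Generator, n: int, p: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=n, p=p)


def _codes_to_str(codes: np.ndarray) -> str:
    return _NUC_BYTES[codes].tobytes().decode("ascii")


def _resample_stops(
    rng: np.random.Generator, codons: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Redraw codon triples (n,3) until none is a stop codon."""
    while True:
        idx = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
        bad = np.isin(idx, _STOP_IDX_SET)
        if not bad.any():
            return codons
        codons[bad] = rng.choice(4, size=(int(bad.sum()), 3), p=p)


def _random_cds_bodies(
    rng: np.random.Generator,
    n_genes: int,
    cds_len_range: tuple[int, int],
    gc: float,
) -> list[str]:
    """ATG + random non-stop codons (terminal stop NOT included)."""
    p = _base_probs(gc)
    lo, hi = cds_len_range
    lengths = rng.integers(lo, hi + 1, size=n_genes)  # codons incl start+stop
    n_internal = lengths - 2
    total = int(n_internal.sum())
    codons = rng.choice(4, size=(total, 3), p=p)
    codons = _resample_stops(rng, codons, p)
    flat = codons.reshape(-1)
    bodies = []
    offsets = np.concatenate([[0], np.cumsum(n_internal * 3)])
    for i in range(n_genes):
        bodies.append("ATG" + _codes_to_str(flat[offsets[i] : offsets[i + 1]]))
    return bodies


def _stop_weights_from_composition(p: np.ndarray) -> np.ndarray:
    """Relative probabilities of TAA/TGA/TAG under i.i.d. composition."""
    a, c, g, t = p
    w = np.array([t * a * a, t * g * a, t * a * g])
    if w.sum() <= 0:
        raise ValueError(
            "infeasible composition: no stop trinucleotide can occur"
        )
    return w / w.sum()


def _draw_utrs(
    rng: np.random.Generator,
    n_genes: int,
    utr_len: int,
    gc: float,
    asc_rate: Optional[float],
) -> list[str]:
    p = _base_probs(gc)
    mat = rng.choice(4, size=(n_genes, utr_len), p=p)
    if asc_rate is not None:
        k = utr_len // 3
        if k == 0:
            raise ValueError("utr_len < 3: cannot control ASC content")
        if not 0 <= asc_rate < 1:
            raise ValueError("asc_rate must lie in [0, 1)")
        q = 1.0 - (1.0 - asc_rate) ** (1.0 / k)
        inframe = mat[:, : 3 * k].reshape(n_genes, k, 3)
        designated = rng.random((n_genes, k)) < q
        # designated codons become stops drawn by composition weight
        if designated.any():
            w = _stop_weights_from_composition(p)
            stop_codes = np.array(
                [[3, 0, 0], [3, 2, 0], [3, 0, 2]]
            )  # TAA, TGA, TAG
            choice = rng.choice(3, size=int(designated.sum()), p=w)
            inframe[designated] = stop_codes[choice]
        # non-designated codons must not be stops
        rest = inframe[~designated]
        inframe[~designated] = _resample_stops(rng, rest, p)
        mat[:, : 3 * k] = inframe.reshape(n_genes, 3 * k)
    return [_codes_to_str(row) for row in mat]


def generate_species(
    species_id: str,
    gc: float,
    spec: PanelSpec,
    seed: int | np.random.SeedSequence,
) -> tuple[str, str, SpeciesTruth]:
    """Generate one species: (FASTA text, GFF3 text, truth table).

    One contig carries ``genes_per_species`` genes on random strands,
    separated by unannotated spacers wide enough that every gene's 3'
    intergenic space exceeds the UTR window.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = spec.genes_per_species
    freqs = stop_freqs_from_gc(gc, spec.stop_model)

    if spec.gene_gc_sd > 0:
        lo, hi = spec.stop_model.feasible_gc_interval()
        eps = 0.02
        gene_gcs = np.clip(
            rng.normal(gc, spec.gene_gc_sd, size=n),
            max(0.05, lo + eps),
            min(0.95, hi - eps),
        )
        bodies, stops, utrs = [], [], []
        for g in gene_gcs:
            f = stop_freqs_from_gc(float(g), spec.stop_model)
            bodies.append(
                _random_cds_bodies(rng, 1, spec.cds_len_range, float(g))[0]
            )
            stops.append(
                STOP_CODONS[rng.choice(3, p=[f[c] for c in STOP_CODONS])]
            )
            utrs.append(
                _draw_utrs(rng, 1, spec.utr_len, float(g), spec.asc_rate)[0]
            )
    else:
        fvec = np.array([freqs[c] for c in STOP_CODONS])
        bodies = _random_cds_bodies(rng, n, spec.cds_len_range, gc)
        stops = [STOP_CODONS[i] for i in rng.choice(3, size=n, p=fvec)]
        utrs = _draw_utrs(rng, n, spec.utr_len, gc, spec.asc_rate)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    contig_id = f"{species_id}_c1"
    chunks: list[str] = []
    gff_lines = ["##gff-version 3"]
    truth_rows = []
    cursor = 0

    def margin() -> str:
        return _codes_to_str(_draw_codes(rng, _MARGIN, _base_probs(gc)))

    first = margin()
    chunks.append(first)
    cursor += len(first)

    for i in range(n):
        gene_id = f"{species_id}_g{i:04d}"
        cds = bodies[i] + stops[i]
        utr = utrs[i]
        strand = str(strands[i])
        if strand == "+":
            g_start, g_end = cursor, cursor + len(cds)  # half-open
            chunks.append(cds)
            chunks.append(utr)
            cursor = g_end + len(utr)
        else:
            chunks.append(reverse_complement(utr))
            g_start = cursor + len(utr)
            g_end = g_start + len(cds)
            chunks.append(reverse_complement(cds))
            cursor = g_end
        m = margin()
        chunks.append(m)
        cursor += len(m)

        gff_lines.append(
            f"{contig_id}\tstopgc\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t."
            f"\tID={gene_id}"
        )
        gff_lines.append(
            f"{contig_id}\tstopgc\tCDS\t{g_start + 1}\t{g_end}\t.\t{strand}\t0"
            f"\tID={gene_id}.cds;Parent={gene_id}"
        )
        truth_rows.append(
            {
                "species_id": species_id,
                "gene_id": gene_id,
                "strand": strand,
                "stop_codon": stops[i],
                "utr3_seq": utr,
                "utr3_gc": gc_content(utr),
                "gc3": _gc3(cds),
            }
        )

    genes = pd.DataFrame(truth_rows)
    truth = SpeciesTruth(
        species_id=species_id,
        gc_target=gc,
        true_stop_freqs=freqs,
        genes=genes,
        mean_utr3_gc=float(genes["utr3_gc"].mean()),
        mean_gc3=float(genes["gc3"].mean()),
    )
    fasta = f">{contig_id}\n" + "\n".join(
        _wrap("".join(chunks), 80)
    ) + "\n"
    gff = "\n".join(gff_lines) + "\n"
    return fasta, gff, truth


def _wrap(seq: str, width: int) -> list[str]:
    return [seq[i : i + width] for i in range(0, len(seq), width)]


def generate_panel(spec: PanelSpec, out_dir: str | Path) -> dict:
    """Generate a full panel directory and return its manifest.

    Species GC targets are evenly spaced over ``gc_grid``; per-species seeds
    are spawned from the master seed.  Writes per-species FASTA/GFF3,
    ``metadata.tsv``, ``truth_species.tsv``, ``truth_genes.tsv`` and
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets = np.linspace(spec.gc_grid[0], spec.gc_grid[1], spec.n_species)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_species)

    meta_rows, species_rows, gene_frames, files = [], [], [], []
    for i, (gc, child) in enumerate(zip(targets, children)):
        sid = f"S{i:03d}"
        fasta, gff, truth = generate_species(sid, float(gc), spec, child)
        (out / f"{sid}.fa").write_text(fasta)
        (out / f"{sid}.gff3").write_text(gff)
        files.extend([f"{sid}.fa", f"{sid}.gff3"])
        meta_rows.append(
            {
                "species_id": sid,
                "organism_name": f"Genus{i:03d} synthetica",
                "domain": spec.domain,
                "translation_table": 11,
            }
        )
        species_rows.append(
            {
                "species_id": sid,
                "gc_target": float(gc),
                **{f"true_f_{c}": truth.true_stop_freqs[c] for c in STOP_CODONS},
                "mean_utr3_gc": truth.mean_utr3_gc,
                "mean_gc3": truth.mean_gc3,
            }
        )
        gene_frames.append(truth.genes)

    pd.DataFrame(meta_rows).to_csv(out / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(species_rows).to_csv(
        out / "truth_species.tsv", sep="\t", index=False
    )
    pd.concat(gene_frames, ignore_index=True).to_csv(
        out / "truth_genes.tsv", sep="\t", index=False
    )
    manifest = {
        "spec": _spec_to_jsonable(spec),
        "n_species": spec.n_species,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _spec_to_jsonable(spec: PanelSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["stop_model"] = {
        "intercepts": dict(spec.stop_model.intercepts),
        "slopes": dict(spec.stop_model.slopes),
    }
    return d


# ---------------------------------------------------------------------------
# Fast statistical samplers (sufficient statistics without sequence realisation)
# ---------------------------------------------------------------------------

def sample_panel_usage(
    spec: PanelSpec, seed: int | None = None
) -> pd.DataFrame:
    """Draw the panel's species-level sufficient statistics directly.

    Per species: canonical stop counts are a multinomial draw from the true
    stop frequencies at that species' GC, and the realised mean 3'UTR GC is a
    binomial draw over ``genes_per_species * utr_len`` UTR positions.  This
    is the same stop-draw model :func:`generate_species` realises as
    sequence, without the sequence, for use in replicated recovery and
    calibration studies.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    targets = np.linspace(spec.gc_grid[0], spec.gc_grid[1], spec.n_species)
    rows = []
    n_utr_nt = spec.genes_per_species * spec.utr_len
    for i, gc in enumerate(targets):
        freqs = stop_freqs_from_gc(float(gc), spec.stop_model)
        counts = rng.multinomial(
            spec.genes_per_species, [freqs[c] for c in STOP_CODONS]
        )
        mean_gc = rng.binomial(n_utr_nt, gc) / n_utr_nt
        row = {
            "species_id": f"S{i:03d}",
            "gc_target": float(gc),
            "mean_utr3_gc": float(mean_gc),
            "n_genes": spec.genes_per_species,
        }
        for c, k in zip(STOP_CODONS, counts):
            row[f"n_{c}"] = int(k)
            row[f"f_{c}"] = k / spec.genes_per_species
            row[f"true_f_{c}"] = freqs[c]
        rows.append(row)
    return pd.DataFrame(rows)


def sample_logistic_genes(
    n_genes: int,
    beta: float,
    codon: str = "TAA",
    mean_gc: float = 0.5,
    utr_len: int = 30,
    seed: int = 0,
) -> list[GeneRecord]:
    """Genes whose stop presence follows a logistic law in their UTR GC.

    Per gene, ``utr3_gc ~ Binomial(utr_len, mean_gc)/utr_len`` and the
    canonical stop equals ``codon`` with probability
    ``sigmoid(beta * (utr3_gc - mean_gc))`` (baseline 0.5 at the mean GC);
    otherwise one of the other two stops, at random.  Records carry minimal
    CDS plumbing; they exist to exercise the regression layer against a known
    coefficient.
    """
    if codon not in STOP_CODONS:
        raise ValueError(f"unknown stop codon {codon!r}")
    rng = np.random.default_rng(seed)
    x = rng.binomial(utr_len, mean_gc, size=n_genes) / utr_len
    p = 1.0 / (1.0 + np.exp(-beta * (x - mean_gc)))
    hit = rng.random(n_genes) < p
    others = [c for c in STOP_CODONS if c != codon]
    alt = rng.choice(2, size=n_genes)
    records = []
    for i in range(n_genes):
        stop = codon if hit[i] else others[alt[i]]
        records.append(
            GeneRecord(
                gene_id=f"g{i:05d}",
                cds_seq="ATGAAA" + stop,
                stop_codon=stop,
                utr3_seq=None,
                utr3_gc=float(x[i]),
                gc3=None,
            )
        )
    return records


def generate_null_matched_species(
    species_id: str,
    gc: float,
    n_genes: int,
    seed: int | np.random.SeedSequence,
    cds_len_range: tuple[int, int] = (50, 150),
    inflate: Mapping[str, float] | None = None,
) -> list[GeneRecord]:
    """A species whose stop usage is drawn from its *own* dinucleotide null.

    CDS bodies are generated first; the Markov null fitted to them yields
    relative stop frequencies, optionally multiplied by per-codon ``inflate``
    factors and renormalised, from which each gene's terminal stop is drawn.
    Used to calibrate the enrichment analysis: without inflation no codon
    should be systematically the most enriched.
    """
    rng = np.random.default_rng(seed)
    bodies = _random_cds_bodies(rng, n_genes, cds_len_range, gc)
    model = fit_markov(bodies)
    tri = analytic_trinucleotide_probs(model)
    w = np.array([tri[c] for c in STOP_CODONS])
    if inflate:
        w = w * np.array([inflate.get(c, 1.0) for c in STOP_CODONS])
    if w.sum() <= 0:
        raise ValueError("null stop frequencies are all zero")
    w = w / w.sum()
    stops = [STOP_CODONS[i] for i in rng.choice(3, size=n_genes, p=w)]
    records = []
    for i, (body, stop) in enumerate(zip(bodies, stops)):
        cds = body + stop
        records.append(
            GeneRecord(
                gene_id=f"{species_id}_g{i:04d}",
                cds_seq=cds,
                stop_codon=stop,
                utr3_seq=None,
                utr3_gc=None,
                gc3=_gc3(cds),
            )
        )
    return records
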