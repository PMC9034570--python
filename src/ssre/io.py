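"""Quantification-table I/O, filtering, gene aggregation and analysis frames.

The on-disk interchange format is a UTF-8 TSV with a header and exactly
these columns::

    transcript_id  gene_id  exon_tpm_unlabeled  intron_tpm_unlabeled
    exon_tpm_labeled  intron_tpm_labeled

Abundances are assumed already length-normalized (TPM or equivalent), so
that intron and exon values are proportional to molecule counts; the
package deliberately does not take raw counts plus feature lengths.
Missing values in output tables are encoded as "NA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import EstimationResult, ObservableRatios

__all__ = [
    "QUANT_COLUMNS",
    "TranscriptRecord",
    "GeneRateRecord",
    "read_quant_table",
    "compute_ratios",
    "filter_by_expression",
    "aggregate_genes",
    "weighted_pearson",
    "responsiveness_frame",
    "write_rates_table",
]

QUANT_COLUMNS = [
    "transcript_id",
    "gene_id",
    "exon_tpm_unlabeled",
    "intron_tpm_unlabeled",
    "exon_tpm_labeled",
    "intron_tpm_labeled",
]

RATES_COLUMNS = [
    "transcript_id",
    "gene_id",
    "status",
    "k",
    "alpha",
    "beta",
    "gamma",
    "r_u",
    "r_l",
    "n_roots",
]

GENE_COLUMNS = ["gene_id", "gamma_gene", "r_l_gene", "weight_total", "n_transcripts"]


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript's exonic/intronic abundances in both pools.

    chi_* are exonic abundances (premature + mature RNA), iota_* intronic
    abundances (premature RNA only); u = unlabeled pool, l = labeled pool.
    """

    transcript_id: str
    gene_id: str
    chi_u: float
    iota_u: float
    chi_l: float
    iota_l: float


@dataclass(frozen=True)
class GeneRateRecord:
    """Expression-weighted gene-level degradation rate.

    ``r_l_gene`` is the same weighted mean applied to the labeled ratio,
    used to weight gene-level correlations by 1 - r_l (transcripts close
    to r_l = 1 saw a labeling pulse too short for their kinetics).
    """

    gene_id: str
    gamma_gene: float
    weight_total: float
    n_transcripts: int
    r_l_gene: float = math.nan


def read_quant_table(path) -> list[TranscriptRecord]:
    """Parse a quantification TSV into records, validating as it goes.

    Missing columns raise a ValueError naming them; non-numeric or negative
    abundances raise with the offending line numbers (header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"quantification table {path} is missing columns: {missing}")
    numeric = QUANT_COLUMNS[2:]
    vals = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad_rows = vals.isna().any(axis=1) | (vals < 0).any(axis=1)
    if bad_rows.any():
        lines = [int(i) + 2 for i in df.index[bad_rows][:20]]
        raise ValueError(
            f"quantification table {path}: non-numeric or negative abundance "
            f"on line(s) {lines}"
        )
    return [
        TranscriptRecord(
            transcript_id=str(t),
            gene_id=str(g),
            chi_u=float(cu),
            iota_u=float(iu),
            chi_l=float(cl),
            iota_l=float(il),
        )
        for t, g, cu, iu, cl, il in zip(
            df["transcript_id"],
            df["gene_id"],
            vals["exon_tpm_unlabeled"],
            vals["intron_tpm_unlabeled"],
            vals["exon_tpm_labeled"],
            vals["intron_tpm_labeled"],
        )
    ]


def compute_ratios(record: TranscriptRecord) -> ObservableRatios:
    """Intron-to-exon ratios (r_u, r_l) of the two pools."""
    if record.chi_u <= 0 or record.chi_l <= 0:
        raise ValueError(
            f"{record.transcript_id}: ratios undefined for non-positive "
            f"exonic abundance"
        )
    return ObservableRatios(
        a=record.iota_u / record.chi_u, b=record.iota_l / record.chi_l
    )


def filter_by_expression(
    records: list[TranscriptRecord], min_exon_tpm: float
) -> list[TranscriptRecord]:
    """Keep records whose mean exonic abundance across pools exceeds the threshold."""
    return [
        r for r in records if 0.5 * (r.chi_u + r.chi_l) > min_exon_tpm
    ]


def aggregate_genes(
    results: list[EstimationResult], records: list[TranscriptRecord]
) -> list[GeneRateRecord]:
    """Expression-weighted gene-level degradation rates.

    Per gene, gamma_gene = sum(w_i gamma_i) / sum(w_i) over its
    non-rejected transcripts, with w_i the arithmetic mean of the two
    pools' exonic abundances.  Scale-equivariant: rescaling all abundances
    rescales all weights uniformly and leaves gamma_gene unchanged.
    """
    by_id = {r.transcript_id: r for r in records}
    acc: dict[str, list[tuple[float, float, float]]] = {}
    for res in results:
        if res.status.rejected or res.transcript_id not in by_id:
            continue
        rec = by_id[res.transcript_id]
        w = 0.5 * (rec.chi_u + rec.chi_l)
        if w <= 0:
            continue
        acc.setdefault(rec.gene_id, []).append((w, res.gamma, res.r_l))
    out = []
    for gene_id in sorted(acc):
        entries = acc[gene_id]
        wt = sum(w for w, _, _ in entries)
        out.append(
            GeneRateRecord(
                gene_id=gene_id,
                gamma_gene=sum(w * g for w, g, _ in entries) / wt,
                r_l_gene=sum(w * rl for w, _, rl in entries) / wt,
                weight_total=wt,
                n_transcripts=len(entries),
            )
        )
    return out


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation (weighted means subtracted).

    Reduces to the ordinary Pearson correlation for equal weights.  Raises
    if either weighted variance vanishes (correlation ill-defined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape):
        raise ValueError("x, y and w must have equal length")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative and not all zero")
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum() / wsum
    vx = (w * (x - mx) ** 2).sum() / wsum
    vy = (w * (y - my) ** 2).sum() / wsum
    if vx <= 0 or vy <= 0:
        raise ValueError("weighted variance vanishes; correlation ill-defined")
    return float(cov / math.sqrt(vx * vy))


def responsiveness_frame(result: EstimationResult) -> tuple[float, float]:
    """Rotate (log alpha, log gamma) into the functionally meaningful axes.

    Returns (abundance, responsiveness) = (log alpha - log gamma,
    log alpha + log gamma): the first is the log steady-state mature
    abundance, the second measures how fast that steady state is reached.
    """
    if result.status.rejected:
        raise ValueError("responsiveness undefined for rejected transcripts")
    la, lg = math.log(result.alpha), math.log(result.gamma)
    return la - lg, la + lg


def write_rates_table(
    results: list[EstimationResult],
    gene_table: list[GeneRateRecord] | None,
    path_prefix,
) -> tuple[Path, Path | None]:
    """Write transcript-level (and optionally gene-level) rate TSVs.

    Produces ``<prefix>_transcript_rates.tsv`` with the fixed column order
    transcript_id, gene_id, status, k, alpha, beta, gamma, r_u, r_l,
    n_roots, and ``<prefix>_gene_rates.tsv`` when a gene table is given.
    NaN is written as "NA".
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tpath = prefix.parent / (prefix.name + "_transcript_rates.tsv")
    tdf = pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "gene_id": r.gene_id,
                "status": r.status.value,
                "k": r.k,
                "alpha": r.alpha,
                "beta": r.beta,
                "gamma": r.gamma,
                "r_u": r.r_u,
                "r_l": r.r_l,
                "n_roots": r.n_roots,
            }
            for r in results
        ],
        columns=RATES_COLUMNS,
    )
    tdf.to_csv(tpath, sep="\t", index=False, na_rep="NA")
    gpath = None
    if gene_table is not None:
        gpath = prefix.parent / (prefix.name + "_gene_rates.tsv")
        gdf = pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "gamma_gene": g.gamma_gene,
                    "r_l_gene": g.r_l_gene,
                    "weight_total": g.weight_total,
                    "n_transcripts": g.n_transcripts,
                }
                for g in gene_table
            ],
            columns=GENE_COLUMNS,
        )
        gdf.to_csv(gpath, sep="\t", index=False, na_rep="NA")
    return tpath, gpath
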