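"""Digital expression: EST-cluster assignment, TPM conversion, and
organ-specificity calls.

Expression is profiled from expressed sequence tag (EST) counts grouped
into UniGene-style clusters.  A gene's coding sequence is assigned to the
best-matching cluster by local alignment under joint score and E-value
thresholds; counts are normalised to transcripts per million (TPM); and a
gene is called organ-specific when its signal across the six surveyed
organs is confined to a single organ (or to the bud+flower pair, the
inflorescence).  Specificity depends only on the zero/nonzero pattern,
so it is invariant to library scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .data_model import ORGANS, ExpressionTable

# Karlin-Altschul parameters for the blastn-like scoring used here
# (match +1 / mismatch -2, gap open -5 / extend -2).
NUC_LAMBDA = 1.28
NUC_K = 0.46


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def evalue(score: float, query_len: int, db_len: float) -> float:
    """Karlin-Altschul expectation for a raw score."""
    return NUC_K * query_len * db_len * math.exp(-NUC_LAMBDA * score)


def assign_est_clusters(
    cds_set: Mapping[str, str],
    cluster_sequences: Mapping[str, str],
    min_score: float = 100.0,
    max_evalue: float = 1e-10,
    db_len: float | None = None,
) -> dict[str, str | None]:
    """Assign each coding sequence to its best-scoring EST cluster.

    A cluster is eligible when the best local alignment passes both the
    raw-score and the E-value threshold; the highest-scoring eligible
    cluster wins (ties break alphabetically for determinism).  Genes with
    no eligible cluster map to ``None``.
    """
    aligner = _nucleotide_aligner()
    if db_len is None:
        db_len = float(sum(len(s) for s in cluster_sequences.values())) or 1.0
    out: dict[str, str | None] = {}
    for gene, cds in cds_set.items():
        best: tuple[float, str] | None = None
        for cid in sorted(cluster_sequences):
            cseq = cluster_sequences[cid]
            alignments = aligner.align(cds, cseq)
            score = float(alignments.score) if len(cseq) and len(cds) else 0.0
            if score < min_score:
                continue
            if evalue(score, len(cds), db_len) > max_evalue:
                continue
            if best is None or score > best[0]:
                best = (score, cid)
        out[gene] = best[1] if best else None
    return out


def tpm(
    counts: pd.DataFrame, library_totals: Mapping[str, float]
) -> ExpressionTable:
    """EST counts -> transcripts per million: count / library total * 1e6."""
    organs = tuple(counts.columns)
    mat = counts.astype(float).copy()
    for organ in organs:
        total = float(library_totals[organ])
        col = mat[organ]
        if total == 0:
            if (col > 0).any():
                raise ValueError(f"{organ}: nonzero counts with zero total")
            continue
        mat[organ] = col / total * 1e6
    return ExpressionTable(
        organs=organs, tpm=mat, counts=counts,
        library_totals=dict(library_totals),
    )


@dataclass(frozen=True)
class SpecificityCall:
    gene: str
    category: str  # "single-organ:<organ>" | "inflorescence" | "broad" | "no-data"
    support: frozenset[str]


def specificity_calls(
    table: ExpressionTable, organs: Sequence[str] = ORGANS
) -> tuple[list[SpecificityCall], dict[str, int]]:
    """Per-gene organ-specificity calls and per-category summary counts.

    single-organ: signal in exactly one of the six organs;
    inflorescence: signal in bud and flower only;
    broad: anything else with numeric data (an all-zero row is "broad"
    with empty support — present in the cluster but not organ-resolved);
    no-data: no numeric organ values.  Auxiliary columns (whole plant,
    unspecified tissue) never disqualify specificity.
    """
    mat = table.tpm if table.tpm is not None else table.counts
    calls: list[SpecificityCall] = []
    summary: dict[str, int] = {}
    for gene in mat.index:
        if gene in table.no_data:
            category, support = "no-data", frozenset()
        else:
            row = mat.loc[gene, list(organs)]
            support = frozenset(o for o in organs if row[o] > 0)
            if len(support) == 1:
                category = f"single-organ:{next(iter(support))}"
            elif support == {"bud", "flower"}:
                category = "inflorescence"
            else:
                category = "broad"
        calls.append(SpecificityCall(gene, category, support))
        key = category.split(":")[0]
        summary[key] = summary.get(key, 0) + 1
    return calls, summary
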