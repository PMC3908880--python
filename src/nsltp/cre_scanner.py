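"""Promoter extraction and cis-regulatory element (CRE) counting.

Promoters are the up-to-2-kb stretch immediately upstream of the
translation start, truncated at the adjacent upstream gene when the
intergenic region is shorter, and reverse-complemented for minus-strand
genes.  CREs are short degenerate nucleotide motifs (IUPAC alphabet)
counted by exact-degenerate matching on both strands with overlapping
occurrences included; an ``N`` in the subject sequence never matches
(promoters interrupted by runs of uncertain nucleotides simply yield
fewer countable windows).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .data_model import GeneModel, MotifDefinition

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    sequence: str
    truncation: str  # "none" | "adjacent-gene" | "contig-end"

    @property
    def length(self) -> int:
        return len(self.sequence)


def extract_promoter(
    gene: GeneModel,
    genome: Mapping[str, str],
    limit: int = 2000,
    upstream_gene_end: int | None = None,
) -> PromoterRegion:
    """Upstream region of ``min(limit, intergenic distance)`` bp ending at
    the base before the translation start.

    ``upstream_gene_end`` is the nearest coordinate of the adjacent gene on
    the upstream side (1-based): for a plus-strand gene, the end of the
    gene before it; for a minus-strand gene, the start of the gene after
    it.  Minus-strand promoters are reverse-complemented so the returned
    sequence always reads toward the start codon.
    """
    chrom = genome[gene.chromosome]
    if gene.strand == "+":
        lo = gene.start - limit
        truncation = "none"
        if upstream_gene_end is not None and upstream_gene_end + 1 > lo:
            lo = upstream_gene_end + 1
            truncation = "adjacent-gene"
        if lo < 1:
            lo = 1
            truncation = "contig-end"
        seq = chrom[lo - 1 : gene.start - 1]
    else:
        hi = gene.end + limit
        truncation = "none"
        if upstream_gene_end is not None and upstream_gene_end - 1 < hi:
            hi = upstream_gene_end - 1
            truncation = "adjacent-gene"
        if hi > len(chrom):
            hi = len(chrom)
            truncation = "contig-end"
        seq = reverse_complement(chrom[gene.end : hi])
    return PromoterRegion(gene.id, seq, truncation)


def _matches_at(seq: str, pos: int, pattern: str) -> bool:
    for off, code in enumerate(pattern):
        if seq[pos + off] not in IUPAC[code]:
            return False
    return True


def count_cre(
    promoter: str,
    motif: str | MotifDefinition,
    strands: str = "both",
    overlapping: bool = True,
) -> int:
    """Number of motif occurrences in a promoter.

    ``strands`` is "plus", "minus" or "both"; minus-strand occurrences are
    counted as plus-strand matches of the reverse-complemented motif.
    With ``overlapping`` False, matches are counted greedily left to right
    per strand.
    """
    pattern = motif.pattern if isinstance(motif, MotifDefinition) else motif
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {sorted(bad)!r} in motif")
    if strands not in {"plus", "minus", "both"}:
        raise ValueError(f"strands must be plus/minus/both, not {strands!r}")

    subject = promoter.upper()

    def scan(pat: str) -> int:
        n, m = len(subject), len(pat)
        count = 0
        i = 0
        while i <= n - m:
            if _matches_at(subject, i, pat):
                count += 1
                i += 1 if overlapping else m
            else:
                i += 1
        return count

    total = 0
    if strands in {"plus", "both"}:
        total += scan(pattern)
    if strands in {"minus", "both"}:
        total += scan(reverse_complement(pattern))
    return total


def load_motifs(path: str | Path | None = None) -> list[MotifDefinition]:
    """Load motif definitions (name -> IUPAC pattern YAML); the packaged
    default carries the pollen-gene and storage-gene elements used in the
    survey, keyed by their PLACE identifiers."""
    if path is None:
        path = Path(str(resources.files("nsltp").joinpath("data", "motifs.yaml")))
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [MotifDefinition(name, pattern) for name, pattern in raw.items()]
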