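"""Genomic context of a gene family: chromosome inventory, tandem
duplication clustering by locus separation, intron counting and phases.

Tandem duplication uses the standard rule for plant gene families: two
family members on one chromosome are tandem duplicates when at most five
other gene loci lie between them.  Separation is measured on genome-wide
gene ordinals (for BRAD loci, the numeric part of the identifier), not in
base pairs, and clusters grow by single linkage, so a cluster may span
more than the bound end-to-end as long as each consecutive gap satisfies
it.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .data_model import GeneModel


@dataclass(frozen=True)
class TandemCluster:
    chromosome: str
    members: tuple[str, ...]  # gene ids ordered by locus ordinal
    max_gap: int  # largest intervening-locus count between neighbours

    def __len__(self) -> int:
        return len(self.members)


def tandem_clusters(
    genes: Sequence[GeneModel], max_intervening: int = 5
) -> list[TandemCluster]:
    """Single-linkage tandem clusters of family members.

    Genes on the same chromosome whose ordinals differ by at most
    ``max_intervening`` + 1 are chained; clusters of size >= 2 are
    returned, ordered by chromosome then ordinal.  Genes without a locus
    ordinal are excluded with a warning.
    """
    usable = []
    for g in genes:
        if g.locus_ordinal is None:
            warnings.warn(f"{g.id}: no locus ordinal; excluded from clustering")
        else:
            usable.append(g)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in usable:
        by_chrom.setdefault(g.chromosome, []).append(g)

    clusters: list[TandemCluster] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: g.locus_ordinal)
        run: list[GeneModel] = [ordered[0]]
        gaps: list[int] = []
        for prev, cur in zip(ordered, ordered[1:]):
            intervening = cur.locus_ordinal - prev.locus_ordinal - 1
            if intervening <= max_intervening:
                run.append(cur)
                gaps.append(intervening)
            else:
                if len(run) >= 2:
                    clusters.append(
                        TandemCluster(chrom, tuple(g.id for g in run), max(gaps))
                    )
                run, gaps = [cur], []
        if len(run) >= 2:
            clusters.append(
                TandemCluster(chrom, tuple(g.id for g in run), max(gaps))
            )
    return clusters


def chromosome_inventory(genes: Iterable[GeneModel]) -> Counter:
    """Family-member count per chromosome (sum equals input size)."""
    return Counter(g.chromosome for g in genes)


@dataclass(frozen=True)
class IntronPhaseProfile:
    gene_id: str
    introns: tuple[tuple[int, int, int], ...]  # (index, length bp, phase)

    @property
    def phases(self) -> tuple[int, ...]:
        return tuple(p for _, _, p in self.introns)


def intron_phases(gene: GeneModel) -> IntronPhaseProfile:
    """Intron lengths and phases of a gene model, in coding orientation.

    Phase 0: the intron falls between codons; phase 1: between the first
    and second nucleotide of a codon; phase 2: between the second and
    third.  Computed as the cumulative upstream coding length mod 3, with
    exons walked in coding orientation (reversed for minus-strand genes);
    the phase list is therefore strand-symmetric by construction.
    """
    exons = list(gene.exons)
    if not exons:
        exons = [(gene.start, gene.end)]
    if gene.strand == "-":
        exons = exons[::-1]

    introns: list[tuple[int, int, int]] = []
    cumulative = 0
    for idx, (exon, nxt) in enumerate(zip(exons, exons[1:]), start=1):
        cumulative += exon[1] - exon[0] + 1
        if gene.strand == "+":
            length = nxt[0] - exon[1] - 1
        else:
            length = exon[0] - nxt[1] - 1
        if length < 0:
            raise ValueError(f"{gene.id}: overlapping exons")
        introns.append((idx, length, cumulative % 3))
    return IntronPhaseProfile(gene.id, tuple(introns))


def count_intron_bearing(intron_lists: Iterable[Sequence[int]]) -> int:
    """Number of genes with at least one intron, from per-gene intron
    length lists (as carried by the family inventory)."""
    return sum(1 for introns in intron_lists if len(introns) >= 1)
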