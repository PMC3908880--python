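"""Core domain types and I/O for the nsLTP survey pipeline.

The pipeline operates on four kinds of records: precursor proteins
(:class:`ProteinRecord`), gene models with genome-wide locus ordinals
(:class:`GeneModel`), per-protein external-predictor annotations
(:class:`AnnotationBundle`), and gene-by-organ expression matrices
(:class:`ExpressionTable`).  Two hand-digitized reference tables from the
B. rapa nsLTP survey ship with the package: the 63-gene family inventory
(:func:`load_table1_fixture`) and the UniGene TPM matrix
(:func:`load_table4_fixture`).  Both are checksummed so silent drift of the
digitization fails loudly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: X is tolerated on input but matches no residue class in motif scans.
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}

ORGANS = ("bud", "flower", "leaf", "root", "seed", "silique")

_FIXTURE_SHA256 = {
    "table1.tsv": "b39d05b878fd3749d45ea7878a11f71e2e9ebbb9467010f1bad67ec36f3f9586",
    "table4.tsv": "bd17008f8bb03d16df906800a648456b393f3804d8cb3dc550dc9cd8b6144fcc",
}


class FixtureError(RuntimeError):
    """A packaged reference table is missing or does not match its checksum."""


class FastaError(ValueError):
    """Malformed FASTA input (duplicate ids, bad alphabet, unparsable entry)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A precursor protein: identifier, free-text description, sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: non-standard residues {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: chromosome, 1-based inclusive coordinates, strand,
    exon structure and a genome-wide gene-rank ordinal.

    Coordinates are 1-based inclusive throughout the package, matching the
    convention of the published tables; :meth:`to_zero_based` converts at
    format boundaries.  ``locus_ordinal`` is the genome-wide gene rank
    (for BRAD loci, the numeric part of the ``Bra######`` identifier) and
    is what the tandem-duplication rule counts, not base pairs.
    """

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    locus_ordinal: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.id}: exon {s}-{e} reversed")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def to_zero_based(self) -> tuple[int, int]:
        """Return (start, end) as 0-based half-open coordinates."""
        return self.start - 1, self.end


@dataclass
class Annotation:
    """External-predictor results for one protein."""

    signal_cleavage: int | None = None  # last residue of the signal peptide
    gpi_anchor: bool = False
    has_ltp_domain: bool | None = None
    storage_like: bool | None = None

    def validate(self, precursor_length: int, pid: str = "?") -> None:
        sc = self.signal_cleavage
        if sc is not None and not (5 <= sc < precursor_length):
            raise ValueError(
                f"{pid}: signal cleavage {sc} outside [5, {precursor_length})"
            )


#: Per-protein map of annotations.
AnnotationBundle = dict[str, Annotation]


@dataclass
class ExpressionTable:
    """Gene x organ expression matrix.

    Either raw EST ``counts`` plus per-organ ``library_totals``, or a ``tpm``
    matrix directly.  Rows whose organ cells carry no numeric value at all
    are tracked in ``no_data`` (the published matrix prints dashes for genes
    whose UniGene cluster had no organ-resolved ESTs).
    """

    organs: tuple[str, ...]
    tpm: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None
    library_totals: Mapping[str, float] | None = None
    no_data: frozenset[str] = frozenset()
    extra: pd.DataFrame | None = None  # auxiliary flags (whole plant etc.)

    def __post_init__(self) -> None:
        for mat in (self.tpm, self.counts):
            if mat is not None and (mat[list(self.organs)] < 0).any().any():
                raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        mat = self.tpm if self.tpm is not None else self.counts
        return [] if mat is None else list(mat.index)


@dataclass(frozen=True)
class MotifDefinition:
    """A named motif: IUPAC nucleotide pattern or residue-class pattern."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"{self.name}: empty pattern")


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA into records.

    Sequences are uppercased and trailing ``*`` stop characters stripped.
    Duplicate identifiers raise :class:`FastaError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        try:
            records.append(
                ProteinRecord(rec.id, seq, rec.description[len(rec.id):].strip())
            )
        except ValueError as exc:
            raise FastaError(str(exc)) from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_nucleotide_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA (genome, CDS or cluster set) as id -> sequence."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FastaError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("nsltp").joinpath("data", name)))


def _read_checked(name: str) -> Path:
    path = _fixture_path(name)
    if not path.exists():
        raise FixtureError(f"packaged fixture {name} missing")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected = _FIXTURE_SHA256[name]
    if digest != expected:
        raise FixtureError(
            f"fixture {name} checksum mismatch: {digest} != {expected}"
        )
    return path


@dataclass(frozen=True)
class InventoryEntry:
    """One row of the digitized 63-gene family inventory."""

    name: str
    locus: str
    chromosome: str
    start: int
    end: int
    strand: str
    introns: tuple[int, ...]
    ecm: str
    sp_len: int
    mp_len: int
    mm: float
    pi: float
    type: str
    tandem: bool

    @property
    def locus_ordinal(self) -> int:
        return int(self.locus.removeprefix("Bra"))

    def gene_model(self) -> GeneModel:
        return GeneModel(
            id=self.locus,
            chromosome=self.chromosome,
            start=self.start,
            end=self.end,
            strand=self.strand,
            locus_ordinal=self.locus_ordinal,
        )


def load_table1_fixture() -> list[InventoryEntry]:
    """Load the digitized 63-gene inventory (names, loci, coordinates,
    intron lengths, ECM strings, signal/mature lengths, mass, pI, type)."""
    path = _read_checked("table1.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for row in df.itertuples(index=False):
        introns = (
            ()
            if row.introns == "none"
            else tuple(int(x) for x in row.introns.split(","))
        )
        entries.append(
            InventoryEntry(
                name=row.name,
                locus=row.locus,
                chromosome=row.chromosome,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                introns=introns,
                ecm=row.ecm,
                sp_len=int(row.sp_len),
                mp_len=int(row.mp_len),
                mm=float(row.mm),
                pi=float(row.pi),
                type=row.type,
                tandem=row.tandem == "1",
            )
        )
    if len(entries) != 63:
        raise FixtureError(f"expected 63 inventory rows, found {len(entries)}")
    return entries


def load_table4_fixture() -> ExpressionTable:
    """Load the digitized UniGene TPM matrix (six organs, 63 genes).

    Organ cells that are not numeric (dashes, stray check marks in the
    source table) mark the row as carrying no organ-resolved data.
    """
    path = _read_checked("table4.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("name")
    organ_raw = df[list(ORGANS)]
    numeric = organ_raw.apply(pd.to_numeric, errors="coerce")
    no_data = frozenset(numeric.index[numeric.isna().any(axis=1)])
    tpm = numeric.dropna(how="any").astype(float)
    extra = df[["unigene", "whole_plant", "unspecified_tissue", "other"]]
    return ExpressionTable(
        organs=ORGANS, tpm=numeric, no_data=no_data, extra=extra
    )


def read_annotations_tsv(path: str | Path) -> AnnotationBundle:
    """Read a predictor-annotation TSV: id, signal_cleavage, gpi, ltp_domain,
    storage_like.  Empty/NA cells mean "not predicted"."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("id")

    def _opt_int(v) -> int | None:
        return None if pd.isna(v) or v in ("", "NA", "-") else int(v)

    def _opt_bool(v) -> bool | None:
        if pd.isna(v) or v in ("", "NA", "-"):
            return None
        return v in ("1", "true", "True", "y")

    bundle: AnnotationBundle = {}
    for pid, row in df.iterrows():
        bundle[str(pid)] = Annotation(
            signal_cleavage=_opt_int(row.get("signal_cleavage")),
            gpi_anchor=bool(_opt_bool(row.get("gpi")) or False),
            has_ltp_domain=_opt_bool(row.get("ltp_domain")),
            storage_like=_opt_bool(row.get("storage_like")),
        )
    return bundle


def write_annotations_tsv(bundle: AnnotationBundle, path: str | Path) -> None:
    rows = []
    for pid, ann in bundle.items():
        rows.append(
            {
                "id": pid,
                "signal_cleavage": (
                    "" if ann.signal_cleavage is None else ann.signal_cleavage
                ),
                "gpi": int(ann.gpi_anchor),
                "ltp_domain": (
                    "" if ann.has_ltp_domain is None else int(ann.has_ltp_domain)
                ),
                "storage_like": (
                    "" if ann.storage_like is None else int(ann.storage_like)
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
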