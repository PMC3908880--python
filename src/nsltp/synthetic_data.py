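"""Seeded synthetic-data generators.

Every pipeline stage is testable without downloads: the generators plant
nsLTPs with type-specific spacing signatures among decoy classes shaped
like the proteins the identification cascade removes, chromosome layouts
with planted tandem clusters, EST tables with planted organ-specific
genes, and promoters with planted motif occurrences.  Each generator
returns a machine-readable truth table recording the intended fate of
every planted object; recovery is exact in the noiseless setting.

Background residues inside motif segments are drawn uniformly from the 19
non-cysteine residues — a stray cysteine would corrupt the planted
signature — and signal peptides are built hydrophobic-core-first in the
lengths typical of the family (21-27 aa for the 9-kDa subfamily, 27-35
for the 7-kDa subfamily).  All randomness flows through one
``numpy.random.Generator``; outputs are identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    Annotation,
    AnnotationBundle,
    ORGANS,
    GeneModel,
    ProteinRecord,
)
from .ecm_engine import EcmMatch, SpacingSignature, signature_of
from .identification import CascadeConfig
from .ltp_classifier import LtpType, classify_signature, load_envelopes

NON_CYS = "ADEFGHIKLMNPQRSTVWY"  # the 20 standard residues minus C
_FLANK_ALPHABET = "ADEFIKLMNQRSTVWY"  # additionally P/H/G-free
_HYDROPHOBIC = "AILMFWV"
_POLAR = "STGNQ"

#: Signal-peptide length ranges: 9-kDa subfamily vs 7-kDa subfamily.
SP_RANGE_TYPE1 = (21, 27)
SP_RANGE_TYPE2 = (27, 35)


@dataclass
class SyntheticConfig:
    """Sizes and plans for the proteome generator."""

    n_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"I": 10, "II": 10, "III": 5, "IV": 5,
                                 "V": 5, "VI": 5, "VIII": 5, "IX": 5, "XI": 10}
    )
    n_cys_free: int = 10
    n_signal_less: int = 10
    n_gpi: int = 10
    n_proline_rich: int = 10
    n_storage_like: int = 10
    n_overlength: int = 10
    n_misannotated: int = 0  # rescuable: domain-negative homolog of a reference
    max_mature_length: int = 120


def _seg(rng: np.random.Generator, n: int, alphabet: str = NON_CYS) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n else ""


def _signal_peptide(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    """M + charged-ish stub + hydrophobic core + polar tail, no cysteine."""
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    core_len = max(8, n // 2)
    stub_len = max(1, (n - 1 - core_len) // 2)
    tail_len = n - 1 - stub_len - core_len
    stub = _seg(rng, stub_len, "KRST")
    core = "".join(rng.choice(list(_HYDROPHOBIC), size=core_len))
    tail = _seg(rng, tail_len, _POLAR)
    return "M" + stub + core + tail


def _pick(rng: np.random.Generator, values: Sequence[int]) -> int:
    return int(rng.choice(np.asarray(values)))


def make_ltp(
    ltp_type: str | LtpType,
    rng: np.random.Generator,
    envelopes: dict | None = None,
    max_mature_length: int = 120,
) -> tuple[ProteinRecord, dict]:
    """One planted family member of the requested type.

    Spacings are sampled from the type's admissible envelope; segments are
    cysteine-free so the planted motif is the only valid assignment.
    Returns the precursor record and a truth dict with the mature
    sequence, cleavage site, planted signature and cysteine positions.
    """
    typ = str(LtpType(str(ltp_type)).value)
    envelopes = envelopes or load_envelopes()
    env = envelopes[typ]
    sp_range = SP_RANGE_TYPE2 if typ == "II" else SP_RANGE_TYPE1

    for _ in range(100):
        sig = SpacingSignature(*(_pick(rng, env[k])
                                 for k in ("s1", "s2", "s3", "s4", "s5")))
        nterm = _pick(rng, env["nterm"])
        cterm = _pick(rng, env["cterm"])
        mature_len = nterm + 8 + 1 + sum(sig) + cterm
        if mature_len <= max_mature_length:
            break
    else:  # pragma: no cover - envelopes always admit short members
        raise ValueError(f"cannot satisfy length cap for type {typ}")

    if classify_signature(sig) is not LtpType(typ):  # pragma: no cover
        raise AssertionError("envelope sample escaped its own type")

    # The flank before Cys1 is the region the proline-rich filter inspects;
    # draw it P/H/G-free so planted members sit clearly below the threshold.
    mature = (
        _seg(rng, nterm, _FLANK_ALPHABET) + "C"
        + _seg(rng, sig.s1) + "C" + _seg(rng, sig.s2)
        + "CC" + _seg(rng, sig.s3) + "C" + _seg(rng, 1) + "C"
        + _seg(rng, sig.s4) + "C" + _seg(rng, sig.s5) + "C" + _seg(rng, cterm)
    )
    signal = _signal_peptide(rng, sp_range)
    c1 = nterm
    positions = (
        c1,
        c1 + sig.s1 + 1,
        c1 + sig.s1 + sig.s2 + 2,
        c1 + sig.s1 + sig.s2 + 3,
        c1 + sig.s1 + sig.s2 + sig.s3 + 4,
        c1 + sig.s1 + sig.s2 + sig.s3 + 6,
        c1 + sig.s1 + sig.s2 + sig.s3 + sig.s4 + 7,
        c1 + sig.s1 + sig.s2 + sig.s3 + sig.s4 + sig.s5 + 8,
    )
    assert signature_of(positions) == sig
    record = ProteinRecord(
        id=f"syn_{typ}_{rng.integers(1 << 30)}",
        sequence=signal + mature,
        description=f"synthetic type {typ} nsLTP",
    )
    truth = {
        "type": typ,
        "signature": tuple(sig),
        "cleavage": len(signal),
        "mature": mature,
        "cys_positions": positions,  # 0-based in the mature sequence
    }
    return record, truth


def _mutate(
    rng: np.random.Generator, sequence: str, rate: float, protect_cys: bool = True
) -> str:
    """Point-mutate a fraction of positions (never creating or destroying
    a cysteine when ``protect_cys``)."""
    seq = list(sequence)
    n_mut = int(round(rate * len(seq)))
    sites = rng.choice(len(seq), size=n_mut, replace=False)
    for i in sites:
        if protect_cys and seq[i] == "C":
            continue
        choices = [a for a in NON_CYS if a != seq[i]]
        seq[i] = str(rng.choice(choices))
    return "".join(seq)


@dataclass
class SyntheticProteome:
    records: list[ProteinRecord]
    annotations: AnnotationBundle
    truth: pd.DataFrame  # id, class, expected_fate, expected_stage, type
    references: list[ProteinRecord]
    exclusion_set: list[ProteinRecord]

    def cascade_config(self, **overrides) -> CascadeConfig:
        return CascadeConfig(
            references=self.references,
            exclusion_set=self.exclusion_set,
            **overrides,
        )


def make_proteome(
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticProteome:
    """A shuffled mixture of planted nsLTPs and decoy classes, with
    annotations consistent with construction and a truth table recording
    the intended cascade fate of every protein."""
    config = config or SyntheticConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    envelopes = load_envelopes()

    records: list[ProteinRecord] = []
    annotations: AnnotationBundle = {}
    rows: list[dict] = []

    def add(rec, ann, cls, fate, stage, typ=""):
        records.append(rec)
        annotations[rec.id] = ann
        rows.append({"id": rec.id, "class": cls, "expected_fate": fate,
                     "expected_stage": stage, "type": typ})

    # --- true family members
    for typ, n in config.n_per_type.items():
        for _ in range(n):
            rec, truth = make_ltp(typ, rng, envelopes,
                                  config.max_mature_length)
            add(rec, Annotation(signal_cleavage=truth["cleavage"],
                                has_ltp_domain=True),
                "ltp", "accepted", "", typ)

    # --- decoys, each built to fail exactly one stage
    for _ in range(config.n_cys_free):
        signal = _signal_peptide(rng, SP_RANGE_TYPE1)
        body = _seg(rng, int(rng.integers(60, 100)))
        rec = ProteinRecord(f"dec_cysfree_{rng.integers(1 << 30)}",
                            signal + body, "decoy: no cysteines")
        add(rec, Annotation(signal_cleavage=len(signal), has_ltp_domain=True),
            "cys_free", "removed", "ecm")

    for _ in range(config.n_signal_less):
        ltp, truth = make_ltp("I", rng, envelopes, config.max_mature_length)
        rec = ProteinRecord(f"dec_nosig_{rng.integers(1 << 30)}",
                            truth["mature"], "decoy: no signal peptide")
        add(rec, Annotation(signal_cleavage=None, has_ltp_domain=True),
            "signal_less", "removed", "signal_peptide")

    for _ in range(config.n_gpi):
        ltp, truth = make_ltp("II", rng, envelopes, config.max_mature_length)
        rec = ProteinRecord(f"dec_gpi_{rng.integers(1 << 30)}",
                            ltp.sequence, "decoy: GPI anchored")
        add(rec, Annotation(signal_cleavage=truth["cleavage"],
                            gpi_anchor=True, has_ltp_domain=True),
            "gpi_anchored", "removed", "gpi_anchor")

    for _ in range(config.n_proline_rich):
        ltp, truth = make_ltp("I", rng, envelopes, config.max_mature_length)
        linker = "".join(rng.choice(list("PHG"), size=30))
        signal = _signal_peptide(rng, SP_RANGE_TYPE1)
        rec = ProteinRecord(f"dec_prich_{rng.integers(1 << 30)}",
                            signal + linker + truth["mature"],
                            "decoy: hybrid proline-rich")
        add(rec, Annotation(signal_cleavage=len(signal), has_ltp_domain=True),
            "proline_rich", "removed", "proline_rich")

    # one storage/inhibitor exemplar; decoys are near-identical mutants
    exclusion_set: list[ProteinRecord] = []
    if config.n_storage_like:
        ex_rec, ex_truth = make_ltp("IV", rng, envelopes,
                                    config.max_mature_length)
        exemplar = ProteinRecord("exemplar_storage", ex_rec.sequence,
                                 "synthetic storage-protein exemplar")
        exclusion_set.append(exemplar)
        for _ in range(config.n_storage_like):
            seq = _mutate(rng, exemplar.sequence, rate=0.05)
            rec = ProteinRecord(f"dec_storage_{rng.integers(1 << 30)}",
                                seq, "decoy: storage-like")
            add(rec, Annotation(signal_cleavage=ex_truth["cleavage"],
                                has_ltp_domain=True),
                "storage_like", "removed", "storage_like")

    for _ in range(config.n_overlength):
        ltp, truth = make_ltp("I", rng, envelopes, config.max_mature_length)
        pad = _seg(rng, config.max_mature_length + 20 - len(truth["mature"]))
        signal = _signal_peptide(rng, SP_RANGE_TYPE1)
        rec = ProteinRecord(f"dec_long_{rng.integers(1 << 30)}",
                            signal + truth["mature"] + pad,
                            "decoy: over-length mature protein")
        add(rec, Annotation(signal_cleavage=len(signal), has_ltp_domain=True),
            "overlength", "removed", "mature_length")

    # rescuable proteins: domain-call negative but homologous to a reference
    references: list[ProteinRecord] = []
    if config.n_misannotated:
        ref_rec, ref_truth = make_ltp("I", rng, envelopes,
                                      config.max_mature_length)
        reference = ProteinRecord("reference_ltp", ref_rec.sequence,
                                  "known nsLTP used as rescue query")
        references.append(reference)
        for _ in range(config.n_misannotated):
            # point mutations preserve length, so the cleavage site carries over
            seq = _mutate(rng, reference.sequence, rate=0.1)
            rec = ProteinRecord(f"mis_{rng.integers(1 << 30)}", seq,
                                "misannotated family member")
            add(rec, Annotation(signal_cleavage=ref_truth["cleavage"],
                                has_ltp_domain=False),
                "misannotated", "rescued", "rescue", "I")

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = pd.DataFrame([rows[i] for i in order]).set_index("id")
    return SyntheticProteome(records, annotations, truth,
                             references, exclusion_set)


# ---------------------------------------------------------------------------
# Gene tables, expression tables, promoters


def make_gene_table(
    cluster_plan: Sequence[tuple[str, Sequence[int]]] | None = None,
    n_singletons: int = 10,
    rng: np.random.Generator | None = None,
    max_intervening: int = 5,
) -> tuple[list[GeneModel], list[tuple[str, ...]]]:
    """Chromosome layout with planted tandem clusters.

    ``cluster_plan`` lists (chromosome, intra-cluster intervening-locus
    gaps); a plan entry ("A01", (0, 0, 1)) plants a 4-gene cluster.
    Between planted items the ordinal gap always exceeds the clustering
    bound.  Returns the gene models and the planted cluster memberships.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if cluster_plan is None:
        cluster_plan = [("A01", (0, 0, 1)), ("A02", (2,)), ("A02", (5,))]

    genes: list[GeneModel] = []
    planted: list[tuple[str, ...]] = []
    counter = 0

    by_chrom: dict[str, list[Sequence[int]]] = {}
    for chrom, gaps in cluster_plan:
        by_chrom.setdefault(chrom, []).append(gaps)

    chroms = sorted(by_chrom) or ["A01"]
    for chrom in chroms:
        ordinal = int(rng.integers(1, 50))
        for gaps in by_chrom.get(chrom, []):
            members = []
            for k in range(len(gaps) + 1):
                counter += 1
                gid = f"g{counter:04d}"
                start = ordinal * 10_000 + 1
                genes.append(GeneModel(gid, chrom, start, start + 999,
                                       "+" if rng.random() < 0.5 else "-",
                                       locus_ordinal=ordinal))
                members.append(gid)
                if k < len(gaps):
                    ordinal += gaps[k] + 1
            planted.append(tuple(members))
            ordinal += max_intervening + int(rng.integers(2, 20))
    # singletons, far apart, spread over the chromosomes
    for _ in range(n_singletons):
        counter += 1
        chrom = chroms[counter % len(chroms)]
        base = max((g.locus_ordinal for g in genes if g.chromosome == chrom),
                   default=0)
        ordinal = base + max_intervening + int(rng.integers(2, 20))
        start = ordinal * 10_000 + 1
        genes.append(GeneModel(f"g{counter:04d}", chrom, start, start + 999,
                               "+", locus_ordinal=ordinal))
    return genes, planted


def make_est_table(
    n_single_per_organ: int = 2,
    n_inflorescence: int = 3,
    n_broad: int = 5,
    n_no_data: int = 2,
    library_total: int = 20_000,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, int], pd.Series]:
    """EST count matrix with planted specificity categories.

    Returns (counts, library_totals, truth) where truth maps gene id to
    its planted category string.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows, truth = {}, {}

    def count() -> int:
        return int(rng.integers(3, 80))

    i = 0
    for organ in ORGANS:
        for _ in range(n_single_per_organ):
            i += 1
            gid = f"e{i:03d}"
            rows[gid] = {o: count() if o == organ else 0 for o in ORGANS}
            truth[gid] = f"single-organ:{organ}"
    for _ in range(n_inflorescence):
        i += 1
        gid = f"e{i:03d}"
        rows[gid] = {o: count() if o in ("bud", "flower") else 0
                     for o in ORGANS}
        truth[gid] = "inflorescence"
    for _ in range(n_broad):
        i += 1
        gid = f"e{i:03d}"
        organs_on = rng.choice(ORGANS, size=3, replace=False)
        rows[gid] = {o: count() if o in organs_on else 0 for o in ORGANS}
        truth[gid] = "broad"
    counts = pd.DataFrame.from_dict(rows, orient="index")[list(ORGANS)]
    totals = {o: library_total for o in ORGANS}
    # no-data genes are absent from the numeric matrix by construction
    for _ in range(n_no_data):
        i += 1
        truth[f"e{i:03d}"] = "no-data"
    return counts, totals, pd.Series(truth)


def make_promoter(
    motif: str,
    n_occurrences: int,
    length: int = 2000,
    rng: np.random.Generator | None = None,
    max_tries: int = 200,
) -> str:
    """A promoter of ``length`` bp containing exactly ``n_occurrences``
    matches of ``motif`` (both strands, overlapping counting).

    The background is screened for accidental hits and regenerated until
    the planted count is exact.
    """
    from .cre_scanner import count_cre

    rng = rng if rng is not None else np.random.default_rng(0)
    m = len(motif)
    for _ in range(max_tries):
        seq = list("".join(rng.choice(list("ACGT"), size=length)))
        starts = sorted(rng.choice(length - m * n_occurrences - n_occurrences,
                                   size=n_occurrences, replace=False)
                        + np.arange(n_occurrences) * (m + 1))
        for s in starts:
            realized = "".join(
                str(rng.choice(list(_iupac_choices(code)))) for code in motif
            )
            seq[s : s + m] = realized
        out = "".join(seq)
        if count_cre(out, motif) == n_occurrences:
            return out
    raise RuntimeError(
        f"could not plant exactly {n_occurrences} x {motif} in {length} bp"
    )


def _iupac_choices(code: str) -> str:
    from .cre_scanner import IUPAC

    return IUPAC[code.upper()]
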