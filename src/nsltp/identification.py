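"""The identification cascade: from a candidate proteome to an accepted
nsLTP set with a per-protein audit trail.

Stages, in order:

1. ``ecm``            — a valid eight-cysteine motif must be present;
2. ``signal_peptide`` — an N-terminal signal sequence is required;
3. ``gpi_anchor``     — GPI-anchored proteins are excluded;
4. ``proline_rich``   — proteins whose signal-to-motif linker is rich in
   Pro/His/Gly (proline-rich and hybrid proline-rich proteins) are removed;
5. ``ltp_domain``     — proteins positively annotated as lacking the
   lipid-transfer domain are removed;
6. ``storage_like``   — proteins aligning to seed-storage / trypsin-alpha-
   amylase-inhibitor exemplars above threshold are removed;
7. ``mature_length``  — mature proteins longer than the cap are removed;
8. ``rescue``         — removed proteins that align strongly to known
   nsLTP references and still pass stages 1-4 and 7 are re-admitted
   (recovers family members lost to mis-annotation).

External predictors (signal peptide, GPI, domain) are *not* reimplemented;
their verdicts enter via the annotation bundle.  A lower-fidelity
hydrophobic-core heuristic can stand in for missing signal-peptide calls
in annotation-free runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .data_model import Annotation, AnnotationBundle, ProteinRecord
from .ecm_engine import DEFAULT_GAP_BOUNDS, EcmMatch, find_ecm
from .protein_features import phg_fraction

STAGES = (
    "ecm",
    "signal_peptide",
    "gpi_anchor",
    "proline_rich",
    "ltp_domain",
    "storage_like",
    "mature_length",
    "rescue",
)

# Hydrophobic residues for the fallback signal-peptide heuristic.
_HYDROPHOBIC = set("AILMFWVC")


@dataclass
class CascadeConfig:
    """Thresholds and reference sets for the cascade.

    ``rescue_min_score`` is a raw local-alignment score; the default maps a
    BLASTP expectation cutoff of 1e-3 through Karlin-Altschul statistics
    (gapped BLOSUM62: lambda = 0.267, K = 0.041, search space ~1e7).
    ``storage_min_score`` is a declared constant — the survey states no
    threshold for the storage/inhibitor exclusion.  The identity rescue
    route requires at least ``rescue_min_cols`` aligned columns so that
    short, chance local alignments cannot rescue.
    """

    max_mature_length: int = 120
    phg_threshold: float = 0.35
    rescue_min_score: float = 75.0
    rescue_min_identity: float = 0.5
    rescue_min_cols: int = 50
    storage_min_score: float = 100.0
    gap_bounds: dict = field(default_factory=lambda: dict(DEFAULT_GAP_BOUNDS))
    references: Sequence[ProteinRecord] = ()
    exclusion_set: Sequence[ProteinRecord] = ()
    fallback_signal_heuristic: bool = False


@dataclass
class FilterTrace:
    """Audit trail: per-protein stage verdicts and per-stage in/out counts."""

    verdicts: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    stage_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def record(self, pid: str, stage: str, verdict: str, reason: str) -> None:
        self.verdicts.setdefault(pid, []).append((stage, verdict, reason))

    def terminal(self, pid: str) -> tuple[str, str, str]:
        return self.verdicts[pid][-1]

    def removed_at(self, pid: str) -> str | None:
        for stage, verdict, _ in self.verdicts.get(pid, []):
            if verdict == "removed":
                return stage
        return None


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def local_alignment_stats(
    aligner: Align.PairwiseAligner, query: str, target: str
) -> tuple[float, float, int]:
    """(score, identity over aligned columns, aligned column count) of the
    best local alignment."""
    alignments = aligner.align(query, target)
    if len(alignments) == 0:
        return 0.0, 0.0, 0
    aln = alignments[0]
    matches = 0
    cols = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        cols += qe - qs
        matches += sum(
            1 for a, b in zip(query[qs:qe], target[ts:te]) if a == b
        )
    identity = matches / cols if cols else 0.0
    return float(aln.score), identity, cols


def fallback_signal_cleavage(sequence: str) -> int | None:
    """Heuristic signal-peptide call: hydrophobic-core scan in the first
    40 residues.  Lower fidelity than a dedicated predictor; used only when
    annotations are absent and the fallback is enabled.

    Looks for an 8-residue window with >= 6 hydrophobic residues within the
    first 30 positions and places the cleavage 5 residues after the core.
    """
    head = sequence[:40]
    for i in range(0, min(len(head) - 8, 30)):
        window = head[i : i + 8]
        if sum(ch in _HYDROPHOBIC for ch in window) >= 6:
            site = min(i + 8 + 5, len(sequence) - 1)
            return site if site >= 5 else None
    return None


def similarity_rescue(
    pool: Sequence[ProteinRecord],
    references: Sequence[ProteinRecord],
    config: CascadeConfig | None = None,
) -> set[str]:
    """Ids of pool members aligning to any reference above threshold.

    A member is rescued when its best local alignment to a reference has
    score >= ``rescue_min_score``, or identity >= ``rescue_min_identity``
    over at least ``rescue_min_cols`` aligned columns.
    """
    config = config or CascadeConfig()
    if not references:
        return set()
    aligner = _protein_aligner()
    rescued: set[str] = set()
    for rec in pool:
        for ref in references:
            score, identity, cols = local_alignment_stats(
                aligner, rec.sequence, ref.sequence
            )
            if score >= config.rescue_min_score or (
                identity >= config.rescue_min_identity
                and cols >= config.rescue_min_cols
            ):
                rescued.add(rec.id)
                break
    return rescued


@dataclass
class CascadeResult:
    accepted: list[ProteinRecord]
    trace: FilterTrace
    matches: dict[str, EcmMatch]
    cleavages: dict[str, int]

    @property
    def accepted_ids(self) -> list[str]:
        return [r.id for r in self.accepted]


def _stage_checks(
    rec: ProteinRecord,
    ann: Annotation,
    config: CascadeConfig,
    storage_aligner: Align.PairwiseAligner | None,
) -> tuple[dict[str, tuple[bool, str]], EcmMatch | None, int | None]:
    """Evaluate every stage predicate for one protein.

    Returns ({stage: (passes, reason)}, ecm match, cleavage site).
    """
    checks: dict[str, tuple[bool, str]] = {}

    match = find_ecm(rec.sequence, config.gap_bounds)
    checks["ecm"] = (match is not None, "no valid eight-cysteine motif")

    cleavage = ann.signal_cleavage
    if cleavage is None and config.fallback_signal_heuristic:
        cleavage = fallback_signal_cleavage(rec.sequence)
    checks["signal_peptide"] = (
        cleavage is not None,
        "no N-terminal signal sequence",
    )

    checks["gpi_anchor"] = (not ann.gpi_anchor, "C-terminal GPI anchor")

    if match is not None and cleavage is not None:
        linker = rec.sequence[cleavage : match.cys_positions[0]]
        frac = phg_fraction(linker)
        checks["proline_rich"] = (
            frac < config.phg_threshold,
            f"Pro/His/Gly fraction {frac:.2f} in signal-to-motif linker",
        )
    else:
        checks["proline_rich"] = (True, "")

    checks["ltp_domain"] = (
        ann.has_ltp_domain is not False,
        "no lipid-transfer domain",
    )

    storage = ann.storage_like is True
    if not storage and storage_aligner is not None:
        for ex in config.exclusion_set:
            score, _, _ = local_alignment_stats(
                storage_aligner, rec.sequence, ex.sequence
            )
            if score >= config.storage_min_score:
                storage = True
                break
    checks["storage_like"] = (
        not storage,
        "similar to storage protein / protease-inhibitor exemplar",
    )

    if cleavage is not None:
        mature_len = len(rec.sequence) - cleavage
    else:
        mature_len = len(rec.sequence)
    checks["mature_length"] = (
        mature_len <= config.max_mature_length,
        f"mature length {mature_len} > {config.max_mature_length}",
    )

    return checks, match, cleavage


def run_cascade(
    proteome: Sequence[ProteinRecord],
    annotations: AnnotationBundle | None = None,
    config: CascadeConfig | None = None,
) -> CascadeResult:
    """Run the full cascade over a proteome.

    Every input protein receives a terminal verdict; stage counts conserve
    totals.  Proteins removed at stage k are not re-examined by later
    stages except by the final similarity rescue.
    """
    config = config or CascadeConfig()
    annotations = annotations or {}
    storage_aligner = _protein_aligner() if config.exclusion_set else None

    trace = FilterTrace()
    matches: dict[str, EcmMatch] = {}
    cleavages: dict[str, int] = {}
    all_checks: dict[str, dict[str, tuple[bool, str]]] = {}
    survivors: list[ProteinRecord] = []
    removed: list[ProteinRecord] = []

    for rec in proteome:
        ann = annotations.get(rec.id, Annotation())
        checks, match, cleavage = _stage_checks(rec, ann, config, storage_aligner)
        all_checks[rec.id] = checks
        if match is not None:
            matches[rec.id] = match
        if cleavage is not None:
            cleavages[rec.id] = cleavage

    pool = list(proteome)
    for stage in STAGES[:-1]:
        next_pool = []
        for rec in pool:
            passed, reason = all_checks[rec.id][stage]
            if passed:
                trace.record(rec.id, stage, "pass", "")
                next_pool.append(rec)
            else:
                trace.record(rec.id, stage, "removed", reason)
                removed.append(rec)
        trace.stage_counts[stage] = (len(pool), len(next_pool))
        pool = next_pool
    survivors = pool

    # Stage 8: similarity rescue over everything previously removed.
    rescued_ids = set()
    if config.references:
        candidates = [
            rec
            for rec in removed
            if all(
                all_checks[rec.id][st][0]
                for st in ("ecm", "signal_peptide", "gpi_anchor",
                           "proline_rich", "mature_length")
            )
        ]
        rescued_ids = similarity_rescue(candidates, config.references, config)
        for rec in removed:
            if rec.id in rescued_ids:
                trace.record(rec.id, "rescue", "rescued",
                             "aligns to reference nsLTP")
                survivors.append(rec)
    trace.stage_counts["rescue"] = (
        len(removed),
        len(rescued_ids),
    )

    order = {rec.id: i for i, rec in enumerate(proteome)}
    survivors.sort(key=lambda r: order[r.id])
    return CascadeResult(
        accepted=survivors, trace=trace, matches=matches, cleavages=cleavages
    )
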