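"""Per-protein descriptors: precursor split, average molecular mass,
Cys-excluded isoelectric point, conserved pentapeptide motifs, the CXC
X-residue class, tryptophan presence and the Pro/His/Gly fraction.

The mass is the average (not monoisotopic) mass of the free mature
peptide.  The isoelectric point uses a Bjellqvist-style pKa table — the
constants behind the common web calculators — and, following the survey's
convention, cysteine side chains are excluded from the charge model by
default (family members are cystine-crosslinked, so free thiol charges
are not physical).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.SeqUtils import molecular_weight

from .data_model import AMINO_ACIDS, ProteinRecord
from .ecm_engine import EcmMatch

# Bjellqvist-style side-chain and terminal pKa values.
PKA_POSITIVE = {"Nterm": 7.50, "K": 10.00, "R": 12.00, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00}

#: Hydropathy classes of the residue between Cys5 and Cys6, as observed in
#: the family (the eleven residues seen at that position), with a standard
#: Kyte-Doolittle fallback for residues outside the observed set.
CXC_HYDROPHOBIC = set("YLFVIAG")
CXC_HYDROPHILIC = set("RKEQ")
_KD_HYDROPHOBIC = set("AVLIMFWCY")  # fallback classes


@dataclass
class FeatureReport:
    sp_length: int
    mp_length: int
    mm: float
    pi: float
    motif_tssdrk: bool
    motif_pyxis: bool
    cxc_x: str | None
    cxc_class: str | None
    has_trp: bool
    phg_fraction: float


def split_precursor(record: ProteinRecord, cleavage_site: int) -> tuple[str, str]:
    """Split a precursor at the signal-peptide cleavage site.

    ``cleavage_site`` is the 1-based index of the last signal residue;
    returns (signal peptide, mature protein).
    """
    if not 1 <= cleavage_site < len(record.sequence):
        raise ValueError(
            f"{record.id}: cleavage site {cleavage_site} outside "
            f"[1, {len(record.sequence)})"
        )
    return record.sequence[:cleavage_site], record.sequence[cleavage_site:]


def average_mass(sequence: str) -> float:
    """Average molecular mass in Da of a free peptide (one water included)."""
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-standard residues for mass: {sorted(bad)!r}")
    if not sequence:
        return 18.0153
    return float(
        molecular_weight(sequence, seq_type="protein", monoisotopic=False)
    )


def net_charge(sequence: str, ph: float, excluded: Iterable[str] = ("C",)) -> float:
    """Henderson-Hasselbalch net charge at ``ph``.

    Residues in ``excluded`` contribute no side-chain charge; termini are
    free.
    """
    excluded = set(excluded)
    pos = {"Nterm": 1}
    neg = {"Cterm": 1}
    for aa in sequence:
        if aa in excluded:
            continue
        if aa in PKA_POSITIVE:
            pos[aa] = pos.get(aa, 0) + 1
        elif aa in PKA_NEGATIVE:
            neg[aa] = neg.get(aa, 0) + 1
    charge = 0.0
    for grp, n in pos.items():
        charge += n / (1.0 + 10.0 ** (ph - PKA_POSITIVE[grp]))
    for grp, n in neg.items():
        charge -= n / (1.0 + 10.0 ** (PKA_NEGATIVE[grp] - ph))
    return charge


def isoelectric_point(
    sequence: str, excluded: Iterable[str] = ("C",), tol: float = 1e-3
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge curve is strictly decreasing in pH, so bisection converges
    to the unique zero.
    """
    excluded = tuple(excluded)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid, excluded) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 3)


def scan_pentapeptides(mature: str) -> tuple[bool, bool, dict[str, list[int]]]:
    """Scan for the two conserved pentapeptides of the 9-kDa subfamily:
    Thr/Ser-X-X-Asp-Arg/Lys and Pro-Tyr-X-Ile-Ser.

    Returns (tssdrk_present, pyxis_present, 0-based match positions).
    X positions match any standard residue but not the unknown residue X.
    """
    hits: dict[str, list[int]] = {"tssdrk": [], "pyxis": []}
    for i in range(len(mature) - 4):
        w = mature[i : i + 5]
        if any(ch not in AMINO_ACIDS for ch in w):
            continue
        if w[0] in "TS" and w[3] == "D" and w[4] in "RK":
            hits["tssdrk"].append(i)
        if w[0] == "P" and w[1] == "Y" and w[3] == "I" and w[4] == "S":
            hits["pyxis"].append(i)
    return bool(hits["tssdrk"]), bool(hits["pyxis"]), hits


def cxc_x_class(match: EcmMatch, mature: str) -> tuple[str, str]:
    """Residue between Cys5 and Cys6 and its hydropathy class."""
    residue = mature[match.cxc_x_position]
    if residue in CXC_HYDROPHOBIC:
        cls = "hydrophobic"
    elif residue in CXC_HYDROPHILIC:
        cls = "hydrophilic"
    else:
        cls = "hydrophobic" if residue in _KD_HYDROPHOBIC else "hydrophilic"
    return residue, cls


def phg_fraction(region: str) -> float:
    """Fraction of Pro+His+Gly in a region (0 for an empty region).

    High values in the stretch between the signal peptide and the first
    motif cysteine mark proline-rich / hybrid proline-rich proteins, which
    the identification cascade removes.
    """
    if not region:
        return 0.0
    return sum(region.count(a) for a in "PHG") / len(region)


def feature_report(
    record: ProteinRecord, cleavage_site: int, match: EcmMatch | None = None
) -> FeatureReport:
    """Full descriptor set for one precursor.

    ``match``, when given, must be located in *mature* coordinates (i.e.
    produced from the sequence downstream of the cleavage site).
    """
    signal, mature = split_precursor(record, cleavage_site)
    tssdrk, pyxis, _ = scan_pentapeptides(mature)
    if match is not None:
        residue, cls = cxc_x_class(match, mature)
        linker = mature[: match.cys_positions[0]]
    else:
        residue, cls = None, None
        linker = ""
    return FeatureReport(
        sp_length=len(signal),
        mp_length=len(mature),
        mm=average_mass(mature),
        pi=isoelectric_point(mature),
        motif_tssdrk=tssdrk,
        motif_pyxis=pyxis,
        cxc_x=residue,
        cxc_class=cls,
        has_trp="W" in mature,
        phg_fraction=phg_fraction(linker),
    )
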