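"""Eight-cysteine motif (ECM) detection.

The hallmark of plant non-specific lipid transfer proteins is the motif

    C-Xs1-C-Xs2-CC-Xs3-CXC-Xs4-C-Xs5-C

eight cysteines with the third and fourth adjacent (CC), the fifth and
sixth separated by exactly one residue (CXC), and five variable inter-
cysteine gaps whose lengths — the spacing signature (s1..s5) — diagnose
the nsLTP type.  The motif is a subsequence pattern: residues inside the
gaps are unconstrained and additional cysteines outside the chosen eight
are permitted.

When a sequence admits more than one valid assignment of eight cysteines,
:func:`find_ecm` applies a deterministic selection rule: prefer an
assignment whose signature classifies to a named type, then the leftmost
first cysteine, then the smallest total span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, NamedTuple

#: Default per-gap (min, max) bounds: the envelope of all observed family
#: spacings, widened with margin.  Configurable per call.
DEFAULT_GAP_BOUNDS: dict[str, tuple[int, int]] = {
    "s1": (3, 20),
    "s2": (8, 25),
    "s3": (5, 35),
    "s4": (8, 35),
    "s5": (3, 25),
}


class SpacingSignature(NamedTuple):
    """The five inter-cysteine gap lengths of an ECM."""

    s1: int
    s2: int
    s3: int
    s4: int
    s5: int

    def to_ecm_string(self) -> str:
        return (
            f"C-X{self.s1}-C-X{self.s2}-CC-X{self.s3}"
            f"-CXC-X{self.s4}-C-X{self.s5}-C"
        )


@dataclass(frozen=True)
class EcmMatch:
    """A located ECM: the eight 0-based cysteine indices, the signature,
    and the flank lengths before Cys1 / after Cys8."""

    cys_positions: tuple[int, int, int, int, int, int, int, int]
    signature: SpacingSignature
    nterm_flank: int
    cterm_tail: int

    @property
    def cxc_x_position(self) -> int:
        """Index of the single residue between Cys5 and Cys6."""
        return self.cys_positions[4] + 1


def _within(bounds: dict[str, tuple[int, int]], sig: SpacingSignature) -> bool:
    return all(
        bounds[k][0] <= v <= bounds[k][1] for k, v in zip(sig._fields, sig)
    )


def signature_of(positions: tuple[int, ...]) -> SpacingSignature:
    """Gap lengths implied by eight cysteine positions (adjacency assumed)."""
    c1, c2, c3, c4, c5, c6, c7, c8 = positions
    return SpacingSignature(
        c2 - c1 - 1, c3 - c2 - 1, c5 - c4 - 1, c7 - c6 - 1, c8 - c7 - 1
    )


def enumerate_ecm_candidates(
    sequence: str,
    gap_bounds: dict[str, tuple[int, int]] | None = None,
) -> list[EcmMatch]:
    """All valid eight-cysteine assignments in ``sequence``.

    Enumerates CC dyads and downstream CXC triads, then extends left to
    (Cys1, Cys2) and right to (Cys7, Cys8) under the gap bounds.
    """
    bounds = gap_bounds or DEFAULT_GAP_BOUNDS
    cys = [i for i, ch in enumerate(sequence) if ch == "C"]
    if len(cys) < 8:
        return []
    cys_set = set(cys)
    lo, hi = {k: b[0] for k, b in bounds.items()}, {k: b[1] for k, b in bounds.items()}

    matches: list[EcmMatch] = []
    # (c3, c4): adjacent CC
    for c3 in cys:
        c4 = c3 + 1
        if c4 not in cys_set:
            continue
        # (c1, c2) upstream with gaps s1, s2
        uppairs = []
        for c2 in cys:
            if not (lo["s2"] <= c3 - c2 - 1 <= hi["s2"]):
                continue
            for c1 in cys:
                if c1 >= c2:
                    break
                if lo["s1"] <= c2 - c1 - 1 <= hi["s1"]:
                    uppairs.append((c1, c2))
        if not uppairs:
            continue
        # (c5, c6): CXC downstream of the dyad with gap s3
        for c5 in cys:
            if c5 <= c4:
                continue
            if not (lo["s3"] <= c5 - c4 - 1 <= hi["s3"]):
                continue
            c6 = c5 + 2
            if c6 not in cys_set:
                continue
            # (c7, c8) downstream with gaps s4, s5
            for c7 in cys:
                if c7 <= c6 or not (lo["s4"] <= c7 - c6 - 1 <= hi["s4"]):
                    continue
                for c8 in cys:
                    if c8 <= c7:
                        continue
                    if lo["s5"] <= c8 - c7 - 1 <= hi["s5"]:
                        for c1, c2 in uppairs:
                            pos = (c1, c2, c3, c4, c5, c6, c7, c8)
                            matches.append(
                                EcmMatch(
                                    cys_positions=pos,
                                    signature=signature_of(pos),
                                    nterm_flank=c1,
                                    cterm_tail=len(sequence) - c8 - 1,
                                )
                            )
    return matches


def find_ecm(
    sequence: str,
    gap_bounds: dict[str, tuple[int, int]] | None = None,
    prefer_named: Callable[[SpacingSignature], bool] | None = None,
) -> EcmMatch | None:
    """Locate the ECM in a mature sequence, or return ``None``.

    ``prefer_named`` is a predicate marking signatures that classify to a
    named nsLTP type; such assignments are preferred.  By default the
    package classifier is used.  Ties break to the leftmost Cys1, then the
    smallest total span, then lexicographic position order — the match is
    therefore a deterministic function of the inputs.
    """
    candidates = enumerate_ecm_candidates(sequence, gap_bounds)
    if not candidates:
        return None
    if prefer_named is None:
        from .ltp_classifier import classifies_to_named_type as prefer_named

    def key(m: EcmMatch):
        span = m.cys_positions[-1] - m.cys_positions[0]
        return (not prefer_named(m.signature), m.cys_positions[0], span,
                m.cys_positions)

    return min(candidates, key=key)


_ECM_RE = re.compile(
    r"^C-X(\d+)-C-X(\d+)-CC-X(\d+)-CXC-X(\d+)-C-X(\d+)-C$"
)


def signature_from_ecm_string(text: str) -> SpacingSignature:
    """Parse a ``C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C`` notation string.

    Underscore/markup decorations around the subscripts are tolerated.
    """
    cleaned = re.sub(r"[_*\s]", "", text)
    m = _ECM_RE.match(cleaned)
    if not m:
        raise ValueError(f"malformed ECM notation: {text!r}")
    return SpacingSignature(*(int(g) for g in m.groups()))
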