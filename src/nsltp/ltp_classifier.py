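"""Spacing-based nsLTP type assignment.

Each family member's spacing signature (s1..s5) is mapped to one of the
named nsLTP types by an ordered decision tree.  The gap between the CC
dyad and the CXC triad (s3) dominates: a protein with s3 = 19 is type I
even when its other gaps resemble type XI (the family contains exactly
such a member), and s3 = 13 defines the type XI group.  The remaining
rules apply each type's single diagnostic gap value, and types IV and VI,
which have no single diagnostic, are resolved by envelope membership.
The rule order is the minimal ordered set consistent with the complete
63-member reference inventory.

Signatures matching no rule are ``UNCLASSIFIED``; the inventory layer
reports such proteins as candidate nsLTP-Y members when they survived the
full identification cascade (the Y group is defined residually).
"""

from __future__ import annotations

from collections import Counter
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .ecm_engine import SpacingSignature


class LtpType(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"
    IX = "IX"
    XI = "XI"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Types a signature can be positively assigned to.
NAMED_TYPES = tuple(t for t in LtpType if t is not LtpType.UNCLASSIFIED)


def classify_signature(sig: SpacingSignature) -> LtpType:
    """Assign an nsLTP type from a spacing signature.

    Rules are evaluated in order; the first hit wins.  Totality: every
    signature maps to exactly one label.
    """
    s1, s2, s3, s4, s5 = sig
    if s3 == 19:
        return LtpType.I
    if s1 == 7:
        return LtpType.II
    if s1 == 14:
        return LtpType.V
    if s1 == 13:
        return LtpType.IX
    if s3 == 13:
        return LtpType.XI
    if s4 == 12:
        return LtpType.III
    if s4 == 27:
        return LtpType.VII
    if s1 == 6 and s4 == 25:
        return LtpType.VIII
    if s1 == 10 and s2 in (16, 17):
        return LtpType.VI
    if s3 in (9, 12) and s1 in (9, 10):
        return LtpType.IV
    return LtpType.UNCLASSIFIED


def classifies_to_named_type(sig: SpacingSignature) -> bool:
    return classify_signature(sig) is not LtpType.UNCLASSIFIED


def classify_inventory(
    signatures: Mapping[str, SpacingSignature] | Sequence[SpacingSignature],
) -> tuple[dict, Counter]:
    """Classify a collection of signatures.

    Returns (labels, counts): per-entry labels keyed like the input, and a
    Counter of per-type totals.  ``UNCLASSIFIED`` entries are counted under
    their own key.
    """
    if isinstance(signatures, Mapping):
        items = signatures.items()
    else:
        items = enumerate(signatures)
    labels = {k: classify_signature(s) for k, s in items}
    return labels, Counter(labels.values())


# ---------------------------------------------------------------------------
# Envelope configuration (per-type admissible spacing sets)


def load_envelopes(path: str | Path | None = None) -> dict[str, dict]:
    """Load per-type admissible spacing sets (s1..s5, flanks, diagnostic).

    The packaged default mirrors the reference family; pass ``path`` to
    override for another genome.
    """
    if path is None:
        path = Path(str(resources.files("nsltp").joinpath("data", "envelopes.yaml")))
    with open(path) as fh:
        env = yaml.safe_load(fh)
    for typ, spec in env.items():
        diag = spec.get("diagnostic")
        if diag is not None and diag["value"] not in spec[diag["gap"]]:
            raise ValueError(f"type {typ}: diagnostic value outside envelope")
    return env


def envelope_signatures(envelope: dict) -> Iterable[SpacingSignature]:
    """All signatures in the product of one type's admissible gap sets."""
    from itertools import product

    for s in product(*(envelope[k] for k in ("s1", "s2", "s3", "s4", "s5"))):
        yield SpacingSignature(*s)
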