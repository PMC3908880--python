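"""Inventory report assembly.

Joins the accepted proteins with their features, gene models and type
labels into a family inventory mirroring the survey's published layout:
one row per member with an auto-assigned name ``<prefix><Type>.<index>``
(indices consecutive from 1 in locus order within each type), locus,
chromosome, coordinates, strand, intron lengths, ECM string, signal/
mature lengths, mass, pI and type.  Unclassified survivors of the full
cascade are reported as candidate Y members, named last.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .data_model import GeneModel
from .ecm_engine import EcmMatch
from .ltp_classifier import LtpType
from .protein_features import FeatureReport

_TYPE_ORDER = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "XI", "Y"]


def build_inventory(
    accepted_ids: list[str],
    matches: Mapping[str, EcmMatch],
    features: Mapping[str, FeatureReport],
    gene_models: Mapping[str, GeneModel],
    labels: Mapping[str, LtpType],
    prefix: str = "nsLtp",
) -> pd.DataFrame:
    """Joined inventory table for the accepted set.

    All inputs must cover every accepted id; orphans raise with the full
    list of missing keys.
    """
    orphans = [
        pid
        for pid in accepted_ids
        if pid not in matches or pid not in features
        or pid not in gene_models or pid not in labels
    ]
    if orphans:
        raise KeyError(f"ids missing from joined inputs: {orphans}")

    # Name within each type by locus order (ordinal, else position).
    def type_key(pid: str) -> str:
        lab = labels[pid]
        return "Y" if lab is LtpType.UNCLASSIFIED else lab.value

    def locus_key(pid: str):
        gm = gene_models[pid]
        return gm.locus_ordinal if gm.locus_ordinal is not None else gm.start

    rows = []
    for typ in _TYPE_ORDER:
        members = sorted(
            (pid for pid in accepted_ids if type_key(pid) == typ),
            key=locus_key,
        )
        for idx, pid in enumerate(members, start=1):
            gm, fr, m = gene_models[pid], features[pid], matches[pid]
            rows.append(
                {
                    "name": f"{prefix}{typ}.{idx}",
                    "id": pid,
                    "locus": gm.id,
                    "chromosome": gm.chromosome,
                    "start": gm.start,
                    "end": gm.end,
                    "strand": gm.strand,
                    "ecm": m.signature.to_ecm_string(),
                    "sp_len": fr.sp_length,
                    "mp_len": fr.mp_length,
                    "mm": round(fr.mm, 2),
                    "pi": round(fr.pi, 2),
                    "type": typ,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["name", "id", "locus", "chromosome", "start", "end",
                 "strand", "ecm", "sp_len", "mp_len", "mm", "pi", "type"],
    )
    assert df["name"].is_unique
    return df


def summary_counts(inventory: pd.DataFrame) -> dict[str, int]:
    counts = inventory["type"].value_counts().to_dict()
    counts["total"] = int(len(inventory))
    return counts
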