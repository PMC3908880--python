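"""Per-protein descriptors: masses, Cys-excluded pI against a dense-grid
oracle, pentapeptide motifs, CXC residue class, linker composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nsltp.data_model import ProteinRecord
from nsltp.ecm_engine import find_ecm
from nsltp.protein_features import (
    average_mass,
    cxc_x_class,
    feature_report,
    isoelectric_point,
    net_charge,
    phg_fraction,
    scan_pentapeptides,
    split_precursor,
)

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40)


class TestSplit:
    def test_splits_at_cleavage(self):
        rec = ProteinRecord("p", "M" + "A" * 127)
        sp, mp = split_precursor(rec, 25)
        assert (len(sp), len(mp)) == (25, 103)
        assert sp + mp == rec.sequence

    @pytest.mark.parametrize("site", [0, 128, 200])
    def test_out_of_range_cleavage_rejected(self, site):
        rec = ProteinRecord("p", "M" + "A" * 127)
        with pytest.raises(ValueError):
            split_precursor(rec, site)


class TestMass:
    def test_water_only(self):
        assert average_mass("") == pytest.approx(18.0153, abs=0.01)

    def test_single_glycine(self):
        assert average_mass("G") == pytest.approx(75.07, abs=0.01)

    def test_rejects_unknown_residue(self):
        with pytest.raises(ValueError):
            average_mass("GX")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(peptides, peptides)
    def test_additivity_up_to_one_water(self, a, b):
        assert average_mass(a + b) == pytest.approx(
            average_mass(a) + average_mass(b) - 18.0153, abs=0.01
        )


def grid_pi(sequence, excluded=("C",), step=1e-4):
    """Dense pH-grid zero of the Henderson-Hasselbalch charge curve,
    recomputed directly from the pKa tables (independent oracle)."""
    from nsltp.protein_features import PKA_NEGATIVE, PKA_POSITIVE

    grid = np.arange(0.0, 14.0 + step, step)
    charge = np.zeros_like(grid)
    charge += 1.0 / (1.0 + 10.0 ** (grid - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["Cterm"] - grid))
    for aa in sequence:
        if aa in excluded:
            continue
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (grid - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - grid))
    return float(grid[int(np.argmin(np.abs(charge)))])


class TestIsoelectricPoint:
    def test_glycine_tetramer_matches_terminal_midpoint(self):
        # no side chains: zero charge at the midpoint of the terminal pKas
        assert isoelectric_point("GGGG") == pytest.approx(
            (7.50 + 3.55) / 2, abs=2e-3
        )
        assert isoelectric_point("GGGG") == pytest.approx(
            grid_pi("GGGG"), abs=2e-3
        )

    def test_cysteine_excluded_by_default(self):
        assert isoelectric_point("CCCC") == pytest.approx(
            isoelectric_point("GGGG"), abs=2e-3
        )
        # with Cys charges included the protein is more acidic
        assert isoelectric_point("CCCC", excluded=()) < isoelectric_point("CCCC")

    def test_adding_lysine_never_decreases_pi(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=15))
            assert isoelectric_point("K" + seq) >= isoelectric_point(seq) - 1e-9

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(peptides)
    def test_bisection_agrees_with_grid_oracle(self, seq):
        assert isoelectric_point(seq) == pytest.approx(grid_pi(seq), abs=2e-3)


class TestPentapeptides:
    @pytest.mark.parametrize(
        "seq,tssdrk,pyxis",
        [
            ("AATAADRAA", True, False),
            ("PYLIS", False, True),
            ("TLLDKXXPYAIS", True, True),
            ("AAAAA", False, False),
            ("TXXDR", False, False),  # unknown residue matches no class
        ],
    )
    def test_window_detection(self, seq, tssdrk, pyxis):
        got_t, got_p, _ = scan_pentapeptides(seq)
        assert (got_t, got_p) == (tssdrk, pyxis)

    def test_positions_reported(self):
        _, _, hits = scan_pentapeptides("GGSAADKGG")
        assert hits["tssdrk"] == [2]


class TestCxcClass:
    @pytest.mark.parametrize(
        "x,expected",
        [("L", "hydrophobic"), ("Y", "hydrophobic"), ("R", "hydrophilic"),
         ("Q", "hydrophilic"), ("N", "hydrophilic")],  # N via fallback
    )
    def test_residue_class(self, x, expected):
        seq = ("A" * 4 + "C" + "A" * 9 + "C" + "A" * 13 + "CC" + "A" * 19
               + "C" + x + "C" + "A" * 22 + "C" + "A" * 13 + "C" + "AAAA")
        match = find_ecm(seq)
        residue, cls = cxc_x_class(match, seq)
        assert residue == x and cls == expected


class TestPhgFraction:
    @pytest.mark.parametrize(
        "region,expected", [("PPPP", 1.0), ("AAAA", 0.0), ("PHGA", 0.75), ("", 0.0)]
    )
    def test_fraction(self, region, expected):
        assert phg_fraction(region) == pytest.approx(expected)


def test_feature_report_joins_everything():
    mature = ("A" * 4 + "C" + "A" * 9 + "C" + "A" * 13 + "CC" + "A" * 19
              + "C" + "L" + "C" + "A" * 20 + "TAADR" + "C" + "A" * 13 + "C")
    rec = ProteinRecord("p", "M" + "L" * 21 + mature)
    match = find_ecm(mature)
    fr = feature_report(rec, 22, match)
    assert fr.sp_length == 22 and fr.mp_length == len(mature)
    assert fr.sp_length + fr.mp_length == len(rec.sequence)
    assert fr.motif_tssdrk and not fr.motif_pyxis
    assert fr.cxc_x == "L" and fr.cxc_class == "hydrophobic"
    assert not fr.has_trp
    assert fr.mm > 0
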