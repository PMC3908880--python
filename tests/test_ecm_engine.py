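"""Eight-cysteine-motif detection: examples, planted round-trips, and an
exhaustive brute-force oracle."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nsltp.ecm_engine import (
    DEFAULT_GAP_BOUNDS,
    SpacingSignature,
    enumerate_ecm_candidates,
    find_ecm,
    signature_from_ecm_string,
    signature_of,
)
from nsltp.synthetic_data import NON_CYS, make_ltp
from nsltp.ltp_classifier import NAMED_TYPES, LtpType


def brute_force_has_ecm(sequence, gap_bounds=DEFAULT_GAP_BOUNDS):
    """Independent oracle: test every 8-subset of cysteine positions."""
    cys = [i for i, ch in enumerate(sequence) if ch == "C"]
    for combo in combinations(cys, 8):
        c1, c2, c3, c4, c5, c6, c7, c8 = combo
        if c4 != c3 + 1 or c6 != c5 + 2:
            continue
        sig = signature_of(combo)
        if all(
            gap_bounds[k][0] <= v <= gap_bounds[k][1]
            for k, v in zip(sig._fields, sig)
        ):
            return True
    return False


def build_sequence(sig, nterm=4, cterm=6, filler="A"):
    """Deterministic sequence realizing a signature with no stray Cys."""
    s1, s2, s3, s4, s5 = sig
    return (
        filler * nterm + "C" + filler * s1 + "C" + filler * s2 + "CC"
        + filler * s3 + "C" + filler + "C" + filler * s4 + "C"
        + filler * s5 + "C" + filler * cterm
    )


def test_published_layout_is_recovered():
    seq = build_sequence((9, 13, 19, 22, 13), nterm=4, cterm=9)
    match = find_ecm(seq)
    assert match is not None
    assert match.signature == SpacingSignature(9, 13, 19, 22, 13)
    assert all(seq[i] == "C" for i in match.cys_positions)


def test_too_few_cysteines_yields_none():
    assert find_ecm("ACDEFG") is None
    assert find_ecm("") is None


def test_match_reports_flanks():
    seq = build_sequence((7, 13, 8, 23, 6), nterm=3, cterm=11)
    match = find_ecm(seq)
    assert match.nterm_flank == 3
    assert match.cterm_tail == 11


def test_extra_cysteine_outside_motif_is_tolerated():
    seq = build_sequence((9, 13, 19, 22, 13), nterm=4, cterm=6) + "AC"
    match = find_ecm(seq)
    assert match is not None
    assert match.signature == SpacingSignature(9, 13, 19, 22, 13)


@pytest.mark.parametrize("ltp_type", [t.value for t in NAMED_TYPES])
def test_planted_signature_roundtrip_per_type(ltp_type, rng):
    """For every type, planted motifs are recovered exactly (50 draws each)."""
    for _ in range(50):
        rec, truth = make_ltp(ltp_type, rng)
        cleavage = truth["cleavage"]
        match = find_ecm(rec.sequence[cleavage:])
        assert match is not None
        assert match.cys_positions == truth["cys_positions"]
        assert tuple(match.signature) == truth["signature"]


def test_determinism_on_ambiguous_input():
    # two overlapping valid assignments: the resolved match must be stable
    seq = "C" * 2 + "A" * 9 + "C" + "A" * 13 + "CC" + "A" * 19 + "CAC" \
        + "A" * 22 + "C" + "A" * 13 + "CC"
    first = find_ecm(seq)
    assert first is not None
    for _ in range(5):
        assert find_ecm(seq) == first


def test_named_type_assignment_preferred():
    # a decoy assignment exists left of the planted type II motif; the
    # selection rule must pick the assignment that classifies
    from nsltp.ltp_classifier import classify_signature

    seq = build_sequence((7, 13, 8, 23, 6), nterm=6, cterm=2)
    match = find_ecm(seq)
    assert classify_signature(match.signature) is LtpType.II


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="CA", min_size=8, max_size=60))
def test_brute_force_oracle_agreement(seq):
    """Accept/reject decisions agree with exhaustive 8-subset enumeration."""
    assert (find_ecm(seq) is not None) == brute_force_has_ecm(seq)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_brute_force_oracle_agreement_dense_cys(seed):
    """Same oracle check on Cys-rich random sequences (<= 10 cysteines)."""
    r = np.random.default_rng(seed)
    n = int(r.integers(20, 61))
    seq = "".join(r.choice(list(NON_CYS), size=n))
    k = int(r.integers(0, 11))
    pos = r.choice(n, size=min(k, n), replace=False)
    chars = list(seq)
    for p in pos:
        chars[p] = "C"
    seq = "".join(chars)
    assert (find_ecm(seq) is not None) == brute_force_has_ecm(seq)


def test_candidate_enumeration_matches_brute_force_count():
    seq = build_sequence((9, 13, 19, 22, 13)) + build_sequence((7, 13, 8, 23, 6))
    found = {m.cys_positions for m in enumerate_ecm_candidates(seq)}
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    expected = set()
    for combo in combinations(cys, 8):
        if combo[3] != combo[2] + 1 or combo[5] != combo[4] + 2:
            continue
        sig = signature_of(combo)
        if all(
            DEFAULT_GAP_BOUNDS[k][0] <= v <= DEFAULT_GAP_BOUNDS[k][1]
            for k, v in zip(sig._fields, sig)
        ):
            expected.add(combo)
    assert found == expected


class TestNotationParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C-X7-C-X13-CC-X8-CXC-X23-C-X6-C", (7, 13, 8, 23, 6)),
            ("C-X9-C-X14-CC-X30-CXC-X23-C-X13-C", (9, 14, 30, 23, 13)),
            ("C-X_9_-C-X_13_-CC-X_19_-CXC-X_21_-C-X_13_-C", (9, 13, 19, 21, 13)),
        ],
    )
    def test_parses_subscripts(self, text, expected):
        assert tuple(signature_from_ecm_string(text)) == expected

    @pytest.mark.parametrize("bad", ["CC-X8", "", "C-Xa-C", "C-X1-C-X2-CC-X3"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError, match="malformed"):
            signature_from_ecm_string(bad)
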