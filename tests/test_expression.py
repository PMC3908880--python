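"""Digital expression: TPM normalisation, specificity calls on the
published matrix, EST-cluster assignment."""

import numpy as np
import pandas as pd
import pytest

from nsltp.data_model import ORGANS, ExpressionTable
from nsltp.expression import assign_est_clusters, specificity_calls, tpm
from nsltp.synthetic_data import make_est_table


class TestTpm:
    def test_basic_scaling(self):
        counts = pd.DataFrame({"root": [3, 0]}, index=["a", "b"])
        table = tpm(counts, {"root": 16546})
        assert table.tpm.loc["a", "root"] == pytest.approx(181.3, abs=0.05)
        assert table.tpm.loc["b", "root"] == 0

    def test_column_sums_to_a_million(self):
        counts = pd.DataFrame({"bud": [10, 20, 70]}, index=list("abc"))
        table = tpm(counts, {"bud": 100})
        assert table.tpm["bud"].sum() == pytest.approx(1e6)

    def test_scale_invariance(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(5, 6)), columns=list(ORGANS)
        )
        totals = {o: 10_000 for o in ORGANS}
        scaled = tpm(counts * 7, {o: 70_000 for o in ORGANS})
        base = tpm(counts, totals)
        pd.testing.assert_frame_equal(base.tpm, scaled.tpm)

    def test_zero_total_with_counts_raises(self):
        counts = pd.DataFrame({"root": [3]}, index=["a"])
        with pytest.raises(ValueError, match="zero total"):
            tpm(counts, {"root": 0})


class TestSpecificityOnPublishedMatrix:
    def test_fifteen_single_organ_genes(self, table4):
        _, summary = specificity_calls(table4)
        assert summary["single-organ"] == 15

    def test_exact_organ_assignments(self, table4):
        calls, _ = specificity_calls(table4)
        single = {c.gene: c.category.split(":")[1] for c in calls
                  if c.category.startswith("single-organ")}
        assert single == {
            "BrnsLtpIII.2": "bud", "BrnsLtpIII.3": "bud", "BrnsLtpIX.2": "bud",
            "BrnsLtpIX.1": "flower",
            "BrnsLtpI.12": "leaf", "BrnsLtpXI.4": "leaf", "BrnsLtpXI.5": "leaf",
            "BrnsLtpXI.6": "leaf", "BrnsLtpIV.2": "leaf", "BrnsLtpIV.3": "leaf",
            "BrnsLtpXI.2": "leaf",
            "BrnsLtpI.17": "root", "BrnsLtpIV.6": "root", "BrnsLtpV.1": "root",
            "BrnsLtpIV.7": "silique",
        }

    def test_bud_flower_pairs_called_inflorescence(self, table4):
        calls, summary = specificity_calls(table4)
        inflo = {c.gene for c in calls if c.category == "inflorescence"}
        # the rule yields seven bud+flower genes; the survey's prose lists
        # six but later argues the seventh (I.7) is inflorescence-specific
        assert inflo == {
            "BrnsLtpI.7", "BrnsLtpI.16", "BrnsLtpI.18", "BrnsLtpII.15",
            "BrnsLtpIII.1", "BrnsLtpIX.3", "BrnsLtpY.1",
        }

    def test_no_data_rows_called_no_data(self, table4):
        calls, summary = specificity_calls(table4)
        cats = {c.gene: c.category for c in calls}
        assert cats["BrnsLtpII.14"] == "no-data"
        assert summary["no-data"] == len(table4.no_data)


class TestSpecificityProperties:
    def test_depends_only_on_zero_pattern(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 5, size=(8, 6)), columns=list(ORGANS),
            index=[f"g{i}" for i in range(8)],
        )
        t1 = ExpressionTable(organs=ORGANS, tpm=counts.astype(float))
        t2 = ExpressionTable(organs=ORGANS, tpm=counts.astype(float) * 123.4)
        c1, _ = specificity_calls(t1)
        c2, _ = specificity_calls(t2)
        assert [(c.gene, c.category) for c in c1] == [
            (c.gene, c.category) for c in c2
        ]

    def test_planted_specificity_recovered(self, rng):
        counts, totals, truth = make_est_table(rng=rng)
        calls, _ = specificity_calls(tpm(counts, totals))
        got = {c.gene: c.category for c in calls}
        for gene, planted in truth.items():
            if planted != "no-data":
                assert got[gene] == planted

    def test_all_zero_row_is_broad_with_empty_support(self):
        mat = pd.DataFrame([[0.0] * 6], columns=list(ORGANS), index=["z"])
        calls, _ = specificity_calls(ExpressionTable(organs=ORGANS, tpm=mat))
        assert calls[0].category == "broad" and calls[0].support == frozenset()


class TestEstClusterAssignment:
    def random_seq(self, rng, n):
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_identical_sequence_assigned(self, rng):
        cds = self.random_seq(rng, 300)
        assignments = assign_est_clusters({"g": cds}, {"clu1": cds})
        assert assignments == {"g": "clu1"}

    def test_unrelated_sequence_unassigned(self, rng):
        cds = self.random_seq(rng, 300)
        clusters = {f"c{i}": self.random_seq(rng, 400) for i in range(3)}
        assert assign_est_clusters({"g": cds}, clusters) == {"g": None}

    def test_two_homologous_genes_share_a_cluster(self, rng):
        cluster = self.random_seq(rng, 350)
        def mutate(seq, rate):
            out = list(seq)
            for i in rng.choice(len(seq), int(rate * len(seq)), replace=False):
                out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
            return "".join(out)
        cds = {"g1": mutate(cluster, 0.08), "g2": mutate(cluster, 0.08)}
        assignments = assign_est_clusters(
            cds, {"target": cluster, "bg": self.random_seq(rng, 350)}
        )
        assert assignments == {"g1": "target", "g2": "target"}

    def test_empty_cluster_set(self, rng):
        assert assign_est_clusters({"g": self.random_seq(rng, 100)}, {}) == {
            "g": None
        }
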