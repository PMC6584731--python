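"""Signature discovery rules, signed-average scoring, and the permutation null."""

import numpy as np
import pytest

from metasurv import (CohortCollection, GeneSignature, MetaEstimate,
                      SelectionConfig, discover_signature,
                      load_breast_module_prototypes,
                      load_multicancer_signature, load_ovarian_gene_list,
                      random_signature_null, signed_average_score)
from metasurv.signature import CoverageError

from conftest import make_dataset, survival_dataset


def me(gene, hr, q, k=5):
    log_hr = float(np.log(hr))
    return MetaEstimate(gene=gene, pooled_log_hr=log_hr, pooled_se=0.1,
                        p_value=q / 2, tau2=0.0, cochran_q=0.0, k=k, q_value=q)


class TestPackagedFixtures:
    def test_signature_counts_and_spot_directions(self):
        sig = load_multicancer_signature()
        assert len(sig) == 53
        dirs = sig.directions
        assert dirs["PLAU"] == +1
        assert dirs["DDB2"] == -1
        assert dirs["FAM189A2"] == -1
        assert sum(1 for _, d in sig.members if d == +1) == 41
        assert sum(1 for _, d in sig.members if d == -1) == 12
        assert sig.entrez_ids["EGFR"] == 1956

    def test_gene_list_fixtures(self):
        assert set(load_ovarian_gene_list()) == {
            "PTCH1", "TGFBR2", "CXCL14", "POSTN", "FAP", "NUAK1"}
        assert len(load_breast_module_prototypes()) == 7
        assert "AURKA" in load_breast_module_prototypes()

    def test_json_round_trip(self):
        sig = load_multicancer_signature()
        again = GeneSignature.from_json(sig.to_json())
        assert again.members == sig.members
        assert again.entrez_ids == sig.entrez_ids


class TestDiscoverSignature:
    def test_gene_passing_in_both_cancers_selected_positive(self):
        metas = {"A": [me("g1", 1.3, 0.04)], "B": [me("g1", 1.2, 0.01)]}
        sig = discover_signature(metas)
        assert sig.members == [("g1", +1)]
        assert sig.provenance["g1"]["A"][0] == pytest.approx(1.3)

    def test_discordant_directions_excluded_under_concordance(self):
        metas = {"A": [me("g1", 1.3, 0.01)], "B": [me("g1", 0.80, 0.01)]}
        assert len(discover_signature(metas)) == 0
        relaxed = discover_signature(
            metas, SelectionConfig(require_concordance=False))
        assert relaxed.genes == ["g1"]

    @pytest.mark.parametrize("hr,q,expect", [
        (1.10, 0.01, 0),   # inside the HR dead zone
        (1.30, 0.06, 0),   # fails FDR
        (0.80, 0.02, 1),   # protective side passes
    ])
    def test_threshold_rules(self, hr, q, expect):
        metas = {"A": [me("g1", hr, q)], "B": [me("g1", hr, q)]}
        sig = discover_signature(metas)
        assert len(sig) == expect
        if expect:
            assert sig.members[0][1] == -1

    def test_invariant_to_gene_and_cancer_order(self):
        a = [me("g2", 1.4, 0.01), me("g1", 0.7, 0.02)]
        b = [me("g1", 0.75, 0.01), me("g2", 1.3, 0.01)]
        s1 = discover_signature({"A": a, "B": b})
        s2 = discover_signature({"B": b[::-1], "A": a[::-1]})
        assert s1.members == s2.members == [("g1", -1), ("g2", +1)]

    def test_needs_two_cancer_types(self):
        with pytest.raises(ValueError):
            discover_signature({"A": [me("g1", 1.3, 0.01)]})


class TestSignedAverageScore:
    def test_opposite_directions_cancel(self):
        vals = np.array([[1.0, -1.0], [1.0, -1.0]])  # z-scores are +-1
        ds = make_dataset(vals, gene_names=["A", "B"])
        sig = GeneSignature("s", [("A", +1), ("B", -1)])
        scores = signed_average_score(ds, sig)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_all_positive_reduces_to_mean_of_standardized(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 2, (3, 20))
        ds = make_dataset(vals, gene_names=["A", "B", "C"])
        sig = GeneSignature("s", [("A", 1), ("B", 1), ("C", 1)])
        scores = signed_average_score(ds, sig)
        z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=1, keepdims=True)
        np.testing.assert_allclose(scores.to_numpy(), z.mean(0), atol=1e-12)

    def test_packaged_signature_score_counts_directions(self):
        # two samples at +1/-1 per gene: sample z-scores are +-1/sqrt(2), so
        # the high sample scores (n_risk - n_protective)/53 * 1/sqrt(2)
        sig = load_multicancer_signature()
        n_pos = sum(1 for _, d in sig.members if d == +1)
        n_neg = len(sig) - n_pos
        vals = np.tile(np.array([1.0, -1.0]), (len(sig), 1))
        ds = make_dataset(vals, gene_names=sig.genes)
        scores = signed_average_score(ds, sig)
        assert scores.iloc[0] == pytest.approx(
            (n_pos - n_neg) / 53 / np.sqrt(2))
        assert (n_pos, n_neg) == (41, 12)

    def test_flipping_all_directions_negates_scores(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.normal(size=(5, 15)))
        sig = GeneSignature("s", [("G000", 1), ("G002", -1), ("G004", 1)])
        a = signed_average_score(ds, sig)
        b = signed_average_score(ds, sig.flipped())
        np.testing.assert_allclose(b.to_numpy(), -a.to_numpy(), atol=1e-12)

    def test_missing_genes_shrink_denominator_and_track_coverage(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.normal(size=(2, 10)), gene_names=["A", "B"])
        sig = GeneSignature("s", [("A", 1), ("ZZZ", 1), ("YYY", 1)])
        with pytest.warns(UserWarning, match="coverage"):
            scores = signed_average_score(ds, sig)
        assert scores.attrs["coverage"] == pytest.approx(1 / 3)

    def test_zero_measured_genes_raises(self):
        ds = make_dataset(np.zeros((2, 4)), gene_names=["A", "B"])
        with pytest.raises(CoverageError):
            signed_average_score(ds, GeneSignature("s", [("Q", 1)]))

    def test_rank_scaling_bounded(self):
        rng = np.random.default_rng(4)
        ds = make_dataset(rng.normal(size=(3, 9)))
        sig = GeneSignature("s", [("G000", 1), ("G001", -1), ("G002", 1)])
        scores = signed_average_score(ds, sig, scaling="rank")
        assert np.all(np.abs(scores.to_numpy()) <= 1.0 + 1e-12)


class TestRandomSignatureNull:
    def _setup(self, seed=0, k=3, n=80, n_genes=60):
        beta = np.zeros(n_genes)
        beta[:5] = 0.5
        coll = CohortCollection([
            survival_dataset(seed=seed + i, n=n, n_genes=n_genes, beta=beta,
                             dataset_id=f"d{i}") for i in range(k)])
        training = [me(f"G{i:03d}", 1.2 if i % 2 == 0 else 0.8, 0.5)
                    for i in range(n_genes)]
        return coll, training

    def test_fixed_seed_reproduces_null_bitwise(self):
        coll, training = self._setup()
        sig = GeneSignature("s", [("G000", 1), ("G001", 1), ("G002", 1)])
        a = random_signature_null(coll, training, sig, n_random=10, seed=42)
        b = random_signature_null(coll, training, sig, n_random=10, seed=42)
        np.testing.assert_array_equal(a.null_distribution, b.null_distribution)
        assert a.p_value == b.p_value

    def test_strong_signature_attains_minimum_p(self):
        coll, training = self._setup()
        sig = GeneSignature("s", [(f"G{i:03d}", 1) for i in range(5)])
        res = random_signature_null(coll, training, sig, n_random=19, seed=1)
        # planted 5-gene signature should beat every random draw here
        assert res.p_value == pytest.approx(1 / 20)

    def test_add_one_permutation_formula(self):
        coll, training = self._setup()
        sig = GeneSignature("s", [("G010", 1), ("G011", 1)])  # unplanted
        res = random_signature_null(coll, training, sig, n_random=19, seed=3)
        worse = int(np.sum(np.abs(res.null_distribution)
                           >= abs(res.observed_log_hr)))
        assert res.p_value == pytest.approx((1 + worse) / 20)

    def test_signature_larger_than_gene_pool_rejected(self):
        coll, training = self._setup()
        big = GeneSignature("big", [(f"G{i:03d}", 1) for i in range(10)])
        with pytest.raises(ValueError, match="pool"):
            random_signature_null(coll, training[:2], big, n_random=2, seed=0)
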