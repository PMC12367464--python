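"""Unit tests for rankings, diversity, ordination and PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import spikequant as sq
from spikequant.composition import PermanovaResult, absolute_values, bray_curtis


class TestTopN:
    def test_simple_ordering(self):
        values = pd.DataFrame(
            {"s1": [6, 3, 1], "s2": [4, 2, 0]}, index=["A", "B", "C"], dtype=float
        )
        report = sq.top_n(values, 3)
        assert list(report.table["taxon"]) == ["A", "B", "C"]
        assert list(report.table["rank"]) == [1, 2, 3]

    def test_per_sample_scaling_reorders_pooled_ranking(self):
        # same reads everywhere, but sample s1 carries a 100x scale factor:
        # taxa dominant in s1 take over the pooled absolute ranking
        reads = pd.DataFrame(
            {
                "s1": [10, 1, 5, 2],
                "s2": [1, 10, 5, 8],
                "s3": [1, 9, 5, 8],
                "s4": [2, 8, 5, 9],
            },
            index=["A", "B", "C", "D"],
            dtype=float,
        )
        scales = pd.Series({"s1": 100.0, "s2": 1.0, "s3": 1.0, "s4": 1.0})
        absolute = reads.mul(scales, axis=1)
        # brute-force oracle: rank by hand-computed sums
        sums = absolute.sum(axis=1)
        expected = list(sums.sort_values(ascending=False).index)
        report = sq.top_n(absolute, 4, basis="absolute")
        assert list(report.table["taxon"]) == expected
        assert report.table["taxon"].iloc[0] == "A"  # s1-dominant taxon wins
        # relative (unscaled) ranking differs
        rel_report = sq.top_n(reads.div(reads.sum(axis=0), axis=1), 4)
        assert list(rel_report.table["taxon"]) != expected

    def test_truncation_flag(self):
        values = pd.DataFrame({"s1": [1.0, 2.0]}, index=["A", "B"])
        assert sq.top_n(values, 5).truncated

    def test_deterministic_tie_break(self):
        values = pd.DataFrame({"s1": [1.0, 1.0, 1.0]}, index=["B", "C", "A"])
        report = sq.top_n(values, 3)
        assert list(report.table["taxon"]) == ["A", "B", "C"]


class TestRankShift:
    def test_entered_and_left_flags(self):
        rel = pd.DataFrame(
            {"g1a": [10, 6, 1], "g1b": [9, 5, 1], "g2a": [1, 1, 3], "g2b": [1, 2, 2]},
            index=["A", "B", "C"],
            dtype=float,
        )
        # relative top-2 is A, B; scaling group-2 samples 100x lifts C
        absolute = rel.mul(
            pd.Series({"g1a": 1.0, "g1b": 1.0, "g2a": 100.0, "g2b": 100.0}), axis=1
        )
        shift = sq.rank_shift(sq.top_n(rel, 2), sq.top_n(absolute, 2, basis="absolute"))
        by_taxon = shift.set_index("taxon")
        assert bool(by_taxon.loc["C", "entered_top_n"])
        assert bool(by_taxon.loc["A", "left_top_n"])

    def test_equal_scale_factors_cannot_reorder(self):
        rng = np.random.default_rng(0)
        reads = pd.DataFrame(
            rng.integers(0, 100, (6, 5)).astype(float),
            index=list("ABCDEF"),
            columns=[f"s{i}" for i in range(5)],
        )
        absolute = reads * 42.0  # equal per-sample scale factor
        rel_rank = list(sq.top_n(reads, 6).table["taxon"])
        abs_rank = list(sq.top_n(absolute, 6, basis="absolute").table["taxon"])
        assert rel_rank == abs_rank


class TestDiffAbundance:
    GROUPS = pd.Series(
        {"a1": "g1", "a2": "g1", "a3": "g1", "a4": "g1",
         "b1": "g2", "b2": "g2", "b3": "g2", "b4": "g2"}
    )

    def test_identical_distributions_not_significant(self):
        values = pd.DataFrame(
            {s: [0.5, 0.5] for s in self.GROUPS.index}, index=["A", "B"]
        )
        out = sq.diff_abundance(values, self.GROUPS)
        assert (out["p_value"] > 0.9).all()

    def test_bh_column_on_request(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            rng.uniform(0, 1, (5, 8)), index=list("ABCDE"), columns=self.GROUPS.index
        )
        out = sq.diff_abundance(values, self.GROUPS, bh_correction=True)
        assert "p_bh" in out.columns
        assert (out["p_bh"] >= out["p_value"] - 1e-12).all()

    def test_small_groups_rejected(self):
        groups = pd.Series({"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"})
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]], index=["A"], columns=groups.index
        )
        with pytest.raises(ValueError, match="n >= 3"):
            sq.diff_abundance(values, groups)


class TestShannon:
    def test_uniform_four_taxa(self):
        assert sq.shannon([5, 5, 5, 5]) == pytest.approx(np.log(4), rel=1e-12)

    def test_single_taxon_zero(self):
        assert sq.shannon([42, 0, 0]) == 0.0

    def test_scale_invariance(self):
        x = np.array([3, 1, 8, 2, 0])
        assert sq.shannon(x * 7) == pytest.approx(sq.shannon(x), rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sq.shannon([0, 0, 0])

    def test_matches_skbio(self):
        from skbio.diversity.alpha import shannon as sk_shannon

        x = np.array([5, 1, 0, 9, 3])
        assert sq.shannon(x) == pytest.approx(float(sk_shannon(x, base=np.e)), rel=1e-10)


class TestChao1:
    def test_no_singletons_returns_observed_richness(self):
        assert sq.chao1([5, 3, 2, 8]) == pytest.approx(4 + 1 * 0 / (2 * 2))
        assert sq.chao1([5, 3, 3, 8]) == 4.0

    def test_bias_corrected_closed_form(self):
        # S_obs = 10, F1 = 4, F2 = 2 -> 10 + 4*3/(2*3) = 12
        counts = [1, 1, 1, 1, 2, 2, 3, 4, 5, 6]
        assert sq.chao1(counts) == pytest.approx(12.0)

    def test_classic_closed_form(self):
        counts = [1, 1, 1, 1, 2, 2, 3, 4, 5, 6]
        assert sq.chao1(counts, bias_corrected=False) == pytest.approx(14.0)

    def test_non_integer_input_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            sq.chao1([1.5, 2.0, 3.0])

    def test_lower_bounded_by_observed_richness(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 20, 50)
        assert sq.chao1(x) >= np.count_nonzero(x)

    def test_matches_skbio(self):
        from skbio.diversity.alpha import chao1 as sk_chao1

        x = np.array([1, 1, 2, 2, 2, 5, 9, 0, 1])
        assert sq.chao1(x) == pytest.approx(float(sk_chao1(x, bias_corrected=True)))


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        values = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0]})
        assert bray_curtis(values).loc["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        values = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 3.0]})
        assert bray_curtis(values).loc["s1", "s2"] == pytest.approx(1.0)

    def test_closed_form_third(self):
        values = pd.DataFrame({"u": [1.0, 2.0, 3.0], "v": [3.0, 2.0, 1.0]})
        assert bray_curtis(values).loc["u", "v"] == pytest.approx(1 / 3)

    def test_metric_properties_on_random_data(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.uniform(0, 5, (8, 6)))
        d = bray_curtis(values).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1

    def test_two_all_zero_samples_rejected(self):
        values = pd.DataFrame({"s1": [0.0, 0.0], "s2": [0.0, 0.0], "s3": [1.0, 2.0]})
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(values)


class TestPcoa:
    def test_equilateral_configuration(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        res = sq.pcoa(d)
        positive = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(positive) == 2
        assert positive[0] == pytest.approx(positive[1], rel=1e-9)

    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [2.5], [4.0]])
        d = pd.DataFrame(squareform(pdist(pts)))
        res = sq.pcoa(d)
        assert (res.eigenvalues[1:] < 1e-9 * res.eigenvalues[0]).all()

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 3))
        d = pd.DataFrame(squareform(pdist(pts)))
        res = sq.pcoa(d)
        recovered = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(recovered - d.to_numpy()).max() <= 1e-8

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            sq.pcoa(d)

    def test_explained_variance_proportions(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        d = pd.DataFrame(squareform(pdist(pts)))
        res = sq.pcoa(d)
        assert res.proportion_explained.sum() == pytest.approx(1.0)
        assert (np.diff(res.proportion_explained) <= 1e-12).all()


def _brute_force_pseudo_f(d: np.ndarray, labels: np.ndarray) -> float:
    """Independent pseudo-F oracle from the among/within decomposition."""
    n = len(labels)
    d2 = d**2
    total = sum(d2[i, j] for i, j in itertools.combinations(range(n), 2)) / n
    within = 0.0
    for g in np.unique(labels):
        idx = [i for i in range(n) if labels[i] == g]
        within += sum(d2[i, j] for i, j in itertools.combinations(idx, 2)) / len(idx)
    k = len(np.unique(labels))
    return ((total - within) / (k - 1)) / (within / (n - k))


class TestPermanova:
    @staticmethod
    def _fixture(seed=0, n=6):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(
            rng.uniform(0, 10, (5, n)), columns=[f"s{i}" for i in range(n)]
        )
        dm = bray_curtis(values)
        groups = pd.Series(
            ["g1"] * (n // 2) + ["g2"] * (n - n // 2), index=dm.index
        )
        return dm, groups

    def test_statistic_matches_brute_force(self):
        dm, groups = self._fixture()
        res = sq.permanova(dm, groups, n_permutations=9, seed=0)
        assert res.pseudo_f == pytest.approx(
            _brute_force_pseudo_f(dm.to_numpy(), groups.to_numpy()), rel=1e-12
        )

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        dm, groups = self._fixture(seed=7, n=10)
        res = sq.permanova(dm, groups, n_permutations=9, seed=0)
        ref = sk_permanova(
            DistanceMatrix(dm.to_numpy(), ids=list(dm.index)),
            groups.to_numpy(),
            permutations=9,
        )
        assert res.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_exhaustive_distribution_equals_enumeration(self):
        dm, groups = self._fixture()
        res = sq.permanova(dm, groups, exhaustive=True)
        d = dm.to_numpy()
        expected = sorted(
            _brute_force_pseudo_f(d, np.array(assignment))
            for assignment in {
                tuple(
                    "g1" if i in chosen else "g2" for i in range(6)
                )
                for chosen in itertools.combinations(range(6), 3)
            }
        )
        assert res.n_permutations == 20
        assert np.allclose(sorted(res.permuted_f), expected)

    def test_separated_clusters_hit_permutation_floor(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.01, (10, 4))
        b = rng.normal(10, 0.01, (10, 4))
        pts = np.vstack([a, b])
        dm = pd.DataFrame(squareform(pdist(pts)))
        groups = pd.Series(["g1"] * 10 + ["g2"] * 10, index=dm.index)
        res = sq.permanova(dm, groups, n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_null_calibration(self):
        """Shuffled labels on unstructured data: P > 0.05 in >= 90% of runs."""
        rng = np.random.default_rng(9)
        values = pd.DataFrame(
            rng.uniform(0, 10, (6, 12)), columns=[f"s{i}" for i in range(12)]
        )
        dm = bray_curtis(values)
        high = 0
        for seed in range(50):
            labels = np.random.default_rng(seed).permutation(["g1"] * 6 + ["g2"] * 6)
            groups = pd.Series(labels, index=dm.index)
            res = sq.permanova(dm, groups, n_permutations=199, seed=seed)
            high += res.p_value > 0.05
        assert high >= 45

    def test_sample_order_exchangeability(self):
        dm, groups = self._fixture(seed=10, n=8)
        perm = np.random.default_rng(0).permutation(8)
        shuffled = dm.iloc[perm, perm]
        res_a = sq.permanova(dm, groups, n_permutations=9, seed=0)
        res_b = sq.permanova(shuffled, groups[shuffled.index], n_permutations=9, seed=0)
        assert res_a.pseudo_f == pytest.approx(res_b.pseudo_f, rel=1e-12)

    def test_seed_reproducibility(self):
        dm, groups = self._fixture()
        a = sq.permanova(dm, groups, n_permutations=99, seed=5)
        b = sq.permanova(dm, groups, n_permutations=99, seed=5)
        assert a.p_value == b.p_value

    def test_singleton_group_rejected(self):
        dm, groups = self._fixture()
        groups = groups.copy()
        groups.iloc[0] = "g3"
        with pytest.raises(ValueError, match="size 1"):
            sq.permanova(dm, groups, n_permutations=9, seed=0)


def test_alpha_diversity_table(baseline_run):
    cm, *_ = baseline_run
    alpha = sq.alpha_diversity(cm)
    assert set(alpha.columns) == {"shannon", "chao1"}
    assert (alpha["shannon"] >= 0).all()
    endo = cm.endogenous()
    observed = (endo > 0).sum(axis=0)
    assert (alpha["chao1"] >= observed - 1e-9).all()
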