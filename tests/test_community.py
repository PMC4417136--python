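"""Preprocessing, Bray-Curtis, NMDS and the ordination-fit permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from rhizopart.community import (
    DistanceMatrix,
    average_subsamples,
    bray_curtis,
    choose_k,
    filter_rare,
    nmds,
    ordination_fit,
    stress_profile,
)
from rhizopart.eigen import pcoa
from rhizopart.io import InputError

from conftest import make_otu_table


def brute_force_bray_curtis(x: np.ndarray) -> np.ndarray:
    """Independent double-loop application of the defining formula."""
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(min(x[i, k], x[j, k]) for k in range(x.shape[1]))
            den = x[i].sum() + x[j].sum()
            out[i, j] = 1.0 - 2.0 * num / den
    return out


class TestAverageSubsamples:
    def test_cellwise_mean(self, tiny_otu_table):
        avg = average_subsamples(tiny_otu_table)
        np.testing.assert_allclose(avg.matrix(), [[0.3, 0.7, 0.0]], atol=1e-15)

    def test_single_subsample_unchanged(self):
        t = make_otu_table([[1.0, 2.0]], ["s1"], ["s1.a"], ["o1", "o2"])
        np.testing.assert_allclose(average_subsamples(t).matrix(), t.matrix())

    def test_preserves_unit_row_sums(self):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(5), size=6)
        t = make_otu_table(
            rows, ["s1"] * 2 + ["s2"] * 2 + ["s3"] * 2,
            [f"ss{i}" for i in range(6)], [f"o{i}" for i in range(5)]
        )
        np.testing.assert_allclose(
            average_subsamples(t).matrix().sum(axis=1), 1.0, atol=1e-12
        )


class TestFilterRare:
    def _presence_table(self, counts, n_rows=168):
        """OTUs present (value 1) in the first ``counts[j]`` of n_rows rows."""
        m = np.zeros((n_rows, len(counts)))
        for j, c in enumerate(counts):
            m[:c, j] = 1.0
        m[:, -1] = 1.0  # keep rows non-empty
        return make_otu_table(
            m, [f"s{i//2}" for i in range(n_rows)],
            [f"ss{i}" for i in range(n_rows)],
            [f"o{j}" for j in range(len(counts))],
        )

    def test_seven_percent_boundary(self):
        # 11/168 = 6.5 % <= 7 % -> removed; 12/168 = 7.14 % > 7 % -> kept
        table = self._presence_table([11, 12, 168])
        kept = filter_rare(table, 0.07)
        assert kept.otu_ids == ["o1", "o2"]

    def test_zero_threshold_drops_only_absent_otus(self):
        table = self._presence_table([0, 5, 168])
        kept = filter_rare(table, 0.0)
        assert kept.otu_ids == ["o1", "o2"]

    def test_all_removed_is_error(self):
        table = self._presence_table([3, 3, 4])
        with pytest.raises(InputError, match="removed every OTU"):
            filter_rare(table, 1.0)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = make_otu_table([[1, 2], [1, 2]], ["a", "b"], ["a", "b"], ["o1", "o2"])
        assert bray_curtis(t).data[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        t = make_otu_table([[1, 0], [0, 3]], ["a", "b"], ["a", "b"], ["o1", "o2"])
        assert bray_curtis(t).data[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        t = make_otu_table([[1, 2, 3], [3, 2, 1]], ["a", "b"], ["a", "b"],
                           ["o1", "o2", "o3"])
        # 1 - 2*(1+2+1)/12 = 1/3
        assert bray_curtis(t).data[0, 1] == pytest.approx(1 / 3)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.gamma(0.5, size=(20, 30))
            t = make_otu_table(
                x, [f"s{i}" for i in range(20)], [f"s{i}" for i in range(20)],
                [f"o{j}" for j in range(30)],
            )
            np.testing.assert_allclose(
                np.asarray(bray_curtis(t).data), brute_force_bray_curtis(x),
                atol=1e-12,
            )

    def test_all_zero_row_rejected(self):
        t = make_otu_table([[0, 0], [1, 2]], ["a", "b"], ["a", "b"], ["o1", "o2"])
        with pytest.raises(InputError, match="all-zero"):
            bray_curtis(t)


def _euclidean_dm(points: np.ndarray) -> DistanceMatrix:
    return DistanceMatrix(squareform(pdist(points)),
                          ids=[f"p{i}" for i in range(len(points))])


class TestNmds:
    def test_embeddable_distances_reach_tiny_stress(self):
        rng = np.random.default_rng(3)
        D = _euclidean_dm(rng.standard_normal((10, 2)))
        ordn = nmds(D, k=2, n_starts=4, seed=0)
        assert ordn.stress < 1e-3

    def test_determinism(self):
        rng = np.random.default_rng(4)
        D = _euclidean_dm(rng.standard_normal((15, 4)))
        a = nmds(D, k=2, n_starts=3, seed=9)
        b = nmds(D, k=2, n_starts=3, seed=9)
        assert a.stress == b.stress
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_stress_non_increasing_in_k(self):
        rng = np.random.default_rng(5)
        for trial in range(6):
            d = squareform(pdist(rng.standard_normal((12, 8))))
            D = DistanceMatrix(d, ids=[f"p{i}" for i in range(12)])
            stresses = [nmds(D, k, n_starts=4, seed=[trial, k]).stress
                        for k in (2, 11)]
            assert stresses[1] <= stresses[0] + 1e-6

    def test_never_worse_than_pcoa_start(self):
        """Majorization from the PCoA start cannot end above its own start."""
        rng = np.random.default_rng(6)
        x = rng.standard_normal((20, 6))
        D = _euclidean_dm(x)
        ordn = nmds(D, k=2, n_starts=1, seed=0)  # start 0 is PCoA
        # stress of the raw PCoA configuration
        from rhizopart.community import _disparities, _stress1

        init = pcoa(D).vectors.to_numpy()[:, :2]
        d = pdist(init)
        dis = squareform(np.asarray(D.data), checks=False)
        dhat = _disparities(dis, d, None)
        assert ordn.stress <= _stress1(d, dhat) + 1e-9

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(Exception):
            DistanceMatrix(np.array([[0, 1.0], [2.0, 0]]), ids=["a", "b"])


class TestStressProfileChoice:
    def test_choose_k_reference_profile(self):
        profile = [(1, 0.35), (2, 0.24), (3, 0.21), (4, 0.12)]
        assert choose_k(profile, 0.20) == 4

    def test_choose_k_immediate_pass(self):
        assert choose_k([(1, 0.10)], 0.20) == 1

    def test_zero_ceiling_errors_with_profile(self):
        with pytest.raises(InputError, match="k=1"):
            choose_k([(1, 0.10)], 0.0)

    def test_profile_matches_individual_fits(self):
        rng = np.random.default_rng(7)
        D = _euclidean_dm(rng.standard_normal((12, 5)))
        profile, fits = stress_profile(D, k_max=3, n_starts=2, seed=3)
        assert [k for k, _ in profile] == [1, 2, 3]
        for k, s in profile:
            assert fits[k].stress == s
            refit = nmds(D, k, n_starts=2, seed=[3, k])
            assert refit.stress == s


class TestOrdinationFit:
    def test_self_fit_is_perfect(self):
        rng = np.random.default_rng(8)
        D = _euclidean_dm(rng.standard_normal((12, 2)))
        ordn = nmds(D, k=2, n_starts=2, seed=1)
        r2, p = ordination_fit(ordn, D, n_permutations=49, seed=0)
        assert r2 > 0.999
        assert p <= 1 / 50 + 1e-12

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((10, 2))
        D = _euclidean_dm(pts)
        ordn = nmds(D, k=2, n_starts=1, seed=1)
        r2a, _ = ordination_fit(ordn, D, n_permutations=19, seed=0)
        perm = rng.permutation(10)
        ids = list(np.array(D.ids)[perm])
        D2 = DistanceMatrix(np.asarray(D.data)[np.ix_(perm, perm)], ids=ids)
        ordn2 = nmds(D2, k=2, n_starts=1, seed=1)
        # permuting both matrices identically leaves the fit unchanged
        r2b, _ = ordination_fit(ordn2, D2, n_permutations=19, seed=0)
        assert r2b == pytest.approx(r2a, abs=1e-6)

    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(10)
        D = _euclidean_dm(rng.standard_normal((8, 2)))
        ordn = nmds(D, k=2, n_starts=2, seed=1)
        with pytest.raises(InputError):
            ordination_fit(ordn, D, n_permutations=0)


class TestBrayCurtisProperties:
    """Property-based checks of the dissimilarity's defining bounds."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(3, 8), st.integers(2, 10)),
            elements=st.floats(0, 100, allow_nan=False),
        )
    )
    def test_bounds_symmetry_and_oracle(self, x):
        import numpy as np

        x = x + 1e-9  # keep every row non-zero
        t = make_otu_table(
            x,
            [f"s{i}" for i in range(x.shape[0])],
            [f"s{i}" for i in range(x.shape[0])],
            [f"o{j}" for j in range(x.shape[1])],
        )
        d = np.asarray(bray_curtis(t).data)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        np.testing.assert_allclose(d, brute_force_bray_curtis(x), atol=1e-10)
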