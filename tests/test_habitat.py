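import numpy as np
import pytest
from scipy import stats

from nichekit import reference
from nichekit.habitat import (CompositionRecord, CompositionalSelection,
                              composition_type2, composition_type3,
                              ranking_matrix, study_area_polygon, wilks_test,
                              zero_replace)
from nichekit.homerange import HomeRange
from nichekit.io import HabitatMap

from conftest import make_locations


def _comp(use, avail, individual="i", habitats=None):
    return CompositionRecord(individual=individual, use=np.asarray(use, float),
                             avail=np.asarray(avail, float),
                             habitats=habitats)


def _random_comps(rng, N, D, shift=0.0):
    """Compositions whose log-ratio differences are iid normal (+ shift on
    the first habitat)."""
    comps = []
    for i in range(N):
        z = rng.normal(size=D) * 0.5
        z[0] += shift
        use = np.exp(z)
        use /= use.sum()
        avail = np.full(D, 1.0 / D)
        comps.append(_comp(use, avail, individual=f"i{i}"))
    return comps


def _half_split_map(n=40, cell=10.0):
    grid = np.zeros((n, n), dtype=int)
    grid[:, n // 2:] = 1
    return HabitatMap(grid=grid, cell_size=cell, origin=(0.0, 0.0),
                      classes=["A", "B"])


def _rect_hr(rows, cols, shape=(40, 40), cell=10.0):
    mask = np.zeros(shape, dtype=bool)
    mask[rows, cols] = True
    return HomeRange(level=0.95, mask=mask, cell_size=cell, origin=(0.0, 0.0))


class TestCompositions:
    def test_type3_all_in_one_class(self):
        hmap = _half_split_map()
        # home range straddles the split 60/40
        hr = _rect_hr(slice(0, 10), slice(8, 28))
        pts = make_locations(np.column_stack([np.full(25, 100.0),
                                              np.linspace(5, 95, 25)]))
        c = composition_type3(pts, hr, hmap)
        np.testing.assert_allclose(c.use, [1.0, 0.0])
        np.testing.assert_allclose(c.avail, [0.6, 0.4])

    def test_type2_use_and_shared_availability(self):
        hmap = _half_split_map()
        hrs = {"a": _rect_hr(slice(5, 15), slice(0, 10)),     # all in A
               "b": _rect_hr(slice(5, 15), slice(15, 25))}    # straddles
        comps = composition_type2(hrs, hmap)
        by_id = {c.individual: c for c in comps}
        np.testing.assert_allclose(by_id["a"].use, [1.0, 0.0])
        np.testing.assert_allclose(by_id["b"].avail, by_id["a"].avail)
        assert by_id["a"].design == "II"

    def test_type2_proportions_match_monte_carlo(self, rng):
        hmap = _half_split_map()
        hrs = {"a": _rect_hr(slice(3, 17), slice(10, 30)),
               "b": _rect_hr(slice(20, 35), slice(5, 25))}
        comps = composition_type2(hrs, hmap)
        poly = study_area_polygon(hrs)
        import shapely
        minx, miny, maxx, maxy = poly.bounds
        pts = rng.uniform([minx, miny], [maxx, maxy], size=(40000, 2))
        inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
        cls = hmap.class_at(pts[inside, 0], pts[inside, 1])
        cls = cls[cls >= 0]
        mc = np.bincount(cls, minlength=2) / len(cls)
        np.testing.assert_allclose(comps[0].avail, mc, atol=0.01)

    def test_uniform_use_matches_availability(self, rng):
        # locations uniform within the home range: use ~ avail
        hmap = _half_split_map()
        hr = _rect_hr(slice(0, 20), slice(10, 30))
        pts = rng.uniform([100, 0], [300, 200], size=(4000, 2))
        c = composition_type3(make_locations(pts), hr, hmap)
        np.testing.assert_allclose(c.use, c.avail, atol=0.02)


class TestZeroReplace:
    def test_replaces_and_renormalizes(self):
        c = zero_replace(_comp([0.5, 0.5, 0.0], [1 / 3] * 3), value=1e-4)
        assert c.use.sum() == pytest.approx(1.0)
        assert c.use[2] == pytest.approx(1e-4 / (1 + 1e-4))
        assert c.use[0] == pytest.approx(0.5 / (1 + 1e-4))

    def test_noop_without_zeros(self):
        c0 = _comp([0.3, 0.7], [0.5, 0.5])
        c1 = zero_replace(c0)
        np.testing.assert_array_equal(c1.use, c0.use)

    def test_all_but_one_zero_still_sums_to_one(self):
        c = zero_replace(_comp([1.0, 0.0, 0.0], [1 / 3] * 3))
        assert c.use.sum() == pytest.approx(1.0)
        assert np.all(c.use > 0)


class TestWilks:
    @pytest.mark.parametrize("lam,N,chi2_printed",
                             [(t[2], t[3], t[4])
                              for t in reference.WILKS_TRIPLES])
    def test_published_chi2_relation(self, lam, N, chi2_printed):
        # chi2 = -N ln(lambda) reproduces every printed triple within the
        # rounding of the printed lambda
        assert -N * np.log(lam) == pytest.approx(chi2_printed, abs=0.15)

    def test_reference_habitat_invariance(self, rng):
        comps = _random_comps(rng, N=8, D=5)
        lams = [wilks_test(comps, reference=r).wilks_lambda for r in range(5)]
        np.testing.assert_allclose(lams, lams[0], rtol=1e-9)

    def test_lambda_bounds_and_chi2_identity(self, rng):
        res = wilks_test(_random_comps(rng, N=10, D=4))
        assert 0 < res.wilks_lambda <= 1
        assert res.chi2 == pytest.approx(-res.N * np.log(res.wilks_lambda),
                                         abs=1e-9)
        assert res.df == 3

    def test_randomization_enumerates_small_n(self, rng):
        comps = _random_comps(rng, N=6, D=3)
        res = wilks_test(comps, mode="both", seed=0)
        assert res.n_resamples == 64
        assert 0 <= res.p_randomization <= 1

    def test_randomization_detects_strong_selection(self, rng):
        comps = _random_comps(rng, N=8, D=4, shift=3.0)
        res = wilks_test(comps, mode="both", seed=0)
        assert res.p_parametric < 0.01
        assert res.p_randomization < 0.05

    def test_parametric_needs_enough_individuals(self, rng):
        with pytest.raises(ValueError, match="N >= D-1"):
            wilks_test(_random_comps(rng, N=2, D=5))

    def test_randomization_size_near_nominal(self, rng):
        # null: log-ratio differences zero-mean iid normal; the sign-flip
        # randomization test should reject at close to the nominal rate
        n_sims, N, D = 200, 20, 5
        rejections = 0
        for _ in range(n_sims):
            comps = _random_comps(rng, N=N, D=D)
            res = wilks_test(comps, mode="randomization", n_resamples=199,
                             seed=int(rng.integers(2 ** 31)))
            if res.p_randomization < 0.05:
                rejections += 1
        assert rejections / n_sims == pytest.approx(0.05, abs=0.035)

    def test_parametric_chi2_is_liberal_at_small_n(self):
        # the chi-square reference for -N ln(lambda) is known to be
        # anti-conservative in small samples; at N=20, D=5 the exact size
        # (via the Hotelling T^2 / F relation) is ~0.090, not 0.05
        N, p = 20, 4
        thr = stats.chi2.ppf(0.95, p)
        t2 = (N - 1) * (np.exp(thr / N) - 1)
        f = t2 * (N - p) / (p * (N - 1))
        size = stats.f.sf(f, p, N - p)
        assert size == pytest.approx(0.090, abs=0.005)
        assert size > 0.05


class TestRanking:
    def test_dominant_habitat_gets_top_rank(self):
        comps = [_comp([0.7, 0.2, 0.1], [1 / 3] * 3, individual=f"i{k}",
                       habitats=["A", "B", "C"]) for k in range(4)]
        rm = ranking_matrix(comps)
        assert rm.ranks["A"] == 2

    def test_antisymmetry_and_rank_permutation(self, rng):
        comps = _random_comps(rng, N=7, D=5)
        rm = ranking_matrix(comps)
        m = rm.mean_diff.to_numpy()
        np.testing.assert_allclose(m, -m.T, atol=1e-12)
        assert sorted(rm.ranks) == [0, 1, 2, 3, 4]

    def test_t_statistics_match_brute_force(self, rng):
        comps = _random_comps(rng, N=6, D=3)
        rm = ranking_matrix(comps)
        d = np.array([np.log(c.use) - np.log(c.avail) for c in comps])
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                diff = d[:, i] - d[:, j]
                se = diff.std(ddof=1) / np.sqrt(len(diff))
                t_bf = diff.mean() / se
                p_bf = 2 * stats.t.sf(abs(t_bf), len(diff) - 1)
                assert rm.t_stat.iloc[i, j] == pytest.approx(t_bf, rel=1e-9)
                assert rm.p_value.iloc[i, j] == pytest.approx(p_bf, rel=1e-9)

    def test_published_rank_ordering_structure(self, rng):
        # construct compositions whose selection strength is ordered
        # savanna > grasslands > scrub > ponds > forest, mirroring the
        # published second-order fox ranking column (4,3,2,1,0)
        habitats = ["savanna", "grasslands", "scrub-savanna", "ponds",
                    "forest"]
        strength = np.array([2.0, 1.0, 0.0, -1.0, -2.0])
        comps = []
        for k in range(7):
            z = strength + rng.normal(size=5) * 0.05
            use = np.exp(z)
            use /= use.sum()
            comps.append(_comp(use, np.full(5, 0.2), individual=f"f{k}",
                               habitats=habitats))
        rm = ranking_matrix(comps)
        assert list(rm.ranks[habitats]) == [4, 3, 2, 1, 0]


class TestModelFrontEnd:
    def test_fit_and_summary(self, rng):
        comps = _random_comps(rng, N=7, D=5, shift=1.5)
        res = CompositionalSelection(comps).fit()
        assert res.wilks_lambda == pytest.approx(
            wilks_test(comps).wilks_lambda)
        txt = res.summary()
        assert "lambda" in txt and "Ranking" in str(res.ranking.to_table())

    def test_zero_replacement_applied_on_construction(self):
        comps = [_comp([0.5, 0.5, 0.0], [1 / 3] * 3, individual=f"i{k}")
                 for k in range(3)]
        model = CompositionalSelection(comps, zero_replacement=1e-4)
        assert all(np.all(c.use > 0) for c in model.comps)
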