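"""Population-genetic statistics against closed forms and independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tests.conftest import make_gm
from uhedge.genotype_io import MISSING
from uhedge.popgen import (
    PopgenError,
    compare_populations,
    diversity_summary,
    evanno_delta_k,
    fit_hs_urban,
    genetic_distance,
    ho_he,
    morans_i,
    pca,
    private_alleles,
    qg_relatedness,
    rarefied_allelic_richness,
    standardized_heterozygosity,
    wc_fst,
)


# ---------------------------------------------------------------------------
# independent Weir-Cockerham oracle: scalar per-locus arithmetic, no vectorised
# code shared with the implementation
# ---------------------------------------------------------------------------

def wc_theta_oracle(pop_genotypes):
    """theta from per-population genotype lists, one locus at a time."""
    n_loci = len(pop_genotypes[0][0])
    A = B = C = 0.0
    for l in range(n_loci):
        ns, ps, hs = [], [], []
        for pop in pop_genotypes:
            calls = [g[l] for g in pop if g[l] != MISSING]
            if not calls:
                continue
            n_i = len(calls)
            ns.append(n_i)
            ps.append(sum(calls) / (2 * n_i))
            hs.append(sum(1 for c in calls if c == 1) / n_i)
        r = len(ns)
        if r < 2 or sum(ns) <= r:
            continue
        nbar = sum(ns) / r
        nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
        if nc <= 0:
            continue
        pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        A, B, C = A + a, B + b, C + c
    return A / (A + B + C)


class TestHs:
    def test_identical_individuals_all_one(self):
        gm = make_gm([[1, 0, 1], [1, 0, 1], [1, 0, 1]])
        hs = standardized_heterozygosity(gm)
        assert np.allclose(hs["hs"], 1.0)

    def test_arithmetic_identity(self):
        g = np.zeros((2, 10), dtype=np.int8)
        g[0, 0] = 1  # proportion 0.1
        g[1, :3] = 1  # proportion 0.3
        hs = standardized_heterozygosity(make_gm(g))
        assert hs["hs"].tolist() == pytest.approx([0.5, 1.5])

    def test_mean_is_exactly_one(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(15, 50)).astype(np.int8)
        hs = standardized_heterozygosity(make_gm(g))
        assert hs["hs"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_uncalled_individual_excluded_with_warning(self):
        g = np.array([[1, 0], [MISSING, MISSING], [0, 1]], dtype=np.int8)
        with pytest.warns(UserWarning, match="no called sites"):
            hs = standardized_heterozygosity(make_gm(g))
        assert list(hs.index) == ["s1", "s3"]


class TestHoHe:
    def test_all_heterozygous_locus(self):
        gm = make_gm([[1], [1], [1]])
        out = ho_he(gm, pd.Series(["P"] * 3, index=gm.samples))
        assert out.loc["P", "ho"] == 1.0

    def test_he_small_sample_correction_closed_form(self):
        # p = 0.5 with n = 2 -> He = 2 * 0.25 * (4/3) = 2/3
        gm = make_gm([[0], [2]])
        out = ho_he(gm, pd.Series(["P"] * 2, index=gm.samples))
        assert out.loc["P", "he"] == pytest.approx(2 / 3)

    def test_hardy_weinberg_limit_on_panmixia(self):
        from uhedge.synthetic_data import simulate_island_genotypes

        gm, pops = simulate_island_genotypes(1, 100, 1000, 0.0, seed=4)
        out = ho_he(gm, pops)
        assert out["ho"].iloc[0] == pytest.approx(out["he"].iloc[0], abs=0.02)

    def test_fis_definition(self):
        gm = make_gm([[0], [1], [2], [1]])
        out = ho_he(gm, pd.Series(["P"] * 4, index=gm.samples))
        assert out.loc["P", "fis"] == pytest.approx(
            1 - out.loc["P", "ho"] / out.loc["P", "he"]
        )

    def test_empty_population_errors(self):
        gm = make_gm([[0], [1]])
        with pytest.raises(PopgenError):
            ho_he(gm, pd.Series(["P", None], index=gm.samples))


class TestAllelicRichness:
    def test_monomorphic_locus_ar_one(self):
        gm = make_gm([[0], [0], [0]])
        ar = rarefied_allelic_richness(gm, pd.Series(["P"] * 3, index=gm.samples), g=4)
        assert ar["P"] == pytest.approx(1.0)

    def test_hypergeometric_closed_form_50_50(self):
        # allele counts (50, 50), g = 6: Ar = 2 (1 - C(50,6)/C(100,6))
        g = np.array([[0]] * 25 + [[2]] * 25, dtype=np.int8)
        gm = make_gm(g)
        ar = rarefied_allelic_richness(gm, pd.Series(["P"] * 50, index=gm.samples), g=6)
        expected = 2 * (1 - math.comb(50, 6) / math.comb(100, 6))
        assert ar["P"] == pytest.approx(expected, abs=1e-9)
        assert ar["P"] == pytest.approx(1.9733, abs=1e-4)

    def test_full_sample_limit_counts_observed_alleles(self):
        g = np.array([[0, 0], [2, 0], [1, 0]], dtype=np.int8)
        gm = make_gm(g)
        ar = rarefied_allelic_richness(gm, pd.Series(["P"] * 3, index=gm.samples), g=6)
        # locus 1 has both alleles (2), locus 2 monomorphic (1)
        assert ar["P"] == pytest.approx(1.5)

    def test_monotone_in_g(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
        gm = make_gm(g)
        pops = pd.Series(["P"] * 12, index=gm.samples)
        values = [rarefied_allelic_richness(gm, pops, g=k)["P"] for k in (2, 6, 12, 24)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_g_below_two_rejected(self):
        gm = make_gm([[0], [1]])
        with pytest.raises(PopgenError):
            rarefied_allelic_richness(gm, pd.Series(["P"] * 2, index=gm.samples), g=1)


class TestPrivateAlleles:
    def test_allele_private_to_one_population(self):
        # alt present only in P1; ref everywhere
        gm = make_gm([[1], [0], [0], [0]])
        pops = pd.Series(["P1", "P1", "P2", "P2"], index=gm.samples)
        counts = private_alleles(gm, pops)
        assert counts["P1"] == 1 and counts["P2"] == 0

    def test_shared_allele_counts_nowhere(self):
        gm = make_gm([[1], [0], [1], [0]])
        pops = pd.Series(["P1", "P1", "P2", "P2"], index=gm.samples)
        counts = private_alleles(gm, pops)
        assert counts.sum() == 0

    def test_fixed_difference_gives_two_privates(self):
        # P1 all ref, P2 all alt: each allele private to one population
        gm = make_gm([[0], [0], [2], [2]])
        pops = pd.Series(["P1", "P1", "P2", "P2"], index=gm.samples)
        counts = private_alleles(gm, pops)
        assert counts["P1"] == 1 and counts["P2"] == 1


class TestWcFst:
    def test_fixed_alternate_alleles_theta_one(self):
        g = np.array([[0] * 5] * 10 + [[2] * 5] * 10, dtype=np.int8)
        gm = make_gm(g)
        pops = pd.Series(["A"] * 10 + ["B"] * 10, index=gm.samples)
        assert wc_fst(gm, pops).estimate == pytest.approx(1.0)

    def test_identical_populations_theta_nonpositive(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        gm = make_gm(np.vstack([block, block]))
        pops = pd.Series(["A"] * 10 + ["B"] * 10, index=gm.samples)
        assert wc_fst(gm, pops).estimate <= 0

    def test_matches_independent_oracle_two_pops(self):
        # pop1 p-hat = 0.9, pop2 p-hat = 0.1, n = 10 each, single locus
        pop1 = [2] * 9 + [0]
        pop2 = [0] * 9 + [2]
        gm = make_gm(np.array([[g] for g in pop1 + pop2], dtype=np.int8))
        pops = pd.Series(["A"] * 10 + ["B"] * 10, index=gm.samples)
        oracle = wc_theta_oracle([[[g] for g in pop1], [[g] for g in pop2]])
        assert wc_fst(gm, pops).estimate == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_oracle_with_missing_data(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(30, 40)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = MISSING
        gm = make_gm(g)
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        pops = pd.Series(labels, index=gm.samples)
        oracle = wc_theta_oracle(
            [[list(g[i]) for i in range(k * 10, (k + 1) * 10)] for k in range(3)]
        )
        assert wc_fst(gm, pops).estimate == pytest.approx(oracle, abs=1e-10)

    def test_bootstrap_ci_brackets_estimate(self):
        from uhedge.synthetic_data import simulate_island_genotypes

        gm, pops = simulate_island_genotypes(4, 10, 300, 0.1, seed=5)
        res = wc_fst(gm, pops, n_boot=200, seed=11)
        assert res.ci_lower <= res.estimate <= res.ci_upper

    def test_pairwise_matrix_symmetric(self):
        from uhedge.synthetic_data import simulate_island_genotypes

        gm, pops = simulate_island_genotypes(3, 8, 200, 0.15, seed=6)
        mat = wc_fst(gm, pops, pairwise=True)
        assert np.allclose(mat.values, mat.values.T)
        assert (np.diag(mat.values) == 0).all()


class TestQgRelatedness:
    def test_invariant_to_locus_order(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(6, 80)).astype(np.int8)
        gm1 = make_gm(g)
        perm = rng.permutation(80)
        gm2 = make_gm(g[:, perm])
        r1 = qg_relatedness(gm1)
        r2 = qg_relatedness(gm2)
        assert np.allclose(r1.values, r2.values, equal_nan=True)

    def test_invariant_to_allele_relabelling(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(6, 80)).astype(np.int8)
        flipped = g.copy()
        flipped[:, :40] = 2 - flipped[:, :40]  # swap ref/alt at half the loci
        r1 = qg_relatedness(make_gm(g))
        r2 = qg_relatedness(make_gm(flipped))
        assert np.allclose(r1.values, r2.values, equal_nan=True)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(5, 60)).astype(np.int8)
        r = qg_relatedness(make_gm(g))
        assert np.allclose(r.values, r.values.T, equal_nan=True)


class TestGeneticDistance:
    def test_identical_rows_zero(self):
        gm = make_gm([[0, 1, 2], [0, 1, 2]])
        assert genetic_distance(gm).values[0, 1] == 0.0

    def test_single_opposite_homozygote(self):
        gm = make_gm([[0, 1], [2, 1]])
        assert genetic_distance(gm).values[0, 1] == pytest.approx(2.0)

    def test_locus_permutation_invariance(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        d1 = genetic_distance(make_gm(g)).values
        d2 = genetic_distance(make_gm(g[:, rng.permutation(30)])).values
        assert np.allclose(d1, d2)

    def test_missing_rescaling(self):
        # one masked locus out of two: rescale by sqrt(2/1)
        gm = make_gm([[0, MISSING], [2, 1]])
        assert genetic_distance(gm).values[0, 1] == pytest.approx(2 * np.sqrt(2))

    def test_no_shared_loci_flagged(self):
        gm = make_gm([[0, MISSING], [MISSING, 1]])
        with pytest.warns(UserWarning, match="no called loci"):
            d = genetic_distance(gm)
        assert np.isnan(d.values[0, 1])


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        g = np.array([[0] * 20] * 5 + [[2] * 20] * 5, dtype=np.int8)
        coords, ratio = pca(make_gm(g))
        assert np.sign(coords[:5, 0]).std() == 0
        assert np.all(np.sign(coords[:5, 0]) != np.sign(coords[5:, 0]))
        assert ratio[0] == pytest.approx(1.0)

    def test_variance_shares_sum_to_at_most_one(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
        _, ratio = pca(make_gm(g))
        assert ratio.sum() <= 1 + 1e-9


class TestEvanno:
    def test_worked_example_peaks_at_k2(self):
        rows = []
        means = {1: -100.0, 2: -50.0, 3: -48.0, 4: -47.0}
        for k, m in means.items():
            rows += [
                {"K": k, "replicate": 1, "lnP": m - 0.5},
                {"K": k, "replicate": 2, "lnP": m + 0.5},
            ]
        out = evanno_delta_k(pd.DataFrame(rows)).set_index("K")
        assert out["delta_k"].idxmax() == 2
        assert np.isnan(out.loc[1, "delta_k"]) and np.isnan(out.loc[4, "delta_k"])

    def test_linear_likelihoods_zero_interior(self):
        rows = []
        for k in range(1, 5):
            for rep, off in ((1, -1.0), (2, 1.0)):
                rows.append({"K": k, "replicate": rep, "lnP": -10.0 * k + off})
        out = evanno_delta_k(pd.DataFrame(rows)).set_index("K")
        assert out.loc[2, "delta_k"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc[3, "delta_k"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_sd_flagged(self):
        rows = []
        for k in range(1, 4):
            for rep in (1, 2):
                rows.append({"K": k, "replicate": rep, "lnP": -5.0 * k * k})
        out = evanno_delta_k(pd.DataFrame(rows)).set_index("K")
        assert not out.loc[2, "defined"]


class TestComparePopulations:
    def test_identical_constant_vectors_p_one(self):
        out = compare_populations({"A": np.ones(5), "B": np.ones(5)})
        assert out.loc["A", "B"] == 1.0

    def test_bh_preserves_ordering(self):
        rng = np.random.default_rng(7)
        vals = {
            "A": rng.normal(0, 1, 100),
            "B": rng.normal(0.2, 1, 100),
            "C": rng.normal(2, 1, 100),
        }
        out = compare_populations(vals)
        assert out.loc["A", "C"] <= out.loc["A", "B"]

    def test_shifted_distributions_significant(self):
        rng = np.random.default_rng(8)
        out = compare_populations(
            {"A": rng.normal(0, 1, 200), "B": rng.normal(2, 1, 200)}
        )
        assert out.loc["A", "B"] < 0.001


class TestMoransI:
    @staticmethod
    def rook_weights(n_side):
        n = n_side * n_side
        w = np.zeros((n, n))
        for r in range(n_side):
            for c in range(n_side):
                i = r * n_side + c
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_side and 0 <= cc < n_side:
                        w[i, rr * n_side + cc] = 1.0
        return w / w.sum(axis=1, keepdims=True)

    def test_checkerboard_is_minus_one(self):
        vals = np.array([(-1) ** (r + c) for r in range(4) for c in range(4)], float)
        res = morans_i(vals, weights=self.rook_weights(4))
        assert res.I == pytest.approx(-1.0)

    def test_null_expectation_for_random_values(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 100, size=(400, 2))
        vals = rng.normal(size=400)
        res = morans_i(vals, coords=coords, k=8)
        assert res.I == pytest.approx(-1 / 399, abs=0.03)
        assert res.p_value > 0.01

    def test_smooth_gradient_positive(self):
        coords = np.array([(r, c) for r in range(10) for c in range(10)], float)
        vals = coords[:, 0] + coords[:, 1]
        res = morans_i(vals, coords=coords, k=8)
        assert res.I > 0.5 and res.p_value < 1e-6

    def test_constant_input_flagged(self):
        res = morans_i(np.ones(10), coords=np.random.default_rng(0).random((10, 2)))
        assert not res.defined and np.isnan(res.I)

    def test_local_values_sum_consistent_with_global(self):
        # with row-standardised W, sum of local I equals n * global I
        rng = np.random.default_rng(10)
        coords = rng.uniform(0, 10, size=(30, 2))
        vals = rng.normal(size=30)
        res = morans_i(vals, coords=coords, k=5)
        assert res.local.sum() / 30 == pytest.approx(res.I)


class TestHsUrbanModel:
    def test_slope_recovery(self):
        rng = np.random.default_rng(11)
        urban = rng.uniform(0, 1, 80)
        hs = 1 - 0.5 * urban + rng.normal(0, 0.01, 80)
        fit, _ = fit_hs_urban(hs, urban)
        assert fit["slope"] == pytest.approx(-0.5, abs=0.05)

    def test_constant_urban_errors(self):
        with pytest.raises(PopgenError, match="constant"):
            fit_hs_urban(np.random.default_rng(0).random(10), np.full(10, 0.3))

    def test_clustered_residuals_detected(self):
        rng = np.random.default_rng(12)
        coords = np.vstack([rng.normal(0, 1, (25, 2)), rng.normal(50, 1, (25, 2))])
        urban = rng.uniform(0, 1, 50)
        hs = 1 - 0.5 * urban + np.r_[np.full(25, 0.3), np.full(25, -0.3)]
        fit, autocorr = fit_hs_urban(hs, urban, coords=coords)
        assert autocorr.I > 0.5 and autocorr.p_value < 1e-4


def test_diversity_summary_layout():
    from uhedge.synthetic_data import simulate_island_genotypes

    gm, pops = simulate_island_genotypes(3, 6, 120, 0.1, seed=13)
    out = diversity_summary(gm, pops)
    assert list(out.columns) == ["n", "private_alleles", "ar", "ho", "he", "fis"]
    assert (out["n"] == 6).all()
    assert ((out["ar"] >= 1) & (out["ar"] <= 2)).all()


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@st.composite
def genotype_matrices(draw, max_n=8, max_loci=12):
    n = draw(st.integers(2, max_n))
    m = draw(st.integers(1, max_loci))
    rows = draw(
        st.lists(
            st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=m, max_size=m),
            min_size=n,
            max_size=n,
        )
    )
    return make_gm(np.array(rows, dtype=np.int8))


@settings(max_examples=40, deadline=None)
@given(genotype_matrices())
def test_hs_mean_is_one_whenever_defined(gm):
    called = (gm.genotypes != MISSING).sum(axis=1)
    if (called > 0).sum() < 2:
        return
    if not (gm.genotypes == 1).any():
        return  # no heterozygous site anywhere: Hs is 0/0, undefined
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        hs = standardized_heterozygosity(gm)
    assert hs["hs"].mean() == pytest.approx(1.0)


@settings(max_examples=40, deadline=None)
@given(genotype_matrices(), st.integers(0, 2**31 - 1))
def test_genetic_distance_is_symmetric_nonnegative_and_permutation_invariant(gm, seed):
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        d1 = genetic_distance(gm).values
        perm = np.random.default_rng(seed).permutation(gm.n_loci)
        d2 = genetic_distance(make_gm(gm.genotypes[:, perm])).values
    finite = np.isfinite(d1)
    assert np.all(d1[finite] >= 0)
    assert np.allclose(d1, d1.T, equal_nan=True)
    assert np.allclose(d1, d2, equal_nan=True)
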