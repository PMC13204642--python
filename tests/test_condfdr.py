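"""Conditional FDR estimation: counting definition, exact/lookup modes,
masking, reduction limits and the enrichment diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from condfdr.core import (CondFdrLookup, ConditionalFdr, brute_force_condfdr,
                          condfdr, conditional_enrichment_qq, exact_condfdr,
                          exclusion_mask_regions, fit_conditional_cdf,
                          qq_stratum_medians)
from condfdr.errors import EstimationError
from condfdr.simulate import SimConfig, simulate_pair
from conftest import build_pair

# ---------------------------------------------------------------------------
# ten-SNP fixture with hand-computed dominance counts
# ---------------------------------------------------------------------------
# unmasked fitting set S = SNPs 0-7; SNPs 8 (chr6 HLA) and 9 (chr8p23.1) are
# masked but still scored. condFDR = min(1, p1 * n2 / n12), counts over S.
TEN_P1 = [0.01, 0.005, 0.5, 0.9, 0.001, 0.3, 0.7, 1.0, 0.002, 0.04]
TEN_P2 = [0.10, 0.05, 0.08, 0.02, 0.5, 0.9, 0.7, 1.0, 0.01, 0.3]
TEN_CHROM = ["1"] * 8 + ["6", "8"]
TEN_BP = [1000 * (i + 1) for i in range(8)] + [26_000_000, 11_000_000]
# hand counts: e.g. SNP0 (p1=.01, p2=.1): n2 = |{.1,.05,.08,.02}| = 4,
# n12 = |{(.01,.1),(.005,.05)}| = 2 -> F = 0.5, condFDR = 0.02.
# SNP5 (p1=.3, p2=.9): n2 = 7 (all of S but SNP7), n12 = |{s0,s1,s4,s5}| = 4
# -> condFDR = 0.3 * 7/4 = 0.525. SNP8 has no S member with p2 <= 0.01 ->
# unconditional fallback: F_unc(0.002) = 1/8 -> condFDR = 0.016.
TEN_EXPECTED = [0.02, 0.01, 0.75, 0.9, 0.005, 0.525, 0.84, 1.0, 0.016, 0.08]


@pytest.fixture
def ten_snp_pair():
    return build_pair(TEN_P1, TEN_P2, chrom=TEN_CHROM, bp=TEN_BP)


def _oracle_double_loop(p1, p2, fit):
    """Definitional double loop, independent of the package implementation."""
    s1 = [a for a, keep in zip(p1, fit) if keep]
    s2 = [b for b, keep in zip(p2, fit) if keep]
    out = []
    for a, b in zip(p1, p2):
        n2 = sum(1 for x in s2 if x <= b)
        n12 = sum(1 for x, y in zip(s1, s2) if x <= a and y <= b)
        if n2 == 0:
            f = sum(1 for x in s1 if x <= a) / len(s1)
        else:
            f = n12 / n2
        out.append(min(1.0, a / f) if f > 0 else 1.0)
    return np.array(out)


class TestCountingDefinition:
    def test_hand_computed_fixture(self, ten_snp_pair):
        mask = exclusion_mask_regions(ten_snp_pair)
        assert list(mask) == [False] * 8 + [True, True]
        got = brute_force_condfdr(ten_snp_pair, mask=mask)
        np.testing.assert_allclose(got, TEN_EXPECTED, rtol=1e-12)

    def test_exact_equals_brute_on_fixture(self, ten_snp_pair):
        mask = exclusion_mask_regions(ten_snp_pair)
        np.testing.assert_array_equal(exact_condfdr(ten_snp_pair, mask=mask),
                                      brute_force_condfdr(ten_snp_pair, mask=mask))

    def test_exact_equals_brute_on_simulated_pair(self, sim_pair_small):
        pair, _, _ = sim_pair_small
        diff = np.abs(exact_condfdr(pair) - brute_force_condfdr(pair))
        assert diff.max() == 0.0

    def test_matches_independent_double_loop(self, rng):
        p1 = rng.uniform(size=80)
        p2 = rng.uniform(size=80)
        fit = rng.uniform(size=80) > 0.2
        pair = build_pair(p1, p2)
        np.testing.assert_allclose(brute_force_condfdr(pair, mask=~fit),
                                   _oracle_double_loop(p1, p2, fit), rtol=1e-12)

    def test_max_p_snp_scores_its_own_p(self):
        pair = build_pair([0.2, 0.5, 1.0], [0.3, 0.6, 1.0])
        assert brute_force_condfdr(pair)[2] == 1.0
        pair2 = build_pair([0.2, 0.5, 0.8], [0.3, 0.6, 1.0])
        assert brute_force_condfdr(pair2)[2] == pytest.approx(0.8)

    def test_empty_fitting_set_raises(self, ten_snp_pair):
        with pytest.raises(EstimationError):
            brute_force_condfdr(ten_snp_pair, mask=np.ones(10, bool))

    @given(st.integers(0, 2**31 - 1))
    def test_bounds_hold_for_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        p1 = rng.uniform(1e-12, 1.0, size=n)
        p2 = rng.uniform(1e-12, 1.0, size=n)
        cf = exact_condfdr(build_pair(p1, p2))
        assert np.all(cf <= 1.0) and np.all(cf > 0)
        assert np.all(cf >= p1 - 1e-15)


class TestReductionLimits:
    def test_all_equal_p2_reduces_to_unconditional_fdr(self, rng):
        p1 = rng.uniform(size=500)
        pair = build_pair(p1, np.full(500, 0.37))
        n = len(p1)
        rank = np.array([(p1 <= v).sum() for v in p1])
        expected = np.minimum(1.0, p1 * n / rank)
        np.testing.assert_allclose(exact_condfdr(pair), expected, rtol=1e-12)

    def test_p1_equal_one_scores_one(self, rng):
        p1 = np.append(rng.uniform(size=200), 1.0)
        p2 = rng.uniform(size=201)
        pair = build_pair(p1, p2)
        assert exact_condfdr(pair)[-1] == 1.0
        lk = fit_conditional_cdf(pair)
        assert lk.score(np.array([1.0]), np.array([0.5]))[0] == 1.0

    def test_independent_conditioning_approaches_unconditional(self):
        # with a uniform independent conditioning trait the conditional and
        # unconditional FDRs coincide as n grows
        diffs = []
        for m in (500, 20_000):
            pair, _, _ = simulate_pair(SimConfig(
                m=m, block_size=1, rho=0.0, pi10=0, pi01=0, pi11=0, seed=5))
            cf = exact_condfdr(pair)
            unc = pair.copy()
            unc["P2"] = 1.0
            diffs.append(np.mean(np.abs(cf - exact_condfdr(unc))))
        assert diffs[1] < diffs[0]
        assert diffs[1] < 0.05


class TestMasking:
    def test_permuting_masked_snps_changes_nothing_unmasked(self, rng):
        # wide spacing so some SNPs land inside the chr6/chr8 masked regions
        pair, _, _ = simulate_pair(SimConfig(m=3000, block_size=1, rho=0.0,
                                             spacing_bp=300_000, seed=2))
        mask = exclusion_mask_regions(pair)
        assert 0 < mask.sum() < len(pair)
        base_exact = exact_condfdr(pair, mask=mask)
        base_lookup = fit_conditional_cdf(pair, mask=mask)

        perm = pair.copy()
        idx = np.where(mask)[0]
        shuffled = rng.permutation(idx)
        for col in ("P1", "P2", "Z1", "Z2"):
            vals = perm[col].to_numpy().copy()
            vals[idx] = vals[shuffled]
            perm[col] = vals
        new_exact = exact_condfdr(perm, mask=mask)
        new_lookup = fit_conditional_cdf(perm, mask=mask)
        np.testing.assert_array_equal(base_exact[~mask], new_exact[~mask])
        np.testing.assert_array_equal(base_lookup.cdf, new_lookup.cdf)

    def test_default_regions_flag_known_positions(self):
        pair = build_pair([0.5] * 4, [0.5] * 4, chrom=["6", "6", "8", "1"],
                          bp=[26_896_889, 24_999_999, 11_119_037, 11_119_037])
        mask = exclusion_mask_regions(pair)
        assert list(mask) == [True, False, True, False]

    def test_excl_column_joins_the_mask(self, ten_snp_pair):
        ten_snp_pair.loc[0, "EXCL"] = True
        est = ConditionalFdr(mode="exact").fit(ten_snp_pair)
        assert est.mask_[0] and est.n_fit_ == 7


class TestLookup:
    def test_single_threshold_equals_unconditional_cdf(self, sim_pair_small):
        pair, _, _ = sim_pair_small
        lk = fit_conditional_cdf(pair, thresholds=(0.0,))
        p1 = np.sort(pair["P1"].to_numpy())
        expected = np.searchsorted(p1, 10.0 ** (-lk.grid), side="right") / len(p1)
        np.testing.assert_allclose(lk.cdf[0], expected)

    def test_grid_cells_match_dominance_counts(self, sim_pair_small):
        pair, _, _ = sim_pair_small
        lk = fit_conditional_cdf(pair)
        p1 = pair["P1"].to_numpy()
        p2 = pair["P2"].to_numpy()
        for k, t in enumerate(lk.thresholds):
            sel = p2 <= 10.0 ** (-t)
            if not sel.any():
                continue
            for m in (0, 10, 40, 300):
                want = np.mean(p1[sel] <= 10.0 ** (-lk.grid[m]))
                assert lk.cdf[k, m] == pytest.approx(want)

    def test_interpolated_mode_tracks_exact_mode(self):
        # stratified-surface scores agree with per-SNP counting within 10%
        # relative for at least 95% of SNPs once strata are well populated
        pair, _, _ = simulate_pair(SimConfig(m=20_000, block_size=1, rho=0.0, seed=11))
        b = exact_condfdr(pair)
        lk = fit_conditional_cdf(pair)
        s = lk.score(pair["P1"].to_numpy(), pair["P2"].to_numpy(),
                     warn_out_of_grid=False)
        rel = np.abs(s - b) / b
        assert np.mean(rel <= 0.10) >= 0.95

    def test_deterministic_without_pruning(self, sim_pair_small):
        pair, _, _ = sim_pair_small
        a = fit_conditional_cdf(pair).to_json()
        b = fit_conditional_cdf(pair).to_json()
        assert a == b

    def test_json_round_trip(self, sim_pair_small):
        pair, _, _ = sim_pair_small
        lk = fit_conditional_cdf(pair)
        back = CondFdrLookup.from_json(lk.to_json())
        np.testing.assert_array_equal(back.cdf, lk.cdf)
        np.testing.assert_array_equal(back.n_k, lk.n_k)
        p1 = pair["P1"].to_numpy()[:50]
        p2 = pair["P2"].to_numpy()[:50]
        np.testing.assert_allclose(back.score(p1, p2, warn_out_of_grid=False),
                                   lk.score(p1, p2, warn_out_of_grid=False))

    def test_empty_stratum_inherits_coarser(self):
        rng = np.random.default_rng(3)
        # no SNP reaches p2 <= 1e-4: the two finest strata inherit
        pair = build_pair(rng.uniform(size=300), rng.uniform(1e-3, 1, size=300))
        lk = fit_conditional_cdf(pair, thresholds=(0, 2, 4, 5))
        assert lk.n_k[2] == 0 and lk.n_k[3] == 0
        np.testing.assert_array_equal(lk.cdf[2], lk.cdf[1])
        np.testing.assert_array_equal(lk.cdf[3], lk.cdf[1])

    def test_cdf_cells_monotone_and_bounded(self, sim_pair_small):
        pair, _, _ = sim_pair_small
        lk = fit_conditional_cdf(pair)
        assert np.all(lk.cdf >= 0) and np.all(lk.cdf <= 1)
        # non-decreasing in p1 == non-increasing along the q axis
        assert np.all(np.diff(lk.cdf, axis=1) <= 1e-15)
        assert np.all(lk.cdf[:, 0] == 1.0)  # F(max p1 | .) = 1
        # stratum sizes shrink as the threshold tightens
        nk = lk.n_k[lk.n_k > 0]
        assert np.all(np.diff(nk) <= 0)

    def test_out_of_grid_clamped_with_warning(self, sim_pair_small):
        pair, _, _ = sim_pair_small
        lk = fit_conditional_cdf(pair)
        with pytest.warns(UserWarning, match="clamped"):
            cf = lk.score(np.array([1e-40]), np.array([1e-9]))
        assert 0 < cf[0] <= 1.0

    def test_score_monotone_in_p1_at_fixed_p2(self, sim_pair_small):
        pair, _, _ = sim_pair_small
        lk = fit_conditional_cdf(pair)
        p1 = np.logspace(-6, 0, 200)
        cf = lk.score(p1, np.full_like(p1, 0.02), warn_out_of_grid=False)
        assert np.all(np.diff(cf) >= -1e-9)

    def test_pruning_averaging_is_seeded_and_logged(self, sim_pair_small):
        pair, truth, ld = sim_pair_small
        a = fit_conditional_cdf(pair, prune_ld=ld, prune_iterations=3,
                                random_state=7)
        b = fit_conditional_cdf(pair, prune_ld=ld, prune_iterations=3,
                                random_state=7)
        np.testing.assert_array_equal(a.cdf, b.cdf)
        assert a.metadata["pruning"]["iterations"] == 3
        assert len(a.metadata["pruning"]["seeds"]) == 3


class TestEstimatorApi:
    def test_exact_mode_matches_brute_force(self, ten_snp_pair):
        est = ConditionalFdr(mode="exact").fit(ten_snp_pair)
        np.testing.assert_allclose(est.predict(ten_snp_pair), TEN_EXPECTED,
                                   rtol=1e-12)

    def test_condfdr_wrapper_adds_column(self, ten_snp_pair):
        scored = condfdr(ten_snp_pair, mode="exact",
                         mask=exclusion_mask_regions(ten_snp_pair))
        assert "CONDFDR" in scored.columns
        np.testing.assert_allclose(scored["CONDFDR"], TEN_EXPECTED, rtol=1e-12)

    def test_sklearn_clone_round_trip(self, sim_pair_small):
        from sklearn.base import clone
        pair, _, _ = sim_pair_small
        est = ConditionalFdr(mode="lookup", thresholds=(0, 1, 2))
        est2 = clone(est)
        assert est2.get_params()["thresholds"] == (0, 1, 2)
        cf = est2.fit(pair).predict(pair)
        assert len(cf) == len(pair)
        assert hasattr(est2, "lookup_") and hasattr(est2, "mask_")

    def test_transform_output_respects_bounds(self, sim_pair_small):
        pair, _, _ = sim_pair_small
        out = ConditionalFdr(mode="lookup").fit(pair).transform(pair)
        assert np.all(out["CONDFDR"] <= 1.0)
        assert np.all(out["CONDFDR"] >= out["P1"] - 1e-15)


class TestEnrichmentQq:
    def test_single_threshold_is_marginal_qq(self, sim_pair_small):
        pair, _, _ = sim_pair_small
        qq = conditional_enrichment_qq(pair, p2_thresholds=(1.0,))
        p1 = np.sort(pair["P1"].to_numpy())
        np.testing.assert_allclose(np.sort(qq["observed"].to_numpy()),
                                   np.sort(-np.log10(p1)))

    def test_shared_causal_pair_shows_enrichment(self):
        pair, _, _ = simulate_pair(SimConfig(m=20_000, block_size=1, rho=0.0,
                                             pi11=0.005, seed=9))
        qq = conditional_enrichment_qq(pair)
        med = qq_stratum_medians(qq)
        assert med.loc[0.001] > med.loc[1.0]

    def test_independent_pair_shows_no_enrichment(self):
        pair, _, _ = simulate_pair(SimConfig(m=20_000, block_size=1, rho=0.0,
                                             pi10=0, pi01=0, pi11=0, seed=13))
        qq = conditional_enrichment_qq(pair, p2_thresholds=(1.0, 0.1, 0.01))
        med = qq_stratum_medians(qq)
        assert abs(med.loc[0.01] - med.loc[1.0]) < 0.1

    def test_empty_stratum_dropped_with_warning(self, rng):
        pair = build_pair(rng.uniform(size=50), rng.uniform(0.5, 1.0, size=50))
        with pytest.warns(UserWarning, match="dropped"):
            qq = conditional_enrichment_qq(pair, p2_thresholds=(1.0, 1e-6))
        assert set(qq["p2_threshold"]) == {1.0}
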