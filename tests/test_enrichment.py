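"""Enrichment scoring: normalization, abundance regression, ES, zones, hits."""

import numpy as np
import pandas as pd
import pytest

from sabrscreen.enrichment import (
    ConfidenceZones,
    ScreenDesign,
    calibrate_zones,
    call_hits,
    compute_es,
    dropout_deconvolute,
    fit_expected_abundance,
    normalize,
)
from sabrscreen.read_processing import CountMatrix
from sabrscreen.simulate import SimulationParams, simulate_screen


def _matrix(cols: dict, index=None) -> CountMatrix:
    counts = pd.DataFrame(cols, index=index)
    totals = pd.DataFrame({
        s: {"assigned": int(counts[s].sum()), "unmatched_insert": 0,
            "unassigned_index": 0} for s in counts
    }).T
    return CountMatrix(counts=counts, totals=totals)


def _ols_normal_equations(x, y):
    """Closed-form OLS with intercept via the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[0], beta[1]  # intercept, slope


class TestNormalize:
    def test_proportional_scaling(self):
        m = _matrix({"s": [1, 1, 2]})
        out = normalize(m, pseudocount=0)
        assert np.allclose(out["s"].values, [250000, 250000, 500000])

    def test_pseudocount_hand_arithmetic(self):
        m = _matrix({"s": [0, 10]})
        out = normalize(m, pseudocount=0.5)
        assert np.allclose(out["s"].values, [0.5 / 11 * 1e6, 10.5 / 11 * 1e6])

    def test_all_zero_column_errors(self):
        m = pd.DataFrame({"bad": [0, 0, 0], "ok": [1, 2, 3]})
        with pytest.raises(ValueError, match="bad"):
            normalize(m, pseudocount=0.5)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 100, size=(50, 4)))
        out = normalize(m, pseudocount=0.5)
        assert np.allclose(out.sum(axis=0), 1e6)


class TestAbundanceModel:
    def test_identity_fit(self):
        x = pd.DataFrame({"u1": [10.0, 20, 30, 40], "u2": [10.0, 20, 30, 40]})
        y = x.mean(axis=1)
        model = fit_expected_abundance(x, y)
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(model.predict(y.index.map(lambda i: x.loc[i].mean())), y)

    def test_five_epitope_normal_equation_oracle(self):
        x = np.array([3.0, 7.0, 11.0, 20.0, 42.0])
        y = np.array([5.0, 6.5, 13.0, 18.0, 40.0])
        unsorted = pd.DataFrame({"u1": x})
        model = fit_expected_abundance(unsorted, pd.Series(y))
        b0, b1 = _ols_normal_equations(x, y)
        assert model.intercept == pytest.approx(b0)
        assert model.slope == pytest.approx(b1)

    def test_exact_linear_data_recovered(self):
        x = pd.Series([1.0, 2, 3, 4, 5])
        model = fit_expected_abundance(pd.DataFrame({"u": x}), 2 * x + 7)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(7.0)
        assert model.r_squared == pytest.approx(1.0)

    def test_zero_variance_covariate_errors(self):
        with pytest.raises(ValueError, match="variance"):
            fit_expected_abundance(pd.DataFrame({"u": [5.0, 5, 5, 5]}),
                                   pd.Series([1.0, 2, 3, 4]))


class TestComputeES:
    def _design(self, n_sorted=2):
        return ScreenDesign(
            unsorted=["u1", "u2"],
            sorted_tcrs={f"s{i}": {"TCR1"} for i in range(1, n_sorted + 1)},
        )

    def test_null_screen_es_zero(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(10, 500, size=20)
        m = _matrix({"u1": counts, "u2": counts, "s1": counts, "s2": counts})
        scorer = compute_es(self._design(), m)
        assert np.allclose(scorer.es_.values, 0.0, atol=1e-8)

    def test_residuals_match_normal_equations(self):
        rng = np.random.default_rng(2)
        m = _matrix({k: rng.integers(1, 1000, size=8) for k in ("u1", "u2", "s1")})
        design = ScreenDesign(unsorted=["u1", "u2"], sorted_tcrs={"s1": {"T"}})
        scorer = compute_es(design, m, pseudocount=0.5)
        ab = normalize(m, 0.5)
        x = ab[["u1", "u2"]].mean(axis=1).values
        y = ab["s1"].values
        b0, b1 = _ols_normal_equations(x, y)
        assert np.allclose(scorer.es_["s1"].values, y - (b0 + b1 * x))

    def test_residual_sum_near_zero_per_replicate(self):
        rng = np.random.default_rng(3)
        m = _matrix({k: rng.integers(1, 2000, size=300)
                     for k in ("u1", "u2", "s1", "s2")})
        scorer = compute_es(self._design(), m)
        for s in ("s1", "s2"):
            assert abs(scorer.es_[s].sum()) < 1e-6 * 1e6

    def test_invariant_to_epitope_relabeling_and_replicate_order(self):
        rng = np.random.default_rng(4)
        cols = {k: rng.integers(1, 1000, size=12) for k in ("u1", "u2", "s1", "s2")}
        ids = [f"e{i}" for i in range(12)]
        m = _matrix(cols, index=ids)
        base = compute_es(self._design(), m).tcr_scores_["TCR1"]

        perm = np.random.default_rng(5).permutation(12)
        m2 = _matrix({k: v[perm] for k, v in cols.items()},
                     index=[ids[i] for i in perm])
        shuffled = compute_es(self._design(), m2).tcr_scores_["TCR1"]
        pd.testing.assert_series_equal(base.sort_index(), shuffled.sort_index(),
                                       check_names=False)

        design_swapped = ScreenDesign(unsorted=["u2", "u1"],
                                      sorted_tcrs={"s2": {"TCR1"}, "s1": {"TCR1"}})
        swapped = compute_es(design_swapped, m).tcr_scores_["TCR1"]
        pd.testing.assert_series_equal(base, swapped, check_names=False)

    def test_epitopes_outside_library_manifest_excluded(self, toy_library, caplog):
        import logging
        ids = [e.id for e in toy_library.epitopes] + ["ghost"]
        rng = np.random.default_rng(6)
        m = _matrix({k: rng.integers(1, 100, size=4) for k in ("u1", "u2", "s1")},
                    index=ids)
        design = ScreenDesign(unsorted=["u1", "u2"], sorted_tcrs={"s1": {"T"}})
        with caplog.at_level(logging.WARNING):
            scorer = compute_es(design, m, library=toy_library)
        assert "ghost" not in scorer.es_.index
        assert any("ghost" in r.message for r in caplog.records)

    def test_studentize_divides_by_residual_sd(self):
        rng = np.random.default_rng(7)
        m = _matrix({k: rng.integers(1, 2000, size=50) for k in ("u1", "u2", "s1")})
        design = ScreenDesign(unsorted=["u1", "u2"], sorted_tcrs={"s1": {"T"}})
        plain = compute_es(design, m)
        stud = compute_es(design, m, studentize=True)
        sd = plain.models_["s1"].resid_sd
        assert np.allclose(stud.es_["s1"].values, plain.es_["s1"].values / sd)


class TestZonesAndHits:
    def test_single_cognate_thresholds(self):
        es = pd.Series({"cog": 10.0, "other": 1.0})
        zones = calibrate_zones(es, ["cog"], fractions=(0.5, 0.25))
        assert zones.high_threshold == 5.0 and zones.low_threshold == 2.5

    def test_min_then_scale(self):
        es = pd.Series({"a": 12.0, "b": 8.0})
        zones = calibrate_zones(es, ["a", "b"])
        assert zones.high_threshold == 4.0 and zones.low_threshold == 2.0
        assert zones.provenance["base"] == 8.0

    def test_nonpositive_cognate_es_is_failed_screen(self):
        es = pd.Series({"cog": -1.0})
        with pytest.raises(ValueError, match="failed screen"):
            calibrate_zones(es, ["cog"])

    def test_tier_boundaries(self):
        zones = ConfidenceZones(high_threshold=5, low_threshold=2.5)
        assert zones.tier(6) == "high"
        assert zones.tier(5) == "high"  # boundary inclusive
        assert zones.tier(3) == "low"
        assert zones.tier(2) == "none"

    def test_hits_sorted_desc_then_id(self):
        zones = ConfidenceZones(high_threshold=5, low_threshold=2.5)
        es = pd.Series({"b": 6.0, "a": 6.0, "c": 3.0, "d": 1.0})
        hits = call_hits(es, zones)
        assert list(hits.index) == ["a", "b", "c"]
        assert list(hits["tier"]) == ["high", "high", "low"]

    def test_invalid_zone_ordering_rejected(self):
        with pytest.raises(ValueError):
            ConfidenceZones(high_threshold=1.0, low_threshold=2.0)


class TestSimulatedScreens:
    def test_single_inflated_cognate_has_max_mean_es(self):
        params = SimulationParams(n_epitopes=400, n_cells=100_000,
                                  reads_per_sample=50_000,
                                  cognate_map={"4-8Ins": "epi0010"}, seed=21)
        matrix, _, _, _ = simulate_screen(
            params, {f"s{i}": {"4-8Ins"} for i in (1, 2, 3)})
        design = ScreenDesign(unsorted=["unsorted_1", "unsorted_2", "unsorted_3"],
                              sorted_tcrs={f"s{i}": {"4-8Ins"} for i in (1, 2, 3)})
        scorer = compute_es(design, matrix)
        assert scorer.mean_es("4-8Ins").idxmax() == "epi0010"

    def test_three_seeded_cognates_called_exactly(self):
        cognates = ["epi0003", "epi0177", "epi0404"]
        params = SimulationParams(n_epitopes=500, n_cells=200_000,
                                  reads_per_sample=100_000,
                                  cognate_map={"ctl": cognates}, seed=22)
        matrix, _, _, _ = simulate_screen(
            params, {f"s{i}": {"ctl"} for i in (1, 2, 3)})
        design = ScreenDesign(unsorted=["unsorted_1", "unsorted_2", "unsorted_3"],
                              sorted_tcrs={f"s{i}": {"ctl"} for i in (1, 2, 3)},
                              control_tcr="ctl", control_cognates=frozenset(cognates))
        scorer = compute_es(design, matrix)
        zones = calibrate_zones(scorer.mean_es("ctl"), cognates)
        hits = call_hits(scorer.mean_es("ctl"), zones)
        assert set(hits.index) == set(cognates)


class TestDropout:
    def _loo_design(self, tcrs):
        all_t = set(tcrs)
        return ScreenDesign(
            unsorted=["unsorted_1", "unsorted_2", "unsorted_3"],
            sorted_tcrs={f"rep_{t}": frozenset(all_t - {t}) for t in tcrs},
        )

    def test_tcr_in_all_replicates_plain_mode_is_overall_mean(self):
        rng = np.random.default_rng(9)
        m = _matrix({k: rng.integers(1, 500, size=30)
                     for k in ("u1", "u2", "s1", "s2", "s3")})
        design = ScreenDesign(unsorted=["u1", "u2"],
                              sorted_tcrs={s: {"T", f"other{s}"} for s in
                                           ("s1", "s2", "s3")})
        scores = dropout_deconvolute(design, m)
        scorer = compute_es(design, m)
        assert np.allclose(scores["T"].values, scorer.es_.mean(axis=1).values)

    def test_contrast_impossible_when_never_dropped(self):
        rng = np.random.default_rng(10)
        m = _matrix({k: rng.integers(1, 500, size=10)
                     for k in ("u1", "u2", "s1", "s2")})
        design = ScreenDesign(unsorted=["u1", "u2"],
                              sorted_tcrs={"s1": {"T"}, "s2": {"T"}})
        with pytest.raises(ValueError, match="every replicate"):
            dropout_deconvolute(design, m, contrast=True)

    def test_contrast_sharpens_tcr_assignment(self):
        # In a leave-one-out multiplex, a cognate epitope is enriched in most
        # replicates, so its plain score is elevated under every TCR; contrast
        # mode subtracts the left-out replicates and should widen the margin
        # between the owning TCR and the runner-up TCR for that epitope.
        tcrs = [f"T{i}" for i in range(1, 5)]
        cognate_map = {t: f"epi{i:04d}" for i, t in enumerate(tcrs, start=1)}
        params = SimulationParams(n_epitopes=300, n_cells=150_000,
                                  reads_per_sample=60_000,
                                  cognate_map=cognate_map, seed=30)
        design = self._loo_design(tcrs)
        matrix, _, _, _ = simulate_screen(params, dict(design.sorted_tcrs))
        plain = dropout_deconvolute(design, matrix)
        contrast = dropout_deconvolute(design, matrix, contrast=True)
        for t, cog in cognate_map.items():
            assert plain[t].idxmax() == cog
            others = [o for o in tcrs if o != t]
            plain_margin = plain.loc[cog, t] - max(plain.loc[cog, o] for o in others)
            contrast_margin = contrast.loc[cog, t] - max(contrast.loc[cog, o]
                                                         for o in others)
            assert contrast_margin > plain_margin > 0
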