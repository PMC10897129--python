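"""Synthetic screen generator: seeding, formula, clamps, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import dblipid as dl
from dblipid.synthetic_screen import ScreenParams


@pytest.fixture(scope="module")
def candidates():
    registry = dl.default_registry()
    table, _ = dl.screen_library(
        registry, [dl.library_1_design(registry), dl.library_2_design(registry)]
    )
    return table[["name", "deviation", "total_carbons", "predicted_potent"]]


class TestSimulate:
    def test_same_seed_identical_output(self, candidates):
        a = dl.simulate(candidates, ScreenParams(seed=42))
        b = dl.simulate(candidates, ScreenParams(seed=42))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, candidates):
        a = dl.simulate(candidates, ScreenParams(seed=1))
        b = dl.simulate(candidates, ScreenParams(seed=2))
        assert not np.allclose(a["invivo_flux"], b["invivo_flux"])

    def test_zero_noise_fixed_boost_formula(self):
        """Compliant lipidoid, boost pinned at 2: flux is exactly bg x 10^2."""
        cands = pd.DataFrame(
            {
                "name": ["1-10-8"],
                "deviation": [0.0],
                "total_carbons": [18],
                "predicted_potent": [True],
            }
        )
        params = ScreenParams(
            seed=0, boost_range=(2.0, 2.0), invivo_noise_sd=0.0, invitro_noise_sd=0.0
        )
        rec = dl.simulate(cands, params)
        assert rec["invivo_flux"].iloc[0] == pytest.approx(
            10**params.log10_bg_flux * 100, rel=1e-9
        )

    def test_noncompliant_sits_at_background(self):
        cands = pd.DataFrame(
            {
                "name": ["2-10-8"],
                "deviation": [0.0],
                "total_carbons": [18],
                "predicted_potent": [False],
            }
        )
        params = ScreenParams(seed=0, invivo_noise_sd=0.0, invitro_noise_sd=0.0)
        rec = dl.simulate(cands, params)
        assert rec["invivo_flux"].iloc[0] == pytest.approx(
            10**params.log10_bg_flux, rel=1e-9
        )
        assert 10**params.log10_bg_flux < 1e7  # background below 10^7 p/s

    @pytest.mark.parametrize("seed", range(8))
    def test_every_hit_clears_the_invitro_threshold(self, candidates, seed):
        """Necessity clamp: P(in vitro >= 10^4 | hit) = 1 on every seed."""
        rec = dl.simulate(candidates, ScreenParams(seed=seed))
        hits = rec[rec["is_hit"]]
        assert (hits["invitro_rlu"] >= 1e4).all()

    def test_readouts_positive(self, candidates):
        rec = dl.simulate(candidates, ScreenParams(seed=0))
        assert (rec["invitro_rlu"] > 0).all()
        assert (rec["invivo_flux"] > 0).all()

    def test_boost_range_bounds_mean_group_difference(self, candidates):
        """With slopes zeroed, the compliant-vs-not mean log10 gap is inside
        the boost range."""
        params = ScreenParams(
            seed=5, deviation_slope=0.0, carbon_penalty=0.0, invivo_noise_sd=0.1
        )
        rec = dl.simulate(candidates, params).merge(candidates, on="name")
        gap = (
            np.log10(rec.loc[rec.predicted_potent, "invivo_flux"]).mean()
            - np.log10(rec.loc[~rec.predicted_potent, "invivo_flux"]).mean()
        )
        assert 1.0 <= gap <= 3.0

    def test_empty_input(self):
        empty = pd.DataFrame(
            columns=["name", "deviation", "total_carbons", "predicted_potent"]
        )
        assert len(dl.simulate(empty, ScreenParams(seed=0))) == 0

    def test_missing_columns_rejected(self):
        with pytest.raises(dl.ValidationError, match="missing columns"):
            dl.simulate(pd.DataFrame({"name": ["x"]}), ScreenParams(seed=0))

    def test_invalid_params_rejected(self):
        with pytest.raises(dl.ValidationError):
            ScreenParams(boost_range=(3.0, 1.0))
        with pytest.raises(dl.ValidationError):
            ScreenParams(rho=1.5)
        with pytest.raises(dl.ValidationError):
            ScreenParams(invivo_noise_sd=-0.1)


class TestCorrelationStructure:
    def test_uncoupled_channels_mostly_non_significant(self, candidates):
        """rho=0: the in vitro/in vivo correlation is non-significant
        (alpha=0.05) in at least 80% of seeds."""
        nonsig = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rec = dl.simulate(candidates, ScreenParams(seed=seed))
            if dl.correlation_test(rec)["p"] >= 0.05:
                nonsig += 1
        assert nonsig / n_seeds >= 0.8

    def test_strong_coupling_detected(self):
        """rho near 1 on structure-free candidates (where noise is the only
        in vivo variance) produces a clearly significant correlation."""
        cands = pd.DataFrame(
            {
                "name": [f"c{i}" for i in range(40)],
                "deviation": 0.5,
                "total_carbons": 16,
                "predicted_potent": False,
            }
        )
        rec = dl.simulate(cands, ScreenParams(seed=0, rho=0.9))
        assert dl.correlation_test(rec)["p"] < 0.05


class TestRecoverParameters:
    def test_zero_noise_exact_recovery(self, factorial_verdicts):
        table, _ = factorial_verdicts
        cands = table[["name", "deviation", "total_carbons", "predicted_potent"]]
        params = ScreenParams(
            seed=3, boost_range=(2.0, 2.0), invivo_noise_sd=0.0, invitro_noise_sd=0.0
        )
        rec = dl.simulate(cands, params)
        est = dl.recover_parameters(rec, cands, n_boot=50, seed=1)
        assert est.deviation_slope == pytest.approx(0.8, abs=1e-9)
        assert est.carbon_penalty == pytest.approx(0.5, abs=1e-9)
        assert est.boost_mean == pytest.approx(2.0, abs=1e-9)

    def test_noisy_recovery_within_ci(self, factorial_verdicts):
        """n=500, noise 0.2: the 95% CIs cover the generating slopes in at
        least 4 of 5 independent replicates (a CI is a random interval)."""
        table, _ = factorial_verdicts
        cands = table[["name", "deviation", "total_carbons", "predicted_potent"]]
        slope_cover = penalty_cover = 0
        for seed in range(5):
            params = ScreenParams(seed=seed, deviation_slope=0.8, invivo_noise_sd=0.2)
            rec = dl.simulate(cands, params)
            est = dl.recover_parameters(rec, cands, n_boot=500, seed=seed)
            slope_cover += (
                est.deviation_slope_ci[0] <= 0.8 <= est.deviation_slope_ci[1]
            )
            penalty_cover += (
                est.carbon_penalty_ci[0] <= 0.5 <= est.carbon_penalty_ci[1]
            )
        assert slope_cover >= 4
        assert penalty_cover >= 4

    def test_shuffled_labels_cover_zero(self, factorial_verdicts):
        """Permuting structure labels destroys the effects: CIs cover 0."""
        table, _ = factorial_verdicts
        cands = table[["name", "deviation", "total_carbons", "predicted_potent"]]
        rec = dl.simulate(cands, ScreenParams(seed=7))
        rng = np.random.default_rng(7)
        shuffled = cands.copy().reset_index(drop=True)
        perm = rng.permutation(len(shuffled))
        for col in ("deviation", "total_carbons", "predicted_potent"):
            shuffled[col] = shuffled[col].to_numpy()[perm]
        est = dl.recover_parameters(rec, shuffled, n_boot=300, seed=2)
        assert est.deviation_slope_ci[0] <= 0.0 <= est.deviation_slope_ci[1]

    def test_too_few_records_rejected(self, candidates):
        rec = dl.simulate(candidates.head(5), ScreenParams(seed=0))
        with pytest.raises(dl.ValidationError, match="at least 20"):
            dl.recover_parameters(rec, candidates.head(5))

    def test_rank_deficiency_rejected(self):
        cands = pd.DataFrame(
            {
                "name": [f"c{i}" for i in range(30)],
                "deviation": [0.5] * 30,
                "total_carbons": [18] * 30,
                "predicted_potent": [True] * 30,
            }
        )
        rec = dl.simulate(cands, ScreenParams(seed=0))
        with pytest.raises(dl.ValidationError, match="rank deficient"):
            dl.recover_parameters(rec, cands)
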