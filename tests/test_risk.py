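"""The intake/risk equations, Monte Carlo driver, and summaries.

Hand-derived oracle values used throughout:
  EDI (non-carcinogenic, mean As, mean AC)
      = 13.51 × 318.9 × 0.1 / (63 × 365 × 1000) = 1.8736e-5 mg/(kg·d)
  HQ_As = 1.8736e-5 / 0.0003 = 0.06245
  EDI (carcinogenic, E_D=40) = 13.51 × 318.9 × 40 × 0.1 / (63 × 70×365 × 1000)
      = 1.0706e-5;  CRi_As = 1.0706e-5 × 1.5 = 1.606e-5
"""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pheretima_risk.datamodel import (
    CARCINOGENS,
    MEASURED_METALS,
    ExposureConfig,
    default_tox_table,
)
from pheretima_risk.errors import ConfigurationError, ValidationError
from pheretima_risk.risk import (
    compute_cri,
    compute_crt,
    compute_edi,
    compute_hi,
    compute_hq,
    deterministic_assessment,
    run_monte_carlo,
    summarize,
)
from pheretima_risk.synthetic import (
    MetalModel,
    calibrate_consumption,
    CONSUMPTION_ANCHORS,
    sample_consumption,
)

NC = ExposureConfig(averaging_mode="noncarcinogenic")
CARC40 = ExposureConfig(
    averaging_mode="carcinogenic", exposure_duration=40, seed=0
)

AS_MEAN = 13.51
AC_MEAN = 318.9


def point_mass_models(means: dict[str, float]) -> dict[str, MetalModel]:
    """Degenerate concentration models fixed at the supplied means."""
    return {
        m: MetalModel(
            metal=m,
            family="lognormal",
            params=(1e-12, means[m]),
            target_mean=means[m],
            target_exceedance=0.0,
        )
        for m in means
    }


class TestEquations:
    def test_edi_noncarcinogenic_hand_value(self):
        edi = compute_edi(AS_MEAN, AC_MEAN, NC)
        assert edi == pytest.approx(1.8736e-5, rel=1e-4)

    def test_edi_carcinogenic_hand_value(self):
        edi = compute_edi(AS_MEAN, AC_MEAN, CARC40)
        assert edi == pytest.approx(1.0706e-5, rel=1e-4)

    def test_zero_concentration_gives_zero_intake(self):
        assert compute_edi(0.0, 500.0, NC) == 0.0

    def test_hq_hand_value_and_threshold_case(self):
        edi = compute_edi(AS_MEAN, AC_MEAN, NC)
        assert compute_hq(edi, 0.0003) == pytest.approx(0.06245, rel=1e-3)
        assert compute_hq(0.0003, 0.0003) == 1.0

    def test_hq_rejects_nonpositive_rfd(self):
        with pytest.raises(ValidationError):
            compute_hq(1e-5, 0.0)

    def test_hi_sums_quotients(self):
        assert compute_hi({"As": 0.5, "Cd": 0.3}) == pytest.approx(0.8)
        assert compute_hi({"As": 0.7}) == pytest.approx(0.7)

    def test_cri_hand_value_and_crt_sum(self):
        cri = compute_cri(1.0706e-5, 1.5)
        assert cri == pytest.approx(1.606e-5, rel=1e-3)
        assert compute_crt({"As": 1e-5, "Cr": 2e-5, "Cd": 0.0, "Pb": 0.0}) == pytest.approx(3e-5)

    @given(
        ci=st.floats(min_value=0, max_value=1e3),
        ac=st.floats(min_value=1e-3, max_value=1e5),
        factor=st.floats(min_value=0.1, max_value=10),
    )
    @settings(derandomize=True, max_examples=50)
    def test_edi_homogeneous_of_degree_one(self, ci, ac, factor):
        base = compute_edi(ci, ac, NC)
        assert compute_edi(ci * factor, ac, NC) == pytest.approx(factor * base, rel=1e-9)
        assert compute_edi(ci, ac * factor, NC) == pytest.approx(factor * base, rel=1e-9)

    def test_noncarcinogenic_edi_invariant_to_duration(self):
        for ed in (5, 20, 40):
            cfg = ExposureConfig(averaging_mode="noncarcinogenic", exposure_duration=ed)
            assert compute_edi(AS_MEAN, AC_MEAN, cfg) == pytest.approx(
                compute_edi(AS_MEAN, AC_MEAN, NC), rel=1e-12
            )

    def test_carcinogenic_edi_proportional_to_duration(self):
        cfg20 = ExposureConfig(averaging_mode="carcinogenic", exposure_duration=20)
        cfg40 = ExposureConfig(averaging_mode="carcinogenic", exposure_duration=40)
        assert compute_edi(AS_MEAN, AC_MEAN, cfg40) == pytest.approx(
            2 * compute_edi(AS_MEAN, AC_MEAN, cfg20), rel=1e-12
        )


@pytest.fixture(scope="module")
def consumption_model():
    return calibrate_consumption(*CONSUMPTION_ANCHORS["annual_consumption"])


@pytest.fixture(scope="module")
def calibrated_draws(metal_models, consumption_model):
    config = ExposureConfig(n_iterations=10_000, seed=123)
    return run_monte_carlo(metal_models, consumption_model, config, user_class="random")


# re-export the session fixture for module-scoped composition
@pytest.fixture(scope="module")
def metal_models():
    from pheretima_risk.synthetic import default_metal_models

    return default_metal_models()


class TestMonteCarlo:
    def test_degenerate_distributions_reproduce_deterministic_value(self, consumption_model):
        means = {m: AS_MEAN if m == "As" else 1.0 for m in MEASURED_METALS}
        config = ExposureConfig(n_iterations=200, seed=1)
        draws = run_monte_carlo(
            point_mass_models(means), consumption_model, config, user_class="average"
        )
        expected = compute_hq(compute_edi(AS_MEAN, consumption_model.mean, config), 0.0003)
        assert np.allclose(draws.hq["As"], expected, rtol=1e-6)

    def test_hi_is_row_sum_of_hq(self, calibrated_draws):
        assert np.allclose(
            calibrated_draws.hi, calibrated_draws.hq.sum(axis=1), rtol=1e-12
        )

    def test_crt_is_row_sum_over_carcinogens(self, calibrated_draws):
        assert list(calibrated_draws.cri.columns) == list(CARCINOGENS)
        assert np.allclose(
            calibrated_draws.crt, calibrated_draws.cri.sum(axis=1), rtol=1e-12
        )

    def test_aggregates_dominate_components(self, calibrated_draws):
        assert (calibrated_draws.hi >= calibrated_draws.hq.max(axis=1) - 1e-15).all()
        assert (calibrated_draws.crt >= calibrated_draws.cri.max(axis=1) - 1e-15).all()

    def test_mean_edi_matches_independence_factorisation(
        self, metal_models, consumption_model, calibrated_draws
    ):
        # E[EDI] = E[C] · E[AC] · T / (BW · 365 · 1000) under independence
        cfg = calibrated_draws.config
        n = calibrated_draws.n_iterations
        for metal in ("As", "Mn", "Cd"):
            model = metal_models[metal]
            expected = (
                model.target_mean * consumption_model.mean * cfg.transfer_ratio
                / (cfg.body_weight * 365.0 * 1000.0)
            )
            draws = calibrated_draws.edi[metal].to_numpy()
            se = draws.std() / np.sqrt(n)
            assert abs(draws.mean() - expected) < 3 * se

    def test_duration_doubling_doubles_cancer_risk_on_same_seed(
        self, metal_models, consumption_model
    ):
        cfg20 = ExposureConfig(
            averaging_mode="carcinogenic", exposure_duration=20, n_iterations=500, seed=77
        )
        cfg40 = dataclasses.replace(cfg20, exposure_duration=40)
        d20 = run_monte_carlo(metal_models, consumption_model, cfg20)
        d40 = run_monte_carlo(metal_models, consumption_model, cfg40)
        assert np.allclose(d40.cri.to_numpy(), 2 * d20.cri.to_numpy(), rtol=1e-12)

    def test_seed_determinism_bit_identical(self, metal_models, consumption_model):
        cfg = ExposureConfig(n_iterations=300, seed=5)
        a = run_monte_carlo(metal_models, consumption_model, cfg)
        b = run_monte_carlo(metal_models, consumption_model, cfg)
        assert a.edi.equals(b.edi) and a.crt.equals(b.crt)

    def test_single_iteration(self, metal_models, consumption_model):
        cfg = ExposureConfig(n_iterations=1, seed=0)
        draws = run_monte_carlo(metal_models, consumption_model, cfg)
        assert draws.n_iterations == 1
        assert draws.hi.iloc[0] == pytest.approx(draws.hq.iloc[0].sum())

    def test_records_user_classes(self, metal_models, consumption_model):
        records = sample_consumption(consumption_model, 2_000, seed=3)
        cfg = ExposureConfig(n_iterations=400, seed=9)
        avg = run_monte_carlo(metal_models, records, cfg, user_class="average")
        high = run_monte_carlo(metal_models, records, cfg, user_class="high")
        # fixed-AC classes scale every iteration by the same factor
        ratio = np.percentile(records.annual_consumption, 95) / np.mean(
            records.annual_consumption
        )
        assert np.allclose(high.edi.to_numpy(), ratio * avg.edi.to_numpy(), rtol=1e-9)

    def test_missing_distribution_is_configuration_error(self, metal_models, consumption_model):
        partial = {m: d for m, d in metal_models.items() if m != "Pb"}
        with pytest.raises(ConfigurationError):
            run_monte_carlo(partial, consumption_model, ExposureConfig())

    def test_unknown_user_class_rejected(self, metal_models, consumption_model):
        with pytest.raises(ValidationError):
            run_monte_carlo(
                metal_models, consumption_model, ExposureConfig(n_iterations=10), user_class="vip"
            )


class TestSummaries:
    def test_point_mass_percentiles_all_equal(self, consumption_model):
        means = {m: 10.0 for m in MEASURED_METALS}
        cfg = ExposureConfig(n_iterations=100, seed=2)
        draws = run_monte_carlo(
            point_mass_models(means), consumption_model, cfg, user_class="average"
        )
        summary = summarize(draws)
        row = summary.table.loc["HQ_As"]
        for col in ("min", "P10", "P50", "P97.5", "max"):
            assert row[col] == pytest.approx(row["mean"], rel=1e-9)
        assert row["exceedance"] == 0.0

    def test_exceedance_counts_fraction_above_threshold(self, calibrated_draws):
        summary = summarize(calibrated_draws)
        manual = float((calibrated_draws.hq["As"] > 1.0).mean())
        assert summary.exceedance("HQ_As") == manual

    def test_percentile_ordering_invariant(self, calibrated_draws):
        table = summarize(calibrated_draws).table
        ordered = ["min", "P10", "P25", "P50", "P75", "P90", "P95", "P97.5", "max"]
        for _, row in table.iterrows():
            vals = row[ordered].to_numpy(dtype=float)
            assert (np.diff(vals) >= -1e-15).all()

    def test_two_draw_exceedance(self):
        # counting semantics on a tiny hand-built set of draws
        cfg = ExposureConfig(n_iterations=2, seed=0)
        hq = pd.DataFrame({m: [0.5, 1.5] if m == "As" else [0.0, 0.0] for m in MEASURED_METALS})
        edi = hq * 0.0003
        cri = pd.DataFrame({m: [0.0, 0.0] for m in CARCINOGENS})
        from pheretima_risk.risk import RiskDraws

        draws = RiskDraws(
            edi=edi, hq=hq, cri=cri, hi=hq.sum(axis=1), crt=cri.sum(axis=1), config=cfg
        )
        assert summarize(draws).exceedance("HQ_As") == 0.5


class TestDeterministic:
    def test_average_and_high_user_hand_values(self):
        conc_mean = {m: AS_MEAN if m == "As" else 1.0 for m in MEASURED_METALS}
        conc_p95 = dict(conc_mean)
        out = deterministic_assessment(
            conc_mean, conc_p95, ac_mean=318.9, ac_p95=1050.0, config=NC
        )
        assert out.loc["HQ_As", "average"] == pytest.approx(0.06245, rel=1e-3)
        assert out.loc["HQ_As", "high"] == pytest.approx(0.2056, rel=1e-3)

    def test_zero_concentrations_give_zero_risk(self):
        zeros = {m: 0.0 for m in MEASURED_METALS}
        out = deterministic_assessment(zeros, zeros, 318.9, 1050.0, NC)
        assert (out.loc[[i for i in out.index if i.startswith(("HQ", "CRi"))]] == 0).all().all()
        assert out.loc["HI", "average"] == 0.0

    def test_matches_degenerate_monte_carlo(self, consumption_model):
        means = {m: 5.0 for m in MEASURED_METALS}
        cfg = ExposureConfig(n_iterations=50, seed=4)
        draws = run_monte_carlo(
            point_mass_models(means), consumption_model, cfg, user_class="average"
        )
        det = deterministic_assessment(
            means, means, ac_mean=consumption_model.mean,
            ac_p95=float(consumption_model.ppf(0.95)), config=cfg,
        )
        summary = summarize(draws).table
        for m in MEASURED_METALS:
            assert summary.loc[f"HQ_{m}", "P50"] == pytest.approx(
                det.loc[f"HQ_{m}", "average"], rel=1e-6
            )
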