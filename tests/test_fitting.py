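import subprocess

import numpy as np
import pandas as pd
import pytest

from phenorate.fitting import (
    TrialObservation,
    build_design_matrix,
    fit_rate_model,
    predict_static,
)
from phenorate.genetics import CALIMA, JAMAPA, MIDPARENT, QTLGenotype
from phenorate.phenology import DailyWeatherSeries, simulate_flowering
from phenorate.rate_model import EnvironmentVector, development_rate
from phenorate.synthetic import (
    DEFAULT_SITE_PROFILES,
    SimulationTruth,
    default_residual_model,
    generate_family_genotypes,
    generate_weather,
    mean_environments,
    rate_scale_observations,
)


def _synthetic_obs(n_rils, sd, correlation, seed, n_sites=5, windowed=False):
    from phenorate.rate_model import default_parameters

    p = default_parameters()
    profs = DEFAULT_SITE_PROFILES[:n_sites]
    sites = [pr.label for pr in profs]
    rng = np.random.default_rng(seed)
    genos = generate_family_genotypes(n_rils, seed=rng)
    weather = {pr.label: generate_weather(pr, seed=rng) for pr in profs}
    env = weather if windowed else mean_environments(weather)
    residual = default_residual_model(sites, sd=sd, correlation=correlation)
    truth = SimulationTruth(p, residual, seed=int(rng.integers(2**31)))
    return rate_scale_observations(genos, env, truth), p, residual


class TestDesignMatrix:
    def test_default_structure_has_25_columns(self):
        obs, p, _ = _synthetic_obs(30, 1e-9, 0.0, seed=1)
        X, y, labels = build_design_matrix(obs)
        assert X.shape[1] == 25
        assert len(labels) == 25
        assert labels[0] == "mu_c"

    def test_centered_midparent_row_is_unit_vector(self, params):
        env = EnvironmentVector(DL=12.37, Srad=18.218, Tmax=27.458, Tmin=16.128)
        obs = [TrialObservation("mid", "S1", 42.0, env, MIDPARENT)]
        X, y, _ = build_design_matrix(obs)
        assert X[0] == pytest.approx([1.0] + [0.0] * 24)
        assert y[0] == pytest.approx(1 / 42.0)

    def test_interaction_column_is_hand_product(self, params):
        env = EnvironmentVector(DL=11.5, Srad=18.2719, Tmax=29, Tmin=21)
        obs = [TrialObservation("cal", "S1", 33.0, env, CALIMA)]
        X, _, labels = build_design_matrix(obs)
        col = labels.index("gamma[DL:TF3]")
        assert X[0, col] == pytest.approx(-0.87 * 1, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        # all observations share one genotype: every operator column is
        # confounded with the intercept
        env = EnvironmentVector(DL=12.0, Srad=18.0, Tmax=27.0, Tmin=16.0)
        obs = [
            TrialObservation(f"r{i}", "S1", 30.0 + i, env, CALIMA) for i in range(30)
        ]
        with pytest.raises(ValueError, match="rank-deficient"):
            build_design_matrix(obs)


class TestFitRateModel:
    def test_noiseless_recovery_exact(self):
        obs, truth_p, _ = _synthetic_obs(60, 1e-12, 0.0, seed=3, windowed=True)
        model = fit_rate_model(obs, method="REML")
        got = model.parameters.coefficient_vector()
        want = truth_p.coefficient_vector()
        assert np.abs(got - want).max() < 1e-8
        assert model.n_fixed_parameters == 25

    def test_single_site_equals_ols(self):
        """With one site the GLS/REML fixed effects collapse to ordinary
        least squares on the 25-column design (closed-form oracle)."""
        obs, _, _ = _synthetic_obs(80, 0.0015, 0.0, seed=4, n_sites=1, windowed=True)
        model = fit_rate_model(obs, method="REML")
        X, y, _ = build_design_matrix(obs)
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert model.parameters.coefficient_vector() == pytest.approx(
            b_ols, abs=1e-8
        )

    def test_reml_invariant_to_observation_order(self):
        obs, _, _ = _synthetic_obs(40, 0.0012, 0.3, seed=5, n_sites=3, windowed=True)
        m1 = fit_rate_model(obs, method="REML")
        rng = np.random.default_rng(0)
        shuffled = list(obs)
        rng.shuffle(shuffled)
        m2 = fit_rate_model(shuffled, method="REML")
        assert m1.parameters.coefficient_vector() == pytest.approx(
            m2.parameters.coefficient_vector(), abs=1e-6
        )
        assert m1.residual.covariance == pytest.approx(
            m2.residual.covariance, rel=1e-3
        )

    def test_unbalanced_sites_fit_via_subblocks(self):
        obs, truth_p, _ = _synthetic_obs(100, 0.0008, 0.3, seed=6, n_sites=3, windowed=True)
        # drop ~20% of records so lines are observed at site subsets
        rng = np.random.default_rng(1)
        keep = rng.random(len(obs)) > 0.2
        obs = [o for o, k in zip(obs, keep) if k]
        model = fit_rate_model(obs, method="REML")
        assert model.converged
        got = model.parameters.coefficient_vector()
        want = truth_p.coefficient_vector()
        # environmental mains are the loosest; genetic terms are tight
        assert np.abs(got[5:] - want[5:]).max() < 5e-4

    def test_bias_shrinks_with_noise(self):
        """|coefficient error| decreases as the residual sd shrinks."""
        errs = []
        for sd in (2e-3, 5e-4, 1e-5):
            obs, truth_p, _ = _synthetic_obs(60, sd, 0.2, seed=7, n_sites=3, windowed=True)
            model = fit_rate_model(obs, method="ML")
            errs.append(
                np.abs(
                    model.parameters.coefficient_vector() - truth_p.coefficient_vector()
                ).max()
            )
        assert errs[2] < errs[1] < errs[0]

    def test_residual_covariance_estimated(self):
        obs, _, truth_R = _synthetic_obs(400, 0.0015, 0.4, seed=8, n_sites=3, windowed=True)
        model = fit_rate_model(obs, method="REML")
        got = model.residual.covariance
        want = truth_R.covariance
        assert np.abs(np.diag(got) - np.diag(want)).max() < 0.35 * want[0, 0]

    def test_more_parameters_than_observations_rejected(self):
        obs, _, _ = _synthetic_obs(4, 1e-4, 0.0, seed=9, n_sites=1)
        with pytest.raises(ValueError, match="more observations"):
            fit_rate_model(obs)


def test_reml_matches_nlme_gls_oracle(tmp_path):
    """Independent cross-check: nlme::gls with corSymm + varIdent fits the
    same unstructured across-site covariance model by REML."""
    obs, _, _ = _synthetic_obs(40, 0.0015, 0.4, seed=11, n_sites=3, windowed=True)
    model = fit_rate_model(obs, method="REML")
    X, y, _ = build_design_matrix(obs)
    df = pd.DataFrame(X[:, 1:], columns=[f"x{i}" for i in range(1, X.shape[1])])
    df["y"] = y
    df["ril"] = [o.ril for o in obs]
    df["site"] = [o.site for o in obs]
    fixture = tmp_path / "gls_fixture.csv"
    df.to_csv(fixture, index=False)
    rscript = tmp_path / "gls.R"
    rscript.write_text(
        """
        suppressMessages(library(nlme))
        args <- commandArgs(trailingOnly=TRUE)
        d <- read.csv(args[1])
        xs <- paste0("x", 1:24)
        f <- as.formula(paste("y ~", paste(xs, collapse="+")))
        fit <- gls(f, data=d,
                   correlation=corSymm(form=~1|ril),
                   weights=varIdent(form=~1|site),
                   method="REML",
                   control=glsControl(maxIter=200, msMaxIter=200, tolerance=1e-10))
        write.csv(data.frame(coef=coef(fit)), args[2], row.names=FALSE)
        """
    )
    out = tmp_path / "gls_coef.csv"
    subprocess.run(
        ["Rscript", str(rscript), str(fixture), str(out)],
        check=True, capture_output=True, cwd=tmp_path,
    )
    theirs = pd.read_csv(out)["coef"].to_numpy()
    ours = model.parameters.coefficient_vector()
    assert np.abs(ours - theirs).max() < 1e-5


class TestPredictStatic:
    def test_midparent_at_centers(self, params):
        env = EnvironmentVector(DL=12.37, Srad=18.218, Tmax=27.458, Tmin=16.128)
        obs = TrialObservation("mid", "S", 42.0, env, MIDPARENT)
        assert predict_static(params, obs) == pytest.approx(
            1 / 0.0235198065831426, rel=1e-12
        )

    def test_calima_warm_short_day(self, params, warm_short_day):
        obs = TrialObservation("cal", "S", 33.0, warm_short_day, CALIMA)
        assert predict_static(params, obs) == pytest.approx(33.08, abs=5e-3)

    def test_reciprocal_of_development_rate(self, params, mild_short_day):
        obs = TrialObservation("jam", "S", 44.0, mild_short_day, JAMAPA)
        assert predict_static(params, obs) == pytest.approx(
            1 / development_rate(mild_short_day, JAMAPA, params), rel=1e-12
        )

    def test_nonpositive_rate_returns_none(self, params):
        cold_long = EnvironmentVector(DL=18.5, Srad=18.2719, Tmax=10.0, Tmin=2.0)
        obs = TrialObservation("cal", "S", 200.0, cold_long, CALIMA)
        assert predict_static(params, obs) is None

    def test_static_equals_dynamic_at_constant_mean_environment(self, params, warm_short_day):
        """Pushing the same constant mean environment through the dynamic
        integrator returns the static prediction (interpolation identity)."""
        obs = TrialObservation("cal", "S", 33.0, warm_short_day, CALIMA)
        ttf_static = predict_static(params, obs)
        series = DailyWeatherSeries.constant(warm_short_day, 200)
        ttf_dynamic = simulate_flowering(series, CALIMA, params).day_interpolated
        assert ttf_static == pytest.approx(ttf_dynamic, rel=1e-9)
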