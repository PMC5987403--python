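import numpy as np
import pytest

from pedeval.multivariate import (
    BivariateSpec,
    CovarianceComponents,
    correlations,
    fit_bivariate,
    fit_gxe,
)
from pedeval.reml import DesignError, ModelSpec, fit
from pedeval.simulate import SimulationConfig, simulate


def two_trait_config(rg=0.6, re=0.3, seed=0, **kw):
    return SimulationConfig(
        trait_names=("w3", "w4"),
        trait_means={"w3": 492.8, "w4": 1073.0},
        phenotypic_sd={"w3": 150.9, "w4": 131.3},
        h2=0.4, c2=0.15,
        genetic_corr=np.array([[1.0, rg], [rg, 1.0]]),
        residual_corr=np.array([[1.0, re], [re, 1.0]]),
        seed=seed, **kw,
    )


def manual_cc(params, theta, cov=None):
    theta = np.asarray(theta, dtype=float)
    info = np.linalg.inv(cov) if cov is not None else np.eye(len(theta))
    return CovarianceComponents(
        traits=("a", "b"), params=params, theta=theta, loglik=0.0,
        info_matrix=info, converged=True, n_iterations=1, n_obs=10,
    )


PARAMS = [("S", 0, 0), ("S", 0, 1), ("S", 1, 1),
          ("C", 0, 0), ("C", 0, 1), ("C", 1, 1),
          ("E", 0, 0), ("E", 1, 1), ("E", 0, 1)]


class TestCorrelations:
    def test_zero_covariance_zero_correlation(self):
        cc = manual_cc(PARAMS, [0.2, 0.0, 0.3, 0.1, 0.0, 0.1, 0.6, 0.5, 0.0])
        out = correlations(cc)
        assert out["genetic"].value == 0.0
        assert out["phenotypic"].value == 0.0

    def test_unit_correlation(self):
        s12 = np.sqrt(0.2 * 0.3)
        cc = manual_cc(PARAMS, [0.2, s12, 0.3, 0.1, 0.0, 0.1, 0.6, 0.5, 0.0])
        assert correlations(cc)["genetic"].value == pytest.approx(1.0)

    def test_delta_se_matches_numerical_jacobian(self):
        rng = np.random.default_rng(11)
        for _ in range(8):
            v = rng.uniform(0.1, 1.0, size=9)
            v[1] = 0.5 * np.sqrt(v[0] * v[2])
            v[4] = -0.3 * np.sqrt(v[3] * v[5])
            v[8] = 0.2 * np.sqrt(v[6] * v[7])
            L = rng.uniform(-0.05, 0.05, size=(9, 9))
            cov = L @ L.T + 0.01 * np.eye(9)
            cc = manual_cc(PARAMS, v, cov=cov)
            est = correlations(cc)["genetic"]

            def rg_of(t):
                return t[1] / np.sqrt(t[0] * t[2])

            eps = 1e-7
            grad = np.array([
                (rg_of(v + eps * np.eye(9)[i]) - rg_of(v - eps * np.eye(9)[i])) / (2 * eps)
                for i in range(9)
            ])
            assert est.se == pytest.approx(np.sqrt(grad @ cov @ grad), abs=1e-6)


class TestFitBivariate:
    def test_exact_copy_gives_unit_correlations(self):
        """A trait paired with its own copy must show genetic and residual
        correlations of one: the likelihood climbs the |r|=1 face."""
        ds = simulate(SimulationConfig(seed=2))
        phen = ds.phenotypes.copy()
        phen["wcopy"] = phen["weight"]
        cc = fit_bivariate(phen, "weight", "wcopy")
        out = correlations(cc)
        assert out["genetic"].value == pytest.approx(1.0, abs=1e-6)
        assert out["phenotypic"].value == pytest.approx(1.0, abs=1e-6)

    def test_recovers_genetic_correlation(self):
        ests = []
        for seed in range(6):
            cc = fit_bivariate(simulate(two_trait_config(seed=seed)).phenotypes,
                               "w3", "w4")
            ests.append(correlations(cc)["genetic"].value)
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.6) < max(2 * se, 0.15)

    def test_marginals_agree_with_univariate(self):
        """Each trait's components from the joint fit match its own
        univariate fit closely on simulated data."""
        phen = simulate(two_trait_config(seed=4)).phenotypes
        cc = fit_bivariate(phen, "w3", "w4")
        for tix, trait in enumerate(("w3", "w4")):
            uni = fit(phen, ModelSpec(trait=trait))
            joint = cc.variance_components(tix)
            for name in ("sire_dam", "family", "residual"):
                denom = uni.components["residual"]
                assert abs(joint[name] - uni.components[name]) / denom < 0.05

    def test_missing_trait_errors(self):
        phen = simulate(SimulationConfig(seed=1)).phenotypes.copy()
        phen["empty"] = np.nan
        with pytest.raises(DesignError, match="non-missing"):
            fit_bivariate(phen, "weight", "empty")


class TestGxE:
    def test_label_invariance(self):
        """Which environment is called trait 1 must not matter."""
        phen = simulate(SimulationConfig(gxe_rg=0.6, seed=21)).phenotypes
        g1 = fit_gxe(phen, "weight")
        relabeled = phen.assign(
            environment=phen["environment"].map({"cage": "x_cage", "tank": "a_tank"})
        )
        g2 = fit_gxe(relabeled, "weight")
        assert g1.rg == pytest.approx(g2.rg, abs=1e-3)

    def test_no_phenotypic_cross_env_correlation(self):
        """With disjoint animals the cross-environment phenotypic correlation
        is undefined and must not be reported."""
        phen = simulate(SimulationConfig(gxe_rg=0.6, seed=22)).phenotypes
        g = fit_gxe(phen, "weight")
        assert "phenotypic" not in correlations(g.components)
        assert not g.components.has("E", 0, 1)

    def test_recovery_smoke(self):
        ests = [
            fit_gxe(simulate(SimulationConfig(gxe_rg=1.0, seed=300 + s)).phenotypes,
                    "weight").rg
            for s in range(4)
        ]
        assert np.mean(ests) > 0.95

    def test_animal_in_both_envs_rejected(self):
        phen = simulate(SimulationConfig(seed=5)).phenotypes.copy()
        dup = phen.iloc[[0]].assign(
            environment="tank" if phen.iloc[0]["environment"] == "cage" else "cage"
        )
        both = np.concatenate([phen["id"].to_numpy(), dup["id"].to_numpy()])
        import pandas as pd

        with pytest.raises(DesignError, match="both environments"):
            fit_gxe(pd.concat([phen, dup], ignore_index=True), "weight")

    def test_single_sire_environment_rejected(self):
        phen = simulate(SimulationConfig(seed=6)).phenotypes
        crippled = phen[(phen["environment"] == "cage") | (phen["sire"] == 1)]
        with pytest.raises(DesignError, match="fewer than 2 sires"):
            fit_gxe(crippled, "weight")


def test_correlation_matrix_report_layout():
    """Genetic estimates go below the diagonal, phenotypic above; pairs
    without a phenotypic estimate leave the upper cell empty."""
    from pedeval.multivariate import correlation_matrix_report

    mat = correlation_matrix_report([
        ("W1", "W2", 0.47, 0.47),
        ("W1", "W3", 0.56, None),
    ])
    assert mat.loc["W2", "W1"] == "0.47"   # genetic, below
    assert mat.loc["W1", "W2"] == "0.47"   # phenotypic, above
    assert mat.loc["W3", "W1"] == "0.56"
    assert mat.loc["W1", "W3"] == ""
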