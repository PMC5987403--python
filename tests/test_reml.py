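import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedeval.reml import (
    DesignError,
    GeneticParameters,
    ModelSpec,
    VarianceComponents,
    build_design,
    fit,
    fit_reml,
    heritability,
    lrt_common_env,
)
from pedeval.simulate import SimulationConfig, simulate


def balanced_halfsib(n_sires=50, k=20, sig_s=0.1, sig_e=0.9, seed=1):
    rng = np.random.default_rng(seed)
    s = np.repeat(np.arange(n_sires), k)
    y = rng.standard_normal(n_sires)[s] * np.sqrt(sig_s)
    y = y + rng.standard_normal(n_sires * k) * np.sqrt(sig_e)
    return pd.DataFrame({"y": y, "sire": s})


SIRE_ONLY = ModelSpec(trait="y", fixed_effects=(), random_effects=("sire",),
                      equate_sire_dam=False)


class TestBuildDesign:
    def test_intercept_only(self):
        ds = simulate(SimulationConfig(n_sires=4, n_offspring_per_family=5,
                                       environment_effects={"cage": 0.0}, seed=1))
        d = build_design(ds.phenotypes, ModelSpec(trait="weight", fixed_effects=()))
        assert d.X.shape[1] == 1

    def test_two_by_two_reference_coding(self):
        ds = simulate(SimulationConfig(n_sires=10, n_offspring_per_family=10,
                                       year_labels=(2015, 2017),
                                       year_effects=(0.0, 50.0), seed=1))
        d = build_design(ds.phenotypes, ModelSpec(trait="weight"))
        assert d.X.shape[1] == 3  # intercept + 1 year + 1 environment contrast

    def test_missing_rows_dropped_and_counted(self):
        ds = simulate(SimulationConfig(n_sires=6, n_offspring_per_family=10, seed=1))
        phen = ds.phenotypes.copy()
        phen.loc[phen.index[:7], "weight"] = np.nan
        d = build_design(phen, ModelSpec(trait="weight"))
        assert d.n_dropped == 7
        assert len(d.y) == len(phen) - 7

    def test_confounded_fixed_effects_reported(self):
        ds = simulate(SimulationConfig(n_sires=6, n_offspring_per_family=10, seed=1))
        phen = ds.phenotypes.copy()
        phen["dup"] = phen["environment"]  # perfectly aliased factor
        with pytest.raises(DesignError, match="confounded"):
            build_design(phen, ModelSpec(trait="weight",
                                         fixed_effects=("environment", "dup")))

    def test_single_family_refuses(self):
        ds = simulate(SimulationConfig(n_sires=2, n_dams_per_sire=1,
                                       n_offspring_per_family=20, seed=1))
        phen = ds.phenotypes[ds.phenotypes["family"] == "F1"]
        d = build_design(phen, ModelSpec(trait="weight", fixed_effects=()))
        with pytest.raises(DesignError, match="identifiable"):
            fit_reml(d, ModelSpec(trait="weight", fixed_effects=()))


class TestFitREML:
    def test_matches_anova_on_balanced_design(self):
        """On a balanced paternal half-sib layout REML equals the
        expected-mean-squares (ANOVA) estimators."""
        df = balanced_halfsib()
        vc = fit(df, SIRE_ONLY)
        y = df["y"].to_numpy().reshape(50, 20)
        msb = 20 * y.mean(1).var(ddof=1)
        msw = y.var(1, ddof=1).mean()
        sig_s = (msb - msw) / 20
        assert vc.converged
        assert abs(vc.components["sire"] - sig_s) / sig_s < 1e-6
        assert abs(vc.components["residual"] - msw) / msw < 1e-6

    def test_null_signal_pinned_at_boundary(self):
        ds = simulate(SimulationConfig(n_sires=30, n_offspring_per_family=15,
                                       h2=0.0, c2=0.0, seed=7))
        vc = fit(ds.phenotypes, ModelSpec(trait="weight"))
        assert vc.boundary["sire_dam"]
        assert vc.components["sire_dam"] < 1e-4 * vc.components["residual"]

    def test_em_iterations_monotone(self):
        ds = simulate(SimulationConfig(seed=5))
        vc = fit(ds.phenotypes, ModelSpec(trait="weight"))
        hist = np.array(vc.loglik_history[: vc.n_em + 1])
        assert np.all(np.diff(hist) >= -1e-7 * np.abs(hist[:-1]))

    def test_recovery_smoke(self):
        """Short parameter-recovery check; the full 20-replicate version runs
        in the acceptance suite."""
        ests = []
        for seed in range(5):
            ds = simulate(SimulationConfig(seed=seed))
            gp = heritability(fit(ds.phenotypes, ModelSpec(trait="weight")))
            ests.append((gp.h2, gp.c2))
        h2 = np.array([e[0] for e in ests])
        assert abs(h2.mean() - 0.4) < 3 * max(h2.std(ddof=1) / np.sqrt(5), 0.02)

    def test_invariances(self):
        ds = simulate(SimulationConfig(seed=13, year_labels=(2015, 2017),
                                       year_effects=(0.0, 80.0)))
        phen = ds.phenotypes
        spec = ModelSpec(trait="weight")
        base = fit(phen, spec)
        # row permutation
        perm = fit(phen.sample(frac=1.0, random_state=0), spec)
        assert perm.loglik == pytest.approx(base.loglik, rel=1e-6)
        assert perm.components["sire_dam"] == pytest.approx(
            base.components["sire_dam"], rel=1e-4)
        # reference-level choice (reverse row order flips the first observed level)
        refl = fit(phen.iloc[::-1], spec)
        assert refl.components["sire_dam"] == pytest.approx(
            base.components["sire_dam"], rel=1e-4)
        # location shift leaves components; scaling by c scales them by c^2
        shifted = phen.assign(weight=phen["weight"] + 1000.0)
        vs = fit(shifted, spec)
        assert vs.components["sire_dam"] == pytest.approx(
            base.components["sire_dam"], rel=1e-4)
        scaled = phen.assign(weight=phen["weight"] * 3.0)
        vk = fit(scaled, spec)
        assert vk.components["residual"] == pytest.approx(
            9.0 * base.components["residual"], rel=1e-4)


def make_vc(theta, names, info=None, trait="t"):
    comps = {n: v for n, v in zip(names, theta[:-1])}
    comps["residual"] = theta[-1]
    info = info if info is not None else np.eye(len(theta))
    return VarianceComponents(components=comps, loglik=0.0, info_matrix=info,
                              converged=True, n_iterations=1,
                              boundary={n: False for n in names}, n_obs=100,
                              n_fixed=1, param_names=list(names), trait=trait)


class TestHeritability:
    def test_arithmetic_identity(self):
        vc = make_vc([0.1, 0.05, 0.75], ["sire_dam", "family"])
        gp = heritability(vc)
        assert vc.sigma2_p == pytest.approx(1.0)
        assert gp.h2 == pytest.approx(0.40)
        assert gp.c2 == pytest.approx(0.05)

    def test_zero_sire_variance(self):
        gp = heritability(make_vc([0.0, 0.2, 0.8], ["sire_dam", "family"]))
        assert gp.h2 == 0.0

    def test_delta_se_matches_numerical_jacobian(self):
        """Delta-method SEs agree with a finite-difference jacobian pushed
        through the same parameter covariance."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            theta = rng.uniform(0.05, 1.0, size=3)
            L = rng.uniform(-0.1, 0.1, size=(3, 3))
            cov = L @ L.T + np.eye(3) * 0.01
            vc = make_vc(theta, ["sire_dam", "family"], info=np.linalg.inv(cov))
            gp = heritability(vc)

            def h2_of(t):
                return 4 * t[0] / (2 * t[0] + t[1] + t[2])

            eps = 1e-7
            grad = np.array([
                (h2_of(theta + eps * np.eye(3)[i]) - h2_of(theta - eps * np.eye(3)[i]))
                / (2 * eps)
                for i in range(3)
            ])
            se_num = np.sqrt(grad @ cov @ grad)
            assert gp.h2_se == pytest.approx(se_num, abs=1e-6)


class TestLRT:
    def test_identical_logliks(self):
        full = make_vc([0.1, 0.05, 0.75], ["sire_dam", "family"])
        red = make_vc([0.1, 0.75], ["sire_dam"])
        stat, p = lrt_common_env(full, red)
        assert stat == 0.0 and p == 1.0

    def test_quantile(self):
        full = make_vc([0.1, 0.05, 0.75], ["sire_dam", "family"])
        red = make_vc([0.1, 0.75], ["sire_dam"])
        full.loglik, red.loglik = 2.706 / 2, 0.0
        stat, p = lrt_common_env(full, red)
        assert stat == pytest.approx(2.706)
        assert p == pytest.approx(0.5 * stats.chi2.sf(2.706, 1))
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_mismatched_data_rejected(self):
        full = make_vc([0.1, 0.05, 0.75], ["sire_dam", "family"])
        red = make_vc([0.1, 0.75], ["sire_dam"])
        red.n_obs = 99
        with pytest.raises(ValueError, match="different data"):
            lrt_common_env(full, red)
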