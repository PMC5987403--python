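import numpy as np
import pandas as pd
import pytest

from pedeval.simulate import SimulationConfig, degrade, simulate


def anova_h2(phen, trait="weight"):
    """Method-of-moments heritability from a one-way family ANOVA on
    single-pair-mating data: between-family variance captures half the
    additive variance, so h2 = 2*sig_b/(sig_b+sig_w) on balanced data."""
    groups = [g[trait].to_numpy() for _, g in phen.groupby("family")]
    k = len(groups[0])
    means = np.array([g.mean() for g in groups])
    msb = k * means.var(ddof=1)
    msw = np.mean([g.var(ddof=1) for g in groups])
    sig_b = (msb - msw) / k
    return 2 * sig_b / (sig_b + msw)


class TestSimulate:
    def test_no_structure_when_h2_c2_zero(self):
        cfg = SimulationConfig(
            n_sires=100, n_dams_per_sire=2, n_offspring_per_family=10,
            h2=0.0, c2=0.0, environment_effects={"cage": 0.0}, seed=5,
        )
        ds = simulate(cfg)
        phen = ds.phenotypes
        groups = [g["weight"].to_numpy() for _, g in phen.groupby("family")]
        k = len(groups[0])
        means = np.array([g.mean() for g in groups])
        msb = k * means.var(ddof=1)
        msw = np.mean([g.var(ddof=1) for g in groups])
        sig_b = (msb - msw) / k
        # between-family variance ~ 0 within sampling noise of 200 families
        se = msw * np.sqrt(2.0 / len(groups)) / k
        assert abs(sig_b) < 3 * se

    def test_survival_fraction_binomial_bound(self):
        cfg = SimulationConfig(
            n_sires=200, n_dams_per_sire=1, n_offspring_per_family=50,
            survival_p=0.5, survival_h2_liability=0.2, seed=11,
        )
        ds = simulate(cfg)
        alive = ds.phenotypes["survival"].mean()
        n = len(ds.phenotypes)
        # family structure inflates the variance of the realized fraction a
        # bit beyond iid binomial; 3 SE on the binomial bound is the spec'd
        # check at this size
        assert abs(alive - 0.5) < 3 * np.sqrt(0.25 / n) + 0.02

    def test_anova_recovers_h2(self):
        ests = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_sires=100, n_dams_per_sire=1, n_offspring_per_family=30,
                h2=0.4, c2=0.0, environment_effects={"cage": 0.0}, seed=seed,
            )
            ests.append(anova_h2(simulate(cfg).phenotypes))
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.4) < 2 * se

    def test_breeding_value_variance_matches_config(self):
        cfg = SimulationConfig(
            n_sires=100, n_dams_per_sire=2, n_offspring_per_family=50,
            h2=0.4, c2=0.1, phenotypic_sd=10.0, trait_means=0.0, seed=3,
        )
        ds = simulate(cfg)
        sigA2 = 0.4 * 100.0
        realized = ds.truth["breeding_values"]["bv_weight"].var(ddof=1)
        assert abs(realized - sigA2) / sigA2 < 0.05

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=42)
        a = simulate(cfg).phenotypes.to_csv()
        b = simulate(cfg).phenotypes.to_csv()
        assert a == b

    def test_half_sib_support_both_directions(self):
        for share in ("sire", "dam"):
            cfg = SimulationConfig(
                n_sires=5, n_dams_per_sire=3, n_offspring_per_family=4,
                share_parent=share, seed=1,
            )
            ds = simulate(cfg)
            counts = ds.phenotypes.groupby("sire" if share == "sire" else "dam")[
                "family"
            ].nunique()
            assert (counts == 3).all()

    def test_env_split_disjoint_and_stratified(self):
        ds = simulate(SimulationConfig(seed=2, tank_fraction=0.3))
        per_fam = ds.phenotypes.groupby("family")["environment"].nunique()
        assert (per_fam == 2).all()
        assert ds.phenotypes.groupby("id")["environment"].nunique().max() == 1

    def test_infeasible_budget_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            SimulationConfig(h2=0.8, c2=0.3).validate()

    def test_bad_corr_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            SimulationConfig(
                trait_names=("a", "b"),
                genetic_corr=np.array([[1.0, 1.5], [1.5, 1.0]]),
            ).validate()


class TestDegrade:
    def _base(self):
        return simulate(
            SimulationConfig(
                n_sires=20, n_dams_per_sire=2, n_offspring_per_family=20,
                trait_names=("W1", "W2", "W3"), trait_means=100.0,
                phenotypic_sd=10.0, environment_effects={"cage": 0.0}, seed=9,
            )
        )

    def test_zero_rates_identity(self):
        ds = self._base()
        out = degrade(ds, [0.0, 0.0, 0.0])
        pd.testing.assert_frame_equal(out.phenotypes, ds.phenotypes)

    def test_full_final_attrition(self):
        ds = self._base()
        out = degrade(ds, [0.0, 0.0, 1.0])
        assert out.phenotypes["W3"].isna().all()
        assert (out.phenotypes["survival"] == 0).all()

    def test_monotone_missingness_and_counts(self):
        ds = self._base()
        rates = [0.1, 0.4, 0.7]
        out = degrade(ds, rates, seed=4)
        p = out.phenotypes
        # missing at an earlier age implies missing later
        assert not (p["W1"].isna() & p["W2"].notna()).any()
        assert not (p["W2"].isna() & p["W3"].notna()).any()
        n = len(p)
        for rate, col in zip(rates, ["W1", "W2", "W3"]):
            target = n * (1 - rate)
            assert abs(p[col].notna().sum() - target) <= 3 * np.sqrt(n * rate * (1 - rate))
        # survival flag consistent with final-age presence
        assert ((p["survival"] == 1) == p["W3"].notna()).all()

    def test_non_monotone_rates_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            degrade(self._base(), [0.5, 0.2, 0.6])
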