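"""Synthetic family-breeding datasets with known genetic parameters.

Emulates the data structure of a nested full-/half-sib aquaculture breeding
program: single-pair or shared-parent matings, a family-level common
environmental effect induced by separate early rearing, a tank/cage split
with each animal tested in exactly one environment, repeated body
measurements at several ages, and binary survival generated on a liability
scale.  Everything is generated from an explicit parameter set so that the
downstream estimators can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, make_pedigree

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "degrade"]


def _per_trait(value, names, label) -> dict:
    if isinstance(value, Mapping):
        out = {t: float(value[t]) for t in names}
    else:
        out = {t: float(value) for t in names}
    return out


def _check_corr(mat, k, label):
    m = np.asarray(mat, dtype=float)
    if m.shape != (k, k) or not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
        raise ValueError(f"{label} must be a symmetric {k}x{k} matrix with unit diagonal")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ValueError(f"{label} is not positive semi-definite")
    return m


@dataclass
class SimulationConfig:
    """Generating parameters for one cohort of a family breeding program.

    Defaults describe a cohort of roughly 45 matings producing nested
    full-/half-sib families (each sire mated to two dams, giving paternal
    half-sib pairs that identify the common full-sib variance), 30 tagged
    offspring per family, an alive fraction near 0.48, and a grow-out split
    between sea cages and tanks with slower growth in tanks.
    """

    n_sires: int = 23
    n_dams_per_sire: int = 2
    n_offspring_per_family: int = 30
    trait_names: tuple[str, ...] = ("weight",)
    h2: float | Mapping[str, float] = 0.4
    c2: float | Mapping[str, float] = 0.15
    trait_means: float | Mapping[str, float] = 1073.0
    phenotypic_sd: float | Mapping[str, float] = 131.3
    genetic_corr: np.ndarray | None = None
    residual_corr: np.ndarray | None = None
    year_labels: tuple = (2015,)
    year_effects: tuple = (0.0,)
    environment_effects: Mapping[str, float] = field(
        default_factory=lambda: {"cage": 0.0, "tank": -300.0}
    )
    tank_fraction: float = 0.25
    survival_p: float = 0.481
    survival_h2_liability: float = 0.2
    gxe_rg: float | None = None
    share_parent: str = "sire"  # which parent is shared across matings
    seed: int = 0

    def validate(self) -> None:
        names = tuple(self.trait_names)
        k = len(names)
        h2 = _per_trait(self.h2, names, "h2")
        c2 = _per_trait(self.c2, names, "c2")
        for t in names:
            if not (0 <= h2[t] <= 1 and 0 <= c2[t] <= 1):
                raise ValueError(f"h2/c2 for {t} must lie in [0,1]")
            if h2[t] + c2[t] > 1:
                raise ValueError(
                    f"infeasible variance budget for {t}: h2 + c2 = "
                    f"{h2[t] + c2[t]:.3f} > 1 leaves no residual variance"
                )
        if self.genetic_corr is not None:
            _check_corr(self.genetic_corr, k, "genetic_corr")
        if self.residual_corr is not None:
            _check_corr(self.residual_corr, k, "residual_corr")
        if not 0 < self.survival_p < 1:
            raise ValueError("survival_p must be in (0,1)")
        if self.gxe_rg is not None and not -1 <= self.gxe_rg <= 1:
            raise ValueError("gxe_rg must be in [-1,1]")
        if self.share_parent not in ("sire", "dam"):
            raise ValueError("share_parent must be 'sire' or 'dam'")


@dataclass
class SimulatedDataset:
    """Pedigree + phenotypes + the generating truth (parameters and realized
    breeding values), so estimators can be scored against what was drawn."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: dict

    def write(self, outdir, prefix="sim") -> None:
        from pathlib import Path
        from .pedigree import write_pedigree

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pedigree(self.pedigree, outdir / f"{prefix}_pedigree.csv")
        self.phenotypes.to_csv(outdir / f"{prefix}_phenotypes.csv", index=False)
        self.truth["breeding_values"].to_csv(outdir / f"{prefix}_truth.csv", index=False)


def _env_shift(value, trait):
    """Environment effects may be one shift per level or per level and trait."""
    if isinstance(value, Mapping):
        return float(value.get(trait, 0.0))
    return float(value)


def _mvn(rng, n, cov):
    """Draws via Cholesky with PSD fallback (eigenvalue clipping)."""
    cov = np.atleast_2d(cov)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        L = v * np.sqrt(np.clip(w, 0, None))
    return rng.standard_normal((n, cov.shape[0])) @ L.T


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate one cohort under the sire-dam transmitting model.

    Per trait with phenotypic variance sP2: sire and dam transmitting effects
    have variance (h2/4)*sP2 each, the within-family Mendelian deviation has
    variance (h2/2)*sP2, the full-sib common effect c2*sP2, and the
    environmental residual (1-h2-c2)*sP2.  An individual's true breeding
    value is sire + dam + Mendelian term.  When ``gxe_rg`` is set, sire/dam
    transmitting effects are drawn separately for tank and cage from a
    bivariate distribution with that correlation, so a family's genetic merit
    re-ranks across environments.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = tuple(config.trait_names)
    k = len(names)
    h2 = np.array([_per_trait(config.h2, names, "h2")[t] for t in names])
    c2 = np.array([_per_trait(config.c2, names, "c2")[t] for t in names])
    mu = np.array([_per_trait(config.trait_means, names, "means")[t] for t in names])
    sd = np.array([_per_trait(config.phenotypic_sd, names, "sd")[t] for t in names])
    Gcor = (
        _check_corr(config.genetic_corr, k, "genetic_corr")
        if config.genetic_corr is not None
        else np.eye(k)
    )
    Rcor = (
        _check_corr(config.residual_corr, k, "residual_corr")
        if config.residual_corr is not None
        else np.eye(k)
    )

    # mating design
    if config.share_parent == "sire":
        n_s, n_d = config.n_sires, config.n_sires * config.n_dams_per_sire
        fam_sire = np.repeat(np.arange(n_s), config.n_dams_per_sire)
        fam_dam = np.arange(n_d)
    else:
        n_d = config.n_sires
        n_s = config.n_sires * config.n_dams_per_sire
        fam_dam = np.repeat(np.arange(n_d), config.n_dams_per_sire)
        fam_sire = np.arange(n_s)
    n_fam = len(fam_sire)
    n_off = config.n_offspring_per_family
    n = n_fam * n_off

    # pedigree: sires 1..n_s, dams n_s+1..n_s+n_d, offspring afterwards
    sire_ids = np.arange(1, n_s + 1)
    dam_ids = np.arange(n_s + 1, n_s + n_d + 1)
    off_ids = np.arange(n_s + n_d + 1, n_s + n_d + n + 1)
    fam_of_off = np.repeat(np.arange(n_fam), n_off)
    ped_frame = pd.DataFrame(
        {
            "id": np.concatenate([sire_ids, dam_ids, off_ids]),
            "sire": np.concatenate(
                [np.zeros(n_s + n_d, dtype=int), sire_ids[fam_sire[fam_of_off]]]
            ),
            "dam": np.concatenate(
                [np.zeros(n_s + n_d, dtype=int), dam_ids[fam_dam[fam_of_off]]]
            ),
        }
    )
    pedigree = make_pedigree(ped_frame)

    # genetic scale per trait
    s_sd = np.sqrt(h2 / 4.0) * sd         # transmitting effects
    m_sd = np.sqrt(h2 / 2.0) * sd         # Mendelian deviation
    c_sd = np.sqrt(c2) * sd               # common full-sib effect
    e_sd = np.sqrt(np.clip(1.0 - h2 - c2, 0, None)) * sd

    Sg = np.outer(s_sd, s_sd) * Gcor
    Mg = np.outer(m_sd, m_sd) * Gcor
    Ce = np.diag(c_sd**2)
    Re = np.outer(e_sd, e_sd) * Rcor

    envs = np.array(sorted(config.environment_effects))
    if config.gxe_rg is not None:
        if len(envs) != 2:
            raise ValueError("gxe_rg requires exactly two environment levels")
        r = config.gxe_rg
        env_cov = np.array([[1.0, r], [r, 1.0]])
        # (env x trait) effects, separable covariance env_cov (x) Sg
        sire_eff = _mvn(rng, n_s, np.kron(env_cov, Sg)).reshape(n_s, 2, k)
        dam_eff = _mvn(rng, n_d, np.kron(env_cov, Sg)).reshape(n_d, 2, k)
    else:
        sire_eff = np.repeat(_mvn(rng, n_s, Sg)[:, None, :], max(len(envs), 1), axis=1)
        dam_eff = np.repeat(_mvn(rng, n_d, Sg)[:, None, :], max(len(envs), 1), axis=1)

    common_eff = _mvn(rng, n_fam, Ce)
    mendel = _mvn(rng, n, Mg)
    resid = _mvn(rng, n, Re)

    # environment split: stratified within family so every family has both
    env_code = np.empty(n, dtype=int)
    tank_idx = int(np.where(envs == "tank")[0][0]) if "tank" in envs else 0
    other_idx = 1 - tank_idx if len(envs) == 2 else 0
    for f in range(n_fam):
        rows = np.where(fam_of_off == f)[0]
        n_tank = int(round(config.tank_fraction * len(rows))) if len(envs) == 2 else 0
        pick = rng.permutation(len(rows))
        env_code[rows[pick[:n_tank]]] = tank_idx
        env_code[rows[pick[n_tank:]]] = other_idx

    # spawning year: families assigned round-robin over labels
    year_of_fam = np.array(
        [config.year_labels[f % len(config.year_labels)] for f in range(n_fam)]
    )
    year_eff = {y: e for y, e in zip(config.year_labels, config.year_effects)}

    s_of_off = fam_sire[fam_of_off]
    d_of_off = fam_dam[fam_of_off]
    bv = sire_eff[s_of_off, env_code, :] + dam_eff[d_of_off, env_code, :] + mendel
    y = (
        mu[None, :]
        + np.array([year_eff[y] for y in year_of_fam[fam_of_off]])[:, None]
        + np.array([[_env_shift(config.environment_effects[envs[e]], t)
                     for t in names] for e in env_code])
        + bv
        + common_eff[fam_of_off]
        + resid
    )

    # binary survival on a standard-normal liability, threshold at the
    # quantile giving the target alive proportion
    from scipy.stats import norm

    hL = config.survival_h2_liability
    s_l = rng.standard_normal(n_s) * np.sqrt(hL / 4)
    d_l = rng.standard_normal(n_d) * np.sqrt(hL / 4)
    liab = (
        s_l[s_of_off]
        + d_l[d_of_off]
        + rng.standard_normal(n) * np.sqrt(hL / 2)
        + rng.standard_normal(n) * np.sqrt(1.0 - hL)
    )
    thresh = norm.isf(config.survival_p)
    alive = (liab > thresh).astype(int)

    phen = pd.DataFrame(
        {
            "id": off_ids,
            "year": year_of_fam[fam_of_off],
            "environment": envs[env_code],
            "sire": sire_ids[s_of_off],
            "dam": dam_ids[d_of_off],
            "family": [f"F{f + 1}" for f in fam_of_off],
        }
    )
    for j, t in enumerate(names):
        phen[t] = y[:, j]
    phen["survival"] = alive

    bv_frame = pd.DataFrame({"id": off_ids})
    for j, t in enumerate(names):
        bv_frame[f"bv_{t}"] = bv[:, j]
    bv_frame["liability"] = liab

    parent_bv = pd.DataFrame(
        {
            "id": np.concatenate([sire_ids, dam_ids]),
            **{
                f"transmitting_{t}": np.concatenate(
                    [sire_eff[:, other_idx, j], dam_eff[:, other_idx, j]]
                )
                for j, t in enumerate(names)
            },
        }
    )

    truth = {
        "config": asdict(config),
        "breeding_values": bv_frame,
        "parent_effects": parent_bv,
        "common_effects": pd.DataFrame(
            {"family": [f"F{f + 1}" for f in range(n_fam)],
             **{t: common_eff[:, j] for j, t in enumerate(names)}}
        ),
        "survival_threshold": float(thresh),
    }
    return SimulatedDataset(pedigree, phen, truth)


def degrade(
    dataset: SimulatedDataset,
    missing_rate_per_age: Sequence[float],
    traits_by_age: Sequence[Sequence[str]] | None = None,
    seed: int = 1,
) -> SimulatedDataset:
    """Impose monotone attrition across measurement ages.

    ``missing_rate_per_age`` gives the fraction of animals missing at each
    age, non-decreasing over ages; an animal missing at one age is missing at
    all later ones (mortality/culling, not intermittent non-measurement).
    The survival flag is rewritten to be 1 exactly when the animal is still
    present at the final age.  Traits are grouped into ages either explicitly
    or by their trailing digit (W1/L1 -> age 1, ...).
    """
    rates = np.asarray(missing_rate_per_age, dtype=float)
    if np.any(rates < 0) or np.any(rates > 1):
        raise ValueError("missing rates must lie in [0,1]")
    if np.any(np.diff(rates) < 0):
        raise ValueError("missing rates must be non-decreasing across ages")

    phen = dataset.phenotypes.copy()
    if traits_by_age is None:
        groups: dict[str, list[str]] = {}
        for col in phen.columns:
            if col[-1:].isdigit() and col not in ("survival",):
                groups.setdefault(col[-1], []).append(col)
        traits_by_age = [groups[a] for a in sorted(groups)]
    if len(traits_by_age) != len(rates):
        raise ValueError("one missing rate per age group is required")

    rng = np.random.default_rng(seed)
    u = rng.random(len(phen))
    for age, (rate, cols) in enumerate(zip(rates, traits_by_age)):
        gone = u < rate
        phen.loc[gone, list(cols)] = np.nan
    if "survival" in phen.columns and len(rates) > 0 and rates.max() > 0:
        phen["survival"] = (u >= rates[-1]).astype(int)
    return SimulatedDataset(dataset.pedigree, phen, dataset.truth)
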