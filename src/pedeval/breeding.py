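"""BLUP breeding values and inbreeding-avoiding mate allocation.

Breeding values are predicted from an animal model that reuses the variance
components of the sire-dam REML fit: additive variance 4*sigmaS^2 on a
pedigree-structured genetic effect, the full-sib common-environment variance
on the family effect, and the remaining phenotypic variance as residual.
Solving the mixed-model equations with the numerator relationship matrix
propagates information through the pedigree, so non-phenotyped parents and
progeny receive EBVs too.

Mate allocation follows a three-step greedy rule used in closed aquaculture
nucleus programs: rank families and individuals within family on genetic
merit, pair the best available male with the best-ranked female whose
prospective progeny would be non-inbred (F = 0), and walk down the female
ranking on failure.  Full- and half-sib matings are excluded by the F = 0
rule and double-checked against the relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, relationship_matrix, inbreeding
from .reml import VarianceComponents

__all__ = ["EBVTable", "MatingList", "blup_ebv", "allocate_matings",
           "realized_selection_response"]


@dataclass
class EBVTable:
    """Estimated breeding values for every pedigree member."""

    table: pd.DataFrame  # id, original_id, family, ebv, accuracy, ranks
    trait: str
    sigma2_a: float

    def of(self, original_id):
        row = self.table[self.table["original_id"] == original_id]
        if row.empty:
            raise KeyError(original_id)
        return float(row["ebv"].iloc[0])


@dataclass
class MatingList:
    pairs: pd.DataFrame          # sire_id, dam_id, prospective_F, rank columns
    exclusions: list = field(default_factory=list)  # (male, female, reason)
    unpaired: list = field(default_factory=list)


def blup_ebv(
    vc: VarianceComponents,
    ped: Pedigree,
    data: pd.DataFrame,
    trait: str | None = None,
    fixed_effects: tuple[str, ...] = ("year", "environment"),
) -> EBVTable:
    """Animal-model BLUP using the components of a fitted sire-dam model.

    The genetic effect carries covariance sigmaA^2 * A with A from the
    pedigree; the common full-sib family effect (when present in the fit) is
    independent per family; the residual takes the remainder of the
    phenotypic variance.  Accuracy is sqrt(1 - PEV / ((1+F_i) sigmaA^2)).
    """
    trait = trait or vc.trait
    A = relationship_matrix(ped)
    F = inbreeding(ped, A)
    n_ped = len(ped)

    sigma_a = vc.sigma2_a
    sigma_c = vc.sigma2_c
    sigma_p = vc.sigma2_p
    sigma_e = sigma_p - sigma_a - sigma_c
    clamped = False
    if sigma_e <= 0:
        # h2 + c2 >= 1 on the animal scale: keep a floor so the MME stay PD
        sigma_e = 0.05 * sigma_p
        clamped = True
    if sigma_a <= 0:
        zero = pd.DataFrame({
            "id": ped.id, "original_id": ped.original_id,
            "family": _family_labels(ped), "ebv": 0.0, "accuracy": 0.0,
        })
        return EBVTable(_add_ranks(zero), trait, 0.0)

    kept = data[data[trait].notna()] if trait in data.columns else data.iloc[:0]
    n = len(kept)
    if n == 0:
        zero = pd.DataFrame({
            "id": ped.id, "original_id": ped.original_id,
            "family": _family_labels(ped), "ebv": 0.0, "accuracy": 0.0,
        })
        return EBVTable(_add_ranks(zero), trait, sigma_a)

    y = kept[trait].to_numpy(dtype=float)
    blocks = [np.ones((n, 1))]
    for c in fixed_effects:
        if c not in kept.columns:
            continue
        codes, levels = pd.factorize(kept[c], sort=False)
        for j in range(1, len(levels)):
            blocks.append((codes == j).astype(float)[:, None])
    X = np.hstack(blocks)
    p = X.shape[1]

    code = np.array([ped.code_of(i) for i in kept["id"]]) - 1
    Za = np.zeros((n, n_ped))
    Za[np.arange(n), code] = 1.0

    use_family = sigma_c > 1e-12 * sigma_p and "family" in kept.columns
    if use_family:
        fcodes, flevels = pd.factorize(kept["family"], sort=False)
        qf = len(flevels)
        Zc = np.zeros((n, qf))
        Zc[np.arange(n), fcodes] = 1.0
        W = np.hstack([X, Za, Zc])
    else:
        qf = 0
        W = np.hstack([X, Za])

    C = W.T @ W
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular relationship matrix; cannot form the mixed-model equations"
        ) from exc
    lam_a = sigma_e / sigma_a
    C[p:p + n_ped, p:p + n_ped] += lam_a * Ainv
    if use_family:
        C[p + n_ped:, p + n_ped:] += (sigma_e / sigma_c) * np.eye(qf)
    rhs = W.T @ y
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular mixed-model equations (confounded fixed effects or "
            "disconnected design)"
        ) from exc
    sol = Cinv @ rhs
    ebv = sol[p:p + n_ped]
    pev = sigma_e * np.diag(Cinv)[p:p + n_ped]
    denom = (1.0 + F) * sigma_a
    acc = np.sqrt(np.clip(1.0 - pev / denom, 0.0, 1.0))

    out = pd.DataFrame({
        "id": ped.id, "original_id": ped.original_id,
        "family": _family_labels(ped), "ebv": ebv, "accuracy": acc,
    })
    table = _add_ranks(out)
    res = EBVTable(table, trait, sigma_a)
    res.residual_clamped = clamped
    return res


def _family_labels(ped: Pedigree) -> np.ndarray:
    lab = np.empty(len(ped), dtype=object)
    for i, (s, d) in enumerate(zip(ped.sire, ped.dam)):
        lab[i] = f"{s}x{d}" if (s > 0 or d > 0) else f"founder:{ped.id[i]}"
    return lab


def _add_ranks(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["rank_overall"] = (
        table["ebv"].rank(ascending=False, method="first").astype(int)
    )
    table["rank_in_family"] = (
        table.groupby("family")["ebv"].rank(ascending=False, method="first").astype(int)
    )
    return table


def allocate_matings(
    ebvs: EBVTable,
    ped: Pedigree,
    n_pairs: int,
    males,
    females,
    f_tol: float = 1e-12,
) -> MatingList:
    """Greedy mate allocation with strict inbreeding avoidance.

    ``males``/``females`` are original ids of the candidates.  Families are
    ranked by the mean EBV of their candidate members (ties broken by family
    label for determinism), individuals within family by EBV.  Each male, in
    rank order, is paired with the highest-ranked unused female whose
    prospective progeny inbreeding is zero (within ``f_tol``); skipped
    females are logged with the offending F.  Any rule-respecting pairing
    that is impossible leaves the male in ``unpaired``.
    """
    t = ebvs.table
    A = relationship_matrix(ped)

    def ordered(candidates):
        sub = t[t["original_id"].isin(list(candidates))].copy()
        fam_rank = (
            sub.groupby("family")["ebv"].mean().sort_values(ascending=False)
        )
        fam_order = {
            f: i
            for i, f in enumerate(
                sorted(fam_rank.index, key=lambda f: (-fam_rank[f], str(f)))
            )
        }
        sub["fam_rank"] = sub["family"].map(fam_order)
        sub = sub.sort_values(["fam_rank", "ebv", "original_id"],
                              ascending=[True, False, True],
                              key=lambda s: s if s.name != "original_id" else s.astype(str))
        return sub

    m = ordered(males)
    f = ordered(females)
    if n_pairs > min(len(m), len(f)):
        raise ValueError(
            f"n_pairs={n_pairs} exceeds available candidates "
            f"({len(m)} males, {len(f)} females)"
        )

    used_f: set = set()
    pairs, exclusions, unpaired = [], [], []
    for _, male in m.iterrows():
        if len(pairs) >= n_pairs:
            break
        mate = None
        mcode = int(male["id"])
        for _, fem in f.iterrows():
            if fem["original_id"] in used_f:
                continue
            fcode = int(fem["id"])
            a = A[mcode - 1, fcode - 1]
            prospective = 0.5 * a
            if prospective <= f_tol:
                mate = fem
                break
            exclusions.append(
                (male["original_id"], fem["original_id"],
                 f"prospective F = {prospective:.4f}")
            )
        if mate is None:
            unpaired.append(male["original_id"])
            continue
        used_f.add(mate["original_id"])
        pairs.append({
            "sire_id": male["original_id"],
            "dam_id": mate["original_id"],
            "sire_ebv": male["ebv"],
            "dam_ebv": mate["ebv"],
            "prospective_F": 0.5 * A[int(male["id"]) - 1, int(mate["id"]) - 1],
        })
    return MatingList(pd.DataFrame(pairs), exclusions, unpaired)


def realized_selection_response(
    config,
    n_generations: int = 3,
    n_pairs: int | None = None,
    seed: int = 0,
):
    """Closed-loop check of the whole evaluation: simulate, fit, select on
    EBVs, mate, breed the next generation from the selected parents' true
    transmitting effects, and report the mean true breeding value per
    generation.  With h2 > 0 the trend should be positive.
    """
    from dataclasses import replace
    from .reml import ModelSpec, fit
    from .simulate import simulate

    rng = np.random.default_rng(seed)
    config = replace(config, seed=int(rng.integers(2**31)))
    trait = config.trait_names[0]
    n_pairs = n_pairs or config.n_sires
    means = []
    ds = simulate(config)
    for gen in range(n_generations):
        bv = ds.truth["breeding_values"]
        means.append(float(bv[f"bv_{trait}"].mean()))
        if gen == n_generations - 1:
            break
        vc = fit(ds.phenotypes, ModelSpec(trait=trait))
        ebvs = blup_ebv(vc, ds.pedigree, ds.phenotypes, trait)
        phen = ds.phenotypes
        half = len(phen) // 2
        males = phen["id"].iloc[:half].tolist()
        females = phen["id"].iloc[half:].tolist()
        matings = allocate_matings(ebvs, ds.pedigree, n_pairs, males, females)
        if len(matings.pairs) == 0:
            break  # F = 0 pairs exhausted in a small closed nucleus
        ds = _breed(ds, matings, config, int(rng.integers(2**31)))
    return np.array(means)


def _breed(ds, matings, config, seed):
    """Next generation from selected pairs, inheriting true transmitting
    effects (parent-average BV plus Mendelian sampling)."""
    from .simulate import simulate, SimulatedDataset
    from .pedigree import make_pedigree
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    trait = config.trait_names[0]
    sd = config.phenotypic_sd if np.isscalar(config.phenotypic_sd) else config.phenotypic_sd[trait]
    h2 = config.h2 if np.isscalar(config.h2) else config.h2[trait]
    c2 = config.c2 if np.isscalar(config.c2) else config.c2[trait]
    mean = config.trait_means if np.isscalar(config.trait_means) else config.trait_means[trait]

    bv = ds.truth["breeding_values"].set_index("id")[f"bv_{trait}"]
    ped_frame = ds.pedigree.to_frame()
    code_to_orig = dict(zip(ds.pedigree.id, ds.pedigree.original_id))
    n_off = config.n_offspring_per_family
    next_id = int(max(int(i) for i in ds.pedigree.original_id)) + 1

    rows, phen_rows = [], []
    bv_rows = []
    for k, pair in matings.pairs.iterrows():
        s_id, d_id = pair["sire_id"], pair["dam_id"]
        mid = 0.5 * (bv.loc[s_id] + bv.loc[d_id])
        fam = f"G{k}"
        for _ in range(n_off):
            child_bv = mid + rng.standard_normal() * np.sqrt(h2 / 2) * sd
            e = rng.standard_normal() * np.sqrt(max(1 - h2 - c2, 0)) * sd
            cfam = 0.0
            rows.append({"id": next_id, "sire": s_id, "dam": d_id})
            phen_rows.append({
                "id": next_id, "year": 9999, "environment": "cage",
                "sire": s_id, "dam": d_id, "family": fam,
                trait: mean + child_bv + cfam + e, "survival": 1,
            })
            bv_rows.append({"id": next_id, f"bv_{trait}": child_bv})
            next_id += 1
    old = ped_frame[["original_id", "sire", "dam"]].rename(columns={"original_id": "id"})
    old["sire"] = [code_to_orig.get(s, 0) for s in ped_frame["sire"]]
    old["dam"] = [code_to_orig.get(d, 0) for d in ped_frame["dam"]]
    new_ped = make_pedigree(pd.concat([old, pd.DataFrame(rows)], ignore_index=True))
    truth = dict(ds.truth)
    truth["breeding_values"] = pd.DataFrame(bv_rows)
    return SimulatedDataset(new_ped, pd.DataFrame(phen_rows), truth)
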