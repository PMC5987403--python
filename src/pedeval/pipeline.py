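"""End-to-end genetic evaluation pipeline.

One structured config drives: data simulation (or file input), trait
summaries, univariate REML fits with heritabilities, survival threshold
models, bivariate trait correlations, between-environment (GxE) genetic
correlations, BLUP breeding values and mate allocation.  Every stage writes
a delimited-text report; a run log records inputs, seed and convergence so
a run can be reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import attach_parents, read_phenotypes, summarize, format_summary
from .pedigree import read_pedigree, write_pedigree
from .reml import ModelSpec, fit, heritability, lrt_common_env
from .multivariate import correlations, fit_bivariate, fit_gxe
from .threshold import fit_threshold, h2_link, observed_to_liability
from .breeding import allocate_matings, blup_ebv
from .simulate import SimulationConfig, simulate

__all__ = ["run_pipeline", "PipelineError", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _validate(config: dict) -> None:
    if ("simulate" in config) == ("inputs" in config):
        raise PipelineError("config", "exactly one of 'simulate' or 'inputs' required")
    analyses = config.get("analyses", {})
    if "gxe" in analyses and "simulate" not in config:
        # file-based runs must carry an environment column; checked after read
        pass
    for key in analyses:
        if key not in ("summary", "univariate", "survival", "bivariate", "gxe",
                       "ebv", "matings", "lrt"):
            raise PipelineError("config", f"unknown analysis {key!r}")


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the in-memory report bundle.

    Reports are also written under ``outdir``.  A stage failure raises
    :class:`PipelineError` naming the stage; reports of completed stages
    remain on disk.
    """
    _validate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    analyses = config.get("analyses", {"summary": True})
    bundle: dict = {}
    log = [f"pedeval {__version__}", f"seed {seed}"]

    # --- data ---------------------------------------------------------
    try:
        if "simulate" in config:
            sim_kw = dict(config["simulate"] or {})
            sim_kw.setdefault("seed", seed)
            for key in ("genetic_corr", "residual_corr"):
                if key in sim_kw:
                    sim_kw[key] = np.asarray(sim_kw[key], dtype=float)
            for key in ("trait_names", "year_labels", "year_effects"):
                if key in sim_kw:
                    sim_kw[key] = tuple(sim_kw[key])
            sim_config = SimulationConfig(**sim_kw)
            ds = simulate(sim_config)
            ped, phen = ds.pedigree, ds.phenotypes
            log.append(f"simulated dataset: {len(phen)} animals, "
                       f"{phen['family'].nunique()} families")
            write_pedigree(ped, outdir / "pedigree.csv")
            phen.to_csv(outdir / "phenotypes.csv", index=False, na_rep="NA")
        else:
            inputs = config["inputs"]
            ped = read_pedigree(inputs["pedigree"])
            phen = read_phenotypes(inputs["phenotypes"])
            phen = attach_parents(phen, ped)
            log.append(f"inputs: pedigree={inputs['pedigree']} "
                       f"phenotypes={inputs['phenotypes']}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("data", exc) from exc

    trait_default = [c for c in phen.columns
                     if c not in ("id", "year", "environment", "sire", "dam",
                                  "family", "survival")]
    fixed = tuple(config.get("fixed_effects",
                             [c for c in ("year", "environment")
                              if c in phen.columns and phen[c].nunique() > 1]))

    # --- stages -------------------------------------------------------
    if analyses.get("summary"):
        try:
            summ = summarize(phen)
            bundle["summary"] = summ
            format_summary(summ).to_csv(outdir / "summary.csv", index=False)
            log.append("summary: ok")
        except Exception as exc:
            raise PipelineError("summary", exc) from exc

    if "univariate" in analyses:
        opts = analyses["univariate"] or {}
        traits = opts.get("traits", trait_default)
        rows = []
        fits = {}
        try:
            for t in traits:
                spec = ModelSpec(trait=t, fixed_effects=fixed,
                                 transform=opts.get("transform"))
                vc = fit(phen, spec)
                gp = heritability(vc)
                fits[t] = vc
                rows.append({
                    "trait": t, "n": vc.n_obs,
                    "sigma2_sire": vc.sigma2_s, "sigma2_common": vc.sigma2_c,
                    "sigma2_residual": vc.sigma2_e, "sigma2_phenotypic": vc.sigma2_p,
                    "h2": gp.h2, "h2_se": gp.h2_se, "c2": gp.c2, "c2_se": gp.c2_se,
                    "loglik": vc.loglik, "iterations": vc.n_iterations,
                    "converged": vc.converged,
                })
                log.append(f"univariate {t}: h2={gp.h2:.3f} converged={vc.converged}")
                if analyses.get("lrt"):
                    red = fit(phen, spec.without_common())
                    stat, p = lrt_common_env(vc, red)
                    rows[-1]["lrt_common"] = stat
                    rows[-1]["lrt_p"] = p
            bundle["univariate"] = pd.DataFrame(rows)
            bundle["univariate_fits"] = fits
            bundle["univariate"].to_csv(outdir / "heritability.csv", index=False)
        except Exception as exc:
            raise PipelineError("univariate", exc) from exc

    if "survival" in analyses:
        opts = analyses["survival"] or {}
        rows = []
        try:
            spec = ModelSpec(trait="survival", fixed_effects=fixed)
            vc_lin = fit(phen, spec)
            gp_lin = heritability(vc_lin)
            p_obs = float(phen["survival"].mean())
            rows.append({"model": "linear", "scale": "observed",
                         "h2": gp_lin.h2, "h2_se": gp_lin.h2_se,
                         "c2": gp_lin.c2, "c2_se": gp_lin.c2_se})
            rows.append({"model": "linear", "scale": "liability (transformed)",
                         "h2": observed_to_liability(gp_lin.h2, p_obs),
                         "h2_se": np.nan, "c2": np.nan, "c2_se": np.nan})
            surv_fixed = tuple(c for c in fixed if c != "environment")
            for link in opts.get("links", ("logit", "probit")):
                tf = fit_threshold(phen, link=link, fixed_effects=surv_fixed)
                gp = h2_link(tf)
                rows.append({"model": f"threshold-{link}", "scale": "liability",
                             "h2": gp.h2, "h2_se": gp.h2_se,
                             "c2": np.nan, "c2_se": np.nan})
                log.append(f"survival {link}: hL2={gp.h2:.3f}")
            bundle["survival"] = pd.DataFrame(rows)
            bundle["survival"].to_csv(outdir / "survival.csv", index=False)
        except Exception as exc:
            raise PipelineError("survival", exc) from exc

    if "bivariate" in analyses:
        opts = analyses["bivariate"] or {}
        rows = []
        try:
            for ta, tb in opts.get("pairs", []):
                cc = fit_bivariate(phen, ta, tb)
                cors = correlations(cc)
                row = {"trait_a": ta, "trait_b": tb,
                       "r_genetic": cors["genetic"].value,
                       "r_genetic_se": cors["genetic"].se,
                       "converged": cc.converged}
                if "phenotypic" in cors:
                    row["r_phenotypic"] = cors["phenotypic"].value
                    row["r_phenotypic_se"] = cors["phenotypic"].se
                rows.append(row)
                log.append(f"bivariate {ta}/{tb}: rg={row['r_genetic']:.3f}")
            bundle["correlations"] = pd.DataFrame(rows)
            bundle["correlations"].to_csv(outdir / "correlations.csv", index=False)
            if rows:
                from .multivariate import correlation_matrix_report

                mat = correlation_matrix_report([
                    (r["trait_a"], r["trait_b"], r["r_genetic"],
                     r.get("r_phenotypic")) for r in rows
                ])
                mat.to_csv(outdir / "correlation_matrix.csv")
        except Exception as exc:
            raise PipelineError("bivariate", exc) from exc

    if "gxe" in analyses:
        opts = analyses["gxe"] or {}
        if "environment" not in phen.columns:
            raise PipelineError(
                "gxe", "data has no 'environment' column; cannot estimate "
                "between-environment correlations")
        rows = []
        try:
            for t in opts.get("traits", trait_default):
                g = fit_gxe(phen, t, fixed_effects=tuple(
                    c for c in fixed if c != "environment"))
                rows.append({"trait": t, "rg_between_env": g.rg, "se": g.rg_se,
                             "rg_fisher_z": g.rg_atanh,
                             "se_fisher_z": g.rg_atanh_se,
                             "environments": "/".join(g.environments),
                             "converged": g.components.converged})
                log.append(f"gxe {t}: rg={g.rg:.3f}")
            bundle["gxe"] = pd.DataFrame(rows)
            bundle["gxe"].to_csv(outdir / "gxe.csv", index=False)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("gxe", exc) from exc

    if "ebv" in analyses:
        opts = analyses["ebv"] or {}
        trait = opts.get("trait", trait_default[0])
        try:
            vc = bundle.get("univariate_fits", {}).get(trait) or fit(
                phen, ModelSpec(trait=trait, fixed_effects=fixed))
            ebvs = blup_ebv(vc, ped, phen, trait, fixed_effects=fixed)
            bundle["ebv"] = ebvs
            ebvs.table.to_csv(outdir / "ebv.csv", index=False)
            log.append(f"ebv: {len(ebvs.table)} animals, trait {trait}")
        except Exception as exc:
            raise PipelineError("ebv", exc) from exc

    if "matings" in analyses:
        opts = analyses["matings"] or {}
        try:
            ebvs = bundle["ebv"]
            cands = phen["id"].tolist()
            males = opts.get("males") or cands[: len(cands) // 2]
            females = opts.get("females") or cands[len(cands) // 2:]
            ml = allocate_matings(ebvs, ped, int(opts.get("n_pairs", 10)),
                                  males, females)
            bundle["matings"] = ml
            ml.pairs.to_csv(outdir / "matings.csv", index=False)
            log.append(f"matings: {len(ml.pairs)} pairs, "
                       f"{len(ml.unpaired)} unpaired")
        except KeyError:
            raise PipelineError("matings", "mate allocation requires the 'ebv' stage")
        except Exception as exc:
            raise PipelineError("matings", exc) from exc

    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    bundle["log"] = log
    return bundle
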