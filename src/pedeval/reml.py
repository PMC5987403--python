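"""Univariate sire-dam linear mixed model fitted by REML.

The model for a continuous trait is

    y = mu + year + environment + sire + dam + family + e

with fixed year/environment effects and independent random sire, dam and
full-sib-family (common environment) effects.  By default the sire and dam
variances are constrained equal (each transmits half the parental genome, so
each explains a quarter of the additive variance); the dam-specific excess
over the sire variance is what the separate full-sib family term absorbs.
Under that parameterization

    sigmaP^2 = 2*sigmaS^2 + sigmaC^2 + sigmaE^2,
    h^2 = 4*sigmaS^2 / sigmaP^2,     c^2 = sigmaC^2 / sigmaP^2.

Estimation maximizes the restricted likelihood with an
expectation-maximization warm start followed by average-information (AI)
Newton updates; all linear algebra runs on the low-rank (random-effect)
scale via the Woodbury identity, so cost grows with the number of families,
not the number of records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ModelSpec",
    "Design",
    "VarianceComponents",
    "GeneticParameters",
    "DesignError",
    "build_design",
    "fit_reml",
    "fit",
    "heritability",
    "lrt_common_env",
]


class DesignError(ValueError):
    pass


@dataclass
class ModelSpec:
    """What to fit: trait, fixed effects, random terms, constraints."""

    trait: str = "weight"
    fixed_effects: tuple[str, ...] = ("year", "environment")
    random_effects: tuple[str, ...] = ("sire", "dam", "family")
    equate_sire_dam: bool = True
    transform: str | None = None  # None | "sqrt"
    max_iter: int = 200
    n_em: int = 10

    def without_common(self) -> "ModelSpec":
        r = tuple(t for t in self.random_effects if t != "family")
        return ModelSpec(self.trait, self.fixed_effects, r, self.equate_sire_dam,
                         self.transform, self.max_iter, self.n_em)


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray                      # n x q incidence, column blocks per term
    term_names: list
    term_slices: list                  # column slice per term
    param_names: list                  # one entry per variance parameter (residual excluded)
    param_terms: list                  # term indices covered by each parameter
    fixed_names: list
    n_dropped: int
    trait: str
    row_index: np.ndarray              # row labels of the records kept


def _dummies(col: pd.Series, name: str):
    codes, levels = pd.factorize(col, sort=False)
    if (codes < 0).any():
        raise DesignError(f"fixed effect {name!r} has missing values")
    k = len(levels)
    D = np.zeros((len(col), max(k - 1, 0)))
    for j in range(1, k):
        D[codes == j, j - 1] = 1.0
    names = [f"{name}[{levels[j]}]" for j in range(1, k)]
    return D, names, levels


def build_design(data: pd.DataFrame, spec: ModelSpec) -> Design:
    """Assemble response, fixed-effect and random-incidence structures.

    Records with a missing trait value are dropped and counted.  The fixed
    design uses reference coding (first observed level is the reference) and
    is checked for full column rank; confounded effects are reported.
    """
    if spec.trait not in data.columns:
        raise DesignError(f"trait column {spec.trait!r} not found")
    for c in spec.fixed_effects + spec.random_effects:
        if c not in data.columns:
            raise DesignError(f"model column {c!r} not found in data")

    kept = data[data[spec.trait].notna()]
    n_dropped = len(data) - len(kept)
    if len(kept) == 0:
        raise DesignError(f"no non-missing records for trait {spec.trait!r}")
    for c in spec.fixed_effects:
        lost = set(data[c].dropna().unique()) - set(kept[c].unique())
        if lost:
            raise DesignError(
                f"fixed-effect level(s) {sorted(map(str, lost))} of {c!r} have "
                f"zero records after missing-data removal for {spec.trait!r}"
            )

    y = kept[spec.trait].to_numpy(dtype=float)
    if spec.transform == "sqrt":
        if (y < 0).any():
            raise DesignError("square-root transform requires non-negative values")
        y = np.sqrt(y)
    elif spec.transform is not None:
        raise DesignError(f"unknown transform {spec.transform!r}")

    n = len(y)
    blocks = [np.ones((n, 1))]
    fixed_names = ["intercept"]
    for c in spec.fixed_effects:
        D, names, _ = _dummies(kept[c], c)
        blocks.append(D)
        fixed_names += names
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(
            f"confounded fixed effects: design for {spec.fixed_effects} is rank-deficient"
        )

    term_slices, zcols, term_names = [], [], []
    start = 0
    for t in spec.random_effects:
        codes, levels = pd.factorize(kept[t], sort=False)
        if (codes < 0).any():
            raise DesignError(f"random effect {t!r} has missing values")
        q = len(levels)
        Zt = np.zeros((n, q))
        Zt[np.arange(n), codes] = 1.0
        zcols.append(Zt)
        term_slices.append(slice(start, start + q))
        term_names.append(t)
        start += q
    Z = np.hstack(zcols) if zcols else np.zeros((n, 0))

    if spec.equate_sire_dam and "sire" in term_names and "dam" in term_names:
        pair = [term_names.index("sire"), term_names.index("dam")]
        params = [("sire_dam", pair)]
        params += [
            (t, [i]) for i, t in enumerate(term_names) if t not in ("sire", "dam")
        ]
    else:
        params = [(t, [i]) for i, t in enumerate(term_names)]
    return Design(
        y=y, X=X, Z=Z,
        term_names=term_names, term_slices=term_slices,
        param_names=[p[0] for p in params], param_terms=[p[1] for p in params],
        fixed_names=fixed_names, n_dropped=n_dropped, trait=spec.trait,
        row_index=kept.index.to_numpy(),
    )


@dataclass
class VarianceComponents:
    """REML estimates of the sire-dam model variance components."""

    components: dict                      # param name -> estimate (+ 'residual')
    loglik: float
    info_matrix: np.ndarray               # AI matrix over (params..., residual)
    converged: bool
    n_iterations: int
    boundary: dict
    n_obs: int
    n_fixed: int
    param_names: list = field(default_factory=list)
    trait: str = ""
    n_dropped: int = 0
    loglik_history: list = field(default_factory=list)
    n_em: int = 0

    def _get(self, name, default=0.0):
        return self.components.get(name, default)

    @property
    def sigma2_s(self):
        return self._get("sire_dam", self._get("sire"))

    @property
    def sigma2_d(self):
        return self._get("sire_dam", self._get("dam"))

    @property
    def sigma2_c(self):
        return self._get("family")

    @property
    def sigma2_e(self):
        return self.components["residual"]

    @property
    def sigma2_p(self):
        """Phenotypic variance: sum of all components, counting the shared
        sire-dam parameter twice (once per parent term)."""
        tot = self.sigma2_e
        for name in self.param_names:
            mult = 2.0 if name == "sire_dam" else 1.0
            tot += mult * self.components[name]
        return tot

    @property
    def sigma2_a(self):
        """Additive genetic variance, 4x the sire variance."""
        return 4.0 * self.sigma2_s

    def theta(self):
        return np.array([self.components[p] for p in self.param_names]
                        + [self.components["residual"]])

    def covariance(self):
        """Asymptotic covariance of the estimates (inverse AI matrix)."""
        try:
            return np.linalg.inv(self.info_matrix)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(self.info_matrix)


class _REMLWork:
    """Precomputed crossproducts; evaluates loglik / scores / AI at a theta."""

    def __init__(self, design: Design):
        self.y, self.X, self.Z = design.y, design.X, design.Z
        self.n, self.p = self.X.shape
        self.q = self.Z.shape[1]
        self.param_terms = design.param_terms
        self.term_slices = design.term_slices
        self.ZtZ = self.Z.T @ self.Z
        self.K = len(design.param_terms)
        # levels per parameter (EM denominators)
        self.df = np.array(
            [sum(self.term_slices[t].stop - self.term_slices[t].start for t in terms)
             for terms in design.param_terms]
        )

    def gvec(self, theta):
        g = np.empty(self.q)
        for k, terms in enumerate(self.param_terms):
            for t in terms:
                g[self.term_slices[t]] = theta[k]
        return g

    def evaluate(self, theta, need_derivs=True):
        y, X, Z = self.y, self.X, self.Z
        n, p, q = self.n, self.p, self.q
        se = theta[-1]
        g = self.gvec(theta[:-1])
        M = self.ZtZ / se + np.diag(1.0 / g)
        cho = cho_factor(M, lower=True)
        logdetM = 2.0 * np.log(np.diag(cho[0])).sum()
        logdetV = n * np.log(se) + np.log(g).sum() + logdetM

        def vinv(W):
            ZtW = Z.T @ W
            return (W - Z @ cho_solve(cho, ZtW / se)) / se

        ViX = vinv(X)
        Viy = vinv(y)
        XtViX = X.T @ ViX
        chox = cho_factor(XtViX, lower=True)
        logdetXVX = 2.0 * np.log(np.diag(chox[0])).sum()
        XtViy = ViX.T @ y
        beta = cho_solve(chox, XtViy)
        Py = Viy - ViX @ beta
        yPy = y @ Py
        loglik = -0.5 * (logdetV + logdetXVX + yPy)
        out = {"loglik": loglik, "Py": Py, "beta": beta, "cho": cho, "chox": chox,
               "ViX": ViX, "se": se, "g": g}
        if not need_derivs:
            return out

        ViZ = (Z - Z @ cho_solve(cho, self.ZtZ / se)) / se
        XtViZ = ViX.T @ Z
        PZ = ViZ - ViX @ cho_solve(chox, XtViZ)
        ZtPZ = Z.T @ PZ
        Ztw = Z.T @ Py

        scores = np.empty(self.K + 1)
        U = np.empty((n, self.K + 1))
        for k, terms in enumerate(self.param_terms):
            tr = sum(np.trace(ZtPZ[self.term_slices[t], self.term_slices[t]])
                     for t in terms)
            quad = sum(float(Ztw[self.term_slices[t]] @ Ztw[self.term_slices[t]])
                       for t in terms)
            scores[k] = -0.5 * (tr - quad)
            U[:, k] = sum(Z[:, self.term_slices[t]] @ Ztw[self.term_slices[t]]
                          for t in terms)
        # residual: V_k = I
        trVi = (n - np.trace(cho_solve(cho, self.ZtZ / se))) / se
        ViX2 = ViX.T @ ViX
        trP = trVi - np.trace(cho_solve(chox, ViX2))
        scores[self.K] = -0.5 * (trP - Py @ Py)
        U[:, self.K] = Py

        ViU = vinv(U)
        PU = ViU - ViX @ cho_solve(chox, ViX.T @ U)
        AI = 0.5 * (U.T @ PU)
        AI = 0.5 * (AI + AI.T)
        out.update({"scores": scores, "AI": AI})
        return out


def fit_reml(design: Design, spec: ModelSpec | None = None) -> VarianceComponents:
    """Maximize the restricted likelihood over non-negative components.

    Ten EM iterations (guaranteed uphill) seed average-information Newton
    updates with step halving; components heading negative are pinned at
    1e-8 times the sample phenotypic variance and flagged as boundary
    estimates.  Convergence requires a relative log-likelihood change below
    1e-8 and a maximum relative parameter change below 1e-6.
    """
    spec = spec or ModelSpec(trait=design.trait)
    for t in ("sire", "family"):
        if t in design.term_names:
            sl = design.term_slices[design.term_names.index(t)]
            if sl.stop - sl.start < 2:
                raise DesignError(
                    f"fewer than two {t} levels: variance components are not "
                    "identifiable from a single family"
                )

    work = _REMLWork(design)
    vary = float(np.var(design.y, ddof=1))
    bound = 1e-8 * vary
    K = work.K

    # start: split the OLS residual variance equally
    beta0, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    v0 = float(np.var(design.y - design.X @ beta0, ddof=1))
    theta = np.full(K + 1, 0.5 * v0 / max(K, 1))
    theta[-1] = 0.5 * v0

    cur = work.evaluate(theta)
    history = [cur["loglik"]]
    converged = False
    it = 0
    em_df = np.append(work.df, work.n - work.p)
    for it in range(1, spec.max_iter + 1):
        if it <= spec.n_em:
            new_theta = theta + 2.0 * theta**2 / em_df * cur["scores"]
            new_theta = np.maximum(new_theta, bound)
            new = work.evaluate(new_theta)
        else:
            try:
                delta = np.linalg.solve(cur["AI"], cur["scores"])
            except np.linalg.LinAlgError:
                delta = 2.0 * theta**2 / em_df * cur["scores"]
            new_theta, new = None, None
            step = 1.0
            for _ in range(25):
                cand = np.maximum(theta + step * delta, bound)
                try:
                    ev = work.evaluate(cand)
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if np.isfinite(ev["loglik"]) and ev["loglik"] >= cur["loglik"] - 1e-10:
                    new_theta, new = cand, ev
                    break
                step *= 0.5
            if new is None:  # EM fallback
                new_theta = np.maximum(theta + 2.0 * theta**2 / em_df * cur["scores"], bound)
                new = work.evaluate(new_theta)
        dl = new["loglik"] - cur["loglik"]
        dp = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), 10 * bound))
        theta, cur = new_theta, new
        history.append(cur["loglik"])
        if it > spec.n_em and abs(dl) < 1e-8 * (1.0 + abs(cur["loglik"])) and dp < 1e-6:
            converged = True
            break

    comps = {name: float(theta[k]) for k, name in enumerate(design.param_names)}
    comps["residual"] = float(theta[-1])
    boundary = {name: bool(theta[k] <= bound * 1.001)
                for k, name in enumerate(design.param_names)}
    return VarianceComponents(
        components=comps, loglik=float(cur["loglik"]), info_matrix=cur["AI"],
        converged=converged, n_iterations=it, boundary=boundary,
        n_obs=work.n, n_fixed=work.p, param_names=list(design.param_names),
        trait=design.trait, n_dropped=design.n_dropped,
        loglik_history=history, n_em=min(spec.n_em, it),
    )


def fit(data: pd.DataFrame, spec: ModelSpec) -> VarianceComponents:
    """Convenience wrapper: build the design and fit in one call."""
    return fit_reml(build_design(data, spec), spec)


@dataclass
class GeneticParameters:
    h2: float
    h2_se: float
    c2: float
    c2_se: float
    scale: str = "observed"
    trait: str = ""


def heritability(vc: VarianceComponents) -> GeneticParameters:
    """Heritability and common full-sib fraction with delta-method SEs.

    h2 = 4*sigmaS^2/sigmaP^2 and c2 = sigmaC^2/sigmaP^2, where sigmaP^2 sums
    the fitted components (the shared sire-dam parameter counts twice).
    Standard errors propagate the inverse average-information matrix through
    the analytic gradient of each ratio.
    """
    if not vc.converged:
        warnings.warn("heritability computed from a non-converged fit", stacklevel=2)
    theta = vc.theta()
    names = vc.param_names + ["residual"]
    mult = np.array([2.0 if n == "sire_dam" else 1.0 for n in names])
    sigP = float(mult @ theta)
    if sigP <= 0:
        raise ValueError("zero phenotypic variance")
    if "sire_dam" in names:
        i_s = names.index("sire_dam")
    elif "sire" in names:
        i_s = names.index("sire")
    else:
        raise ValueError("model has no sire term; heritability undefined")
    sS = theta[i_s]
    h2 = 4.0 * sS / sigP
    grad_h = -4.0 * sS * mult / sigP**2
    grad_h[i_s] += 4.0 / sigP
    cov = vc.covariance()
    h2_se = float(np.sqrt(max(grad_h @ cov @ grad_h, 0.0)))

    if "family" in names:
        i_c = names.index("family")
        sC = theta[i_c]
        c2 = sC / sigP
        grad_c = -sC * mult / sigP**2
        grad_c[i_c] += 1.0 / sigP
        c2_se = float(np.sqrt(max(grad_c @ cov @ grad_c, 0.0)))
    else:
        c2, c2_se = 0.0, float("nan")
    return GeneticParameters(h2=float(h2), h2_se=h2_se, c2=float(c2), c2_se=c2_se,
                             scale="observed", trait=vc.trait)


def lrt_common_env(fit_full: VarianceComponents, fit_reduced: VarianceComponents):
    """Boundary likelihood-ratio test for the common full-sib variance.

    The null value lies on the boundary of the parameter space, so the
    statistic is referred to the 50:50 mixture of a point mass at zero and a
    chi-square with one degree of freedom.  Returns (statistic, p_value).
    """
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("full and reduced fits use different data")
    if "family" not in fit_full.param_names or "family" in fit_reduced.param_names:
        raise ValueError("reduced model must be the full model minus the family term")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = 1.0 if stat == 0.0 else 0.5 * stats.chi2.sf(stat, df=1)
    return stat, float(p)
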