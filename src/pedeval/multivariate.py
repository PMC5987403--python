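"""Bivariate sire-dam REML: trait-trait correlations and GxE.

Two traits are fitted jointly with trait-specific fixed effects and random
sire, dam and full-sib-family effects whose 2x2 covariance matrices are
estimated by average-information REML.  The genetic correlation is the sire
covariance divided by the product of sire standard deviations; the
phenotypic correlation sums component (co)variances.

The genotype-by-environment analysis treats the same trait measured in two
environments (tank vs sea cage) as two traits.  Because every animal is
tested in exactly one environment the residual covariance is structurally
zero and is fixed there, the environment fixed effect is dropped (it is
absorbed by the trait-specific means), and the trait is square-root
transformed first to even out the scale difference between environments.
The sire-level correlation of the two expressions is then the
between-environment genetic correlation: a value below one means families
re-rank across environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .reml import DesignError

__all__ = [
    "BivariateSpec",
    "CovarianceComponents",
    "CorrelationEstimate",
    "fit_bivariate",
    "correlations",
    "fit_gxe",
    "GxEResult",
]

_RCAP = 1.0 - 1e-7  # correlation magnitude cap keeping covariance blocks invertible


@dataclass
class BivariateSpec:
    fixed_effects: tuple[str, ...] = ("year", "environment")
    include_common: bool = True
    common_cov: bool = True     # estimate the cross-trait family covariance
    residual_cov: bool = True   # estimate the residual covariance (needs co-observed animals)
    transform: str | None = None
    max_iter: int = 300


@dataclass
class CovarianceComponents:
    """Joint variance/covariance estimates from a two-trait sire-dam fit.

    ``params`` names each element of theta as (matrix, i, j) with matrix "S"
    (sire=dam genetic), "C" (common full-sib) or "E" (residual); trait 0/1
    order follows ``traits``.
    """

    traits: tuple[str, str]
    params: list
    theta: np.ndarray
    loglik: float
    info_matrix: np.ndarray
    converged: bool
    n_iterations: int
    n_obs: int
    boundary: dict = field(default_factory=dict)

    def matrix(self, name: str) -> np.ndarray:
        m = np.zeros((2, 2))
        found = False
        for (nm, i, j), v in zip(self.params, self.theta):
            if nm == name:
                m[i, j] = m[j, i] = v
                found = True
        if not found:
            raise KeyError(name)
        return m

    def has(self, name, i, j):
        return (name, i, j) in self.params

    def covariance(self):
        try:
            return np.linalg.inv(self.info_matrix)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(self.info_matrix)

    def variance_components(self, trait_index: int) -> dict:
        """Marginal (per-trait) components implied by the joint fit."""
        out = {"sire_dam": self.matrix("S")[trait_index, trait_index]}
        if any(p[0] == "C" for p in self.params):
            out["family"] = self.matrix("C")[trait_index, trait_index]
        out["residual"] = self.matrix("E")[trait_index, trait_index]
        return out


class _BivWork:
    def __init__(self, y, X, Z, term_offsets, term_sizes, cell_trait, pairs, params,
                 include_common):
        self.y, self.X, self.Z = y, X, Z
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.term_offsets = term_offsets  # name -> column offset
        self.term_sizes = term_sizes      # name -> levels per trait
        self.cell_trait = cell_trait
        self.pairs = pairs                # (m,2) cell indices of co-observed animals
        self.params = params
        self.include_common = include_common
        self.trait_mask = [cell_trait == t for t in (0, 1)]

    def cols(self, term, trait):
        off, q = self.term_offsets[term], self.term_sizes[term]
        return slice(off + trait * q, off + (trait + 1) * q)

    def _terms_of(self, name):
        return ("sire", "dam") if name == "S" else ("family",)

    def matrices(self, theta):
        out = {"S": np.zeros((2, 2)), "C": np.zeros((2, 2)), "E": np.zeros((2, 2))}
        for (nm, i, j), v in zip(self.params, theta):
            out[nm][i, j] = out[nm][j, i] = v
        return out

    def rinv(self, E):
        """Blockwise inverse of the residual covariance over cells."""
        n = self.n
        diag = np.where(self.cell_trait == 0, 1.0 / E[0, 0], 1.0 / E[1, 1])
        off = np.zeros(0)
        if len(self.pairs):
            det = E[0, 0] * E[1, 1] - E[0, 1] ** 2
            i0, i1 = self.pairs[:, 0], self.pairs[:, 1]
            diag = diag.copy()
            diag[i0] = E[1, 1] / det
            diag[i1] = E[0, 0] / det
            off = np.full(len(self.pairs), -E[0, 1] / det)
        return diag, off

    def rmul(self, diag, off, W):
        out = W * diag[:, None] if W.ndim == 2 else W * diag
        if len(self.pairs):
            i0, i1 = self.pairs[:, 0], self.pairs[:, 1]
            if W.ndim == 2:
                out[i0] += off[:, None] * W[i1]
                out[i1] += off[:, None] * W[i0]
            else:
                out[i0] += off * W[i1]
                out[i1] += off * W[i0]
        return out

    def evaluate(self, theta, need_derivs=True):
        y, X, Z = self.y, self.X, self.Z
        n, p, q = self.n, self.p, self.q
        mats = self.matrices(theta)
        S, C, E = mats["S"], mats["C"], mats["E"]
        for nm in ("S", "C", "E"):
            m = mats[nm]
            if nm == "C" and not self.include_common:
                continue
            if m[0, 0] <= 0 or m[1, 1] <= 0 or np.linalg.det(m) <= 0:
                raise np.linalg.LinAlgError(f"{nm} block not positive definite")

        # G^{-1} assembled per term: inverse of 2x2 matrix on paired level blocks
        Ginv = np.zeros((q, q))
        logdetG = 0.0
        for nm in ("S", "C"):
            if nm == "C" and not self.include_common:
                continue
            m = mats[nm]
            minv = np.linalg.inv(m)
            for term in self._terms_of(nm):
                qt = self.term_sizes[term]
                logdetG += qt * np.log(np.linalg.det(m))
                for a in (0, 1):
                    for b in (0, 1):
                        ia = np.arange(self.cols(term, a).start, self.cols(term, a).stop)
                        ib = np.arange(self.cols(term, b).start, self.cols(term, b).stop)
                        Ginv[ia, ib] += minv[a, b]

        rdiag, roff = self.rinv(E)
        n0 = int(self.trait_mask[0].sum()) - len(self.pairs)
        n1 = int(self.trait_mask[1].sum()) - len(self.pairs)
        logdetR = n0 * np.log(E[0, 0]) + n1 * np.log(E[1, 1])
        if len(self.pairs):
            logdetR += len(self.pairs) * np.log(E[0, 0] * E[1, 1] - E[0, 1] ** 2)

        RZ = self.rmul(rdiag, roff, Z)
        ZtRZ = Z.T @ RZ
        M = Ginv + ZtRZ
        cho = cho_factor(M, lower=True, check_finite=False)
        logdetM = 2.0 * np.log(np.diag(cho[0])).sum()
        logdetV = logdetR + logdetG + logdetM

        def vinv(W):
            return self.rmul(rdiag, roff, W) - RZ @ cho_solve(
                cho, RZ.T @ W, check_finite=False
            )

        ViX = vinv(X)
        Viy = vinv(y)
        XtViX = X.T @ ViX
        chox = cho_factor(XtViX, lower=True, check_finite=False)
        logdetXVX = 2.0 * np.log(np.diag(chox[0])).sum()
        beta = cho_solve(chox, ViX.T @ y, check_finite=False)
        Py = Viy - ViX @ beta
        yPy = y @ Py
        loglik = -0.5 * (logdetV + logdetXVX + yPy)
        out = {"loglik": loglik, "beta": beta, "Py": Py}
        if not need_derivs:
            return out

        ViZ = RZ - RZ @ cho_solve(cho, ZtRZ, check_finite=False)
        PZ = ViZ - ViX @ cho_solve(chox, ViX.T @ Z, check_finite=False)
        ZtPZ = Z.T @ PZ
        w = Py
        Ztw = Z.T @ w

        Kx = cho_solve(chox, np.eye(p), check_finite=False)
        Q = cho_solve(cho, RZ.T, check_finite=False).T   # n x q
        diagVinv = rdiag - np.einsum("ij,ij->i", RZ, Q)
        diagP = diagVinv - np.einsum("ip,pq,iq->i", ViX, Kx, ViX)

        K = len(self.params)
        scores = np.empty(K)
        U = np.empty((n, K))
        for k, (nm, a, b) in enumerate(self.params):
            if nm in ("S", "C"):
                tr = quad = 0.0
                u = np.zeros(n)
                for term in self._terms_of(nm):
                    ca, cb = self.cols(term, a), self.cols(term, b)
                    if a == b:
                        tr += np.trace(ZtPZ[ca, ca])
                        quad += float(Ztw[ca] @ Ztw[ca])
                        u += Z[:, ca] @ Ztw[ca]
                    else:
                        ia = np.arange(ca.start, ca.stop)
                        ib = np.arange(cb.start, cb.stop)
                        tr += 2.0 * ZtPZ[ia, ib].sum()
                        quad += 2.0 * float(Ztw[ca] @ Ztw[cb])
                        u += Z[:, ca] @ Ztw[cb] + Z[:, cb] @ Ztw[ca]
            else:  # residual
                if a == b:
                    mask = self.trait_mask[a]
                    tr = float(diagP[mask].sum())
                    quad = float(w[mask] @ w[mask])
                    u = np.where(mask, w, 0.0)
                else:
                    i0, i1 = self.pairs[:, 0], self.pairs[:, 1]
                    voff = (self.rinv(E)[1]
                            - np.einsum("ij,ij->i", RZ[i0], Q[i1]))
                    poff = voff - np.einsum("ip,pq,iq->i", ViX[i0], Kx, ViX[i1])
                    tr = 2.0 * float(poff.sum())
                    quad = 2.0 * float(w[i0] @ w[i1])
                    u = np.zeros(n)
                    u[i0] = w[i1]
                    u[i1] = w[i0]
            scores[k] = -0.5 * (tr - quad)
            U[:, k] = u
        PU = vinv(U) - ViX @ cho_solve(chox, ViX.T @ U, check_finite=False)
        AI = 0.5 * (U.T @ PU)
        AI = 0.5 * (AI + AI.T)
        out.update({"scores": scores, "AI": AI})
        return out


def _stack(data, trait_a, trait_b, spec: BivariateSpec):
    for t in (trait_a, trait_b):
        if t not in data.columns:
            raise DesignError(f"trait column {t!r} not found")
        if data[t].notna().sum() == 0:
            raise DesignError(f"trait {t!r} has no non-missing records")
    for c in spec.fixed_effects + ("sire", "dam", "id"):
        if c not in data.columns:
            raise DesignError(f"column {c!r} required for the bivariate model")
    if spec.include_common and "family" not in data.columns:
        raise DesignError("column 'family' required for the common full-sib term")

    cells = []
    for tix, trait in enumerate((trait_a, trait_b)):
        sub = data[data[trait].notna()].copy()
        sub["_y"] = sub[trait].astype(float)
        if spec.transform == "sqrt":
            if (sub["_y"] < 0).any():
                raise DesignError("square-root transform requires non-negative values")
            sub["_y"] = np.sqrt(sub["_y"])
        sub["_trait"] = tix
        cells.append(sub)
    cells = pd.concat(cells, ignore_index=True)
    n = len(cells)
    y = cells["_y"].to_numpy()
    cell_trait = cells["_trait"].to_numpy()

    # trait-specific fixed designs, block-diagonal
    xblocks, pcols = [], []
    for tix in (0, 1):
        mask = cell_trait == tix
        sub = cells[mask]
        cols = [np.ones((mask.sum(), 1))]
        for c in spec.fixed_effects:
            codes, levels = pd.factorize(sub[c], sort=False)
            for j in range(1, len(levels)):
                cols.append((codes == j).astype(float)[:, None])
        xblocks.append((mask, np.hstack(cols)))
        pcols.append(xblocks[-1][1].shape[1])
    X = np.zeros((n, sum(pcols)))
    X[xblocks[0][0], : pcols[0]] = xblocks[0][1]
    X[xblocks[1][0], pcols[0]:] = xblocks[1][1]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("confounded fixed effects in the bivariate design")

    terms = ["sire", "dam"] + (["family"] if spec.include_common else [])
    term_offsets, term_sizes = {}, {}
    zcols = []
    offset = 0
    for term in terms:
        codes, levels = pd.factorize(cells[term], sort=False)
        qt = len(levels)
        Zt = np.zeros((n, 2 * qt))
        Zt[np.arange(n), cell_trait * qt + codes] = 1.0
        zcols.append(Zt)
        term_offsets[term] = offset
        term_sizes[term] = qt
        offset += 2 * qt
    Z = np.hstack(zcols)

    # co-observed animals -> residual pairs
    ids = cells["id"].to_numpy()
    pos0 = {i: k for k, i in enumerate(ids) if cell_trait[k] == 0}
    pairs = [
        (pos0[i], k) for k, i in enumerate(ids) if cell_trait[k] == 1 and i in pos0
    ]
    pairs = np.array(pairs, dtype=int).reshape(-1, 2)

    params = [("S", 0, 0), ("S", 0, 1), ("S", 1, 1)]
    if spec.include_common:
        params.append(("C", 0, 0))
        if spec.common_cov:
            params.append(("C", 0, 1))
        params.append(("C", 1, 1))
    params += [("E", 0, 0), ("E", 1, 1)]
    est_resid_cov = spec.residual_cov and len(pairs) > 0
    if est_resid_cov:
        params.append(("E", 0, 1))
    if not est_resid_cov:
        pairs = pairs[:0]  # residual blocks stay diagonal
    return _BivWork(y, X, Z, term_offsets, term_sizes, cell_trait, pairs, params,
                    spec.include_common)


def _project(work: _BivWork, theta, bounds):
    th = theta.copy()
    idx = {p: k for k, p in enumerate(work.params)}
    for nm in ("S", "C", "E"):
        if (nm, 0, 0) not in idx:
            continue
        for t in (0, 1):
            k = idx[(nm, t, t)]
            th[k] = max(th[k], bounds[nm][t])
        if (nm, 0, 1) in idx:
            k = idx[(nm, 0, 1)]
            cap = _RCAP * np.sqrt(th[idx[(nm, 0, 0)]] * th[idx[(nm, 1, 1)]])
            th[k] = np.clip(th[k], -cap, cap)
    return th


def _ai_loop(work, theta, bounds, idx, vt, max_iter, force_ride=()):
    """Average-information ascent with trust region, line search and an
    active set; params in ``force_ride`` are covariances held on the |r|-cap
    face (they track the cap as the variances move)."""
    cur = work.evaluate(theta)
    converged = False
    it = 0
    n_small = 0
    ll_window = [cur["loglik"]]
    for it in range(1, max_iter + 1):
        AI = cur["AI"]
        scores = cur["scores"]
        # active set: variances held at the floor and covariances held at the
        # |r|-cap whose score points outward are frozen for this step, so the
        # Newton direction is taken in the feasible subspace only
        free = np.ones(len(theta), dtype=bool)
        for k, (nm, a, b) in enumerate(work.params):
            if k in force_ride:
                free[k] = False
            elif a == b:
                if theta[k] <= bounds[nm][a] * 1.001 and scores[k] < 0:
                    free[k] = False
            else:
                capv = _RCAP * np.sqrt(theta[idx[(nm, a, a)]] * theta[idx[(nm, b, b)]])
                if abs(theta[k]) >= capv * (1 - 1e-6) and np.sign(theta[k]) * scores[k] > 0:
                    free[k] = False
        delta = np.zeros(len(theta))
        if free.any():
            sub = AI[np.ix_(free, free)]
            try:
                delta[free] = np.linalg.solve(
                    sub + 1e-10 * np.eye(free.sum()) * np.trace(sub), scores[free]
                )
            except np.linalg.LinAlgError:
                delta[free] = scores[free] * np.abs(theta[free]) / (
                    np.abs(scores[free]).max() + 1e-12
                )
        # trust region: no parameter moves more than half its own scale per
        # iteration, so a single Newton overshoot cannot pin a variance at
        # the boundary (where the quadratic model is useless)
        denom = np.empty(len(theta))
        for k, (nm, a, b) in enumerate(work.params):
            if a == b:
                denom[k] = abs(theta[k]) + 1e-4 * vt[a]
            else:
                va = theta[idx[(nm, a, a)]]
                vb = theta[idx[(nm, b, b)]]
                denom[k] = np.sqrt(max(va * vb, 0.0)) + 1e-4 * np.sqrt(vt[a] * vt[b])
        cap = 0.5 if it <= 5 else 2.0
        m = np.max(np.abs(delta) / denom)
        if m > cap:
            delta = delta * (cap / m)
        riding = [
            k for k, (nm, a, b) in enumerate(work.params) if a != b and not free[k]
        ]
        new_theta, new = None, None
        step = 1.0
        for _ in range(16):
            cand = theta + step * delta
            for k in riding:  # covariances at the |r|-cap track the moving cap
                nm, a, b = work.params[k]
                sign = np.sign(theta[k]) or 1.0
                cand[k] = sign * _RCAP * np.sqrt(
                    max(cand[idx[(nm, a, a)]], bounds[nm][a])
                    * max(cand[idx[(nm, b, b)]], bounds[nm][b])
                )
            cand = _project(work, cand, bounds)
            try:
                ev = work.evaluate(cand, need_derivs=False)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if np.isfinite(ev["loglik"]) and ev["loglik"] >= cur["loglik"] - 1e-7 * (
                1.0 + abs(cur["loglik"])
            ):
                new_theta, new = cand, work.evaluate(cand)
                break
            step *= 0.5
        if new is None:
            # no feasible uphill move beyond numerical resolution: at the
            # (possibly boundary) maximum
            converged = it > 1
            break
        dl = new["loglik"] - cur["loglik"]
        theta, cur = new_theta, new
        ll_window.append(cur["loglik"])
        if abs(dl) < 1e-8 * (1.0 + abs(cur["loglik"])):
            n_small += 1
            if n_small >= 2:
                converged = True
                break
        else:
            n_small = 0
        # stall detector: on a flat boundary ridge the per-step gain can sit
        # just above tolerance indefinitely; stop once 10 steps buy < 1e-5
        if it > 25 and len(ll_window) > 10:
            if ll_window[-1] - ll_window[-11] < 1e-5 * (1.0 + abs(cur["loglik"])):
                converged = True
                break
    return theta, cur, converged, it


def fit_bivariate(
    data: pd.DataFrame, trait_a: str, trait_b: str, spec: BivariateSpec | None = None
) -> CovarianceComponents:
    """Two-trait sire-dam REML fit (sire and dam share the genetic 2x2 block).

    Animals may carry either or both traits.  Average-information updates
    with step halving maximize the restricted likelihood; covariance blocks
    are kept positive definite by capping each implied correlation just
    inside +/-1, so reported correlations never exceed 1 in magnitude.
    """
    spec = spec or BivariateSpec()
    work = _stack(data, trait_a, trait_b, spec)
    vt = [float(np.var(work.y[work.trait_mask[t]], ddof=1)) for t in (0, 1)]
    bounds = {nm: [1e-8 * vt[0], 1e-8 * vt[1]] for nm in ("S", "C", "E")}

    theta = np.zeros(len(work.params))
    idx = {p: k for k, p in enumerate(work.params)}
    for t in (0, 1):
        theta[idx[("S", t, t)]] = 0.15 * vt[t]
        if ("C", t, t) in idx:
            theta[idx[("C", t, t)]] = 0.10 * vt[t]
        theta[idx[("E", t, t)]] = 0.60 * vt[t]
    for nm in ("S", "C", "E"):
        if (nm, 0, 1) in idx:
            theta[idx[(nm, 0, 1)]] = 0.5 * np.sqrt(
                theta[idx[(nm, 0, 0)]] * theta[idx[(nm, 1, 1)]]
            )

    theta, cur, converged, it = _ai_loop(work, theta, bounds, idx, vt, spec.max_iter)

    # boundary-face search: when a correlation ends near |1| the interior AI
    # path may have stalled below the supremum on the |r|=1 face (the
    # likelihood can be nearly singular there).  Pin every covariance at the
    # cap, re-optimize the variances on that face, then release; keep
    # whichever mode has the higher restricted likelihood.
    covs = [k for k, (nm, a, b) in enumerate(work.params) if a != b]
    if covs:
        rmax = 0.0
        for k in covs:
            nm, a, b = work.params[k]
            denomr = np.sqrt(theta[idx[(nm, a, a)]] * theta[idx[(nm, b, b)]])
            rmax = max(rmax, abs(theta[k]) / max(denomr, 1e-300))
        if rmax > 0.8:
            th_b = theta.copy()
            for k in covs:
                nm, a, b = work.params[k]
                sign = np.sign(theta[k]) or 1.0
                th_b[k] = sign * _RCAP * np.sqrt(
                    theta[idx[(nm, a, a)]] * theta[idx[(nm, b, b)]]
                )
            try:
                th_b, cur_b, conv_b, it_b = _ai_loop(
                    work, th_b, bounds, idx, vt, 30, force_ride=tuple(covs)
                )
                th_b, cur_b, conv_b, it_b = _ai_loop(work, th_b, bounds, idx, vt, 20)
                if cur_b["loglik"] > cur["loglik"] + 1e-7 * (1 + abs(cur["loglik"])):
                    theta, cur, converged = th_b, cur_b, conv_b
                    it += it_b
            except np.linalg.LinAlgError:
                pass

    boundary = {}
    for (nm, a, b), v in zip(work.params, theta):
        if a == b:
            boundary[(nm, a, b)] = bool(v <= bounds[nm][a] * 1.001)
    return CovarianceComponents(
        traits=(trait_a, trait_b), params=list(work.params), theta=theta,
        loglik=float(cur["loglik"]), info_matrix=cur["AI"], converged=converged,
        n_iterations=it, n_obs=work.n, boundary=boundary,
    )


@dataclass
class CorrelationEstimate:
    value: float
    se: float
    kind: str  # "genetic" | "phenotypic"


def _delta_corr(cc: CovarianceComponents, weights: dict):
    """Correlation c / sqrt(v1 v2) where c, v1, v2 are linear in theta with
    coefficient dicts weights = {'c': {...}, 'v1': {...}, 'v2': {...}}."""
    idx = {p: k for k, p in enumerate(cc.params)}

    def lin(w):
        val = sum(coef * cc.theta[idx[p]] for p, coef in w.items() if p in idx)
        grad = np.zeros(len(cc.theta))
        for p, coef in w.items():
            if p in idx:
                grad[idx[p]] += coef
        return val, grad

    c, gc = lin(weights["c"])
    v1, g1 = lin(weights["v1"])
    v2, g2 = lin(weights["v2"])
    if v1 <= 0 or v2 <= 0:
        raise ValueError("zero variance: correlation undefined")
    s = np.sqrt(v1 * v2)
    r = c / s
    grad = gc / s - 0.5 * r * (g1 / v1 + g2 / v2)
    cov = cc.covariance()
    se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return float(r), se


def correlations(cc: CovarianceComponents):
    """Genetic and phenotypic correlations with delta-method SEs.

    The genetic correlation uses the sire (co)variances; the phenotypic one
    sums components (sire + dam + family + residual), which requires the
    residual covariance to have been estimable (co-observed animals).
    Returns a dict with keys "genetic" and, when defined, "phenotypic".
    """
    out = {}
    rg, se = _delta_corr(cc, {
        "c": {("S", 0, 1): 1.0},
        "v1": {("S", 0, 0): 1.0},
        "v2": {("S", 1, 1): 1.0},
    })
    out["genetic"] = CorrelationEstimate(rg, se, "genetic")
    if cc.has("E", 0, 1):
        wc = {("S", 0, 1): 2.0, ("C", 0, 1): 1.0, ("E", 0, 1): 1.0}
        w1 = {("S", 0, 0): 2.0, ("C", 0, 0): 1.0, ("E", 0, 0): 1.0}
        w2 = {("S", 1, 1): 2.0, ("C", 1, 1): 1.0, ("E", 1, 1): 1.0}
        rp, sep = _delta_corr(cc, {"c": wc, "v1": w1, "v2": w2})
        out["phenotypic"] = CorrelationEstimate(rp, sep, "phenotypic")
    return out


def correlation_matrix_report(results: list) -> pd.DataFrame:
    """Square correlation table with phenotypic correlations above the
    diagonal and genetic correlations below it, from a list of
    (trait_a, trait_b, r_genetic, r_phenotypic) tuples (r_phenotypic may be
    None for disjoint-animal pairs)."""
    traits: list = []
    for ta, tb, *_ in results:
        for t in (ta, tb):
            if t not in traits:
                traits.append(t)
    mat = pd.DataFrame("", index=traits, columns=traits, dtype=object)
    for ta, tb, rg, rp in results:
        mat.loc[tb, ta] = f"{rg:.2f}"
        if rp is not None:
            mat.loc[ta, tb] = f"{rp:.2f}"
    return mat


@dataclass
class GxEResult:
    trait: str
    environments: tuple
    rg: float
    rg_se: float
    rg_atanh: float       # estimate on the unbounded (Fisher-z) scale
    rg_atanh_se: float    # delta-method SE on that scale
    components: CovarianceComponents


def fit_gxe(
    data: pd.DataFrame,
    trait: str,
    env_column: str = "environment",
    fixed_effects: tuple[str, ...] = ("year",),
    common_cov: bool = True,
    max_iter: int = 300,
) -> GxEResult:
    """Between-environment genetic correlation for one trait.

    The trait's expression in each environment is treated as a separate
    trait; the residual covariance is fixed at zero (no animal is measured
    in both environments), the environment fixed effect is excluded, and the
    square-root transform is applied.  The full-sib family effect is shared
    machinery across environments: its cross-environment covariance is
    estimated by default (families were reared together before the split)
    or can be fixed at zero via ``common_cov=False``.
    """
    if env_column not in data.columns:
        raise DesignError(f"environment column {env_column!r} not found")
    sub = data[data[trait].notna()]
    envs = tuple(sorted(sub[env_column].dropna().unique()))
    if len(envs) != 2:
        raise DesignError(f"expected exactly two environments, found {envs}")
    dup = sub.groupby("id")[env_column].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()[:5]
        raise DesignError(f"animals measured in both environments: {bad}")
    for e in envs:
        if sub.loc[sub[env_column] == e, "sire"].nunique() < 2:
            raise DesignError(f"environment {e!r} has fewer than 2 sires")

    wide = sub.copy()
    for e in envs:
        wide[f"__{trait}@{e}"] = np.where(sub[env_column] == e, sub[trait], np.nan)
    spec = BivariateSpec(
        fixed_effects=tuple(f for f in fixed_effects if f != env_column),
        include_common="family" in data.columns,
        common_cov=common_cov,
        residual_cov=False,
        transform="sqrt",
        max_iter=max_iter,
    )
    cc = fit_bivariate(wide, f"__{trait}@{envs[0]}", f"__{trait}@{envs[1]}", spec)
    est = correlations(cc)["genetic"]
    r_in = np.clip(est.value, -_RCAP, _RCAP)
    z = float(np.arctanh(r_in))
    z_se = float(est.se / max(1.0 - r_in**2, 1e-12))
    return GxEResult(trait=trait, environments=envs, rg=est.value, rg_se=est.se,
                     rg_atanh=z, rg_atanh_se=z_se, components=cc)
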