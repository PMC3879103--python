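"""REML-fitted linear mixed models for the two-stage analysis.

Stage 1 estimates adjusted genotype means (BLUEs) and their full
variance-covariance matrix from plot data with genotype fixed and design
effects random.  Stage 2 fits the adjusted means with either the RR-BLUP
linear variance structure var(g) = ZZ' sigma_u2 or the independent-genotype
alternative var(g) = I sigma_g2, and exposes the mixed-model-equation
quantities (BLUPs, prediction-error variances, the genotype-scale C22
block) that the accuracy estimators consume.

The restricted likelihood is maximized on the observation scale: models
with a single random term use a spectral profiled-likelihood path
(eigendecomposition of the covariance kernel, one-dimensional search over
the variance ratio); multi-component models use bounded quasi-Newton on
log variances with analytic gradients.  Variance components that hit the
zero lower boundary are returned as exactly 0 with a boundary flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .genomes import MarkerMatrix
from .trial_sim import PlotData

__all__ = [
    "RandomTerm",
    "REMLResult",
    "reml_fit",
    "AdjustedMeans",
    "RRBlupFit",
    "IndependentFit",
    "stage1_adjusted_means",
    "fit_rrblup_means",
    "fit_independent_genotypes",
    "mean_variance_of_difference",
]

# convergence / boundary tolerances (stand-ins for unstated software defaults)
REML_TOL = 1e-8
REML_MAX_ITER = 200
BOUNDARY_REL = 1e-8  # sigma2 below this fraction of var(y) counts as 0
RANK_TOL = 1e-10     # pseudo-inverse rank tolerance, relative to largest sv


@dataclass
class RandomTerm:
    """One random model term: y-side design Z (n x q) and optional kernel.

    ``kernel=None`` means iid effects (identity kernel), so the term
    contributes Z Z' sigma2 to var(y); otherwise it contributes
    Z K Z' sigma2.
    """

    name: str
    Z: np.ndarray
    kernel: np.ndarray | None = None

    def cov_kernel(self, n: int) -> np.ndarray:
        Z = np.asarray(self.Z, dtype=float)
        if Z.shape[0] != n:
            raise ValueError(f"term {self.name!r}: design has {Z.shape[0]} rows, expected {n}")
        K = Z @ Z.T if self.kernel is None else Z @ self.kernel @ Z.T
        return (K + K.T) / 2.0


@dataclass
class REMLResult:
    components: dict            # term name -> sigma2 (0 exactly at boundary)
    sigma_e2: float
    beta: np.ndarray
    vcov_beta: np.ndarray
    V: np.ndarray
    converged: bool
    boundary: tuple
    neg2_restricted_ll: float
    n_iter: int
    flags: tuple = ()


def _gls(V: np.ndarray, X: np.ndarray, y: np.ndarray):
    """GLS beta, vcov(beta) and the projected residual V^-1 (y - X beta)."""
    cho = linalg.cho_factor(V, lower=True)
    ViX = linalg.cho_solve(cho, X)
    Viy = linalg.cho_solve(cho, y)
    A = X.T @ ViX
    Ainv = np.linalg.pinv(A, rcond=RANK_TOL)
    beta = Ainv @ (X.T @ Viy)
    vcov = (Ainv + Ainv.T) / 2.0
    return beta, vcov, Viy - ViX @ beta


def _single_kernel_reml(y, X, K, tol=REML_TOL):
    """Profiled REML for V = sigma_k2 K + sigma_e2 I.

    Returns (sigma_k2, sigma_e2, neg2llr, n_eval, flags).
    """
    n, q = X.shape
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    scale = max(np.trace(K) / n, np.finfo(float).tiny)  # typical kernel size

    def crit(lam: float):
        h = lam * w + 1.0
        Xh = Xt / h[:, None]
        A = Xt.T @ Xh
        xty = Xh.T @ yt
        try:
            cho = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError:
            return np.inf, np.nan
        logdet_a = 2.0 * np.log(np.diag(cho[0])).sum()
        quad = float(yt @ (yt / h) - xty @ linalg.cho_solve(cho, xty))
        if quad <= 0.0:
            return np.inf, 0.0
        se2 = quad / (n - q)
        f = (n - q) * np.log(se2) + np.log(h).sum() + logdet_a
        return f, se2

    # coarse grid on the variance ratio, then local refinement
    grid = np.concatenate([[0.0], np.logspace(-8, 8, 33) / scale])
    vals = np.array([crit(l)[0] for l in grid])
    if not np.isfinite(vals).any():
        return 0.0, max(np.var(y), np.finfo(float).eps), np.inf, len(grid), ("degenerate",)
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    n_eval = len(grid)
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda t: crit(np.expm1(t))[0] if np.expm1(t) >= 0 else np.inf,
            bounds=(np.log1p(lo), np.log1p(hi)),
            method="bounded",
            options={"xatol": tol},
        )
        lam = float(np.expm1(res.x))
        n_eval += res.nfev
        if crit(lam)[0] > vals[i]:
            lam = float(grid[i])
    else:
        lam = float(grid[i])

    flags = ()
    if lam * scale < 1e-8:  # zero lower boundary for the kernel variance
        lam = 0.0
        flags = ("boundary",)
    f, se2 = crit(lam)
    return lam * se2, se2, f, n_eval, flags


def _dense_reml(y, X, kernels, tol=REML_TOL, max_iter=REML_MAX_ITER):
    """Multi-component REML by L-BFGS-B on log variances.

    ``kernels`` is a list of n x n PSD matrices; the residual identity
    component is handled implicitly.  Returns (sigma2s, sigma_e2, neg2llr,
    n_iter, converged, boundary_mask).
    """
    n, q = X.shape
    m = len(kernels)
    vy = max(np.var(y), np.finfo(float).eps)
    cs = [max(np.trace(K) / n, np.finfo(float).tiny) for K in kernels]

    def build(theta):
        V = np.eye(n) * theta[-1]
        for s2, K in zip(theta[:-1], kernels):
            V = V + s2 * K
        return V

    def obj(x):
        theta = np.exp(x)
        V = build(theta)
        try:
            cho = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            # repair near-singular V with a small ridge; a finite value with
            # a usable gradient keeps the line search alive
            V = V + np.eye(n) * (1e-10 * max(np.trace(V) / n, vy))
            cho = linalg.cho_factor(V, lower=True)
        logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
        ViX = linalg.cho_solve(cho, X)
        Viy = linalg.cho_solve(cho, y)
        A = X.T @ ViX
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, np.zeros_like(x)
        Ainv = np.linalg.pinv(A, rcond=RANK_TOL)
        Py = Viy - ViX @ (Ainv @ (X.T @ Viy))
        f = logdet_v + logdet_a + float(y @ Py)
        grad = np.empty_like(x)
        for j, K in enumerate(kernels + [np.eye(n)]):
            ViK = linalg.cho_solve(cho, K)
            tr_pk = np.trace(ViK) - np.trace(Ainv @ (ViX.T @ (K @ ViX)))
            grad[j] = theta[j] * (tr_pk - float(Py @ (K @ Py)))
        return f, grad

    x0 = np.log(np.r_[[0.5 * vy / (m * c) for c in cs], 0.5 * vy])
    bounds = [(np.log(vy) - np.log(c) - 21.0, np.log(vy) - np.log(c) + 9.0) for c in cs]
    bounds.append((np.log(vy) - 21.0, np.log(vy) + 9.0))
    res = optimize.minimize(
        obj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
    )
    theta = np.exp(res.x)
    boundary = np.array([t < BOUNDARY_REL * vy / c for t, c in zip(theta[:-1], cs)])
    theta[:-1][boundary] = 0.0
    theta[-1] = max(theta[-1], BOUNDARY_REL * vy)
    f, _ = obj(np.log(np.where(theta > 0, theta, np.finfo(float).tiny)))
    return theta[:-1], theta[-1], f, res.nit, bool(res.success), boundary


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    random_terms: Sequence[RandomTerm],
    tol: float = REML_TOL,
    max_iter: int = REML_MAX_ITER,
) -> REMLResult:
    """Fit y = X beta + sum_j Z_j u_j + e by REML.

    Each random term contributes Z_j K_j Z_j' sigma_j2 to var(y); the
    residual is I sigma_e2.  Non-convergence is flagged, not raised, so the
    evaluation layer can count failures per dataset.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, q = X.shape
    if n <= q:
        raise ValueError("more fixed-effect columns than observations")
    kernels = [t.cov_kernel(n) for t in random_terms]
    names = [t.name for t in random_terms]

    flags: list = []
    if len(kernels) == 1:
        s2k, se2, f, n_iter, fl = _single_kernel_reml(y, X, kernels[0], tol)
        sigmas = np.array([s2k])
        converged = "degenerate" not in fl
        boundary_mask = np.array(["boundary" in fl])
        flags.extend(fl)
    elif len(kernels) == 0:
        # pure fixed-effects model: sigma_e2 from OLS residuals
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta0
        se2 = float(resid @ resid) / (n - q)
        sigmas, f, n_iter, converged = np.array([]), np.nan, 0, True
        boundary_mask = np.array([], dtype=bool)
    else:
        sigmas, se2, f, n_iter, converged, boundary_mask = _dense_reml(
            y, X, kernels, tol, max_iter
        )
        if not converged:
            flags.append("nonconverged")

    V = np.eye(n) * se2
    for s2, K in zip(sigmas, kernels):
        V = V + s2 * K
    beta, vcov, _ = _gls(V, X, y)
    return REMLResult(
        components=dict(zip(names, map(float, sigmas))),
        sigma_e2=float(se2),
        beta=beta,
        vcov_beta=vcov,
        V=V,
        converged=bool(converged),
        boundary=tuple(np.array(names)[boundary_mask]) if len(names) else (),
        neg2_restricted_ll=float(f) if np.isfinite(f) else np.nan,
        n_iter=int(n_iter),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# stage 1: adjusted means


@dataclass
class AdjustedMeans:
    """Stage-1 BLUEs of genotype means with their variance-covariance matrix."""

    entry_ids: list
    p: np.ndarray
    Omega: np.ndarray
    sigma_e2_plot: float
    components: dict
    n_reps: int
    converged: bool
    flags: tuple = ()

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).ravel()
        self.Omega = np.asarray(self.Omega, dtype=float)
        n = len(self.entry_ids)
        if self.p.size != n or self.Omega.shape != (n, n):
            raise ValueError("adjusted-means dimensions are inconsistent")

    @property
    def n(self) -> int:
        return len(self.entry_ids)

    def subset(self, entry_ids: Sequence) -> "AdjustedMeans":
        idx = {e: i for i, e in enumerate(self.entry_ids)}
        rows = [idx[e] for e in entry_ids]
        return AdjustedMeans(
            list(entry_ids),
            self.p[rows],
            self.Omega[np.ix_(rows, rows)],
            self.sigma_e2_plot,
            self.components,
            self.n_reps,
            self.converged,
            self.flags,
        )


def _dummies(labels: pd.Series, drop_first_within: pd.Series | None = None):
    """One-hot columns; optionally drop the first level within each group."""
    labels = labels.astype(str)
    if drop_first_within is None:
        levels = sorted(labels.unique())
        keep = levels
    else:
        df = pd.DataFrame({"lab": labels, "grp": drop_first_within.astype(str)})
        keep = []
        for _, sub in df.groupby("grp", sort=True):
            lvls = sorted(sub["lab"].unique())
            keep.extend(lvls[1:])
    cols = [(labels == lv).to_numpy(float) for lv in keep]
    return (np.column_stack(cols) if cols else np.empty((len(labels), 0))), keep


def stage1_adjusted_means(plots: PlotData, drop_checks: bool = True) -> AdjustedMeans:
    """Adjusted genotype means (BLUEs) and their vcov from plot data.

    Genotype enters as a fixed effect (checks and non-genotyped entries get
    their own fixed levels so they adjust the block-variance estimation but
    are dropped from the output).  Single-trial layouts add fixed replicate
    effects and random blocks-within-replicates; multi-trial layouts treat
    trial and trial x replicate as additional random terms.  Group and
    tester labels, where present with several levels, enter as fixed
    effects.
    """
    df = plots.plots
    obs = df[df["yield"].notna()].reset_index(drop=True)
    flags: list = []

    all_entries = sorted(df["entry_id"].unique())
    observed = set(obs["entry_id"])
    inestimable = [e for e in all_entries if e not in observed]
    if inestimable:
        flags.append("inestimable_entries")
        all_entries = [e for e in all_entries if e in observed]

    entry_cols = np.column_stack(
        [(obs["entry_id"] == e).to_numpy(float) for e in all_entries]
    )
    X_parts = [entry_cols]
    trials = sorted(df["trial"].unique())
    multi_trial = len(trials) > 1
    if not multi_trial:
        rep_cols, _ = _dummies(obs["replicate"], obs["trial"])
        X_parts.append(rep_cols)
    for col in ("group_label", "tester_label"):
        lab = obs[col].astype(str)
        if lab.nunique() > 1:
            c, _ = _dummies(lab, pd.Series("all", index=obs.index))
            X_parts.append(c)
    X = np.column_stack(X_parts)

    # drop linearly dependent non-entry columns (confounded design effects)
    n_entry = entry_cols.shape[1]
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    dep = piv[diag < RANK_TOL * max(diag[0], 1.0) * X.shape[0]] if diag.size else []
    dep_extra = [j for j in np.atleast_1d(dep) if j >= n_entry]
    dep_entry = [j for j in np.atleast_1d(dep) if j < n_entry]
    if dep_entry:
        flags.append("disconnected_design")
    if dep_extra:
        X = np.delete(X, dep_extra, axis=1)

    blk = obs[["trial", "replicate", "block"]].astype(str).agg("|".join, axis=1)
    terms = [RandomTerm("block", _dummies(blk)[0])]
    if multi_trial:
        terms.append(RandomTerm("trial", _dummies(obs["trial"])[0]))
        tr = obs[["trial", "replicate"]].astype(str).agg("|".join, axis=1)
        terms.append(RandomTerm("trial_rep", _dummies(tr)[0]))

    res = reml_fit(obs["yield"].to_numpy(float), X, terms)
    if not res.converged:
        flags.append("nonconverged")

    geno = [e for e in all_entries if (df.loc[df["entry_id"] == e, "entry_class"].iloc[0]
                                       == "genotyped" or not drop_checks)]
    rows = [all_entries.index(e) for e in geno]
    n_reps = int(df.groupby("trial")["replicate"].nunique().max())
    return AdjustedMeans(
        entry_ids=geno,
        p=res.beta[rows],
        Omega=res.vcov_beta[np.ix_(rows, rows)],
        sigma_e2_plot=res.sigma_e2,
        components=dict(res.components),
        n_reps=n_reps,
        converged=res.converged,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# stage 2: RR-BLUP and independent-genotype fits on the adjusted means


@dataclass
class RRBlupFit:
    """Stage-2 RR-BLUP fit of adjusted means with var(g) = ZZ' sigma_u2."""

    entry_ids: list
    sigma_u2_hat: float
    sigma_e2_hat: float
    G: np.ndarray
    V: np.ndarray
    phi_hat: float
    g_hat: np.ndarray
    C_mat: np.ndarray        # G V^-1 Q, so that g_hat = C_mat p
    C22: np.ndarray          # genotype-scale MME block: var(g) - var(g_hat)
    converged: bool
    boundary: bool
    neg2_restricted_ll: float
    flags: tuple = ()

    @property
    def R(self) -> np.ndarray:
        return np.eye(len(self.entry_ids)) * self.sigma_e2_hat

    @property
    def var_g_hat(self) -> np.ndarray:
        """var(g_hat) = cov(g, g_hat) = G - C22 on the genotype scale."""
        return self.G - self.C22


@dataclass
class IndependentFit:
    """Stage-2 fit assuming uncorrelated genotypic effects, var(g) = I sigma_g2.

    The adjusted means carry their stage-1 variance-covariance matrix Omega,
    which is taken as the (fixed) error structure: V = I sigma_g2 + Omega.
    An iid error I sigma_e2 would be confounded with I sigma_g2 on the means
    scale, so the only free component is the genetic variance.
    ``sigma_e2_hat`` reports the effective means-scale error variance,
    half the mean variance of a difference of two BLUEs.
    """

    entry_ids: list
    sigma_g2_hat: float
    sigma_e2_hat: float
    phi_hat: float
    g_hat: np.ndarray
    pev: np.ndarray          # prediction-error variance matrix var(g_hat - g)
    v_bar_blup: float        # mean PEV of a BLUP difference
    converged: bool
    boundary: bool
    flags: tuple = ()


def _stage2_fit(p: np.ndarray, K: np.ndarray):
    """Shared stage-2 machinery: REML + BLUP + MME blocks for V = s2k K + s2e I."""
    p = np.asarray(p, dtype=float).ravel()
    n = p.size
    ones = np.ones((n, 1))
    flags: list = []
    if np.var(p) < 1e-14 * max(1.0, np.mean(p) ** 2):
        flags.append("constant_p")
        z = np.zeros(n)
        zero = np.zeros((n, n))
        s2e = float(np.var(p) + np.finfo(float).eps)
        return (0.0, s2e, float(np.mean(p)), z, zero, np.eye(n) * s2e, zero,
                False, True, np.nan, flags, zero)

    s2k, s2e, f, _, fl = _single_kernel_reml(p, ones, K)
    boundary = "boundary" in fl
    converged = "degenerate" not in fl
    flags.extend(fl)

    G = s2k * K
    V = G + np.eye(n) * s2e
    cho = linalg.cho_factor(V, lower=True)
    Vi1 = linalg.cho_solve(cho, np.ones(n))
    denom = float(np.ones(n) @ Vi1)
    phi = float(Vi1 @ p) / denom
    ViQp = linalg.cho_solve(cho, p - phi)      # V^-1 Q p = V^-1 (p - 1 phi)
    g_hat = G @ ViQp
    # P = V^-1 - V^-1 1 (1' V^-1 1)^-1 1' V^-1 ; C = G P ; var(g_hat) = G P G
    ViG = linalg.cho_solve(cho, G)
    P_G = ViG - np.outer(Vi1, Vi1 @ G) / denom  # P applied to G columns
    C_mat = P_G.T                               # G P (symmetric P)
    var_ghat = G @ P_G
    var_ghat = (var_ghat + var_ghat.T) / 2.0
    C22 = G - var_ghat
    return s2k, s2e, phi, g_hat, G, V, C_mat, converged, boundary, f, flags, C22


def fit_rrblup_means(means: AdjustedMeans, Zm: MarkerMatrix) -> RRBlupFit:
    """REML RR-BLUP of the adjusted means under V = ZZ' sigma_u2 + I sigma_e2.

    The marker-effect and genotype-effect parameterizations coincide on the
    n-dimensional scale through K = ZZ', so no p-dimensional system is ever
    formed.  g_hat = G V^-1 (p - 1 phi_hat) with the general mean phi_hat
    estimated by GLS; C22 is the genotype-scale prediction-error-variance
    block G - G P G of the mixed model equations.
    """
    Zs = Zm.subset(means.entry_ids)
    K = Zs.Z @ Zs.Z.T
    K = (K + K.T) / 2.0
    out = _stage2_fit(means.p, K)
    s2k, s2e, phi, g_hat, G, V, C_mat, converged, boundary, f, flags, C22 = out
    return RRBlupFit(
        entry_ids=list(means.entry_ids),
        sigma_u2_hat=float(s2k),
        sigma_e2_hat=float(s2e),
        G=G,
        V=V,
        phi_hat=phi,
        g_hat=g_hat,
        C_mat=C_mat,
        C22=C22,
        converged=converged,
        boundary=boundary,
        neg2_restricted_ll=f,
        flags=tuple(flags),
    )


def _fixed_noise_reml(y, X, Omega, tol=REML_TOL):
    """REML of a single iid genetic variance with fixed noise structure:
    V = sigma_g2 I + Omega.  Returns (sigma_g2, neg2llr, flags)."""
    y = np.asarray(y, dtype=float).ravel()
    n, q = X.shape
    d, U = np.linalg.eigh((Omega + Omega.T) / 2.0)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    vy = max(np.var(y), np.finfo(float).eps)

    def crit(s: float):
        h = s + d
        if h.min() <= 0.0:
            return np.inf
        Xh = Xt / h[:, None]
        A = Xt.T @ Xh
        xty = Xh.T @ yt
        try:
            cho = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError:
            return np.inf
        logdet_a = 2.0 * np.log(np.diag(cho[0])).sum()
        quad = float(yt @ (yt / h) - xty @ linalg.cho_solve(cho, xty))
        return np.log(h).sum() + logdet_a + quad

    grid = np.concatenate([[0.0], np.logspace(-8, 2, 41) * vy])
    vals = np.array([crit(s) for s in grid])
    if not np.isfinite(vals).any():
        return 0.0, np.inf, ["degenerate"]
    i = int(np.nanargmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    s = float(grid[i])
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda t: crit(np.expm1(t)) if np.expm1(t) >= 0 else np.inf,
            bounds=(np.log1p(lo), np.log1p(hi)),
            method="bounded",
            options={"xatol": tol},
        )
        if crit(float(np.expm1(res.x))) <= vals[i]:
            s = float(np.expm1(res.x))
    flags = []
    if s < 1e-8 * vy:  # zero lower boundary
        s = 0.0
        flags.append("boundary")
    return s, crit(s) if s > 0 or crit(0.0) < np.inf else np.inf, flags


def fit_independent_genotypes(means: AdjustedMeans) -> IndependentFit:
    """Stage-2 fit with uncorrelated genotypes, G = I sigma_g2, noise Omega.

    REML estimates the genetic variance under V = I sigma_g2 + Omega with
    the stage-1 BLUE variance-covariance matrix Omega held fixed; BLUPs,
    their prediction-error-variance matrix and v_bar_BLUP (the mean PEV of
    a difference of two genotype BLUPs, the Method-3 ingredient) follow
    from the genotype-scale mixed-model-equation blocks.
    """
    n = means.n
    p = means.p
    ones = np.ones((n, 1))
    flags: list = []
    v_bar_omega = mean_variance_of_difference(means.Omega) if n >= 2 else 0.0

    if np.var(p) < 1e-14 * max(1.0, np.mean(p) ** 2):
        flags.append("constant_p")
        zero = np.zeros((n, n))
        return IndependentFit(
            list(means.entry_ids), 0.0, v_bar_omega / 2.0, float(np.mean(p)),
            np.zeros(n), zero, 0.0, False, True, tuple(flags),
        )

    s2g, f, fl = _fixed_noise_reml(p, ones, means.Omega)
    flags.extend(fl)
    boundary = "boundary" in fl
    converged = "degenerate" not in fl

    G = np.eye(n) * s2g
    V = G + means.Omega
    # ridge for the singular sigma_g2 = 0 corner with PSD-singular Omega
    jitter = 1e-10 * max(np.trace(V) / n, 1.0)
    cho = linalg.cho_factor(V + np.eye(n) * jitter, lower=True)
    Vi1 = linalg.cho_solve(cho, np.ones(n))
    denom = float(np.ones(n) @ Vi1)
    phi = float(Vi1 @ p) / denom
    g_hat = s2g * linalg.cho_solve(cho, p - phi)
    ViG = linalg.cho_solve(cho, G)
    PG = ViG - np.outer(Vi1, Vi1 @ G) / denom
    var_ghat = G @ PG
    pev = G - (var_ghat + var_ghat.T) / 2.0
    v_bar = mean_variance_of_difference(pev) if n >= 2 else 0.0
    return IndependentFit(
        entry_ids=list(means.entry_ids),
        sigma_g2_hat=float(s2g),
        sigma_e2_hat=float(v_bar_omega / 2.0),
        phi_hat=phi,
        g_hat=g_hat,
        pev=pev,
        v_bar_blup=float(v_bar),
        converged=converged,
        boundary=boundary,
        flags=tuple(flags),
    )


def mean_variance_of_difference(Omega: np.ndarray) -> float:
    """Mean variance of a difference over all pairs:
    (2 / (n (n - 1))) * sum_{i<j} (O_ii + O_jj - 2 O_ij).

    Adding a constant to every element of Omega leaves the result unchanged
    because differences annihilate constants.
    """
    Omega = np.asarray(Omega, dtype=float)
    n = Omega.shape[0]
    if Omega.ndim != 2 or Omega.shape != (n, n):
        raise ValueError("Omega must be square")
    if n < 2:
        raise ValueError("need at least two entries")
    scale = max(np.abs(Omega).max(), 1.0)
    if not np.allclose(Omega, Omega.T, atol=1e-8 * scale):
        raise ValueError("Omega must be symmetric")
    tr = np.trace(Omega)
    return float((2.0 / (n * (n - 1))) * (n * tr - Omega.sum()))
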