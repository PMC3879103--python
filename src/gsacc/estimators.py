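"""Heritability measures and predictive-accuracy estimators.

Seven estimators of the accuracy r(g, g_hat) — the correlation between true
and predicted breeding values — are provided.  Methods 1-4 are indirect:
they divide a cross-validated predictive ability r(g_hat, p) by the square
root of a heritability estimate (standard plot-basis H2, the BLUE-based and
BLUP-based ad hoc measures, and an expected-variance-ratio measure built
from quadratic forms).  Methods 5-7 are direct: a trace-ratio plug-in for
the expected correlation, a covariance-rescaling of the cross-validation
statistics, and the mean mixed-model-equation reliability familiar from
animal breeding.

Every estimator retains its untruncated value; values outside [0, 1] are
clamped for reporting, with overshoot/undershoot flags, and degenerate
inputs (zero heritability, zero genetic variance) produce breakdown flags
rather than exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg

from .genomes import MarkerMatrix

__all__ = [
    "FLAG_OK",
    "FLAG_OVERSHOOT",
    "FLAG_UNDERSHOOT",
    "FLAG_BREAKDOWN",
    "FLAG_NONCONVERGED",
    "FLAG_DEGENERATE",
    "FLAG_UNDEFINED",
    "Estimate",
    "CenteringOperator",
    "HeritabilitySet",
    "AccuracySet",
    "centering_operator",
    "expected_sample_variance",
    "h2_standard",
    "h2_blue",
    "h2_blup",
    "h2_expected_variance",
    "predictive_ability",
    "indirect_accuracy",
    "accuracy_m5",
    "accuracy_m6",
    "accuracy_m7",
    "reliability_from_components",
    "true_accuracy",
    "true_heritability",
]

FLAG_OK = "ok"
FLAG_OVERSHOOT = "overshoot"
FLAG_UNDERSHOOT = "undershoot"
FLAG_BREAKDOWN = "breakdown_H_zero"
FLAG_NONCONVERGED = "nonconverged"
FLAG_DEGENERATE = "degenerate"
FLAG_UNDEFINED = "undefined"

#: trace(Pu G) below this fraction of trace(Pu V) counts as a degenerate G
DEGENERATE_G_REL = 1e-12


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its untruncated value and status flag."""

    value: float            # reported (possibly truncated) value; nan if undefined
    untruncated: float      # raw value; nan if undefined
    flag: str = FLAG_OK

    def __float__(self) -> float:
        return float(self.value)


def _estimate(untruncated: float, flag: str = FLAG_OK) -> Estimate:
    """Clamp to [0, 1] and set overshoot/undershoot flags."""
    x = float(untruncated)
    if not np.isfinite(x):
        return Estimate(np.nan, np.nan, flag if flag != FLAG_OK else FLAG_UNDEFINED)
    if x > 1.0:
        return Estimate(1.0, x, FLAG_OVERSHOOT)
    if x < 0.0:
        return Estimate(0.0, x, FLAG_UNDERSHOOT)
    return Estimate(x, x, flag)


def _breakdown() -> Estimate:
    return Estimate(np.nan, np.nan, FLAG_BREAKDOWN)


@dataclass
class CenteringOperator:
    """Pu = (1/(n-1)) (I_n - J_n / n): g' Pu g is the sample variance of g."""

    n: int
    Pu: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return self.Pu


def centering_operator(n: int) -> CenteringOperator:
    if n < 2:
        raise ValueError("centering operator needs n >= 2")
    Pu = (np.eye(n) - np.ones((n, n)) / n) / (n - 1)
    return CenteringOperator(n, Pu)


def expected_sample_variance(A: np.ndarray) -> float:
    """trace(Pu A) without forming Pu: (trace A - sum(A)/n) / (n - 1).

    For A = var(x) this is E[sample variance of x]; rank-one J components of
    A are annihilated.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    return float((np.trace(A) - A.sum() / n) / (n - 1))


@dataclass
class HeritabilitySet:
    """The five heritability estimates plus the simulated truth."""

    H2_m1: Estimate
    H2_m2: Estimate
    H2_m3: Estimate
    H2_m4: Estimate
    H2_m5: Estimate
    H2_true: float = np.nan

    def as_dict(self) -> dict:
        d = {f"H2_m{i}": getattr(self, f"H2_m{i}") for i in range(1, 6)}
        d["H2_true"] = self.H2_true
        return d


@dataclass
class AccuracySet:
    """True accuracy and the seven estimates with flags."""

    r_true: float
    m1: Estimate
    m2: Estimate
    m3: Estimate
    m4: Estimate
    m5: Estimate
    m6: Estimate
    m7: Estimate

    def estimate(self, k: int) -> Estimate:
        return getattr(self, f"m{k}")

    def as_dict(self) -> dict:
        d = {"r_true": self.r_true}
        d.update({f"m{k}": getattr(self, f"m{k}") for k in range(1, 8)})
        return d


# ---------------------------------------------------------------------------
# heritability measures


def h2_standard(sigma_g2: float, sigma_e2: float, r: int) -> float:
    """Standard single-trial heritability sigma_g2 / (sigma_g2 + sigma_e2/r).

    ``r`` is the number of replicates and sigma_e2 the plot-error variance.
    Exact for randomized complete blocks, an ad hoc approximation for
    incomplete block designs.
    """
    if r < 1:
        raise ValueError("replicate count r must be >= 1")
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variances must be non-negative")
    if sigma_g2 == 0.0:
        return 0.0
    return sigma_g2 / (sigma_g2 + sigma_e2 / r)


def h2_blue(sigma_g2: float, v_bar: float) -> float:
    """BLUE-based measure sigma_g2 / (sigma_g2 + v_bar / 2).

    ``v_bar`` is the mean variance of a difference of two adjusted genotype
    means; on a balanced complete-block design v_bar = 2 sigma_e2 / r and
    this equals the standard measure.
    """
    if sigma_g2 < 0 or v_bar < 0:
        raise ValueError("inputs must be non-negative")
    if sigma_g2 == 0.0:
        return 0.0
    return sigma_g2 / (sigma_g2 + v_bar / 2.0)


def h2_blup(v_bar_blup: float, sigma_g2: float) -> float:
    """BLUP-based measure 1 - v_bar_BLUP / (2 sigma_g2); may be negative.

    Breaks down (raises) when sigma_g2 = 0: callers should flag rather than
    divide by zero.
    """
    if sigma_g2 <= 0.0:
        raise ZeroDivisionError("BLUP-based heritability undefined for sigma_g2 = 0")
    return 1.0 - v_bar_blup / (2.0 * sigma_g2)


def h2_expected_variance(G: np.ndarray, R: np.ndarray) -> float:
    """Expected-variance-ratio measure trace(Pu G) / trace(Pu V), V = G + R.

    The numerator is the expected genetic sample variance E[s_g2] under
    var(g) = G; the denominator adds the error contribution trace(R Pu).
    Constant (J-type) components of G or R do not contribute.
    """
    G = np.asarray(G, dtype=float)
    R = np.asarray(R, dtype=float)
    if G.shape != R.shape or G.shape[0] != G.shape[1]:
        raise ValueError("G and R must be square and conformable")
    e_sg2 = expected_sample_variance(G)
    e_sp2 = e_sg2 + expected_sample_variance(R)
    if e_sp2 <= 0.0:
        return 0.0
    return e_sg2 / e_sp2


# ---------------------------------------------------------------------------
# correlations


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    sx = x - x.mean()
    sy = y - y.mean()
    den = np.sqrt((sx @ sx) * (sy @ sy))
    if den == 0.0:
        return np.nan
    return float(sx @ sy / den)


def predictive_ability(g_hat: np.ndarray, p: np.ndarray) -> Estimate:
    """Sample correlation r(g_hat, p) between predictions and phenotypes."""
    r = _pearson(g_hat, p)
    if np.isnan(r):
        return Estimate(np.nan, np.nan, FLAG_UNDEFINED)
    return Estimate(r, r, FLAG_OK)


def true_accuracy(g: np.ndarray, g_hat: np.ndarray) -> Estimate:
    """True accuracy r(g, g_hat) using the n-1 sample moments."""
    r = _pearson(g, g_hat)
    if np.isnan(r):
        return Estimate(np.nan, np.nan, FLAG_UNDEFINED)
    return Estimate(r, r, FLAG_OK)


def true_heritability(g: np.ndarray, g_hat: np.ndarray) -> float:
    """H2_true = r(g, g_hat)^2."""
    r = true_accuracy(g, g_hat)
    return float(r.untruncated**2) if np.isfinite(r.untruncated) else np.nan


# ---------------------------------------------------------------------------
# accuracy estimators


def indirect_accuracy(r_gp: float, H2: float) -> Estimate:
    """Methods 1-4: predictive ability divided by sqrt(heritability).

    H2 <= 0 signals estimator breakdown (zero estimated heritability);
    values outside [0, 1] are truncated with overshoot/undershoot flags.
    """
    if not np.isfinite(H2) or H2 <= 0.0:
        return _breakdown()
    if not np.isfinite(r_gp):
        return Estimate(np.nan, np.nan, FLAG_UNDEFINED)
    return _estimate(r_gp / np.sqrt(H2))


def accuracy_m5(G: np.ndarray, V: np.ndarray, tol: float = DEGENERATE_G_REL) -> Estimate:
    """Direct trace-ratio estimator (Method 5).

    With C = G V^-1 Q and Q = I - 1 (1' V^-1 1)^-1 1' V^-1,

        rho = trace(Pu C G) / sqrt(trace(Pu G) trace(C' Pu C V)).

    Plugging REML estimates into G and V gives the estimated accuracy; its
    square serves as the Method-5 heritability.  A degenerate G
    (trace(Pu G) below ``tol`` times trace(Pu V)) returns 0 with a flag.
    """
    G = np.asarray(G, dtype=float)
    V = np.asarray(V, dtype=float)
    n = G.shape[0]
    t_g = expected_sample_variance(G)
    t_v = expected_sample_variance(V)
    if t_g <= tol * max(t_v, np.finfo(float).tiny):
        return Estimate(0.0, 0.0, FLAG_DEGENERATE)
    cho = linalg.cho_factor(V, lower=True)
    Vi1 = linalg.cho_solve(cho, np.ones(n))
    denom = float(np.ones(n) @ Vi1)
    ViG = linalg.cho_solve(cho, G)
    PG = ViG - np.outer(Vi1, Vi1 @ G) / denom   # P G with P = V^-1 Q
    C = PG.T                                    # C = G P (P symmetric)
    num = expected_sample_variance(C @ G)
    t_chat = expected_sample_variance(C @ V @ C.T)
    if t_chat <= 0.0:
        return Estimate(0.0, 0.0, FLAG_DEGENERATE)
    rho = num / np.sqrt(t_g * t_chat)
    return _estimate(rho)


def accuracy_m6(s_gp: float, s_g2hat: float, E_sg2: float) -> Estimate:
    """Direct covariance-rescaling estimator (Method 6):
    s(g_hat, p) / sqrt(s(g_hat)^2 * E[s_g2]).

    ``E_sg2`` = trace(Pu G) replaces the unobservable sample variance of the
    true breeding values.  Non-positive variances are flagged.
    """
    if not np.isfinite(s_gp):
        return Estimate(np.nan, np.nan, FLAG_UNDEFINED)
    if s_g2hat <= 0.0 or E_sg2 <= 0.0:
        return _breakdown()
    return _estimate(s_gp / np.sqrt(s_g2hat * E_sg2))


def reliability_from_components(
    G: np.ndarray,
    sigma_e2: float,
    absorb_mean: bool = True,
    tol: float = 1e-10,
) -> tuple[np.ndarray, Estimate]:
    """Per-genotype MME reliabilities and their mean-root accuracy.

    With V = G + I sigma_e2 and P the V-inverse projector (absorbing the
    general mean when ``absorb_mean``), var(g_hat) = cov(g, g_hat) = G P G,
    so rho_i^2 = var(g_hat)_ii / var(g)_ii; the dataset accuracy is the
    square root of the mean reliability.  Genotypes with negligible genetic
    variance are skipped.
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    V = G + np.eye(n) * float(sigma_e2)
    cho = linalg.cho_factor(V, lower=True)
    ViG = linalg.cho_solve(cho, G)
    if absorb_mean:
        Vi1 = linalg.cho_solve(cho, np.ones(n))
        denom = float(np.ones(n) @ Vi1)
        PG = ViG - np.outer(Vi1, Vi1 @ G) / denom
    else:
        PG = ViG
    var_ghat = np.einsum("ij,ji->i", G, PG)
    var_g = np.diag(G).copy()
    scale = max(var_g.max(initial=0.0), np.finfo(float).tiny)
    ok = var_g > tol * scale
    flag = FLAG_OK
    if var_ghat.min(initial=0.0) < -1e-6 * scale:
        flag = FLAG_DEGENERATE  # reliability numerator not PSD beyond tolerance
    rho2 = np.full(n, np.nan)
    rho2[ok] = np.clip(var_ghat[ok], 0.0, None) / var_g[ok]
    if not ok.any():
        return rho2, Estimate(np.nan, np.nan, FLAG_DEGENERATE)
    mean_rho2 = float(np.nanmean(rho2[ok]))
    est = _estimate(np.sqrt(mean_rho2), flag)
    return rho2, est


def accuracy_m7(fit, Zm: Optional[MarkerMatrix] = None) -> Estimate:
    """Mean MME reliability-root (Method 7) from a fitted RR-BLUP model.

    Uses the genotype-scale identities var(g) = ZZ' sigma_u2 and
    cov(g, g_hat) = var(g_hat) = var(g) - Z C22 Z', taking C22 from the
    fit; ``Zm`` is accepted for interface symmetry but the fit already
    carries everything on the genotype scale.
    """
    if not getattr(fit, "converged", True):
        return Estimate(np.nan, np.nan, FLAG_NONCONVERGED)
    G = np.asarray(fit.G, dtype=float)
    var_ghat_mat = G - np.asarray(fit.C22, dtype=float)
    n = G.shape[0]
    var_g = np.diag(G)
    var_ghat = np.diag(var_ghat_mat)
    scale = max(var_g.max(initial=0.0), np.finfo(float).tiny)
    ok = var_g > 1e-10 * scale
    if not ok.any():
        return Estimate(np.nan, np.nan, FLAG_DEGENERATE)
    flag = FLAG_OK
    if var_ghat.min(initial=0.0) < -1e-6 * scale:
        flag = FLAG_DEGENERATE
    rho2 = np.clip(var_ghat[ok], 0.0, None) / var_g[ok]
    return _estimate(np.sqrt(float(np.mean(rho2))), flag)
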