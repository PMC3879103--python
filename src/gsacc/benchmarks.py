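"""Monte-Carlo oracles and parameter-recovery benchmarks.

These routines exercise the estimators against independent ground truth:
the Method-5 trace formula against the Monte-Carlo mean of the sample
correlation r(g, g_hat) at known components, the Method-7 mean reliability
against empirical per-genotype squared correlations, and REML recovery of
the simulation variance components at the reference alpha-design geometry
(177 genotypes, 10 blocks x 18 plots, 2 replicates).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from . import estimators as est
from . import study, trial_sim
from .genomes import MarkerMatrix, code_genotypes, generate_dh_markers
from .lmm import fit_rrblup_means, stage1_adjusted_means

__all__ = [
    "simulate_blup_draws",
    "m5_oracle",
    "m7_oracle",
    "reml_recovery",
]


def _fixed_panel(n: int, p: int, seed: int) -> MarkerMatrix:
    return code_genotypes(generate_dh_markers(n, p, seed=seed))


def simulate_blup_draws(
    Zm: MarkerMatrix,
    sigma_u2: float,
    sigma_e2: float,
    n_sims: int,
    seed: int,
):
    """Draw (g, g_hat) pairs at known components.

    g = Z u with u ~ N(0, sigma_u2 I); phenotypes p = g + e with
    e ~ N(0, sigma_e2 I); g_hat is the RR-BLUP G V^-1 (p - 1 phi_hat) with
    the true components plugged in and phi_hat estimated per draw.
    """
    rng = np.random.default_rng(seed)
    n = Zm.n
    G = Zm.Z @ Zm.Z.T * sigma_u2
    V = G + np.eye(n) * sigma_e2
    cho = linalg.cho_factor(V, lower=True)
    Vi1 = linalg.cho_solve(cho, np.ones(n))
    denom = float(np.ones(n) @ Vi1)

    u = rng.normal(0.0, np.sqrt(sigma_u2), size=(Zm.p, n_sims))
    g = Zm.Z @ u
    p = g + rng.normal(0.0, np.sqrt(sigma_e2), size=(n, n_sims))
    phi = (Vi1 @ p) / denom
    g_hat = G @ linalg.cho_solve(cho, p - phi)
    return g, g_hat, G, V


def m5_oracle(
    n: int = 100,
    p: int = 200,
    sigma_u2: float = 0.2019,
    sigma_e2: float = 48.6728 / 2,
    n_sims: int = 2000,
    seed: int = 0,
):
    """Method-5 trace formula vs the Monte-Carlo mean of r(g, g_hat).

    Returns (formula_value, mc_mean, abs_gap).  The error variance defaults
    to the reference plot error over two replicates, the effective
    means-scale noise of the reference design.
    """
    rng = np.random.default_rng(seed)
    Zm = _fixed_panel(n, p, int(rng.integers(2**31)))
    g, g_hat, G, V = simulate_blup_draws(
        Zm, sigma_u2, sigma_e2, n_sims, int(rng.integers(2**31))
    )
    gc = g - g.mean(axis=0)
    hc = g_hat - g_hat.mean(axis=0)
    rs = (gc * hc).sum(0) / np.sqrt((gc**2).sum(0) * (hc**2).sum(0))
    formula = est.accuracy_m5(G, V).value
    mc = float(rs.mean())
    return formula, mc, abs(formula - mc)


def m7_oracle(
    n: int = 100,
    p: int = 200,
    sigma_u2: float = 0.2019,
    sigma_e2: float = 48.6728 / 2,
    n_sims: int = 2000,
    seed: int = 0,
):
    """Method-7 mean reliability vs empirical per-genotype squared
    correlation between g and g_hat across simulations.

    Returns (formula_value, mc_value, abs_gap), both on the accuracy
    (square-root) scale.
    """
    rng = np.random.default_rng(seed)
    Zm = _fixed_panel(n, p, int(rng.integers(2**31)))
    g, g_hat, G, V = simulate_blup_draws(
        Zm, sigma_u2, sigma_e2, n_sims, int(rng.integers(2**31))
    )
    gc = g - g.mean(axis=1, keepdims=True)
    hc = g_hat - g_hat.mean(axis=1, keepdims=True)
    num = (gc * hc).sum(1)
    den = np.sqrt((gc**2).sum(1) * (hc**2).sum(1))
    rho2_emp = (num / den) ** 2
    mc = float(np.sqrt(rho2_emp.mean()))
    _, formula = est.reliability_from_components(G, sigma_e2, absorb_mean=True)
    return formula.value, mc, abs(formula.value - mc)


def reml_recovery(
    n_datasets: int = 200,
    seed: int = 0,
    cfg: "study.ScenarioConfig | None" = None,
):
    """Median REML estimates of the plot-error and marker variances.

    Simulates ``n_datasets`` datasets at the reference geometry and
    components, runs stage 1 (plot data -> adjusted means) and stage 2
    (RR-BLUP of the means), and returns the medians together with the
    simulated truths.
    """
    if cfg is None:
        cfg = study.load_scenario("scenario1")
    rng = np.random.default_rng(seed)
    Zm = study.build_markers(cfg, int(rng.integers(2**31)))
    layout = study.build_layout(cfg, Zm, int(rng.integers(2**31)))
    vc = cfg.variance_components

    se2, su2 = [], []
    for _ in range(n_datasets):
        s = rng.integers(2**31, size=2)
        eff = trial_sim.simulate_true_effects(Zm, layout, vc, seed=int(s[0]))
        plots = trial_sim.simulate_plot_data(
            eff, layout, vc, missing_rate=cfg.missing_yield_rate, seed=int(s[1])
        )
        means = stage1_adjusted_means(plots)
        rr = fit_rrblup_means(means, Zm)
        se2.append(means.sigma_e2_plot)
        su2.append(rr.sigma_u2_hat)
    return {
        "sigma_e2_median": float(np.median(se2)),
        "sigma_e2_truth": vc.residual,
        "sigma_u2_median": float(np.median(su2)),
        "sigma_u2_truth": vc.marker,
        "n_datasets": n_datasets,
    }
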