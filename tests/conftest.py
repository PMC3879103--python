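import numpy as np
import pandas as pd
import pytest

from gsacc import genomes, study, trial_sim
from gsacc.lmm import AdjustedMeans


@pytest.fixture(scope="session")
def scenario1_cfg():
    return study.load_scenario("scenario1")


@pytest.fixture(scope="session")
def small_markers():
    """A clean 60-genotype x 80-marker DH panel (no artefact calls)."""
    raw = genomes.generate_dh_markers(60, 80, seed=421)
    return genomes.code_genotypes(raw)


def make_rcbd(n_entries: int, n_reps: int, sigma_g2: float, sigma_e2: float,
              seed: int, rep_effects=None):
    """Balanced complete-block data: one block per replicate.

    Returns (PlotData, true genotype effects dict).  Genotype effects are
    iid N(0, sigma_g2); complete blocks coincide with replicates so the
    genotype BLUE reduces to the arithmetic mean up to a constant.
    """
    rng = np.random.default_rng(seed)
    entries = [f"G{i + 1:04d}" for i in range(n_entries)]
    g = dict(zip(entries, rng.normal(0, np.sqrt(sigma_g2), n_entries)))
    rep_effects = rep_effects or {}
    rows = []
    plot = 1
    for k in range(n_reps):
        for e in entries:
            rows.append(
                {
                    "plot_id": f"P{plot:04d}",
                    "trial": "T1",
                    "replicate": f"R{k + 1}",
                    "block": f"B{k + 1}",
                    "entry_id": e,
                    "entry_class": "genotyped",
                    "group_label": "",
                    "tester_label": "",
                    "yield": g[e]
                    + rep_effects.get(f"R{k + 1}", 0.0)
                    + rng.normal(0, np.sqrt(sigma_e2)),
                }
            )
            plot += 1
    return trial_sim.PlotData(pd.DataFrame(rows)), g


@pytest.fixture()
def rcbd_factory():
    return make_rcbd


def synthetic_means(n: int, K: np.ndarray, sigma_u2: float, omega_diag: float,
                    seed: int) -> tuple[AdjustedMeans, np.ndarray]:
    """Adjusted means drawn from the stage-2 generative model.

    p = phi + g + e with g ~ N(0, K sigma_u2), e ~ N(0, omega_diag I);
    returns the means object and the true g.
    """
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(K * sigma_u2 + 1e-10 * np.eye(n))
    g = L @ rng.normal(size=n)
    p = 10.0 + g + rng.normal(0, np.sqrt(omega_diag), n)
    ids = [f"G{i + 1:04d}" for i in range(n)]
    means = AdjustedMeans(
        entry_ids=ids,
        p=p,
        Omega=np.eye(n) * omega_diag,
        sigma_e2_plot=omega_diag * 2,
        components={"block": 0.0},
        n_reps=2,
        converged=True,
    )
    return means, g


@pytest.fixture()
def means_factory():
    return synthetic_means
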