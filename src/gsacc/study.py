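"""Scenario runner and evaluation layer.

Simulates N datasets for a scenario (marker matrix shared across datasets
by default, as when a real marker panel is reused), runs the two-stage
analysis and all seven accuracy estimators on each, applies the
exclusion/truncation bookkeeping (datasets with negative or undefined true
accuracy are excluded; estimates are truncated to [0, 1] with flags), and
summarizes per-method descriptive statistics, mean squared deviation from
truth, and pairwise between-method correlations.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import estimators as est
from . import genomes, trial_sim
from .cv import cv_predictive_ability, make_folds
from .lmm import (
    fit_independent_genotypes,
    fit_rrblup_means,
    mean_variance_of_difference,
    stage1_adjusted_means,
)

__all__ = [
    "ScenarioConfig",
    "AccuracyRecord",
    "load_scenario",
    "msd",
    "truncate01",
    "run_dataset",
    "run_scenario",
    "summarize",
    "SCENARIO_PRESETS",
]

SCENARIO_PRESETS = ("scenario1", "scenario2", "scenario3", "scenario4")

METHODS = [f"m{k}" for k in range(1, 8)]


@dataclass
class ScenarioConfig:
    """Everything needed to simulate and evaluate one scenario."""

    name: str
    n_genotypes: int
    n_markers: int
    design: dict
    variance_components: trial_sim.VarianceComponents
    n_datasets: int = 1000
    seed: int = 1
    cv_k: int = 3
    cv_reps: int = 5
    marker_mode: str = "shared"          # or "per-dataset"
    ability_mode: str = "foldwise"       # or "pooled"
    markers: dict = field(default_factory=dict)
    fixed_offsets: dict = field(default_factory=dict)
    missing_yield_rate: float = 0.0
    n_nongenotyped: int = 0
    include_nongenotyped: bool = False

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if not isinstance(self.variance_components, trial_sim.VarianceComponents):
            self.variance_components = trial_sim.VarianceComponents(
                **dict(self.variance_components)
            )

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        cv = d.pop("cv", None)
        if cv:
            d.setdefault("cv_k", cv.get("k", 3))
            d.setdefault("cv_reps", cv.get("n_reps", 5))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["variance_components"] = {
            k: v
            for k, v in self.variance_components.as_dict().items()
            if v is not None
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def scaled(self, **overrides) -> "ScenarioConfig":
        """Copy with overrides (used for reduced-size runs)."""
        d = asdict(self)
        d["variance_components"] = self.variance_components
        d.update(overrides)
        return ScenarioConfig(**d)


def load_scenario(name_or_path) -> ScenarioConfig:
    """Load a shipped preset (scenario1..scenario4) or a YAML file."""
    name = str(name_or_path)
    if name in SCENARIO_PRESETS:
        ref = importlib.resources.files("gsacc") / "presets" / f"{name}.yaml"
        with importlib.resources.as_file(ref) as path:
            return ScenarioConfig.from_yaml(path)
    return ScenarioConfig.from_yaml(name_or_path)


# ---------------------------------------------------------------------------
# elementary bookkeeping operations


def msd(estimates, truths) -> float:
    """Mean squared deviation sum((est - truth)^2) / N over complete pairs."""
    a = np.asarray(estimates, dtype=float).ravel()
    b = np.asarray(truths, dtype=float).ravel()
    if a.size != b.size or a.size < 1:
        raise ValueError("need equal-length non-empty vectors")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("inputs must be pairwise complete")
    return float(np.mean((a - b) ** 2))


def truncate01(x: float) -> tuple[float, str]:
    """Clamp to [0, 1]; returns (value, flag). Idempotent."""
    if not np.isfinite(x):
        raise ValueError("truncate01 requires a finite value")
    if x > 1.0:
        return 1.0, est.FLAG_OVERSHOOT
    if x < 0.0:
        return 0.0, est.FLAG_UNDERSHOOT
    return float(x), est.FLAG_OK


# ---------------------------------------------------------------------------
# dataset pipeline


@dataclass
class AccuracyRecord:
    """Everything measured on one simulated dataset."""

    dataset: int
    seed: int
    r_true: float
    H2_true: float
    heritability: est.HeritabilitySet
    accuracy: est.AccuracySet
    ability: float
    cv_nonconverged: int
    converged: bool
    excluded: bool
    exclusion_reason: str

    def as_row(self) -> dict:
        row = {
            "dataset": self.dataset,
            "seed": self.seed,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "converged": self.converged,
            "r_true": self.r_true,
            "H2_true": self.H2_true,
            "ability": self.ability,
            "cv_nonconverged": self.cv_nonconverged,
        }
        for i in range(1, 6):
            h = getattr(self.heritability, f"H2_m{i}")
            row[f"H2_m{i}"] = h.untruncated
            row[f"H2_m{i}_flag"] = h.flag
        for k in range(1, 8):
            e = self.accuracy.estimate(k)
            row[f"m{k}"] = e.value
            row[f"m{k}_untrunc"] = e.untruncated
            row[f"m{k}_flag"] = e.flag
        return row


def build_markers(cfg: ScenarioConfig, seed: int):
    """Generate, QC-filter and code the scenario's marker panel."""
    m = dict(cfg.markers)
    raw = genomes.generate_dh_markers(
        n=cfg.n_genotypes,
        p=cfg.n_markers,
        maf_spectrum=("uniform", m.get("maf_low", 0.05), m.get("maf_high", 0.5)),
        missing_rate=m.get("missing_rate", 0.0),
        het_rate=m.get("het_rate", 0.0),
        seed=seed,
    )
    raw, _ = genomes.qc_filter(raw)
    return genomes.code_genotypes(raw)


def build_layout(cfg: ScenarioConfig, Zm: genomes.MarkerMatrix, seed: int):
    """Construct the scenario's field layout around the genotyped entries."""
    d = dict(cfg.design)
    kind = d.pop("type", "alpha")
    entry_ids = list(Zm.genotype_ids)
    classes = {}
    if cfg.include_nongenotyped and cfg.n_nongenotyped > 0:
        extra = [f"NG{i + 1:04d}" for i in range(cfg.n_nongenotyped)]
        classes = {e: "non_genotyped" for e in extra}
        entry_ids = entry_ids + extra
    if kind == "alpha":
        return trial_sim.make_alpha_design(
            n_entries=len(entry_ids),
            n_blocks_per_rep=d["n_blocks_per_rep"],
            block_size=d["block_size"],
            n_reps=d["n_reps"],
            seed=seed,
            entry_ids=entry_ids,
        )
    if kind == "lattice":
        return trial_sim.make_multitrial_design(
            n_trials=d["n_trials"],
            lattice_dim=d["lattice_dim"],
            n_reps=d["n_reps"],
            seed=seed,
            entry_ids=entry_ids,
            entry_classes=classes,
        )
    raise ValueError(f"unknown design type {kind!r}")


def _h2_estimate(value: float, breakdown_if_nonpositive: bool = True) -> est.Estimate:
    if not np.isfinite(value):
        return est.Estimate(np.nan, np.nan, est.FLAG_UNDEFINED)
    flag = est.FLAG_OK
    if breakdown_if_nonpositive and value <= 0.0:
        flag = est.FLAG_BREAKDOWN
    return est.Estimate(float(value), float(value), flag)


def run_dataset(
    cfg: ScenarioConfig,
    Zm: genomes.MarkerMatrix,
    layout: trial_sim.TrialLayout,
    dataset_seed: int,
    dataset_index: int = 0,
) -> AccuracyRecord:
    """Simulate one dataset and evaluate all heritability and accuracy methods.

    All failures propagate as flags; the record always comes back.
    """
    rng = np.random.default_rng(dataset_seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)

    effects = trial_sim.simulate_true_effects(
        Zm, layout, cfg.variance_components, cfg.fixed_offsets, seed=int(seeds[0])
    )
    plots = trial_sim.simulate_plot_data(
        effects, layout, cfg.variance_components,
        missing_rate=cfg.missing_yield_rate, seed=int(seeds[1]),
    )
    means = stage1_adjusted_means(plots)
    rr = fit_rrblup_means(means, Zm)
    ind = fit_independent_genotypes(means)

    gi = {g: i for i, g in enumerate(effects.genotype_ids)}
    g_true = effects.g[[gi[e] for e in means.entry_ids]]

    # true accuracy / heritability from the full-data RR-BLUP predictions
    r_true_est = est.true_accuracy(g_true, rr.g_hat)
    r_true = r_true_est.untruncated
    H2_true = r_true**2 if np.isfinite(r_true) else np.nan

    # heritabilities (computed once per dataset, from the full-data fits)
    v_bar = mean_variance_of_difference(means.Omega)
    H2_m1 = _h2_estimate(
        est.h2_standard(ind.sigma_g2_hat, means.sigma_e2_plot, means.n_reps)
    )
    H2_m2 = _h2_estimate(est.h2_blue(ind.sigma_g2_hat, v_bar))
    try:
        H2_m3 = _h2_estimate(est.h2_blup(ind.v_bar_blup, ind.sigma_g2_hat))
    except ZeroDivisionError:
        H2_m3 = est.Estimate(np.nan, np.nan, est.FLAG_BREAKDOWN)
    H2_m4 = _h2_estimate(est.h2_expected_variance(rr.G, rr.R))
    m5 = est.accuracy_m5(rr.G, rr.V)
    H2_m5 = _h2_estimate(
        m5.untruncated**2 if np.isfinite(m5.untruncated) else np.nan
    )

    # cross-validated predictive ability (Methods 1-4 and 6)
    folds = make_folds(means.entry_ids, cfg.cv_k, cfg.cv_reps, seed=int(seeds[2]))
    cvres = cv_predictive_ability(means, Zm, folds, mode=cfg.ability_mode)
    ability = cvres.mean_ability

    m1 = est.indirect_accuracy(ability, H2_m1.untruncated)
    m2 = est.indirect_accuracy(ability, H2_m2.untruncated)
    m3 = est.indirect_accuracy(ability, H2_m3.untruncated)
    m4 = est.indirect_accuracy(ability, H2_m4.untruncated)

    e_sg2 = est.expected_sample_variance(rr.G)
    fold_vals = [
        est.accuracy_m6(row.s_gp, row.s_g2hat, e_sg2).untruncated
        for row in cvres.table.itertuples()
        if row.converged and np.isfinite(row.s_gp)
    ]
    fold_vals = [v for v in fold_vals if np.isfinite(v)]
    if fold_vals and e_sg2 > 0:
        m6 = est._estimate(float(np.mean(fold_vals)))
    else:
        m6 = est.Estimate(np.nan, np.nan, est.FLAG_BREAKDOWN)

    m7 = est.accuracy_m7(rr)

    converged = means.converged and rr.converged
    excluded, reason = False, ""
    if not converged:
        excluded, reason = True, "nonconverged"
    elif not np.isfinite(r_true):
        excluded, reason = True, "true_accuracy_undefined"
    elif r_true < 0.0:
        excluded, reason = True, "negative_true_accuracy"

    return AccuracyRecord(
        dataset=dataset_index,
        seed=int(dataset_seed),
        r_true=r_true,
        H2_true=H2_true,
        heritability=est.HeritabilitySet(H2_m1, H2_m2, H2_m3, H2_m4, H2_m5, H2_true),
        accuracy=est.AccuracySet(r_true, m1, m2, m3, m4, m5, m6, m7),
        ability=ability,
        cv_nonconverged=cvres.n_nonconverged,
        converged=converged,
        excluded=excluded,
        exclusion_reason=reason,
    )


def run_scenario(
    cfg: ScenarioConfig,
    n_datasets: int | None = None,
    seed: int | None = None,
    progress: bool = False,
):
    """Run a whole scenario; returns (records DataFrame, summary dict).

    One marker matrix and one layout are generated per scenario and shared
    across its datasets unless ``marker_mode='per-dataset'``.
    """
    n = int(n_datasets if n_datasets is not None else cfg.n_datasets)
    master = int(seed if seed is not None else cfg.seed)
    rng = np.random.default_rng(master)
    marker_seed, layout_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    dataset_seeds = rng.integers(0, 2**31 - 1, size=n)

    Zm = build_markers(cfg, marker_seed)
    layout = build_layout(cfg, Zm, layout_seed)

    rows = []
    for j in range(n):
        if cfg.marker_mode == "per-dataset":
            Zm = build_markers(cfg, int(dataset_seeds[j]) ^ marker_seed)
            layout = build_layout(cfg, Zm, layout_seed)
        rec = run_dataset(cfg, Zm, layout, int(dataset_seeds[j]), dataset_index=j)
        rows.append(rec.as_row())
        if progress and (j + 1) % 25 == 0:
            print(f"[{cfg.name}] dataset {j + 1}/{n}", flush=True)
    records = pd.DataFrame(rows)
    return records, summarize(records)


# ---------------------------------------------------------------------------
# summaries


def _complete_cases(records: pd.DataFrame) -> pd.DataFrame:
    """Shared-N convention: kept datasets where every method has a value."""
    keep = ~records["excluded"]
    for m in METHODS:
        keep &= np.isfinite(records[m])
    keep &= np.isfinite(records["r_true"])
    return records[keep]


def summarize(records: pd.DataFrame) -> dict:
    """Descriptive statistics, MSD, event counts, pairwise correlations.

    Statistics are computed over the common complete-case set (datasets
    where all methods delivered a value), mirroring the shared-N reporting
    convention; truncated estimates are compared against the untruncated
    true accuracy.
    """
    import warnings

    cc = _complete_cases(records)
    n_excluded = int(records["excluded"].sum())
    out: dict = {"n_datasets": len(records), "n_excluded": n_excluded}

    def stat_row(name, vals, truths):
        q1, med, q3 = (
            np.percentile(vals, [25, 50, 75]) if len(vals) else (np.nan,) * 3
        )
        return {
            "method": name,
            "N": len(vals),
            "MIN": np.min(vals) if len(vals) else np.nan,
            "MEAN": np.mean(vals) if len(vals) else np.nan,
            "MAX": np.max(vals) if len(vals) else np.nan,
            "STD": np.std(vals, ddof=1) if len(vals) > 1 else np.nan,
            "MSD": msd(vals, truths) if len(vals) else np.nan,
            "Q1": q1,
            "MEDIAN": med,
            "Q3": q3,
        }

    if len(cc) == 0:
        warnings.warn("all datasets excluded; summary tables are empty", stacklevel=2)
        out["accuracy"] = pd.DataFrame()
        out["heritability"] = pd.DataFrame()
        out["pairwise"] = pd.DataFrame()
        out["events"] = pd.DataFrame()
        out["ttests"] = pd.DataFrame()
        return out

    truths = cc["r_true"].to_numpy()
    acc_rows = [stat_row("M0", truths, truths)]
    for m in METHODS:
        acc_rows.append(stat_row(m.upper(), cc[m].to_numpy(), truths))
    out["accuracy"] = pd.DataFrame(acc_rows)

    h_ok = cc[np.isfinite(cc[[f"H2_m{i}" for i in range(1, 6)]]).all(axis=1)]
    h_truths = h_ok["H2_true"].to_numpy()
    h_rows = [stat_row("H2_true", h_truths, h_truths)]
    for i in range(1, 6):
        h_rows.append(stat_row(f"H2_M{i}", h_ok[f"H2_m{i}"].to_numpy(), h_truths))
    out["heritability"] = pd.DataFrame(h_rows)

    corr = cc[METHODS].corr().round(6)
    corr.index = corr.columns = [m.upper() for m in METHODS]
    out["pairwise"] = corr

    ev_rows = []
    for m in METHODS:
        flags = records[f"{m}_flag"]
        ev_rows.append(
            {
                "method": m.upper(),
                "overshoot": int((flags == est.FLAG_OVERSHOOT).sum()),
                "undershoot": int((flags == est.FLAG_UNDERSHOOT).sum()),
                "breakdown_H_zero": int((flags == est.FLAG_BREAKDOWN).sum()),
                "nonconverged": int((flags == est.FLAG_NONCONVERGED).sum()),
            }
        )
    out["events"] = pd.DataFrame(ev_rows)

    # paired two-sided t-tests of each method against truth, Bonferroni over
    # the seven methods (a simplification of fancier multiplicity schemes)
    tt = []
    for m in METHODS:
        d = cc[m].to_numpy() - truths
        if len(d) > 2 and np.std(d, ddof=1) > 0:
            t, pval = sps.ttest_rel(cc[m].to_numpy(), truths)
        else:
            t, pval = np.nan, np.nan
        tt.append(
            {
                "method": m.upper(),
                "mean_bias": float(np.mean(d)),
                "t": t,
                "p": pval,
                "p_bonferroni": min(1.0, pval * len(METHODS)) if np.isfinite(pval) else np.nan,
            }
        )
    out["ttests"] = pd.DataFrame(tt)
    return out


def write_outputs(records: pd.DataFrame, summary: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "records.csv", index=False)
    for key in ("accuracy", "heritability", "events", "ttests"):
        df = summary.get(key)
        if df is not None and len(df):
            df.to_csv(out / (f"summary.csv" if key == "accuracy" else f"{key}.csv"),
                      index=False)
    pw = summary.get("pairwise")
    if pw is not None and len(pw):
        pw.to_csv(out / "pairwise_corr.csv")
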