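"""Field-trial layouts and phenotype simulation.

Supports two geometries: a single-location resolvable alpha design (complete
replicates, incomplete blocks nested within replicates) and a multi-trial
lattice-square layout (each trial a s x s lattice; rows form the blocks of
one replicate, columns those of the next).  Plot yields are simulated as

    y = phi + fixed offsets + trial + trial.rep + block + entry effect + e

with all random terms iid normal with their named variance components and
true breeding values g = Zu for genotyped entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomes import MarkerMatrix

__all__ = [
    "TrialLayout",
    "VarianceComponents",
    "TrueEffects",
    "PlotData",
    "make_alpha_design",
    "make_multitrial_design",
    "simulate_true_effects",
    "simulate_plot_data",
    "read_plot_csv",
    "write_plot_csv",
]

LAYOUT_COLUMNS = [
    "plot_id",
    "trial",
    "replicate",
    "block",
    "entry_id",
    "entry_class",
    "group_label",
    "tester_label",
]

ENTRY_CLASSES = ("genotyped", "non_genotyped", "check")


@dataclass
class TrialLayout:
    """Plot-level field-design records."""

    plots: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.plots.copy()
        for col in LAYOUT_COLUMNS:
            if col not in df.columns:
                if col in ("group_label", "tester_label"):
                    df[col] = ""
                else:
                    raise ValueError(f"layout missing column {col!r}")
        self.plots = df[LAYOUT_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.plots
        if df["plot_id"].duplicated().any():
            raise ValueError("duplicate plot_ids")
        bad = set(df["entry_class"]) - set(ENTRY_CLASSES)
        if bad:
            raise ValueError(f"unknown entry classes: {sorted(bad)}")
        noncheck = df[df["entry_class"] != "check"]
        counts = noncheck.groupby(["trial", "replicate"])["entry_id"].value_counts()
        if (counts != 1).any():
            raise ValueError("a non-check entry appears more than once in a replicate")

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    def entries(self, entry_class: str | None = "genotyped") -> list[str]:
        df = self.plots
        if entry_class is not None:
            df = df[df["entry_class"] == entry_class]
        return sorted(df["entry_id"].unique())

    def n_reps(self) -> int:
        """Replicates per trial (maximum over trials)."""
        return int(self.plots.groupby("trial")["replicate"].nunique().max())

    def block_sizes(self) -> pd.Series:
        return self.plots.groupby(["trial", "replicate", "block"]).size()


@dataclass
class VarianceComponents:
    """Named variance components of the simulation / analysis model.

    Units are squared yield units.  ``marker`` is the per-marker effect
    variance (sigma_u2) of the RR-BLUP model; ``genotype`` is the
    independent-genotype variance (sigma_g2) used by the uncorrelated
    alternative; ``nongeno`` is the variance of non-genotyped-line effects.
    """

    marker: float = 0.0
    block: float = 0.0
    residual: float = 1.0
    trial: float | None = None
    trial_rep: float | None = None
    nongeno: float | None = None
    genotype: float | None = None

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v is not None and (not np.isfinite(v) or v < 0.0):
                raise ValueError(f"variance component {name!r} must be finite and >= 0")
        if self.residual is None or self.residual < 0.0:
            raise ValueError("residual variance must be present and >= 0")

    def as_dict(self) -> dict[str, float | None]:
        return {
            "marker": self.marker,
            "block": self.block,
            "residual": self.residual,
            "trial": self.trial,
            "trial_rep": self.trial_rep,
            "nongeno": self.nongeno,
            "genotype": self.genotype,
        }

    def require(self, name: str) -> float:
        v = getattr(self, name)
        if v is None:
            raise ValueError(f"layout requires variance component {name!r}")
        return float(v)


@dataclass
class TrueEffects:
    """Simulated true effects behind one dataset."""

    u: np.ndarray                      # p marker effects
    g: np.ndarray                      # n breeding values, g = Z u
    genotype_ids: list[str]            # aligned with g
    block_effects: dict                # (trial, replicate, block) -> effect
    trial_effects: dict                # trial -> effect
    trial_rep_effects: dict            # (trial, replicate) -> effect
    nongeno_effects: dict              # entry_id -> effect
    check_values: dict                 # entry_id -> fixed value
    phi: float
    rep_offsets: dict                  # (trial, replicate) -> fixed offset
    group_offsets: dict                # group_label -> fixed offset
    tester_offsets: dict               # tester_label -> fixed offset
    seed: int | None

    def entry_effect(self, entry_id: str, entry_class: str) -> float:
        if entry_class == "genotyped":
            return float(self.g[self._index[entry_id]])
        if entry_class == "non_genotyped":
            return float(self.nongeno_effects[entry_id])
        return float(self.check_values.get(entry_id, 0.0))

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genotype_ids)}


@dataclass
class PlotData:
    """A trial layout plus one simulated (or observed) yield per plot."""

    plots: pd.DataFrame

    def __post_init__(self) -> None:
        if "yield" not in self.plots.columns:
            raise ValueError("plot data requires a 'yield' column")
        layout_cols = self.plots[LAYOUT_COLUMNS]
        TrialLayout(layout_cols)  # reuse layout validation
        if self.plots["yield"].isna().all():
            raise ValueError("every yield is missing")
        self.plots = self.plots.reset_index(drop=True)

    @property
    def layout(self) -> TrialLayout:
        return TrialLayout(self.plots[LAYOUT_COLUMNS])


def _check_ids_for(n_checks: int) -> list[str]:
    return [f"CHK{i + 1:02d}" for i in range(n_checks)]


def make_alpha_design(
    n_entries: int,
    n_blocks_per_rep: int,
    block_size: int,
    n_reps: int,
    n_checks: int | None = None,
    seed: int | None = None,
    entry_ids: Sequence[str] | None = None,
    trial: str = "T1",
) -> TrialLayout:
    """Resolvable alpha design by cyclic-shift construction.

    Capacity per replicate is ``n_blocks_per_rep * block_size``; surplus
    plots beyond ``n_entries`` are filled with check entries (standard
    varieties), which may repeat.  Writing slot m = x + b*y with
    b = n_blocks_per_rep, replicate k assigns slot m to block (x + k*y) mod
    b, so each replicate is complete and block assignment rotates between
    replicates.  Block order and within-block plot order are randomized.
    """
    if n_entries < 1 or n_blocks_per_rep < 1 or block_size < 1 or n_reps < 1:
        raise ValueError("design dimensions must be positive")
    capacity = n_blocks_per_rep * block_size
    if capacity < n_entries:
        raise ValueError(
            f"capacity {capacity} (= {n_blocks_per_rep} blocks x {block_size}) "
            f"is less than {n_entries} entries"
        )
    fill = capacity - n_entries
    if n_checks is None:
        n_checks = fill
    if fill > 0 and n_checks < 1:
        raise ValueError("surplus plots exist but n_checks = 0")

    if entry_ids is None:
        entry_ids = [f"G{i + 1:04d}" for i in range(n_entries)]
    elif len(entry_ids) != n_entries:
        raise ValueError("entry_ids length must equal n_entries")
    check_ids = _check_ids_for(n_checks) if fill > 0 else []
    # slot -> (entry, class); check slots cycle through the check varieties
    slot_entries = list(entry_ids) + [check_ids[i % n_checks] for i in range(fill)]
    slot_classes = ["genotyped"] * n_entries + ["check"] * fill

    rng = np.random.default_rng(seed)
    perm = rng.permutation(capacity)  # random entry-to-slot assignment
    slot_entries = [slot_entries[perm[m]] for m in range(capacity)]
    slot_classes = [slot_classes[perm[m]] for m in range(capacity)]

    rows = []
    plot = 1
    b = n_blocks_per_rep
    for k in range(n_reps):
        block_of_slot = np.empty(capacity, dtype=int)
        for m in range(capacity):
            x, y = m % b, m // b
            block_of_slot[m] = (x + k * y) % b
        block_relabel = rng.permutation(b)
        for blk in range(b):
            members = [m for m in range(capacity) if block_of_slot[m] == blk]
            rng.shuffle(members)
            for slot in members:
                rows.append(
                    {
                        "plot_id": f"{trial}_P{plot:05d}",
                        "trial": trial,
                        "replicate": f"R{k + 1}",
                        "block": f"B{block_relabel[blk] + 1:02d}",
                        "entry_id": slot_entries[slot],
                        "entry_class": slot_classes[slot],
                        "group_label": "",
                        "tester_label": "",
                    }
                )
                plot += 1
    return TrialLayout(pd.DataFrame(rows))


def make_multitrial_design(
    n_trials: int,
    lattice_dim: int,
    n_reps: int,
    seed: int | None = None,
    entry_ids: Sequence[str] | None = None,
    entry_classes: Mapping[str, str] | None = None,
) -> TrialLayout:
    """Concatenated lattice-square trials (s x s entries each).

    Entries are split over trials disjointly, ``lattice_dim**2`` per trial.
    Within a trial the entries are arranged on an s x s grid; odd replicates
    use the grid rows as incomplete blocks and even replicates the columns,
    so every block has exactly ``lattice_dim`` plots and each replicate is
    complete.  If fewer entries than ``n_trials * lattice_dim**2`` are given,
    the shortfall is filled with check plots in the last trial(s).
    """
    if n_trials < 1 or lattice_dim < 1 or n_reps < 1:
        raise ValueError("design dimensions must be positive")
    s = lattice_dim
    per_trial = s * s
    total = n_trials * per_trial
    if entry_ids is None:
        entry_ids = [f"G{i + 1:04d}" for i in range(total)]
    if len(entry_ids) > total:
        raise ValueError(f"{len(entry_ids)} entries exceed capacity {total}")
    fill = total - len(entry_ids)
    check_ids = _check_ids_for(max(1, min(fill, 6))) if fill else []
    all_entries = list(entry_ids) + [check_ids[i % len(check_ids)] for i in range(fill)]
    classes = {e: "genotyped" for e in entry_ids}
    if entry_classes:
        classes.update({str(k): v for k, v in entry_classes.items()})
    for c in check_ids:
        classes[c] = "check"

    rng = np.random.default_rng(seed)
    order = rng.permutation(total)
    rows = []
    plot = 1
    for t in range(n_trials):
        trial = f"T{t + 1}"
        trial_slots = [all_entries[order[t * per_trial + i]] for i in range(per_trial)]
        grid = np.array(trial_slots, dtype=object).reshape(s, s)
        for k in range(n_reps):
            by_rows = k % 2 == 0
            for blk in range(s):
                members = list(grid[blk, :] if by_rows else grid[:, blk])
                rng.shuffle(members)
                for e in members:
                    rows.append(
                        {
                            "plot_id": f"T{t + 1}_P{plot:05d}",
                            "trial": trial,
                            "replicate": f"R{k + 1}",
                            "block": f"{'B' if by_rows else 'C'}{blk + 1:02d}",
                            "entry_id": e,
                            "entry_class": classes[e],
                            "group_label": "",
                            "tester_label": "",
                        }
                    )
                    plot += 1
    return TrialLayout(pd.DataFrame(rows))


def simulate_true_effects(
    Zm: MarkerMatrix,
    layout: TrialLayout,
    vc: VarianceComponents,
    fixed_offsets: Mapping | None = None,
    seed: int | None = None,
) -> TrueEffects:
    """Draw all true effects for one dataset.

    Marker effects u ~ N(0, sigma_u2 I_p) give breeding values g = Z u
    exactly.  Block (and, for multi-trial layouts, trial and
    trial x replicate) effects are iid normal with their components;
    non-genotyped entries get iid N(0, sigma_g2_2) effects; check entries
    take configurable fixed values (default 0).
    """
    rng = np.random.default_rng(seed)
    fixed_offsets = dict(fixed_offsets or {})

    u = rng.normal(0.0, np.sqrt(vc.require("marker")), size=Zm.p)
    g = Zm.Z @ u

    df = layout.plots
    missing = set(df.loc[df["entry_class"] == "genotyped", "entry_id"]) - set(
        Zm.genotype_ids
    )
    if missing:
        raise ValueError(f"genotyped entries absent from marker matrix: {sorted(missing)[:5]}")

    blocks = sorted(
        df.groupby(["trial", "replicate", "block"]).groups.keys()
    )
    sd_b = np.sqrt(vc.require("block"))
    block_effects = {key: rng.normal(0.0, sd_b) for key in blocks}

    trials = sorted(df["trial"].unique())
    trial_effects, trial_rep_effects = {}, {}
    if len(trials) > 1:
        sd_t = np.sqrt(vc.require("trial"))
        sd_r = np.sqrt(vc.require("trial_rep"))
        trial_effects = {t: rng.normal(0.0, sd_t) for t in trials}
        trial_rep_effects = {
            key: rng.normal(0.0, sd_r)
            for key in sorted(df.groupby(["trial", "replicate"]).groups.keys())
        }

    nongeno = sorted(df.loc[df["entry_class"] == "non_genotyped", "entry_id"].unique())
    nongeno_effects = {}
    if nongeno:
        sd_g2 = np.sqrt(vc.require("nongeno"))
        nongeno_effects = {e: rng.normal(0.0, sd_g2) for e in nongeno}

    checks = sorted(df.loc[df["entry_class"] == "check", "entry_id"].unique())
    check_values = dict(fixed_offsets.get("checks", {}))
    for c in checks:
        check_values.setdefault(c, 0.0)

    return TrueEffects(
        u=u,
        g=g,
        genotype_ids=list(Zm.genotype_ids),
        block_effects=block_effects,
        trial_effects=trial_effects,
        trial_rep_effects=trial_rep_effects,
        nongeno_effects=nongeno_effects,
        check_values=check_values,
        phi=float(fixed_offsets.get("phi", 0.0)),
        rep_offsets=dict(fixed_offsets.get("replicates", {})),
        group_offsets=dict(fixed_offsets.get("groups", {})),
        tester_offsets=dict(fixed_offsets.get("testers", {})),
        seed=seed,
    )


def simulate_plot_data(
    effects: TrueEffects,
    layout: TrialLayout,
    vc: VarianceComponents,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> PlotData:
    """Assemble plot yields from the true effects plus iid residual error.

    Missing yields are introduced completely at random at ``missing_rate``.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    df = layout.plots.copy()
    n = len(df)

    y = np.full(n, effects.phi)
    rep_keys = list(zip(df["trial"], df["replicate"]))
    y += np.array([effects.rep_offsets.get(k, 0.0) for k in rep_keys])
    y += np.array([effects.group_offsets.get(gl, 0.0) for gl in df["group_label"]])
    y += np.array([effects.tester_offsets.get(tl, 0.0) for tl in df["tester_label"]])
    y += np.array([effects.trial_effects.get(t, 0.0) for t in df["trial"]])
    y += np.array([effects.trial_rep_effects.get(k, 0.0) for k in rep_keys])
    blk_keys = list(zip(df["trial"], df["replicate"], df["block"]))
    y += np.array([effects.block_effects[k] for k in blk_keys])
    y += np.array(
        [
            effects.entry_effect(e, c)
            for e, c in zip(df["entry_id"], df["entry_class"])
        ]
    )
    y += rng.normal(0.0, np.sqrt(vc.require("residual")), size=n)

    if missing_rate > 0.0:
        y = np.where(rng.random(n) < missing_rate, np.nan, y)
    df["yield"] = y
    return PlotData(df)


def write_plot_csv(data: PlotData | TrialLayout, path) -> None:
    df = data.plots.copy()
    df.to_csv(path, index=False)


def read_plot_csv(path) -> PlotData | TrialLayout:
    df = pd.read_csv(path, keep_default_na=True)
    for col in ("group_label", "tester_label"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    if "yield" in df.columns:
        return PlotData(df)
    return TrialLayout(df)
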