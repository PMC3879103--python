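"""Synthetic doubled-haploid SNP marker data: generation, coding and QC.

Doubled-haploid (DH) lines are fully homozygous, so an ideal biallelic SNP
call is either ``AA`` or ``BB``; heterozygous (``AB``) and missing (``NA``)
calls occur only as genotyping artefacts.  Calls are coded numerically as
+1 (``AA``), -1 (``BB``) and 0 (``AB`` or ``NA``), giving the marker
covariate matrix Z whose cross-product ZZ' scaled by the marker-effect
variance is the genomic covariance of breeding values g = Zu.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawCalls",
    "MarkerMatrix",
    "generate_dh_markers",
    "code_genotypes",
    "qc_filter",
    "genomic_covariance",
    "read_calls_tsv",
    "write_calls_tsv",
    "read_marker_tsv",
    "write_marker_tsv",
    "read_vcf_calls",
]

#: canonical raw-call tokens (AA = A1A1, BB = A2A2, AB = heterozygous)
CALL_TOKENS = ("AA", "AB", "BB", "NA")

#: numeric codes for each raw-call token
CALL_CODES = {"AA": 1.0, "AB": 0.0, "BB": -1.0, "NA": 0.0}


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class RawCalls:
    """Raw biallelic SNP calls for n genotypes x p markers.

    ``calls`` holds the string tokens ``AA``/``AB``/``BB``/``NA``.
    """

    genotype_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.genotype_ids = _check_ids(self.genotype_ids, "genotype")
        self.marker_ids = _check_ids(self.marker_ids, "marker")
        self.calls = np.asarray(self.calls, dtype="U2")
        n, p = len(self.genotype_ids), len(self.marker_ids)
        if self.calls.shape != (n, p):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} genotypes x {p} markers"
            )
        bad = set(np.unique(self.calls)) - set(CALL_TOKENS)
        if bad:
            raise ValueError(f"unknown call symbols: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.genotype_ids)

    @property
    def p(self) -> int:
        return len(self.marker_ids)

    def marker_stats(self) -> pd.DataFrame:
        """Per-marker missing fraction, heterozygous fraction and MAF.

        MAF is computed on non-missing calls only; a heterozygote
        contributes one copy of each allele.
        """
        n = self.n
        n_aa = (self.calls == "AA").sum(axis=0)
        n_ab = (self.calls == "AB").sum(axis=0)
        n_bb = (self.calls == "BB").sum(axis=0)
        n_na = (self.calls == "NA").sum(axis=0)
        n_obs = n - n_na
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_a1 = np.where(n_obs > 0, (2.0 * n_aa + n_ab) / (2.0 * n_obs), np.nan)
        maf = np.minimum(freq_a1, 1.0 - freq_a1)
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "n_obs": n_obs,
                "missing_frac": n_na / n,
                "het_frac": np.where(n_obs > 0, n_ab / n_obs, np.nan),
                "freq_a1": freq_a1,
                "maf": maf,
            }
        )


@dataclass
class MarkerMatrix:
    """Coded SNP covariates Z (entries in {-1, 0, +1})."""

    genotype_ids: list[str]
    marker_ids: list[str]
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.genotype_ids = _check_ids(self.genotype_ids, "genotype")
        self.marker_ids = _check_ids(self.marker_ids, "marker")
        self.Z = np.asarray(self.Z, dtype=float)
        n, p = len(self.genotype_ids), len(self.marker_ids)
        if self.Z.shape != (n, p):
            raise ValueError(
                f"Z shape {self.Z.shape} does not match {n} genotypes x {p} markers"
            )
        if not np.isin(self.Z, (-1.0, 0.0, 1.0)).all():
            raise ValueError("coded marker entries must be in {-1, 0, +1}")

    @property
    def n(self) -> int:
        return len(self.genotype_ids)

    @property
    def p(self) -> int:
        return len(self.marker_ids)

    def subset(self, genotype_ids: Sequence[str]) -> "MarkerMatrix":
        """Row-subset (and reorder) by genotype id."""
        index = {g: i for i, g in enumerate(self.genotype_ids)}
        try:
            rows = [index[str(g)] for g in genotype_ids]
        except KeyError as err:
            raise KeyError(f"genotype {err} not in marker matrix") from err
        return MarkerMatrix(list(genotype_ids), list(self.marker_ids), self.Z[rows])


def _maf_sampler(
    maf_spectrum: float | tuple | Callable[[np.random.Generator, int], np.ndarray],
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Normalize a MAF-spectrum spec into a callable rng, p -> frequencies."""
    if callable(maf_spectrum):
        return maf_spectrum
    if np.isscalar(maf_spectrum):
        f = float(maf_spectrum)
        if not 0.0 < f < 1.0:
            raise ValueError("fixed allele frequency must be in (0, 1)")
        return lambda rng, p: np.full(p, f)
    kind, *args = maf_spectrum
    if kind == "uniform":
        lo, hi = (args + [0.05, 0.5][len(args):]) if args else (0.05, 0.5)
        lo, hi = float(lo), float(hi)
        return lambda rng, p: rng.uniform(lo, hi, size=p)
    raise ValueError(f"unknown maf_spectrum spec: {maf_spectrum!r}")


def generate_dh_markers(
    n: int,
    p: int,
    maf_spectrum=("uniform", 0.05, 0.5),
    missing_rate: float = 0.0,
    het_rate: float = 0.0,
    seed: int | None = None,
    ld_blocks: int | None = None,
    ld_within: float = 0.0,
) -> RawCalls:
    """Simulate raw SNP calls for a doubled-haploid population.

    Each marker's A1 allele frequency is drawn from ``maf_spectrum`` (default
    uniform on [0.05, 0.5], the intermediate-frequency regime of biparental
    DH populations).  Each call is independently ``AA`` with that frequency
    and ``BB`` otherwise (DH lines are homozygous), then overwritten as
    heterozygous with probability ``het_rate`` and as missing with
    probability ``missing_rate``, emulating genotyping artefacts.

    Markers are unlinked by default.  The optional block-correlation mode
    (``ld_blocks`` blocks; within a block each genotype copies the block's
    founder call with probability ``ld_within``) gives a crude LD structure;
    it is off by default because the estimators consume Z only through ZZ'.
    """
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 genotypes and p >= 1 markers")
    for name, rate in (("missing_rate", missing_rate), ("het_rate", het_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    if missing_rate + het_rate >= 1.0:
        raise ValueError("missing_rate + het_rate must be < 1")

    rng = np.random.default_rng(seed)
    freqs = np.asarray(_maf_sampler(maf_spectrum)(rng, p), dtype=float)
    if freqs.shape != (p,):
        raise ValueError("maf_spectrum callable must return p frequencies")

    is_a1 = rng.random((n, p)) < freqs
    if ld_blocks:
        block = np.minimum(np.arange(p) * ld_blocks // p, ld_blocks - 1)
        founder = is_a1[:, np.searchsorted(block, np.unique(block))]
        copy = rng.random((n, p)) < ld_within
        is_a1 = np.where(copy, founder[:, block], is_a1)
    calls = np.where(is_a1, "AA", "BB").astype("U2")
    if het_rate > 0.0:
        calls[rng.random((n, p)) < het_rate] = "AB"
    if missing_rate > 0.0:
        calls[rng.random((n, p)) < missing_rate] = "NA"

    genotype_ids = [f"G{i + 1:04d}" for i in range(n)]
    marker_ids = [f"M{k + 1:05d}" for k in range(p)]
    return RawCalls(genotype_ids, marker_ids, calls)


def code_genotypes(raw: RawCalls) -> MarkerMatrix:
    """Code raw calls numerically: AA -> +1, BB -> -1, AB/NA -> 0."""
    Z = np.zeros(raw.calls.shape, dtype=float)
    Z[raw.calls == "AA"] = 1.0
    Z[raw.calls == "BB"] = -1.0
    return MarkerMatrix(list(raw.genotype_ids), list(raw.marker_ids), Z)


def qc_filter(
    raw: RawCalls,
    max_missing: float = 0.20,
    max_het: float = 0.05,
    min_maf: float = 0.025,
) -> tuple[RawCalls, pd.DataFrame]:
    """Discard markers failing any of three quality rules.

    A marker is removed when its missing fraction exceeds ``max_missing``,
    its heterozygous fraction exceeds ``max_het``, or its minor-allele
    frequency is strictly below ``min_maf`` (all inequalities strict, so a
    marker sitting exactly on a threshold is retained).  Genotypes are never
    removed.  Returns the surviving-marker subset together with a per-marker
    log recording the statistics and removal reasons.
    """
    import warnings

    for name, t in (("max_missing", max_missing), ("max_het", max_het), ("min_maf", min_maf)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    stats = raw.marker_stats()
    rm_missing = stats["missing_frac"].to_numpy() > max_missing
    het = stats["het_frac"].to_numpy()
    rm_het = np.where(np.isnan(het), False, het > max_het)
    maf = stats["maf"].to_numpy()
    rm_maf = np.where(np.isnan(maf), True, maf < min_maf)  # all-missing removed

    reasons = []
    for miss, h, m in zip(rm_missing, rm_het, rm_maf):
        r = [tag for tag, hit in (("missing", miss), ("het", h), ("maf", m)) if hit]
        reasons.append(";".join(r))
    log = stats.assign(removed=rm_missing | rm_het | rm_maf, reason=reasons)

    keep = ~log["removed"].to_numpy()
    if not keep.any():
        warnings.warn("qc_filter removed every marker", stacklevel=2)
    kept_ids = [m for m, k in zip(raw.marker_ids, keep) if k]
    out = RawCalls(list(raw.genotype_ids), kept_ids, raw.calls[:, keep])
    return out, log


def genomic_covariance(Zm: MarkerMatrix, sigma_u2: float) -> np.ndarray:
    """Genomic covariance G = ZZ' * sigma_u2 of the breeding values g = Zu."""
    if sigma_u2 < 0.0:
        raise ValueError("sigma_u2 must be non-negative")
    G = Zm.Z @ Zm.Z.T * float(sigma_u2)
    return (G + G.T) / 2.0  # enforce exact symmetry


# ---------------------------------------------------------------------------
# external interfaces: tab-separated marker files (lossless round trip)

def write_calls_tsv(raw: RawCalls, path) -> None:
    df = pd.DataFrame(raw.calls, columns=raw.marker_ids)
    df.insert(0, "genotype_id", raw.genotype_ids)
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> RawCalls:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    ids = df["genotype_id"].tolist()
    markers = [c for c in df.columns if c != "genotype_id"]
    return RawCalls(ids, markers, df[markers].to_numpy(dtype="U2"))


def write_marker_tsv(Zm: MarkerMatrix, path) -> None:
    df = pd.DataFrame(Zm.Z.astype(int), columns=Zm.marker_ids)
    df.insert(0, "genotype_id", Zm.genotype_ids)
    df.to_csv(path, sep="\t", index=False)


def read_marker_tsv(path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t")
    ids = df["genotype_id"].astype(str).tolist()
    markers = [c for c in df.columns if c != "genotype_id"]
    return MarkerMatrix(ids, markers, df[markers].to_numpy(dtype=float))


def read_vcf_calls(path) -> RawCalls:
    """Minimal VCF import (GT field only) into the raw-call layer.

    Homozygous-ref -> AA, homozygous-alt -> BB, het -> AB, missing -> NA.
    Requires :mod:`pysam`; intended for small, uncompressed, biallelic VCFs.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        marker_ids, cols = [], []
        for rec in vf.fetch() if vf.index is not None else vf:
            marker_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            col = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                alleles = [a for a in (gt or ()) if a is not None]
                if not alleles:
                    col.append("NA")
                elif all(a == 0 for a in alleles):
                    col.append("AA")
                elif all(a > 0 for a in alleles):
                    col.append("BB")
                else:
                    col.append("AB")
            cols.append(col)
    calls = np.array(cols, dtype="U2").T if cols else np.empty((len(samples), 0), "U2")
    return RawCalls(samples, marker_ids, calls)
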