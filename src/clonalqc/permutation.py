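"""Permutation-based selection of cohort-specific filter thresholds.

The idea: a good threshold produces CH call sets that are stable under
subsampling of the cohort.  For one scanned parameter (VAF lower bound,
cohort prevalence cutoff, DP, SOR upper bound, or the joint SAF/SAR lower
bound) and each candidate grid value, the cohort is repeatedly partitioned
into k disjoint subsets (k = 1/proportion), the full filter pipeline is run
independently inside every subset (so cohort prevalence is recomputed per
subset), subset calls are pooled, and consistency — the fraction of
full-cohort calls recovered in the pooled subset calls — is averaged over
permutations.  The smallest grid value at which the consistency curve
saturates (the inflection) is the suggested cohort-specific cutoff.

Two engines produce identical results: a vectorised one (the default; one
boolean matrix per partition) and a literal per-subset engine that reruns
:func:`~clonalqc.filters.run_chipfilter` on every subset, kept as the
reference implementation.  The same partitions are reused across grid
values (common random numbers) so curves differ only through the scanned
parameter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import CohortTable
from .errors import ConfigError, InputError
from . import filters
from .filters import FilterConfig, MODE_PAIRED

CallSet = set[tuple[str, tuple[str, int, str, str]]]

METRIC_VAF = "VAF"
METRIC_PREVALENCE = "PREVALENCE"
METRIC_DP = "DP"
METRIC_SOR = "SOR"
METRIC_SAFSAR = "SAFSAR"
METRICS = [METRIC_VAF, METRIC_PREVALENCE, METRIC_DP, METRIC_SOR, METRIC_SAFSAR]
_METRIC_CODE = {m: i for i, m in enumerate(METRICS)}

#: Scanned reason codes per metric (excluded from the fixed flag set).
_SCANNED_REASONS = {
    METRIC_VAF: [filters.VAF_LOW],
    METRIC_PREVALENCE: [],
    METRIC_DP: [filters.DP],
    METRIC_SOR: [filters.SOR],
    METRIC_SAFSAR: [filters.SAF, filters.SAR],
}


def default_grid(metric: str) -> list[float]:
    if metric == METRIC_VAF:
        return [round(0.005 * i, 3) for i in range(21)]          # 0 .. 0.1
    if metric == METRIC_PREVALENCE:
        return [round(0.01 * i, 2) for i in range(16)]           # 0 .. 0.15
    if metric == METRIC_DP:
        return [5.0 * i for i in range(11)]                      # 0 .. 50
    if metric == METRIC_SOR:
        return [0.5 * i for i in range(1, 13)]                   # 0.5 .. 6
    if metric == METRIC_SAFSAR:
        return [float(i) for i in range(11)]                     # 0 .. 10
    raise ConfigError(f"unknown metric {metric!r}; expected one of {METRICS}")


def config_for(metric: str, base: FilterConfig, value: float) -> FilterConfig:
    """Base config with the scanned parameter set to ``value``."""
    if metric == METRIC_VAF:
        return base.replace(vaf_min=value)
    if metric == METRIC_PREVALENCE:
        return base.replace(prevalence_max=value)
    if metric == METRIC_DP:
        return base.replace(dp_min=value)
    if metric == METRIC_SOR:
        return base.replace(sor_max=value)
    if metric == METRIC_SAFSAR:
        v = int(value)
        return base.replace(saf_min=v, sar_min=v)
    raise ConfigError(f"unknown metric {metric!r}")


@dataclass
class PermutationPlan:
    """What to scan and how hard to permute."""

    metric_name: str = METRIC_VAF
    grid: list[float] | None = None
    proportions: list[float] = field(
        default_factory=lambda: [1.0 / k for k in range(2, 11)])
    n_perm: int = 100
    seed: int = 0
    single_subset: bool = False  # alternative semantics: one subset per perm

    def __post_init__(self) -> None:
        if self.metric_name not in METRICS:
            raise ConfigError(
                f"metric must be one of {METRICS}, got {self.metric_name!r}")
        if self.grid is None:
            self.grid = default_grid(self.metric_name)
        g = np.asarray(self.grid, dtype=float)
        if len(g) == 0 or np.any(np.diff(g) <= 0):
            raise ConfigError("grid must be non-empty and strictly increasing")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        for p in self.proportions:
            if not (0.0 < p <= 1.0):
                raise ConfigError(f"proportions must be in (0, 1], got {p}")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")


@dataclass
class ConsistencyStats:
    """Overlap between full-cohort and pooled subset call sets."""

    common_fraction: float
    unique_full_fraction: float
    unique_pooled_fraction: float


def consistency(full_calls: CallSet, pooled_calls: CallSet) -> ConsistencyStats:
    """Set-level consistency; empty denominators follow the (1, 0, 0) convention."""
    n_full = len(full_calls)
    n_pooled = len(pooled_calls)
    n_common = len(full_calls & pooled_calls)
    if n_full == 0:
        common, uniq_full = 1.0, 0.0
    else:
        common = n_common / n_full
        uniq_full = (n_full - n_common) / n_full
    uniq_pooled = 0.0 if n_pooled == 0 else (n_pooled - n_common) / n_pooled
    return ConsistencyStats(common, uniq_full, uniq_pooled)


def precision_recall(calls: CallSet, truth: CallSet) -> tuple[float, float]:
    """Precision/recall of a call set against curated truth (empty -> 1)."""
    tp = len(calls & truth)
    precision = 1.0 if not calls else tp / len(calls)
    recall = 1.0 if not truth else tp / len(truth)
    return precision, recall


def make_partition(sample_ids: Sequence[str], proportion: float,
                   rng: np.random.Generator) -> list[list[str]]:
    """Uniformly random partition into k = round(1/proportion) subsets.

    Subset sizes are floor(N/k) or ceil(N/k) with the remainder spread one
    per subset; the subsets are disjoint and cover the cohort.
    """
    if not (0.0 < proportion <= 1.0):
        raise ConfigError(f"proportion must be in (0, 1], got {proportion}")
    k = int(round(1.0 / proportion))
    n = len(sample_ids)
    if k < 1:
        raise ConfigError("k = round(1/proportion) must be >= 1")
    if n < k:
        raise InputError(f"cannot split {n} samples into {k} subsets")
    order = rng.permutation(n)
    base, rem = divmod(n, k)
    subsets, start = [], 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        subsets.append([sample_ids[j] for j in order[start:start + size]])
        start += size
    return subsets


@dataclass
class InflectionResult:
    value: float
    saturated: bool


def detect_inflection(grid: Sequence[float], means: Sequence[float],
                      method: str = "plateau",
                      epsilon: float = 0.02) -> InflectionResult:
    """Locate the saturation point of a consistency curve.

    ``plateau`` (default): smallest grid value whose mean is within
    ``epsilon`` (relative) of the curve maximum.  ``curvature``: interior
    grid value maximising the negative second central difference.  Ties go
    to the smallest grid value.  ``saturated`` is False when only the final
    grid point qualifies (no saturation before the end of the grid).
    """
    grid = np.asarray(grid, dtype=float)
    means = np.asarray(means, dtype=float)
    if len(grid) < 3 or len(grid) != len(means):
        raise InputError("inflection detection needs >= 3 (grid, mean) pairs")
    if method == "plateau":
        threshold = (1.0 - epsilon) * float(np.max(means))
        qualifying = np.flatnonzero(means >= threshold)
        idx = int(qualifying[0])
        return InflectionResult(float(grid[idx]), idx < len(grid) - 1)
    if method == "curvature":
        second = means[2:] - 2.0 * means[1:-1] + means[:-2]
        idx = int(np.argmin(second)) + 1
        return InflectionResult(float(grid[idx]), True)
    raise ConfigError(f"unknown inflection method {method!r}")


@dataclass
class ConsistencyCurve:
    """Scan result: long-format table plus per-proportion inflections."""

    metric: str
    table: pd.DataFrame  # metric, grid_value, proportion, mean/sd, n_perm, P/R
    inflection: dict[float, float]
    saturated: dict[float, bool]

    def means(self, proportion: float) -> pd.Series:
        sub = self.table[np.isclose(self.table["proportion"], proportion)]
        return sub.set_index("grid_value")["mean_consistency"]

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("#metric=%s\n" % self.metric)
            for p in sorted(self.inflection):
                fh.write("#inflection\t%.6g\t%.6g\t%s\n"
                         % (p, self.inflection[p],
                            "saturated" if self.saturated[p] else "no_saturation"))
            self.table.to_csv(fh, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# Scan engines
# ---------------------------------------------------------------------------

def _validate_grid(metric: str, grid: Sequence[float],
                   base: FilterConfig) -> None:
    g = np.asarray(grid, dtype=float)
    if metric == METRIC_VAF and (g.min() < 0 or g.max() >= base.vaf_max):
        raise ConfigError(
            f"VAF grid must lie in [0, vaf_max={base.vaf_max})")
    if metric == METRIC_PREVALENCE and (g.min() < 0 or g.max() > 1):
        raise ConfigError("prevalence grid must lie in [0, 1]")
    if metric in (METRIC_DP, METRIC_SAFSAR, METRIC_SOR) and g.min() < 0:
        raise ConfigError(f"{metric} grid values must be >= 0")


class _ScanComponents:
    """Per-record quantities reused across partitions and grid values."""

    def __init__(self, table: CohortTable, base: FilterConfig, metric: str,
                 grid: np.ndarray):
        table = table.sort_canonical()
        self.table = table
        blood = table.blood.reset_index(drop=True)
        self.blood = blood
        self.n_rows = len(blood)
        self.grid = grid

        # fixed (non-scanned, non-population) fail flags under the base config
        flags = pd.concat([filters.technical_flags(blood, base),
                           filters.functional_flags(blood, base)], axis=1)
        if base.mode == MODE_PAIRED:
            pf, _ = filters.paired_flags(blood, table, base)
            flags = pd.concat([flags, pf], axis=1)
        drop = [c for c in _SCANNED_REASONS[metric] if c in flags.columns]
        self.fixed_fail = flags.drop(columns=drop).to_numpy().any(axis=1)

        # scanned-criterion fail matrix (rows x grid); NaN metric passes
        vaf = blood["vaf"].to_numpy(float)
        if metric == METRIC_VAF:
            self.scan_fail = vaf[:, None] < grid[None, :]
        elif metric == METRIC_DP:
            self.scan_fail = blood["dp"].to_numpy(float)[:, None] <= grid[None, :]
        elif metric == METRIC_SOR:
            sor = blood["sor"].to_numpy(float)
            self.scan_fail = sor[:, None] > grid[None, :]
        elif metric == METRIC_SAFSAR:
            saf = blood["saf"].to_numpy(dtype=float, na_value=np.nan)
            sar = blood["sar"].to_numpy(dtype=float, na_value=np.nan)
            self.scan_fail = ((saf[:, None] < grid[None, :])
                              | (sar[:, None] < grid[None, :]))
        else:  # PREVALENCE: handled through the population tier
            self.scan_fail = np.zeros((self.n_rows, len(grid)), dtype=bool)
        self.metric = metric
        self.base = base

        # factorised keys for fast per-subset prevalence
        self.sample_index = {s: i for i, s in enumerate(table.sample_ids)}
        self.row_sample = blood["sample_id"].map(self.sample_index).to_numpy(np.int64)
        vkey = (blood["chrom"].astype(str) + ":" + blood["pos"].astype(str)
                + ":" + blood["ref"].astype(str) + ":" + blood["alt"].astype(str))
        self.row_vk = pd.factorize(vkey)[0]
        lkey = blood["chrom"].astype(str) + ":" + blood["pos"].astype(str)
        self.row_lk = pd.factorize(lkey)[0]
        self.n_vk = self.row_vk.max() + 1 if self.n_rows else 0
        self.n_lk = self.row_lk.max() + 1 if self.n_rows else 0
        # first occurrence of each (sample, locus) pair — for distinct-sample
        # locus carrier counts under multi-allelic sites
        sl = pd.MultiIndex.from_arrays([self.row_sample, self.row_lk])
        self.first_sample_locus = ~sl.duplicated()
        self.row_pairs = [
            (sid, key) for sid, key in zip(
                blood["sample_id"],
                blood[["chrom", "pos", "ref", "alt"]]
                .itertuples(index=False, name=None))]

    def _prevalence(self, subset_of_sample: np.ndarray, k: int,
                    subset_sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Allele/locus prevalence of each record within its own subset."""
        row_subset = subset_of_sample[self.row_sample]
        a_counts = np.bincount(self.row_vk * k + row_subset,
                               minlength=self.n_vk * k)
        l_rows = self.first_sample_locus
        l_counts = np.bincount(self.row_lk[l_rows] * k + row_subset[l_rows],
                               minlength=self.n_lk * k)
        denom = subset_sizes[row_subset]
        ap = a_counts[self.row_vk * k + row_subset] / denom
        lp = l_counts[self.row_lk * k + row_subset] / denom
        return ap, lp

    def call_matrix(self, subset_of_sample: np.ndarray | None = None,
                    k: int = 1,
                    subset_sizes: np.ndarray | None = None) -> np.ndarray:
        """Boolean (rows x grid) call matrix within the given partition.

        ``subset_of_sample=None`` means the full cohort (k = 1).
        """
        if subset_of_sample is None:
            subset_of_sample = np.zeros(len(self.sample_index), dtype=np.int64)
            subset_sizes = np.array([len(self.sample_index)], dtype=float)
            k = 1
        ap, lp = self._prevalence(subset_of_sample, k, subset_sizes)
        if self.metric == METRIC_PREVALENCE:
            pop_fail = ((ap[:, None] > self.grid[None, :])
                        | (lp[:, None] > self.grid[None, :]))
        else:
            cut = self.base.prevalence_max
            pop_fail = ((ap > cut) | (lp > cut))[:, None]
        return (~self.fixed_fail[:, None]) & (~self.scan_fail) & (~pop_fail)


def _partition_rng(plan: PermutationPlan, prop_index: int,
                   perm_index: int) -> np.random.Generator:
    # Seed stream indexed by (metric, proportion, permutation) — NOT the grid
    # value — so identical partitions are reused across the grid.
    ss = np.random.SeedSequence(
        [plan.seed, _METRIC_CODE[plan.metric_name], prop_index, perm_index])
    return np.random.default_rng(ss)


def permutation_scan(table: CohortTable, base_config: FilterConfig,
                     plan: PermutationPlan,
                     truth: CallSet | None = None,
                     engine: str = "vectorized") -> ConsistencyCurve:
    """Scan one parameter over its grid and measure subset consistency.

    Deterministic given (inputs, seed).  ``engine="per-subset"`` reruns
    ``run_chipfilter`` literally on every subset and is provided as the
    reference implementation (slow; results are identical).
    """
    if table.df.empty or table.n_samples == 0:
        raise InputError("empty cohort table")
    grid = np.asarray(plan.grid, dtype=float)
    _validate_grid(plan.metric_name, grid, base_config)
    if engine not in ("vectorized", "per-subset"):
        raise ConfigError(f"unknown engine {engine!r}")

    comp = _ScanComponents(table, base_config, plan.metric_name, grid)
    n_grid = len(grid)
    full_mat = comp.call_matrix()
    if engine == "per-subset":
        full_mat = _full_matrix_naive(comp, base_config, plan, grid)

    truth_row = None
    if truth is not None:
        truth_set = set(truth)
        truth_row = np.array([p in truth_set for p in comp.row_pairs])

    rows = []
    inflection: dict[float, float] = {}
    saturated: dict[float, bool] = {}
    n_full = full_mat.sum(axis=0).astype(float)

    for pi, prop in enumerate(plan.proportions):
        cf = np.empty((plan.n_perm, n_grid), dtype=float)
        for r in range(plan.n_perm):
            rng = _partition_rng(plan, pi, r)
            if plan.single_subset:
                size = max(1, int(round(prop * table.n_samples)))
                chosen = rng.permutation(table.n_samples)[:size]
                in_subset = np.zeros(table.n_samples, dtype=bool)
                in_subset[chosen] = True
                subset_of_sample = np.where(in_subset, 0, 1).astype(np.int64)
                sizes = np.array([float(size), float(table.n_samples - size)
                                  or 1.0])
                if engine == "per-subset":
                    ids = [table.sample_ids[j] for j in sorted(chosen)]
                    pooled = _pooled_matrix_naive(comp, base_config, plan,
                                                  grid, [ids])
                else:
                    pooled = comp.call_matrix(subset_of_sample, 2, sizes)
                    pooled &= in_subset[comp.row_sample][:, None]
                row_in = in_subset[comp.row_sample]
                restricted = full_mat & row_in[:, None]
                nf = restricted.sum(axis=0).astype(float)
                common = (restricted & pooled).sum(axis=0)
                cf[r] = np.where(nf > 0, common / np.maximum(nf, 1), 1.0)
            else:
                subsets = make_partition(table.sample_ids, prop, rng)
                if engine == "per-subset":
                    pooled = _pooled_matrix_naive(comp, base_config, plan,
                                                  grid, subsets)
                else:
                    k = len(subsets)
                    subset_of_sample = np.empty(table.n_samples, dtype=np.int64)
                    sizes = np.empty(k, dtype=float)
                    for si, subset in enumerate(subsets):
                        sizes[si] = len(subset)
                        for s in subset:
                            subset_of_sample[comp.sample_index[s]] = si
                    pooled = comp.call_matrix(subset_of_sample, k, sizes)
                common = (full_mat & pooled).sum(axis=0)
                cf[r] = np.where(n_full > 0, common / np.maximum(n_full, 1), 1.0)
        mean = cf.mean(axis=0)
        sd = cf.std(axis=0, ddof=1) if plan.n_perm > 1 else np.zeros(n_grid)
        for gi, v in enumerate(grid):
            rows.append({
                "metric": plan.metric_name, "grid_value": float(v),
                "proportion": float(prop),
                "mean_consistency": float(mean[gi]),
                "sd_consistency": float(sd[gi]), "n_perm": plan.n_perm,
            })
        if n_grid >= 3:
            res = detect_inflection(grid, mean)
            inflection[float(prop)] = res.value
            saturated[float(prop)] = res.saturated

    curve = pd.DataFrame(rows)
    if truth_row is not None:
        tp = (full_mat & truth_row[:, None]).sum(axis=0).astype(float)
        n_truth = float(truth_row.sum()) if truth is None else float(len(truth))
        prec = np.where(n_full > 0, tp / np.maximum(n_full, 1), 1.0)
        rec = (tp / n_truth) if n_truth > 0 else np.ones(n_grid)
        pr = pd.DataFrame({"grid_value": grid, "precision": prec,
                           "recall": rec})
        curve = curve.merge(pr, on="grid_value", how="left")
    else:
        curve["precision"] = np.nan
        curve["recall"] = np.nan
    return ConsistencyCurve(plan.metric_name, curve, inflection, saturated)


def _full_matrix_naive(comp: _ScanComponents, base: FilterConfig,
                       plan: PermutationPlan, grid: np.ndarray) -> np.ndarray:
    mat = np.zeros((comp.n_rows, len(grid)), dtype=bool)
    pair_index = {p: i for i, p in enumerate(comp.row_pairs)}
    for gi, v in enumerate(grid):
        calls = filters.run_chipfilter(
            comp.table, config_for(plan.metric_name, base, v)).calls
        for c in calls:
            mat[pair_index[c], gi] = True
    return mat


def _pooled_matrix_naive(comp: _ScanComponents, base: FilterConfig,
                         plan: PermutationPlan, grid: np.ndarray,
                         subsets: list[list[str]]) -> np.ndarray:
    mat = np.zeros((comp.n_rows, len(grid)), dtype=bool)
    pair_index = {p: i for i, p in enumerate(comp.row_pairs)}
    for subset in subsets:
        sub_table = comp.table.subset(subset)
        if sub_table.blood.empty:
            continue
        cfg = base
        if cfg.mode == MODE_PAIRED and sub_table.paired.empty:
            cfg = cfg.replace(mode="single")
        for gi, v in enumerate(grid):
            calls = filters.run_chipfilter(
                sub_table, config_for(plan.metric_name, cfg, v)).calls
            for c in calls:
                mat[pair_index[c], gi] = True
    return mat


def read_truth(path: str | os.PathLike) -> CallSet:
    """Read a curated-truth TSV (sample_id, chrom, pos, ref, alt)."""
    if not os.path.exists(path):
        raise InputError(f"truth file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    required = {"sample_id", "chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise InputError(f"truth file needs columns {sorted(required)}")
    return {(r.sample_id, (r.chrom, int(r.pos), r.ref, r.alt))
            for r in df.itertuples(index=False)}
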