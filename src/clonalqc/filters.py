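"""Four-tier quality filtering of cohort variant tables.

Tier order follows the method's rationale: cohort **population** prevalence
first (recurrent low-VAF artifacts are best recognised at cohort level and
must not confound the other metrics), then per-record **technical** metrics
(VAF, DP, Alt_AD, SAF/SAR, SOR, TLOD), **functional** annotations
(synonymity, repeat regions, germline databases), and finally the
**individual** tier comparing blood against a paired non-blood sample from
the same person.  Every blood record receives a :class:`FilterDecision`
with the complete list of failed criteria (no short-circuiting), so removals
are auditable; the surviving (sample, variant) pairs form the CH call set.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .cohort_io import CohortTable, VariantRecord, TISSUE_BLOOD
from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

# Reason codes in tier order (population, technical, functional, individual).
POP_ALLELE = "POP_ALLELE"
POP_LOCUS = "POP_LOCUS"
VAF_LOW = "VAF_LOW"
VAF_HIGH = "VAF_HIGH"
DP = "DP"
ALT_AD = "ALT_AD"
SAF = "SAF"
SAR = "SAR"
SOR = "SOR"
TLOD = "TLOD"
SYNONYMOUS = "SYNONYMOUS"
EFFECT = "EFFECT"
REPEAT = "REPEAT"
GERMLINE_DB = "GERMLINE_DB"
PAIR_GERMLINE = "PAIR_GERMLINE"
PAIR_TUMOR = "PAIR_TUMOR"

REASON_ORDER = [
    POP_ALLELE, POP_LOCUS,
    VAF_LOW, VAF_HIGH, DP, ALT_AD, SAF, SAR, SOR, TLOD,
    SYNONYMOUS, EFFECT, REPEAT, GERMLINE_DB,
    PAIR_GERMLINE, PAIR_TUMOR,
]

TECHNICAL_REASONS = [VAF_LOW, VAF_HIGH, DP, ALT_AD, SAF, SAR, SOR, TLOD]
FUNCTIONAL_REASONS = [SYNONYMOUS, EFFECT, REPEAT, GERMLINE_DB]

DEFAULT_KEEP_EFFECTS = frozenset({
    "nonsynonymous SNV",
    "stopgain",
    "stoploss",
    "frameshift insertion",
    "frameshift deletion",
    "nonframeshift insertion",
    "nonframeshift deletion",
    "splicing",
})

MODE_SINGLE = "single"
MODE_PAIRED = "paired"


@dataclass
class FilterConfig:
    """Every tunable threshold, with comparator semantics fixed per field.

    Pass conditions: ``vaf_min <= vaf <= vaf_max`` (boundaries pass),
    ``dp > dp_min`` (strict, the conventional DP > 20), ``alt_ad >=
    alt_ad_min``, ``saf >= saf_min``, ``sar >= sar_min``, ``sor <=
    sor_max``, ``tlod >= tlod_min``.  A variant is removed cohort-wide when
    its allele- or locus-level prevalence is strictly greater than
    ``prevalence_max``.  A missing metric passes its criterion.
    """

    vaf_min: float = 0.02
    vaf_max: float = 0.35
    dp_min: int = 20
    alt_ad_min: int = 5
    saf_min: int = 3
    sar_min: int = 3
    sor_max: float = 3.0
    tlod_min: float = 6.3
    prevalence_max: float = 0.10
    gnomad_max: float = 0.001
    keep_effects: frozenset[str] = DEFAULT_KEEP_EFFECTS
    paired_alpha: float = 0.05
    mode: str = MODE_SINGLE
    gene_allowlist: frozenset[str] | None = None  # optional, off by default

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.vaf_min < self.vaf_max <= 1.0):
            raise ConfigError(
                f"need 0 <= vaf_min < vaf_max <= 1, got "
                f"({self.vaf_min}, {self.vaf_max})")
        for name in ("dp_min", "alt_ad_min", "saf_min", "sar_min"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.sor_max < 0:
            raise ConfigError("sor_max must be >= 0")
        if not (0.0 < self.paired_alpha < 1.0):
            raise ConfigError("paired_alpha must be in (0, 1)")
        if not (0.0 <= self.prevalence_max <= 1.0):
            raise ConfigError("prevalence_max must be in [0, 1]")
        if not (0.0 <= self.gnomad_max <= 1.0):
            raise ConfigError("gnomad_max must be in [0, 1]")
        if self.mode not in (MODE_SINGLE, MODE_PAIRED):
            raise ConfigError(f"mode must be single or paired, got {self.mode!r}")

    def replace(self, **kwargs) -> "FilterConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "FilterConfig":
        """Build from a flat key/value mapping; unknown keys are errors."""
        known = set(cls.field_names())
        unknown = [k for k in mapping if k not in known]
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        kwargs: dict[str, object] = {}
        for f in dataclasses.fields(cls):
            if f.name not in mapping:
                continue
            raw = mapping[f.name]
            kwargs[f.name] = _coerce_config_value(f.name, raw)
        return cls(**kwargs)


def _coerce_config_value(name: str, raw: object):
    if name in ("keep_effects", "gene_allowlist"):
        if raw is None:
            return None
        if isinstance(raw, str):
            items = [s.strip() for s in raw.split(",") if s.strip()]
        else:
            items = list(raw)
        return frozenset(items)
    if name == "mode":
        return str(raw)
    if name in ("dp_min", "alt_ad_min", "saf_min", "sar_min"):
        return int(float(raw))
    return float(raw)


def load_filter_config(path: str | os.PathLike) -> FilterConfig:
    """Load a flat key=value (or TOML) config file into a FilterConfig."""
    if not os.path.exists(path):
        raise InputError(f"config file not found: {path}")
    text = open(path).read()
    if str(path).endswith(".toml"):
        import tomllib
        mapping = tomllib.loads(text)
    else:
        mapping = {}
        for ln, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{ln}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            mapping[key] = val
    return FilterConfig.from_mapping(mapping)


@dataclass
class PrevalenceStats:
    """Cohort carrier fractions of one variant at allele and locus level."""

    allele_prevalence: float
    locus_prevalence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.allele_prevalence <= self.locus_prevalence <= 1.0):
            raise InputError(
                f"invalid prevalence pair ({self.allele_prevalence}, "
                f"{self.locus_prevalence})")


@dataclass
class FilterDecision:
    keep: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.keep == (len(self.reasons) == 0)


# ---------------------------------------------------------------------------
# Vectorised tier flags (shared by run_chipfilter and the permutation scan)
# ---------------------------------------------------------------------------

def _bool(series: pd.Series) -> np.ndarray:
    """Nullable-safe boolean array: NA compares as False (missing passes)."""
    if series.dtype == bool:
        return series.to_numpy()
    return series.fillna(False).to_numpy(dtype=bool)


def technical_flags(df: pd.DataFrame, config: FilterConfig) -> pd.DataFrame:
    """Per-record fail flags for every technical criterion (NaN passes)."""
    out = pd.DataFrame(index=df.index)
    out[VAF_LOW] = _bool(df["vaf"] < config.vaf_min)
    out[VAF_HIGH] = _bool(df["vaf"] > config.vaf_max)
    out[DP] = _bool(df["dp"] <= config.dp_min)
    out[ALT_AD] = _bool(df["alt_ad"] < config.alt_ad_min)
    out[SAF] = _bool(df["saf"] < config.saf_min)
    out[SAR] = _bool(df["sar"] < config.sar_min)
    out[SOR] = _bool(df["sor"] > config.sor_max)
    out[TLOD] = _bool(df["tlod"] < config.tlod_min)
    return out


def functional_flags(df: pd.DataFrame, config: FilterConfig) -> pd.DataFrame:
    """Per-record fail flags for the functional/annotation criteria.

    A record is flagged GERMLINE_DB when its gnomAD frequency exceeds the
    cutoff, or when it is a bare dbSNP member (no gnomAD frequency and no
    cancer-database evidence) — COSMIC membership rescues dbSNP-only hits.
    """
    out = pd.DataFrame(index=df.index)
    ef = df["exonic_function"]
    present = ef.notna()
    out[SYNONYMOUS] = _bool(ef == "synonymous SNV")
    effect_bad = present & (ef != "synonymous SNV") & ~ef.isin(config.keep_effects)
    if config.gene_allowlist is not None:
        gene = df["gene"]
        effect_bad |= gene.notna() & ~gene.isin(config.gene_allowlist)
    out[EFFECT] = _bool(effect_bad)
    out[REPEAT] = _bool(df["in_repeat_region"] == True)  # noqa: E712 (nullable)
    gn = df["gnomad_af"]
    out[GERMLINE_DB] = _bool(
        (gn > config.gnomad_max)
        | (df["dbsnp_id"].notna() & gn.isna() & df["cosmic_id"].isna()))
    return out


def prevalence_table(blood: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Per-record allele/locus carrier fractions over ``n_samples``."""
    if n_samples < 1:
        raise InputError("empty cohort: prevalence undefined")
    out = pd.DataFrame(index=blood.index)
    vkey = ["chrom", "pos", "ref", "alt"]
    lkey = ["chrom", "pos"]
    allele_carriers = blood.groupby(vkey)["sample_id"].transform("nunique")
    # locus level: distinct carrier samples of ANY alt at the position
    locus_carriers = blood.groupby(lkey)["sample_id"].transform("nunique")
    out["allele_prevalence"] = allele_carriers / n_samples
    out["locus_prevalence"] = locus_carriers / n_samples
    return out


def population_flags(blood: pd.DataFrame, n_samples: int,
                     config: FilterConfig) -> pd.DataFrame:
    """Fail flags for the population tier (strict > cutoff removes)."""
    prev = prevalence_table(blood, n_samples)
    out = pd.DataFrame(index=blood.index)
    out[POP_ALLELE] = (prev["allele_prevalence"] > config.prevalence_max).to_numpy()
    out[POP_LOCUS] = (prev["locus_prevalence"] > config.prevalence_max).to_numpy()
    return out


def paired_flags(blood: pd.DataFrame, table: CohortTable,
                 config: FilterConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Individual-tier fail flags plus enrichment p-values.

    For each blood record of a sample with a paired VCF, a one-sided exact
    test (hypergeometric tail, equivalent to one-sided Fisher) asks whether
    the blood alt fraction exceeds the paired sample's.  Significant
    enrichment keeps the record; otherwise it is reason-coded PAIR_TUMOR
    (paired VAF higher: cfDNA-contamination pattern) or PAIR_GERMLINE
    (similar VAF).  Variants absent from the paired VCF are tested against
    alt=0 at the paired sample's median depth (imputations are logged).
    """
    out = pd.DataFrame(
        {PAIR_GERMLINE: False, PAIR_TUMOR: False}, index=blood.index)
    pvals = pd.Series(np.nan, index=blood.index, dtype=float)
    paired = table.paired
    pair_map = table.paired_map
    if not pair_map or paired.empty:
        return out, pvals

    median_dp = paired.groupby("sample_id")["dp"].median()
    b = blood[blood["sample_id"].isin(pair_map)].copy()
    if b.empty:
        return out, pvals
    b["_pair_id"] = b["sample_id"].map(pair_map)
    has_data = b["_pair_id"].isin(median_dp.index)
    n_no_pair_data = int((~has_data).sum())
    if n_no_pair_data:
        logger.warning("paired tier: %d record(s) from samples whose paired "
                       "VCF has no records; single-sample logic applied",
                       n_no_pair_data)
    b = b[has_data]
    if b.empty:
        return out, pvals

    t = paired[["sample_id", "chrom", "pos", "ref", "alt", "alt_ad", "dp"]]
    t = t.rename(columns={"sample_id": "_pair_id",
                          "alt_ad": "_t_alt", "dp": "_t_dp"})
    merged = b.merge(t, on=["_pair_id", "chrom", "pos", "ref", "alt"],
                     how="left")
    merged.index = b.index
    n_imputed = int(merged["_t_alt"].isna().sum())
    if n_imputed:
        logger.warning("paired tier: imputed paired depth (alt=0, median DP) "
                       "for %d blood-only site(s)", n_imputed)
    merged["_t_alt"] = merged["_t_alt"].fillna(0).astype(np.int64)
    imput = merged["_t_dp"].isna()
    merged.loc[imput, "_t_dp"] = (
        merged.loc[imput, "_pair_id"].map(median_dp).round())
    merged["_t_dp"] = merged["_t_dp"].astype(np.int64).clip(lower=1)

    b_alt = merged["alt_ad"].to_numpy(np.int64)
    b_dp = merged["dp"].to_numpy(np.int64)
    t_alt = merged["_t_alt"].to_numpy(np.int64)
    t_dp = merged["_t_dp"].to_numpy(np.int64)
    p = hypergeom.sf(b_alt - 1, b_dp + t_dp, b_alt + t_alt, b_dp)
    enriched = p < config.paired_alpha
    t_vaf = t_alt / t_dp
    b_vaf = b_alt / b_dp
    out.loc[merged.index, PAIR_TUMOR] = ~enriched & (t_vaf > b_vaf)
    out.loc[merged.index, PAIR_GERMLINE] = ~enriched & ~(t_vaf > b_vaf)
    pvals.loc[merged.index] = p
    return out, pvals


def all_fail_flags(table: CohortTable, config: FilterConfig,
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Fail-flag matrix (rows = blood records, columns = reason codes)."""
    blood = table.blood
    flags = pd.concat([
        population_flags(blood, table.n_samples, config),
        technical_flags(blood, config),
        functional_flags(blood, config),
    ], axis=1)
    if config.mode == MODE_PAIRED:
        pf, pvals = paired_flags(blood, table, config)
    else:
        pf = pd.DataFrame({PAIR_GERMLINE: False, PAIR_TUMOR: False},
                          index=blood.index)
        pvals = pd.Series(np.nan, index=blood.index, dtype=float)
    flags = pd.concat([flags, pf], axis=1)
    return flags[REASON_ORDER], pvals


# ---------------------------------------------------------------------------
# Scalar (per-record) operations
# ---------------------------------------------------------------------------

def technical_filter(record: VariantRecord, config: FilterConfig) -> FilterDecision:
    """Technical tier on one blood record; all criteria evaluated."""
    reasons = []
    if record.vaf is not None and record.vaf < config.vaf_min:
        reasons.append(VAF_LOW)
    if record.vaf is not None and record.vaf > config.vaf_max:
        reasons.append(VAF_HIGH)
    if record.dp <= config.dp_min:
        reasons.append(DP)
    if record.alt_ad < config.alt_ad_min:
        reasons.append(ALT_AD)
    if record.saf is not None and record.saf < config.saf_min:
        reasons.append(SAF)
    if record.sar is not None and record.sar < config.sar_min:
        reasons.append(SAR)
    if record.sor is not None and record.sor > config.sor_max:
        reasons.append(SOR)
    if record.tlod is not None and record.tlod < config.tlod_min:
        reasons.append(TLOD)
    return FilterDecision(keep=not reasons, reasons=reasons)


def functional_filter(record: VariantRecord, config: FilterConfig,
                      mask=None) -> FilterDecision:
    """Functional tier on one record (optionally against a region mask)."""
    a = record.annotations
    reasons = []
    if a.exonic_function == "synonymous SNV":
        reasons.append(SYNONYMOUS)
    elif a.exonic_function is not None and a.exonic_function not in config.keep_effects:
        reasons.append(EFFECT)
    in_repeat = a.in_repeat_region
    if mask is not None and in_repeat is None:
        in_repeat = mask.contains(record.chrom, record.pos)
    if in_repeat:
        reasons.append(REPEAT)
    if ((a.gnomad_af is not None and a.gnomad_af > config.gnomad_max)
            or (a.dbsnp_id is not None and a.gnomad_af is None
                and a.cosmic_id is None)):
        reasons.append(GERMLINE_DB)
    reasons.sort(key=REASON_ORDER.index)
    return FilterDecision(keep=not reasons, reasons=reasons)


def paired_classify(blood: VariantRecord, paired: VariantRecord | None,
                    config: FilterConfig,
                    imputed_dp: int | None = None) -> tuple[str, float]:
    """Classify one blood record against its paired-sample counterpart.

    Returns ``("ch_enriched" | "pair_germline" | "pair_tumor", p_value)``
    from the one-sided exact test of blood alt fraction > paired alt
    fraction on the 2x2 read-count table.  When ``paired`` is None the
    paired counts are imputed as alt=0 at ``imputed_dp`` (the paired
    sample's median depth).
    """
    if blood.dp <= 0:
        raise InputError("paired test requires positive blood depth")
    if paired is not None:
        t_alt, t_dp = paired.alt_ad, paired.dp
    else:
        if imputed_dp is None or imputed_dp < 1:
            raise InputError("missing paired record requires imputed_dp >= 1")
        t_alt, t_dp = 0, int(imputed_dp)
    p = float(hypergeom.sf(blood.alt_ad - 1, blood.dp + t_dp,
                           blood.alt_ad + t_alt, blood.dp))
    if p < config.paired_alpha:
        return "ch_enriched", p
    if t_alt / t_dp > blood.alt_ad / blood.dp:
        return "pair_tumor", p
    return "pair_germline", p


def population_prevalence_filter(
        table: CohortTable, config: FilterConfig,
) -> tuple[dict[tuple, PrevalenceStats], pd.DataFrame]:
    """Population tier over the full table passed in.

    Returns the per-variant prevalence stats and the per-blood-record fail
    flags (POP_ALLELE / POP_LOCUS).  Prevalence is always computed over the
    sample set of the table given, so subset runs use subset prevalence.
    """
    if table.n_samples < 1:
        raise InputError("empty cohort")
    blood = table.blood
    prev = prevalence_table(blood, table.n_samples)
    stats: dict[tuple, PrevalenceStats] = {}
    keys = blood[["chrom", "pos", "ref", "alt"]].itertuples(index=False, name=None)
    for key, ap, lp in zip(keys, prev["allele_prevalence"], prev["locus_prevalence"]):
        stats[key] = PrevalenceStats(float(ap), float(lp))
    return stats, population_flags(blood, table.n_samples, config)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class CHCallSet:
    """Filter outcome: surviving calls plus an auditable decision per record."""

    calls: set[tuple[str, tuple[str, int, str, str]]]
    decisions: dict[tuple[str, tuple[str, int, str, str]], FilterDecision]
    config_used: FilterConfig
    frame: pd.DataFrame  # blood records + keep + semicolon-joined reasons

    def calls_frame(self) -> pd.DataFrame:
        cols = ["sample_id", "chrom", "pos", "ref", "alt", "vaf", "dp",
                "gene", "exonic_function"]
        kept = self.frame[self.frame["keep"]]
        return (kept[cols]
                .sort_values(["sample_id", "chrom", "pos", "ref", "alt"],
                             kind="mergesort")
                .reset_index(drop=True))

    def decisions_frame(self) -> pd.DataFrame:
        cols = ["sample_id", "chrom", "pos", "ref", "alt", "keep", "reasons"]
        return (self.frame[cols]
                .sort_values(["sample_id", "chrom", "pos", "ref", "alt"],
                             kind="mergesort")
                .reset_index(drop=True))

    def removal_summary(self) -> pd.Series:
        """Count of removed records per reason code (a record may recur)."""
        counts = {r: 0 for r in REASON_ORDER}
        for dec in self.decisions.values():
            for r in dec.reasons:
                counts[r] += 1
        return pd.Series(counts, name="n_removed")


def run_chipfilter(table: CohortTable, config: FilterConfig) -> CHCallSet:
    """Run all four tiers over a cohort table; deterministic in its inputs.

    Paired mode requires paired data for at least one sample; samples
    without a pair fall back to single-sample logic (logged by the paired
    tier).  Decisions are recorded for every blood record with every failed
    criterion, including tiers after the first failure.
    """
    if table.df.empty or table.n_samples == 0:
        raise InputError("empty cohort table")
    if config.mode == MODE_PAIRED and (not table.paired_map or table.paired.empty):
        raise ConfigError("paired mode requested but the table has no paired data")

    table = table.sort_canonical()
    blood = table.blood
    flags, pvals = all_fail_flags(table, config)
    fail_any = flags.to_numpy().any(axis=1)

    n_missing = {
        SAF: int(blood["saf"].isna().sum()),
        SOR: int(blood["sor"].isna().sum()),
        TLOD: int(blood["tlod"].isna().sum()),
    }
    for reason, n in n_missing.items():
        if n:
            logger.info("run_chipfilter: %d record(s) passed %s because the "
                        "metric is missing", n, reason)

    frame = blood.copy()
    frame["keep"] = ~fail_any
    reason_names = np.array(REASON_ORDER, dtype=object)
    flag_mat = flags.to_numpy()
    frame["reasons"] = [";".join(reason_names[row]) for row in flag_mat]
    frame["pair_p"] = pvals

    calls: set = set()
    decisions: dict = {}
    samples = frame["sample_id"].to_numpy()
    keys = list(frame[["chrom", "pos", "ref", "alt"]]
                .itertuples(index=False, name=None))
    keeps = frame["keep"].to_numpy()
    for sid, key, keep, row in zip(samples, keys, keeps, flag_mat):
        reasons = [r for r, f in zip(REASON_ORDER, row) if f]
        decisions[(sid, key)] = FilterDecision(bool(keep), reasons)
        if keep:
            calls.add((sid, key))
    return CHCallSet(calls=calls, decisions=decisions, config_used=config,
                     frame=frame.reset_index(drop=True))
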