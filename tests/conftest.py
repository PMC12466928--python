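"""Shared fixtures and independent oracles for the test suite.

The brute-force oracle here re-implements every filter comparator in plain
Python (dict/set arithmetic, lgamma-based hypergeometric tails) with no
shared code paths with the package internals; it is the reference the
vectorised pipeline is checked against.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
import pandas as pd
import pytest

from clonalqc.cohort_io import (AnnotationBundle, VariantRecord, merge_cohort,
                                TISSUE_BLOOD, TISSUE_PAIRED)
from clonalqc.filters import FilterConfig
from clonalqc.simulate import SimParams, simulate_cohort_table


def make_record(sample_id="S1", tissue=TISSUE_BLOOD, chrom="chr1", pos=100,
                ref="A", alt="T", vaf=0.05, dp=100, alt_ad=None, saf=None,
                sar=None, ref_fw=None, ref_rv=None, sor=None, tlod=None,
                **ann) -> VariantRecord:
    if alt_ad is None:
        alt_ad = int(round(vaf * dp))
    return VariantRecord(
        sample_id=sample_id, tissue=tissue, chrom=chrom, pos=pos, ref=ref,
        alt=alt, vaf=vaf, dp=dp, alt_ad=alt_ad, saf=saf, sar=sar,
        ref_fw=ref_fw, ref_rv=ref_rv, sor=sor, tlod=tlod,
        annotations=AnnotationBundle(**ann))


@pytest.fixture(scope="session")
def wes_cohort():
    """Default WES-regime synthetic cohort (n=100), with its truth table."""
    return simulate_cohort_table(SimParams(n_samples=100, seed=101))


@pytest.fixture(scope="session")
def ultradeep_cohort():
    """Ultra-deep regime cohort (n=100) where low-VAF events are well read-supported."""
    return simulate_cohort_table(
        SimParams(n_samples=100, seed=202, depth_mode="ultradeep"))


@pytest.fixture(scope="session")
def paired_wes_cohort():
    """Paired blood/tumor WES cohort with cfDNA contamination events."""
    return simulate_cohort_table(
        SimParams(n_samples=60, seed=2, paired=True))


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def hyper_tail_p(b_alt: int, b_dp: int, t_alt: int, t_dp: int) -> float:
    """P(X >= b_alt) for X ~ Hypergeom(M=b_dp+t_dp, K=b_alt+t_alt, n=b_dp).

    Direct tail sum over lgamma-based log binomials — the one-sided exact
    test of blood alt-fraction enrichment, written independently of scipy.
    """
    M, K, n = b_dp + t_dp, b_alt + t_alt, b_dp

    def lchoose(a: int, b: int) -> float:
        if b < 0 or b > a:
            return float("-inf")
        return (math.lgamma(a + 1) - math.lgamma(b + 1)
                - math.lgamma(a - b + 1))

    denom = lchoose(M, n)
    total = 0.0
    for x in range(b_alt, min(K, n) + 1):
        num = lchoose(K, x) + lchoose(M - K, n - x)
        if num != float("-inf"):
            total += math.exp(num - denom)
    return min(total, 1.0)


def _missing(x) -> bool:
    if x is None or x is pd.NA:
        return True
    return isinstance(x, float) and math.isnan(x)


def oracle_calls(table, cfg: FilterConfig) -> set:
    """Independent re-implementation of every comparator, applied per record."""
    n_cohort = len(table.sample_ids)
    blood = table.df[table.df["tissue"] == TISSUE_BLOOD].to_dict("records")
    paired = table.df[table.df["tissue"] == TISSUE_PAIRED].to_dict("records")

    allele_carriers: dict[tuple, set] = {}
    locus_carriers: dict[tuple, set] = {}
    for r in blood:
        vkey = (r["chrom"], r["pos"], r["ref"], r["alt"])
        allele_carriers.setdefault(vkey, set()).add(r["sample_id"])
        locus_carriers.setdefault(vkey[:2], set()).add(r["sample_id"])

    pair_lookup: dict[tuple, tuple] = {}
    pair_depths: dict[str, list] = {}
    for r in paired:
        pair_lookup[(r["sample_id"], r["chrom"], r["pos"], r["ref"],
                     r["alt"])] = (int(r["alt_ad"]), int(r["dp"]))
        pair_depths.setdefault(r["sample_id"], []).append(int(r["dp"]))
    median_dp = {s: int(round(statistics.median(v)))
                 for s, v in pair_depths.items()}

    calls = set()
    for r in blood:
        vkey = (r["chrom"], r["pos"], r["ref"], r["alt"])
        keep = True
        # population tier (strict > removes)
        if len(allele_carriers[vkey]) / n_cohort > cfg.prevalence_max:
            keep = False
        if len(locus_carriers[vkey[:2]]) / n_cohort > cfg.prevalence_max:
            keep = False
        # technical tier (missing passes)
        if r["vaf"] < cfg.vaf_min or r["vaf"] > cfg.vaf_max:
            keep = False
        if r["dp"] <= cfg.dp_min:
            keep = False
        if r["alt_ad"] < cfg.alt_ad_min:
            keep = False
        if not _missing(r["saf"]) and r["saf"] < cfg.saf_min:
            keep = False
        if not _missing(r["sar"]) and r["sar"] < cfg.sar_min:
            keep = False
        if not _missing(r["sor"]) and r["sor"] > cfg.sor_max:
            keep = False
        if not _missing(r["tlod"]) and r["tlod"] < cfg.tlod_min:
            keep = False
        # functional tier
        ef = r["exonic_function"]
        if not _missing(ef):
            if ef == "synonymous SNV" or ef not in cfg.keep_effects:
                keep = False
        irr = r["in_repeat_region"]
        if not _missing(irr) and bool(irr):
            keep = False
        gn = r["gnomad_af"]
        if not _missing(gn) and gn > cfg.gnomad_max:
            keep = False
        if (_missing(gn) and not _missing(r["dbsnp_id"])
                and _missing(r["cosmic_id"])):
            keep = False
        # individual tier (paired mode; samples without data fall back)
        if cfg.mode == "paired" and r["sample_id"] in table.paired_map:
            pid = table.paired_map[r["sample_id"]]
            if pid in median_dp:
                hit = pair_lookup.get((pid,) + vkey)
                t_alt, t_dp = hit if hit else (0, median_dp[pid])
                p = hyper_tail_p(int(r["alt_ad"]), int(r["dp"]), t_alt, t_dp)
                if p >= cfg.paired_alpha:
                    keep = False
        if keep:
            calls.add((r["sample_id"], vkey))
    return calls


# ---------------------------------------------------------------------------
# Random micro-cohorts
# ---------------------------------------------------------------------------

_EFFECTS = [None, "synonymous SNV", "nonsynonymous SNV", "stopgain",
            "unknown", "frameshift deletion"]


def random_micro_cohort(rng: np.random.Generator):
    """Tiny random cohort (<=5 samples x <=20 variants) plus a random config.

    Exercises missing metrics, annotation combinations, multi-allelic loci,
    shared variants (prevalence), and — in half the draws — paired tumor
    records including blood-only sites (depth imputation).
    """
    n_samples = int(rng.integers(2, 6))
    n_variants = int(rng.integers(1, 21))
    paired_mode = bool(rng.random() < 0.5)
    sample_ids = [f"M{i}" for i in range(n_samples)]

    variants = []
    pos = 1000
    for _ in range(n_variants):
        if variants and rng.random() < 0.3:
            chrom, p0, ref, _ = variants[-1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append((chrom, p0, ref, alt))  # multi-allelic locus
        else:
            pos += int(rng.integers(5, 50))
            ref = str(rng.choice(list("ACGT")))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append(("chr1", pos, ref, alt))
    variants = list(dict.fromkeys(variants))

    collections, paired_map = [], {}
    for sid in sample_ids:
        blood, tumor = [], []
        pid = f"{sid}_T"
        for chrom, p0, ref, alt in variants:
            if rng.random() > 0.5:
                continue
            dp = int(rng.integers(10, 200))
            vaf_true = float(rng.choice(
                [rng.uniform(0.001, 0.02), rng.uniform(0.02, 0.35),
                 rng.uniform(0.4, 0.6)]))
            alt_ad = int(np.clip(rng.binomial(dp, vaf_true), 1, dp))
            saf = sar = ref_fw = ref_rv = sor = None
            if rng.random() < 0.8:
                saf = int(rng.binomial(alt_ad, rng.uniform(0.2, 0.8)))
                sar = alt_ad - saf
                ref_fw = int(rng.binomial(dp - alt_ad, 0.5))
                ref_rv = (dp - alt_ad) - ref_fw
                if rng.random() < 0.7:
                    from clonalqc.cohort_io import compute_sor
                    sor = compute_sor(ref_fw, ref_rv, saf, sar)
            tlod = float(rng.uniform(0, 20)) if rng.random() < 0.8 else None
            gnomad = (None if rng.random() < 0.5
                      else float(rng.choice([rng.uniform(0, 0.001),
                                             rng.uniform(0.002, 0.5)])))
            blood.append(make_record(
                sample_id=sid, chrom=chrom, pos=p0, ref=ref, alt=alt,
                vaf=alt_ad / dp, dp=dp, alt_ad=alt_ad, saf=saf, sar=sar,
                ref_fw=ref_fw, ref_rv=ref_rv, sor=sor, tlod=tlod,
                exonic_function=_EFFECTS[int(rng.integers(len(_EFFECTS)))],
                gnomad_af=gnomad,
                dbsnp_id="rs1" if rng.random() < 0.3 else None,
                cosmic_id="COSM1" if rng.random() < 0.3 else None,
                in_repeat_region=bool(rng.random() < 0.1) if rng.random() < 0.5
                else None))
            if paired_mode and rng.random() < 0.6:
                t_dp = int(rng.integers(10, 200))
                t_vaf = float(rng.choice([0.0, rng.uniform(0.001, 0.6)]))
                t_alt = int(np.clip(rng.binomial(t_dp, t_vaf), 0, t_dp))
                if t_alt > 0:
                    tumor.append(make_record(
                        sample_id=pid, tissue=TISSUE_PAIRED, chrom=chrom,
                        pos=p0, ref=ref, alt=alt, vaf=t_alt / t_dp, dp=t_dp,
                        alt_ad=t_alt))
        if blood:
            collections.append(blood)
        if tumor:
            collections.append(tumor)
            paired_map[sid] = pid

    if not collections:
        collections = [[make_record(sample_id=sample_ids[0])]]
    table = merge_cohort(collections,
                         paired_map=paired_map if paired_mode else {},
                         sample_ids=sample_ids)
    cfg = FilterConfig(
        vaf_min=float(rng.choice([0.0, 0.02, 0.05])),
        vaf_max=float(rng.choice([0.35, 0.5])),
        dp_min=int(rng.choice([0, 20, 50])),
        alt_ad_min=int(rng.choice([0, 5])),
        saf_min=int(rng.choice([0, 3])),
        sar_min=int(rng.choice([0, 3])),
        sor_max=float(rng.choice([1.0, 3.0, 6.0])),
        tlod_min=float(rng.choice([0.0, 6.3])),
        prevalence_max=float(rng.choice([0.1, 0.3, 0.6])),
        gnomad_max=float(rng.choice([0.001, 0.1])),
        paired_alpha=float(rng.choice([0.05, 0.2])),
        mode="paired" if paired_mode and paired_map else "single",
    )
    return table, cfg
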