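"""Cohort assembly from per-sample somatic VCFs.

Blood-sample VCFs (Mutect2-dialect FORMAT ``AD/AF/DP/SB``, INFO ``TLOD/SOR``,
optionally ANNOVAR-style annotation keys) are parsed into flat
:class:`VariantRecord` rows and merged into a single long-format
:class:`CohortTable` that downstream filtering and permutation analysis
operate on.  Paired non-blood (e.g. tumor) VCFs are optional and are kept in
the same table, distinguished by the ``tissue`` column.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

TISSUE_BLOOD = "blood"
TISSUE_PAIRED = "paired"

#: Semantic annotation field -> default VCF INFO key (ANNOVAR refGene naming).
DEFAULT_ANNOTATION_SCHEMA: dict[str, str] = {
    "exonic_function": "ExonicFunc.refGene",
    "gene": "Gene.refGene",
    "gnomad_af": "gnomAD_exome_ALL",
    "dbsnp_id": "avsnp150",
    "cosmic_id": "cosmic70",
}

#: Fixed column order of the cohort table TSV snapshot.
COHORT_COLUMNS = [
    "sample_id", "tissue", "chrom", "pos", "ref", "alt",
    "vaf", "dp", "alt_ad", "saf", "sar", "ref_fw", "ref_rv",
    "sor", "tlod",
    "gene", "exonic_function", "gnomad_af", "dbsnp_id", "cosmic_id",
    "in_repeat_region",
]

_INT_COLS = ["pos", "dp", "alt_ad"]
_NULLABLE_INT_COLS = ["saf", "sar", "ref_fw", "ref_rv"]
_FLOAT_COLS = ["vaf", "sor", "tlod", "gnomad_af"]
_STR_COLS = ["sample_id", "tissue", "chrom", "ref", "alt",
             "gene", "exonic_function", "dbsnp_id", "cosmic_id"]


@dataclass
class AnnotationBundle:
    """Functional/database annotations attached upstream (e.g. by ANNOVAR)."""

    exonic_function: str | None = None
    gene: str | None = None
    gnomad_af: float | None = None
    dbsnp_id: str | None = None
    cosmic_id: str | None = None
    in_repeat_region: bool | None = None

    def __post_init__(self) -> None:
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise InputError(f"gnomad_af outside [0,1]: {self.gnomad_af}")


@dataclass
class VariantRecord:
    """One observed variant allele in one sample — the atom of the pipeline.

    Positions follow the VCF convention (1-based).  ``vaf`` is the caller's
    allele fraction when reported, else ``alt_ad / dp``.  Strand counts and
    SOR/TLOD may be missing depending on the caller; downstream filters treat
    a missing metric as passing that one criterion.
    """

    sample_id: str
    tissue: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    dp: int
    alt_ad: int
    saf: int | None = None
    sar: int | None = None
    ref_fw: int | None = None
    ref_rv: int | None = None
    sor: float | None = None
    tlod: float | None = None
    annotations: AnnotationBundle = field(default_factory=AnnotationBundle)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"VCF position must be >= 1, got {self.pos}")
        if self.dp < 0 or self.alt_ad < 0 or self.alt_ad > self.dp:
            raise InputError(
                f"inconsistent depths at {self.chrom}:{self.pos} "
                f"(alt_ad={self.alt_ad}, dp={self.dp})")
        if self.tissue not in (TISSUE_BLOOD, TISSUE_PAIRED):
            raise InputError(f"unknown tissue {self.tissue!r}")

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def locus_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def compute_sor(ref_fw: int, ref_rv: int, alt_fw: int, alt_rv: int) -> float:
    """Symmetric strand odds ratio with pseudocount 1 on every count.

    With primed counts ``x' = x + 1``::

        r        = (ref_fw' * alt_rv') / (ref_rv' * alt_fw')
        sym      = r + 1/r
        refRatio = min(ref_fw', ref_rv') / max(ref_fw', ref_rv')
        altRatio = min(alt_fw', alt_rv') / max(alt_fw', alt_rv')
        SOR      = ln(sym) + ln(refRatio) - ln(altRatio)

    Balanced strands give exactly ``ln 2``; an alternate allele seen on one
    strand only gives large values.
    """
    counts = (ref_fw, ref_rv, alt_fw, alt_rv)
    if any(c < 0 for c in counts):
        raise InputError(f"strand counts must be non-negative: {counts}")
    rf, rr, af, ar = (c + 1.0 for c in counts)
    r = (rf * ar) / (rr * af)
    sym = r + 1.0 / r
    ref_ratio = min(rf, rr) / max(rf, rr)
    alt_ratio = min(af, ar) / max(af, ar)
    return math.log(sym) + math.log(ref_ratio) - math.log(alt_ratio)


class RegionMask:
    """Set of genomic intervals (e.g. repeat regions) queryable by position."""

    def __init__(self) -> None:
        from intervaltree import IntervalTree
        self._trees: dict[str, "IntervalTree"] = {}
        self._IntervalTree = IntervalTree

    def add(self, chrom: str, start0: int, end0: int) -> None:
        """Add a 0-based half-open interval (BED convention)."""
        if end0 <= start0:
            return
        self._trees.setdefault(chrom, self._IntervalTree()).addi(start0, end0)

    def contains(self, chrom: str, pos1: int) -> bool:
        """Membership of a 1-based VCF position."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos1 - 1))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def load_bed_mask(path: str | os.PathLike) -> RegionMask:
    """Load a BED file (0-based half-open) into a :class:`RegionMask`."""
    if not os.path.exists(path):
        raise InputError(f"BED file not found: {path}")
    mask = RegionMask()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"malformed BED line: {line!r}")
            mask.add(parts[0], int(parts[1]), int(parts[2]))
    return mask


def _clean_info_str(value: object) -> str | None:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
        if value is None:
            return None
    text = str(value).strip()
    if text in ("", ".", "NA"):
        return None
    return text


def _info_float(value: object) -> float | None:
    text = _clean_info_str(value)
    if text is None:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def parse_vcf(
    path: str | os.PathLike,
    sample_id: str,
    tissue: str = TISSUE_BLOOD,
    annotation_schema: Mapping[str, str] | None = None,
    repeat_mask: RegionMask | None = None,
) -> list[VariantRecord]:
    """Parse a single-sample VCF into :class:`VariantRecord` rows.

    Multi-allelic sites are split into one record per alternate allele with
    per-allele AD.  VAF precedence: FORMAT ``AF`` first, else ``alt_ad/dp``.
    SOR precedence: INFO ``SOR`` first, else computed from the per-sample
    strand-count table (FORMAT ``SB``) when present.  Records without
    positive depth are skipped with a logged count.  Missing annotation
    columns yield missing fields, never an error.
    """
    if not os.path.exists(path):
        raise InputError(f"VCF not found: {path}")
    schema = dict(DEFAULT_ANNOTATION_SCHEMA)
    if annotation_schema:
        schema.update(annotation_schema)

    records: list[VariantRecord] = []
    n_skipped_depth = 0
    n_body = 0
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        sample_key = vcf_samples[0] if vcf_samples else None
        if len(vcf_samples) > 1:
            logger.warning("%s: %d samples in VCF, using first (%s)",
                           path, len(vcf_samples), sample_key)
        for rec in vcf:
            n_body += 1
            alts = rec.alts or ()
            fmt = rec.samples[sample_key] if sample_key is not None else {}
            ad = fmt.get("AD")
            af = fmt.get("AF")
            dp = fmt.get("DP")
            sb = fmt.get("SB")
            if dp is None and ad is not None and None not in ad:
                dp = int(sum(ad))
            info_sor = _info_float(rec.info.get("SOR")) if "SOR" in rec.info else None
            tlod_raw = rec.info.get("TLOD") if "TLOD" in rec.info else None

            ref_fw = ref_rv = saf = sar = None
            if sb is not None and len(sb) == 4 and None not in sb:
                ref_fw, ref_rv, saf, sar = (int(x) for x in sb)

            ann_common = AnnotationBundle(
                exonic_function=_decode_exonic(
                    _clean_info_str(rec.info.get(schema["exonic_function"]))
                    if schema["exonic_function"] in rec.info else None),
                gene=_clean_info_str(rec.info.get(schema["gene"]))
                if schema["gene"] in rec.info else None,
                gnomad_af=_info_float(rec.info.get(schema["gnomad_af"]))
                if schema["gnomad_af"] in rec.info else None,
                dbsnp_id=_clean_info_str(rec.info.get(schema["dbsnp_id"]))
                if schema["dbsnp_id"] in rec.info else None,
                cosmic_id=_clean_info_str(rec.info.get(schema["cosmic_id"]))
                if schema["cosmic_id"] in rec.info else None,
                in_repeat_region=(repeat_mask.contains(rec.chrom, rec.pos)
                                  if repeat_mask is not None else None),
            )

            for i, alt in enumerate(alts):
                if alt is None:
                    continue
                alt_ad = None
                if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                    alt_ad = int(ad[i + 1])
                if dp is None or dp <= 0 or alt_ad is None:
                    n_skipped_depth += 1
                    continue
                alt_ad = min(alt_ad, int(dp))
                if af is not None and len(af) > i and af[i] is not None:
                    vaf = float(af[i])
                else:
                    vaf = alt_ad / float(dp)
                sor = info_sor
                if sor is None and saf is not None:
                    sor = compute_sor(ref_fw, ref_rv, saf, sar)
                tlod = None
                if tlod_raw is not None:
                    if isinstance(tlod_raw, (tuple, list)):
                        if len(tlod_raw) > i and tlod_raw[i] is not None:
                            tlod = float(tlod_raw[i])
                        elif tlod_raw and tlod_raw[0] is not None:
                            tlod = float(tlod_raw[0])
                    else:
                        tlod = float(tlod_raw)
                records.append(VariantRecord(
                    sample_id=sample_id, tissue=tissue, chrom=rec.chrom,
                    pos=rec.pos, ref=rec.ref, alt=str(alt),
                    vaf=vaf, dp=int(dp), alt_ad=alt_ad,
                    saf=saf, sar=sar, ref_fw=ref_fw, ref_rv=ref_rv,
                    sor=sor, tlod=tlod, annotations=ann_common,
                ))
    if n_body == 0:
        logger.warning("%s: no parseable body lines", path)
    if n_skipped_depth:
        logger.warning("%s: skipped %d allele(s) without positive depth",
                       path, n_skipped_depth)
    return records


def _decode_exonic(value: str | None) -> str | None:
    # ANNOVAR writes e.g. "nonsynonymous_SNV" into INFO; the tabular form
    # uses spaces.  Normalise to the space form used by FilterConfig.
    return value.replace("_", " ") if value is not None else None


def _records_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        a = r.annotations
        rows.append((r.sample_id, r.tissue, r.chrom, r.pos, r.ref, r.alt,
                     r.vaf, r.dp, r.alt_ad, r.saf, r.sar, r.ref_fw, r.ref_rv,
                     r.sor, r.tlod, a.gene, a.exonic_function, a.gnomad_af,
                     a.dbsnp_id, a.cosmic_id, a.in_repeat_region))
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return _coerce_dtypes(df)


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    for c in _INT_COLS:
        df[c] = df[c].astype(np.int64)
    for c in _NULLABLE_INT_COLS:
        df[c] = df[c].astype("Int64")
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(np.float64)
    for c in _STR_COLS:
        df[c] = df[c].astype(object).where(df[c].notna(), None)
    df["in_repeat_region"] = df["in_repeat_region"].astype("boolean")
    return df


class CohortTable:
    """Merged long-format table of variant records across samples/tissues.

    ``sample_ids`` is the full blood-sample roster (it may include samples
    that contributed zero records — they still count in prevalence
    denominators).  ``paired_map`` maps blood sample id -> paired sample id.
    """

    def __init__(self, df: pd.DataFrame, sample_ids: Sequence[str],
                 paired_map: Mapping[str, str] | None = None) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"cohort table missing columns: {missing}")
        self.df = df[COHORT_COLUMNS].reset_index(drop=True)
        self.sample_ids = list(dict.fromkeys(sample_ids))
        self.paired_map = dict(paired_map or {})

    # -- derived views ----------------------------------------------------
    @property
    def blood(self) -> pd.DataFrame:
        return self.df[self.df["tissue"] == TISSUE_BLOOD]

    @property
    def paired(self) -> pd.DataFrame:
        return self.df[self.df["tissue"] == TISSUE_PAIRED]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Sequence[str]) -> "CohortTable":
        """Restrict to the given blood samples (and their paired samples)."""
        keep = set(sample_ids)
        paired_keep = {self.paired_map[s] for s in keep if s in self.paired_map}
        mask = ((self.df["tissue"].eq(TISSUE_BLOOD) & self.df["sample_id"].isin(keep))
                | (self.df["tissue"].eq(TISSUE_PAIRED)
                   & self.df["sample_id"].isin(paired_keep)))
        pm = {s: self.paired_map[s] for s in sample_ids if s in self.paired_map}
        return CohortTable(self.df[mask].copy(), list(sample_ids), pm)

    def sort_canonical(self) -> "CohortTable":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        df = self.df.copy()
        df["_s"] = df["sample_id"].map(
            lambda s: order.get(s, len(order)))
        df = df.sort_values(
            ["_s", "sample_id", "tissue", "chrom", "pos", "ref", "alt"],
            kind="mergesort").drop(columns="_s").reset_index(drop=True)
        return CohortTable(df, self.sample_ids, self.paired_map)

    # -- TSV snapshot ------------------------------------------------------
    def to_tsv(self, path: str | os.PathLike) -> None:
        """Write a snapshot so large cohorts need not re-parse VCFs."""
        with open(path, "w") as fh:
            fh.write("#cohort_samples=" + ",".join(self.sample_ids) + "\n")
            fh.write("#paired_map=" + ";".join(
                f"{k}:{v}" for k, v in self.paired_map.items()) + "\n")
            fh.write("#" + "\t".join(COHORT_COLUMNS) + "\n")
            self.df.to_csv(fh, sep="\t", header=False, index=False, na_rep=".")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CohortTable":
        if not os.path.exists(path):
            raise InputError(f"cohort table not found: {path}")
        sample_ids: list[str] = []
        paired_map: dict[str, str] = {}
        n_meta = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                n_meta += 1
                body = line[1:].rstrip("\n")
                if body.startswith("cohort_samples="):
                    val = body.split("=", 1)[1]
                    sample_ids = [s for s in val.split(",") if s]
                elif body.startswith("paired_map="):
                    val = body.split("=", 1)[1]
                    for item in val.split(";"):
                        if item:
                            k, v = item.split(":", 1)
                            paired_map[k] = v
        df = pd.read_csv(
            path, sep="\t", skiprows=n_meta, header=None,
            names=COHORT_COLUMNS, na_values=["."], keep_default_na=False,
            dtype={c: object for c in _STR_COLS},
        )
        if df.empty:
            df = pd.DataFrame(columns=COHORT_COLUMNS)
        df["in_repeat_region"] = df["in_repeat_region"].map(
            {"True": True, "False": False, True: True, False: False})
        df = _coerce_dtypes(df)
        if not sample_ids:
            sample_ids = list(df.loc[df["tissue"] == TISSUE_BLOOD, "sample_id"]
                              .drop_duplicates())
        return cls(df, sample_ids, paired_map)


def merge_cohort(
    per_sample_records: Iterable[Iterable[VariantRecord]],
    paired_map: Mapping[str, str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> CohortTable:
    """Merge per-sample record collections into one deduplicated table.

    Each input collection must come from distinct (sample, tissue) VCFs;
    the same (sample, tissue) appearing in two collections is a
    configuration error.  Within the table, duplicate
    ``(sample, tissue, variant)`` rows collapse to the one with the highest
    depth (ties keep the first encountered, logged).
    """
    paired_map = dict(paired_map or {})
    frames = []
    seen_sources: set[tuple[str, str]] = set()
    blood_order: list[str] = []
    for coll in per_sample_records:
        coll = list(coll)
        if not coll:
            continue
        sources = {(r.sample_id, r.tissue) for r in coll}
        dup = sources & seen_sources
        if dup:
            raise ConfigError(f"duplicate sample input(s): {sorted(dup)}")
        seen_sources |= sources
        for sid, tis in sources:
            if tis == TISSUE_BLOOD and sid not in blood_order:
                blood_order.append(sid)
        frames.append(_records_to_frame(coll))

    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = _records_to_frame([])

    if len(df):
        key_cols = ["sample_id", "tissue", "chrom", "pos", "ref", "alt"]
        before = len(df)
        df = (df.sort_values("dp", ascending=False, kind="mergesort")
                .drop_duplicates(key_cols, keep="first"))
        n_dropped = before - len(df)
        if n_dropped:
            logger.info("merge_cohort: collapsed %d duplicate record(s) "
                        "keeping highest depth", n_dropped)

    ids = list(sample_ids) if sample_ids is not None else blood_order
    bad = [b for b in paired_map if b not in ids]
    if bad:
        raise ConfigError(f"paired_map keys not in blood samples: {bad}")
    return CohortTable(df.reset_index(drop=True), ids, paired_map).sort_canonical()


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, blood_vcf_path[, paired_vcf_path]."""
    if not os.path.exists(path):
        raise InputError(f"sample sheet not found: {path}")
    sheet = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    sheet.columns = [c.lstrip("#") for c in sheet.columns]
    required = {"sample_id", "blood_vcf_path"}
    if not required.issubset(sheet.columns):
        raise InputError(
            f"sample sheet must have columns {sorted(required)}; "
            f"got {list(sheet.columns)}")
    if "paired_vcf_path" not in sheet.columns:
        sheet["paired_vcf_path"] = None
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ConfigError(f"duplicate sample_id in sheet: {dups}")
    for i, row in sheet.iterrows():
        if not isinstance(row["sample_id"], str) or not row["sample_id"]:
            raise InputError(f"sample sheet row {i + 1}: missing sample_id")
        if not isinstance(row["blood_vcf_path"], str) or not row["blood_vcf_path"]:
            raise InputError(
                f"sample sheet row {i + 1} ({row['sample_id']}): "
                "missing blood_vcf_path")
    return sheet
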