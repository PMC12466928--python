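"""Seeded synthetic cohorts with the statistical structure the filters assume.

Each sample's blood VCF mixes four record classes:

``ch``
    True clonal-hematopoiesis variants: per-sample Poisson counts, VAF drawn
    uniformly on [vaf_floor, 0.2] (clones are subclonal, never dominant),
    balanced strands, driver-gene annotations, absent from germline
    databases.
``germline``
    Heterozygous inherited variants at VAF ~ 0.5 (binomial read sampling),
    carrying gnomAD frequencies and dbSNP ids.
``artifact``
    Recurrent low-VAF strand-skewed errors at a fixed set of loci, each with
    a per-locus cohort occurrence probability.  Their VAF ceiling sits below
    the CH VAF floor by default (separability is the point of the fixture),
    and occurrence probabilities straddle the prevalence cutoff so that
    full-cohort and subset prevalence filtering can disagree — the
    partition-sensitive behaviour the permutation analysis detects.
``contamination`` (paired mode)
    Tumor-derived variants leaking into blood as cell-free DNA: high VAF in
    the paired tumor sample, trace VAF in blood.

Read counts are binomial given a negative-binomial per-site depth; only
fields the filters actually read are synthesised.  TLOD is a monotone
function of alt depth with noise — enough to exercise the threshold, with
no claim of caller fidelity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import (AnnotationBundle, CohortTable, VariantRecord,
                        TISSUE_BLOOD, TISSUE_PAIRED, merge_cohort)
from .errors import ConfigError

_BASES = np.array(list("ACGT"))

#: (gene, chrom, base position) for the panel; CH driver genes first.
_GENE_FOOTPRINTS = [
    ("DNMT3A", "chr2", 25_234_300),
    ("TET2", "chr4", 105_233_900),
    ("ASXL1", "chr20", 32_358_000),
    ("TP53", "chr17", 7_571_700),
    ("JAK2", "chr9", 5_021_900),
    ("PPM1D", "chr17", 60_600_100),
    ("SF3B1", "chr2", 197_389_700),
    ("SRSF2", "chr17", 76_736_800),
]

_DEPTH_MEANS = {"wes": 150.0, "ultradeep": 5000.0}


@dataclass
class SimParams:
    """Cohort-level simulation settings (all rates are per sample)."""

    n_samples: int = 100
    depth_mode: str = "wes"            # "wes" (~150x) or "ultradeep" (~5000x)
    depth_dispersion: float = 0.3      # NB overdispersion: var = m + disp*m^2
    n_loci: int = 300                  # panel size
    ch_rate: float = 2.0               # Poisson mean of true CH per sample
    ch_vaf_floor: float = 0.02
    ch_vaf_max: float = 0.2
    artifact_loci: int = 15
    artifact_vaf_floor: float = 0.004
    artifact_vaf_ceiling: float = 0.015
    artifact_occurrence: float | tuple[float, float] = (0.05, 0.12)
    artifact_strand_skew: float = 0.65  # major-strand fraction of alt reads
    germline_rate: float = 3.0
    contamination_rate: float = 1.0    # paired mode only
    paired: bool = False
    seed: int = 0
    enforce_separability: bool = True  # artifact VAFs stay below the CH floor

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.depth_mode not in _DEPTH_MEANS:
            raise ConfigError(f"depth_mode must be one of {list(_DEPTH_MEANS)}")
        if self.n_loci < self.artifact_loci:
            raise ConfigError("n_loci must be >= artifact_loci")
        if (self.enforce_separability
                and self.artifact_vaf_ceiling >= self.ch_vaf_floor):
            raise ConfigError(
                "artifact VAF ceiling must lie below the CH VAF floor "
                "(set enforce_separability=False to allow overlap)")
        occ = self.artifact_occurrence
        lo, hi = (occ, occ) if np.isscalar(occ) else occ
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("artifact_occurrence must lie in (0, 1)")
        if not (0.0 < self.artifact_strand_skew < 1.0):
            raise ConfigError("artifact_strand_skew must lie in (0, 1)")

    @property
    def depth_mean(self) -> float:
        return _DEPTH_MEANS[self.depth_mode]


@dataclass
class _Locus:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str


def _build_panel(params: SimParams, rng: np.random.Generator) -> list[_Locus]:
    loci = []
    for i in range(params.n_loci):
        gene, chrom, base = _GENE_FOOTPRINTS[i % len(_GENE_FOOTPRINTS)]
        pos = base + 3 * (i // len(_GENE_FOOTPRINTS))
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice(_BASES[_BASES != ref]))
        loci.append(_Locus(chrom, pos, ref, alt, gene))
    return loci


def _draw_depth(params: SimParams, rng: np.random.Generator, n: int) -> np.ndarray:
    m = params.depth_mean
    disp = params.depth_dispersion
    if disp <= 0:
        return np.maximum(1, rng.poisson(m, size=n))
    r = 1.0 / disp
    p = r / (r + m)
    return np.maximum(1, rng.negative_binomial(r, p, size=n))


def _tlod(rng: np.random.Generator, alt_ad: int) -> float:
    return float(max(0.0, rng.normal(1.8 * alt_ad, 1.0)))


def _split_strands(rng: np.random.Generator, alt_ad: int, dp: int,
                   skew: float = 0.5, forward_major: bool = True,
                   ) -> tuple[int, int, int, int]:
    major = int(rng.binomial(alt_ad, skew))
    saf, sar = (major, alt_ad - major) if forward_major else (alt_ad - major, major)
    ref_fw = int(rng.binomial(dp - alt_ad, 0.5))
    return ref_fw, (dp - alt_ad) - ref_fw, saf, sar


def _record(rng, sample_id, tissue, locus, vaf_true, dp, skew=0.5,
            forward_major=True, ann=None):
    alt_ad = int(rng.binomial(dp, vaf_true))
    if alt_ad == 0:
        return None
    ref_fw, ref_rv, saf, sar = _split_strands(rng, alt_ad, dp, skew,
                                              forward_major)
    return VariantRecord(
        sample_id=sample_id, tissue=tissue, chrom=locus.chrom, pos=locus.pos,
        ref=locus.ref, alt=locus.alt, vaf=alt_ad / dp, dp=int(dp),
        alt_ad=alt_ad, saf=saf, sar=sar, ref_fw=ref_fw, ref_rv=ref_rv,
        sor=None, tlod=_tlod(rng, alt_ad),
        annotations=ann or AnnotationBundle())


def simulate_cohort(params: SimParams,
                    ) -> tuple[dict[str, dict[str, list[VariantRecord]]],
                               pd.DataFrame]:
    """Simulate per-sample record collections plus the ground-truth table.

    Returns ``(records, truth)`` where ``records[sample_id][tissue]`` is a
    list of :class:`VariantRecord` and ``truth`` has one row per emitted
    record (sample_id, tissue, chrom, pos, ref, alt, class, sim_vaf,
    sim_dp).  Fully deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    panel = _build_panel(params, rng)
    artifact_sites = panel[:params.artifact_loci]
    remaining = panel[params.artifact_loci:]
    n_germ_pool = max(1, min(len(remaining) // 4, 45))
    germ_pool = remaining[:n_germ_pool]
    ch_pool = remaining[n_germ_pool:]
    if not ch_pool:
        raise ConfigError("panel too small: no loci left for CH variants")

    occ = params.artifact_occurrence
    if np.isscalar(occ):
        art_occ = np.full(len(artifact_sites), float(occ))
    else:
        art_occ = rng.uniform(occ[0], occ[1], size=len(artifact_sites))
    art_forward_major = rng.random(len(artifact_sites)) < 0.5
    germ_gnomad = rng.uniform(0.01, 0.5, size=len(germ_pool))
    germ_carrier_p = min(1.0, params.germline_rate / len(germ_pool))

    sample_ids = [f"S{i + 1:04d}" for i in range(params.n_samples)]
    records: dict[str, dict[str, list[VariantRecord]]] = {}
    truth_rows = []

    def emit(owner: str, rec: VariantRecord | None, cls: str,
             sim_vaf: float, dp: int):
        if rec is None:
            return
        records[owner].setdefault(rec.tissue, []).append(rec)
        truth_rows.append((rec.sample_id, rec.tissue, rec.chrom, rec.pos,
                           rec.ref, rec.alt, cls, sim_vaf, dp))

    effect_choices = np.array(["nonsynonymous SNV", "stopgain",
                               "frameshift insertion", "synonymous SNV"])
    effect_p = np.array([0.7, 0.1, 0.1, 0.1])

    for si, sid in enumerate(sample_ids):
        records[sid] = {TISSUE_BLOOD: []}
        pair_id = f"{sid}_T"
        if params.paired:
            records[sid][TISSUE_PAIRED] = []
        used_ch_loci: set[int] = set()

        # -- true CH -------------------------------------------------------
        n_ch = rng.poisson(params.ch_rate)
        ch_idx = rng.choice(len(ch_pool), size=min(n_ch, len(ch_pool)),
                            replace=False)
        for li in ch_idx:
            used_ch_loci.add(int(li))
            locus = ch_pool[li]
            vaf = float(rng.uniform(params.ch_vaf_floor, params.ch_vaf_max))
            dp = int(_draw_depth(params, rng, 1)[0])
            ann = AnnotationBundle(
                exonic_function=str(rng.choice(effect_choices, p=effect_p)),
                gene=locus.gene,
                cosmic_id=(f"COSM{li + 10000}" if rng.random() < 0.5 else None))
            emit(sid, _record(rng, sid, TISSUE_BLOOD, locus, vaf, dp,
                              ann=ann), "ch", vaf, dp)
            if params.paired:
                t_dp = int(_draw_depth(params, rng, 1)[0])
                t_rec = _record(rng, pair_id, TISSUE_PAIRED, locus, 0.002,
                                t_dp, ann=ann)
                emit(sid, t_rec, "ch", 0.002, t_dp)

        # -- germline heterozygotes ---------------------------------------
        carried = np.flatnonzero(rng.random(len(germ_pool)) < germ_carrier_p)
        for li in carried:
            locus = germ_pool[li]
            dp = int(_draw_depth(params, rng, 1)[0])
            ann = AnnotationBundle(
                exonic_function="nonsynonymous SNV", gene=locus.gene,
                gnomad_af=float(germ_gnomad[li]),
                dbsnp_id=f"rs{li + 500000}")
            emit(sid, _record(rng, sid, TISSUE_BLOOD, locus, 0.5, dp,
                              ann=ann), "germline", 0.5, dp)
            if params.paired:
                t_dp = int(_draw_depth(params, rng, 1)[0])
                emit(sid, _record(rng, pair_id, TISSUE_PAIRED, locus, 0.5,
                                  t_dp, ann=ann), "germline", 0.5, t_dp)

        # -- recurrent strand-skewed artifacts ----------------------------
        hit = np.flatnonzero(rng.random(len(artifact_sites)) < art_occ)
        for li in hit:
            locus = artifact_sites[li]
            vaf = float(rng.uniform(params.artifact_vaf_floor,
                                    params.artifact_vaf_ceiling))
            dp = int(_draw_depth(params, rng, 1)[0])
            ann = AnnotationBundle(exonic_function="nonsynonymous SNV",
                                   gene=locus.gene)
            emit(sid, _record(rng, sid, TISSUE_BLOOD, locus, vaf, dp,
                              skew=params.artifact_strand_skew,
                              forward_major=bool(art_forward_major[li]),
                              ann=ann), "artifact", vaf, dp)

        # -- tumor cfDNA contamination of blood (paired mode) -------------
        if params.paired and params.contamination_rate > 0:
            n_cont = rng.poisson(params.contamination_rate)
            free = [i for i in range(len(ch_pool)) if i not in used_ch_loci]
            cont_idx = rng.choice(free, size=min(n_cont, len(free)),
                                  replace=False) if free else []
            for li in cont_idx:
                locus = ch_pool[li]
                b_vaf = float(rng.uniform(0.001, 0.01))
                t_vaf = float(rng.uniform(0.2, 0.6))
                dp = int(_draw_depth(params, rng, 1)[0])
                t_dp = int(_draw_depth(params, rng, 1)[0])
                ann = AnnotationBundle(
                    exonic_function="nonsynonymous SNV", gene=locus.gene,
                    cosmic_id=(f"COSM{li + 20000}"
                               if rng.random() < 0.7 else None))
                emit(sid, _record(rng, sid, TISSUE_BLOOD, locus, b_vaf,
                                  dp, ann=ann), "contamination", b_vaf, dp)
                emit(sid, _record(rng, pair_id, TISSUE_PAIRED, locus,
                                  t_vaf, t_dp, ann=ann),
                     "contamination", t_vaf, t_dp)

    truth = pd.DataFrame(truth_rows, columns=[
        "sample_id", "tissue", "chrom", "pos", "ref", "alt", "class",
        "sim_vaf", "sim_dp"])
    return records, truth


def cohort_table_from_records(
        records: Mapping[str, Mapping[str, list[VariantRecord]]],
        paired: bool = False) -> CohortTable:
    """Merge simulated records into a :class:`CohortTable`."""
    collections = []
    paired_map = {}
    sample_ids = list(records)
    for sid, tissues in records.items():
        collections.append(tissues.get(TISSUE_BLOOD, []))
        if paired and TISSUE_PAIRED in tissues:
            collections.append(tissues[TISSUE_PAIRED])
            if tissues[TISSUE_PAIRED]:
                paired_map[sid] = tissues[TISSUE_PAIRED][0].sample_id
    return merge_cohort(collections, paired_map=paired_map,
                        sample_ids=sample_ids)


def simulate_cohort_table(params: SimParams) -> tuple[CohortTable, pd.DataFrame]:
    """Convenience wrapper: simulate and merge in one step."""
    records, truth = simulate_cohort(params)
    return cohort_table_from_records(records, paired=params.paired), truth


def truth_call_set(truth: pd.DataFrame, cls: str = "ch"):
    """Ground-truth (sample, variant key) pairs of one class (blood only)."""
    sub = truth[(truth["class"] == cls) & (truth["tissue"] == TISSUE_BLOOD)]
    return {(r.sample_id, (r.chrom, int(r.pos), r.ref, r.alt))
            for r in sub.itertuples(index=False)}


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
{contigs}\
##INFO=<ID=TLOD,Number=A,Type=Float,Description="Log odds that the variant exists">
##INFO=<ID=Gene.refGene,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=ExonicFunc.refGene,Number=1,Type=String,Description="Exonic function">
##INFO=<ID=gnomAD_exome_ALL,Number=1,Type=String,Description="gnomAD exome allele frequency">
##INFO=<ID=avsnp150,Number=1,Type=String,Description="dbSNP id">
##INFO=<ID=cosmic70,Number=1,Type=String,Description="COSMIC id">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=SB,Number=4,Type=Integer,Description="Per-sample strand counts: ref-fw,ref-rv,alt-fw,alt-rv">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

_CONTIG_LENGTHS = {"chr2": 243_199_373, "chr4": 191_154_276,
                   "chr9": 141_213_431, "chr17": 81_195_210,
                   "chr20": 63_025_520}


def _vcf_line(rec: VariantRecord) -> str:
    a = rec.annotations
    info = [f"TLOD={rec.tlod:.4g}" if rec.tlod is not None else None,
            f"Gene.refGene={a.gene}" if a.gene else None,
            (f"ExonicFunc.refGene={a.exonic_function.replace(' ', '_')}"
             if a.exonic_function else None),
            (f"gnomAD_exome_ALL={a.gnomad_af:.6g}"
             if a.gnomad_af is not None else None),
            f"avsnp150={a.dbsnp_id}" if a.dbsnp_id else None,
            f"cosmic70={a.cosmic_id}" if a.cosmic_id else None]
    info_str = ";".join(x for x in info if x) or "."
    fmt_vals = [
        "0/1",
        f"{rec.dp - rec.alt_ad},{rec.alt_ad}",
        f"{rec.vaf:.6g}",
        str(rec.dp),
        f"{rec.ref_fw},{rec.ref_rv},{rec.saf},{rec.sar}",
    ]
    return "\t".join([rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".",
                      ".", info_str, "GT:AD:AF:DP:SB",
                      ":".join(fmt_vals)]) + "\n"


def write_cohort_vcfs(
        records: Mapping[str, Mapping[str, list[VariantRecord]]],
        out_dir: str | os.PathLike,
        truth: pd.DataFrame | None = None) -> str:
    """Write one VCF per sample per tissue plus a sample sheet (and truth).

    Returns the sample sheet path.  Files are valid VCF 4.2 with the
    FORMAT/INFO keys the default annotation schema expects, and parse
    cleanly back through :func:`clonalqc.cohort_io.parse_vcf`.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    chrom_order = {c: i for i, c in enumerate(_CONTIG_LENGTHS)}
    sheet_rows = []
    for sid, tissues in records.items():
        paths = {}
        for tissue, recs in tissues.items():
            vcf_sample = recs[0].sample_id if recs else (
                sid if tissue == TISSUE_BLOOD else f"{sid}_T")
            fname = os.path.join(out_dir, f"{vcf_sample}.{tissue}.vcf")
            contigs = "".join(
                f"##contig=<ID={c},length={ln}>\n"
                for c, ln in _CONTIG_LENGTHS.items())
            with open(fname, "w") as fh:
                fh.write(_VCF_HEADER_TEMPLATE.format(contigs=contigs,
                                                     sample=vcf_sample))
                for rec in sorted(recs, key=lambda r: (
                        chrom_order.get(r.chrom, 99), r.pos, r.ref, r.alt)):
                    fh.write(_vcf_line(rec))
            paths[tissue] = fname
        sheet_rows.append((sid, paths.get(TISSUE_BLOOD, ""),
                           paths.get(TISSUE_PAIRED, "")))
    sheet_path = os.path.join(out_dir, "sample_sheet.tsv")
    with open(sheet_path, "w") as fh:
        fh.write("sample_id\tblood_vcf_path\tpaired_vcf_path\n")
        for row in sheet_rows:
            fh.write("\t".join(row) + "\n")
    if truth is not None:
        truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    return sheet_path
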