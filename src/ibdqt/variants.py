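"""Sequence-region variant QC, CADD-based deleteriousness, and marker-level GWAS QC.

Two filter tiers are implemented:

* region filter (whole-genome-sequence variants at a mapped locus): drop
  variants with no variation (MAF = 0), more than two alleles, or a missing
  genotype rate strictly above 15 %;
* marker QC (array genotypes): drop markers with missing rate >= 5 %,
  MAF <= 1 %, MAF <= 5 % combined with missing rate >= 1 %, or a
  Hardy-Weinberg exact-test p-value < 1e-4.

Boundary conventions follow that wording literally: "more than 15 %" is a
strict inequality, "5 % or greater" and "1 % or less" are inclusive.  MAF is
always computed on non-missing genotypes.  Retained region variants with a
CADD scaled score strictly above 20 (roughly the top 1 % most deleterious
substitutions genome-wide) are classified deleterious; the deleterious set,
the phenotype vector, and the covariate matrix are exported aligned by
individual for an external kernel association test (e.g. SKAT-O).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IbdqtError
from .phenotype import adjust_dbp, pc_columns

__all__ = [
    "VariantRecord",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "filter_region_variants",
    "classify_deleterious",
    "hwe_exact_p",
    "marker_qc",
    "export_kernel_inputs",
    "read_cadd_table",
]


@dataclass
class VariantRecord:
    """One VCF variant with per-individual alternate-allele dosages.

    ``genotypes`` holds 0/1/2 alt-allele counts with NaN for missing calls;
    ``alts`` may list several alternate alleles (such variants fail QC).
    ``cadd_scaled`` is attached by :func:`classify_deleterious`.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: np.ndarray
    cadd_scaled: float | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, ",".join(self.alts))

    @property
    def missing_rate(self) -> float:
        return float(np.isnan(self.genotypes).mean())

    @property
    def maf(self) -> float:
        """Minor allele frequency over non-missing genotypes (nan if all missing)."""
        g = self.genotypes[~np.isnan(self.genotypes)]
        if g.size == 0:
            return np.nan
        f = g.sum() / (2 * g.size)
        return float(min(f, 1 - f))


@dataclass
class FilterReport:
    """Per-rule exclusion counts; reconciles exactly with the input size."""

    input_count: int = 0
    excluded: dict = field(default_factory=dict)
    retained_count: int = 0
    deleterious_count: int = 0

    @property
    def excluded_count(self) -> int:
        return sum(self.excluded.values())

    def check(self) -> None:
        if self.excluded_count + self.retained_count != self.input_count:
            raise IbdqtError("filter report does not reconcile with input count")


def read_vcf(path, region: tuple[str, int, int] | None = None):
    """Read a VCF into (sample ids, list of VariantRecord) via cyvcf2.

    ``region`` is an optional inclusive (chrom, start_bp, end_bp) window.
    Genotype coding: 0 hom-ref, 1 het, 2 hom-alt, NaN missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    dosage_of = np.array([0.0, 1.0, np.nan, 2.0])
    records = []
    for v in vcf:
        if region is not None:
            chrom, start, end = region
            if v.CHROM != chrom or not (start <= v.POS <= end):
                continue
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                genotypes=dosage_of[v.gt_types],
            )
        )
    vcf.close()
    return samples, records


def write_vcf(samples, records, path, contig: str | None = None) -> None:
    """Write VariantRecords as a minimal uncompressed VCF v4.2 (GT only)."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for rec in records:
            gts = "\t".join(
                "./." if math.isnan(g) else gt_of[float(g)] for g in rec.genotypes
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{','.join(rec.alts)}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def filter_region_variants(variants) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the sequence-region QC: multi-allelic, MAF = 0, missing > 15 %.

    Multi-allelic exclusion is applied first (MAF is undefined under the
    0/1/2 coding for >2 alleles); attribution of an exclusion is to the first
    rule triggered.  Empty input yields an empty output and a zeroed report.
    """
    report = FilterReport(input_count=len(variants))
    report.excluded = {"multiallelic": 0, "monomorphic": 0, "missing_gt_15pct": 0}
    retained = []
    for v in variants:
        if len(v.alts) > 1:
            report.excluded["multiallelic"] += 1
        elif not v.maf > 0:  # MAF 0 or undefined (all calls missing)
            report.excluded["monomorphic"] += 1
        elif v.missing_rate > 0.15:
            report.excluded["missing_gt_15pct"] += 1
        else:
            retained.append(v)
    report.retained_count = len(retained)
    report.check()
    return retained, report


def read_cadd_table(path) -> pd.DataFrame:
    """Read a CADD score TSV: chrom, pos, ref, alt, scaled score."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = {"chrom", "pos", "ref", "alt", "cadd_scaled"}
    if not expected.issubset(table.columns):
        raise IbdqtError(f"CADD table must have columns {sorted(expected)}")
    return table


def classify_deleterious(
    variants, cadd: pd.DataFrame, threshold: float = 20.0
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Attach CADD scaled scores and return (deleterious, unmatched).

    Scores are joined by (chrom, pos, ref, alt); a variant is deleterious when
    its scaled score is strictly above ``threshold`` (default 20, i.e. the
    top 1 % genome-wide).  Duplicate score rows for one variant raise;
    variants without a score are returned in ``unmatched`` (and are never
    called deleterious).
    """
    keys = list(zip(cadd["chrom"].astype(str), cadd["pos"], cadd["ref"], cadd["alt"]))
    if len(keys) != len(set(keys)):
        seen, dupes = set(), set()
        for k in keys:
            (dupes if k in seen else seen).add(k)
        raise IbdqtError(f"duplicate CADD rows for variants: {sorted(dupes)[:5]}")
    score_of = dict(zip(keys, cadd["cadd_scaled"].astype(float)))

    deleterious, unmatched = [], []
    for v in variants:
        k = (v.chrom, v.pos, v.ref, ",".join(v.alts))
        if k not in score_of:
            unmatched.append(v)
            continue
        v.cadd_scaled = float(score_of[k])
        if v.cadd_scaled > threshold:
            deleterious.append(v)
    return deleterious, unmatched


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value from genotype counts.

    The conditional distribution of the heterozygote count given the allele
    counts is enumerated exactly and the p-value sums the probabilities of
    all configurations no more likely than the observed one (the standard
    exact-test convention, no mid-p correction).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise IbdqtError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    # possible heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalised log-probabilities of the conditional distribution
    from scipy.special import gammaln

    n_rare_hom = (n_rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        hets * math.log(2)
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_common_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    observed = prob[hets == n_het]
    if observed.size == 0:
        raise IbdqtError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, prob[prob <= observed[0] * (1 + 1e-12)].sum()))


def _genotype_counts(genotypes: np.ndarray) -> tuple[int, int, int]:
    g = genotypes[~np.isnan(genotypes)]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def marker_qc(genotypes: np.ndarray, hwe_alpha: float = 1e-4):
    """Marker-level GWAS QC on a variants x samples dosage matrix.

    Rules, applied in order with first-triggered attribution:
    missing rate >= 5 %; MAF <= 1 %; MAF <= 5 % AND missing rate >= 1 %;
    HWE exact p < ``hwe_alpha``.  Returns (boolean retain mask, FilterReport).
    """
    genotypes = np.asarray(genotypes, dtype=float)
    if genotypes.ndim != 2:
        raise IbdqtError("expected a 2-D variants x samples matrix")
    n_var = genotypes.shape[0]
    report = FilterReport(input_count=n_var)
    report.excluded = {
        "missing_ge_5pct": 0,
        "maf_le_1pct": 0,
        "maf_le_5pct_and_missing_ge_1pct": 0,
        "hwe_p_lt_1e-4": 0,
    }
    keep = np.ones(n_var, dtype=bool)
    for i in range(n_var):
        row = genotypes[i]
        missing = float(np.isnan(row).mean())
        g = row[~np.isnan(row)]
        if missing >= 0.05:
            report.excluded["missing_ge_5pct"] += 1
            keep[i] = False
            continue
        freq = g.sum() / (2 * g.size) if g.size else np.nan
        maf = min(freq, 1 - freq) if np.isfinite(freq) else 0.0
        if maf <= 0.01:
            report.excluded["maf_le_1pct"] += 1
            keep[i] = False
            continue
        if maf <= 0.05 and missing >= 0.01:
            report.excluded["maf_le_5pct_and_missing_ge_1pct"] += 1
            keep[i] = False
            continue
        if hwe_exact_p(*_genotype_counts(row)) < hwe_alpha:
            report.excluded["hwe_p_lt_1e-4"] += 1
            keep[i] = False
    report.retained_count = int(keep.sum())
    report.check()
    return keep, report


def export_kernel_inputs(
    variants, vcf_samples, phenotypes: pd.DataFrame, out_dir, n_pcs: int = 3
) -> dict[str, str]:
    """Write aligned genotype / phenotype / covariate matrices for SKAT-O.

    Rows are the individuals present in both the VCF and the phenotype table
    (in phenotype-table order); the covariates are gender, age, smoking and
    the first ``n_pcs`` principal components.  The phenotype exported is the
    treatment-adjusted DBP (the kernel test fits covariates itself).
    """
    if not variants:
        raise IbdqtError("no variants to export: the deleterious set is empty")
    shared = [s for s in phenotypes["id"] if s in set(vcf_samples)]
    if not shared:
        raise IbdqtError("no individuals shared between VCF and phenotype table")
    col_of = {s: i for i, s in enumerate(vcf_samples)}
    sample_cols = [col_of[s] for s in shared]

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno = pd.DataFrame(
        {f"{v.chrom}:{v.pos}:{v.ref}:{','.join(v.alts)}": v.genotypes[sample_cols] for v in variants},
        index=pd.Index(shared, name="id"),
    )
    pheno = phenotypes.set_index("id").loc[shared]
    pcs = pc_columns(phenotypes)[:n_pcs]
    covar = pheno[["gender", "age", "smoking", *pcs]].astype(float)
    trait = pd.Series(
        adjust_dbp(pheno["dbp"].to_numpy(), pheno["treated"].to_numpy()),
        index=pheno.index, name="adjusted_dbp",
    )

    paths = {
        "genotypes": str(out / "kernel_genotypes.tsv"),
        "phenotype": str(out / "kernel_phenotype.tsv"),
        "covariates": str(out / "kernel_covariates.tsv"),
    }
    geno.to_csv(paths["genotypes"], sep="\t", float_format="%.10g")
    trait.to_frame().to_csv(paths["phenotype"], sep="\t", float_format="%.10g")
    covar.to_csv(paths["covariates"], sep="\t", float_format="%.10g")
    return paths
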