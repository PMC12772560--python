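"""Recessive rare-variant collapsing burden test.

Qualifying variants (rare, protein-altering) are collapsed per individual
under a recessive model: a person carries the "affected" genotype when they
are homozygous for one qualifying variant or carry two distinct qualifying
variants (compound heterozygote, called without phase). Carrier status is
then tested against case/control labels with a two-sided Fisher's exact
test; the odds ratio is the sample OR with a Woolf (logit) 95% CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QualifyingVariantRule",
    "ContingencyTable2x2",
    "BurdenResult",
    "qualify_variants",
    "collapse_recessive",
    "genotypes_from_vcf",
    "fisher_burden",
    "read_annotation",
    "read_phenotypes",
]

NONSYNONYMOUS = frozenset({"missense", "stop_gained", "frameshift", "splice"})


@dataclass
class QualifyingVariantRule:
    """Filter defining which variants count toward the recessive burden:
    protein-altering consequence and rare (strictly below the MAF ceilings)
    in BOTH the analysis cohort and the external reference."""

    consequence_classes: frozenset = NONSYNONYMOUS
    maf_cohort_max: float = 0.0005
    maf_reference_max: float = 0.0005

    def __post_init__(self):
        for v in (self.maf_cohort_max, self.maf_reference_max):
            if not (0.0 < v < 1.0):
                raise ValueError("MAF thresholds must be in (0, 1)")


@dataclass
class ContingencyTable2x2:
    """Carrier-genotype by disease-status counts: a = carrier cases,
    b = non-carrier cases, c = carrier controls, d = non-carrier controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass
class BurdenResult:
    table: ContingencyTable2x2
    fisher_p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool = False


def qualify_variants(variants: pd.DataFrame,
                     rule: QualifyingVariantRule = QualifyingVariantRule(),
                     ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Filter an annotation table (columns ``variant_id``, ``consequence``,
    ``maf_cohort``, ``maf_reference``) to qualifying variants.

    Both MAF comparisons are strict; a variant missing its reference
    frequency cannot be shown rare in both sources and is excluded
    (conservative). Returns the qualifying subset and an exclusion log.
    """
    log: list[tuple[str, str]] = []
    keep_idx = []
    for idx, row in variants.iterrows():
        vid = str(row["variant_id"])
        if row["consequence"] not in rule.consequence_classes:
            log.append((vid, "consequence_not_qualifying"))
            continue
        maf_ref = row.get("maf_reference")
        if maf_ref is None or (isinstance(maf_ref, float) and math.isnan(maf_ref)):
            log.append((vid, "missing_reference_maf"))
            continue
        if not (float(row["maf_cohort"]) < rule.maf_cohort_max):
            log.append((vid, "cohort_maf_too_high"))
            continue
        if not (float(maf_ref) < rule.maf_reference_max):
            log.append((vid, "reference_maf_too_high"))
            continue
        keep_idx.append(idx)
    return variants.loc[keep_idx], log


def collapse_recessive(genotypes: np.ndarray) -> np.ndarray:
    """Collapse a (samples x qualifying-variants) matrix of allele counts
    {0, 1, 2; negative = missing} to a per-sample boolean carrier-genotype
    indicator: homozygous for any qualifying variant, or heterozygous for
    two or more distinct qualifying variants. Missing calls count as 0."""
    g = np.asarray(genotypes)
    if g.ndim == 1:
        g = g[:, None]
    g = np.where(g < 0, 0, g)
    hom = (g == 2).any(axis=1)
    comphet = (g >= 1).sum(axis=1) >= 2
    return hom | comphet


def genotypes_from_vcf(vcf_path, variant_ids=None,
                       require_pass: bool = True):
    """Read biallelic GT calls from a VCF into a (samples x variants)
    allele-count matrix (-1 for missing), using the upstream FILTER column
    as the quality gate (non-PASS rows are skipped when ``require_pass``).

    Returns (matrix, sample_ids, variant_ids_in_order).
    """
    from cyvcf2 import VCF

    wanted = set(variant_ids) if variant_ids is not None else None
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    cols, ids = [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if wanted is not None and vid not in wanted:
            continue
        if require_pass and rec.FILTER is not None:  # cyvcf2: None == PASS
            continue
        if len(rec.ALT) != 1:
            continue
        gt = rec.gt_types  # 0=hom_ref, 1=het, 2=hom_alt? (cyvcf2: 3=hom_alt)
        counts = np.select(
            [gt == 0, gt == 1, gt == 3, gt == 2],
            [0, 1, 2, -1], default=-1)
        cols.append(counts)
        ids.append(vid)
    vcf.close()
    if cols:
        mat = np.stack(cols, axis=1)
    else:
        mat = np.zeros((len(samples), 0), dtype=int)
    return mat, samples, ids


def fisher_burden(carrier: np.ndarray, phenotype: np.ndarray) -> BurdenResult:
    """Two-sided Fisher's exact test of carrier-genotype status against
    case/control labels.

    The two-sided p sums hypergeometric point probabilities not exceeding
    the observed table's. The odds ratio is the sample OR ad/bc with a Woolf
    95% CI, exp(ln OR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d)); when any cell
    is zero the Haldane-Anscombe 0.5 continuity correction is applied to
    the OR and CI (never to the p-value).
    """
    carrier = np.asarray(carrier, bool)
    case = np.asarray(phenotype, bool)
    if carrier.shape != case.shape:
        raise ValueError("carrier and phenotype vectors differ in length")
    if case.all() or (~case).all():
        raise ValueError("need at least one case and one control")
    table = ContingencyTable2x2(
        a=int((carrier & case).sum()), b=int((~carrier & case).sum()),
        c=int((carrier & ~case).sum()), d=int((~carrier & ~case).sum()))
    return fisher_from_table(table)


def fisher_from_table(table: ContingencyTable2x2) -> BurdenResult:
    a, b, c, d = table.a, table.b, table.c, table.d
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    p = min(p, 1.0)
    corrected = min(a, b, c, d) == 0
    if corrected:
        af, bf, cf, df_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        af, bf, cf, df_ = float(a), float(b), float(c), float(d)
    or_ = (af * df_) / (bf * cf)
    half = 1.96 * math.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df_)
    return BurdenResult(table=table, fisher_p=p, odds_ratio=or_,
                        ci_low=or_ * math.exp(-half),
                        ci_high=or_ * math.exp(half),
                        haldane_corrected=corrected)


def read_annotation(path) -> pd.DataFrame:
    """Annotation TSV: variant_id, consequence, maf_cohort, maf_reference."""
    return pd.read_csv(path, sep="\t", dtype={"variant_id": str})


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV: sample_id, status in {case, control}, phenotype_name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    bad = set(df["status"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown status value(s): {sorted(bad)}")
    return df


def run_burden(vcf_path, phenotype_path, annotation_path,
               rule: QualifyingVariantRule = QualifyingVariantRule(),
               phenotype_name: str | None = None) -> BurdenResult:
    """File-level entry point: qualify variants, collapse genotypes under the
    recessive model, and run the Fisher burden test."""
    ann = read_annotation(annotation_path)
    qual, _ = qualify_variants(ann, rule)
    pheno = read_phenotypes(phenotype_path)
    if phenotype_name is not None:
        pheno = pheno[pheno["phenotype_name"] == phenotype_name]
    mat, samples, ids = genotypes_from_vcf(
        vcf_path, variant_ids=list(qual["variant_id"]))
    order = {s: i for i, s in enumerate(samples)}
    rows = [order[s] for s in pheno["sample_id"]]
    carrier = (collapse_recessive(mat)[rows] if ids
               else np.zeros(len(rows), bool))
    case = (pheno["status"] == "case").to_numpy()
    if not carrier.any():
        # degenerate cohort with no carrier genotypes: report the null table
        table = ContingencyTable2x2(0, int(case.sum()), 0, int((~case).sum()))
        return BurdenResult(table=table, fisher_p=1.0, odds_ratio=float("nan"),
                            ci_low=float("nan"), ci_high=float("nan"))
    return fisher_burden(carrier, case)
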