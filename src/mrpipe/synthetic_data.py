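"""Synthetic GWAS summary statistics, LD tables and diploid cohorts with
known ground truth.

The summary-statistics generator emulates a two-sample MR design: true
SNP-exposure effects are drawn from a normal distribution, observed effects
add sampling noise with SE 1/sqrt(n) (standardised trait scale), and the
outcome effect of each SNP is theta times its true exposure effect plus an
optional pleiotropic effect (balanced around zero, directional with nonzero
mean, or proportional to the exposure effect, which shifts every affected
SNP's Wald ratio by a constant). Positions are laid out in LD blocks with a
constant within-block r-squared and zero r-squared between blocks, giving
clumping tests a known answer.

The cohort generator emulates a rare-variant resequencing study: qualifying
variants at matched rare allele frequencies, Hardy-Weinberg genotypes, and
a recessive penetrance model in which only the carrier genotype (homozygous
or compound heterozygous across qualifying variants) multiplies the disease
odds by psi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .gwas_io import SummaryStatsSet, VariantAssociation
from .instruments import LDTable

__all__ = [
    "SummarySimParams",
    "CohortSimParams",
    "SimulationTruth",
    "simulate_summary_stats",
    "simulate_mvmr_stats",
    "simulate_cohort",
]

# non-palindromic allele pairs only, so no simulated SNP is dropped for
# strand ambiguity unless a test builds one deliberately
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SummarySimParams:
    """Generating parameters for a pair of GWAS summary-statistic sets.

    Defaults describe a well-powered two-sample design: 50 independent
    instruments with strong, tightly distributed effects (mean 0.1, SD 0.02
    on the standardised scale; F around 1000 at n = 100 000) and a causal
    effect of 0.2.
    """

    J: int = 50
    theta: float = 0.2
    effect_mean: float = 0.1
    effect_sd: float = 0.02
    n_exp: float = 100_000.0
    n_out: float = 100_000.0
    pleiotropy: str = "none"          # none | balanced | directional
    pleiotropy_prop: float = 0.0      # pi: fraction of SNPs affected
    pleiotropy_mean: float = 0.0      # mu_alpha (directional only)
    pleiotropy_sd: float = 0.0        # sigma_alpha
    pleiotropy_proportional: bool = False  # alpha_j = mu_alpha * true beta_x_j
    weak_fraction: float = 0.0
    ld_block_size: int = 1
    ld_block_r2: float = 0.0
    seed: int = 0
    noise: bool = True

    def __post_init__(self):
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if not (0.0 <= self.pleiotropy_prop <= 1.0):
            raise ValueError("pleiotropy_prop must be in [0, 1]")
        if self.effect_sd < 0 or self.pleiotropy_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy must be none|balanced|directional")


@dataclass
class CohortSimParams:
    """Generating parameters for a diploid case/control cohort.

    Defaults mirror a biobank-scale recessive burden design: 300 000
    individuals, 50 qualifying variants whose shared allele frequency is
    solved so the recessive carrier-genotype frequency hits 3e-4, disease
    base rate 1e-3, and a carrier-genotype odds ratio of 20.
    """

    N: int = 300_000
    n_variants: int = 50
    carrier_freq: float = 3e-4
    base_rate: float = 1e-3
    psi: float = 20.0
    seed: int = 0
    n_nonqualifying: int = 5   # decoy variants the annotation filter must drop

    def __post_init__(self):
        for v in (self.carrier_freq, self.base_rate):
            if not (0.0 < v < 1.0):
                raise ValueError("frequencies must be in (0, 1)")
        if self.psi <= 0:
            raise ValueError("psi must be > 0")


@dataclass
class SimulationTruth:
    """Every generating parameter and latent draw, for recovery tests."""

    params: object
    seed: int
    true_beta_exp: np.ndarray | None = None
    alpha: np.ndarray | None = None
    allele_freq: float | None = None
    extras: dict = field(default_factory=dict)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def simulate_summary_stats(params: SummarySimParams
                           ) -> tuple[SummaryStatsSet, SummaryStatsSet,
                                      LDTable, SimulationTruth]:
    """Generate matched exposure and outcome summary statistics plus the LD
    table of the block structure. Outputs satisfy every summary-statistics
    invariant and are fully determined by ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    j = params.J
    se_x = np.full(j, 1.0 / math.sqrt(params.n_exp))
    se_y = np.full(j, 1.0 / math.sqrt(params.n_out))

    true_bx = rng.normal(params.effect_mean, params.effect_sd, j)
    if params.weak_fraction > 0:
        n_weak = int(round(params.weak_fraction * j))
        weak_idx = rng.choice(j, size=n_weak, replace=False)
        true_bx[weak_idx] = rng.normal(0.0, se_x[weak_idx] / 2.0)

    alpha = np.zeros(j)
    if params.pleiotropy != "none" and params.pleiotropy_prop > 0:
        n_pl = int(round(params.pleiotropy_prop * j))
        idx = rng.choice(j, size=n_pl, replace=False)
        if params.pleiotropy_proportional:
            alpha[idx] = params.pleiotropy_mean * true_bx[idx]
        else:
            mu = params.pleiotropy_mean if params.pleiotropy == "directional" else 0.0
            alpha[idx] = rng.normal(mu, params.pleiotropy_sd, n_pl)

    true_by = params.theta * true_bx + alpha
    if params.noise:
        obs_bx = true_bx + rng.normal(0.0, se_x)
        obs_by = true_by + rng.normal(0.0, se_y)
    else:
        obs_bx, obs_by = true_bx.copy(), true_by.copy()

    eaf = rng.uniform(0.05, 0.95, j)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), j)

    block = max(1, params.ld_block_size)
    block_id = np.arange(j) // block
    pos = 1_000_000 * (1 + block_id) + 1_000 * (np.arange(j) % block)

    width = len(str(j))
    ids = [f"rs{i + 1:0{width}d}" for i in range(j)]
    px, py = _pvals(obs_bx, se_x), _pvals(obs_by, se_y)

    def make_set(name, beta, se, p, n):
        recs = [VariantAssociation(
            snp_id=ids[i], chrom="1", pos=int(pos[i]),
            effect_allele=_ALLELE_PAIRS[pair_idx[i]][0],
            other_allele=_ALLELE_PAIRS[pair_idx[i]][1],
            eaf=float(eaf[i]), beta=float(beta[i]), se=float(se[i]),
            pval=float(p[i]), n=float(n)) for i in range(j)]
        return SummaryStatsSet(name, recs)

    exposure = make_set("sim_exposure", obs_bx, se_x, px, params.n_exp)
    outcome = make_set("sim_outcome", obs_by, se_y, py, params.n_out)

    ld = LDTable()
    if params.ld_block_r2 > 0 and block > 1:
        for b in range(int(block_id.max()) + 1):
            members = [ids[i] for i in range(j) if block_id[i] == b]
            for i in range(len(members)):
                for k in range(i + 1, len(members)):
                    ld.add(members[i], members[k], params.ld_block_r2)

    truth = SimulationTruth(params=params, seed=params.seed,
                            true_beta_exp=true_bx, alpha=alpha)
    return exposure, outcome, ld, truth


def simulate_mvmr_stats(theta1: float, theta2: float, gamma: float,
                        J: int = 60, effect_mean: float = 0.1,
                        effect_sd: float = 0.02, n: float = 100_000.0,
                        seed: int = 0):
    """Two correlated exposures with known direct effects on one outcome.

    Half the SNPs instrument exposure 1 and half exposure 2; exposure 1
    feeds into exposure 2 with weight ``gamma`` (so exposure 1's marginal
    effect on the outcome is theta1 + gamma * theta2 while its direct effect
    is theta1). Returns (exposure1, exposure2, outcome) summary-statistic
    sets and a truth object whose ``extras`` carry the observed effect
    arrays for direct use in multivariable fits.
    """
    rng = np.random.default_rng(seed)
    half = J // 2
    se = 1.0 / math.sqrt(n)
    bx1_true = np.zeros(J)
    bx1_true[:half] = rng.normal(effect_mean, effect_sd, half)
    own2 = np.zeros(J)
    own2[half:] = rng.normal(effect_mean, effect_sd, J - half)
    bx2_true = gamma * bx1_true + own2
    by_true = theta1 * bx1_true + theta2 * bx2_true
    obs_bx1 = bx1_true + rng.normal(0, se, J)
    obs_bx2 = bx2_true + rng.normal(0, se, J)
    obs_by = by_true + rng.normal(0, se, J)
    se_vec = np.full(J, se)
    eaf = rng.uniform(0.05, 0.95, J)
    width = len(str(J))
    ids = [f"rs{i + 1:0{width}d}" for i in range(J)]

    def make_set(name, beta):
        return SummaryStatsSet(name, [VariantAssociation(
            snp_id=ids[i], chrom="1", pos=1_000_000 * (i + 1),
            effect_allele="A", other_allele="G", eaf=float(eaf[i]),
            beta=float(beta[i]), se=se, pval=float(_pvals(
                np.array([beta[i]]), np.array([se]))[0]), n=n)
            for i in range(J)])

    truth = SimulationTruth(
        params={"theta1": theta1, "theta2": theta2, "gamma": gamma, "J": J},
        seed=seed, true_beta_exp=bx1_true,
        extras={"obs_bx1": obs_bx1, "obs_bx2": obs_bx2, "obs_by": obs_by,
                "se_x1": se_vec.copy(), "se_x2": se_vec.copy(),
                "se_y": se_vec.copy(), "true_bx2": bx2_true})
    return (make_set("sim_exposure1", obs_bx1),
            make_set("sim_exposure2", obs_bx2),
            make_set("sim_outcome", obs_by), truth)


def _solve_allele_freq(carrier_freq: float, m: int) -> float:
    """Shared per-variant allele frequency f such that, under HWE with m
    independent qualifying variants, P(hom or compound het) = carrier_freq.
    Not-carrier means no homozygote and at most one heterozygous variant."""

    def p_carrier(f):
        p0 = (1 - f) ** 2
        p1 = 2 * f * (1 - f)
        not_carrier = p0 ** m + m * p1 * p0 ** (m - 1)
        return 1.0 - not_carrier

    return float(optimize.brentq(
        lambda f: p_carrier(f) - carrier_freq, 1e-9, 0.49))


def _distinct_indices(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct uniform indices in [0, n); rejection sampling is cheap for
    the rare-variant carrier counts involved (k << n)."""
    idx = rng.integers(0, n, k)
    while len(np.unique(idx)) < k:
        kept = np.unique(idx)
        idx = np.concatenate([kept, rng.integers(0, n, k - len(kept))])
    rng.shuffle(idx)
    return idx


def simulate_genotypes(params: CohortSimParams, rng: np.random.Generator):
    """Draw the (N x variants) genotype matrix and disease labels.

    Per variant the hom/het carrier counts are multinomial under HWE and get
    assigned to distinct uniformly chosen individuals — exactly the joint
    law of independent Binomial(2, f) genotypes, but linear in the carrier
    count rather than in N x variants.
    """
    f = _solve_allele_freq(params.carrier_freq, params.n_variants)
    p2 = f * f
    p1 = 2.0 * f * (1.0 - f)
    g = np.zeros((params.N, params.n_variants), dtype=np.int8)
    for v in range(params.n_variants):
        n2 = rng.binomial(params.N, p2)
        n1 = rng.binomial(params.N - n2, p1 / (1.0 - p2))
        if n1 + n2 == 0:
            continue
        idx = _distinct_indices(rng, params.N, n1 + n2)
        g[idx[:n2], v] = 2
        g[idx[n2:], v] = 1
    hom = (g == 2).any(axis=1)
    carrier = hom | ((g >= 1).sum(axis=1) >= 2)
    logit = math.log(params.base_rate / (1 - params.base_rate))
    prob = 1.0 / (1.0 + np.exp(-(logit + math.log(params.psi) * carrier)))
    case = rng.random(params.N) < prob
    return g, carrier, case, f


def simulate_cohort(params: CohortSimParams, out_dir
                    ) -> tuple[str, str, str, SimulationTruth]:
    """Write a VCF, phenotype TSV and annotation TSV for a simulated cohort;
    returns their paths and the generating truth.

    The annotation table includes ``n_nonqualifying`` decoy variants (too
    common, or synonymous) whose genotype columns are all reference, so the
    qualifying-variant filter is exercised end to end.
    """
    import os

    rng = np.random.default_rng(params.seed)
    g, carrier, case, f = simulate_genotypes(params, rng)
    n, m = params.N, params.n_variants
    samples = [f"S{i + 1:06d}" for i in range(n)]

    os.makedirs(out_dir, exist_ok=True)
    vcf_path = os.path.join(out_dir, "cohort.vcf")
    pheno_path = os.path.join(out_dir, "phenotypes.tsv")
    ann_path = os.path.join(out_dir, "annotation.tsv")

    decoys = []
    for i in range(params.n_nonqualifying):
        if i % 2 == 0:
            decoys.append((f"decoy{i + 1}", "synonymous", f, f))
        else:
            decoys.append((f"decoy{i + 1}", "missense", 0.01, 0.01))

    gt_text = np.array(["0/0", "0/1", "1/1"])
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=2>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in range(m):
            row = gt_text[g[:, v]]
            fh.write(f"2\t{136_500_000 + 100 * v}\tqv{v + 1}\tC\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(row) + "\n")
        for i, (vid, _, _, _) in enumerate(decoys):
            fh.write(f"2\t{136_600_000 + 100 * i}\t{vid}\tG\tA\t.\tPASS\t.\tGT\t"
                     + "\t".join(["0/0"] * n) + "\n")

    consequences = rng.choice(["missense", "stop_gained", "frameshift"], m,
                              p=[0.7, 0.2, 0.1])
    with open(ann_path, "w") as fh:
        fh.write("variant_id\tconsequence\tmaf_cohort\tmaf_reference\n")
        for v in range(m):
            maf_cohort = float(g[:, v].sum()) / (2 * n)
            fh.write(f"qv{v + 1}\t{consequences[v]}\t{maf_cohort:.3e}\t{f:.3e}\n")
        for vid, cons, maf_c, maf_r in decoys:
            fh.write(f"{vid}\t{cons}\t{maf_c:.3e}\t{maf_r:.3e}\n")

    with open(pheno_path, "w") as fh:
        fh.write("sample_id\tstatus\tphenotype_name\n")
        for i, s in enumerate(samples):
            fh.write(f"{s}\t{'case' if case[i] else 'control'}\tsim_disease\n")

    truth = SimulationTruth(
        params=params, seed=params.seed, allele_freq=f,
        extras={"carrier": carrier, "case": case,
                "carrier_freq_empirical": float(carrier.mean())})
    return vcf_path, pheno_path, ann_path, truth
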