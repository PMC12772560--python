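"""Instrument selection: p-value thresholding, greedy LD clumping, proxy
substitution, pleiotropy filtering and F-statistics.

All comparisons at quoted boundaries are strict exactly as the filters are
stated: instruments require p < threshold, clumping retains pairs with
r² ≤ the clump cutoff, proxies require r² ≥ the proxy minimum, the
pleiotropy filter removes SNPs with outcome p strictly below exposure p,
and mean F must exceed 10 (strictly) to escape the weak-instruments flag.
Tie-breaking is lexicographic on snp_id throughout so runs are reproducible.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

from .gwas_io import (HarmonizedInstrumentSet, HarmonizedRecord,
                      SummaryStatsSet, VariantAssociation)

__all__ = [
    "LDTable",
    "InstrumentConfig",
    "FStats",
    "select_instruments",
    "clump",
    "resolve_proxies",
    "attach_proxies",
    "pleiotropy_filter",
    "f_statistics",
]


class LDTable:
    """Symmetric pairwise r² lookup; absent pairs read as r² = 0.

    Optionally stores allele phase per pair (``pos``/``neg``): ``neg`` means
    the stated alleles of the two SNPs are anti-correlated, so a proxy's
    outcome effect must be sign-flipped when standing in for its index SNP.
    """

    def __init__(self, entries=()):
        # keyed on sorted snp-id pair
        self._r2: dict[tuple[str, str], float] = {}
        self._phase: dict[tuple[str, str], str] = {}
        for e in entries:
            self.add(*e)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, snp_a: str, snp_b: str, r2: float, phase: str | None = None):
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 out of [0,1] for pair ({snp_a},{snp_b}): {r2}")
        k = self._key(snp_a, snp_b)
        self._r2[k] = r2
        if phase is not None:
            self._phase[k] = phase

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._r2.get(self._key(snp_a, snp_b), 0.0)

    def phase(self, snp_a: str, snp_b: str) -> str | None:
        return self._phase.get(self._key(snp_a, snp_b))

    def partners(self, snp: str) -> list[str]:
        out = []
        for a, b in self._r2:
            if a == snp:
                out.append(b)
            elif b == snp:
                out.append(a)
        return out

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path) -> "LDTable":
        table = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                table.add(row["SNP_A"], row["SNP_B"], float(row["R2"]),
                          row.get("PHASE") or None)
        return table

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["SNP_A", "SNP_B", "R2", "PHASE"])
            for (a, b), r2 in sorted(self._r2.items()):
                w.writerow([a, b, repr(r2), self._phase.get((a, b), "")])


@dataclass
class InstrumentConfig:
    """Thresholds governing instrument selection."""

    p_threshold: float = 5e-8
    clump_window_bp: int = 10_000
    clump_r2: float = 0.001
    proxy_r2_min: float = 0.9
    palindromic_maf: float = 0.42

    def __post_init__(self):
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.clump_window_bp < 0:
            raise ValueError("clump_window_bp must be >= 0")
        for name in ("clump_r2", "proxy_r2_min", "palindromic_maf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


def select_instruments(exposure: SummaryStatsSet,
                       p_threshold: float = 5e-8) -> SummaryStatsSet:
    """Retain records with p strictly below the threshold, order preserved."""
    return exposure.subset([r for r in exposure if r.pval < p_threshold])


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


def clump(candidates: SummaryStatsSet, ld: LDTable,
          window_bp: int = 10_000, r2_max: float = 0.001) -> SummaryStatsSet:
    """Greedy LD clumping: repeatedly index the remaining SNP with the lowest
    p (ties by snp_id), then discard every remaining SNP on the same
    chromosome within ``window_bp`` whose r² with the index exceeds
    ``r2_max``. Retained SNPs are returned sorted by chromosome and position.
    """
    for r in candidates:
        if r.pos is None:
            raise ValueError(f"SNP {r.snp_id} has no position; cannot clump")
    remaining = sorted(candidates, key=lambda r: (r.pval, r.snp_id))
    kept: list[VariantAssociation] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        remaining = [
            r for r in remaining
            if not (r.chrom == index.chrom
                    and abs(r.pos - index.pos) <= window_bp
                    and ld.r2(r.snp_id, index.snp_id) > r2_max)
        ]
    kept.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.pos, r.snp_id))
    return candidates.subset(kept)


def resolve_proxies(missing_snps, outcome: SummaryStatsSet, ld: LDTable,
                    r2_min: float = 0.9) -> dict[str, tuple[str, float]]:
    """For each exposure SNP absent from the outcome, find the
    outcome-present SNP with maximal r² ≥ ``r2_min`` (ties broken
    lexicographically on snp_id). SNPs with no adequate proxy are omitted
    from the returned mapping."""
    subs: dict[str, tuple[str, float]] = {}
    for snp in missing_snps:
        best: tuple[float, str] | None = None
        for cand in ld.partners(snp):
            if cand not in outcome:
                continue
            r2 = ld.r2(snp, cand)
            if r2 < r2_min:
                continue
            # maximise r2; break ties on lexicographically smallest id
            key = (-r2, cand)
            if best is None or key < (-best[0], best[1]):
                best = (r2, cand)
        if best is not None:
            subs[snp] = (best[1], best[0])
    return subs


def attach_proxies(hset: HarmonizedInstrumentSet, exposure: SummaryStatsSet,
                   outcome: SummaryStatsSet, ld: LDTable,
                   r2_min: float = 0.9) -> HarmonizedInstrumentSet:
    """Resolve the set's unmatched SNPs through proxies and append the
    substituted records (flagged ``proxy``).

    The proxy's outcome effect is oriented to the index SNP's exposure
    effect allele using the LD table's phase when stated, else by frequency
    agreement (effect-allele frequencies on the same side of 0.5); without
    either, the written orientation is trusted and flagged.
    """
    missing = hset.unmatched_snp_ids()
    subs = resolve_proxies(missing, outcome, ld, r2_min)
    records = list(hset.records)
    log: list[tuple[str, str, str]] = []
    # rewrite unmatched dispositions in place
    new_log = []
    for snp, disp, reason in hset.audit_log:
        if disp == "unmatched" and snp in subs:
            proxy_id, r2 = subs[snp]
            exp = exposure.get(snp)
            out = outcome.get(proxy_id)
            beta_out, eaf_out = out.beta, out.eaf
            flags = {"proxy"}
            phase = ld.phase(snp, proxy_id)
            if phase == "neg":
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                flags.add("allele_flipped")
            elif phase is None and not (math.isnan(exp.eaf) or math.isnan(out.eaf)):
                if (exp.eaf - 0.5) * (out.eaf - 0.5) < 0:
                    beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                    flags.add("allele_flipped")
                flags.add("proxy_freq_oriented")
            else:
                flags.add("proxy_phase_assumed")
            records.append(HarmonizedRecord(
                snp_id=snp, beta_exp=exp.beta, se_exp=exp.se, p_exp=exp.pval,
                beta_out=beta_out, se_out=out.se, p_out=out.pval,
                proxy_used=True, provenance_flags=flags,
                chrom=exp.chrom, pos=exp.pos, eaf_exp=exp.eaf, eaf_out=eaf_out))
            new_log.append((snp, "kept", f"proxy:{proxy_id}:r2={r2:g}"))
        elif disp == "unmatched":
            new_log.append((snp, "dropped", "no_proxy"))
        else:
            new_log.append((snp, disp, reason))
    return HarmonizedInstrumentSet(hset.exposure_name, hset.outcome_name,
                                   records, new_log + log)


def pleiotropy_filter(hset: HarmonizedInstrumentSet) -> HarmonizedInstrumentSet:
    """Remove SNPs whose outcome association is stronger than their exposure
    association (p_out strictly below p_exp) — such variants likely act on
    the outcome through a pathway other than the exposure."""
    kept, extra = [], []
    for r in hset.records:
        if r.p_out < r.p_exp:
            extra.append((r.snp_id, "dropped", "outcome_p_below_exposure_p"))
        else:
            kept.append(r)
    return hset.replaced(kept, extra)


@dataclass
class FStats:
    """Per-SNP and mean instrument-strength F-statistics."""

    per_snp: dict[str, float] = field(default_factory=dict)
    mean_f: float = float("nan")
    weak_instruments: bool = False


def f_statistics(hset: HarmonizedInstrumentSet) -> FStats:
    """F_j = (beta_exp_j / se_exp_j)²; mean F ≤ 10 flags weak instruments."""
    if len(hset) == 0:
        raise ValueError("no instruments")
    per = {r.snp_id: (r.beta_exp / r.se_exp) ** 2 for r in hset.records}
    mean_f = sum(per.values()) / len(per)
    return FStats(per_snp=per, mean_f=mean_f, weak_instruments=mean_f <= 10.0)
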