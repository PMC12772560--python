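"""Reading, validation and harmonization of GWAS summary statistics.

The on-disk dialect is a tab-separated table with a header row and columns
``SNP CHR POS EA OA EAF BETA SE P N`` (renameable through a column map).
Harmonization aligns the outcome dataset onto the exposure's effect alleles,
flipping signs and complementing frequencies where the allele pair is
recorded in the opposite orientation, resolving strand by reverse
complement for unambiguous pairs, and dropping palindromic (A/T, C/G)
variants whose minor allele frequency is too close to 0.5 to orient.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "VariantAssociation",
    "SummaryStatsSet",
    "HarmonizedRecord",
    "HarmonizedInstrumentSet",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "COLUMNS",
]

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: canonical column order of the summary-statistics dialect
COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in PALINDROMIC_PAIRS


@dataclass
class VariantAssociation:
    """One SNP's association record in one GWAS.

    ``eaf`` is the effect-allele frequency; it may be ``nan`` when the source
    GWAS did not report frequencies (palindromic variants then cannot be
    oriented and are dropped at harmonization).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def validation_error(self) -> str | None:
        """Return a short reason string if any invariant is violated."""
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            return "invalid_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not (self.se > 0):
            return "nonpositive_se"
        if not (math.isnan(self.eaf) or 0.0 <= self.eaf <= 1.0):
            return "eaf_out_of_range"
        if not (0.0 < self.pval <= 1.0):
            return "pval_out_of_range"
        if not (self.n > 0):
            return "nonpositive_n"
        return None

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class SummaryStatsSet:
    """An ordered collection of :class:`VariantAssociation` for one trait."""

    trait_name: str
    records: list[VariantAssociation] = field(default_factory=list)
    #: rows rejected at read time, as (row_label, reason)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {r.snp_id: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            raise ValueError(f"duplicate snp_id in set '{self.trait_name}'")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, snp_id: str) -> VariantAssociation | None:
        i = self._index.get(snp_id)
        return None if i is None else self.records[i]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def subset(self, keep: list[VariantAssociation]) -> "SummaryStatsSet":
        return SummaryStatsSet(self.trait_name, list(keep))


@dataclass
class HarmonizedRecord:
    """Per-SNP exposure and outcome effects signed to the same allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    p_exp: float
    beta_out: float
    se_out: float
    p_out: float
    proxy_used: bool = False
    provenance_flags: set = field(default_factory=set)
    chrom: str = ""
    pos: int = 0
    eaf_exp: float = float("nan")
    eaf_out: float = float("nan")


@dataclass
class HarmonizedInstrumentSet:
    """Aligned exposure/outcome effects plus a per-SNP disposition log.

    ``audit_log`` holds one (snp_id, disposition, reason) triple per input
    exposure SNP, disposition in {kept, dropped, unmatched}; SNPs left
    ``unmatched`` were absent from the outcome GWAS and await proxy
    resolution.
    """

    exposure_name: str
    outcome_name: str
    records: list[HarmonizedRecord] = field(default_factory=list)
    audit_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def unmatched_snp_ids(self) -> list[str]:
        return [s for s, d, _ in self.audit_log if d == "unmatched"]

    def arrays(self):
        """(beta_exp, se_exp, p_exp, beta_out, se_out, p_out) as numpy arrays."""
        import numpy as np

        r = self.records
        return (
            np.array([x.beta_exp for x in r]),
            np.array([x.se_exp for x in r]),
            np.array([x.p_exp for x in r]),
            np.array([x.beta_out for x in r]),
            np.array([x.se_out for x in r]),
            np.array([x.p_out for x in r]),
        )

    def replaced(self, records: list[HarmonizedRecord],
                 extra_log: list[tuple[str, str, str]] = ()) -> "HarmonizedInstrumentSet":
        log = [e for e in self.audit_log] + list(extra_log)
        return HarmonizedInstrumentSet(self.exposure_name, self.outcome_name,
                                       records, log)

    def write_audit(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["snp_id", "disposition", "reason"])
            w.writerows(self.audit_log)


def _num(text: str) -> float:
    v = float(text)
    if math.isinf(v):
        raise ValueError("non-finite")
    return v


def read_summary_stats(path, column_map: dict[str, str] | None = None,
                       trait_name: str | None = None) -> SummaryStatsSet:
    """Read a summary-statistics TSV into a validated :class:`SummaryStatsSet`.

    ``column_map`` maps canonical names (``SNP``, ``CHR``, ...) to the names
    used in the file. A missing mandatory column is fatal; rows that fail
    numeric parsing or a field invariant are rejected individually with a
    reason recorded in ``SummaryStatsSet.rejected``. Row order is preserved.
    """
    colmap = {c: c for c in COLUMNS}
    if column_map:
        colmap.update(column_map)
    records: list[VariantAssociation] = []
    rejected: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [colmap[c] for c in COLUMNS if colmap[c] not in header]
        if missing:
            raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
        for i, row in enumerate(reader, start=2):
            label = row.get(colmap["SNP"]) or f"line{i}"
            try:
                eaf_text = (row[colmap["EAF"]] or "").strip()
                rec = VariantAssociation(
                    snp_id=row[colmap["SNP"]].strip(),
                    chrom=row[colmap["CHR"]].strip(),
                    pos=int(row[colmap["POS"]]),
                    effect_allele=row[colmap["EA"]].strip().upper(),
                    other_allele=row[colmap["OA"]].strip().upper(),
                    eaf=float("nan") if eaf_text in ("", "NA", "nan") else _num(eaf_text),
                    beta=_num(row[colmap["BETA"]]),
                    se=_num(row[colmap["SE"]]),
                    pval=_num(row[colmap["P"]]),
                    n=_num(row[colmap["N"]]),
                )
            except (ValueError, TypeError):
                rejected.append((label, "unparseable_numeric"))
                continue
            reason = rec.validation_error()
            if reason is not None:
                rejected.append((rec.snp_id, reason))
                continue
            if rec.snp_id in seen:
                rejected.append((rec.snp_id, "duplicate_snp_id"))
                continue
            seen.add(rec.snp_id)
            records.append(rec)
    name = trait_name if trait_name is not None else str(path)
    out = SummaryStatsSet(name, records)
    out.rejected = rejected
    return out


def write_summary_stats(stats: SummaryStatsSet, path) -> None:
    """Write a set back to the TSV dialect; round-trips exactly through
    :func:`read_summary_stats` (floats serialised with ``repr``)."""

    def fmt(v: float) -> str:
        if isinstance(v, float) and math.isnan(v):
            return "NA"
        return repr(v) if isinstance(v, float) else str(v)

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(COLUMNS)
        for r in stats.records:
            w.writerow([r.snp_id, r.chrom, r.pos, r.effect_allele,
                        r.other_allele, fmt(r.eaf), fmt(r.beta), fmt(r.se),
                        fmt(r.pval), fmt(r.n)])


def _orient_outcome(exp: VariantAssociation, out: VariantAssociation):
    """Classify the outcome record's allele orientation vs the exposure.

    Returns one of
      ("same", flags), ("flip", flags)  — usable, possibly strand-complemented
      ("mismatch", flags)               — incompatible allele pair
    Palindromic pairs are handled by the caller (strand cannot be resolved
    from the alleles alone).
    """
    ea, oa = exp.effect_allele, exp.other_allele
    ea2, oa2 = out.effect_allele, out.other_allele
    if (ea2, oa2) == (ea, oa):
        return "same", set()
    if (ea2, oa2) == (oa, ea):
        return "flip", set()
    cea2, coa2 = COMPLEMENT[ea2], COMPLEMENT[oa2]
    if (cea2, coa2) == (ea, oa):
        return "same", {"strand_complemented"}
    if (cea2, coa2) == (oa, ea):
        return "flip", {"strand_complemented"}
    return "mismatch", set()


def harmonize(exposure: SummaryStatsSet, outcome: SummaryStatsSet,
              palindromic_maf_cutoff: float = 0.42) -> HarmonizedInstrumentSet:
    """Align outcome effects onto the exposure's effect alleles.

    For each exposure SNP present in the outcome: matching orientations keep
    the outcome beta as-is; swapped orientations negate the beta and
    complement the frequency (``allele_flipped``); non-palindromic pairs are
    additionally matched under reverse complement. Palindromic pairs with
    MAF > ``palindromic_maf_cutoff`` in either dataset are dropped
    (``palindromic_high_maf``, strict ``>``); at or below the cutoff they are
    oriented so the effect-allele frequencies fall on the same side of 0.5.
    Exposure SNPs absent from the outcome are logged ``unmatched`` for
    downstream proxy search.
    """
    records: list[HarmonizedRecord] = []
    log: list[tuple[str, str, str]] = []
    for exp in exposure:
        out = outcome.get(exp.snp_id)
        if out is None:
            log.append((exp.snp_id, "unmatched", "absent_from_outcome"))
            continue
        allele_set = frozenset((exp.effect_allele, exp.other_allele))
        if _is_palindromic(exp.effect_allele, exp.other_allele):
            if frozenset((out.effect_allele, out.other_allele)) != allele_set:
                log.append((exp.snp_id, "dropped", "allele_mismatch"))
                continue
            if math.isnan(exp.eaf) or math.isnan(out.eaf):
                log.append((exp.snp_id, "dropped", "palindromic_missing_eaf"))
                continue
            if exp.maf > palindromic_maf_cutoff or out.maf > palindromic_maf_cutoff:
                log.append((exp.snp_id, "dropped", "palindromic_high_maf"))
                continue
            # Orient by frequency agreement: written orientation first, then
            # flip if the effect-allele frequencies straddle 0.5.
            flags = {"palindromic_freq_oriented"}
            beta_out, eaf_out = out.beta, out.eaf
            if out.effect_allele != exp.effect_allele:
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                flags.add("allele_flipped")
        else:
            orient, flags = _orient_outcome(exp, out)
            if orient == "mismatch":
                log.append((exp.snp_id, "dropped", "allele_mismatch"))
                continue
            beta_out, eaf_out = out.beta, out.eaf
            if orient == "flip":
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out if not math.isnan(eaf_out) else eaf_out
                flags = flags | {"allele_flipped"}
        records.append(HarmonizedRecord(
            snp_id=exp.snp_id, beta_exp=exp.beta, se_exp=exp.se,
            p_exp=exp.pval, beta_out=beta_out, se_out=out.se, p_out=out.pval,
            provenance_flags=flags, chrom=exp.chrom, pos=exp.pos,
            eaf_exp=exp.eaf, eaf_out=eaf_out))
        log.append((exp.snp_id, "kept", "|".join(sorted(flags)) or "as_is"))
    return HarmonizedInstrumentSet(exposure.trait_name, outcome.trait_name,
                                   records, log)
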