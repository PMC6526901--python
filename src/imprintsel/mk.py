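"""McDonald-Kreitman counting and the derived statistic battery.

Per gene, within-population polymorphisms (PN, PS) and fixed differences to
an outgroup (DN, DS) are counted from aligned CDS haplotypes (or a SNP
matrix applied to a reference CDS).  The battery aggregates counts across
genes into DN/DS, PN/PS, the fixation index FI = (DN/DS)/(PN/PS), an
expected fixation index eFI from per-gene contingency-table margins, the
Direction of Selection DoS = DN/(DN+DS) - PN/(PN+PS), the Tarone-Greenland
neutrality index NI_TG, and alpha = (FI - eFI)/eFI.

Counting conventions (documented in the methods note): codons with several
changed positions are pathway-averaged over orderings that avoid stop
codons, giving fractional counts; a site that is both polymorphic and
divergent counts as polymorphic only; fractional counts are rounded half-up
for Fisher tables only.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import InputError, SNPMatrix
from .genetics import NUCLEOTIDES, GeneticCode, get_code


@dataclass
class MKCounts:
    gene: str
    DN: float
    DS: float
    PN: float
    PS: float

    def __post_init__(self):
        for v in (self.DN, self.DS, self.PN, self.PS):
            if v < 0:
                raise InputError("MK counts must be non-negative")

    @property
    def dnds(self) -> float | None:
        return self.DN / self.DS if self.DS > 0 else None

    @property
    def pnps(self) -> float | None:
        return self.PN / self.PS if self.PS > 0 else None

    @property
    def dos(self) -> float | None:
        d, p = self.DN + self.DS, self.PN + self.PS
        if d == 0 or p == 0:
            return None
        return self.DN / d - self.PN / p


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def _complete(codon: str) -> bool:
    return all(n in NUCLEOTIDES for n in codon)


def count_mk(population, outgroup: str, gene: str = "gene",
             code: GeneticCode | None = None) -> MKCounts:
    """Count DN/DS/PN/PS for one gene.

    Parameters
    ----------
    population : list of str
        Aligned CDS haplotypes (>= 2), same frame and length as the outgroup.
    outgroup : str
        Outgroup CDS.

    A nucleotide site segregating within the population contributes to
    PN/PS; a site monomorphic in the population but different from the
    outgroup contributes to DN/DS.  Codon-context classification with
    pathway averaging yields fractional counts for multi-hit codons.
    """
    code = code or get_code(1)
    population = [str(h).upper() for h in population]
    outgroup = str(outgroup).upper()
    if not population:
        raise InputError("population must contain at least one haplotype")
    if len(population) < 2:
        raise InputError("need >= 2 haplotypes to assess segregation")
    length = len(outgroup)
    if any(len(h) != length for h in population):
        raise InputError("population and outgroup sequences differ in length")
    if length % 3 != 0:
        raise InputError(f"CDS length {length} not divisible by 3 (frame mismatch)")

    DN = DS = PN = PS = 0.0
    for c in range(length // 3):
        out_codon = outgroup[3 * c: 3 * c + 3]
        pop_codons = [h[3 * c: 3 * c + 3] for h in population]
        pop_codons = [p for p in pop_codons if _complete(p)]
        if not pop_codons or not _complete(out_codon):
            continue
        # major codon and per-position allele inventory
        major = Counter(pop_codons).most_common(1)[0][0]
        poly_pos, minor_alleles = [], {}
        for k in range(3):
            alleles = {p[k] for p in pop_codons}
            if len(alleles) > 1:
                poly_pos.append(k)
                minor_alleles[k] = sorted(alleles - {major[k]})
        # polymorphism: pathway between major codon and all-minor codon
        if poly_pos:
            derived = list(major)
            for k in poly_pos:
                derived[k] = minor_alleles[k][0]
            s, n = code.pathway_counts(major, "".join(derived))
            PS += s
            PN += n
            # additional alleles beyond biallelic counted independently
            for k in poly_pos:
                for extra in minor_alleles[k][1:]:
                    alt = major[:k] + extra + major[k + 1:]
                    s, n = code.pathway_counts(major, alt)
                    PS += s
                    PN += n
        # divergence: positions monomorphic in population but != outgroup
        div_pos = [
            k for k in range(3)
            if k not in poly_pos and major[k] != out_codon[k]
        ]
        if div_pos:
            target = list(major)
            for k in div_pos:
                target[k] = out_codon[k]
            s, n = code.pathway_counts(major, "".join(target))
            DS += s
            DN += n
    return MKCounts(gene, DN, DS, PN, PS)


def snp_matrix_to_haplotypes(snps: SNPMatrix, reference_cds: str) -> list[str]:
    """Expand a SNP matrix over a reference CDS into per-accession haplotypes.

    Missing calls propagate as 'N' so the site is excluded from segregation
    assessment for that accession.
    """
    reference_cds = reference_cds.upper()
    haps = []
    for acc in snps.accessions:
        seq = list(reference_cds)
        for pos, ref, alt in zip(snps.positions, snps.ref_alleles, snps.alt_alleles):
            call = snps.genotypes.loc[acc, pos]
            if isinstance(call, (np.ndarray, list)):
                call = call[0]
            if call == SNPMatrix.MISSING or call == "N":
                seq[pos - 1] = "N"
            else:
                seq[pos - 1] = call
        haps.append("".join(seq))
    return haps


# ---------------------------------------------------------------------------
# Fisher test and classification
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mk_fisher(counts: MKCounts) -> tuple[float, bool]:
    """Two-sided Fisher exact p on [[DN, DS], [PN, PS]].

    Fractional (pathway-averaged) counts are rounded half-up.  Returns
    ``(p, degenerate)``; a degenerate all-zero table reports p = 1 flagged.
    """
    table = [
        [_round_half_up(counts.DN), _round_half_up(counts.DS)],
        [_round_half_up(counts.PN), _round_half_up(counts.PS)],
    ]
    if sum(table[0]) + sum(table[1]) == 0:
        return 1.0, True
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), False


@dataclass
class ClassificationThresholds:
    neutral_log_band: float = math.log(1.5)
    low_ratio: float = 0.5
    high_ratio: float = 1.0
    alpha: float = 0.05


def classify_gene(
    counts: MKCounts,
    fisher_p: float | None = None,
    thresholds: ClassificationThresholds | None = None,
) -> str:
    """Quadrant classification of a gene's selective regime.

    positive: DN/DS well above PN/PS with a significant Fisher excess of DN;
    purifying: both ratios low; pseudogenization-candidate: both ratios high
    without divergence excess; neutral: ratios comparable; unclassified when
    a ratio is undefined.
    """
    th = thresholds or ClassificationThresholds()
    dnds, pnps = counts.dnds, counts.pnps
    if dnds is None or pnps is None:
        return "unclassified"
    if fisher_p is None:
        fisher_p, _ = mk_fisher(counts)
    if pnps > 0:
        log_ratio = math.log(dnds / pnps) if dnds > 0 else -math.inf
    else:
        log_ratio = math.inf
    if dnds > pnps and log_ratio > th.neutral_log_band and fisher_p < th.alpha:
        return "positive"
    if dnds < th.low_ratio and pnps < th.low_ratio:
        return "purifying"
    if dnds > th.high_ratio and pnps > th.high_ratio and fisher_p >= th.alpha:
        return "pseudogenization-candidate"
    if abs(log_ratio) <= th.neutral_log_band:
        return "neutral"
    return "unclassified"


# ---------------------------------------------------------------------------
# Battery aggregation
# ---------------------------------------------------------------------------

@dataclass
class MKBatteryResult:
    genes: list[str]
    DN: float
    DS: float
    PN: float
    PS: float
    dnds: float | None
    pnps: float | None
    FI: float | None
    eFI: float | None
    alpha: float | None
    DoS: float | None
    NI_TG: float | None
    per_gene: list[dict] = field(default_factory=list)
    notes: dict = field(default_factory=dict)


def aggregate_battery(
    counts_list, efi: float | None = None
) -> MKBatteryResult:
    """Aggregate MK counts into the statistic battery.

    Counts are summed over all genes; genes with undefined DN/DS or PN/PS
    are excluded from the FI/eFI aggregation (but still listed per gene).
    ``efi`` overrides the internally computed expected fixation index (used
    when an externally reported eFI is supplied); alpha always satisfies
    alpha = (FI - eFI)/eFI.

    The internal eFI sums per-gene expected 2x2 cells under row/column
    independence given each gene's margins, then applies the FI formula to
    the expected aggregates (interpretation of the cited recipe; flagged in
    ``notes``).
    """
    counts_list = list(counts_list)
    if not counts_list:
        raise InputError("need at least one gene")
    per_gene = []
    tot = dict(DN=0.0, DS=0.0, PN=0.0, PS=0.0)
    etot = dict(DN=0.0, DS=0.0, PN=0.0, PS=0.0)
    ni_num = ni_den = 0.0
    for c in counts_list:
        fisher_p, degenerate = mk_fisher(c)
        record = {
            "gene": c.gene, "DN": c.DN, "DS": c.DS, "PN": c.PN, "PS": c.PS,
            "dnds": c.dnds, "pnps": c.pnps, "DoS": c.dos,
            "fisher_p": fisher_p, "fisher_degenerate": degenerate,
            "classification": classify_gene(c, fisher_p),
            "in_fi": c.dnds is not None and c.pnps is not None,
        }
        per_gene.append(record)
        for k in tot:
            tot[k] += getattr(c, k)
        if record["in_fi"]:
            n = c.DN + c.DS + c.PN + c.PS
            if n > 0:
                row_d, row_p = c.DN + c.DS, c.PN + c.PS
                col_n, col_s = c.DN + c.PN, c.DS + c.PS
                etot["DN"] += row_d * col_n / n
                etot["DS"] += row_d * col_s / n
                etot["PN"] += row_p * col_n / n
                etot["PS"] += row_p * col_s / n
        if c.PS + c.DS > 0:
            ni_num += c.DS * c.PN / (c.PS + c.DS)
            ni_den += c.PS * c.DN / (c.PS + c.DS)

    dnds = tot["DN"] / tot["DS"] if tot["DS"] > 0 else None
    pnps = tot["PN"] / tot["PS"] if tot["PS"] > 0 else None
    fi = dnds / pnps if dnds is not None and pnps not in (None, 0) else None
    notes = {"efi_method": "expected 2x2 cells from per-gene margins, summed"}
    if efi is None:
        if etot["DS"] > 0 and etot["PS"] > 0 and etot["PN"] > 0:
            e_dnds = etot["DN"] / etot["DS"]
            e_pnps = etot["PN"] / etot["PS"]
            efi_val = e_dnds / e_pnps if e_pnps > 0 else None
        else:
            efi_val = None
    else:
        efi_val = float(efi)
        notes["efi_method"] = "supplied externally"
    alpha = (fi - efi_val) / efi_val if fi is not None and efi_val else None
    d_tot, p_tot = tot["DN"] + tot["DS"], tot["PN"] + tot["PS"]
    dos = (tot["DN"] / d_tot - tot["PN"] / p_tot) if d_tot > 0 and p_tot > 0 else None
    ni_tg = ni_num / ni_den if ni_den > 0 else None
    if fi is None:
        notes["fi_missing"] = "aggregate DS or PS is zero"
    return MKBatteryResult(
        [c.gene for c in counts_list], tot["DN"], tot["DS"], tot["PN"], tot["PS"],
        dnds, pnps, fi, efi_val, alpha, dos, ni_tg, per_gene, notes,
    )
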