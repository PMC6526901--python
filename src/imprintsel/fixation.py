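"""Fixation check of positively selected sites across an accession panel.

For each confirmed positively selected codon site, every accession's
alleles are applied jointly to the reference codon, translated, and the
amino acid compared with the reference.  A site is *fixed* when all called
accessions share the reference amino acid; synonymous variation never
breaks fixation because the comparison is at the amino-acid level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import InputError, SNPMatrix
from .genetics import GeneticCode, get_code


def snp_matrix_from_haplotypes(gene, reference, haplotypes, accessions) -> SNPMatrix:
    """Build an SNPMatrix by diffing aligned haplotypes against a reference.

    Sites where a haplotype deviates from the reference become SNP rows; the
    first observed non-reference allele defines ``alt`` (additional alleles
    at the same site are recorded as that accession's call).  'N' or gap
    characters propagate as missing calls.
    """
    import pandas as pd

    reference = reference.upper()
    haplotypes = [h.upper() for h in haplotypes]
    positions: list[int] = []
    ref_alleles: list[str] = []
    alt_alleles: list[str] = []
    calls: dict[int, list[str]] = {}
    for pos in range(1, len(reference) + 1):
        ref = reference[pos - 1]
        column = [h[pos - 1] for h in haplotypes]
        non_ref = [c for c in column if c != ref and c in "ACGT"]
        if not non_ref:
            continue
        positions.append(pos)
        ref_alleles.append(ref)
        alt_alleles.append(non_ref[0])
        calls[pos] = [c if c in "ACGT" else SNPMatrix.MISSING for c in column]
    genotypes = pd.DataFrame(
        {pos: calls[pos] for pos in positions}, index=list(accessions)
    )
    if not positions:
        genotypes = pd.DataFrame(index=list(accessions))
    return SNPMatrix(gene, positions, ref_alleles, alt_alleles, genotypes,
                     cds_length=len(reference))


@dataclass
class ConservationReport:
    gene: str
    site: int  # 1-based codon index
    reference_aa: str
    n_accessions_called: int
    fraction_reference: float
    fixed: bool
    variant_aas: list[str] = field(default_factory=list)


def site_conservation(
    snps: SNPMatrix,
    cds_reference: str,
    ps_sites,
    posteriors=None,
    posterior_threshold: float = 0.95,
    code: GeneticCode | None = None,
) -> list[ConservationReport]:
    """Per-site conservation of positively selected codons across accessions.

    Parameters
    ----------
    ps_sites : iterable of int
        1-based codon indices of candidate positively selected sites.
    posteriors : array-like, optional
        Per-codon empirical-Bayes posteriors; when given, only sites with
        posterior strictly above ``posterior_threshold`` are assessed.

    Heterozygous calls are not expected in inbred accessions; any
    non-reference, non-missing call counts as non-reference.  Missing calls
    reduce ``n_accessions_called``.
    """
    code = code or get_code(1)
    cds = cds_reference.upper()
    n_codons = len(cds) // 3
    if len(cds) % 3 != 0:
        raise InputError("reference CDS length not divisible by 3")
    out_of_range = snps.positions[(snps.positions < 1) | (snps.positions > len(cds))]
    if out_of_range.size:
        raise InputError(
            f"SNP position {int(out_of_range[0])} outside CDS (length {len(cds)})"
        )
    sites = sorted(set(int(s) for s in ps_sites))
    if posteriors is not None:
        posteriors = np.asarray(posteriors, dtype=float)
        sites = [s for s in sites if posteriors[s - 1] > posterior_threshold]
    reports = []
    pos_by_codon: dict[int, list[int]] = {}
    for k, pos in enumerate(snps.positions):
        pos_by_codon.setdefault((pos - 1) // 3 + 1, []).append(k)
    for site in sites:
        if not 1 <= site <= n_codons:
            raise InputError(f"codon site {site} outside CDS of {n_codons} codons")
        ref_codon = cds[3 * (site - 1): 3 * site]
        ref_aa = code.translate(ref_codon)
        snp_idx = pos_by_codon.get(site, [])
        n_called = 0
        n_ref = 0
        variants: set[str] = set()
        for acc in snps.accessions:
            codon = list(ref_codon)
            missing = False
            for k in snp_idx:
                call = snps.genotypes.loc[acc, snps.positions[k]]
                if call in (SNPMatrix.MISSING, "N"):
                    missing = True
                    break
                codon[(snps.positions[k] - 1) % 3] = call
            if missing:
                continue
            n_called += 1
            aa = code.translate("".join(codon))
            if aa == ref_aa:
                n_ref += 1
            else:
                variants.add(aa if aa is not None else "*")
        fraction = n_ref / n_called if n_called else 1.0
        reports.append(
            ConservationReport(
                snps.gene, site, ref_aa, n_called, fraction,
                fixed=(fraction == 1.0), variant_aas=sorted(variants),
            )
        )
    return reports
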