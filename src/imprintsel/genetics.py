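"""Genetic-code tables and codon-level helpers.

Everything downstream (likelihood engine, ancestor counting, MK
classification, simulators) works on the ordered set of *sense* codons of a
single genetic code.  The standard nuclear code is the default; any NCBI
table id supported by Biopython can be injected.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable, IUPACData

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
GAP_CODON = "---"

#: nucleotide ambiguity letter -> compatible unambiguous bases
AMBIGUITY = {k.upper(): set(v.upper()) for k, v in IUPACData.ambiguous_dna_values.items()}
AMBIGUITY["-"] = set(NUCLEOTIDES)  # a gap is treated as fully unobserved
AMBIGUITY["?"] = set(NUCLEOTIDES)


def is_transition(a: str, b: str) -> bool:
    """True when the unordered nucleotide pair ``{a, b}`` is a transition."""
    pair = {a, b}
    return pair <= PURINES or pair <= PYRIMIDINES


class GeneticCode:
    """Sense-codon state space for one genetic-code table.

    Attributes
    ----------
    sense_codons : list of str
        Codons excluding stops, in lexicographic (ACGT) order.  All rate
        matrices, stationary distributions and partial likelihoods are
        indexed in this order.
    """

    def __init__(self, table_id: int = 1):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.stop_codons = frozenset(table.stop_codons)
        all_codons = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
        self.sense_codons = [c for c in all_codons if c not in self.stop_codons]
        self.n_states = len(self.sense_codons)
        self.codon_index = {c: i for i, c in enumerate(self.sense_codons)}
        self.amino_acids = [table.forward_table[c] for c in self.sense_codons]
        self._aa_array = np.array(self.amino_acids)
        self._build_single_step_pairs()
        self._syn_fraction = None

    # -- state-space structure -------------------------------------------

    def _build_single_step_pairs(self) -> None:
        """Precompute all ordered sense-codon pairs differing at one site."""
        ii, jj, ts, nonsyn = [], [], [], []
        for i, a in enumerate(self.sense_codons):
            for j, b in enumerate(self.sense_codons):
                if i == j:
                    continue
                diffs = [k for k in range(3) if a[k] != b[k]]
                if len(diffs) != 1:
                    continue
                k = diffs[0]
                ii.append(i)
                jj.append(j)
                ts.append(is_transition(a[k], b[k]))
                nonsyn.append(self.amino_acids[i] != self.amino_acids[j])
        self.pair_i = np.array(ii, dtype=np.intp)
        self.pair_j = np.array(jj, dtype=np.intp)
        self.pair_transition = np.array(ts, dtype=bool)
        self.pair_nonsyn = np.array(nonsyn, dtype=bool)

    # -- translation and codon compatibility ------------------------------

    def translate(self, codon: str):
        """Amino acid for a codon; ``'-'`` for gaps, ``None`` if ambiguous/stop."""
        codon = codon.upper()
        if codon == GAP_CODON:
            return "-"
        if any(n not in NUCLEOTIDES for n in codon):
            return None
        if codon in self.stop_codons:
            return None
        return self.amino_acids[self.codon_index[codon]]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def state_mask(self, codon: str) -> np.ndarray:
        """Boolean mask over sense codons compatible with an observed triplet.

        Unambiguous sense codons map to a single state; triplets containing
        gaps or IUPAC ambiguity codes map to every compatible sense codon
        (missing-data treatment under the pruning algorithm).
        """
        codon = codon.upper()
        idx = self.codon_index.get(codon)
        if idx is not None:
            mask = np.zeros(self.n_states, dtype=bool)
            mask[idx] = True
            return mask
        sets = []
        for n in codon:
            allowed = AMBIGUITY.get(n)
            if allowed is None:
                raise ValueError(f"unknown nucleotide symbol {n!r}")
            sets.append(allowed)
        mask = np.zeros(self.n_states, dtype=bool)
        for triple in itertools.product(*sets):
            i = self.codon_index.get("".join(triple))
            if i is not None:
                mask[i] = True
        if not mask.any():  # e.g. an unambiguous stop codon
            mask[:] = True
        return mask

    # -- mutational opportunity -------------------------------------------

    def synonymous_site_fraction(self, codon_idx: int) -> float:
        """Fraction of single-nucleotide non-stop changes that are synonymous."""
        if self._syn_fraction is None:
            counts_syn = np.zeros(self.n_states)
            counts_all = np.zeros(self.n_states)
            np.add.at(counts_all, self.pair_i, 1.0)
            np.add.at(counts_syn, self.pair_i, (~self.pair_nonsyn).astype(float))
            with np.errstate(invalid="ignore"):
                self._syn_fraction = np.where(counts_all > 0, counts_syn / counts_all, 0.0)
        return float(self._syn_fraction[codon_idx])

    def pathway_counts(self, codon_a: str, codon_b: str) -> tuple[float, float]:
        """Average (synonymous, nonsynonymous) change counts between codons.

        Averages over every ordering of the differing positions, skipping
        orderings that pass through a stop codon.  If every ordering is
        blocked by stops, each differing site is classified independently in
        the context of ``codon_a`` (rare fallback).
        """
        return _pathway_counts_cached(self.table_id, codon_a.upper(), codon_b.upper())


@lru_cache(maxsize=8)
def get_code(table_id: int = 1) -> GeneticCode:
    return GeneticCode(table_id)


@lru_cache(maxsize=65536)
def _pathway_counts_cached(table_id: int, a: str, b: str) -> tuple[float, float]:
    code = get_code(table_id)
    diffs = [k for k in range(3) if a[k] != b[k]]
    if not diffs:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diffs):
        cur = a
        syn = nonsyn = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate(cur) == code.translate(nxt):
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        if ok:
            totals.append((syn, nonsyn))
    if not totals:
        # classify each site change independently in the context of `a`
        syn = nonsyn = 0.0
        for pos in diffs:
            nxt = a[:pos] + b[pos] + a[pos + 1:]
            if code.is_stop(nxt):
                nonsyn += 1.0
            elif code.translate(a) == code.translate(nxt):
                syn += 1.0
            else:
                nonsyn += 1.0
        return syn, nonsyn
    syn = sum(t[0] for t in totals) / len(totals)
    nonsyn = sum(t[1] for t in totals) / len(totals)
    return syn, nonsyn
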