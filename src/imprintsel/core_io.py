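"""Domain types, file I/O, and the pre-analysis quality gates.

The central containers are :class:`CodonAlignment` (in-frame aligned CDS),
:class:`PhyloTree` (tree with branch lengths and optional foreground branch
marks for branch-site tests), :class:`OrthologCluster` and
:class:`SNPMatrix`.  Gates implemented here: minimum cluster size (orthologs
from at least six species besides the focal gene), an alignment-quality
score gating at 0.6 with optional drop-worst-and-retry, and per-column gap
fractions used later to mask positively selected sites in poorly aligned
regions (strictly more than 40% gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import NUCLEOTIDES, GeneticCode, get_code


class FrameError(ValueError):
    """Sequence breaks the in-frame CDS contract (length or internal stop)."""


class InputError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# CodonAlignment
# ---------------------------------------------------------------------------

class CodonAlignment:
    """In-frame aligned coding sequences over a shared genetic code.

    Parameters
    ----------
    taxa : list of str
        Unique sequence identifiers, order preserved.
    sequences : list of str
        Aligned nucleotide sequences; equal lengths divisible by 3.  Codon
        columns are 1-based in all reports.
    code : GeneticCode, optional
        Defaults to the standard nuclear code.
    """

    def __init__(self, taxa, sequences, code: GeneticCode | None = None):
        self.code = code or get_code(1)
        self.taxa = list(taxa)
        self.sequences = [str(s).upper().replace("U", "T") for s in sequences]
        self._validate()

    def _validate(self):
        if len(self.taxa) != len(self.sequences):
            raise InputError("taxa and sequences differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise InputError(f"duplicated sequence identifier(s): {', '.join(dup)}")
        if not self.sequences:
            raise InputError("empty alignment")
        length = len(self.sequences[0])
        for taxon, seq in zip(self.taxa, self.sequences):
            if len(seq) != length:
                raise FrameError(f"sequence {taxon!r} length {len(seq)} != {length}")
            if len(seq) % 3 != 0:
                raise FrameError(f"sequence {taxon!r} length {len(seq)} not divisible by 3")
        n_cod = length // 3
        for taxon, seq in zip(self.taxa, self.sequences):
            for c in range(n_cod - 1):  # terminal stop codons are allowed
                codon = seq[3 * c: 3 * c + 3]
                if self.code.is_stop(codon):
                    raise FrameError(
                        f"internal stop codon {codon} in {taxon!r} at codon {c + 1}"
                    )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon(self, taxon_index: int, column: int) -> str:
        """Codon of one taxon at a 1-based codon column."""
        c = column - 1
        return self.sequences[taxon_index][3 * c: 3 * c + 3]

    def codon_column(self, column: int) -> list[str]:
        return [self.codon(i, column) for i in range(self.n_taxa)]

    def subset_taxa(self, keep) -> "CodonAlignment":
        keep = set(keep)
        idx = [i for i, t in enumerate(self.taxa) if t in keep]
        return CodonAlignment(
            [self.taxa[i] for i in idx], [self.sequences[i] for i in idx], self.code
        )

    def translated(self) -> list[str]:
        """Per-taxon residue strings; gaps/ambiguity/stop rendered as '-'."""
        rows = []
        for i in range(self.n_taxa):
            aas = []
            for c in range(1, self.n_codons + 1):
                aa = self.code.translate(self.codon(i, c))
                aas.append(aa if aa is not None else "-")
            rows.append("".join(aas))
        return rows

    def __eq__(self, other):
        return (
            isinstance(other, CodonAlignment)
            and self.taxa == other.taxa
            and self.sequences == other.sequences
        )

    def __repr__(self):
        return f"CodonAlignment({self.n_taxa} taxa x {self.n_codons} codons)"


def read_codon_fasta(path, code: GeneticCode | None = None) -> CodonAlignment:
    """Read an aligned in-frame CDS FASTA into a validated CodonAlignment."""
    taxa, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        seqs.append(str(rec.seq))
    if not taxa:
        raise InputError(f"no FASTA records in {path}")
    return CodonAlignment(taxa, seqs, code)


def write_codon_fasta(alignment: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in zip(alignment.taxa, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

_FG_SENTINEL = "__FOREGROUND__"


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    foreground: bool = False
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Phylogeny with branch lengths and optional foreground branch marks.

    Branch lengths are expected substitutions per codon site.  Foreground
    branches (for branch-site tests) can be marked with the conventional ``#1``
    suffix in the newick string, or programmatically via
    :meth:`set_foreground`.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        for node in self.postorder():
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise InputError(f"negative branch length at {node.name!r}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        newick = newick.replace("#1", _FG_SENTINEL)
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )

        def convert(dnode) -> TreeNode:
            label = None
            if dnode.taxon is not None and dnode.taxon.label:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            fg = False
            if label and label.endswith(_FG_SENTINEL):
                label = label[: -len(_FG_SENTINEL)] or None
                fg = True
            node = TreeNode(
                name=label,
                length=dnode.edge.length if dnode.edge.length is not None else 0.0,
                foreground=fg,
            )
            node.children = [convert(ch) for ch in dnode.child_nodes()]
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            tag = "#1" if node.foreground else ""
            if node.is_leaf:
                return f"{node.name}{tag}:{node.length:.6g}"
            inner = ",".join(fmt(ch) for ch in node.children)
            name = node.name or ""
            return f"({inner}){name}{tag}:{node.length:.6g}"

        inner = ",".join(fmt(ch) for ch in self.root.children)
        return f"({inner});"

    # -- traversal ---------------------------------------------------------

    def postorder(self):
        out = []

        def walk(node):
            for ch in node.children:
                walk(ch)
            out.append(node)

        walk(self.root)
        return out

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def foreground(self) -> set[str]:
        marks = set()
        for i, node in enumerate(self.postorder()):
            if node.foreground:
                marks.add(node.name or f"node{i}")
        return marks

    def set_foreground(self, leaf_names) -> None:
        """Mark the terminal branches of the named leaves as foreground."""
        names = set(leaf_names)
        missing = names - set(self.leaf_names)
        if missing:
            raise InputError(f"foreground leaves not in tree: {sorted(missing)}")
        for node in self.postorder():
            if node.is_leaf:
                node.foreground = node.name in names

    def branch_lengths(self) -> np.ndarray:
        return np.array([n.length for n in self.postorder()[:-1]])

    def scale(self, factor: float) -> "PhyloTree":
        clone = PhyloTree.from_newick(self.to_newick())
        for node in clone.postorder():
            node.length *= factor
        return clone

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick())


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# OrthologCluster and SNPMatrix
# ---------------------------------------------------------------------------

@dataclass
class OrthologCluster:
    """One focal gene with its ortholog alignment and tree."""

    focal_gene: str
    alignment: CodonAlignment
    tree: PhyloTree

    def __post_init__(self):
        extra = set(self.tree.leaf_names) - set(self.alignment.taxa)
        if extra:
            raise InputError(f"tree leaves missing from alignment: {sorted(extra)}")

    @property
    def n_species(self) -> int:
        """Distinct non-focal species, derived from the alignment taxa."""
        return len([t for t in self.alignment.taxa if t != self.focal_gene])


@dataclass
class GateDecision:
    gate: str
    passed: bool
    reason: str
    details: dict = field(default_factory=dict)


def cluster_size_gate(cluster: OrthologCluster, min_species: int = 6) -> GateDecision:
    """Pass iff orthologs from at least ``min_species`` non-focal species."""
    n = cluster.n_species
    passed = n >= min_species
    reason = (
        f"{n} non-focal species >= required {min_species}"
        if passed
        else f"only {n} non-focal species, {min_species} required"
    )
    return GateDecision("cluster_size", passed, reason, {"n_species": n})


class SNPMatrix:
    """Per-gene SNP table over a panel of accessions.

    ``genotypes`` is a DataFrame (accessions x positions) of allele
    characters, with ``'.'`` marking an explicit missing call.  Positions are
    1-based CDS nucleotide coordinates.
    """

    MISSING = "."

    def __init__(self, gene, positions, ref_alleles, alt_alleles, genotypes: pd.DataFrame,
                 cds_length: int | None = None):
        self.gene = gene
        self.positions = np.asarray(positions, dtype=int)
        self.ref_alleles = list(ref_alleles)
        self.alt_alleles = list(alt_alleles)
        self.genotypes = genotypes
        if len(self.positions) != len(self.ref_alleles) or len(self.positions) != len(
            self.alt_alleles
        ):
            raise InputError("positions/ref/alt length mismatch")
        for arr, what in ((self.ref_alleles, "ref"), (self.alt_alleles, "alt")):
            bad = [a for a in arr if a not in NUCLEOTIDES]
            if bad:
                raise InputError(f"invalid {what} allele(s): {sorted(set(bad))}")
        if (self.positions < 1).any():
            raise InputError("SNP positions must be 1-based and positive")
        if cds_length is not None:
            out = self.positions[self.positions > cds_length]
            if out.size:
                raise InputError(
                    f"SNP position {int(out[0])} outside CDS of length {cds_length}"
                )
        valid = set(NUCLEOTIDES) | {self.MISSING, "N"}
        bad = set(np.unique(self.genotypes.values)) - valid
        if bad:
            raise InputError(f"invalid genotype symbols: {sorted(bad)}")

    @property
    def n_accessions(self) -> int:
        return self.genotypes.shape[0]

    @property
    def accessions(self) -> list[str]:
        return list(self.genotypes.index)


def read_snp_table(path) -> dict[str, SNPMatrix]:
    """Read a SNP TSV (gene, pos, ref, alt, one column per accession)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise InputError(f"SNP table needs columns {sorted(required)}")
    accession_cols = [c for c in df.columns if c not in required]
    out = {}
    for gene, sub in df.groupby("gene", sort=True):
        genotypes = sub[accession_cols].T
        genotypes.columns = sub["pos"].astype(int).values
        out[gene] = SNPMatrix(
            gene,
            sub["pos"].astype(int).values,
            sub["ref"].values,
            sub["alt"].values,
            genotypes,
        )
    return out


def read_gene_sets(path) -> pd.DataFrame:
    """Gene-set membership TSV: gene_id, set_label (+ optional extra columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "set_label": str})
    if "gene_id" not in df.columns or "set_label" not in df.columns:
        raise InputError("gene-set table needs gene_id and set_label columns")
    return df


def read_hit_table(path) -> pd.DataFrame:
    """Homology-hit TSV for ageing: gene_id, clade_index, evalue."""
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "clade_index", "evalue"}
    if not needed <= set(df.columns):
        raise InputError(f"hit table needs columns {sorted(needed)}")
    return df


# ---------------------------------------------------------------------------
# Alignment quality score (norMD-style surrogate) and gap bookkeeping
# ---------------------------------------------------------------------------

_BLOSUM = substitution_matrices.load("BLOSUM62")
_BLOSUM_MIN = float(min(_BLOSUM.values()))


def _pair_similarity(a: str, b: str) -> float:
    """BLOSUM62 similarity of two residues normalised to [0, 1].

    Normalisation is per pair: (S(a,b) - S_min) / (max(S(a,a), S(b,b)) - S_min),
    so identical residues always score 1.
    """
    try:
        s = float(_BLOSUM[a, b])
        m = max(float(_BLOSUM[a, a]), float(_BLOSUM[b, b]))
    except (KeyError, IndexError):
        return 0.0
    if m <= _BLOSUM_MIN:
        return 0.0
    return (s - _BLOSUM_MIN) / (m - _BLOSUM_MIN)


def alignment_quality_score(alignment: CodonAlignment) -> float:
    """Column-averaged normalised mean pairwise similarity in [0, 1].

    For each codon column the translated residues are compared over all
    sequence pairs with a normalised BLOSUM62 similarity; residue-gap pairs
    score 0, gap-gap pairs are excluded from the pair count.  Columns with no
    countable pair are skipped.  Deterministic and invariant to taxon order.
    """
    if alignment.n_taxa < 2:
        raise InputError("quality score undefined for single-sequence alignment")
    residues = alignment.translated()
    col_scores = []
    for c in range(alignment.n_codons):
        col = [row[c] for row in residues]
        total = 0.0
        n_pairs = 0
        for i in range(len(col)):
            for j in range(i + 1, len(col)):
                a, b = col[i], col[j]
                if a == "-" and b == "-":
                    continue
                n_pairs += 1
                if a == "-" or b == "-":
                    continue
                total += _pair_similarity(a, b)
        if n_pairs:
            col_scores.append(total / n_pairs)
    if not col_scores:
        raise InputError("no scorable columns in alignment")
    return float(np.mean(col_scores))


@dataclass
class QualityGateResult:
    passed: bool
    score: float
    removed: list[str]
    alignment: CodonAlignment
    reason: str


def quality_gate(
    alignment: CodonAlignment,
    threshold: float = 0.6,
    drop_and_retry: bool = False,
) -> QualityGateResult:
    """Gate an alignment on its quality score.

    When the score falls below ``threshold`` and ``drop_and_retry`` is set,
    the single sequence whose exclusion maximally increases the score is
    removed and the score recomputed once, mirroring the drop-worst-then-
    rescore protocol used for low-quality alignments.
    """
    score = alignment_quality_score(alignment)
    if score >= threshold:
        return QualityGateResult(True, score, [], alignment, f"score {score:.4f} >= {threshold}")
    if not drop_and_retry:
        return QualityGateResult(False, score, [], alignment, f"score {score:.4f} < {threshold}")
    if alignment.n_taxa <= 2:
        return QualityGateResult(
            False, score, [], alignment,
            "removal would leave fewer than 2 sequences",
        )
    best_taxon, best_score = None, -np.inf
    for taxon in alignment.taxa:
        reduced = alignment.subset_taxa([t for t in alignment.taxa if t != taxon])
        s = alignment_quality_score(reduced)
        if s > best_score:
            best_taxon, best_score = taxon, s
    reduced = alignment.subset_taxa([t for t in alignment.taxa if t != best_taxon])
    passed = best_score >= threshold
    reason = (
        f"score {score:.4f} < {threshold}; removed {best_taxon!r}, rescored {best_score:.4f}"
    )
    return QualityGateResult(passed, best_score, [best_taxon], reduced, reason)


def column_gap_fraction(alignment: CodonAlignment) -> np.ndarray:
    """Per codon column, the fraction of taxa contributing a gap triplet."""
    fractions = np.empty(alignment.n_codons)
    for c in range(1, alignment.n_codons + 1):
        gaps = sum(1 for codon in alignment.codon_column(c) if "-" in codon)
        fractions[c - 1] = gaps / alignment.n_taxa
    return fractions
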