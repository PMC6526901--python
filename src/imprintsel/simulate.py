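"""Synthetic-data generators with known ground truth.

Three generators cover every input the analysis consumes: codon alignments
evolved along a tree under omega site classes (optionally with a foreground
omega on marked branches), population samples of haplotypes plus an
outgroup with controlled synonymous/nonsynonymous polymorphism and
divergence, and labelled gene sets with a specified incidence of positive
selection.  ``make_study_bundle`` assembles a self-contained on-disk input
set emulating the study design (ortholog clusters for ~8 species, an
80-haplotype accession panel, control pools) on which the full pipeline
runs end to end.

Every generator is a pure function of its parameters and seed; the returned
truth records suffice to recompute the expected value of each downstream
statistic.

The population generator is a per-site mutation sprinkler, not a coalescent:
MK counting depends only on realised variant configurations, so linkage and
genealogy are deliberately not modelled (documented limitation).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .codon_model import CodonModelParams, SiteClass, neutral_scaled_rate_matrix
from .core_io import (
    CodonAlignment,
    InputError,
    PhyloTree,
    write_codon_fasta,
    write_newick,
)
from .genetics import GeneticCode, get_code
from .genesets import GeneRecord


@dataclass
class SimulationTruth:
    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    per_site: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=_jsonable, indent=1)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


# ---------------------------------------------------------------------------
# Codon alignments along a tree
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    tree: PhyloTree,
    params: CodonModelParams,
    n_sites: int,
    seed: int = 0,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve a codon alignment along a tree under omega site classes.

    Root codons are drawn from the stationary distribution; each branch
    applies the transition probabilities of its site's class (foreground
    branches use the class's foreground omega when set).  Deterministic
    under the seed.
    """
    if n_sites < 1:
        raise InputError("n_sites must be >= 1")
    code = get_code(1)
    rng = np.random.default_rng(seed)
    pi = (
        np.asarray(params.freqs, float)
        if params.freqs is not None
        else np.full(code.n_states, 1.0 / code.n_states)
    )
    pi = pi / pi.sum()
    props = np.array([c.proportion for c in params.site_classes])
    site_class = rng.choice(len(props), size=n_sites, p=props)

    # transition matrices per (class, background/foreground); neutral-scaled
    # generators match the likelihood engine's branch-length convention
    def pmat(omega: float, t: float) -> np.ndarray:
        Q = neutral_scaled_rate_matrix(params.kappa, omega, pi, code)
        from scipy.linalg import expm

        P = expm(Q * t)
        P = np.maximum(P, 0.0)
        return P / P.sum(axis=1, keepdims=True)

    nodes = tree.postorder()
    parent_state: dict[int, np.ndarray] = {}
    root_states = rng.choice(code.n_states, size=n_sites, p=pi)
    # preorder traversal
    order = []

    def pre(node):
        order.append(node)
        for ch in node.children:
            pre(ch)

    pre(tree.root)
    states = {id(tree.root): root_states}
    for node in order:
        if node is tree.root:
            continue
        parent = _find_parent(tree.root, node)
        ps = states[id(parent)]
        child = np.empty(n_sites, dtype=int)
        for k, cls in enumerate(params.site_classes):
            sel = site_class == k
            if not sel.any():
                continue
            omega = cls.effective(node.foreground)
            P = pmat(omega, node.length)
            cum = P.cumsum(axis=1)
            u = rng.random(int(sel.sum()))
            sub_parents = ps[sel]
            child_states = np.array(
                [np.searchsorted(cum[p], uu, side="right") for p, uu in zip(sub_parents, u)]
            )
            child[sel] = np.minimum(child_states, code.n_states - 1)
        states[id(node)] = child

    taxa, seqs = [], []
    for node in nodes:
        if node.is_leaf:
            taxa.append(node.name)
            seqs.append("".join(code.sense_codons[s] for s in states[id(node)]))
    truth = SimulationTruth(
        "codon_alignment",
        seed,
        params={
            "kappa": params.kappa,
            "classes": [
                {"omega": c.omega, "proportion": c.proportion,
                 "foreground_omega": c.foreground_omega}
                for c in params.site_classes
            ],
            "n_sites": n_sites,
        },
        per_site={"class_index": site_class.tolist()},
    )
    return CodonAlignment(taxa, seqs, code), truth


def _find_parent(root, target):
    for node in _walk(root):
        if any(ch is target for ch in node.children):
            return node
    raise ValueError("node not in tree")


def _walk(node):
    yield node
    for ch in node.children:
        yield from _walk(ch)


# ---------------------------------------------------------------------------
# Population samples (MK inputs)
# ---------------------------------------------------------------------------

def _random_cds(n_codons: int, rng, code: GeneticCode) -> list[int]:
    return list(rng.choice(code.n_states, size=n_codons))


def _mutation_options(codon_idx: int, synonymous: bool, code: GeneticCode):
    """Single-step neighbours of a codon with the requested change class."""
    sel = (code.pair_i == codon_idx) & (code.pair_nonsyn != synonymous)
    return code.pair_j[sel]


def simulate_population(
    n_codons: int,
    n_haplotypes: int = 80,
    theta_syn: float = 8.0,
    theta_nonsyn: float = 8.0,
    div_syn: float = 20.0,
    div_nonsyn: float = 20.0,
    seed: int = 0,
) -> tuple[list[str], str, SimulationTruth]:
    """Population haplotypes plus outgroup CDS with controlled MK structure.

    The outgroup accumulates Poisson(div_syn)/Poisson(div_nonsyn) fixed
    changes from a random ancestral CDS; the population carries
    Poisson(theta_syn)/Poisson(theta_nonsyn) segregating variants at
    distinct codon sites (derived-allele carriers drawn uniformly).  The
    placed counts are recorded as the expected MK cells.
    """
    if n_haplotypes < 2:
        raise InputError("need at least 2 haplotypes")
    if min(theta_syn, theta_nonsyn, div_syn, div_nonsyn) < 0:
        raise InputError("rates must be non-negative")
    code = get_code(1)
    rng = np.random.default_rng(seed)
    ancestral = _random_cds(n_codons, rng, code)
    used_codons: set[int] = set()
    placed = {"DN": 0, "DS": 0, "PN": 0, "PS": 0}

    def place(target_counts, synonymous, kind):
        n = int(rng.poisson(target_counts))
        done = 0
        attempts = 0
        changes = []
        while done < n and attempts < 200 * max(n, 1):
            attempts += 1
            c = int(rng.integers(n_codons))
            if c in used_codons:
                continue
            options = _mutation_options(ancestral[c], synonymous, code)
            if options.size == 0:
                continue
            j = int(options[rng.integers(options.size)])
            used_codons.add(c)
            changes.append((c, j))
            done += 1
        placed[kind] += done
        return changes

    div_changes = place(div_syn, True, "DS") + place(div_nonsyn, False, "DN")
    outgroup = list(ancestral)
    for c, j in div_changes:
        outgroup[c] = j

    poly_changes = place(theta_syn, True, "PS") + place(theta_nonsyn, False, "PN")
    haplotypes = [list(ancestral) for _ in range(n_haplotypes)]
    poly_records = []
    for c, j in poly_changes:
        n_carriers = int(rng.integers(1, n_haplotypes))
        carriers = rng.choice(n_haplotypes, size=n_carriers, replace=False)
        for h in carriers:
            haplotypes[h][c] = j
        poly_records.append({"codon": c, "derived": j, "carriers": int(n_carriers)})

    to_seq = lambda idxs: "".join(code.sense_codons[i] for i in idxs)
    truth = SimulationTruth(
        "population",
        seed,
        params={
            "n_codons": n_codons, "n_haplotypes": n_haplotypes,
            "theta_syn": theta_syn, "theta_nonsyn": theta_nonsyn,
            "div_syn": div_syn, "div_nonsyn": div_nonsyn,
        },
        per_site={"polymorphisms": poly_records},
        expected=dict(placed),
    )
    return [to_seq(h) for h in haplotypes], to_seq(outgroup), truth


# ---------------------------------------------------------------------------
# Labelled gene sets
# ---------------------------------------------------------------------------

def simulate_geneset(
    n_target: int,
    n_control: int,
    ps_rate_target: float,
    ps_rate_control: float,
    seed: int = 0,
) -> tuple[list[GeneRecord], SimulationTruth]:
    """Bernoulli positive-selection flags for a target and a control set."""
    for r in (ps_rate_target, ps_rate_control):
        if not 0.0 <= r <= 1.0:
            raise InputError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_target):
        flag = bool(rng.random() < ps_rate_target)
        records.append(GeneRecord(f"T{i:04d}", "target", ps_lineage=flag))
    for i in range(n_control):
        flag = bool(rng.random() < ps_rate_control)
        records.append(GeneRecord(f"C{i:04d}", "control", ps_lineage=flag))
    odds = lambda r: r / (1 - r) if 0 < r < 1 else np.inf
    true_or = (
        odds(ps_rate_target) / odds(ps_rate_control)
        if 0 < ps_rate_control < 1 and 0 < ps_rate_target < 1
        else np.nan
    )
    truth = SimulationTruth(
        "geneset", seed,
        params={"n_target": n_target, "n_control": n_control,
                "ps_rate_target": ps_rate_target, "ps_rate_control": ps_rate_control},
        expected={"odds_ratio": true_or},
    )
    return records, truth


# ---------------------------------------------------------------------------
# Study bundle
# ---------------------------------------------------------------------------

def _bundle_tree(focal: str, n_taxa: int, rng) -> PhyloTree:
    """Ladder tree over the focal taxon and n_taxa-1 relatives."""
    names = [focal] + [f"sp{i}" for i in range(1, n_taxa)]
    lengths = 0.08 + 0.3 * rng.random(2 * n_taxa)
    lengths[0] = 0.25 + 0.1 * rng.random()  # focal terminal branch
    newick = f"{names[0]}#1:{lengths[0]:.4f}"
    for k, name in enumerate(names[1:], start=1):
        newick = f"({newick},{name}:{lengths[2 * k]:.4f}):{lengths[2 * k + 1] * 0.3:.4f}"
    return PhyloTree.from_newick(f"({newick},{names[-1]}_og:{0.4:.4f});")


def make_study_bundle(
    out_dir,
    seed: int = 0,
    n_genes: int = 20,
    n_taxa: int = 8,
    n_codons: int = 200,
    ps_fraction: float = 0.3,
    foreground_omega: float = 5.0,
    n_haplotypes: int = 80,
    n_controls: int = 100,
) -> dict:
    """Write a self-contained study-shaped input directory.

    Layout: ``genes/<id>/alignment.fasta`` + ``tree.nwk`` (foreground-marked
    focal branch), ``populations/<id>.fasta`` + ``<id>_outgroup.fasta``,
    ``genesets.tsv`` (iMEG/iPEG labels), ``controls.tsv`` (control-set PS
    flags), ``hits.tsv`` (ageing input) and ``truth.json``.  Byte-identical
    for identical seed and parameters.
    """
    out = Path(out_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    (out / "populations").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    code = get_code(1)
    truth: dict = {"seed": seed, "genes": {}}
    geneset_rows = ["gene_id\tset_label"]
    hit_rows = ["gene_id\tclade_index\tevalue"]

    n_ps = int(round(ps_fraction * n_genes))
    for g in range(n_genes):
        gene = f"G{g + 1:03d}"
        under_ps = g < n_ps
        tree = _bundle_tree(gene, n_taxa, rng)
        if under_ps:
            classes = [
                SiteClass(0.0, 0.55, None),
                SiteClass(1.0, 0.25, None),
                SiteClass(0.0, 0.12, foreground_omega, positive=True),
                SiteClass(1.0, 0.08, foreground_omega, positive=True),
            ]
        else:
            from .codon_model import discretize_beta

            classes = [SiteClass(w, p, None) for w, p in discretize_beta(0.4, 1.3, 10)]
        params = CodonModelParams(kappa=2.0, site_classes=classes)
        aln, aln_truth = simulate_codon_alignment(
            tree, params, n_codons, seed=int(rng.integers(2**31 - 1))
        )
        gene_dir = out / "genes" / gene
        gene_dir.mkdir(exist_ok=True)
        write_codon_fasta(aln, gene_dir / "alignment.fasta")
        write_newick(tree, gene_dir / "tree.nwk")

        haps, outgroup, pop_truth = simulate_population(
            n_codons, n_haplotypes, seed=int(rng.integers(2**31 - 1))
        )
        with open(out / "populations" / f"{gene}.fasta", "w") as fh:
            for i, h in enumerate(haps):
                fh.write(f">acc{i + 1:03d}\n{h}\n")
        with open(out / "populations" / f"{gene}_outgroup.fasta", "w") as fh:
            fh.write(f">outgroup\n{outgroup}\n")

        label = "iPEG" if g % 2 == 0 else "iMEG"
        geneset_rows.append(f"{gene}\t{label}")
        age = int(rng.integers(0, 10))
        for clade in range(age + 1):
            ev = 10.0 ** float(-(4 + rng.random() * 30))
            hit_rows.append(f"{gene}\t{clade}\t{ev:.3e}")
        truth["genes"][gene] = {
            "under_ps": under_ps,
            "label": label,
            "age_class": age,
            "alignment_seed": aln_truth.seed,
            "population_expected": pop_truth.expected,
        }

    # control pools with PS flags at a background incidence
    control_rows = ["gene_id\tset_label\tps_lineage\tps_site"]
    for kind, rate in (("control-genome", 0.05), ("control-endosperm", 0.08)):
        for i in range(n_controls):
            lin = int(rng.random() < rate)
            site = int(rng.random() < rate * 1.5)
            control_rows.append(f"{kind[8:10]}{i:04d}\t{kind}\t{lin}\t{site}")
    truth["controls"] = {"genome_rate": 0.05, "endosperm_rate": 0.08}

    (out / "genesets.tsv").write_text("\n".join(geneset_rows) + "\n")
    (out / "controls.tsv").write_text("\n".join(control_rows) + "\n")
    (out / "hits.tsv").write_text("\n".join(hit_rows) + "\n")
    (out / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1) + "\n")
    return truth
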