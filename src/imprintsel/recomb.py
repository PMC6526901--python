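"""Recombination screening and the two-family consensus removal rule.

Two detectors are implemented, one per method family: a substitution-based
MaxChi scan (sliding breakpoint over variable sites, 2x2 chi-square of
match/mismatch in flanking windows, permutation significance) and a
phylogenetic bootscan-style scan (bootstrap neighbour joining per window; a
sequence is flagged when its nearest neighbour changes between adjacent
windows with high support on both sides).  A sequence is removed only when
flagged by at least one method of *each* family.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .core_io import CodonAlignment, InputError

SUBSTITUTION_METHODS = {"MaxChi"}
PHYLOGENETIC_METHODS = {"BootScanLike"}


@dataclass
class RecombinationCall:
    sequence: str
    method: str
    breakpoint: int  # 1-based nucleotide column
    statistic: float
    p_value: float | None = None
    support: float | None = None
    details: dict = field(default_factory=dict)


def _nucleotide_matrix(alignment: CodonAlignment) -> np.ndarray:
    return np.array([list(s) for s in alignment.sequences])


# ---------------------------------------------------------------------------
# MaxChi
# ---------------------------------------------------------------------------

def _chi2_2x2(a, b, c, d) -> float:
    """Pearson chi-square without continuity correction; 0 for empty margins."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def maxchi_scan(
    alignment: CodonAlignment,
    window: int = 200,
    permutations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[RecombinationCall]:
    """MaxChi breakpoint scan over all sequence pairs.

    For each pair, the match/mismatch vector over the pair's comparable
    nucleotide columns is scanned for the breakpoint maximising the 2x2
    chi-square of (left/right window) x (match/mismatch).  Significance is
    assessed by permuting column order with a fixed seed.  The statistic is
    pair-autonomous: removing an unrelated sequence never changes it.  Both
    sequences of a significant pair are reported (the pairwise statistic
    carries no direction).
    """
    if alignment.n_taxa < 3:
        raise InputError("MaxChi needs at least 3 sequences")
    mat = _nucleotide_matrix(alignment)
    calls: list[RecombinationCall] = []
    for i in range(alignment.n_taxa):
        for j in range(i + 1, alignment.n_taxa):
            # pair-local stream: permutation p-values do not depend on which
            # other sequences are present
            pair_tag = zlib.crc32(f"{alignment.taxa[i]}|{alignment.taxa[j]}".encode())
            rng = np.random.default_rng([seed, pair_tag])
            valid = np.nonzero(
                np.isin(mat[i], list("ACGT")) & np.isin(mat[j], list("ACGT"))
            )[0]
            if valid.size < 4:
                continue
            mism = (mat[i, valid] != mat[j, valid]).astype(int)
            if mism.sum() == 0:
                continue
            win = min(window, max(2, valid.size // 2))
            stat, k_best = _maxchi_stat(mism, win)
            if stat <= 0:
                continue
            exceed = 0
            for _ in range(permutations):
                perm = rng.permutation(mism)
                s, _k = _maxchi_stat(perm, win)
                if s >= stat:
                    exceed += 1
            p = (1 + exceed) / (1 + permutations)
            if p < alpha:
                bp = int(valid[k_best]) + 1
                for taxon in (alignment.taxa[i], alignment.taxa[j]):
                    calls.append(
                        RecombinationCall(
                            taxon, "MaxChi", bp, float(stat), p,
                            details={"pair": (alignment.taxa[i], alignment.taxa[j])},
                        )
                    )
    return calls


def _maxchi_stat(mismatch: np.ndarray, window: int) -> tuple[float, int]:
    """Maximal 2x2 chi-square over breakpoints; returns (stat, index)."""
    n = mismatch.size
    best, best_k = 0.0, 0
    for k in range(1, n):
        left = mismatch[max(0, k - window): k]
        right = mismatch[k: k + window]
        if left.size < 2 or right.size < 2:
            continue
        a = int(left.sum())          # left mismatches
        b = left.size - a            # left matches
        c = int(right.sum())
        d = right.size - c
        stat = _chi2_2x2(a, b, c, d)
        if stat > best:
            best, best_k = stat, k
    return best, best_k


# ---------------------------------------------------------------------------
# Bootscan-like phylogenetic scan
# ---------------------------------------------------------------------------

def _p_distance_matrix(mat: np.ndarray, cols: np.ndarray) -> np.ndarray:
    sub = mat[:, cols]
    n = sub.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (sub[i] != "-") & (sub[j] != "-") & (sub[i] != "N") & (sub[j] != "N")
            total = int(valid.sum())
            d = float((sub[i][valid] != sub[j][valid]).sum() / total) if total else 0.75
            dist[i, j] = dist[j, i] = d
    return dist


def _nearest_neighbor(dist: np.ndarray, taxa: list[str], query: int) -> str:
    """Nearest neighbour of the query from an NJ tree on the distances.

    The neighbour is the leaf with minimal path length within the query's
    sister clade; ties and degenerate matrices fall back to the minimal raw
    distance, then lexicographic order.
    """
    others = [t for k, t in enumerate(taxa) if k != query]
    if np.allclose(dist, 0):
        return min(others)
    try:
        tree = nj(DistanceMatrix(dist, ids=taxa))
        qnode = tree.find(taxa[query])
        parent = qnode.parent
        candidates = [t.name for t in parent.tips() if t.name != taxa[query]]
        if not candidates:
            candidates = others
        dists = {t: tree.find(taxa[query]).distance(tree.find(t)) for t in candidates}
        best = min(dists.values())
        return min(t for t, d in dists.items() if abs(d - best) < 1e-12)
    except Exception:
        row = dist[query].copy()
        row[query] = np.inf
        best = row.min()
        return min(t for k, t in enumerate(taxa) if k != query and abs(row[k] - best) < 1e-12)


def bootscan_like_scan(
    alignment: CodonAlignment,
    window: int = 200,
    step: int = 50,
    replicates: int = 100,
    support_threshold: float = 0.70,
    seed: int = 0,
) -> list[RecombinationCall]:
    """Window-wise bootstrap NJ nearest-neighbour scan.

    Per window, columns are bootstrapped and the modal nearest neighbour of
    each sequence recorded with its bootstrap support.  A sequence is
    flagged when the modal neighbour changes between adjacent windows with
    support at or above the threshold on both sides.
    """
    if alignment.n_taxa < 4:
        raise InputError("bootscan-like scan needs at least 4 sequences")
    mat = _nucleotide_matrix(alignment)
    n_cols = mat.shape[1]
    if window < 20 or window > n_cols:
        raise InputError(f"window {window} unusable for alignment of {n_cols} columns")
    rng = np.random.default_rng(seed)
    taxa = alignment.taxa
    starts = list(range(0, n_cols - window + 1, step))
    if not starts:
        starts = [0]
    modal: list[dict[str, tuple[str, float]]] = []
    for s in starts:
        cols = np.arange(s, min(s + window, n_cols))
        votes: dict[str, dict[str, int]] = {t: {} for t in taxa}
        for _ in range(replicates):
            boot = rng.choice(cols, size=cols.size, replace=True)
            dist = _p_distance_matrix(mat, boot)
            for qi, t in enumerate(taxa):
                nb = _nearest_neighbor(dist, taxa, qi)
                votes[t][nb] = votes[t].get(nb, 0) + 1
        summary = {}
        for t in taxa:
            nb = max(sorted(votes[t]), key=lambda k: votes[t][k])
            summary[t] = (nb, votes[t][nb] / replicates)
        modal.append(summary)
    calls: list[RecombinationCall] = []
    for w in range(1, len(modal)):
        for t in taxa:
            nb_prev, sup_prev = modal[w - 1][t]
            nb_cur, sup_cur = modal[w][t]
            if (
                nb_prev != nb_cur
                and sup_prev >= support_threshold
                and sup_cur >= support_threshold
            ):
                bp = starts[w] + 1  # boundary between the two windows, 1-based
                calls.append(
                    RecombinationCall(
                        t, "BootScanLike", bp,
                        float(min(sup_prev, sup_cur)),
                        support=float(min(sup_prev, sup_cur)),
                        details={"from": nb_prev, "to": nb_cur},
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# Consensus removal rule
# ---------------------------------------------------------------------------

def recombination_consensus(calls) -> list[str]:
    """Sequences flagged by >= 1 substitution-based AND >= 1 phylogenetic method."""
    by_seq: dict[str, set[str]] = {}
    for call in calls:
        by_seq.setdefault(call.sequence, set()).add(call.method)
    removed = []
    for seq, methods in sorted(by_seq.items()):
        if methods & SUBSTITUTION_METHODS and methods & PHYLOGENETIC_METHODS:
            removed.append(seq)
    return removed
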