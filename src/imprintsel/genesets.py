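"""Gene-set comparisons: enrichment, rank tests, ageing, WGD participation.

Compares a target gene set (e.g. imprinted paternally expressed genes)
against control sets drawn from the genome-wide or endosperm-expressed
background: Mann-Whitney U tests on pairwise omega, odds-ratio enrichment of
positive-selection calls with Fisher exact tests, phylostratigraphic age-
class assignment with an r x c exact test on the age distribution, and
whole-genome-duplication participation tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exact import rxc_fisher_exact
from .core_io import InputError

N_AGE_CLASSES = 10  # AC0 (species-specific) .. AC9 (oldest clade)


@dataclass
class GeneRecord:
    gene_id: str
    set_label: str = ""
    omega: float | None = None
    ps_lineage: bool = False
    ps_site: bool = False
    age_class: int | None = None
    wgd: str = "none"  # At-alpha | At-beta | At-gamma | none
    confidence: str = "high"

    def __post_init__(self):
        if self.age_class is not None and not 0 <= self.age_class <= 9:
            raise InputError(f"age class {self.age_class} outside [0, 9]")

    @property
    def ps_any(self) -> bool:
        return self.ps_lineage or self.ps_site


# ---------------------------------------------------------------------------
# Rank test on omega
# ---------------------------------------------------------------------------

def omega_rank_test(target_omegas, background_omegas) -> dict:
    """Two-sided Mann-Whitney U test of target vs background omega.

    Missing (None/NaN) values are excluded.  Returns the p-value together
    with group means/medians for summary-table reporting.
    """
    t = np.array([w for w in target_omegas if w is not None and np.isfinite(w)])
    b = np.array([w for w in background_omegas if w is not None and np.isfinite(w)])
    if t.size == 0 or b.size == 0:
        raise InputError("omega rank test needs at least one value per group")
    stat, p = stats.mannwhitneyu(t, b, alternative="two-sided")
    return {
        "U": float(stat), "p_value": float(p),
        "target_mean": float(t.mean()), "target_median": float(np.median(t)),
        "background_mean": float(b.mean()), "background_median": float(np.median(b)),
        "n_target": int(t.size), "n_background": int(b.size),
    }


# ---------------------------------------------------------------------------
# Control-set sampling
# ---------------------------------------------------------------------------

def sample_control_sets(
    pool, set_size: int = 100, n_sets: int = 100, eligible=None, seed: int = 0
) -> list[list[str]]:
    """Uniform random control gene sets from an eligible pool.

    ``eligible`` is an optional predicate (e.g. the >= 6-species cluster
    gate); only genes passing it enter the pool.  Sampling is without
    replacement within each set and deterministic under the seed.
    """
    pool = [g for g in pool if eligible is None or eligible(g)]
    if len(pool) < set_size:
        raise InputError(
            f"eligible pool of {len(pool)} genes smaller than set size {set_size}"
        )
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        idx = rng.choice(len(pool), size=set_size, replace=False)
        sets.append([pool[i] for i in sorted(idx)])
    return sets


# ---------------------------------------------------------------------------
# Enrichment (odds ratio + Fisher)
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    table: tuple  # ((target_ps, target_not), (control_ps, control_not))
    corrected: bool = False  # Haldane-Anscombe 0.5 added to a zero cell


def _enrichment_from_table(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    corrected = 0 in (a, b, c, d)
    if corrected:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(float(orr), float(p), ((a, b), (c, d)), corrected)


def ps_enrichment(target_flags, control_flags) -> EnrichmentResult:
    """Odds-ratio enrichment of positive-selection calls, target vs control."""
    target_flags = list(target_flags)
    control_flags = list(control_flags)
    if not target_flags or not control_flags:
        raise InputError("both gene sets must be non-empty")
    a = sum(bool(f) for f in target_flags)
    b = len(target_flags) - a
    c = sum(bool(f) for f in control_flags)
    d = len(control_flags) - c
    return _enrichment_from_table(a, b, c, d)


def wgd_enrichment(target_flags, background_in: int, background_out: int) -> EnrichmentResult:
    """Fisher enrichment of WGD participation vs supplied background totals."""
    target_flags = list(target_flags)
    if not target_flags:
        raise InputError("target set must be non-empty")
    a = sum(bool(f) for f in target_flags)
    b = len(target_flags) - a
    return _enrichment_from_table(a, b, background_in, background_out)


# ---------------------------------------------------------------------------
# Phylostratigraphic ageing
# ---------------------------------------------------------------------------

def assign_age_class(hit_table, evalue_cutoff: float = 1e-3) -> int:
    """Age class of a gene from its homology-hit table.

    ``hit_table`` maps clade index (0 = focal species ... 9 = deepest clade)
    to best e-values (a DataFrame with clade_index/evalue columns, a mapping,
    or (clade, evalue) pairs).  The class is the highest clade index with a
    hit strictly below the cutoff; no hit outside the focal species gives
    class 0.
    """
    if isinstance(hit_table, pd.DataFrame):
        pairs = list(zip(hit_table["clade_index"], hit_table["evalue"]))
    elif isinstance(hit_table, dict):
        pairs = list(hit_table.items())
    else:
        pairs = list(hit_table)
    if not pairs:
        raise InputError("empty hit table")
    best = 0
    for clade, evalue in pairs:
        clade = int(clade)
        if not 0 <= clade <= 9:
            raise InputError(f"clade index {clade} outside [0, 9]")
        if float(evalue) < evalue_cutoff and clade > best:
            best = clade
    return best


def age_distribution_test(ages_a, ages_b, seed: int = 0) -> float:
    """Exact Fisher p on the age-class x set contingency table.

    All-zero class rows are dropped; tables larger than 2x2 use exact
    enumeration where feasible and a seeded margin-conditional Monte-Carlo
    estimate otherwise.
    """
    ages_a, ages_b = list(ages_a), list(ages_b)
    if not ages_a or not ages_b:
        raise InputError("both sets must be non-empty")
    table = np.zeros((N_AGE_CLASSES, 2), dtype=int)
    for a in ages_a:
        table[int(a), 0] += 1
    for b in ages_b:
        table[int(b), 1] += 1
    table = table[table.sum(axis=1) > 0]
    return float(rxc_fisher_exact(table, seed=seed))


# ---------------------------------------------------------------------------
# Category summary (counts of lineage-only / site-only / both)
# ---------------------------------------------------------------------------

def _percent(x: float, total: float) -> float:
    """Percentage rounded half-up to one decimal."""
    if total == 0:
        return 0.0
    return math.floor(1000.0 * x / total + 0.5) / 10.0


def summarize_categories(records, set_labels=("iMEG", "iPEG")) -> pd.DataFrame:
    """Category summary of positive-selection calls by gene set.

    Rows: tested, lineage-only, site-only, both, total-under-PS (with
    percentages of tested genes); columns: one per set label plus a Total
    column.  Categories are mutually exclusive and partition the tested
    genes together with the 'none' remainder.
    """
    records = list(records)
    cols = list(set_labels) + ["Total"]
    rows = ["tested", "lineage_only", "site_only", "both", "total_ps"]
    counts = {c: dict.fromkeys(rows, 0) for c in cols}
    for rec in records:
        targets = [rec.set_label] if rec.set_label in set_labels else []
        targets.append("Total")
        for t in targets:
            counts[t]["tested"] += 1
            if rec.ps_lineage and rec.ps_site:
                counts[t]["both"] += 1
            elif rec.ps_lineage:
                counts[t]["lineage_only"] += 1
            elif rec.ps_site:
                counts[t]["site_only"] += 1
            if rec.ps_any:
                counts[t]["total_ps"] += 1
    data = {}
    for c in cols:
        tested = counts[c]["tested"]
        data[c] = [counts[c][r] for r in rows]
        data[f"{c}_pct"] = [
            np.nan,
            _percent(counts[c]["lineage_only"], tested),
            _percent(counts[c]["site_only"], tested),
            _percent(counts[c]["both"], tested),
            _percent(counts[c]["total_ps"], tested),
        ]
    return pd.DataFrame(data, index=rows)
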