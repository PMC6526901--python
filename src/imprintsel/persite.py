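"""Per-site positive-selection detectors and the multi-method consensus rule.

Two detector families complement the empirical-Bayes site posteriors of the
mixture models: an ancestor-counting test (SLAC-style — count synonymous and
nonsynonymous changes over the tree at each site and compare with the
mutational opportunity of the codons present) and a fixed-effects likelihood
test (FEL-style — per-site ML fit of a synonymous rate alpha and a
nonsynonymous rate beta with an LRT of beta = alpha).  A site is *confirmed*
positively selected when at least ``min_methods`` methods flag it, and
confirmed sites falling in alignment columns with more than 40% gaps are
masked out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .codon_model import PruningEngine, SiteClassFit, SitePosteriorResult
from .core_io import OrthologCluster

METHOD_FAMILIES = ("NEB", "BEB", "FEL", "SLAC")


@dataclass
class SiteCall:
    site: int  # 1-based codon column
    method: str
    direction: str  # positive | negative | none
    score: float  # posterior for NEB/BEB, p-value for FEL/SLAC
    passed: bool
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Ancestral reconstruction (marginal ML under fitted M0)
# ---------------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    engine: PruningEngine
    states: np.ndarray        # (n_nodes, n_patterns) codon state indices
    informative: np.ndarray   # (n_nodes, n_patterns) node carries data at pattern
    kappa: float
    omega: float
    branch_lengths: np.ndarray


def reconstruct_ancestors(data, m0_fit: SiteClassFit) -> AncestralReconstruction:
    """Marginal ML codon states at every node under the M0 estimates.

    Ties are broken toward the smallest codon index (lexicographic order),
    which keeps the reconstruction deterministic.
    """
    engine = m0_fit._engine
    if engine is None:
        alignment, tree = (data.alignment, data.tree) if isinstance(data, OrthologCluster) else data
        engine = PruningEngine(alignment, tree)
    kappa = m0_fit.params.kappa
    omega = m0_fit.params.site_classes[0].omega
    bl = m0_fit.branch_lengths
    dec = engine._decomp(kappa, omega)

    # upward (partial) pass, keeping every node's array
    partial = [None] * engine.n_nodes
    up_msg = [None] * engine.n_nodes  # partial[ch] @ P_ch.T for each child
    for i in range(engine.n_nodes):
        if engine.node_is_leaf[i]:
            partial[i] = engine.leaf_partials[i]
        else:
            acc = np.ones((engine.n_patterns, engine.code.n_states))
            for ch in engine.node_children[i]:
                P = engine._pmatrix(dec, bl[ch])
                msg = partial[ch] @ P.T
                up_msg[ch] = (msg, P)
                acc = acc * msg
            m = np.maximum(acc.max(axis=1, keepdims=True), 1e-300)
            partial[i] = acc / m

    # downward (outside) pass
    outside = [None] * engine.n_nodes
    outside[engine.root_index] = np.tile(engine.pi, (engine.n_patterns, 1))
    for i in range(engine.n_nodes - 1, -1, -1):
        if engine.node_is_leaf[i]:
            continue
        for ch in engine.node_children[i]:
            msg = outside[i].copy()
            for sib in engine.node_children[i]:
                if sib != ch:
                    msg = msg * up_msg[sib][0]
            P = up_msg[ch][1]
            out = msg @ P
            m = np.maximum(out.max(axis=1, keepdims=True), 1e-300)
            outside[ch] = out / m

    n_states = engine.code.n_states
    states = np.zeros((engine.n_nodes, engine.n_patterns), dtype=int)
    informative = np.zeros((engine.n_nodes, engine.n_patterns), dtype=bool)
    for i in range(engine.n_nodes):
        post = outside[i] * partial[i]
        if engine.node_is_leaf[i]:
            mask = engine.leaf_partials[i] > 0
            states[i] = np.argmax(post * mask, axis=1)
            informative[i] = mask.sum(axis=1) < n_states
        else:
            states[i] = np.argmax(post, axis=1)
            informative[i] = True
    return AncestralReconstruction(engine, states, informative, kappa, omega, np.asarray(bl))


# ---------------------------------------------------------------------------
# SLAC-style ancestor-counting test
# ---------------------------------------------------------------------------

def _binomial_tail_fractional(x: float, n: float, p: float) -> tuple[float, float]:
    """P[X >= x] and P[X <= x] for a binomial extended to fractional counts.

    Uses the regularised incomplete beta function, which reduces to the
    exact binomial tail at integer arguments.
    """
    if n <= 0:
        return 1.0, 1.0
    p = min(max(p, 1e-12), 1 - 1e-12)
    sf = 1.0 if x <= 0 else float(special.betainc(x, n - x + 1, p))
    cdf = 1.0 if x >= n else float(special.betainc(n - x, x + 1, 1 - p))
    return sf, cdf


def slac_site_test(
    recon: AncestralReconstruction, site: int, threshold: float = 0.05
) -> SiteCall:
    """Counting test at one 1-based codon site.

    Counts pathway-averaged synonymous/nonsynonymous changes along branches
    between reconstructed (or observed) codons, compares the nonsynonymous
    count against the expected nonsynonymous fraction given the codons
    present, using a two-sided extended binomial test.
    """
    engine = recon.engine
    pat = int(engine.pattern_of_site[site - 1])
    code = engine.code
    syn = nonsyn = 0.0
    present: set[int] = set()
    for i in range(engine.n_nodes - 1):  # every non-root node has a parent edge
        parent = _parent_of(engine, i)
        if not recon.informative[i, pat]:
            continue
        a = code.sense_codons[recon.states[parent, pat]]
        b = code.sense_codons[recon.states[i, pat]]
        present.add(recon.states[parent, pat])
        present.add(recon.states[i, pat])
        s, n = code.pathway_counts(a, b)
        syn += s
        nonsyn += n
    total = syn + nonsyn
    if total == 0:
        return SiteCall(site, "SLAC", "none", 1.0,
                        False, {"syn": 0.0, "nonsyn": 0.0, "expected_nonsyn_fraction": np.nan})
    syn_frac = float(np.mean([code.synonymous_site_fraction(s) for s in sorted(present)]))
    p_nonsyn = 1.0 - syn_frac
    sf, cdf = _binomial_tail_fractional(nonsyn, total, p_nonsyn)
    p = min(1.0, 2.0 * min(sf, cdf))
    if nonsyn > total * p_nonsyn:
        direction = "positive"
    elif nonsyn < total * p_nonsyn:
        direction = "negative"
    else:
        direction = "none"
    passed = direction != "none" and p < threshold
    return SiteCall(site, "SLAC", direction, p, passed,
                    {"syn": syn, "nonsyn": nonsyn, "expected_nonsyn_fraction": p_nonsyn})


def _parent_of(engine: PruningEngine, node: int) -> int:
    if not hasattr(engine, "_parent_cache"):
        parent = np.full(engine.n_nodes, -1)
        for i, children in enumerate(engine.node_children):
            for ch in children:
                parent[ch] = i
        engine._parent_cache = parent
    return int(engine._parent_cache[node])


def slac_all_sites(recon: AncestralReconstruction, threshold: float = 0.05) -> list[SiteCall]:
    return [slac_site_test(recon, s, threshold) for s in range(1, recon.engine.n_sites + 1)]


# ---------------------------------------------------------------------------
# FEL-style fixed-effects likelihood test
# ---------------------------------------------------------------------------

def fel_site_test(
    data_or_engine, m0_fit: SiteClassFit, site: int, threshold: float = 0.05
) -> SiteCall:
    """Per-site ML fit of synonymous rate alpha and nonsynonymous rate beta.

    Branch lengths and kappa are fixed at the M0 estimates; the rates are
    absolute multipliers of the gene-average rate.  LRT of beta = alpha on
    one degree of freedom; positive iff beta > alpha with p below threshold.
    """
    engine = m0_fit._engine if m0_fit._engine is not None else _engine_from(data_or_engine)
    pat = np.array([engine.pattern_of_site[site - 1]])
    kappa = m0_fit.params.kappa
    bl = m0_fit.branch_lengths

    # degenerate site: fewer than two distinct observed states
    observed = set()
    for i in range(engine.n_nodes):
        if engine.node_is_leaf[i]:
            mask = engine.leaf_partials[i][pat[0]]
            if mask.sum() < engine.code.n_states:
                observed.add(tuple(np.nonzero(mask)[0]))
    distinct = {s for tup in observed for s in tup} if observed else set()
    if len(observed) <= 1 or len(distinct) <= 1:
        return SiteCall(site, "FEL", "none", 1.0, False, {"alpha": 0.0, "beta": 0.0})

    lo, hi = np.log(1e-4), np.log(100.0)

    def neg_alt(x):
        return -float(engine.general_site_loglik(kappa, np.exp(x[0]), np.exp(x[1]), bl, pat)[0])

    def neg_null(x):
        r = np.exp(x[0])
        return -float(engine.general_site_loglik(kappa, r, r, bl, pat)[0])

    best_alt = optimize.minimize(neg_alt, np.array([0.0, 0.0]), method="L-BFGS-B",
                                 bounds=[(lo, hi)] * 2, options={"ftol": 1e-8})
    res_null = optimize.minimize(neg_null, np.array([0.0]), method="L-BFGS-B",
                                 bounds=[(lo, hi)], options={"ftol": 1e-8})
    alpha_hat, beta_hat = np.exp(best_alt.x)
    stat = max(0.0, 2.0 * (res_null.fun - best_alt.fun))
    p = float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
    if beta_hat > alpha_hat:
        direction = "positive"
    elif beta_hat < alpha_hat:
        direction = "negative"
    else:
        direction = "none"
    passed = direction != "none" and p < threshold
    return SiteCall(site, "FEL", direction, p, passed,
                    {"alpha": float(alpha_hat), "beta": float(beta_hat), "stat": stat})


def _engine_from(data):
    if isinstance(data, PruningEngine):
        return data
    if isinstance(data, OrthologCluster):
        return PruningEngine(data.alignment, data.tree)
    alignment, tree = data
    return PruningEngine(alignment, tree)


def fel_all_sites(data_or_engine, m0_fit: SiteClassFit, threshold: float = 0.05) -> list[SiteCall]:
    """FEL test over every codon site, computed once per unique site pattern."""
    engine = m0_fit._engine if m0_fit._engine is not None else _engine_from(data_or_engine)
    by_pattern: dict[int, SiteCall] = {}
    calls = []
    for s in range(1, engine.n_sites + 1):
        pat = int(engine.pattern_of_site[s - 1])
        if pat in by_pattern:
            ref = by_pattern[pat]
            calls.append(SiteCall(s, ref.method, ref.direction, ref.score,
                                  ref.passed, dict(ref.details)))
        else:
            call = fel_site_test(engine, m0_fit, s, threshold)
            by_pattern[pat] = call
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# Empirical-Bayes calls, consensus rule, gap masking
# ---------------------------------------------------------------------------

def eb_site_calls(result: SitePosteriorResult) -> list[SiteCall]:
    """Convert NEB/BEB posteriors into SiteCall records (positive direction)."""
    calls = []
    for s, post in enumerate(result.posterior, start=1):
        passed = post > result.threshold
        calls.append(
            SiteCall(s, result.method, "positive" if passed else "none",
                     float(post), bool(passed))
        )
    return calls


def consensus_ps_sites(calls, min_methods: int = 2) -> list[int]:
    """Sites flagged positive by at least ``min_methods`` distinct methods."""
    by_site: dict[int, set[str]] = {}
    for call in calls:
        if call.passed and call.direction == "positive":
            by_site.setdefault(call.site, set()).add(call.method)
    return sorted(s for s, methods in by_site.items() if len(methods) >= min_methods)


def mask_sites_by_gap(sites, gap_fractions, cutoff: float = 0.40) -> list[int]:
    """Drop confirmed sites in columns with gap fraction strictly above cutoff."""
    gap_fractions = np.asarray(gap_fractions)
    return [s for s in sites if gap_fractions[s - 1] <= cutoff]
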