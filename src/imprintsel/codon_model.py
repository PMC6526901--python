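"""GY94-style codon substitution models, likelihood engine, and site-model fits.

The engine implements Felsenstein pruning over the 61 sense codons with
transition/transversion bias kappa, nonsynonymous/synonymous ratio omega and
stationary codon frequencies (F3x4 or F61).  On top of it sit the classic
site and branch-site model fits (M0, M1Neutral, M7, M8, M8a, Model A and its
null), likelihood-ratio tests, and empirical-Bayes site posteriors (NEB, and
BEB for M8).

Conventions
-----------
* Omega-class generators are scaled by the rate of the *neutral* (omega = 1)
  matrix: branch lengths read as expected substitutions per codon site under
  neutral composition, and a class with omega > 1 evolves proportionally
  faster.  The scaling constant depends only on (kappa, frequencies), so the
  per-site likelihood of a class is a function of that class's omega alone
  given fixed branch lengths — the mixture optimiser exploits this by
  caching exact per-site log-likelihoods on an omega grid and interpolating
  with cubic splines; reported log-likelihoods are always recomputed exactly
  at the optimum.
* Mixture models reuse branch lengths and kappa from an M0 fit of the same
  data (re-estimation of kappa available via ``FitOptions.reestimate_kappa``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .core_io import CodonAlignment, InputError, OrthologCluster, PhyloTree
from .genetics import GeneticCode, get_code


class ModelUsageError(ValueError):
    """A model operation was requested outside its contract."""


# ---------------------------------------------------------------------------
# Parameters and fitted-model records
# ---------------------------------------------------------------------------

@dataclass
class SiteClass:
    """One omega class of a site-model mixture.

    ``foreground_omega`` (branch-site models) applies on marked foreground
    branches; ``None`` means the background omega applies tree-wide.
    ``positive`` marks the class whose membership defines a positively
    selected site, independent of the numeric estimate.
    """

    omega: float
    proportion: float
    foreground_omega: float | None = None
    positive: bool = False

    def effective(self, foreground: bool) -> float:
        if foreground and self.foreground_omega is not None:
            return self.foreground_omega
        return self.omega


@dataclass
class CodonModelParams:
    kappa: float
    site_classes: list[SiteClass]
    freqs: np.ndarray | None = None
    beta_params: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kappa <= 0:
            raise ModelUsageError("kappa must be positive")
        total = sum(c.proportion for c in self.site_classes)
        if abs(total - 1.0) > 1e-9:
            raise ModelUsageError(f"class proportions sum to {total}, not 1")
        for c in self.site_classes:
            if c.omega < 0 or (c.foreground_omega is not None and c.foreground_omega < 0):
                raise ModelUsageError("omega must be non-negative")
        if self.freqs is not None:
            self.freqs = np.asarray(self.freqs, dtype=float)
            if abs(self.freqs.sum() - 1.0) > 1e-9:
                raise ModelUsageError("codon frequencies must sum to 1")


@dataclass
class SiteClassFit:
    model_id: str
    lnL: float
    params: CodonModelParams
    branch_lengths: np.ndarray
    site_posteriors: np.ndarray  # (n_sites, n_classes)
    converged: bool
    n_free_params: int
    # private plumbing for empirical-Bayes posteriors
    _engine: "PruningEngine | None" = field(default=None, repr=False)
    _site_class_loglik: np.ndarray | None = field(default=None, repr=False)


@dataclass
class LRTResult:
    stat: float
    df: int
    p_value: float
    alt_id: str
    null_id: str


# ---------------------------------------------------------------------------
# Rate matrices and stationary frequencies
# ---------------------------------------------------------------------------

def build_rate_matrix(
    kappa: float,
    omega: float,
    freqs: np.ndarray,
    code: GeneticCode | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Instantaneous GY94 rate matrix over sense codons.

    ``q_ij`` is nonzero only for single-nucleotide changes and equals
    ``pi_j * kappa^[transition] * omega^[nonsynonymous]``; rows sum to zero.
    With ``normalize`` the matrix is scaled to one expected substitution per
    unit time at stationarity.
    """
    return _rate_matrix_general(kappa, 1.0, omega, freqs, code, normalize)


def _rate_matrix_general(kappa, syn_rate, nonsyn_rate, freqs, code=None, normalize=True):
    code = code or get_code(1)
    pi = np.asarray(freqs, dtype=float)
    if pi.shape != (code.n_states,):
        raise ModelUsageError(f"need {code.n_states} codon frequencies")
    if pi.sum() <= 0:
        raise ModelUsageError("all-zero codon frequencies")
    Q = np.zeros((code.n_states, code.n_states))
    rate = pi[code.pair_j] * np.where(code.pair_transition, kappa, 1.0)
    rate = rate * np.where(code.pair_nonsyn, nonsyn_rate, syn_rate)
    Q[code.pair_i, code.pair_j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mean_rate = -(pi * np.diag(Q)).sum()
        if mean_rate <= 0:
            raise ModelUsageError("degenerate rate matrix (zero mean rate)")
        Q = Q / mean_rate
    return Q


def substitution_fractions(kappa, omega, freqs, code=None) -> tuple[float, float]:
    """Fractions of substitutions that are synonymous / nonsynonymous."""
    code = code or get_code(1)
    pi = np.asarray(freqs, dtype=float)
    rate = pi[code.pair_j] * np.where(code.pair_transition, kappa, 1.0)
    rate = rate * np.where(code.pair_nonsyn, omega, 1.0)
    flux = pi[code.pair_i] * rate
    total = flux.sum()
    syn = flux[~code.pair_nonsyn].sum()
    return syn / total, 1.0 - syn / total


def neutral_scaled_rate_matrix(kappa, omega, freqs, code=None) -> np.ndarray:
    """GY94 rate matrix scaled by the rate of the neutral (omega = 1) matrix.

    This is the engine's convention for omega classes: branch lengths read
    as expected substitutions per codon site under neutral composition, and
    a class with omega > 1 evolves proportionally faster (omega < 1 slower),
    preserving the rate-elevation signature that branch-site tests rely on.
    The scaling constant depends only on (kappa, freqs), so the per-site
    likelihood of a class is a function of that class's omega alone.
    """
    code = code or get_code(1)
    pi = np.asarray(freqs, dtype=float)
    neutral = _rate_matrix_general(kappa, 1.0, 1.0, pi, code, normalize=False)
    neutral_rate = -(pi * np.diag(neutral)).sum()
    if neutral_rate <= 0:
        raise ModelUsageError("degenerate neutral rate")
    return _rate_matrix_general(kappa, 1.0, omega, pi, code, normalize=False) / neutral_rate


def relative_class_rate(kappa, omega, freqs, code=None) -> float:
    """Total substitution rate of an omega class relative to neutral."""
    code = code or get_code(1)
    pi = np.asarray(freqs, dtype=float)
    q = _rate_matrix_general(kappa, 1.0, omega, pi, code, normalize=False)
    q1 = _rate_matrix_general(kappa, 1.0, 1.0, pi, code, normalize=False)
    return float((pi * np.diag(q)).sum() / (pi * np.diag(q1)).sum())


def codon_frequencies(alignment: CodonAlignment, mode: str = "f3x4") -> np.ndarray:
    """Stationary codon frequencies from the alignment (F3x4 or F61)."""
    code = alignment.code
    floor = 1e-8
    if mode == "f61":
        counts = np.full(code.n_states, 0.5)  # pseudocount
        for i in range(alignment.n_taxa):
            for c in range(1, alignment.n_codons + 1):
                idx = code.codon_index.get(alignment.codon(i, c))
                if idx is not None:
                    counts[idx] += 1.0
        pi = counts / counts.sum()
    elif mode == "f3x4":
        pos_counts = np.full((3, 4), 0.5)
        nuc_index = {n: k for k, n in enumerate("ACGT")}
        for i in range(alignment.n_taxa):
            for c in range(1, alignment.n_codons + 1):
                codon = alignment.codon(i, c)
                if codon in code.codon_index:
                    for p, n in enumerate(codon):
                        pos_counts[p, nuc_index[n]] += 1.0
        pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                pos_freq[0, nuc_index[c[0]]]
                * pos_freq[1, nuc_index[c[1]]]
                * pos_freq[2, nuc_index[c[2]]]
                for c in code.sense_codons
            ]
        )
    else:
        raise ModelUsageError(f"unknown frequency mode {mode!r}")
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def discretize_beta(p: float, q: float, K: int = 10) -> list[tuple[float, float]]:
    """K equal-probability classes for a beta(p, q) omega distribution.

    Each class omega is the conditional mean of the beta distribution within
    its quantile bin, so the class means average exactly to p/(p+q).
    """
    if p <= 0 or q <= 0:
        raise ModelUsageError("beta shapes must be positive")
    if K < 1:
        raise ModelUsageError("K must be >= 1")
    bounds = stats.beta.ppf(np.linspace(0.0, 1.0, K + 1), p, q)
    mean = p / (p + q)
    upper = special.betainc(p + 1, q, bounds[1:])
    lower = special.betainc(p + 1, q, bounds[:-1])
    omegas = K * mean * (upper - lower)
    omegas = np.clip(omegas, 0.0, 1.0)
    return [(float(w), 1.0 / K) for w in omegas]


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------

class PruningEngine:
    """Felsenstein pruning over sense codons for one alignment + tree.

    Site columns are compressed to unique patterns; gaps and ambiguous
    codons contribute a partial-likelihood vector that is 1 on every
    compatible codon (missing-data integration).
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhyloTree,
        freqs: np.ndarray | None = None,
        freqs_mode: str = "f3x4",
    ):
        self.alignment = alignment
        self.tree = tree
        self.code = alignment.code
        leaf_names = tree.leaf_names
        missing = set(leaf_names) - set(alignment.taxa)
        if missing:
            raise InputError(f"tree leaves missing from alignment: {sorted(missing)}")
        self.pi = np.asarray(freqs, float) if freqs is not None else codon_frequencies(
            alignment, freqs_mode
        )
        self._sqrt_pi = np.sqrt(self.pi)

        # --- flatten tree (postorder; root last) ---
        nodes = tree.postorder()
        self.n_nodes = len(nodes)
        self.node_children: list[list[int]] = []
        self.node_is_leaf = np.zeros(self.n_nodes, bool)
        self.node_foreground = np.zeros(self.n_nodes, bool)
        self.input_lengths = np.zeros(self.n_nodes)
        index_of = {id(n): i for i, n in enumerate(nodes)}
        leaf_taxon: dict[int, int] = {}
        taxon_row = {t: i for i, t in enumerate(alignment.taxa)}
        for i, node in enumerate(nodes):
            self.node_children.append([index_of[id(ch)] for ch in node.children])
            self.node_is_leaf[i] = node.is_leaf
            self.node_foreground[i] = node.foreground
            self.input_lengths[i] = node.length
            if node.is_leaf:
                leaf_taxon[i] = taxon_row[node.name]
        self.root_index = self.n_nodes - 1
        self.n_edges = self.n_nodes - 1

        # --- compress site patterns ---
        n_sites = alignment.n_codons
        columns = []
        for c in range(1, n_sites + 1):
            columns.append(
                tuple(alignment.sequences[leaf_taxon[i]][3 * (c - 1): 3 * (c - 1) + 3]
                      for i in sorted(leaf_taxon))
            )
        uniq: dict[tuple, int] = {}
        self.pattern_of_site = np.zeros(n_sites, dtype=int)
        for s, col in enumerate(columns):
            if col not in uniq:
                uniq[col] = len(uniq)
            self.pattern_of_site[s] = uniq[col]
        self.n_patterns = len(uniq)
        self.pattern_counts = np.bincount(self.pattern_of_site, minlength=self.n_patterns).astype(float)
        self.n_sites = n_sites

        # leaf partials (n_patterns, n_states) per leaf node
        sorted_leaves = sorted(leaf_taxon)
        leaf_pos = {node_i: k for k, node_i in enumerate(sorted_leaves)}
        self.leaf_partials: dict[int, np.ndarray] = {}
        mask_cache: dict[str, np.ndarray] = {}
        for node_i in sorted_leaves:
            arr = np.empty((self.n_patterns, self.code.n_states))
            for pat, row in uniq.items():
                codon = pat[leaf_pos[node_i]]
                if codon not in mask_cache:
                    mask_cache[codon] = self.code.state_mask(codon).astype(float)
                arr[row] = mask_cache[codon]
            self.leaf_partials[node_i] = arr

        self._decomp_cache: dict[tuple, tuple] = {}

    # -- spectral machinery ------------------------------------------------

    def _decomp(self, kappa: float, omega: float):
        key = (round(float(kappa), 12), round(float(omega), 12))
        hit = self._decomp_cache.get(key)
        if hit is not None:
            return hit
        Q = neutral_scaled_rate_matrix(kappa, omega, self.pi, self.code)
        d = self._sqrt_pi
        B = Q * (d[:, None] / d[None, :])
        B = 0.5 * (B + B.T)  # symmetrise numerical noise
        lam, U = np.linalg.eigh(B)
        left = U / d[:, None]     # D^{-1/2} U
        right = U.T * d[None, :]  # U^T D^{1/2}
        out = (lam, left, right)
        if len(self._decomp_cache) > 4096:
            self._decomp_cache.clear()
        self._decomp_cache[key] = out
        return out

    def _pmatrix(self, decomp, t: float) -> np.ndarray:
        lam, left, right = decomp
        P = (left * np.exp(lam * t)) @ right
        np.maximum(P, 0.0, out=P)
        return P

    def general_site_loglik(
        self,
        kappa: float,
        syn_rate: float,
        nonsyn_rate: float,
        branch_lengths: np.ndarray | None = None,
        patterns: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-pattern log-likelihood under site-specific syn/nonsyn rates.

        alpha = beta = 1 reproduces the neutral matrix, so the site-specific
        rates of the FEL test are absolute multipliers of the gene-average
        branch lengths.  Internally Q(alpha, beta) = alpha * Q(1, beta/alpha),
        so the cached omega decompositions are reused with branch lengths
        scaled by alpha.  ``patterns`` restricts the computation to a subset
        of pattern rows (used by the per-site FEL fits).
        """
        bl = self.input_lengths if branch_lengths is None else np.asarray(branch_lengths)
        syn = max(float(syn_rate), 1e-9)
        ratio = min(float(nonsyn_rate) / syn, 1e6)
        dec = self._decomp(kappa, ratio)
        bl = bl * syn
        rows = np.arange(self.n_patterns) if patterns is None else np.asarray(patterns)
        partial = [None] * self.n_nodes
        log_scale = np.zeros(len(rows))
        for i in range(self.n_nodes):
            if self.node_is_leaf[i]:
                partial[i] = self.leaf_partials[i][rows]
                continue
            acc = np.ones((len(rows), self.code.n_states))
            for ch in self.node_children[i]:
                P = self._pmatrix(dec, bl[ch])
                acc = acc * (partial[ch] @ P.T)
            m = acc.max(axis=1)
            safe = m > 0
            acc[safe] /= m[safe, None]
            with np.errstate(divide="ignore"):
                log_scale += np.where(safe, np.log(np.maximum(m, 1e-300)), -np.inf)
            partial[i] = acc
        lik = partial[self.root_index] @ self.pi
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(lik, 1e-300)) + log_scale

    # -- likelihood --------------------------------------------------------

    def class_site_loglik(
        self,
        kappa: float,
        omega: float,
        foreground_omega: float | None = None,
        branch_lengths: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-pattern log-likelihood for a single omega class."""
        bl = self.input_lengths if branch_lengths is None else np.asarray(branch_lengths)
        dec_bg = self._decomp(kappa, omega)
        dec_fg = self._decomp(kappa, foreground_omega) if foreground_omega is not None else dec_bg
        partial = [None] * self.n_nodes
        log_scale = np.zeros(self.n_patterns)
        for i in range(self.n_nodes):
            if self.node_is_leaf[i]:
                partial[i] = self.leaf_partials[i]
                continue
            acc = np.ones((self.n_patterns, self.code.n_states))
            for ch in self.node_children[i]:
                dec = dec_fg if self.node_foreground[ch] else dec_bg
                P = self._pmatrix(dec, bl[ch])
                acc = acc * (partial[ch] @ P.T)
            m = acc.max(axis=1)
            safe = m > 0
            acc[safe] /= m[safe, None]
            with np.errstate(divide="ignore"):
                log_scale += np.where(safe, np.log(np.maximum(m, 1e-300)), -np.inf)
            partial[i] = acc
        lik = partial[self.root_index] @ self.pi
        with np.errstate(divide="ignore"):
            out = np.where(lik > 0, np.log(np.maximum(lik, 1e-300)), -np.inf) + log_scale
        if np.any(np.isnan(out)):
            bad = int(np.argmax(np.isnan(out)))
            site = int(np.argmax(self.pattern_of_site == bad)) + 1
            raise ModelUsageError(f"non-finite likelihood at codon site {site}")
        return out

    def class_matrix(self, kappa, classes, branch_lengths=None) -> np.ndarray:
        """Stack of per-pattern log-likelihoods, one row per (bg, fg) class."""
        return np.vstack(
            [self.class_site_loglik(kappa, bg, fg, branch_lengths) for bg, fg in classes]
        )

    def mixture_loglik(self, kappa, site_classes, branch_lengths=None):
        """(total lnL, per-pattern lnL, per-pattern-per-class lnL matrix)."""
        used = [(c.omega, c.foreground_omega, c.proportion) for c in site_classes]
        mat = self.class_matrix(kappa, [(b, f) for b, f, _ in used], branch_lengths)
        logw = np.array([np.log(p) if p > 0 else -np.inf for _, _, p in used])
        per_pattern = special.logsumexp(mat + logw[:, None], axis=0)
        total = float(np.dot(per_pattern, self.pattern_counts))
        return total, per_pattern, mat

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map per-pattern values back to per-site order (1 row per site)."""
        return per_pattern[..., self.pattern_of_site]


def log_likelihood(alignment, tree, params: CodonModelParams):
    """Total log-likelihood and per-site log-likelihood vector."""
    engine = PruningEngine(alignment, tree, freqs=params.freqs)
    total, per_pattern, _ = engine.mixture_loglik(params.kappa, params.site_classes)
    return total, engine.expand(per_pattern)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    freqs_mode: str = "f3x4"
    starts: int = 3
    omega_starts: tuple = (0.1, 0.4, 1.5)
    branch_mode: str = "free"  # for M0: free | scale | fixed
    kappa: float | None = None  # fix kappa at this value
    base_fit: SiteClassFit | None = None  # M0 fit supplying BLs + kappa
    m1_variant: str = "omega0_zero"  # or "m1a"
    reestimate_kappa: bool = False
    omega_max: float = 20.0
    grid_points: int = 20
    tol: float = 1e-6


_KAPPA_BOUNDS = (np.log(0.05), np.log(50.0))
_BL_BOUNDS = (np.log(1e-6), np.log(30.0))

MODEL_IDS = ("M0", "M1Neutral", "M7", "M8", "M8a", "ModelA", "ModelAnull")

#: registered nested pairs -> LRT degrees of freedom
LRT_NESTING = {
    ("M8", "M7"): 2,
    ("M8", "M8a"): 1,
    ("ModelA", "ModelAnull"): 1,
    ("ModelA", "M1Neutral"): 2,
    ("M1Neutral", "M0"): 1,
}


def _unpack(data):
    if isinstance(data, OrthologCluster):
        return data.alignment, data.tree
    alignment, tree = data
    return alignment, tree


class _OmegaGrid:
    """Cubic-spline cache of exact per-pattern log-likelihoods over omega."""

    def __init__(self, engine, kappa, branch_lengths, omega_max=20.0,
                 foreground: bool = False):
        from scipy.interpolate import CubicSpline

        self.engine = engine
        self.kappa = kappa
        self.bl = branch_lengths
        self.omega_floor = 1e-4  # structural-zero guard; documented floor
        lo_log = np.geomspace(self.omega_floor, 0.06, 7)
        lo_lin = np.linspace(0.06, 1.0, 17)
        self.gridlo = lo_log
        self.grid01 = lo_lin
        self.gridpos = np.geomspace(1.0, omega_max, 10)
        if foreground:
            # background omega 0 makes some patterns structurally impossible
            # (-inf for every omega2); spline only the finite columns
            y0 = np.vstack([
                engine.class_site_loglik(kappa, 0.0, w, branch_lengths) for w in self.gridpos
            ])
            y1 = np.vstack([
                engine.class_site_loglik(kappa, 1.0, w, branch_lengths) for w in self.gridpos
            ])
            self._fg0_finite = np.isfinite(y0).all(axis=0)
            self._fg0 = CubicSpline(np.log(self.gridpos), y0[:, self._fg0_finite], axis=0)
            self._fg1 = CubicSpline(np.log(self.gridpos), y1, axis=0)
            self._bg01 = None
            self._bgpos = None
        else:
            ylo = np.vstack([
                engine.class_site_loglik(kappa, w, None, branch_lengths)
                for w in self.gridlo
            ])
            self._bglo = CubicSpline(np.log(self.gridlo), ylo, axis=0)
            y = np.vstack([
                engine.class_site_loglik(kappa, w, None, branch_lengths)
                for w in self.grid01
            ])
            self._bg01 = CubicSpline(self.grid01, y, axis=0)
            ypos = np.vstack([
                engine.class_site_loglik(kappa, w, None, branch_lengths) for w in self.gridpos
            ])
            self._bgpos = CubicSpline(np.log(self.gridpos), ypos, axis=0)

    def background(self, omegas) -> np.ndarray:
        omegas = np.clip(np.atleast_1d(np.asarray(omegas, float)), self.omega_floor, None)
        out = np.empty((omegas.size, self.engine.n_patterns))
        low = omegas < 0.06
        mid = (omegas >= 0.06) & (omegas <= 1.0)
        high = omegas > 1.0
        if low.any():
            out[low] = self._bglo(np.log(omegas[low]))
        if mid.any():
            out[mid] = self._bg01(omegas[mid])
        if high.any():
            out[high] = self._bgpos(np.log(omegas[high]))
        return out

    def foreground(self, bg: float, omega2: float) -> np.ndarray:
        x = np.log(np.clip(omega2, 1.0, None))
        if bg == 0.0:
            out = np.full(self.engine.n_patterns, -np.inf)
            out[self._fg0_finite] = self._fg0(x)
            return out
        return self._fg1(x)


def _mix_lnL(logliks: np.ndarray, props: np.ndarray, counts: np.ndarray) -> float:
    logw = np.where(props > 0, np.log(np.maximum(props, 1e-300)), -np.inf)
    per_pattern = special.logsumexp(logliks + logw[:, None], axis=0)
    return float(np.dot(per_pattern, counts))


def _optimize_multistart(neg, x0_list, bounds, tol):
    """Bounded L-BFGS over several starts; Nelder-Mead polish on failure.

    Flat likelihood surfaces (boundary optima under null data) occasionally
    abort the L-BFGS line search; the simplex polish confirms or improves
    the optimum so the converged flag stays honest.
    """
    best = None
    for x0 in x0_list:
        res = optimize.minimize(
            neg, np.asarray(x0, dtype=float), method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not best.success and np.isfinite(best.fun):
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        polish = optimize.minimize(
            lambda x: neg(np.clip(x, lo, hi)), best.x, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
        )
        x = np.clip(polish.x, lo, hi)
        fun = float(neg(x))
        if fun <= best.fun + 1e-9:
            best = optimize.OptimizeResult(
                x=x, fun=fun, success=bool(polish.success), status=0
            )
    return best


def _posteriors(logliks, props):
    logw = np.where(props > 0, np.log(np.maximum(props, 1e-300)), -np.inf)
    joint = logliks + logw[:, None]
    joint -= special.logsumexp(joint, axis=0, keepdims=True)
    return np.exp(joint)


def _fit_m0(engine: PruningEngine, options: FitOptions) -> SiteClassFit:
    counts = engine.pattern_counts
    bl0 = np.maximum(engine.input_lengths[: engine.n_edges], 1e-4)
    fix_kappa = options.kappa is not None
    mode = options.branch_mode

    def unpack(x):
        k = 0
        kappa = options.kappa if fix_kappa else np.exp(x[0])
        if not fix_kappa:
            k = 1
        omega = np.exp(x[k])
        k += 1
        if mode == "free":
            bl = np.exp(x[k:])
        elif mode == "scale":
            bl = bl0 * np.exp(x[k])
        else:
            bl = bl0
        return kappa, omega, bl

    def negloglik(x):
        kappa, omega, bl = unpack(x)
        ll = engine.class_site_loglik(kappa, omega, None, bl)
        return -float(np.dot(ll, counts))

    n_starts = max(1, options.starts)
    starts, bounds = [], []
    for w0 in options.omega_starts[:n_starts]:
        x0 = []
        bounds = []
        if not fix_kappa:
            x0.append(np.log(2.0))
            bounds.append(_KAPPA_BOUNDS)
        x0.append(np.log(w0))
        bounds.append((np.log(1e-4), np.log(options.omega_max)))
        if mode == "free":
            x0.extend(np.log(bl0))
            bounds.extend([_BL_BOUNDS] * engine.n_edges)
        elif mode == "scale":
            x0.append(0.0)
            bounds.append((np.log(1e-3), np.log(100.0)))
        starts.append(x0)
    best = _optimize_multistart(negloglik, starts, bounds, options.tol)
    kappa, omega, bl = unpack(best.x)
    lnL = -best.fun
    params = CodonModelParams(kappa, [SiteClass(omega, 1.0)],
                              freqs=engine.pi)
    full_bl = np.zeros(engine.n_nodes)
    full_bl[: engine.n_edges] = bl
    n_free = 1 + (0 if fix_kappa else 1)
    n_free += engine.n_edges if mode == "free" else (1 if mode == "scale" else 0)
    return SiteClassFit(
        "M0", lnL, params, full_bl, np.ones((engine.n_sites, 1)),
        bool(best.success) and np.isfinite(lnL), n_free, _engine=engine,
    )


def _finalize_mixture(engine, model_id, kappa, classes, props, bl, n_free,
                      success, beta_params=None):
    """Exact recompute at the optimum and assembly of the fit record."""
    mat = engine.class_matrix(kappa, [(c[0], c[1]) for c in classes], bl)
    props = np.asarray(props, float)
    lnL = _mix_lnL(mat, props, engine.pattern_counts)
    site_classes = [
        SiteClass(bg, p, fg, positive=pos)
        for (bg, fg, pos), p in zip(classes, props)
    ]
    params = CodonModelParams(kappa, site_classes, freqs=engine.pi,
                              beta_params=beta_params)
    post = engine.expand(_posteriors(mat, props)).T  # (n_sites, n_classes)
    return SiteClassFit(
        model_id, lnL, params, np.array(bl if bl is not None else engine.input_lengths),
        post, bool(success) and np.isfinite(lnL), n_free,
        _engine=engine, _site_class_loglik=mat,
    )


def fit_model(data, model_id: str, options: FitOptions | None = None) -> SiteClassFit:
    """Maximum-likelihood fit of one registered site/branch-site model.

    ``data`` is an OrthologCluster or an ``(alignment, tree)`` pair.  Branch-
    site models (ModelA / ModelAnull) require a non-empty foreground set on
    the tree.  Mixture models reuse branch lengths and kappa from
    ``options.base_fit`` (an M0 fit) or fit M0 internally first.
    """
    options = options or FitOptions()
    if model_id not in MODEL_IDS:
        raise ModelUsageError(f"unknown model {model_id!r}")
    alignment, tree = _unpack(data)
    if model_id in ("ModelA", "ModelAnull") and not any(
        n.foreground for n in tree.postorder()
    ):
        raise ModelUsageError(f"{model_id} requires a foreground branch set")
    engine = PruningEngine(alignment, tree, freqs_mode=options.freqs_mode)

    if model_id == "M0":
        return _fit_m0(engine, options)

    base = options.base_fit
    if base is None or base.model_id != "M0":
        base = _fit_m0(engine, options)
    kappa = base.params.kappa
    bl = base.branch_lengths
    counts = engine.pattern_counts

    fit = _fit_mixture_once(engine, model_id, kappa, bl, options)
    if options.reestimate_kappa:
        classes = [(c.omega, c.foreground_omega) for c in fit.params.site_classes]
        props = np.array([c.proportion for c in fit.params.site_classes])

        def neg_kappa(logk):
            mat = engine.class_matrix(float(np.exp(logk)), classes, bl)
            return -_mix_lnL(mat, props, counts)

        res = optimize.minimize_scalar(neg_kappa, bounds=_KAPPA_BOUNDS, method="bounded")
        kappa = float(np.exp(res.x))
        fit = _fit_mixture_once(engine, model_id, kappa, bl, options)
    return fit


def _fit_mixture_once(engine, model_id, kappa, bl, options) -> SiteClassFit:
    counts = engine.pattern_counts
    K = 10  # beta discretisation classes

    if model_id == "M1Neutral" and options.m1_variant == "omega0_zero":
        mat = engine.class_matrix(kappa, [(0.0, None), (1.0, None)], bl)

        def neg(p0):
            return -_mix_lnL(mat, np.array([p0, 1.0 - p0]), counts)

        res = optimize.minimize_scalar(neg, bounds=(1e-6, 1 - 1e-6), method="bounded")
        p0 = float(res.x)
        return _finalize_mixture(
            engine, model_id, kappa, [(0.0, None, False), (1.0, None, False)],
            [p0, 1 - p0], bl, 1, True,
        )

    if model_id == "ModelAnull" or model_id == "ModelA":
        grid = _OmegaGrid(engine, kappa, bl, options.omega_max, foreground=True)
        L00 = engine.class_site_loglik(kappa, 0.0, None, bl)
        L11 = engine.class_site_loglik(kappa, 1.0, None, bl)
        if model_id == "ModelAnull":
            L01 = engine.class_site_loglik(kappa, 0.0, 1.0, bl)

            def neg(x):
                s, r = x
                props = np.array([s * r, s * (1 - r), (1 - s) * r, (1 - s) * (1 - r)])
                mat = np.vstack([L00, L11, L01, L11])
                return -_mix_lnL(mat, props, counts)

            best = _optimize_multistart(
                neg, [(0.8, 0.6), (0.95, 0.3), (0.6, 0.8)][: max(1, options.starts)],
                [(1e-4, 1 - 1e-4)] * 2, options.tol,
            )
            s, r = best.x
            props = [s * r, s * (1 - r), (1 - s) * r, (1 - s) * (1 - r)]
            classes = [(0.0, None, False), (1.0, None, False),
                       (0.0, 1.0, True), (1.0, 1.0, True)]
            return _finalize_mixture(engine, model_id, kappa, classes, props, bl,
                                     2, best.success)

        def neg(x):
            s, r, w2 = x
            props = np.array([s * r, s * (1 - r), (1 - s) * r, (1 - s) * (1 - r)])
            mat = np.vstack([L00, L11, grid.foreground(0.0, w2), grid.foreground(1.0, w2)])
            return -_mix_lnL(mat, props, counts)

        w2_starts = [max(1.5, w) for w in options.omega_starts]
        best = _optimize_multistart(
            neg,
            [(0.8, 0.6, w2_0) for w2_0 in w2_starts[: max(1, options.starts)]],
            [(1e-4, 1 - 1e-4), (1e-4, 1 - 1e-4), (1.0, options.omega_max)],
            options.tol,
        )
        s, r, w2 = best.x
        props = [s * r, s * (1 - r), (1 - s) * r, (1 - s) * (1 - r)]
        classes = [(0.0, None, False), (1.0, None, False),
                   (0.0, float(w2), True), (1.0, float(w2), True)]
        return _finalize_mixture(engine, model_id, kappa, classes, props, bl,
                                 3, best.success)

    # beta-family site models: M7, M8, M8a
    grid = _OmegaGrid(engine, kappa, bl, options.omega_max)

    def beta_mat(p, q):
        omegas = np.array([w for w, _ in discretize_beta(p, q, K)])
        return omegas, grid.background(omegas)

    if model_id == "M7":
        def neg(x):
            p, q = np.exp(x)
            _, mat = beta_mat(p, q)
            return -_mix_lnL(mat, np.full(K, 1.0 / K), counts)

        best = _optimize_multistart(
            neg,
            [np.log([p0, q0]) for p0, q0 in
             ((1.0, 2.0), (0.3, 1.0), (2.0, 1.0))[: max(1, options.starts)]],
            [(np.log(0.01), np.log(99.0))] * 2, options.tol,
        )
        p, q = np.exp(best.x)
        omegas, _ = beta_mat(p, q)
        classes = [(float(w), None, False) for w in omegas]
        return _finalize_mixture(engine, model_id, kappa, classes,
                                 np.full(K, 1.0 / K), bl, 2, best.success,
                                 beta_params=(float(p), float(q)))

    if model_id in ("M8", "M8a"):
        fixed_ws = model_id == "M8a"

        def neg(x):
            p, q = np.exp(x[0]), np.exp(x[1])
            p0 = x[2]
            ws = 1.0 if fixed_ws else x[3]
            omegas, mat = beta_mat(p, q)
            extra = grid.background(np.array([ws]))
            full = np.vstack([mat, extra])
            props = np.concatenate([np.full(K, p0 / K), [1.0 - p0]])
            return -_mix_lnL(full, props, counts)

        # seed from the best beta-only fit so the nested optimum is reachable
        def neg_beta_only(x):
            _, mat = beta_mat(*np.exp(x))
            return -_mix_lnL(mat, np.full(K, 1.0 / K), counts)

        beta_best = _optimize_multistart(
            neg_beta_only,
            [np.log([1.0, 2.0]), np.log([0.3, 1.0])],
            [(np.log(0.01), np.log(99.0))] * 2, options.tol,
        )
        p7, q7 = np.exp(beta_best.x)

        bounds = [(np.log(0.01), np.log(99.0))] * 2 + [(1e-4, 1 - 1e-4)]
        if not fixed_ws:
            bounds.append((1.0, options.omega_max))
        start_list = (
            [(p7, q7, 1 - 1e-4, 2.0), (p7, q7, 0.9, 3.0), (1.0, 2.0, 0.8, 1.5)]
            if not fixed_ws
            else [(p7, q7, 1 - 1e-4), (p7, q7, 0.9), (1.0, 2.0, 0.8)]
        )
        starts = [
            [np.log(st[0]), np.log(st[1]), st[2]] + ([st[3]] if not fixed_ws else [])
            for st in start_list[: max(1, options.starts)]
        ]
        best = _optimize_multistart(neg, starts, bounds, options.tol)
        p, q = np.exp(best.x[0]), np.exp(best.x[1])
        p0 = float(best.x[2])
        ws = 1.0 if fixed_ws else float(best.x[3])
        omegas = np.array([w for w, _ in discretize_beta(p, q, K)])
        classes = [(float(w), None, False) for w in omegas] + [
            (ws, None, not fixed_ws)
        ]
        props = np.concatenate([np.full(K, p0 / K), [1.0 - p0]])
        return _finalize_mixture(engine, model_id, kappa, classes, props, bl,
                                 3 if fixed_ws else 4, best.success,
                                 beta_params=(float(p), float(q)))

    if model_id == "M1Neutral":  # m1a variant: omega0 estimated in [0, 1)
        L1 = engine.class_site_loglik(kappa, 1.0, None, bl)

        def neg(x):
            w0, p0 = x
            mat = np.vstack([grid.background(np.array([w0]))[0], L1])
            return -_mix_lnL(mat, np.array([p0, 1 - p0]), counts)

        best = _optimize_multistart(
            neg, [(0.1, 0.8), (0.5, 0.5), (0.01, 0.95)][: max(1, options.starts)],
            [(0.0, 1.0 - 1e-6), (1e-4, 1 - 1e-4)], options.tol,
        )
        w0, p0 = best.x
        return _finalize_mixture(
            engine, "M1Neutral", kappa,
            [(float(w0), None, False), (1.0, None, False)],
            [p0, 1 - p0], bl, 2, best.success,
        )

    raise ModelUsageError(f"unhandled model {model_id!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# LRT machinery and decision rules
# ---------------------------------------------------------------------------

def lrt(alt: SiteClassFit, null: SiteClassFit, allow_unconverged: bool = False) -> LRTResult:
    """Likelihood-ratio test between registered nested fits."""
    pair = (alt.model_id, null.model_id)
    if pair not in LRT_NESTING:
        raise ModelUsageError(f"model pair {pair} is not a registered nesting")
    if not (alt.converged and null.converged) and not allow_unconverged:
        raise ModelUsageError("both fits must be converged (or pass allow_unconverged)")
    df = LRT_NESTING[pair]
    stat = max(0.0, 2.0 * (alt.lnL - null.lnL))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(stat, df, p, alt.model_id, null.model_id)


@dataclass
class LineageCall:
    positive: bool
    near_threshold: bool
    lrt_vs_null: LRTResult
    lrt_vs_m1: LRTResult


def lineage_specific_call(
    fit_a: SiteClassFit,
    fit_null: SiteClassFit,
    fit_m1: SiteClassFit,
    alpha: float = 0.05,
) -> LineageCall:
    """Lineage-specific positive-selection decision.

    Positive iff Model A beats *both* its null and M1Neutral at ``alpha``.
    Tests whose p-value lands in the [alpha, 0.10) band are flagged
    near-threshold (relaxed-criteria follow-up band).
    """
    for f, what in ((fit_a, "ModelA"), (fit_null, "ModelAnull"), (fit_m1, "M1Neutral")):
        if f is None:
            raise ModelUsageError(f"missing fit {what}")
    t1 = lrt(fit_a, fit_null)
    t2 = lrt(fit_a, fit_m1)
    # alpha >= 1 is the degenerate accept-everything threshold
    positive = alpha >= 1.0 or (t1.p_value < alpha and t2.p_value < alpha)
    near = any(alpha <= t.p_value < 0.10 for t in (t1, t2))
    return LineageCall(positive, near and not positive, t1, t2)


# ---------------------------------------------------------------------------
# Empirical-Bayes site posteriors
# ---------------------------------------------------------------------------

@dataclass
class SitePosteriorResult:
    method: str  # NEB or BEB
    posterior: np.ndarray  # per-site posterior of the positive class
    sites: list[int]  # 1-based codon sites above threshold
    threshold: float
    fallback: bool = False


def _positive_class_indices(fit: SiteClassFit) -> list[int]:
    idx = [i for i, c in enumerate(fit.params.site_classes) if c.positive]
    if not idx:
        raise ModelUsageError(
            f"model {fit.model_id} has no positive-selection class"
        )
    return idx


def site_posteriors_neb(fit: SiteClassFit, threshold: float = 0.95) -> SitePosteriorResult:
    """Naive empirical-Bayes posterior of the positive class at the MLEs."""
    idx = _positive_class_indices(fit)
    post = fit.site_posteriors[:, idx].sum(axis=1)
    sites = [int(s) + 1 for s in np.nonzero(post > threshold)[0]]
    return SitePosteriorResult("NEB", post, sites, threshold)


def site_posteriors_beb(
    fit: SiteClassFit, threshold: float = 0.95, n_grid: int = 10
) -> SitePosteriorResult:
    """Bayes empirical-Bayes posteriors for M8 (grid prior on p0 and omega_s).

    Integrates over a flat ``n_grid x n_grid`` grid on the positive-class
    weight p0 and its omega, holding the beta shapes at their MLEs.  Models
    without a BEB scheme here (Model A) fall back to NEB with a flag, as do
    numerically degenerate grids.
    """
    if fit.model_id != "M8" or fit._engine is None or fit._site_class_loglik is None:
        neb = site_posteriors_neb(fit, threshold)
        return SitePosteriorResult("NEB", neb.posterior, neb.sites, threshold, fallback=True)
    engine = fit._engine
    mat = fit._site_class_loglik  # rows: 10 beta classes + omega_s class
    beta_rows = mat[:-1]
    K = beta_rows.shape[0]
    kappa = fit.params.kappa
    bl = fit.branch_lengths
    p0_grid = (2 * np.arange(1, n_grid + 1) - 1) / (2 * n_grid)
    ws_grid = np.geomspace(1.0, 15.0, n_grid)
    ws_rows = np.vstack([
        engine.class_site_loglik(kappa, float(w), None, bl) for w in ws_grid
    ])
    counts = engine.pattern_counts
    log_data = np.empty((n_grid, n_grid))
    post_pos = np.zeros((n_grid, n_grid, engine.n_patterns))
    for a, p0 in enumerate(p0_grid):
        logw = np.concatenate([np.full(K, np.log(p0 / K)), [np.log(1 - p0)]])
        for b in range(n_grid):
            full = np.vstack([beta_rows, ws_rows[b]])
            joint = full + logw[:, None]
            norm = special.logsumexp(joint, axis=0)
            log_data[a, b] = float(np.dot(norm, counts))
            post_pos[a, b] = np.exp(joint[-1] - norm)
    log_data -= log_data.max()
    w = np.exp(log_data)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        neb = site_posteriors_neb(fit, threshold)
        return SitePosteriorResult("NEB", neb.posterior, neb.sites, threshold, fallback=True)
    w /= total
    post_pattern = np.tensordot(w, post_pos, axes=([0, 1], [0, 1]))
    post = engine.expand(post_pattern)
    sites = [int(s) + 1 for s in np.nonzero(post > threshold)[0]]
    return SitePosteriorResult("BEB", post, sites, threshold)


def preferred_site_posteriors(fit: SiteClassFit, threshold: float = 0.95) -> SitePosteriorResult:
    """BEB when available, NEB otherwise (reporting preference rule)."""
    beb = site_posteriors_beb(fit, threshold)
    if beb.method == "BEB":
        return beb
    return site_posteriors_neb(fit, threshold)


# ---------------------------------------------------------------------------
# Pairwise omega
# ---------------------------------------------------------------------------

@dataclass
class PairwiseOmega:
    dn: float
    ds: float
    omega: float | None
    t: float
    kappa: float
    reason: str = ""


def estimate_pairwise_omega(seq_a: str, seq_b: str, code: GeneticCode | None = None) -> PairwiseOmega:
    """ML estimate of (dN, dS, omega) for an in-frame ortholog pair (M0).

    omega is reported missing when there are no substitutions or no
    synonymous substitutions (dS = 0), matching the exclusion rule used for
    summary tables.
    """
    code = code or get_code(1)
    aln = CodonAlignment(["A", "B"], [seq_a, seq_b], code)
    syn_obs = nonsyn_obs = 0.0
    for c in range(1, aln.n_codons + 1):
        ca, cb = aln.codon(0, c), aln.codon(1, c)
        if ca in code.codon_index and cb in code.codon_index:
            s, n = code.pathway_counts(ca, cb)
            syn_obs += s
            nonsyn_obs += n
    if syn_obs + nonsyn_obs == 0:
        return PairwiseOmega(0.0, 0.0, None, 0.0, 1.0, "no substitutions")

    tree = PhyloTree.from_newick("(A:0.5,B:0.5);")
    engine = PruningEngine(aln, tree)
    counts = engine.pattern_counts
    fix_omega_zero = nonsyn_obs == 0

    def neg(x):
        kappa, scale = np.exp(x[0]), np.exp(x[1])
        omega = 1e-6 if fix_omega_zero else np.exp(x[2])
        bl = engine.input_lengths[: engine.n_edges] * scale
        return -float(np.dot(engine.class_site_loglik(kappa, omega, None, bl), counts))

    t0 = max((syn_obs + nonsyn_obs) / aln.n_codons, 1e-3)
    x0 = [np.log(2.0), np.log(t0)] + ([] if fix_omega_zero else [np.log(0.4)])
    bounds = [_KAPPA_BOUNDS, (np.log(1e-4), np.log(30.0))] + (
        [] if fix_omega_zero else [(np.log(1e-4), np.log(50.0))]
    )
    res = optimize.minimize(neg, np.array(x0), method="L-BFGS-B", bounds=bounds)
    kappa, t = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    omega = 0.0 if fix_omega_zero else float(np.exp(res.x[2]))

    pi = engine.pi
    rel = relative_class_rate(kappa, omega, pi, code)  # t is in neutral units
    syn_frac, nonsyn_frac = substitution_fractions(kappa, omega, pi, code)
    syn1, nonsyn1 = substitution_fractions(kappa, 1.0, pi, code)
    s_sites, n_sites = 3.0 * syn1, 3.0 * nonsyn1
    dn = t * rel * nonsyn_frac / n_sites
    ds = t * rel * syn_frac / s_sites
    if fix_omega_zero:
        dn, omega = 0.0, 0.0
        return PairwiseOmega(dn, ds, omega, t, kappa, "no nonsynonymous substitutions")
    if syn_obs == 0 or ds < 1e-9:
        return PairwiseOmega(dn, 0.0, None, t, kappa, "dS = 0, omega undefined")
    return PairwiseOmega(dn, ds, omega, t, kappa)
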