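"""Maximum-likelihood phylogenetics under GTR+F+I+G4.

The substitution model is the general time-reversible (GTR) model with
empirical base frequencies (+F), an invariant-site proportion (+I) and
4-category discrete-gamma rate heterogeneity (+G4).  Likelihoods are
computed by Felsenstein pruning over compressed site patterns; the rate
matrix is scaled to one expected substitution per site at stationarity,
and the +I+G mixture is rescaled so the mean rate over categories is 1.

Tree search starts from a neighbor-joining tree on Jukes-Cantor-corrected
pairwise distances and alternates bounded coordinate-wise optimization of
branch lengths and model parameters with nearest-neighbor-interchange
(NNI) hill climbing.  Branch support comes from standard nonparametric
bootstrap (site resampling), not any fast approximation.

Base order throughout is A, C, G, T; exchangeability order is
(AC, AG, AT, CG, CT, GT) with GT fixed to 1 during optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .alignment import Alignment

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_PAIR_ORDER = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloModel:
    """GTR exchangeabilities + base frequencies + invariant fraction + gamma.

    ``rates`` are the six symmetric exchangeabilities in order
    (AC, AG, AT, CG, CT, GT); ``freqs`` are stationary base frequencies
    (A, C, G, T) summing to 1; ``alpha`` is the discrete-gamma shape
    (``None`` disables rate heterogeneity); ``p_inv`` the invariant-site
    proportion.
    """

    rates: tuple[float, ...] = (1.0,) * 6
    freqs: tuple[float, ...] = (0.25,) * 4
    p_inv: float = 0.0
    alpha: float | None = None
    n_cat: int = 4

    def __post_init__(self) -> None:
        if len(self.rates) != 6 or any(r < 0 for r in self.rates):
            raise ValueError("need 6 nonnegative exchangeabilities")
        if len(self.freqs) != 4 or abs(sum(self.freqs) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be positive")

    def rate_matrix(self) -> np.ndarray:
        """GTR rate matrix Q scaled to mean rate 1 at stationarity."""
        pi = np.asarray(self.freqs)
        Q = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, _PAIR_ORDER):
            Q[i, j] = r * pi[j]
            Q[j, i] = r * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(pi @ np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return Q / mu

    def gamma_category_rates(self) -> np.ndarray:
        """Mean rates of ``n_cat`` equal-probability discrete-gamma bands.

        Category k's rate is the mean of the unit-mean gamma density over
        its quantile band (Yang's discretization); the rates average 1.
        """
        if self.alpha is None:
            return np.array([1.0])
        a = self.alpha
        edges = gamma_dist.ppf(np.linspace(0, 1, self.n_cat + 1), a, scale=1 / a)
        upper_cdf = gamma_dist.cdf(edges, a + 1, scale=1 / a)
        return self.n_cat * np.diff(upper_cdf)

    def mixture(self) -> list[tuple[float, float]]:
        """(weight, rate) pairs of the +I+G mixture; rates average to 1."""
        cats: list[tuple[float, float]] = []
        if self.p_inv > 0:
            cats.append((self.p_inv, 0.0))
        g = self.gamma_category_rates()
        w = (1.0 - self.p_inv) / len(g)
        scale = 1.0 / (1.0 - self.p_inv)
        cats.extend((w, float(r) * scale) for r in g)
        return cats


class _TransitionCache:
    """Eigendecomposition of a reversible Q for cheap P(t) evaluation."""

    def __init__(self, model: PhyloModel):
        Q = model.rate_matrix()
        pi = np.asarray(model.freqs)
        d = np.sqrt(pi)
        A = (Q * d[:, None]) / d[None, :]  # symmetric similarity transform
        w, U = np.linalg.eigh((A + A.T) / 2)
        self.w = w
        self.L = U / d[:, None]        # D^{-1/2} U
        self.R = (U * d[:, None]).T    # U^T D^{1/2}
        self.pi = pi

    def P(self, t: float) -> np.ndarray:
        """Transition probability matrix exp(Q t), clipped to [0, 1]."""
        P = (self.L * np.exp(self.w * t)) @ self.R
        np.clip(P, 0.0, 1.0, out=P)
        return P


def empirical_frequencies(alignment: Alignment,
                          pseudocount: float = 0.0) -> tuple[float, ...]:
    """Empirical base frequencies over all rows (the '+F' frequencies)."""
    counts = np.full(4, pseudocount)
    for row in alignment.rows:
        for ch in row:
            i = _BASE_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no unambiguous bases")
    return tuple(counts / total)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class PhyloTree:
    """An unrooted tree with branch lengths, stored as an adjacency map.

    Tips carry labels; internal nodes are unlabeled.  Edge supports (from
    bootstrap) are attached per split.
    """

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}
        self.supports: dict[frozenset[str], float] = {}
        self._next = 0

    # -- construction ------------------------------------------------------
    def add_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def set_length(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t.adj = {u: dict(nb) for u, nb in self.adj.items()}
        t.labels = dict(self.labels)
        t.supports = dict(self.supports)
        t._next = self._next
        return t

    # -- queries -----------------------------------------------------------
    @property
    def tip_ids(self) -> list[int]:
        return sorted(n for n in self.adj if len(self.adj[n]) == 1)

    @property
    def tip_names(self) -> list[str]:
        return sorted(self.labels[t] for t in self.tip_ids)

    def node_by_name(self, name: str) -> int:
        for nid, lbl in self.labels.items():
            if lbl == name:
                return nid
        raise KeyError(f"no tip named {name!r}")

    def edges(self) -> list[tuple[int, int, float]]:
        return [(u, v, l) for u, nb in sorted(self.adj.items())
                for v, l in sorted(nb.items()) if u < v]

    def internal_edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, v, _ in self.edges()
                if len(self.adj[u]) > 1 and len(self.adj[v]) > 1]

    def postorder(self, root: int) -> list[tuple[int, int | None]]:
        """(node, parent) pairs, children before parents."""
        out: list[tuple[int, int | None]] = []
        stack: list[tuple[int, int | None]] = [(root, None)]
        while stack:
            node, parent = stack.pop()
            out.append((node, parent))
            for nb in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        out.reverse()
        return out

    def _side_tips(self, u: int, v: int) -> frozenset[str]:
        """Tip names on v's side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        names = []
        while stack:
            node = stack.pop()
            if len(self.adj[node]) == 1 and node in self.labels:
                names.append(self.labels[node])
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(names)

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each as the side not containing the
        lexicographically smallest tip name."""
        all_tips = set(self.tip_names)
        ref = min(all_tips)
        out = set()
        for u, v in self.internal_edges():
            side = self._side_tips(u, v)
            if ref in side:
                side = frozenset(all_tips - side)
            if 2 <= len(side) <= len(all_tips) - 2:
                out.add(side)
        return out

    # -- newick ------------------------------------------------------------
    def to_newick(self, root: int | None = None, decimals: int = 6) -> str:
        if root is None:
            internals = [n for n in sorted(self.adj) if len(self.adj[n]) > 1]
            root = internals[0] if internals else sorted(self.adj)[0]
        all_tips = set(self.tip_names)
        ref = min(all_tips) if all_tips else ""

        def fmt_len(x: float) -> str:
            return f"{x:.{decimals}g}"

        def rec(node: int, parent: int | None) -> str:
            children = [nb for nb in sorted(self.adj[node]) if nb != parent]
            if not children:
                return self.labels.get(node, f"n{node}")
            inner = ",".join(
                rec(c, node) + f":{fmt_len(self.adj[node][c])}" for c in children)
            label = ""
            if parent is not None and self.supports:
                side = self._side_tips(parent, node)
                key = side if ref not in side else frozenset(all_tips - side)
                if key in self.supports:
                    label = f"{self.supports[key]:.0f}"
            return f"({inner}){label}"

        return rec(root, None) + ";"

    @staticmethod
    def from_newick(text: str) -> "PhyloTree":
        """Parse a Newick string (labels, branch lengths, internal labels
        ignored except as supports are not restored)."""
        tree = PhyloTree()
        s = text.strip().rstrip(";")
        pos = 0

        def parse() -> int:
            nonlocal pos
            if s[pos] == "(":
                node = tree.add_node()
                pos += 1
                while True:
                    child = parse()
                    length = 1.0
                    # optional internal label
                    start = pos
                    while pos < len(s) and s[pos] not in ":,();":
                        pos += 1
                    pos = pos if pos > start else pos
                    if pos < len(s) and s[pos] == ":":
                        pos += 1
                        start = pos
                        while pos < len(s) and s[pos] not in ",()":
                            pos += 1
                        length = float(s[start:pos])
                    tree.add_edge(node, child, length)
                    if pos < len(s) and s[pos] == ",":
                        pos += 1
                        continue
                    if pos < len(s) and s[pos] == ")":
                        pos += 1
                    break
                return node
            start = pos
            while pos < len(s) and s[pos] not in ":,()":
                pos += 1
            return tree.add_node(label=s[start:pos].strip())

        root = parse()
        # suppress a degree-2 root: splice its two neighbors together
        if len(tree.adj[root]) == 2:
            (a, la), (b, lb) = tree.adj[root].items()
            tree.remove_edge(root, a)
            tree.remove_edge(root, b)
            del tree.adj[root]
            tree.add_edge(a, b, la + lb)
        return tree


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference (Robinson-Foulds) distance between two unrooted
    trees on the same tip set."""
    if set(t1.tip_names) != set(t2.tip_names):
        raise ValueError("trees have different tip sets")
    return len(t1.splits() ^ t2.splits())


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

def jc_distance_matrix(alignment: Alignment) -> np.ndarray:
    """Jukes-Cantor ML distances from pairwise mismatch proportions.

    Gap/N columns are excluded pairwise; saturated pairs (p >= 0.749) are
    capped at 5 substitutions/site.
    """
    n = alignment.n_taxa
    rows = alignment.rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = valid = 0
            for a, b in zip(rows[i], rows[j]):
                if a in "-N" or b in "-N":
                    continue
                valid += 1
                diff += a != b
            p = diff / valid if valid else 0.0
            if p >= 0.749:
                d = 5.0
            else:
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return D


def neighbor_joining(D: np.ndarray, names: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining; negative branch estimates are clamped
    to zero.  Exact on additive distance matrices."""
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    tree = PhyloTree()
    active: dict[int, int] = {}
    for i, name in enumerate(names):
        active[i] = tree.add_node(label=name)
    D = np.array(D, dtype=float)
    idx = list(range(n))

    while len(idx) > 3:
        m = len(idx)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        a, b = np.unravel_index(np.argmin(Qm), Qm.shape)
        if a > b:
            a, b = b, a
        ia, ib = idx[a], idx[b]
        dab = D[ia, ib]
        va = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        vb = dab - va
        new = tree.add_node()
        tree.add_edge(new, active[ia], max(va, 0.0))
        tree.add_edge(new, active[ib], max(vb, 0.0))
        # distances from the new node
        dnew = 0.5 * (D[ia, :] + D[ib, :] - dab)
        D = np.vstack([D, dnew])
        D = np.column_stack([D, np.append(dnew, 0.0)])
        knew = D.shape[0] - 1
        active[knew] = new
        idx = [k for k in idx if k not in (ia, ib)] + [knew]

    i, j, k = idx
    center = tree.add_node()
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    tree.add_edge(center, active[i], max(li, 0.0))
    tree.add_edge(center, active[j], max(lj, 0.0))
    tree.add_edge(center, active[k], max(lk, 0.0))
    return tree


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

# rows: A, C, G, T, missing (gap or N)
_TIP_TABLE = np.vstack([np.eye(4), np.ones(4)])

_CHAR_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CHAR_LUT[_b] = _i


def _compress_patterns(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Unique site-pattern codes (npat, ntaxa; 0-3 = ACGT, 4 = missing) and
    their multiplicities.  Cached on the alignment object."""
    cache = getattr(alignment, "_pattern_cache", None)
    if cache is None:
        cols = alignment.columns()
        patterns, counts = np.unique(cols, axis=0, return_counts=True)
        codes = _CHAR_LUT[patterns.view(np.uint8)]
        cache = (codes, counts.astype(float))
        alignment._pattern_cache = cache
    return cache


def log_likelihood(tree: PhyloTree, alignment: Alignment, model: PhyloModel,
                   root: int | None = None) -> float:
    """Felsenstein-pruning log-likelihood of an alignment on a tree.

    Gaps and N are treated as fully missing.  The result is invariant to
    the choice of ``root`` (pulley principle) and to taxon order.
    """
    names = set(alignment.names)
    if set(tree.tip_names) != names:
        raise ValueError("tree tips and alignment taxa differ")
    codes, counts = _compress_patterns(alignment)
    npat = codes.shape[0]
    taxon_col = {name: k for k, name in enumerate(alignment.names)}

    if root is None:
        internals = [n for n in sorted(tree.adj) if len(tree.adj[n]) > 1]
        root = internals[0] if internals else sorted(tree.adj)[0]

    cache = _TransitionCache(model)
    pi = cache.pi
    order = tree.postorder(root)
    mixture = model.mixture()

    site_log = np.full((len(mixture), npat), -np.inf)
    for ci, (weight, rate) in enumerate(mixture):
        partials: dict[int, np.ndarray] = {}
        scale_log = np.zeros(npat)
        for node, parent in order:
            children = [nb for nb in tree.adj[node] if nb != parent]
            is_tip = len(tree.adj[node]) == 1 and node in tree.labels
            if is_tip and not children:
                partials[node] = _TIP_TABLE[codes[:, taxon_col[tree.labels[node]]]]
                continue
            # a tip used as root keeps its own observation as the base state
            part = (_TIP_TABLE[codes[:, taxon_col[tree.labels[node]]]].copy()
                    if is_tip else np.ones((npat, 4)))
            for child in children:
                t = tree.adj[node][child] * rate
                P = cache.P(t) if rate > 0 else np.eye(4)
                part = part * (partials.pop(child) @ P.T)
            # rescale to avoid underflow
            m = part.max(axis=1)
            nz = m > 0
            part[nz] = part[nz] / m[nz, None]
            with np.errstate(divide="ignore"):
                scale_log += np.where(nz, np.log(np.where(nz, m, 1.0)), -np.inf)
            partials[node] = part
        lik = partials[root] @ pi
        with np.errstate(divide="ignore"):
            site_log[ci] = np.log(weight) + np.log(lik) + scale_log

    site_logsum = site_log.max(axis=0)
    with np.errstate(invalid="ignore"):
        site_total = site_logsum + np.log(
            np.exp(site_log - site_logsum[None, :]).sum(axis=0))
    site_total = np.where(np.isfinite(site_logsum), site_total, -np.inf)
    total = float(counts @ site_total)
    if not np.isfinite(total):
        raise FloatingPointError("non-finite log-likelihood")
    return total


# ---------------------------------------------------------------------------
# optimization and search
# ---------------------------------------------------------------------------

@dataclass
class SearchSettings:
    """Knobs for :func:`fit_and_search`.

    ``optimize_rates``/``optimize_alpha``/``optimize_pinv`` toggle model
    parameter estimation; fixed values come from ``initial_model``.
    ``tol`` is the log-likelihood convergence tolerance.
    """

    optimize_rates: bool = True
    optimize_alpha: bool = True
    optimize_pinv: bool = True
    initial_model: PhyloModel | None = None
    max_rounds: int = 20
    tol: float = 1e-6
    branch_max: float = 10.0
    nni: bool = True
    max_nni_rounds: int = 10


@dataclass
class FitResult:
    tree: PhyloTree
    model: PhyloModel
    log_likelihood: float
    converged: bool = True


def _optimize_branches(tree: PhyloTree, alignment: Alignment,
                       model: PhyloModel, settings: SearchSettings) -> float:
    best = log_likelihood(tree, alignment, model)
    for u, v, _l in tree.edges():
        def neg(x: float) -> float:
            tree.set_length(u, v, x)
            return -log_likelihood(tree, alignment, model)
        res = minimize_scalar(neg, bounds=(1e-9, settings.branch_max),
                              method="bounded",
                              options={"xatol": 1e-7})
        if -res.fun >= best:
            tree.set_length(u, v, float(res.x))
            best = -res.fun
        else:  # keep previous value
            tree.set_length(u, v, _l)
    return best


def _optimize_model(tree: PhyloTree, alignment: Alignment, model: PhyloModel,
                    settings: SearchSettings) -> tuple[PhyloModel, float]:
    best = log_likelihood(tree, alignment, model)

    def try_param(make_model, lo, hi, log_scale=False):
        nonlocal model, best

        def neg(x: float) -> float:
            m = make_model(10 ** x if log_scale else x)
            return -log_likelihood(tree, alignment, m)

        b = (np.log10(lo), np.log10(hi)) if log_scale else (lo, hi)
        res = minimize_scalar(neg, bounds=b, method="bounded",
                              options={"xatol": 1e-6})
        if -res.fun > best:
            best = -res.fun
            model = make_model(10 ** float(res.x) if log_scale else float(res.x))

    if settings.optimize_rates:
        for k in range(5):  # GT (last) fixed at 1 as reference
            def make(x, k=k):
                r = list(model.rates)
                r[k] = x
                return replace(model, rates=tuple(r))
            try_param(make, 1e-3, 1e3, log_scale=True)
    if settings.optimize_alpha and model.alpha is not None:
        try_param(lambda x: replace(model, alpha=x), 0.02, 100.0,
                  log_scale=True)
    if settings.optimize_pinv:
        try_param(lambda x: replace(model, p_inv=x), 0.0, 0.95)
    return model, best


def _nni_trees(tree: PhyloTree, u: int, v: int) -> list[PhyloTree]:
    """The two NNI rearrangements around internal edge (u, v)."""
    a_nbrs = [x for x in sorted(tree.adj[u]) if x != v]
    b_nbrs = [x for x in sorted(tree.adj[v]) if x != u]
    if len(a_nbrs) < 2 or len(b_nbrs) < 2:
        return []
    a2 = a_nbrs[1]
    out = []
    for b in b_nbrs[:2]:
        t = tree.copy()
        la = t.adj[u][a2]
        lb = t.adj[v][b]
        t.remove_edge(u, a2)
        t.remove_edge(v, b)
        t.add_edge(u, b, lb)
        t.add_edge(v, a2, la)
        out.append(t)
    return out


def fit_and_search(alignment: Alignment,
                   settings: SearchSettings | None = None) -> FitResult:
    """Estimate tree and model by ML: NJ start, coordinate-wise parameter
    and branch-length optimization, NNI hill climbing.

    Deterministic given the input order; raises for fewer than 4 taxa.
    """
    settings = settings or SearchSettings()
    if alignment.n_taxa < 4:
        raise ValueError("tree search needs at least 4 taxa")

    D = jc_distance_matrix(alignment)
    tree = neighbor_joining(D, alignment.names)
    for u, v, l in tree.edges():
        if l < 1e-8:
            tree.set_length(u, v, 1e-8)

    if settings.initial_model is not None:
        model = settings.initial_model
    else:
        freqs = empirical_frequencies(alignment)
        if min(freqs) == 0.0:  # degenerate alignment: regularize
            freqs = empirical_frequencies(alignment, pseudocount=1.0)
        model = PhyloModel(freqs=freqs, alpha=1.0, p_inv=0.0)

    best = log_likelihood(tree, alignment, model)
    converged = False
    for _round in range(settings.max_rounds):
        prev = best
        best = _optimize_branches(tree, alignment, model, settings)
        model, best = _optimize_model(tree, alignment, model, settings)
        if best - prev < settings.tol:
            converged = True
            break

    if settings.nni:
        for _nni_round in range(settings.max_nni_rounds):
            candidates = []
            for u, v in tree.internal_edges():
                for t in _nni_trees(tree, u, v):
                    candidates.append(t)
            improved = False
            scored = [(log_likelihood(t, alignment, model), i, t)
                      for i, t in enumerate(candidates)]
            if scored:
                top, _i, ttree = max(scored, key=lambda x: (x[0], -x[1]))
                if top > best + settings.tol:
                    tree = ttree
                    best = _optimize_branches(tree, alignment, model, settings)
                    model, best = _optimize_model(tree, alignment, model,
                                                  settings)
                    improved = True
            if not improved:
                break

    if not converged:
        warnings.warn("ML optimization did not fully converge; returning "
                      "best tree found", stacklevel=2)
    return FitResult(tree=tree, model=model, log_likelihood=best,
                     converged=converged)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(alignment: Alignment, settings: SearchSettings | None,
                      replicates: int, seed: int,
                      fit: FitResult | None = None) -> FitResult:
    """Nonparametric bootstrap: resample sites with replacement, refit, and
    report each original split's frequency (percent) as its support.

    With zero variable sites supports are undefined and a warning is
    raised.  Replicate searches reuse the original model parameters (only
    branch lengths and topology are re-estimated) — the standard practice
    for desk-scale bootstrap.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    settings = settings or SearchSettings()
    if fit is None:
        fit = fit_and_search(alignment, settings)

    cols = alignment.columns()
    variable = sum(1 for i in range(alignment.n_sites)
                   if len({c for c in cols[i] if c not in (b"-", b"N")}) > 1)
    if variable == 0:
        warnings.warn("no variable sites: bootstrap supports are undefined",
                      stacklevel=2)

    rng = np.random.default_rng(seed)
    target_splits = fit.tree.splits()
    hits = {s: 0 for s in target_splits}
    rep_settings = replace(settings, optimize_rates=False,
                           optimize_alpha=False, optimize_pinv=False,
                           initial_model=fit.model, max_rounds=3)
    n = alignment.n_sites
    for _rep in range(replicates):
        pick = rng.integers(0, n, size=n)
        rows = ["".join(row[i] for i in pick) for row in alignment.rows]
        rep_aln = Alignment(names=list(alignment.names), rows=rows)
        rep_fit = fit_and_search(rep_aln, rep_settings)
        rep_splits = rep_fit.tree.splits()
        for s in target_splits:
            if s in rep_splits:
                hits[s] += 1

    tree = fit.tree.copy()
    tree.supports = {s: 100.0 * h / replicates for s, h in hits.items()}
    return FitResult(tree=tree, model=fit.model,
                     log_likelihood=fit.log_likelihood, converged=fit.converged)


# ---------------------------------------------------------------------------
# monophyly classification
# ---------------------------------------------------------------------------

def _rooted_clades(tree: PhyloTree, outgroup: set[str]) -> list[frozenset[str]]:
    """Tip sets of all clades after rooting on the outgroup.

    The outgroup must be a tip or a set of tips forming one side of an
    edge; the root is placed on that edge and clades are the subtree tip
    sets of every node on the ingroup side (tips included).
    """
    all_tips = set(tree.tip_names)
    if not outgroup <= all_tips:
        raise ValueError(f"unknown outgroup taxa {sorted(outgroup - all_tips)}")
    # find the edge whose one side is exactly the outgroup
    root_edge = None
    if len(outgroup) == 1:
        tip = tree.node_by_name(next(iter(outgroup)))
        parent = next(iter(tree.adj[tip]))
        root_edge = (parent, tip)
    else:
        for u, v, _l in tree.edges():
            side = tree._side_tips(u, v)
            if side == frozenset(outgroup):
                root_edge = (u, v)
                break
            if frozenset(all_tips) - side == frozenset(outgroup):
                root_edge = (v, u)
                break
        if root_edge is None:
            raise ValueError("outgroup is not a clade on any rooting edge")
    ingroup_node, _out_node = root_edge

    clades: list[frozenset[str]] = []

    def rec(node: int, parent: int) -> frozenset[str]:
        if len(tree.adj[node]) == 1 and node in tree.labels:
            s = frozenset([tree.labels[node]])
            clades.append(s)
            return s
        acc: set[str] = set()
        for nb in tree.adj[node]:
            if nb != parent:
                acc |= rec(nb, node)
        s = frozenset(acc)
        clades.append(s)
        return s

    rec(ingroup_node, _out_node)
    return clades


def classify_group(tree: PhyloTree, group: Iterable[str],
                   outgroup: str | Iterable[str]) -> str:
    """Classify a taxon set as monophyletic, paraphyletic or polyphyletic.

    The tree is rooted on ``outgroup`` (a tip name or set of tip names
    forming a clade).  The group is monophyletic if it is exactly the tip
    set of some clade; paraphyletic if the non-group tips inside its
    minimal spanning clade themselves form a single clade; polyphyletic
    otherwise.
    """
    group_set = frozenset([group] if isinstance(group, str) else group)
    og = {outgroup} if isinstance(outgroup, str) else set(outgroup)
    if not group_set:
        raise ValueError("empty group")
    if og & group_set:
        raise ValueError(f"outgroup taxa inside group: {sorted(og & group_set)}")
    all_tips = set(tree.tip_names)
    unknown = group_set - all_tips
    if unknown:
        raise ValueError(f"unknown group taxa {sorted(unknown)}")
    if group_set == all_tips - og:
        return "monophyletic"  # the full ingroup is the root clade

    clades = _rooted_clades(tree, og)
    if group_set in clades:
        return "monophyletic"
    spanning = min((c for c in clades if group_set <= c), key=len)
    intruders = frozenset(spanning - group_set)
    return "paraphyletic" if intruders in clades else "polyphyletic"
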