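"""Phylogenetic signal in polymorphism abundance.

Given a rooted tree with branch lengths and one polymorphic-site count per
tip, this module provides:

* tip preparation (averaging multiple samples per taxon and collapsing tip
  pairs separated by zero patristic distance);
* exact squared-change parsimony (SCP) ancestral states — the assignment of
  internal-node values minimizing the sum of squared changes along branches,
  optionally weighted by inverse branch length;
* a permutation test comparing the observed SCP tree length against lengths
  from uniform permutations of tip values;
* Pagel's lambda: maximum-likelihood estimation under Brownian motion with
  the off-diagonal phylogenetic covariances scaled by lambda in [0, 1], and
  a 1-df chi-square likelihood-ratio test against lambda = 0;
* Brownian-motion fitting (multi-start, with the analytic GLS solution as
  one start) and trait simulation bounded below at zero by reflection;
* per-clade extremeness of observed ancestral states against simulated ones,
  with a Bonferroni-corrected critical count.

SCP minimizes a convex quadratic, so ancestral states solve a sparse linear
system exactly; the minimized length is a quadratic form t' S t in the tip
values, which makes the 10,000-fold permutation and simulation comparisons a
matrix product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import dendropy
from scipy import optimize, stats

__all__ = [
    "PhyloTrait",
    "ASRResult",
    "SignalTestResult",
    "CladeTestResult",
    "prepare_tips",
    "scp_ancestral_states",
    "permutation_signal_test",
    "lambda_transform",
    "lambda_vcv",
    "tree_vcv",
    "fit_lambda",
    "lrt_lambda",
    "fit_bm",
    "simulate_bm_bounded",
    "clade_extremeness",
]


@dataclass
class PhyloTrait:
    """A rooted tree with branch lengths plus one numeric value per tip."""

    tree: dendropy.Tree
    values: Dict[str, float]

    def __post_init__(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        if tips != set(self.values):
            raise ValueError(
                "tip labels of values and tree differ: "
                f"{sorted(tips ^ set(self.values))}"
            )
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None or edge.length < 0:
                raise ValueError("all branch lengths must be present and >= 0")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError("tip values must be finite")

    @property
    def tip_labels(self) -> List[str]:
        return sorted(self.values)

    def value_vector(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        order = self.tip_labels if order is None else list(order)
        return np.array([self.values[t] for t in order], dtype=float)


@dataclass
class ASRResult:
    """Squared-change parsimony reconstruction: one state per internal node
    and the minimized total squared-change score."""

    node_states: Dict[dendropy.Node, float]
    scp_length: float

    @property
    def root_state(self) -> float:
        for node, state in self.node_states.items():
            if node.parent_node is None:
                return state
        raise ValueError("no root among reconstructed nodes")


@dataclass
class SignalTestResult:
    """Permutation and lambda-LRT evidence for phylogenetic signal."""

    perm_p: float
    lambda_hat: float
    logL_lambda: float
    logL_zero: float
    lrt_stat: float
    lrt_p: float


@dataclass
class CladeTestResult:
    """Per-clade extremeness of observed ancestral states against simulated
    ones; a clade is significant when ``n_more_extreme`` does not exceed
    ``bonferroni_critical``."""

    clades: List[Tuple[str, ...]]  # tip labels subtended by each node
    observed: np.ndarray
    direction: List[str]  # "high" | "low" per node
    n_more_extreme: np.ndarray
    n_sims: int
    n_clades: int
    bonferroni_critical: int


# ---------------------------------------------------------------------------
# tree plumbing


def _index_tree(tree: dendropy.Tree, tip_order: Sequence[str]):
    """Index tips 0..n-1 in the given label order and internal nodes after;
    returns (edges [(parent, child, length)], internal dendropy nodes)."""
    tip_idx = {label: i for i, label in enumerate(tip_order)}
    n_tips = len(tip_order)
    index: Dict[dendropy.Node, int] = {}
    internals: List[dendropy.Node] = []
    k = n_tips
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            index[node] = tip_idx[node.taxon.label]
        else:
            index[node] = k
            internals.append(node)
            k += 1
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        edges.append((index[node.parent_node], index[node], node.edge.length))
    return edges, internals


def _scp_operators(
    edges, n_tips: int, n_int: int, weighted: bool
) -> Tuple[np.ndarray, np.ndarray]:
    """(A, S): internal states = A @ tips; minimized length = tips' S tips.

    Derived from the graph Laplacian of the tree with edge weights 1 (or
    1/branch length): minimizing x' L x over internal states gives the Schur
    complement S = L_TT - L_TI L_II^{-1} L_IT and A = -L_II^{-1} L_IT.
    """
    N = n_tips + n_int
    L = np.zeros((N, N))
    for u, v, length in edges:
        if weighted:
            if length is None or length <= 0:
                raise ValueError(
                    "weighted SCP requires all branch lengths > 0; "
                    "collapse zero-length branches first"
                )
            w = 1.0 / length
        else:
            w = 1.0
        L[u, u] += w
        L[v, v] += w
        L[u, v] -= w
        L[v, u] -= w
    T = slice(0, n_tips)
    I = slice(n_tips, N)
    LII = L[I, I]
    LIT = L[I, T]
    A = -np.linalg.solve(LII, LIT)
    S = L[T, T] + L[T, I] @ A
    return A, S


def scp_ancestral_states(phylo: PhyloTrait, weighted: bool = False) -> ASRResult:
    """Exact squared-change parsimony ancestral states.

    Minimizes sum over edges of (state change)^2 / w with w = branch length
    (``weighted=True``) or 1 (default); solved as a linear system.
    """
    order = phylo.tip_labels
    edges, internals = _index_tree(phylo.tree, order)
    if not internals:
        raise ValueError("tree has no internal nodes")
    A, S = _scp_operators(edges, len(order), len(internals), weighted)
    t = phylo.value_vector(order)
    states = A @ t
    length = float(t @ S @ t)
    return ASRResult(dict(zip(internals, states)), max(length, 0.0))


def permutation_signal_test(
    phylo: PhyloTrait,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    weighted: bool = False,
) -> float:
    """Permutation test of phylogenetic signal in SCP tree length.

    Tip values are permuted uniformly ``n_perm`` times; the returned p-value
    is the fraction of permutations with an SCP length strictly shorter than
    the observed one (observed data with signal produce short trees, so small
    values indicate signal).  With constant tip values every permutation ties
    and the fraction is 0 — degenerate, not evidence of signal.
    """
    order = phylo.tip_labels
    if len(order) < 3:
        raise ValueError("need at least 3 tips")
    edges, internals = _index_tree(phylo.tree, order)
    _, S = _scp_operators(edges, len(order), len(internals), weighted)
    t = phylo.value_vector(order)
    observed = float(t @ S @ t)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, t.size))
    for i in range(n_perm):
        perms[i] = rng.permutation(t)
    lengths = np.einsum("ij,jk,ik->i", perms, S, perms)
    # strict "shorter than", with a relative tolerance so permutations that
    # tie the observed length (identical multisets, constant values) do not
    # count as shorter through floating-point noise
    tol = 1e-9 * max(1.0, abs(observed))
    return float(np.count_nonzero(lengths < observed - tol) / n_perm)


# ---------------------------------------------------------------------------
# Brownian motion / Pagel's lambda


def tree_vcv(tree: dendropy.Tree, tip_order: Sequence[str]) -> np.ndarray:
    """Phylogenetic covariance matrix: V[i, j] = root-to-MRCA path length."""
    n = len(tip_order)
    tip_idx = {label: i for i, label in enumerate(tip_order)}
    V = np.zeros((n, n))
    depth: Dict[dendropy.Node, float] = {}
    tipsets: Dict[dendropy.Node, List[int]] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
        depth[node] = d
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = tip_idx[node.taxon.label]
            V[i, i] = depth[node]
            tipsets[node] = [i]
        else:
            groups = [tipsets.pop(c) for c in node.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.array(groups[a])[:, None]
                    ib = np.array(groups[b])[None, :]
                    V[ia, ib] = depth[node]
                    V[ib.T, ia.T] = depth[node]
            tipsets[node] = [i for g in groups for i in g]
    return V


def lambda_vcv(V: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal phylogenetic covariances by lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    return lam * V + (1.0 - lam) * np.diag(np.diag(V))


def lambda_transform(tree: dendropy.Tree, lam: float) -> dendropy.Tree:
    """Lambda-transform a tree: internal branches scaled by lambda, terminal
    branches extended so every root-to-tip distance is preserved.

    Equivalent to multiplying the off-diagonal entries of the phylogenetic
    covariance matrix by lambda while keeping the diagonal.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    clone = tree.clone(depth=1)
    depth: Dict[dendropy.Node, float] = {}
    for node in clone.preorder_node_iter():
        parent = node.parent_node
        depth[node] = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
    for node in clone.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.is_leaf():
            node.edge.length = depth[node] - lam * depth[node.parent_node]
        else:
            node.edge.length = lam * (node.edge.length or 0.0)
    return clone


def _bm_profile_loglik(V: np.ndarray, t: np.ndarray) -> Tuple[float, float, float]:
    """(logL, sigma2_hat, root_hat) with sigma2 and the root state profiled
    out analytically (ML, not REML)."""
    n = t.size
    cho = np.linalg.cholesky(V)
    logdet = 2.0 * np.sum(np.log(np.diag(cho)))
    ones = np.ones(n)
    Vi_t = np.linalg.solve(V, t)
    Vi_1 = np.linalg.solve(V, ones)
    root = float(ones @ Vi_t / (ones @ Vi_1))
    resid = t - root
    q = float(resid @ np.linalg.solve(V, resid))
    sigma2 = q / n
    if sigma2 <= 0:
        return math.inf, 0.0, root  # degenerate: perfect fit
    logL = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return logL, sigma2, root


@dataclass
class LambdaFit:
    lambda_hat: float
    logL_lambda: float
    logL_zero: float
    sigma2_hat: float
    root_hat: float


def fit_lambda(phylo: PhyloTrait) -> LambdaFit:
    """Maximum-likelihood Pagel's lambda on [0, 1] under Brownian motion.

    sigma^2 and the root state are profiled out analytically; lambda is
    maximized by bounded 1-D optimization (tolerance 1e-8), with the
    endpoints evaluated explicitly.  ``logL_zero`` is the likelihood with
    lambda held at 0 (phylogenetic independence).
    """
    order = phylo.tip_labels
    if len(order) < 4:
        raise ValueError("need at least 4 tips")
    V = tree_vcv(phylo.tree, order)
    t = phylo.value_vector(order)

    def negll(lam: float) -> float:
        try:
            ll, _, _ = _bm_profile_loglik(lambda_vcv(V, lam), t)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular phylogenetic covariance matrix") from exc
        return -ll

    res = optimize.minimize_scalar(
        negll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-8}
    )
    candidates = [(0.0, -negll(0.0)), (1.0, -negll(1.0)), (float(res.x), -res.fun)]
    lam_hat, logL = max(candidates, key=lambda c: c[1])
    logL_zero = candidates[0][1]
    _, sigma2, root = _bm_profile_loglik(lambda_vcv(V, lam_hat), t)
    return LambdaFit(lam_hat, logL, logL_zero, sigma2, root)


def lrt_lambda(logL_lambda: float, logL_zero: float) -> Tuple[float, float]:
    """Likelihood-ratio test of lambda against lambda = 0 (chi-square, 1 df)."""
    if logL_lambda < logL_zero - 1e-9:
        raise ValueError("logL_lambda must be >= logL_zero (nested models)")
    stat = max(0.0, 2.0 * (logL_lambda - logL_zero))
    return stat, float(stats.chi2.sf(stat, df=1))


@dataclass
class BMFit:
    sigma2_hat: float
    root_hat: float
    logL: float


def fit_bm(
    phylo: PhyloTrait, n_starts: int = 100, seed: Optional[int] = None
) -> BMFit:
    """ML Brownian-motion rate and root state by multi-start optimization.

    The analytic GLS solution is always one start; the remaining starts are
    random perturbations, and the best likelihood wins (so the result is
    never worse than the analytic start).  Run on the lambda-transformed
    tree when a lambda estimate is in play.
    """
    order = phylo.tip_labels
    if len(order) < 3:
        raise ValueError("need at least 3 tips")
    V = tree_vcv(phylo.tree, order)
    t = phylo.value_vector(order)
    n = t.size
    cho = np.linalg.cholesky(V)
    logdet = 2.0 * np.sum(np.log(np.diag(cho)))
    ll_gls, s2_gls, root_gls = _bm_profile_loglik(V, t)
    if s2_gls == 0.0:
        return BMFit(0.0, root_gls, math.inf)

    def negll(params: np.ndarray) -> float:
        root, log_s2 = params
        s2 = math.exp(log_s2)
        resid = t - root
        q = float(resid @ np.linalg.solve(V, resid))
        return 0.5 * (n * math.log(2 * math.pi * s2) + logdet + q / s2)

    best = (ll_gls, s2_gls, root_gls)
    rng = np.random.default_rng(seed)
    scale = max(float(np.std(t)), 1e-6)
    for _ in range(n_starts):
        x0 = np.array(
            [
                root_gls + rng.normal(0, scale),
                math.log(s2_gls) + rng.normal(0, 1.0),
            ]
        )
        res = optimize.minimize(negll, x0, method="Nelder-Mead")
        if -res.fun > best[0]:
            best = (-res.fun, math.exp(res.x[1]), float(res.x[0]))
    return BMFit(best[1], best[2], best[0])


def simulate_bm_bounded(
    tree: dendropy.Tree,
    sigma2: float,
    root: float,
    bounds: Tuple[float, float] = (0.0, math.inf),
    n_sims: int = 10_000,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, List[str]]:
    """Simulate trait evolution under Brownian motion with reflecting bounds.

    Increments are drawn branchwise (variance sigma2 * branch length); node
    values straying past a bound are reflected back (not truncated), so the
    default (0, inf) keeps simulated counts non-negative.  Returns an
    (n_sims, n_tips) array and the tip-label order (sorted).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    lo, hi = bounds
    if not lo <= root <= hi:
        raise ValueError("root state must lie within the bounds")
    rng = np.random.default_rng(seed)
    states: Dict[dendropy.Node, np.ndarray] = {}
    tip_labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    out = np.empty((n_sims, len(tip_labels)))
    col = {label: j for j, label in enumerate(tip_labels)}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            x = np.full(n_sims, float(root))
        else:
            b = node.edge.length or 0.0
            x = states[parent] + rng.normal(0.0, math.sqrt(sigma2 * b), size=n_sims)
            x = _reflect(x, lo, hi)
        states[node] = x
        if node.is_leaf():
            out[:, col[node.taxon.label]] = x
    return out, tip_labels


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values back into [lo, hi] by reflection at the bounds."""
    if math.isinf(hi) and math.isinf(-lo):
        return x
    for _ in range(64):  # repeated folding for values far outside
        below = x < lo
        above = x > hi
        if not (below.any() or above.any()):
            break
        x = np.where(below, 2 * lo - x, x)
        x = np.where(above, 2 * hi - x, x)
    return x


def clade_extremeness(
    phylo: PhyloTrait,
    sims: np.ndarray,
    sim_tip_labels: Sequence[str],
    alpha: float = 0.05,
    weighted: bool = False,
    two_sided: bool = False,
) -> CladeTestResult:
    """Compare observed SCP ancestral states against simulated ones per clade.

    For each resolved internal node the observed state is compared to the
    distribution of SCP states over the simulated trait vectors;
    ``n_more_extreme`` counts simulations strictly beyond the observed value
    in the direction of the observed deviation from the simulation mean
    (both directions when ``two_sided``).  The Bonferroni critical count is
    floor(n_sims * alpha / n_clades).
    """
    order = phylo.tip_labels
    if list(sim_tip_labels) != order:
        raise ValueError("simulation tip order does not match the trait tree")
    edges, internals = _index_tree(phylo.tree, order)
    A, _ = _scp_operators(edges, len(order), len(internals), weighted)
    observed = A @ phylo.value_vector(order)
    sim_states = sims @ A.T  # (n_sims, n_internal)
    n_sims = sims.shape[0]
    resolved = [i for i, node in enumerate(internals) if len(node.child_nodes()) == 2]
    clades, direction, n_more = [], [], []
    for i in resolved:
        obs = observed[i]
        col = sim_states[:, i]
        if two_sided:
            d = "high" if obs > col.mean() else "low"
            n = int(np.count_nonzero(np.abs(col - col.mean()) > abs(obs - col.mean())))
        elif obs > col.mean():
            d, n = "high", int(np.count_nonzero(col > obs))
        else:
            d, n = "low", int(np.count_nonzero(col < obs))
        clades.append(tuple(sorted(
            leaf.taxon.label for leaf in internals[i].leaf_iter()
        )))
        direction.append(d)
        n_more.append(n)
    n_clades = len(resolved)
    critical = int(math.floor(n_sims * alpha / n_clades)) if n_clades else 0
    return CladeTestResult(
        clades=clades,
        observed=observed[resolved],
        direction=direction,
        n_more_extreme=np.array(n_more),
        n_sims=n_sims,
        n_clades=n_clades,
        bonferroni_critical=critical,
    )


# ---------------------------------------------------------------------------
# tip preparation


def prepare_tips(
    tree: dendropy.Tree,
    per_sample_counts: Union[Mapping[str, object], Iterable[Tuple[str, float]]],
) -> PhyloTrait:
    """Attach per-sample polymorphism counts to tree tips.

    ``per_sample_counts`` maps tip labels to a count or list of counts, or is
    an iterable of (tip_label, count) pairs.  Samples whose label is not a
    tip are dropped; multiple samples per tip are averaged; tips separated by
    zero patristic distance are collapsed into one tip (the first label in
    sorted order) carrying the mean of all contributing samples.  Tips with
    no samples are pruned.
    """
    if isinstance(per_sample_counts, Mapping):
        items: List[Tuple[str, float]] = []
        for label, v in per_sample_counts.items():
            if isinstance(v, (list, tuple, np.ndarray)):
                items.extend((label, float(x)) for x in v)
            else:
                items.append((label, float(v)))
    else:
        items = [(label, float(v)) for label, v in per_sample_counts]
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    by_tip: Dict[str, List[float]] = {}
    for label, value in items:
        if label in tip_labels:
            by_tip.setdefault(label, []).append(value)
    if len(by_tip) < 2:
        raise ValueError("fewer than 2 samples map to tree tips")
    work = tree.clone(depth=1)
    work.retain_taxa_with_labels(sorted(by_tip))
    # collapse tips at zero patristic distance
    labels = sorted(by_tip)
    depth: Dict[dendropy.Node, float] = {}
    for node in work.preorder_node_iter():
        parent = node.parent_node
        depth[node] = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
    leaf_by_label = {leaf.taxon.label: leaf for leaf in work.leaf_node_iter()}
    merged: Dict[str, str] = {}
    for label in labels:
        leaf = leaf_by_label[label]
        if (leaf.edge.length or 0.0) != 0.0:
            continue
        parent = leaf.parent_node
        sibs = [
            c
            for c in parent.child_nodes()
            if c.is_leaf() and (c.edge.length or 0.0) == 0.0
        ]
        if len(sibs) > 1:
            keep = min(s.taxon.label for s in sibs)
            for s in sibs:
                if s.taxon.label != keep:
                    merged[s.taxon.label] = keep
    if merged:
        for src, dst in merged.items():
            by_tip[dst].extend(by_tip.pop(src))
        work.retain_taxa_with_labels(sorted(by_tip))
    values = {label: float(np.mean(v)) for label, v in by_tip.items()}
    return PhyloTrait(tree=work, values=values)


def signal_tests(
    phylo: PhyloTrait,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    weighted: bool = False,
) -> SignalTestResult:
    """Run both phylogenetic-signal tests and bundle the results."""
    perm_p = permutation_signal_test(phylo, n_perm=n_perm, seed=seed, weighted=weighted)
    lam = fit_lambda(phylo)
    stat, p = lrt_lambda(lam.logL_lambda, lam.logL_zero)
    return SignalTestResult(
        perm_p=perm_p,
        lambda_hat=lam.lambda_hat,
        logL_lambda=lam.logL_lambda,
        logL_zero=lam.logL_zero,
        lrt_stat=stat,
        lrt_p=p,
    )
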