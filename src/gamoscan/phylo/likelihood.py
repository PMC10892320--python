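"""Felsenstein pruning likelihood under WAG+Γ, with branch optimization.

Columns are compressed to unique site patterns with multiplicities, partials
are vectorised over patterns, and the rate mixture is a leading axis.  Gaps
and 'X' are missing data (all-ones partials).  Branch lengths are optimised
one edge at a time: with the conditionals on both sides of an edge cached,
the likelihood as a function of that single length costs one transition-
matrix application per evaluation, which is what makes exhaustive topology
sweeps affordable at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .substitution import AA_INDEX, GammaRates, SubstitutionModel
from .trees import Subtree, TreeTopology, edge_key, leaf_set

MISSING = 20  # state code for gap / X
MIN_BL = 1e-8
MAX_BL = 20.0


@dataclass
class _Node:
    children: list["_Node"] = field(default_factory=list)
    label: Optional[str] = None  # leaf label
    key: Optional[frozenset[str]] = None  # bipartition key of the edge above
    length: float = 0.1
    # caches (k, npat, 20)
    down: Optional[np.ndarray] = None  # conditional of data below, given state here
    msg: Optional[np.ndarray] = None  # down propagated across the edge above
    above: Optional[np.ndarray] = None  # conditional of everything outside, at the parent


def compress_alignment(sequences: dict[str, str]) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Encode and compress columns to unique patterns.

    Returns (taxa, codes (ntaxa, npat), weights (npat,), pattern_index (ncols,)).
    """
    taxa = sorted(sequences)
    ncols = len(next(iter(sequences.values())))
    for t in taxa:
        if len(sequences[t]) != ncols:
            raise ValueError(f"row {t!r} length mismatch")
    mat = np.empty((len(taxa), ncols), dtype=np.int8)
    for i, t in enumerate(taxa):
        for j, ch in enumerate(sequences[t].upper()):
            if ch in AA_INDEX:
                mat[i, j] = AA_INDEX[ch]
            elif ch in ("-", "X", "?"):
                mat[i, j] = MISSING
            else:
                raise ValueError(f"row {t!r}: unknown residue {ch!r} at column {j}")
    patterns, pattern_index, counts = np.unique(
        mat.T, axis=0, return_inverse=True, return_counts=True
    )
    return taxa, patterns.T, counts.astype(float), pattern_index


class LikelihoodEngine:
    """Per-topology pruning likelihood over a fixed pattern-compressed alignment."""

    def __init__(
        self,
        sequences: dict[str, str],
        model: Optional[SubstitutionModel] = None,
        rates: Optional[GammaRates] = None,
    ) -> None:
        self.model = model or SubstitutionModel.wag()
        self.rates = rates or GammaRates(alpha=1.0, k=4)
        self.taxa, self.codes, self.weights, self.pattern_index = compress_alignment(sequences)
        self.ncols = len(self.pattern_index)
        self.npat = self.codes.shape[1]
        self._leaf_partials = {}
        eye = np.vstack([np.eye(20), np.ones(20)])  # MISSING row = all ones
        for i, taxon in enumerate(self.taxa):
            self._leaf_partials[taxon] = eye[self.codes[i]]  # (npat, 20)

    def set_rates(self, rates: GammaRates) -> None:
        self.rates = rates

    # -- tree construction -------------------------------------------------

    def build_tree(
        self, topology: TreeTopology, branch_lengths: Optional[dict[frozenset[str], float]] = None
    ) -> _Node:
        missing = set(topology.leaves) - set(self.taxa)
        if missing:
            raise ValueError(f"alignment lacks rows for leaves {sorted(missing)}")
        leaves = leaf_set(topology.structure)
        bl = branch_lengths or {}

        def build(sub: Subtree) -> _Node:
            key = edge_key(leaf_set(sub), leaves)
            if isinstance(sub, str):
                node = _Node(label=sub, key=key)
            else:
                node = _Node(children=[build(c) for c in sub], key=key)
            node.length = float(bl.get(key, 0.1))
            return node

        if len(topology.leaves) == 2:
            # single-edge tree: root at one leaf, the other hangs below
            a, b = topology.structure
            child = build(b)
            return _Node(label=a, children=[child])
        root = _Node(children=[build(c) for c in topology.structure])
        return root

    def branch_lengths_of(self, root: _Node) -> dict[frozenset[str], float]:
        out: dict[frozenset[str], float] = {}

        def walk(node: _Node) -> None:
            for c in node.children:
                out[c.key] = c.length
                walk(c)

        walk(root)
        return out

    # -- likelihood --------------------------------------------------------

    def _edge_pmats(self, length: float) -> np.ndarray:
        return self.model.transition_matrices(length * self.rates.rates)  # (k, 20, 20)

    def _down_pass(self, node: _Node) -> None:
        k = self.rates.k
        parts = []
        if node.label is not None:
            lp = self._leaf_partials[node.label]  # (npat, 20)
            parts.append(np.broadcast_to(lp, (k, *lp.shape)))
        for c in node.children:
            self._down_pass(c)
            parts.append(c.msg)
        node.down = parts[0].copy()
        for p in parts[1:]:
            node.down *= p
        if node.key is not None:  # not the root: propagate across the edge above
            P = self._edge_pmats(node.length)  # (k, 20, 20)
            node.msg = node.down @ P.transpose(0, 2, 1)

    def _up_pass(self, root: _Node) -> None:
        """Fill node.above: conditional of all data outside the node's subtree,
        evaluated at the *parent* end of the node's edge (π not yet applied)."""
        k, npat = self.rates.k, self.npat
        root_above = np.ones((k, npat, 20))
        stack = [(root, root_above)]
        while stack:
            node, above = stack.pop()
            if node.label is not None:  # a labelled root (2-leaf case)
                lp = self._leaf_partials[node.label]
                above = above * np.broadcast_to(lp, (k, *lp.shape))
            msgs = [c.msg for c in node.children]
            for i, c in enumerate(node.children):
                prod = above.copy()
                for j, m in enumerate(msgs):
                    if j != i:
                        prod *= m
                c.above = prod
                if c.children:
                    # move the outside-conditional across c's edge; with the
                    # equilibrium prior applied at whichever node hosts the
                    # final sum, reversibility lets the same P serve both
                    # directions via pi_i P_ij = pi_j P_ji
                    P = self._edge_pmats(c.length)
                    child_above = prod @ P
                    stack.append((c, child_above))

    def _pattern_site_likelihood(self, root: _Node) -> np.ndarray:
        lik = root.down @ self.model.equilibrium_freqs  # (k, npat)
        return lik.mean(axis=0)

    def log_likelihood(self, root: _Node) -> float:
        self._down_pass(root)
        site = self._pattern_site_likelihood(root)
        return float(self.weights @ np.log(np.maximum(site, 1e-300)))

    def site_log_likelihoods(self, root: _Node) -> np.ndarray:
        """Per-column (not per-pattern) natural-log site likelihoods."""
        self._down_pass(root)
        site = np.log(np.maximum(self._pattern_site_likelihood(root), 1e-300))
        return site[self.pattern_index]

    def log_likelihood_reweighted(self, root: _Node, weights: np.ndarray) -> float:
        self._down_pass(root)
        site = self._pattern_site_likelihood(root)
        return float(weights @ np.log(np.maximum(site, 1e-300)))

    # -- branch-length optimisation -----------------------------------------

    def _edge_loglik_fn(self, node: _Node):
        """lnL as a function of this node's edge length, everything else fixed."""
        A = node.above * self.model.equilibrium_freqs[None, None, :]  # (k,npat,20)
        B = node.down
        w = self.weights

        def fn(t: float) -> float:
            P = self._edge_pmats(t)  # (k,20,20)
            m = B @ P.transpose(0, 2, 1)
            site = np.einsum("kni,kni->n", A, m) / P.shape[0]
            return float(w @ np.log(np.maximum(site, 1e-300)))

        return fn

    def optimize_branch_lengths(
        self,
        topology: TreeTopology,
        init: Optional[dict[frozenset[str], float]] = None,
        tol: float = 1e-6,
        max_sweeps: int = 50,
        brent_xtol: float = 1e-6,
    ) -> tuple[dict[frozenset[str], float], float, bool]:
        """Coordinate-wise ML branch lengths; returns (lengths, lnL, converged)."""
        root = self.build_tree(topology, init)
        nodes: list[_Node] = []

        def collect(n: _Node) -> None:
            for c in n.children:
                nodes.append(c)
                collect(c)

        collect(root)
        lnl = self.log_likelihood(root)
        converged = False
        for _ in range(max_sweeps):
            self._down_pass(root)
            self._up_pass(root)
            for node in nodes:
                fn = self._edge_loglik_fn(node)
                res = minimize_scalar(
                    lambda t: -fn(t),
                    bounds=(MIN_BL, MAX_BL),
                    method="bounded",
                    options={"xatol": brent_xtol},
                )
                if -res.fun >= fn(node.length):
                    node.length = float(res.x)
                # refresh caches along this edge so later edges in the sweep
                # see the updated length
                self._refresh_after(root, node)
            new_lnl = self.log_likelihood(root)
            if new_lnl - lnl < tol:
                lnl = max(lnl, new_lnl)
                converged = True
                break
            lnl = new_lnl
        return self.branch_lengths_of(root), lnl, converged

    def _refresh_after(self, root: _Node, changed: _Node) -> None:
        # full recompute of down/msg/above; O(nodes) matmuls, cheap at this scale
        self._down_pass(root)
        self._up_pass(root)


def brute_force_log_likelihood(
    sequences: dict[str, str],
    topology: TreeTopology,
    branch_lengths: dict[frozenset[str], float],
    model: SubstitutionModel,
    rates: GammaRates,
) -> np.ndarray:
    """Per-column lnL by explicit summation over all internal-node states.

    Exponential in the number of internal nodes; an independent oracle for
    trees with up to ~4 leaves.
    """
    taxa = sorted(sequences)
    ncols = len(next(iter(sequences.values())))
    leaves = leaf_set(topology.structure)

    nodes: list[Subtree] = []

    def collect_internal(sub: Subtree) -> None:
        if isinstance(sub, str):
            return
        nodes.append(sub)
        for c in sub:
            collect_internal(c)

    root = topology.structure
    internal: list = ["ROOT"]
    for c in root:
        collect_internal(c)
    internal += nodes

    pi = model.equilibrium_freqs
    out = np.zeros(ncols)
    for col in range(ncols):
        obs = {t: sequences[t][col].upper() for t in taxa}
        total = 0.0
        for kcat in range(rates.k):
            rate = rates.rates[kcat]
            pmats = {}

            def pmat(sub: Subtree) -> np.ndarray:
                key = edge_key(leaf_set(sub), leaves)
                if key not in pmats:
                    pmats[key] = model.transition_matrix(branch_lengths[key] * rate)
                return pmats[key]

            def states(sub: Subtree):
                if isinstance(sub, str):
                    ch = obs[sub]
                    if ch in AA_INDEX:
                        return [AA_INDEX[ch]]
                    return list(range(20))
                return list(range(20))

            def enum(sub: Subtree, parent_state: int) -> float:
                P = pmat(sub)
                tot = 0.0
                for s in states(sub):
                    p = P[parent_state, s]
                    if isinstance(sub, str):
                        tot += p
                    else:
                        term = p
                        for c in sub:
                            term *= enum(c, s)
                        tot += term
                return tot

            cat = 0.0
            for s_root in range(20):
                term = pi[s_root]
                for c in root:
                    term *= enum(c, s_root)
                cat += term
            total += cat * rates.weights[kcat]
        out[col] = np.log(total)
    return out
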