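"""Maximum-likelihood phylogeny estimation as a model/results pair.

`MLPhylogeny` is constructed from a (masked) protein alignment; `fit()`
exhaustively enumerates the constrained topology space, optimises branch
lengths and the discrete-gamma shape, and returns an `MLPhylogenyResults`
carrying the ML tree, per-topology log-likelihoods, and methods for
nonparametric bootstrap support and KH/SH/AU topology tests (RELL
resampling; the AU test follows Shimodaira's multiscale-bootstrap
construction, with no claim of bit-compatibility with CONSEL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .likelihood import LikelihoodEngine
from .substitution import GammaRates, SubstitutionModel
from .trees import Subtree, TreeTopology, enumerate_topologies

MAX_EFFECTIVE_LEAVES = 9  # (2*9-5)!! = 135135 topologies; beyond this, fix subtrees

DEFAULT_AU_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


@dataclass
class TopologyFit:
    topology: TreeTopology
    branch_lengths: dict
    loglike: float
    converged: bool


class MLPhylogeny:
    """WAG+Γ maximum-likelihood phylogeny over an exhaustive topology space.

    Parameters
    ----------
    sequences : mapping id -> aligned (or equal-length) protein string.
        Pass masked columns only; gaps and 'X' are treated as missing data.
    model : substitution model (default WAG).
    n_rate_categories : discrete-gamma categories (default 4).
    constraints : resolved subtrees to fix, as nested tuples of leaf labels;
        each collapses to one effective OTU during enumeration.
    """

    def __init__(
        self,
        sequences: dict[str, str],
        *,
        model: Optional[SubstitutionModel] = None,
        n_rate_categories: int = 4,
        constraints: Optional[Sequence[Subtree]] = None,
    ) -> None:
        self.model = model or SubstitutionModel.wag()
        self.k = int(n_rate_categories)
        self.constraints = list(constraints or [])
        self.sequences = dict(sequences)
        self.engine = LikelihoodEngine(
            self.sequences, self.model, GammaRates(alpha=1.0, k=self.k)
        )
        if _effective_leaves(len(sequences), self.constraints) > MAX_EFFECTIVE_LEAVES:
            raise ValueError(
                "too many effective leaves for exhaustive search; fix resolved "
                "subtrees via `constraints` to reduce the OTU count"
            )
        self.topologies = enumerate_topologies(sorted(sequences), self.constraints)

    @classmethod
    def from_alignment(cls, msa, mask=None, **kwargs) -> "MLPhylogeny":
        """Build from a MultipleAlignment, optionally applying a ColumnMask."""
        if mask is not None:
            msa = msa.subset_columns(mask.keep)
        return cls({r.id: r.residues for r in msa.records}, **kwargs)

    def fit(
        self,
        alpha: Optional[float] = None,
        alpha_bounds: tuple[float, float] = (0.02, 50.0),
        tol: float = 1e-6,
        max_sweeps: int = 50,
    ) -> "MLPhylogenyResults":
        """Fit branch lengths per topology and (unless given) the gamma shape.

        The shape is fitted on the provisional ML topology by scalar search
        with branch lengths re-optimised at each candidate alpha; all
        topologies are then re-optimised under the fitted shape so that
        per-topology likelihoods are comparable.
        """
        if alpha_bounds[0] >= alpha_bounds[1] or alpha_bounds[0] <= 0:
            raise ValueError("degenerate alpha bounds")
        fit_shape = alpha is None
        self.engine.set_rates(GammaRates(alpha=alpha if alpha else 1.0, k=self.k))

        fits = self._fit_all(tol=max(tol, 1e-4), max_sweeps=max_sweeps)
        best = max(fits, key=lambda f: f.loglike)

        if fit_shape and self.k > 1:
            alpha_hat = self._fit_alpha(best, alpha_bounds, tol)
            self.engine.set_rates(GammaRates(alpha=alpha_hat, k=self.k))
            fits = self._fit_all(tol=tol, max_sweeps=max_sweeps, warm=fits)
        else:
            alpha_hat = alpha if alpha is not None else float("nan")
            fits = self._fit_all(tol=tol, max_sweeps=max_sweeps, warm=fits)

        order = np.argsort([-f.loglike for f in fits], kind="stable")
        fits = [fits[i] for i in order]
        return MLPhylogenyResults(model=self, fits=fits, gamma=self.engine.rates)

    # -- internals ----------------------------------------------------------

    def _fit_all(self, tol: float, max_sweeps: int, warm=None) -> list[TopologyFit]:
        out = []
        for i, topo in enumerate(self.topologies):
            init = None
            if warm is not None:
                for f in warm:
                    if f.topology.canonical_id == topo.canonical_id:
                        init = f.branch_lengths
                        break
            bl, lnl, ok = self.engine.optimize_branch_lengths(
                topo, init=init, tol=tol, max_sweeps=max_sweeps
            )
            out.append(TopologyFit(topo, bl, lnl, ok))
        return out

    def _fit_alpha(self, best: TopologyFit, bounds, tol: float) -> float:
        engine = self.engine
        topo, init = best.topology, best.branch_lengths

        def neg(alpha: float) -> float:
            engine.set_rates(GammaRates(alpha=float(alpha), k=self.k))
            _, lnl, _ = engine.optimize_branch_lengths(
                topo, init=init, tol=max(tol, 1e-3), max_sweeps=10
            )
            return -lnl

        res = minimize_scalar(neg, bounds=bounds, method="bounded",
                              options={"xatol": 1e-3})
        return float(res.x)


def _effective_leaves(n: int, constraints) -> int:
    from .trees import leaf_set

    covered = sum(len(leaf_set(c)) for c in constraints)
    return n - covered + len(constraints)


class MLPhylogenyResults:
    """Estimates from an exhaustive ML topology search."""

    def __init__(self, model: MLPhylogeny, fits: list[TopologyFit], gamma: GammaRates):
        self.model = model
        self.fits = fits  # sorted, best first
        self.gamma = gamma

    @property
    def tree(self) -> TreeTopology:
        return self.fits[0].topology

    @property
    def branch_lengths(self) -> dict:
        return self.fits[0].branch_lengths

    @property
    def loglike(self) -> float:
        return self.fits[0].loglike

    @property
    def alpha(self) -> float:
        return self.gamma.alpha

    def newick(self, support: Optional[dict] = None) -> str:
        return self.tree.newick(self.branch_lengths, support)

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-column lnL matrix, one row per fitted topology (best first)."""
        eng = self.model.engine
        eng.set_rates(self.gamma)
        rows = []
        for f in self.fits:
            root = eng.build_tree(f.topology, f.branch_lengths)
            rows.append(eng.site_log_likelihoods(root))
        return np.array(rows)

    # -- inference ----------------------------------------------------------

    def bootstrap(self, n_boot: int = 200, seed: Optional[int] = None,
                  tol: float = 1e-2, max_sweeps: int = 2) -> dict:
        """Nonparametric bootstrap support for the ML tree's internal edges.

        Columns are resampled with replacement; the full constrained topology
        search is re-run per replicate (branch lengths warm-started, shape
        fixed at the fitted value).  Returns bipartition -> support in [0, 1].
        """
        if n_boot < 1:
            raise ValueError("need at least one replicate")
        eng = self.model.engine
        eng.set_rates(self.gamma)
        rng = np.random.default_rng(seed)
        ncols = eng.ncols
        splits = self.tree.splits()
        counts = {s: 0 for s in splits}
        for _ in range(n_boot):
            cols = rng.integers(0, ncols, size=ncols)
            w = np.bincount(eng.pattern_index[cols], minlength=eng.npat).astype(float)
            best_lnl, best_topo = -np.inf, None
            for f in self.fits:
                bl, lnl = _optimize_weighted(eng, f.topology, f.branch_lengths, w,
                                             tol=tol, max_sweeps=max_sweeps)
                if lnl > best_lnl:
                    best_lnl, best_topo = lnl, f.topology
            rep_splits = best_topo.splits()
            for s in splits:
                if s in rep_splits:
                    counts[s] += 1
        return {s: counts[s] / n_boot for s in splits}

    def topology_tests(
        self,
        n_rell: int = 10000,
        au_scales: Sequence[float] = DEFAULT_AU_SCALES,
        seed: Optional[int] = None,
    ) -> pd.DataFrame:
        """KH, SH and AU tests over the fitted topology set via RELL."""
        site_lnl = self.site_log_likelihoods()
        table = topology_test_table(site_lnl, n_rell=n_rell, au_scales=au_scales,
                                    seed=seed)
        table.insert(0, "topology", [f.topology.canonical_id for f in self.fits])
        table.insert(1, "newick", [f.topology.newick() for f in self.fits])
        return table

    def summary(self) -> str:
        eng = self.model.engine
        lines = [
            "ML phylogeny (exhaustive constrained search)",
            "=" * 44,
            f"model:            {self.model.model.name}+G{self.gamma.k}",
            f"alignment:        {len(self.model.sequences)} taxa, "
            f"{eng.ncols} columns ({eng.npat} patterns)",
            f"topologies:       {len(self.fits)} evaluated",
            f"log-likelihood:   {self.loglike:.4f}",
            f"gamma shape:      {self.alpha:.4g} ({self.gamma.k} categories)",
            f"ML tree:          {self.newick()}",
        ]
        if len(self.fits) > 1:
            second = self.fits[1]
            lines.append(
                f"runner-up dlnL:   {self.loglike - second.loglike:.4f}"
            )
        return "\n".join(lines)


def _optimize_weighted(eng: LikelihoodEngine, topology, init, weights,
                       tol: float, max_sweeps: int):
    """Branch-length optimisation under resampled pattern weights."""
    saved = eng.weights
    try:
        eng.weights = weights
        bl, lnl, _ = eng.optimize_branch_lengths(
            topology, init=init, tol=tol, max_sweeps=max_sweeps, brent_xtol=1e-4
        )
    finally:
        eng.weights = saved
    return bl, lnl


def topology_test_table(
    site_lnl: np.ndarray,
    n_rell: int = 10000,
    au_scales: Sequence[float] = DEFAULT_AU_SCALES,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-topology lnL, ΔlnL and KH/SH/AU p-values from a per-site lnL matrix.

    Rows are topologies; the best (highest total lnL) row anchors ΔlnL.  KH
    and SH use centred RELL resampling; AU fits Shimodaira's z-regression
    over the multiscale bootstrap proportions.
    """
    site_lnl = np.asarray(site_lnl, dtype=float)
    if site_lnl.ndim != 2 or site_lnl.shape[0] < 2:
        raise ValueError("need a (topologies x sites) matrix with >=2 topologies")
    ntopo, nsites = site_lnl.shape
    rng = np.random.default_rng(seed)
    totals = site_lnl.sum(axis=1)
    best = int(np.argmax(totals))
    delta = totals[best] - totals

    # RELL replicates at scale 1 (shared by KH and SH)
    rell = _rell_sums(site_lnl, rng, n_rell, nsites)  # (n_rell, ntopo)

    p_kh = np.ones(ntopo)
    for t in range(ntopo):
        if t == best:
            continue
        d_rep = rell[:, best] - rell[:, t]
        d_cent = d_rep - d_rep.mean()
        p_kh[t] = float(np.mean(d_cent >= delta[t]))

    centred = rell - rell.mean(axis=0, keepdims=True)  # (n_rell, ntopo)
    dmax = centred.max(axis=1, keepdims=True)
    p_sh = np.array([
        float(np.mean((dmax[:, 0] - centred[:, t]) >= delta[t])) for t in range(ntopo)
    ])

    p_au = _au_pvalues(site_lnl, rng, au_scales, n_rell)

    df = pd.DataFrame(
        dict(
            lnL=totals,
            delta_lnL=delta,
            p_au=np.clip(p_au, 0.0, 1.0),
            p_kh=np.clip(p_kh, 0.0, 1.0),
            p_sh=np.clip(p_sh, 0.0, 1.0),
        )
    )
    df["is_ml"] = [t == best for t in range(ntopo)]
    return df


def _rell_sums(site_lnl: np.ndarray, rng, n_rell: int, n_prime: int,
               chunk: int = 1000) -> np.ndarray:
    """Resampled per-topology lnL sums, (n_rell, ntopo), memory-bounded.

    Site resampling with replacement is realised as multinomial column
    weights, so each replicate is a weights @ lnL matrix product.
    """
    ntopo, nsites = site_lnl.shape
    out = np.empty((n_rell, ntopo))
    p = np.full(nsites, 1.0 / nsites)
    done = 0
    while done < n_rell:
        m = min(chunk, n_rell - done)
        w = rng.multinomial(n_prime, p, size=m).astype(np.float64)
        out[done : done + m] = w @ site_lnl.T
        done += m
    return out


def _au_pvalues(site_lnl: np.ndarray, rng, scales, n_rell: int) -> np.ndarray:
    """Approximately-unbiased p via multiscale bootstrap and z-regression.

    For each scale r, n' = round(r * nsites) sites are resampled and the
    bootstrap proportion bp(r) of replicates in which a topology attains the
    maximum resampled lnL is recorded; Φ^{-1}(1 - bp) is regressed on
    (d √r + c / √r) by weighted least squares and p_AU = 1 - Φ(d - c).
    """
    ntopo, nsites = site_lnl.shape
    scales = np.asarray(scales, dtype=float)
    bps = np.zeros((len(scales), ntopo))
    for si, r in enumerate(scales):
        n_prime = max(1, int(round(r * nsites)))
        sums = _rell_sums(site_lnl, rng, n_rell, n_prime)  # (n_rell, ntopo)
        maxima = sums.max(axis=1, keepdims=True)
        is_best = sums >= maxima - 1e-10  # ties count for every tied topology
        bps[si] = is_best.mean(axis=0)

    out = np.zeros(ntopo)
    eps = 0.5 / n_rell
    for t in range(ntopo):
        bp = bps[:, t]
        if np.all(bp >= 1 - eps):
            out[t] = 1.0
            continue
        if np.all(bp <= eps):
            out[t] = 0.0
            continue
        usable = (bp > eps) & (bp < 1 - eps)
        if usable.sum() < 2:
            # fallback: plain bootstrap proportion at the scale nearest 1
            nearest = int(np.argmin(np.abs(scales - 1.0)))
            out[t] = float(bp[nearest])
            continue
        r = scales[usable]
        b = np.clip(bp[usable], eps, 1 - eps)
        z = norm.ppf(1.0 - b)
        X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        w = n_rell * norm.pdf(z) ** 2 / (b * (1.0 - b))
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
        d, c = coef
        out[t] = float(norm.sf(d - c))
    return out
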