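"""Felsenstein pruning likelihood for partitioned GTR(+G)(+I) models.

The engine works on an unrooted tree held as a plain adjacency structure
(:class:`LightTree`).  Site columns are compressed to unique patterns per
subset.  Because the models are time-reversible, likelihoods are computed
by message passing: the "message" over a directed edge is the conditional
likelihood of everything on the sender's side, propagated through that
edge's transition matrix.  With all 2(N-1) directed messages cached, the
likelihood restricted to any single edge — needed for branch-length
optimisation and for scoring nearest-neighbour-interchange candidates —
costs O(patterns) instead of a full tree traversal.

State order is T, C, A, G throughout (matching the simulator).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .alignment import AlignmentMatrix
from .simulate import gtr_rate_matrix, _eigen_reversible

__all__ = [
    "GTRModel",
    "LightTree",
    "discrete_gamma_rates",
    "PartitionedLikelihood",
]

_BL_MIN, _BL_MAX = 1e-9, 15.0


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of *ncat* equal-probability gamma categories (mean 1)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    edges = _gamma_dist.ppf(np.linspace(0.0, 1.0, ncat + 1), alpha, scale=1.0 / alpha)
    cum = gammainc(alpha + 1.0, alpha * edges)
    cum[-1] = 1.0
    return ncat * np.diff(cum)


@dataclass(frozen=True)
class GTRModel:
    """GTR(+G)(+I) parameter set, states in T, C, A, G order.

    ``exchangeabilities`` follow the C-T, A-T, G-T, A-C, G-C order with
    G-A fixed to 1; ``None`` means all equal (F81/JC-style).  ``scale``
    multiplies every branch length, which is how linked-branch-length
    partitioned models give each subset its own overall rate.
    """

    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    exchangeabilities: tuple[float, ...] | None = None
    alpha: float | None = None
    p_inv: float = 0.0
    scale: float = 1.0
    ncat: int = 4

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the discrete rate mixture, mean 1 overall."""
        if self.alpha is not None:
            g = discrete_gamma_rates(self.alpha, self.ncat)
            w = np.full(self.ncat, 1.0 / self.ncat)
        else:
            g, w = np.ones(1), np.ones(1)
        if self.p_inv > 0.0:
            rates = np.concatenate([[0.0], g / (1.0 - self.p_inv)])
            weights = np.concatenate([[self.p_inv], w * (1.0 - self.p_inv)])
            return rates, weights
        return g, w


class LightTree:
    """Mutable unrooted tree: integer nodes, adjacency lists, edge lengths.

    Leaves are ``0..n_leaves-1`` and carry labels; internal nodes follow.
    """

    def __init__(self, labels: Sequence[str]):
        self.labels = list(labels)
        self.adj: dict[int, list[int]] = {i: [] for i in range(len(labels))}
        self.lengths: dict[tuple[int, int], float] = {}
        self._next = len(labels)

    # -- construction --------------------------------------------------

    def new_internal(self) -> int:
        node = self._next
        self.adj[node] = []
        self._next += 1
        return node

    @staticmethod
    def _key(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u < v else (v, u)

    def connect(self, u: int, v: int, length: float) -> None:
        self.adj[u].append(v)
        self.adj[v].append(u)
        self.lengths[self._key(u, v)] = float(length)

    def disconnect(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)
        del self.lengths[self._key(u, v)]

    def length(self, u: int, v: int) -> float:
        return self.lengths[self._key(u, v)]

    def set_length(self, u: int, v: int, length: float) -> None:
        self.lengths[self._key(u, v)] = float(length)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def edges(self) -> list[tuple[int, int]]:
        return list(self.lengths)

    def internal_edges(self) -> list[tuple[int, int]]:
        n = self.n_leaves
        return [(u, v) for (u, v) in self.lengths if u >= n and v >= n]

    def copy(self) -> "LightTree":
        t = LightTree(self.labels)
        t.adj = {k: list(v) for k, v in self.adj.items()}
        t.lengths = dict(self.lengths)
        t._next = self._next
        return t

    def apply_nni(self, u: int, v: int, b: int, c: int) -> None:
        """Swap subtree *b* (attached at *u*) with subtree *c* (at *v*)."""
        lb, lc = self.length(u, b), self.length(v, c)
        self.disconnect(u, b)
        self.disconnect(v, c)
        self.connect(u, c, lc)
        self.connect(v, b, lb)

    # -- conversion ----------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree, labels: Sequence[str] | None = None,
                      default_length: float = 0.01) -> "LightTree":
        """Convert a dendropy tree; degree-2 nodes (rooted roots) collapse."""
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if labels is None:
            labels = sorted(leaf_labels)
        if sorted(labels) != sorted(leaf_labels):
            raise ValueError("tree leaves do not match the requested labels")
        lt = cls(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        node_id: dict[int, int] = {}

        def get_id(nd):
            key = id(nd)
            if key not in node_id:
                if nd.is_leaf():
                    node_id[key] = index[nd.taxon.label]
                else:
                    node_id[key] = lt.new_internal()
            return node_id[key]

        root = tree.seed_node
        for nd in tree.preorder_node_iter():
            parent = nd.parent_node
            if parent is None:
                continue
            u, v = get_id(parent), get_id(nd)
            lt.connect(u, v, nd.edge.length if nd.edge.length is not None
                       else default_length)
        # collapse a degree-2 root if present
        root_id = get_id(root)
        if len(lt.adj[root_id]) == 2:
            a, b = lt.adj[root_id]
            total = lt.length(root_id, a) + lt.length(root_id, b)
            lt.disconnect(root_id, a)
            lt.disconnect(root_id, b)
            del lt.adj[root_id]
            lt.connect(a, b, total)
        return lt

    def to_newick(self) -> str:
        """Serialise unrooted, rooted at an arbitrary internal node."""
        root = max(self.adj)
        if root < self.n_leaves:  # two-leaf tree
            a, b = 0, 1
            return f"({self.labels[a]}:{self.length(a, b)},{self.labels[b]}:0.0);"

        def rec(node: int, parent: int) -> str:
            if node < self.n_leaves:
                return f"{self.labels[node]}:{self.length(node, parent):.10g}"
            inner = ",".join(
                rec(ch, node) for ch in self.adj[node] if ch != parent
            )
            return f"({inner}):{self.length(node, parent):.10g}"

        inner = ",".join(rec(ch, root) for ch in self.adj[root])
        return f"({inner});"


@dataclass
class _Subset:
    """Pattern-compressed data and model state for one scheme subset."""

    name: str
    tips: np.ndarray  # (n_taxa, n_patterns, 4) tip partials
    weights: np.ndarray  # (n_patterns,)
    n_variable: int
    model: GTRModel = field(default_factory=GTRModel)
    # model-derived caches
    lam: np.ndarray | None = None
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    pi: np.ndarray | None = None
    cat_rates: np.ndarray | None = None
    cat_weights: np.ndarray | None = None

    def set_model(self, model: GTRModel) -> None:
        self.model = model
        pi = np.asarray(model.freqs, dtype=float)
        q = gtr_rate_matrix(model.freqs, model.exchangeabilities)
        self.lam, self.u, self.v = _eigen_reversible(q, pi)
        self.pi = pi
        self.cat_rates, self.cat_weights = model.category_rates()

    def transition(self, t: float) -> np.ndarray:
        """(ncat, 4, 4) transition matrices for branch length *t*."""
        arg = np.outer(self.cat_rates * self.model.scale * t, self.lam)
        p = np.einsum("xm,cm,my->cxy", self.u, np.exp(arg), self.v)
        return np.clip(p, 0.0, None)


def _compress(aln: AlignmentMatrix, sites_1based: Sequence[int] | None):
    codes = aln.state_codes()
    if sites_1based is not None:
        codes = codes[:, np.asarray(sites_1based, dtype=int) - 1]
    patterns, inverse, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    n_var = int(
        sum(
            c
            for p, c in zip(patterns, counts)
            if len(set(int(x) for x in p if x < 4)) > 1
        )
    )
    tips = np.ones((aln.n_taxa, patterns.shape[0], 4))
    for s in range(4):
        hit = patterns.T == s  # (n_taxa, n_pat)
        for sp in range(4):
            if sp != s:
                tips[:, :, sp][hit] = 0.0
    return tips, counts.astype(float), n_var


class PartitionedLikelihood:
    """Joint likelihood of one alignment under a partition scheme.

    All subsets share the tree topology and branch lengths; each subset
    has its own substitution model and, through ``GTRModel.scale``, its
    own overall rate.
    """

    def __init__(
        self,
        aln: AlignmentMatrix,
        scheme=None,
        models: Sequence[GTRModel] | None = None,
        ncat: int = 4,
    ):
        self.aln = aln
        self.labels = list(aln.taxa)
        subsets: list[_Subset] = []
        if scheme is None:
            groups = [("all", None)]
        else:
            groups = [(name, sites) for name, sites, _ in scheme.subsets]
        for k, (name, sites) in enumerate(groups):
            tips, weights, n_var = _compress(aln, sites)
            sub = _Subset(name=name, tips=tips, weights=weights, n_variable=n_var)
            default = GTRModel(
                freqs=tuple(self._empirical_freqs(aln, sites)),
                exchangeabilities=(1.0,) * 5,
                alpha=1.0,
                ncat=ncat,
            )
            sub.set_model(models[k] if models is not None else default)
            subsets.append(sub)
        self.subsets = subsets
        self.tree: LightTree | None = None
        self._messages: list[dict] | None = None

    @staticmethod
    def _empirical_freqs(aln: AlignmentMatrix, sites) -> np.ndarray:
        codes = aln.state_codes()
        if sites is not None:
            codes = codes[:, np.asarray(sites, dtype=int) - 1]
        counts = np.bincount(codes[codes < 4].ravel(), minlength=4) + 1.0
        return counts / counts.sum()

    # -- tree management ----------------------------------------------

    def set_tree(self, tree: LightTree) -> None:
        if sorted(tree.labels) != sorted(self.labels):
            raise ValueError("tree leaves do not match alignment taxa")
        if tree.labels != self.labels:
            remap = tree.copy()
            remap.labels = list(self.labels)
            perm = {tree.labels.index(lab): i for i, lab in enumerate(self.labels)}
            n = tree.n_leaves
            mapping = {old: perm[old] for old in range(n)}
            remap.adj = {}
            for node, nbrs in tree.adj.items():
                remap.adj[mapping.get(node, node)] = [
                    mapping.get(x, x) for x in nbrs
                ]
            remap.lengths = {
                LightTree._key(mapping.get(u, u), mapping.get(v, v)): l
                for (u, v), l in tree.lengths.items()
            }
            tree = remap
        self.tree = tree
        self._messages = None

    # -- message passing -----------------------------------------------

    def _ordered_edges(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """Directed edges inward to a fixed collect node, then outward."""
        tree = self.tree
        root = max(tree.adj)
        parent: dict[int, int | None] = {root: None}
        order = [root]
        stack = [root]
        while stack:
            node = stack.pop()
            for nb in tree.adj[node]:
                if nb != parent.get(node):
                    parent[nb] = node
                    order.append(nb)
                    stack.append(nb)
        inward = [(n, parent[n]) for n in reversed(order) if parent[n] is not None]
        outward = [(parent[n], n) for n in order if parent[n] is not None]
        self._collect_node = root
        return inward, outward

    def _pass_message(self, sub_idx: int, frm: int, to: int, msgs: dict) -> None:
        tree, sub = self.tree, self.subsets[sub_idx]
        p = sub.transition(tree.length(frm, to))
        if frm < tree.n_leaves:
            out = np.einsum("cxy,py->pcx", p, sub.tips[frm])
            logsc = 0.0
        else:
            partial, logsc = None, 0.0
            for nb in tree.adj[frm]:
                if nb == to:
                    continue
                m, ls = msgs[(nb, frm)]
                partial = m if partial is None else partial * m
                logsc = logsc + ls
            # out[p,c,x] = sum_y P[c,x,y] partial[p,c,y], batched over c
            out = np.matmul(
                partial.transpose(1, 0, 2), p.transpose(0, 2, 1)
            ).transpose(1, 0, 2)
        smax = out.max(axis=(1, 2))
        smax = np.where(smax > 0, smax, 1.0)
        out = out / smax[:, None, None]
        msgs[(frm, to)] = (out, logsc + np.log(smax))

    def compute_messages(self) -> None:
        inward, outward = self._ordered_edges()
        self._messages = []
        for k in range(len(self.subsets)):
            msgs: dict = {}
            for frm, to in inward:
                self._pass_message(k, frm, to, msgs)
            for frm, to in outward:
                self._pass_message(k, frm, to, msgs)
            self._messages.append(msgs)

    def _collect(self, sub_idx: int) -> float:
        """Log-likelihood of one subset from cached messages."""
        tree, sub = self.tree, self.subsets[sub_idx]
        node = self._collect_node
        msgs = self._messages[sub_idx]
        partial, logsc = None, 0.0
        for nb in tree.adj[node]:
            m, ls = msgs[(nb, node)]
            partial = m if partial is None else partial * m
            logsc = logsc + ls
        if node < tree.n_leaves:  # two-leaf tree: collect node is a tip
            partial = partial * sub.tips[node][:, None, :]
        site = np.einsum("pcx,x,c->p", partial, sub.pi, sub.cat_weights)
        site = np.maximum(site, 1e-300)
        return float(sub.weights @ (np.log(site) + logsc))

    def loglik(self, recompute: bool = True) -> float:
        if self._messages is None or recompute:
            self.compute_messages()
        return sum(self._collect(k) for k in range(len(self.subsets)))

    # -- per-edge likelihood machinery ---------------------------------

    def _edge_sides(self, sub_idx: int, u: int, v: int):
        """π-weighted side partials (A at u-side, B at v-side) for an edge."""
        tree, sub = self.tree, self.subsets[sub_idx]
        msgs = self._messages[sub_idx]

        def side(node: int, other: int):
            if node < tree.n_leaves:
                ncat = len(sub.cat_rates)
                return np.repeat(sub.tips[node][:, None, :], ncat, axis=1), 0.0
            partial, logsc = None, 0.0
            for nb in tree.adj[node]:
                if nb == other:
                    continue
                m, ls = msgs[(nb, node)]
                partial = m if partial is None else partial * m
                logsc = logsc + ls
            return partial, logsc

        a, la = side(u, v)
        b, lb = side(v, u)
        return a * sub.pi[None, None, :], la, b, lb

    def _edge_loglik_fn(self, u: int, v: int):
        """Return f(t) = joint log-likelihood as a function of edge length."""
        pieces = []
        for k, sub in enumerate(self.subsets):
            a, la, b, lb = self._edge_sides(k, u, v)
            am = np.einsum("pcx,xm->pcm", a, sub.u)
            bm = np.einsum("my,pcy->pcm", sub.v, b)
            g = (am * bm) * sub.cat_weights[None, :, None]
            factor = np.outer(sub.cat_rates * sub.model.scale, sub.lam)
            pieces.append((g.reshape(g.shape[0], -1), factor,
                           la + lb, sub.weights))

        def f(t: float) -> float:
            total = 0.0
            for g2, factor, logsc, w in pieces:
                site = g2 @ np.exp(factor * t).ravel()
                site = np.maximum(site, 1e-300)
                total += float(w @ (np.log(site) + logsc))
            return total

        return f

    def optimize_edge(self, u: int, v: int) -> float:
        """Optimise one branch length from cached messages; returns new t."""
        f = self._edge_loglik_fn(u, v)
        res = minimize_scalar(
            lambda t: -f(t),
            bounds=(_BL_MIN, _BL_MAX),
            method="bounded",
            options={"xatol": 1e-7, "maxiter": 40},
        )
        t_new = float(res.x)
        cur = self.tree.length(u, v)
        if f(t_new) >= f(cur):
            self.tree.set_length(u, v, t_new)
            return t_new
        return cur

    def optimize_branch_lengths(self, rounds: int = 3) -> float:
        """Cycle per-edge optimisation with message refresh between rounds."""
        best = self.loglik()
        for _ in range(rounds):
            old_lengths = dict(self.tree.lengths)
            for (u, v) in self.tree.edges():
                self.optimize_edge(u, v)
            lnl = self.loglik()  # refreshes messages
            if lnl < best - 1e-9:
                # simultaneous updates overshot; fall back to halfway steps
                for key, old in old_lengths.items():
                    self.tree.lengths[key] = 0.5 * (old + self.tree.lengths[key])
                lnl = self.loglik()
                if lnl < best - 1e-9:
                    self.tree.lengths.update(old_lengths)
                    lnl = self.loglik()
            if abs(lnl - best) < 1e-6:
                best = max(best, lnl)
                break
            best = max(best, lnl)
        return best

    # -- NNI scoring ----------------------------------------------------

    def score_nni_candidates(self):
        """Score both swaps of every internal edge from cached messages.

        Yields ``(u, v, b, c, lnl, t_opt)`` where swapping the subtrees at
        *b* (neighbour of *u*) and *c* (neighbour of *v*) and setting the
        focal edge length to ``t_opt`` gives joint log-likelihood ``lnl``
        with every other branch length and all model parameters held.
        """
        if self._messages is None:
            self.compute_messages()
        tree = self.tree
        for (u, v) in tree.internal_edges():
            nb_u = [x for x in tree.adj[u] if x != v]
            nb_v = [x for x in tree.adj[v] if x != u]
            a, b = nb_u
            c, d = nb_v
            for swap_b, swap_c in ((b, c), (b, d)):
                keep_u = [x for x in nb_u if x != swap_b] + [swap_c]
                keep_v = [x for x in nb_v if x != swap_c] + [swap_b]
                pieces = []
                for k, sub in enumerate(self.subsets):
                    msgs = self._messages[k]

                    def gather(node, members):
                        partial, logsc = None, 0.0
                        for x in members:
                            key = (x, u) if (x, u) in msgs else (x, v)
                            m, ls = msgs[key]
                            partial = m if partial is None else partial * m
                            logsc += ls
                        return partial, logsc

                    pa, la = gather(u, keep_u)
                    pb, lb = gather(v, keep_v)
                    am = np.einsum("pcx,x,xm->pcm", pa, sub.pi, sub.u)
                    bm = np.einsum("my,pcy->pcm", sub.v, pb)
                    g = (am * bm) * sub.cat_weights[None, :, None]
                    factor = np.outer(sub.cat_rates * sub.model.scale, sub.lam)
                    pieces.append((g.reshape(g.shape[0], -1), factor,
                                   la + lb, sub.weights))

                def f(t: float) -> float:
                    total = 0.0
                    for g2, factor, logsc, w in pieces:
                        site = g2 @ np.exp(factor * t).ravel()
                        site = np.maximum(site, 1e-300)
                        total += float(w @ (np.log(site) + logsc))
                    return total

                res = minimize_scalar(
                    lambda t: -f(t),
                    bounds=(_BL_MIN, _BL_MAX),
                    method="bounded",
                    options={"xatol": 1e-5, "maxiter": 30},
                )
                yield u, v, swap_b, swap_c, float(f(float(res.x))), float(res.x)

    # -- model fitting ---------------------------------------------------

    def subset_loglik(self, sub_idx: int) -> float:
        """Rooted single-subset likelihood (no message cache)."""
        tree, sub = self.tree, self.subsets[sub_idx]
        root = max(tree.adj)
        msgs: dict = {}
        inward, _ = self._ordered_edges()
        for frm, to in inward:
            self._pass_message(sub_idx, frm, to, msgs)
        partial, logsc = None, 0.0
        for nb in tree.adj[root]:
            m, ls = msgs[(nb, root)]
            partial = m if partial is None else partial * m
            logsc = logsc + ls
        if root < tree.n_leaves:  # two-leaf tree: root is a tip
            partial = partial * sub.tips[root][:, None, :]
        site = np.einsum("pcx,x,c->p", partial, sub.pi, sub.cat_weights)
        site = np.maximum(site, 1e-300)
        return float(sub.weights @ (np.log(site) + logsc))

    def fit_models(
        self,
        fit_scale: bool = True,
        fix_first_scale: bool = False,
        fit_freqs: bool = True,
        maxfun: int = 150,
        tol: float = 1e-8,
    ) -> float:
        """Fit each subset's GTR+G parameters (and rate scale) by L-BFGS-B.

        Branch lengths and topology stay fixed.  With ``fit_freqs=False``
        base frequencies are held at their current (typically empirical)
        values, the common fast setting for tree searches.  Returns the
        joint lnL.
        """
        from scipy.optimize import minimize

        total = 0.0
        for k, sub in enumerate(self.subsets):
            lock_scale = not fit_scale or (fix_first_scale and k == 0)
            fit_alpha = sub.n_variable > 0
            base = sub.model

            def unpack(theta):
                i = 0
                exch = tuple(np.exp(theta[i : i + 5])); i += 5
                if fit_freqs:
                    raw = np.concatenate([[0.0], theta[i : i + 3]]); i += 3
                    freqs = tuple(np.exp(raw) / np.exp(raw).sum())
                else:
                    freqs = base.freqs
                alpha = float(np.exp(theta[i])) if fit_alpha else base.alpha
                if fit_alpha:
                    i += 1
                scale = base.scale if lock_scale else float(np.exp(theta[i]))
                return replace(
                    base,
                    exchangeabilities=exch,
                    freqs=freqs,
                    alpha=alpha,
                    scale=scale,
                )

            f0 = np.asarray(base.freqs)
            theta0 = list(np.log(base.exchangeabilities or (1.0,) * 5))
            bounds = [(-9.0, 9.0)] * 5
            if fit_freqs:
                theta0 += list(np.log(f0[1:] / f0[0]))
                bounds += [(-9.0, 9.0)] * 3
            if fit_alpha:
                theta0.append(np.log(base.alpha if base.alpha else 1.0))
                bounds.append((np.log(0.02), np.log(100.0)))
            if not lock_scale:
                theta0.append(np.log(max(base.scale, 1e-6)))
                bounds.append((-7.0, 7.0))

            def objective(theta):
                sub.set_model(unpack(np.asarray(theta)))
                return -self.subset_loglik(k)

            res = minimize(
                objective,
                np.asarray(theta0),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxfun": maxfun, "ftol": tol},
            )
            sub.set_model(unpack(res.x))
            total += -float(res.fun)
        self._messages = None
        return total
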