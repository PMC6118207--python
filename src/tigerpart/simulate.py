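"""Benchmark sequence simulation on fixed 17-leaf trees.

Datasets are simulated on two reference topologies — a fully pectinate
(asymmetrical) ladder and a fully balanced (symmetrical) tree — each with
16 ingroup leaves ``A..P`` plus an ``outgroup``, terminal branches of 0.1
expected substitutions/site, and a configurable internal branch length.
An alignment is the concatenation of four 1,000-site blocks, each evolved
under its own substitution model (F81 or GTR, optionally with a proportion
of invariant sites and continuous gamma rate variation with mean 1).

Fourteen standard parameter combinations ``S1..S14`` are built in; they
differ in base composition, exchangeabilities, P-inv, gamma shape and
internal branch length, spanning easy (long internals, mild rate
variation) to hard (0.001 internals, extreme rate variation) regimes.

All randomness flows through :class:`numpy.random.SeedSequence`, with
per-block child streams spawned deterministically from the caller's seed,
so any block/replicate is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .alignment import AlignmentMatrix

__all__ = [
    "STATE_ORDER",
    "BlockModel",
    "SimulationCondition",
    "SimulationResult",
    "CONDITION_IDS",
    "get_condition",
    "build_tree",
    "gtr_rate_matrix",
    "simulate_block",
    "simulate_condition",
    "inject_missing",
]

#: Simulator state order; base frequencies and exchangeabilities follow it.
STATE_ORDER = "TCAG"

#: Exchangeability order: C-T, A-T, G-T, A-C, G-C (G-A fixed to 1).
_EXCH_PAIRS = ((1, 0), (2, 0), (3, 0), (2, 1), (3, 1))

ASYMMETRIC_NEWICK = (
    "(outgroup,P,(O,(N,(M,(L,(K,(J,(I,(H,(G,(F,(E,(D,(C,(B,A)))))))))))))));"
)
SYMMETRIC_NEWICK = (
    "(outgroup,(((A,B),(C,D)),((E,F),(G,H))),(((I,J),(K,L)),((M,N),(O,P))));"
)


@dataclass(frozen=True)
class BlockModel:
    """Substitution model for one simulated block.

    ``base_freqs`` are stationary frequencies in T, C, A, G order.
    ``exchangeabilities`` are the five free GTR terms in C-T, A-T, G-T,
    A-C, G-C order with G-A fixed to 1; ``None`` selects F81 (all equal).
    ``alpha`` is the gamma shape for among-site rate variation (mean 1,
    continuous); ``None`` disables it.  ``p_inv`` is the proportion of
    sites forced invariant.
    """

    base_freqs: tuple[float, float, float, float]
    exchangeabilities: tuple[float, float, float, float, float] | None = None
    p_inv: float = 0.0
    alpha: float | None = None
    internal_branch_length: float = 0.01
    block_length: int = 1000

    def __post_init__(self) -> None:
        f = np.asarray(self.base_freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError(
                f"base frequencies must be 4 positive values summing to 1, "
                f"got {self.base_freqs}"
            )
        if self.exchangeabilities is not None:
            r = np.asarray(self.exchangeabilities, dtype=float)
            if r.shape != (5,) or np.any(r <= 0):
                raise ValueError("exchangeabilities must be 5 positive values")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError(f"p_inv must lie in [0, 1), got {self.p_inv}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError(f"gamma shape must be positive, got {self.alpha}")
        if self.internal_branch_length < 0:
            raise ValueError("branch lengths must be non-negative")
        if self.block_length < 1:
            raise ValueError("block length must be >= 1")


@dataclass(frozen=True)
class SimulationCondition:
    """One benchmark condition: a tree shape plus four block models."""

    id: str
    tree_shape: str
    blocks: tuple[BlockModel, BlockModel, BlockModel, BlockModel]
    terminal_branch_length: float = 0.1

    def __post_init__(self) -> None:
        if self.tree_shape not in ("asymmetric", "symmetric"):
            raise ValueError(f"unknown tree shape {self.tree_shape!r}")
        if len(self.blocks) != 4:
            raise ValueError("a condition has exactly four blocks")


@dataclass(frozen=True)
class SimulationResult:
    """A simulated alignment plus its generating tree and block layout."""

    alignment: AlignmentMatrix
    tree: dendropy.Tree = field(repr=False)
    block_boundaries: tuple[tuple[int, int], ...]
    condition_id: str


# -- Table of benchmark conditions ------------------------------------

_FREQS = (
    (0.40, 0.10, 0.40, 0.10),
    (0.30, 0.20, 0.30, 0.20),
    (0.20, 0.30, 0.20, 0.30),
    (0.10, 0.40, 0.10, 0.40),
)
_GTR_RATES = (
    (0.01, 0.01, 0.001, 0.01, 0.001),
    (1.0, 0.1, 0.1, 0.2, 0.1),
    (0.7, 0.4, 0.2, 0.15, 0.15),
    (0.8, 0.5, 0.5, 0.2, 0.2),
)
_PINV_EVEN = (0.80, 0.60, 0.40, 0.20)
_ALPHA_DEFAULT = (0.5, 0.5, 0.5, 0.5)

# per condition: (uses_gtr, alphas, internal branch length per block)
_CONDITIONS: dict[str, tuple[bool, tuple, tuple]] = {}
for _sid, _gtr, _alphas, _internal in [
    ("S1", False, _ALPHA_DEFAULT, (0.01,) * 4),
    ("S2", False, _ALPHA_DEFAULT, (0.01,) * 4),
    ("S3", False, _ALPHA_DEFAULT, (0.05,) * 4),
    ("S4", False, _ALPHA_DEFAULT, (0.05,) * 4),
    ("S5", False, _ALPHA_DEFAULT, (0.001,) * 4),
    ("S6", False, _ALPHA_DEFAULT, (0.001,) * 4),
    ("S7", False, _ALPHA_DEFAULT, (0.005,) * 4),
    ("S8", False, _ALPHA_DEFAULT, (0.005,) * 4),
    ("S9", True, _ALPHA_DEFAULT, (0.005,) * 4),
    ("S10", True, _ALPHA_DEFAULT, (0.005,) * 4),
    ("S11", True, (0.7, 0.5, 0.3, 0.1), (0.005,) * 4),
    ("S12", True, (0.1, 0.3, 0.5, 0.7), (0.005,) * 4),
    ("S13", True, _ALPHA_DEFAULT, (0.005, 0.01, 0.015, 0.02)),
    ("S14", True, _ALPHA_DEFAULT, (0.005, 0.01, 0.015, 0.02)),
]:
    _CONDITIONS[_sid] = (_gtr, _alphas, _internal)

CONDITION_IDS = tuple(_CONDITIONS)


def get_condition(cond_id: str, tree_shape: str) -> SimulationCondition:
    """Look up a built-in condition ``S1..S14`` for a tree shape."""
    if cond_id not in _CONDITIONS:
        raise KeyError(f"unknown condition {cond_id!r}; expected S1..S14")
    uses_gtr, alphas, internals = _CONDITIONS[cond_id]
    even = int(cond_id[1:]) % 2 == 0
    blocks = tuple(
        BlockModel(
            base_freqs=_FREQS[b],
            exchangeabilities=_GTR_RATES[b] if uses_gtr else None,
            p_inv=_PINV_EVEN[b] if even else 0.0,
            alpha=alphas[b],
            internal_branch_length=internals[b],
        )
        for b in range(4)
    )
    return SimulationCondition(id=cond_id, tree_shape=tree_shape, blocks=blocks)


# -- trees -------------------------------------------------------------


def build_tree(
    shape: str, internal_bl: float, terminal_bl: float = 0.1
) -> dendropy.Tree:
    """Build one of the two reference 17-leaf topologies with set lengths."""
    if shape == "asymmetric":
        newick = ASYMMETRIC_NEWICK
    elif shape == "symmetric":
        newick = SYMMETRIC_NEWICK
    else:
        raise ValueError(f"unknown tree shape {shape!r}")
    if internal_bl < 0 or terminal_bl < 0:
        raise ValueError("branch lengths must be non-negative")
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        edge.length = terminal_bl if edge.head_node.is_leaf() else internal_bl
    return tree


# -- substitution machinery -------------------------------------------


def gtr_rate_matrix(
    base_freqs: Sequence[float],
    exchangeabilities: Sequence[float] | None = None,
) -> np.ndarray:
    """Normalised GTR rate matrix (states in T, C, A, G order).

    The matrix is scaled so the expected substitution rate at stationarity
    is 1, i.e. branch lengths are in expected substitutions per site.
    """
    pi = np.asarray(base_freqs, dtype=float)
    rel = np.ones((4, 4))
    if exchangeabilities is not None:
        for (i, j), r in zip(_EXCH_PAIRS, exchangeabilities):
            rel[i, j] = rel[j, i] = r
        # G-A (indices 3, 2) stays at the reference value 1
    q = rel * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    q /= -(pi @ np.diag(q))
    return q


def _eigen_reversible(q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible rate matrix via symmetrisation."""
    sqrt_pi = np.sqrt(pi)
    sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
    lam, w = np.linalg.eigh((sym + sym.T) / 2.0)
    u = w / sqrt_pi[:, None]
    v = w.T * sqrt_pi[None, :]
    return lam, u, v


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _tree_traversal(tree: dendropy.Tree):
    """Preorder (node, parent_index, edge_length) triples and leaf labels."""
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    out = []
    for n in nodes:
        parent = index[id(n.parent_node)] if n.parent_node is not None else None
        length = n.edge.length if parent is not None else 0.0
        out.append((n, parent, float(length or 0.0)))
    return out


def simulate_block(
    tree: dendropy.Tree,
    model: BlockModel,
    n_sites: int | None = None,
    seed=None,
) -> AlignmentMatrix:
    """Evolve one block of sites down *tree* under *model*.

    Root states are drawn from the stationary frequencies.  Each site is
    invariant with probability ``p_inv``; otherwise it receives a
    gamma-distributed rate multiplier (mean 1) that scales every branch.
    """
    if n_sites is None:
        n_sites = model.block_length
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _as_generator(seed)
    pi = np.asarray(model.base_freqs)
    q = gtr_rate_matrix(model.base_freqs, model.exchangeabilities)
    lam, u, v = _eigen_reversible(q, pi)

    invariant = rng.random(n_sites) < model.p_inv
    if model.alpha is not None:
        site_rate = rng.gamma(model.alpha, 1.0 / model.alpha, size=n_sites)
    else:
        site_rate = np.ones(n_sites)
    site_rate[invariant] = 0.0

    traversal = _tree_traversal(tree)
    states = np.empty((len(traversal), n_sites), dtype=np.int8)
    states[0] = rng.choice(4, size=n_sites, p=pi)
    uniforms = rng.random((len(traversal) - 1, n_sites))
    for k, (node, parent, length) in enumerate(traversal[1:], start=1):
        t_eff = site_rate * length
        decay = np.exp(np.outer(t_eff, lam))  # (sites, 4)
        rows = np.einsum(
            "xm,sm,my->sxy", u, decay, v
        )[np.arange(n_sites), states[parent]]
        rows = np.clip(rows, 0.0, None)
        rows /= rows.sum(axis=1, keepdims=True)
        cum = np.cumsum(rows, axis=1)
        states[k] = (uniforms[k - 1][:, None] > cum).sum(axis=1)

    chars = np.array(list(STATE_ORDER), dtype="<U1")
    taxa, rows_out = [], []
    for (node, _parent, _length), row in zip(traversal, states):
        if node.is_leaf():
            taxa.append(node.taxon.label)
            rows_out.append(chars[row])
    return AlignmentMatrix(tuple(taxa), np.array(rows_out))


def simulate_condition(
    cond: SimulationCondition, seed=None
) -> SimulationResult:
    """Simulate the four concatenated blocks of one benchmark condition."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(cond.blocks))
    parts: list[AlignmentMatrix] = []
    boundaries: list[tuple[int, int]] = []
    offset = 0
    for model, child in zip(cond.blocks, children):
        tree = build_tree(
            cond.tree_shape,
            internal_bl=model.internal_branch_length,
            terminal_bl=cond.terminal_branch_length,
        )
        block = simulate_block(
            tree, model, model.block_length, np.random.default_rng(child)
        )
        parts.append(block)
        boundaries.append((offset + 1, offset + model.block_length))
        offset += model.block_length
    taxa = parts[0].taxa
    for p in parts[1:]:
        if p.taxa != taxa:
            raise RuntimeError("block simulations disagree on taxon order")
    matrix = np.concatenate([p.matrix for p in parts], axis=1)
    true_tree = build_tree(
        cond.tree_shape,
        internal_bl=cond.blocks[0].internal_branch_length,
        terminal_bl=cond.terminal_branch_length,
    )
    return SimulationResult(
        alignment=AlignmentMatrix(taxa, matrix),
        tree=true_tree,
        block_boundaries=tuple(boundaries),
        condition_id=cond.id,
    )


def inject_missing(
    aln: AlignmentMatrix,
    block_boundaries: Sequence[tuple[int, int]],
    n_taxa: int = 3,
    seed=None,
    outgroup: str = "outgroup",
    independent_blocks: bool = True,
) -> AlignmentMatrix:
    """Blank one block (to ``?``) for each of ``n_taxa`` random taxa.

    The outgroup is never selected.  By default each chosen taxon loses an
    independently chosen block; with ``independent_blocks=False`` a single
    block is drawn and removed for all chosen taxa.
    """
    candidates = [t for t in aln.taxa if t != outgroup]
    if n_taxa > len(candidates):
        raise ValueError(
            f"cannot pick {n_taxa} taxa from {len(candidates)} non-outgroup taxa"
        )
    if n_taxa == 0:
        return aln
    rng = _as_generator(seed)
    chosen = rng.choice(len(candidates), size=n_taxa, replace=False)
    matrix = np.array(aln.matrix)  # writable copy
    shared_block = int(rng.integers(len(block_boundaries)))
    for c in chosen:
        b = (
            int(rng.integers(len(block_boundaries)))
            if independent_blocks
            else shared_block
        )
        start, end = block_boundaries[b]
        row = aln.taxa.index(candidates[int(c)])
        matrix[row, start - 1 : end] = "?"
    return AlignmentMatrix(aln.taxa, matrix)
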