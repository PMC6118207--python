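"""Robinson–Foulds distances and replicate-level benchmark summaries.

The raw RF distance is the size of the symmetric difference between the
two trees' sets of non-trivial bipartitions, treating both trees as
unrooted; for binary trees on ``n`` taxa it ranges from 0 to ``2(n-3)``,
which is also the normalisation denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare as _dtc

__all__ = [
    "LeafSetMismatchError",
    "RFResult",
    "robinson_foulds",
    "summarize_replicates",
]


class LeafSetMismatchError(ValueError):
    """The two trees are not on the same leaf label set."""


@dataclass(frozen=True)
class RFResult:
    """Raw and normalised Robinson–Foulds distance between two trees."""

    raw: int
    normalized: float
    n_taxa: int


def _as_newick(tree) -> str:
    if isinstance(tree, str):
        return tree
    if isinstance(tree, dendropy.Tree):
        return tree.as_string(schema="newick")
    raise TypeError(f"expected newick string or dendropy.Tree, got {type(tree)}")


def robinson_foulds(t1, t2) -> RFResult:
    """Symmetric-difference RF distance between two unrooted trees.

    Accepts newick strings or :class:`dendropy.Tree` objects.  Polytomies
    are allowed: only the splits actually present in each tree are
    compared, while the normalisation denominator stays ``2(n-3)``.
    """
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=_as_newick(t1), schema="newick",
                          taxon_namespace=ns)
    try:
        b = dendropy.Tree.get(data=_as_newick(t2), schema="newick",
                              taxon_namespace=ns)
    except dendropy.utility.error.ImmutableTaxonNamespaceError as err:
        raise LeafSetMismatchError(str(err)) from None
    leaves_a = {lf.taxon.label for lf in a.leaf_node_iter()}
    leaves_b = {lf.taxon.label for lf in b.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise LeafSetMismatchError(
            f"leaf sets differ: {sorted(leaves_a ^ leaves_b)}"
        )
    for t in (a, b):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    raw = int(_dtc.symmetric_difference(a, b))
    n = len(leaves_a)
    denom = 2 * (n - 3)
    return RFResult(raw=raw, normalized=raw / denom if denom else 0.0, n_taxa=n)


def summarize_replicates(rfds: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation of replicate values."""
    arr = np.asarray(list(rfds), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty replicate list")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
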