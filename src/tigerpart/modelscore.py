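"""BIC scoring of partition schemes on a fixed tree.

Alternative partitionings of the same alignment are compared by fitting,
for every subset of a scheme, a GTR model with four discrete gamma rate
categories on a shared, fixed topology, and combining the fits into
``BIC = -2 lnL + K ln N`` with ``N`` the total number of sites.  Branch
lengths are linked across subsets: the supplied tree's lengths are shared
and each subset beyond the first gets a free multiplicative rate scale.
Lower BIC means the scheme explains the data better per parameter spent —
the standard yardstick for choosing between, say, an unpartitioned model,
a by-gene split, and a rate-based scheme.

Parameter counting per subset: 5 free exchangeabilities + 3 free base
frequencies + 1 gamma shape; plus one rate scale per subset after the
first; plus the ``2n - 3`` shared branch lengths counted once.
"""

from __future__ import annotations

from dataclasses import dataclass
import dendropy
import numpy as np

from .alignment import AlignmentMatrix
from .likelihood import GTRModel, LightTree, PartitionedLikelihood
from .ratepartitions import PartitionScheme

__all__ = [
    "SubsetFit",
    "SchemeScore",
    "pruning_loglik",
    "fit_subset",
    "score_scheme",
    "PARAMS_PER_SUBSET",
]

#: 5 exchangeabilities + 3 frequencies + 1 gamma shape.
PARAMS_PER_SUBSET = 9


@dataclass(frozen=True)
class SubsetFit:
    """Fitted model for one subset of a partition scheme."""

    name: str
    loglik: float
    n_params: int
    model: GTRModel
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SchemeScore:
    """Joint score of a scheme: total lnL, parameter count, and BIC."""

    loglik: float
    n_params: int
    n_sites: int
    bic: float
    subset_fits: tuple[SubsetFit, ...]

    def __post_init__(self) -> None:
        expected = -2.0 * self.loglik + self.n_params * np.log(self.n_sites)
        if abs(expected - self.bic) > 1e-6:
            raise ValueError("BIC inconsistent with lnL, K and N")


def _as_light_tree(tree, labels) -> LightTree:
    if isinstance(tree, LightTree):
        return tree
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    return LightTree.from_dendropy(tree, labels=list(labels))


def pruning_loglik(
    aln_subset: AlignmentMatrix,
    tree,
    model: GTRModel,
    ncat: int | None = None,
) -> float:
    """Exact log-likelihood of an alignment under GTR(+G)(+I).

    *tree* may be a newick string, a dendropy tree or a
    :class:`~tigerpart.likelihood.LightTree`; its leaf labels must match
    the alignment taxa.  Missing or ambiguous states integrate over all
    four bases.
    """
    if ncat is not None and model.alpha is not None:
        model = GTRModel(
            freqs=model.freqs,
            exchangeabilities=model.exchangeabilities,
            alpha=model.alpha,
            p_inv=model.p_inv,
            scale=model.scale,
            ncat=ncat,
        )
    pl = PartitionedLikelihood(aln_subset, scheme=None, models=[model])
    pl.set_tree(_as_light_tree(tree, aln_subset.taxa))
    return pl.subset_loglik(0)


def fit_subset(
    aln_subset: AlignmentMatrix,
    tree,
    model: str = "GTR+G",
    fit_scale: bool = True,
    tol: float = 1e-6,
    maxfun: int = 400,
) -> SubsetFit:
    """Maximise the subset likelihood over model parameters.

    Optimises exchangeabilities, base frequencies, gamma shape and (by
    default) a branch-length scale on the fixed topology.  A subset with
    no variable site leaves the gamma shape unidentifiable; the fit is
    then flagged ``"alpha_unidentifiable"`` and the shape is not fitted.
    """
    if model != "GTR+G":
        raise ValueError(f"unsupported model {model!r}")
    pl = PartitionedLikelihood(aln_subset, scheme=None)
    pl.set_tree(_as_light_tree(tree, aln_subset.taxa))
    lnl = pl.fit_models(fit_scale=fit_scale, maxfun=maxfun, tol=tol)
    sub = pl.subsets[0]
    flags = () if sub.n_variable > 0 else ("alpha_unidentifiable",)
    n_params = PARAMS_PER_SUBSET + (1 if fit_scale else 0)
    return SubsetFit(
        name=sub.name,
        loglik=lnl,
        n_params=n_params,
        model=sub.model,
        flags=flags,
    )


def score_scheme(
    aln: AlignmentMatrix,
    scheme: PartitionScheme,
    tree,
    tol: float = 1e-6,
    maxfun: int = 400,
) -> SchemeScore:
    """Fit every subset of *scheme* on the fixed *tree* and combine BIC.

    The first subset's rate scale is fixed to 1 (the tree's branch
    lengths carry the overall rate); each further subset contributes one
    free scale.  Branch lengths are counted once, as ``2n - 3``.
    """
    if scheme.total_sites != aln.n_sites:
        raise ValueError(
            f"scheme covers {scheme.total_sites} sites but alignment has "
            f"{aln.n_sites}"
        )
    pl = PartitionedLikelihood(aln, scheme=scheme)
    pl.set_tree(_as_light_tree(tree, aln.taxa))
    pl.fit_models(fit_scale=True, fix_first_scale=True, maxfun=maxfun, tol=tol)
    fits = []
    total_lnl = 0.0
    for k, sub in enumerate(pl.subsets):
        lnl = pl.subset_loglik(k)
        flags = () if sub.n_variable > 0 else ("alpha_unidentifiable",)
        n_params = PARAMS_PER_SUBSET + (1 if k > 0 else 0)
        fits.append(
            SubsetFit(name=sub.name, loglik=lnl, n_params=n_params,
                      model=sub.model, flags=flags)
        )
        total_lnl += lnl
    n_taxa = aln.n_taxa
    k_total = sum(f.n_params for f in fits) + (2 * n_taxa - 3)
    n_sites = aln.n_sites
    bic = -2.0 * total_lnl + k_total * np.log(n_sites)
    return SchemeScore(
        loglik=total_lnl,
        n_params=k_total,
        n_sites=n_sites,
        bic=bic,
        subset_fits=tuple(fits),
    )
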