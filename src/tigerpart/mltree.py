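"""Tree inference backends for the benchmark pipeline.

The benchmark needs, per replicate, a maximum-likelihood tree inferred
under a given partition scheme.  Several backends expose the same
``infer(alignment, scheme) -> newick`` contract:

``builtin``
    The package's own partitioned ML search: a neighbour-joining start
    tree, per-subset GTR+G model fits, then hill-climbing over
    nearest-neighbour interchanges with branch-length optimisation, all
    on the linked-branch-length partitioned likelihood.  Deterministic.
``nj``
    Distance (JC-corrected) neighbour joining only; quick smoke tests.
``fasttree``
    The external FastTree program (GTR+gamma).  FastTree does not accept
    partition files, so the scheme is ignored; useful as an independent
    cross-check, not for comparing partitioning strategies.
``raxml`` / ``iqtree``
    Adapters that drive the respective external programs with the
    scheme written in their partition dialect; they raise
    :class:`BackendNotAvailableError` when the binary is not installed.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import skbio

from .alignment import AlignmentMatrix, write_alignment
from .likelihood import LightTree, PartitionedLikelihood
from .ratepartitions import PartitionScheme, write_scheme

__all__ = [
    "BackendNotAvailableError",
    "jc_distance_matrix",
    "nj_start_tree",
    "BuiltinMLBackend",
    "NJBackend",
    "FastTreeBackend",
    "RaxmlBackend",
    "IqtreeBackend",
    "get_backend",
]


class BackendNotAvailableError(RuntimeError):
    """The requested external inference program is not on PATH."""


def jc_distance_matrix(aln: AlignmentMatrix) -> np.ndarray:
    """Pairwise JC69-corrected distances with pairwise deletion of missing.

    Saturated or incomparable pairs are capped at a large finite distance
    so neighbour joining stays defined.
    """
    codes = aln.state_codes()
    n = aln.n_taxa
    valid = codes < 4
    dist = np.zeros((n, n))
    cap = 5.0
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (codes[i] != codes[i + 1 :]) & both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(denom > 0, diff.sum(axis=1) / np.maximum(denom, 1), 1.0)
        arg = 1.0 - 4.0 * p / 3.0
        d = np.where(arg > 1e-9, -0.75 * np.log(np.maximum(arg, 1e-9)), cap)
        d = np.minimum(d, cap)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    return dist


def nj_start_tree(aln: AlignmentMatrix) -> LightTree:
    """JC-distance neighbour-joining tree with lengths clamped positive."""
    dm = skbio.DistanceMatrix(jc_distance_matrix(aln), ids=list(aln.taxa))
    tree = skbio.tree.nj(dm)
    import dendropy

    dtree = dendropy.Tree.get(data=str(tree), schema="newick")
    lt = LightTree.from_dendropy(dtree, labels=list(aln.taxa))
    for key, length in lt.lengths.items():
        lt.lengths[key] = max(length, 1e-6)
    return lt


class BuiltinMLBackend:
    """Partitioned ML inference: NJ start + NNI hill-climb with restarts.

    ``max_sweeps`` caps accepted rearrangements; ``refit`` re-estimates
    the substitution models once on the improved topology and continues
    searching, which matters for strongly non-stationary subsets.  When
    the landscape is rugged (the first climb accepted rearrangements),
    ``restarts`` ratchet cycles perturb the best tree with a few random
    interchanges and climb again, keeping the best tree by likelihood;
    the perturbations are deterministically seeded so inference stays
    reproducible.
    """

    name = "builtin"

    def __init__(self, ncat: int = 4, max_sweeps: int = 60,
                 refit: bool = True, fit_maxfun: int = 80,
                 restarts: int = 2, perturb_moves: int = 4,
                 perturb_seed: int = 1):
        self.ncat = ncat
        self.max_sweeps = max_sweeps
        self.refit = refit
        self.fit_maxfun = fit_maxfun
        self.restarts = restarts
        self.perturb_moves = perturb_moves
        self.perturb_seed = perturb_seed

    @staticmethod
    def _perturb(tree: LightTree, rng: np.random.Generator,
                 n_moves: int) -> None:
        for _ in range(n_moves):
            edges = tree.internal_edges()
            u, v = edges[int(rng.integers(len(edges)))]
            nb_u = [x for x in tree.adj[u] if x != v]
            nb_v = [x for x in tree.adj[v] if x != u]
            b = nb_u[int(rng.integers(2))]
            c = nb_v[int(rng.integers(2))]
            tree.apply_nni(u, v, b, c)

    def _search(self, pl: PartitionedLikelihood) -> tuple[float, int]:
        best = pl.optimize_branch_lengths(rounds=3)
        accepted = 0
        for _ in range(self.max_sweeps):
            cands = list(pl.score_nni_candidates())
            if not cands:
                break
            u, v, b, c, lnl, t_opt = max(cands, key=lambda x: x[4])
            if lnl <= best + 1e-4:
                break
            pl.tree.apply_nni(u, v, b, c)
            pl.tree.set_length(u, v, t_opt)
            best = pl.optimize_branch_lengths(rounds=2)
            accepted += 1
        return best, accepted

    def infer(self, aln: AlignmentMatrix,
              scheme: PartitionScheme | None = None) -> str:
        pl = PartitionedLikelihood(aln, scheme=scheme, ncat=self.ncat)
        pl.set_tree(nj_start_tree(aln))
        # empirical frequencies are kept fixed during the search, the
        # usual fast setting for GTR tree searches
        pl.fit_models(fit_scale=True, fix_first_scale=True, fit_freqs=False,
                      maxfun=self.fit_maxfun)
        best, accepted = self._search(pl)
        if self.refit and accepted:
            # the topology moved: model estimates from the start tree may
            # have steered it, so refit and search again
            pl.fit_models(fit_scale=True, fix_first_scale=True,
                          fit_freqs=False, maxfun=self.fit_maxfun)
            best, _ = self._search(pl)
        best_tree = pl.tree.copy()
        if accepted:
            # rugged landscape: ratchet from perturbed copies of the best
            rng = np.random.default_rng(self.perturb_seed)
            for _ in range(self.restarts):
                candidate = best_tree.copy()
                self._perturb(candidate, rng, self.perturb_moves)
                pl.set_tree(candidate)
                lnl, _ = self._search(pl)
                if lnl > best + 1e-6:
                    best = lnl
                    best_tree = pl.tree.copy()
        pl.set_tree(best_tree)
        return pl.tree.to_newick()


class NJBackend:
    """Distance neighbour joining; no likelihood, smoke tests only."""

    name = "nj"

    def infer(self, aln: AlignmentMatrix,
              scheme: PartitionScheme | None = None) -> str:
        return nj_start_tree(aln).to_newick()


class _ExternalBackend:
    binary: str = ""

    def _require(self) -> str:
        path = shutil.which(self.binary)
        if path is None:
            raise BackendNotAvailableError(
                f"{self.binary!r} not found on PATH; install it or choose "
                f"another backend"
            )
        return path


class FastTreeBackend(_ExternalBackend):
    """External FastTree (GTR+gamma, unpartitioned).

    FastTree has no partitioned-model support, so the scheme argument is
    accepted for interface compatibility and ignored.
    """

    name = "fasttree"
    binary = "fasttree"

    def infer(self, aln: AlignmentMatrix,
              scheme: PartitionScheme | None = None) -> str:
        exe = self._require()
        with tempfile.TemporaryDirectory() as tmp:
            aln_path = Path(tmp) / "aln.fasta"
            write_alignment(aln, aln_path, format="fasta")
            proc = subprocess.run(
                [exe, "-nt", "-gtr", "-gamma", "-quiet", "-nopr",
                 str(aln_path)],
                capture_output=True,
                text=True,
                check=False,
            )
        if proc.returncode != 0 or not proc.stdout.strip():
            raise RuntimeError(f"FastTree failed: {proc.stderr[:500]}")
        return proc.stdout.strip()


class RaxmlBackend(_ExternalBackend):
    """Adapter for RAxML-style invocation (partitioned GTR+GAMMA search).

    Extra command-line options pass through ``extra_args``.
    """

    name = "raxml"
    binary = "raxmlHPC"

    def __init__(self, extra_args: Sequence[str] = (), seed: int = 12345):
        self.extra_args = list(extra_args)
        self.seed = seed

    def infer(self, aln: AlignmentMatrix,
              scheme: PartitionScheme | None = None) -> str:
        exe = self._require()
        with tempfile.TemporaryDirectory() as tmp:
            tmpdir = Path(tmp)
            aln_path = tmpdir / "aln.phy"
            write_alignment(aln, aln_path, format="phylip")
            cmd = [exe, "-s", str(aln_path), "-n", "run", "-m", "GTRGAMMA",
                   "-p", str(self.seed), "-w", str(tmpdir)]
            if scheme is not None:
                part = tmpdir / "part.txt"
                write_scheme(scheme, "raxml", part)
                cmd += ["-q", str(part)]
            cmd += self.extra_args
            proc = subprocess.run(cmd, capture_output=True, text=True,
                                  check=False)
            best = tmpdir / "RAxML_bestTree.run"
            if proc.returncode != 0 or not best.exists():
                raise RuntimeError(f"RAxML failed: {proc.stderr[:500]}")
            return best.read_text().strip()


class IqtreeBackend(_ExternalBackend):
    """Adapter for IQ-TREE-style invocation with an edge-linked scheme."""

    name = "iqtree"
    binary = "iqtree"

    def __init__(self, extra_args: Sequence[str] = (), seed: int = 12345):
        self.extra_args = list(extra_args)
        self.seed = seed

    def infer(self, aln: AlignmentMatrix,
              scheme: PartitionScheme | None = None) -> str:
        exe = self._require()
        with tempfile.TemporaryDirectory() as tmp:
            tmpdir = Path(tmp)
            aln_path = tmpdir / "aln.phy"
            write_alignment(aln, aln_path, format="phylip")
            cmd = [exe, "-s", str(aln_path), "-m", "GTR+G",
                   "-seed", str(self.seed), "-quiet"]
            if scheme is not None:
                part = tmpdir / "part.nex"
                write_scheme(scheme, "nexus", part)
                cmd += ["-p", str(part)]
            cmd += self.extra_args
            proc = subprocess.run(cmd, capture_output=True, text=True,
                                  check=False)
            treefile = next(tmpdir.glob("*.treefile"), None)
            if proc.returncode != 0 or treefile is None:
                raise RuntimeError(f"IQ-TREE failed: {proc.stderr[:500]}")
            return treefile.read_text().strip()


_BACKENDS = {
    "builtin": BuiltinMLBackend,
    "nj": NJBackend,
    "fasttree": FastTreeBackend,
    "raxml": RaxmlBackend,
    "iqtree": IqtreeBackend,
}


def get_backend(name: str, **kwargs):
    """Instantiate an inference backend by name."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ValueError(
            f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    return cls(**kwargs)
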