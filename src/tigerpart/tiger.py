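"""TIGER-style relative evolutionary rates from set-partition agreement.

Each alignment column induces a *set partition* of the taxa: one block per
observed canonical state, with missing/ambiguous taxa left out.  A site's
rate is the average, over all other sites, of how compatible the other
site's grouping is with this site's grouping.  Invariable sites — whose
single block spans every scored taxon — are compatible with everything and
receive a rate of exactly 1; sites whose grouping conflicts with most of
the matrix drift towards 0.  The rate is *relative*: it orders sites from
conserved to idiosyncratic without reference to any tree.

Agreement of site ``j`` against reference site ``i`` is the fraction of
``j``'s blocks contained in some block of ``i``, where taxa that are
missing at the reference are unconstrained (equivalently, they are added
to every reference block before the containment test).  This convention is
what keeps "invariable implies rate 1" true in the presence of missing
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .alignment import AlignmentMatrix, CANONICAL_STATES, LengthMismatchError

__all__ = [
    "SiteSetPartition",
    "SiteRates",
    "site_partition",
    "partition_agreement",
    "tiger_rates",
    "write_rates",
    "read_rates",
]


@dataclass(frozen=True)
class SiteSetPartition:
    """Set partition of the taxa induced by one alignment column.

    ``blocks`` holds one frozenset of 0-based taxon indices per canonical
    state observed at the site; missing/ambiguous taxa appear in no block.
    """

    site: int
    n_taxa: int
    blocks: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        union: set[int] = set()
        for b in self.blocks:
            if union & b:
                raise ValueError("blocks must be disjoint")
            union |= b
        if union and (min(union) < 0 or max(union) >= self.n_taxa):
            raise ValueError("taxon index out of range")

    @property
    def scored_taxa(self) -> frozenset[int]:
        """Taxa with an unambiguous state at this site."""
        return frozenset().union(*self.blocks) if self.blocks else frozenset()


@dataclass(frozen=True)
class SiteRates:
    """Per-site relative rates in ``[0, 1]``, parallel to alignment columns."""

    rates: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.rates, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("rates must be a non-empty 1-D vector")
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            bad = arr[(arr < 0.0) | (arr > 1.0)][0]
            raise ValueError(f"rates must lie in [0, 1]; found {bad}")
        arr.setflags(write=False)
        object.__setattr__(self, "rates", arr)

    def __len__(self) -> int:
        return int(self.rates.size)

    def __iter__(self):
        return iter(self.rates)


def site_partition(aln: AlignmentMatrix, site: int) -> SiteSetPartition:
    """Group taxa by their canonical state at 1-based *site*."""
    if not 1 <= site <= aln.n_sites:
        raise IndexError(f"site {site} out of range 1..{aln.n_sites}")
    col = aln.matrix[:, site - 1]
    blocks = []
    for state in CANONICAL_STATES:
        members = frozenset(int(i) for i in np.nonzero(col == state)[0])
        if members:
            blocks.append(members)
    return SiteSetPartition(site=site, n_taxa=aln.n_taxa, blocks=tuple(blocks))


def partition_agreement(
    reference: SiteSetPartition, other: SiteSetPartition
) -> float:
    """Fraction of ``other``'s blocks nested within ``reference``'s grouping.

    Taxa missing at the reference site are unconstrained: a block of
    ``other`` agrees if its restriction to the reference's scored taxa fits
    inside one reference block.  An ``other`` with no blocks carries no
    grouping information and agrees fully (returns 1).
    """
    if reference.n_taxa != other.n_taxa:
        raise ValueError("partitions come from different taxa sets")
    if not other.blocks:
        return 1.0
    if not reference.blocks:
        return 1.0  # reference entirely missing: no constraint to violate
    scored = reference.scored_taxa
    hits = 0
    for b in other.blocks:
        restricted = b & scored
        if not restricted or any(restricted <= rb for rb in reference.blocks):
            hits += 1
    return hits / len(other.blocks)


def _pattern_masks(
    aln: AlignmentMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Collapse identical columns; return (state_masks, nonmissing, weights).

    ``state_masks`` is ``(U, 4, W)`` uint64 bitmasks of taxa per canonical
    state for each unique pattern; ``nonmissing`` is ``(U, W)``; ``weights``
    counts column multiplicity.  ``W`` 64-bit words cover the taxa.
    """
    codes = aln.state_codes()  # (n_taxa, L), 4 = missing
    patterns, inverse, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    n_taxa = aln.n_taxa
    n_words = (n_taxa + 63) // 64
    u = patterns.shape[0]
    masks = np.zeros((u, 4, n_words), dtype=np.uint64)
    word = np.arange(n_taxa) // 64
    bit = np.uint64(1) << (np.arange(n_taxa) % 64).astype(np.uint64)
    for s in range(4):
        hit = patterns == s  # (U, n_taxa)
        for w in range(n_words):
            sel = word == w
            masks[:, s, w] = (hit[:, sel] * bit[sel]).sum(axis=1, dtype=np.uint64)
    nonmissing = masks.sum(axis=1, dtype=np.uint64)  # disjoint => OR == sum
    return masks, nonmissing, counts.astype(float), inverse.reshape(-1)


def tiger_rates(aln: AlignmentMatrix) -> SiteRates:
    """Compute per-site TIGER rates for the whole alignment.

    rate(i) = mean over j != i of ``partition_agreement(site i, site j)``.
    Identical columns are collapsed to unique patterns, so the pairwise
    sweep costs O(U^2) for U unique patterns rather than O(L^2).
    """
    if aln.n_sites < 2:
        raise ValueError("need at least two sites to compare against")
    masks, nonmiss, weights, inverse = _pattern_masks(aln)
    u = masks.shape[0]
    zero = np.uint64(0)
    n_blocks = (masks.any(axis=2)).sum(axis=1)  # blocks per pattern
    # every pairwise agreement is a multiple of 1/12 (1..4 blocks), so the
    # sum over sites is carried as an exact integer numerator: the result
    # is then the correctly rounded rational, independent of summation
    # order, and matches a brute-force oracle bit for bit
    twelfth = np.where(n_blocks > 0, 12 // np.maximum(n_blocks, 1), 0)
    rate_num = np.zeros(u)  # integer-valued
    for i in range(u):
        ref = masks[i]  # (4, W)
        nm = nonmiss[i]  # (W,)
        if not ref.any():
            # entirely-missing reference constrains nothing: pa = 1 for all
            pa12 = np.full(u, 12, dtype=np.int64)
        else:
            # block s of pattern v agrees with ref iff for some ref state
            # s', (block & nonmissing_ref) is contained in ref block s'
            agree_blocks = np.zeros(u, dtype=np.int64)
            for s in range(4):
                b = masks[:, s, :]  # (U, W)
                present = (b != zero).any(axis=1)
                if not present.any():
                    continue
                restricted = b & nm  # (U, W)
                ok = np.zeros(u, dtype=bool)
                for sp in range(4):
                    ok |= ~((restricted & ~ref[sp]).any(axis=1))
                agree_blocks += np.where(present, ok, False)
            pa12 = np.where(n_blocks > 0, agree_blocks * twelfth, 12)
        rate_num[i] = float(weights @ pa12 - pa12[i])
    total = weights.sum()
    rates = rate_num[inverse] / (12.0 * (total - 1.0))
    return SiteRates(np.clip(rates, 0.0, 1.0))


def write_rates(rates: SiteRates, path: str | Path) -> None:
    """One rate per line, full float precision, original site order."""
    with Path(path).open("w") as fh:
        for r in rates.rates:
            fh.write(format(float(r), ".17g") + "\n")


def read_rates(
    path: str | Path, expected_length: int | None = None
) -> SiteRates:
    """Read a rates file; optionally validate against an alignment length."""
    values = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            values.append(float(line))
        except ValueError:
            raise ValueError(
                f"non-numeric rate {line!r} on line {lineno} of {path}"
            ) from None
    if expected_length is not None and len(values) != expected_length:
        raise LengthMismatchError(
            f"rates file has {len(values)} entries but alignment has "
            f"{expected_length} sites"
        )
    return SiteRates(np.asarray(values))
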