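"""Alignment container, PHYLIP/FASTA I/O and the high-missing-site filter.

The central object is :class:`AlignmentMatrix`, a taxa x sites DNA character
matrix.  Characters are upper-case; the canonical alphabet is ``A C G T``;
gaps (``-``), unknowns (``?``, ``N``) and IUPAC ambiguity codes are all
treated as *missing* throughout the package, because the downstream
set-partition machinery needs unambiguous state assignments.

Site indices are 1-based in every user-facing API, matching the conventions
of RAxML / NEXUS character sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = [
    "CANONICAL_STATES",
    "MISSING_SYMBOLS",
    "AlignmentError",
    "LengthMismatchError",
    "DuplicateTaxonError",
    "AlphabetError",
    "AlignmentMatrix",
    "SiteMask",
    "read_alignment",
    "write_alignment",
    "missing_fraction",
    "filter_high_missing_sites",
    "write_site_mask",
]

CANONICAL_STATES = ("A", "C", "G", "T")
#: IUPAC ambiguity codes plus gap/unknown symbols; all treated as missing.
MISSING_SYMBOLS = frozenset("?-NRYSWKMBDHV")

_VALID = frozenset(CANONICAL_STATES) | MISSING_SYMBOLS


class AlignmentError(ValueError):
    """Base class for alignment validation problems."""


class LengthMismatchError(AlignmentError):
    """Sequences (or a rates/sites vector) have inconsistent lengths."""


class DuplicateTaxonError(AlignmentError):
    """Two rows share the same taxon label."""


class AlphabetError(AlignmentError):
    """A character outside the canonical + missing alphabet was found."""


@dataclass(frozen=True)
class AlignmentMatrix:
    """A taxa x sites character matrix over the DNA alphabet.

    Parameters
    ----------
    taxa:
        Ordered, unique, non-empty taxon labels.
    matrix:
        ``(n_taxa, n_sites)`` array of single upper-case characters.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        taxa = tuple(str(t) for t in self.taxa)
        if len(taxa) == 0:
            raise AlignmentError("alignment must contain at least one taxon")
        if any(not t for t in taxa):
            raise AlignmentError("taxon labels must be non-empty")
        seen: set[str] = set()
        for t in taxa:
            if t in seen:
                raise DuplicateTaxonError(f"duplicate taxon label {t!r}")
            seen.add(t)
        mat = np.asarray(self.matrix)
        if mat.ndim != 2 or mat.shape[0] != len(taxa):
            raise AlignmentError(
                f"matrix shape {mat.shape} does not match {len(taxa)} taxa"
            )
        if mat.shape[1] < 1:
            raise AlignmentError("alignment must have at least one site")
        mat = np.char.upper(mat.astype("<U1"))
        bad = ~np.isin(mat, sorted(_VALID))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise AlphabetError(
                f"illegal character {mat[i, j]!r} at site {j + 1} "
                f"in taxon {taxa[i]!r}"
            )
        object.__setattr__(self, "taxa", taxa)
        mat.setflags(write=False)
        object.__setattr__(self, "matrix", mat)

    # -- basic queries -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[1])

    def sequence(self, taxon: str) -> str:
        """Return the full sequence for *taxon* as a string."""
        try:
            idx = self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None
        return "".join(self.matrix[idx])

    def is_missing(self) -> np.ndarray:
        """Boolean ``(n_taxa, n_sites)`` mask of missing/ambiguous cells."""
        return np.isin(self.matrix, sorted(MISSING_SYMBOLS))

    def state_codes(self) -> np.ndarray:
        """Encode A,C,G,T as 0..3 and anything missing as 4."""
        codes = np.full(self.matrix.shape, 4, dtype=np.int8)
        for k, state in enumerate(CANONICAL_STATES):
            codes[self.matrix == state] = k
        return codes

    def take_sites(self, sites_1based: Sequence[int]) -> "AlignmentMatrix":
        """Sub-alignment of the given 1-based site indices, order preserved."""
        idx = np.asarray(sites_1based, dtype=int) - 1
        if idx.size == 0:
            raise AlignmentError("cannot build an alignment with zero sites")
        if idx.min() < 0 or idx.max() >= self.n_sites:
            raise IndexError("site index out of range")
        return AlignmentMatrix(self.taxa, self.matrix[:, idx])

    @classmethod
    def from_sequences(
        cls, taxa: Iterable[str], sequences: Iterable[str]
    ) -> "AlignmentMatrix":
        taxa = tuple(taxa)
        seqs = [str(s) for s in sequences]
        if len(seqs) != len(taxa):
            raise AlignmentError("taxa and sequences differ in count")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise LengthMismatchError(
                f"sequences have differing lengths {sorted(lengths)}"
            )
        mat = np.array([list(s.upper()) for s in seqs], dtype="<U1")
        return cls(taxa, mat)


@dataclass(frozen=True)
class SiteMask:
    """Bookkeeping for a site filter: which original sites survived.

    ``kept`` and ``dropped`` are disjoint ordered 1-based indices whose
    union is ``1..L`` of the original alignment.
    """

    kept: tuple[int, ...]
    dropped: tuple[int, ...]

    def __post_init__(self) -> None:
        kept, dropped = set(self.kept), set(self.dropped)
        if kept & dropped:
            raise ValueError("kept and dropped site sets overlap")
        n = len(kept) + len(dropped)
        if kept | dropped != set(range(1, n + 1)):
            raise ValueError("kept+dropped must tile 1..L")

    @property
    def n_original(self) -> int:
        return len(self.kept) + len(self.dropped)


# -- I/O ---------------------------------------------------------------


def _from_biopython(records) -> AlignmentMatrix:
    taxa = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return AlignmentMatrix.from_sequences(taxa, seqs)


def read_alignment(path: str | Path, format: str = "phylip") -> AlignmentMatrix:
    """Read an alignment from *path*.

    ``format`` is ``"phylip"`` (relaxed labels; sequential or interleaved)
    or ``"fasta"``.  Input is case-normalised to upper case.
    """
    path = Path(path)
    if format == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise AlignmentError(f"no sequences found in {path}")
        return _from_biopython(records)
    if format == "phylip":
        text = path.read_text()
        last_err: Exception | None = None
        for dialect in ("phylip-relaxed", "phylip-sequential"):
            try:
                aln = AlignIO.read(StringIO(text), dialect)
                return _from_biopython(list(aln))
            except AlignmentError:
                raise
            except Exception as err:  # biopython parse failure; try next
                last_err = err
        raise AlignmentError(f"could not parse {path} as PHYLIP: {last_err}")
    raise ValueError(f"unsupported alignment format {format!r}")


def write_alignment(
    aln: AlignmentMatrix, path: str | Path, format: str = "phylip"
) -> None:
    """Write *aln* to *path* (PHYLIP written sequential, relaxed labels)."""
    path = Path(path)
    if format == "phylip":
        with path.open("w") as fh:
            fh.write(f" {aln.n_taxa} {aln.n_sites}\n")
            for i, taxon in enumerate(aln.taxa):
                fh.write(f"{taxon}  {''.join(aln.matrix[i])}\n")
    elif format == "fasta":
        with path.open("w") as fh:
            for i, taxon in enumerate(aln.taxa):
                fh.write(f">{taxon}\n{''.join(aln.matrix[i])}\n")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


# -- missing-data filter ----------------------------------------------


def missing_fraction(aln: AlignmentMatrix, site: int) -> float:
    """Fraction of taxa with a missing/ambiguous state at 1-based *site*."""
    if not 1 <= site <= aln.n_sites:
        raise IndexError(f"site {site} out of range 1..{aln.n_sites}")
    col = aln.is_missing()[:, site - 1]
    return float(col.mean())


def filter_high_missing_sites(
    aln: AlignmentMatrix,
    threshold: float = 0.80,
    exempt_fraction: float = 0.01,
) -> tuple[AlignmentMatrix, SiteMask]:
    """Drop sites whose missing fraction strictly exceeds *threshold*.

    If the proportion of such sites over the whole alignment is at most
    *exempt_fraction*, the alignment is returned unchanged (the filter is
    considered unnecessary for an essentially complete matrix).
    """
    for name, val in (("threshold", threshold), ("exempt_fraction", exempt_fraction)):
        if not 0.0 < val < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {val}")
    frac = aln.is_missing().mean(axis=0)
    high = frac > threshold
    all_sites = tuple(range(1, aln.n_sites + 1))
    if high.mean() <= exempt_fraction:
        return aln, SiteMask(kept=all_sites, dropped=())
    kept = tuple(int(i) for i in np.nonzero(~high)[0] + 1)
    dropped = tuple(int(i) for i in np.nonzero(high)[0] + 1)
    if not kept:
        raise AlignmentError("filter would remove every site")
    return aln.take_sites(kept), SiteMask(kept=kept, dropped=dropped)


def write_site_mask(mask: SiteMask, path: str | Path) -> None:
    """Write a two-column text file: 1-based site index, ``kept``/``dropped``."""
    kept, dropped = set(mask.kept), set(mask.dropped)
    with Path(path).open("w") as fh:
        for site in range(1, mask.n_original + 1):
            status = "kept" if site in kept else "dropped"
            fh.write(f"{site}\t{status}\n")
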