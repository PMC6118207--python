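"""Group sites into partitions by iteratively dividing the rate range.

Sites carry relative rates in ``[0, 1]`` (1 = invariable, towards 0 =
fastest).  Starting from the observed maximum ``x`` and minimum ``y``, the
first rate-span reaches down to ``z = x - (x - y)/d`` and each later span
``p`` to ``z = x - (x - y)/(d + 0.3 p)``, with the previous lower limit
becoming the new upper limit.  The shrinking divisor makes spans narrower
as rates fall, so slow sites form a few large partitions and fast sites
many small ones, tracking the empirical rate distribution.  Iteration
stops once fewer than 10% of the sites remain unassigned; those leftovers
become the final, fastest partition.

The division factor ``d`` (> 1) is the single knob: larger ``d`` means
narrower spans and therefore more partitions.

A site with rate ``r`` belongs to span ``p`` when ``z_p < r <= x_p``; the
first span is closed at the top so the maximum-rate sites are always
captured.  Spans that catch no site are skipped in the output (downstream
model fitters reject empty subsets) and surviving partitions are renamed
``p1..pk`` from slowest to fastest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import re
from typing import Iterable, Sequence

import numpy as np

from .tiger import SiteRates

__all__ = [
    "InvalidDivisionFactorError",
    "RateSpan",
    "PartitionScheme",
    "first_boundary",
    "next_boundary",
    "build_scheme",
    "write_scheme",
    "read_scheme",
    "compress_ranges",
    "expand_ranges",
]

#: Fixed increment applied to the divisor per partition number.
SPAN_SHRINK = 0.3
#: Default fraction of sites below which the remainder rule triggers.
REMAINDER_FRACTION = 0.10

_EPS = 1e-12
_MAX_EMPTY_SPANS = 50


class InvalidDivisionFactorError(ValueError):
    """The division factor must be strictly greater than 1."""


def _check_d(d: float) -> None:
    if not d > 1.0:
        raise InvalidDivisionFactorError(
            f"division factor must be greater than 1, got {d}"
        )


def first_boundary(x: float, y: float, d: float) -> float:
    """Lower limit of the first (slowest) rate-span: ``x - (x - y)/d``."""
    _check_d(d)
    if y > x:
        raise ValueError(f"minimum rate {y} exceeds upper limit {x}")
    return x - (x - y) / d


def next_boundary(x: float, y: float, d: float, p: int) -> float:
    """Lower limit of span ``p`` (>1): ``x - (x - y)/(d + 0.3 p)``."""
    _check_d(d)
    if p < 2:
        raise ValueError(f"partition number must be >= 2, got {p}")
    if y > x:
        raise ValueError(f"minimum rate {y} exceeds upper limit {x}")
    return x - (x - y) / (d + SPAN_SHRINK * p)


@dataclass(frozen=True)
class RateSpan:
    """One rate interval ``(lower, upper]`` of the iterative division."""

    index: int
    upper: float
    lower: float
    is_remainder: bool = False

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("partition number must be >= 1")
        if self.lower > self.upper:
            raise ValueError("span lower limit exceeds upper limit")


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered, disjoint, exhaustive grouping of sites into named subsets.

    ``subsets`` maps each name to its sorted 1-based site indices and,
    when the scheme came from the span algorithm, the generating span.
    Subsets are ordered slowest to fastest.
    """

    subsets: tuple[tuple[str, tuple[int, ...], RateSpan | None], ...]
    total_sites: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        if not self.subsets:
            raise ValueError("scheme must contain at least one subset")
        for name, sites, _span in self.subsets:
            if not sites:
                raise ValueError(f"subset {name!r} is empty")
            s = set(sites)
            if len(s) != len(sites):
                raise ValueError(f"subset {name!r} has duplicate sites")
            if s & seen:
                raise ValueError("subsets overlap")
            seen |= s
        if seen != set(range(1, self.total_sites + 1)):
            raise ValueError("subsets do not cover sites 1..total_sites")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.subsets)

    def sites(self, name: str) -> tuple[int, ...]:
        for n, sites, _ in self.subsets:
            if n == name:
                return sites
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.subsets)


def build_scheme(
    rates: SiteRates | Sequence[float],
    d: float,
    remainder_fraction: float = REMAINDER_FRACTION,
) -> PartitionScheme:
    """Partition sites by iterated rate-spans with the remainder rule.

    Sites whose rate equals the dataset minimum are only reachable through
    the remainder rule (every span is open at the bottom), so two guards
    guarantee termination when many sites share the minimum: a vanishing
    remaining range, or 50 consecutive spans that capture nothing.
    """
    _check_d(d)
    arr = np.asarray(
        rates.rates if isinstance(rates, SiteRates) else rates, dtype=float
    )
    if arr.size == 0:
        raise ValueError("rates vector is empty")
    total = arr.size
    x, y = float(arr.max()), float(arr.min())

    if x - y < _EPS:  # degenerate: all rates equal
        span = RateSpan(index=1, upper=x, lower=y)
        sites = tuple(range(1, total + 1))
        return PartitionScheme(((("p1"), sites, span),), total)

    unassigned = np.ones(total, dtype=bool)
    collected: list[tuple[tuple[int, ...], RateSpan]] = []
    p = 0
    empty_streak = 0
    while True:
        p += 1
        z = first_boundary(x, y, d) if p == 1 else next_boundary(x, y, d, p)
        member = unassigned & (arr > z) & (arr <= x)
        sites = tuple(int(i) for i in np.nonzero(member)[0] + 1)
        collected.append((sites, RateSpan(index=p, upper=x, lower=z)))
        unassigned[member] = False
        empty_streak = empty_streak + 1 if not sites else 0
        remaining = int(unassigned.sum())
        exhausted = (x - y < _EPS) or (z - y < _EPS)
        if (
            remaining < remainder_fraction * total
            or exhausted
            or empty_streak >= _MAX_EMPTY_SPANS
        ):
            if remaining:
                rem_sites = tuple(int(i) for i in np.nonzero(unassigned)[0] + 1)
                collected.append(
                    (rem_sites, RateSpan(index=p + 1, upper=z, lower=y,
                                         is_remainder=True))
                )
            break
        x = z

    subsets = tuple(
        (f"p{k}", sites, span)
        for k, (sites, span) in enumerate(
            ((s, sp) for s, sp in collected if s), start=1
        )
    )
    return PartitionScheme(subsets, total)


# -- range compression and partition-file dialects ---------------------


def compress_ranges(sites: Iterable[int]) -> list[tuple[int, int]]:
    """Collapse sorted 1-based indices into maximal (start, end) runs."""
    runs: list[tuple[int, int]] = []
    for s in sorted(sites):
        if runs and s == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], s)
        else:
            runs.append((s, s))
    return runs


def expand_ranges(runs: Iterable[tuple[int, int]]) -> tuple[int, ...]:
    out: list[int] = []
    for a, b in runs:
        out.extend(range(a, b + 1))
    return tuple(out)


def _ranges_str(sites: Sequence[int], sep: str) -> str:
    return sep.join(
        f"{a}-{b}" if a != b else str(a) for a, b in compress_ranges(sites)
    )


def write_scheme(
    scheme: PartitionScheme, format: str, path: str | Path
) -> None:
    """Serialize *scheme* in a partition-file dialect.

    ``raxml``      one ``DNA, name = ranges`` line per subset;
    ``nexus``      a ``sets`` block with ``charset`` statements;
    ``pfinder``    a PartitionFinder ``[data_blocks]`` section.
    """
    path = Path(path)
    if format == "raxml":
        lines = [
            f"DNA, {name} = {_ranges_str(sites, ',')}"
            for name, sites, _ in scheme.subsets
        ]
        path.write_text("\n".join(lines) + "\n")
    elif format == "nexus":
        lines = ["#NEXUS", "begin sets;"]
        for name, sites, _ in scheme.subsets:
            lines.append(f"    charset {name} = {_ranges_str(sites, ' ')};")
        lines.append("end;")
        path.write_text("\n".join(lines) + "\n")
    elif format == "pfinder":
        lines = ["[data_blocks]"]
        for name, sites, _ in scheme.subsets:
            lines.append(f"{name} = {_ranges_str(sites, ',')};")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported partition format {format!r}")


_RAXML_RE = re.compile(r"^\s*DNA\s*,\s*(\S+)\s*=\s*(.+?)\s*$", re.I)
_CHARSET_RE = re.compile(r"charset\s+(\S+)\s*=\s*([^;]+);", re.I)
_PF_RE = re.compile(r"^\s*(\S+)\s*=\s*([^;]+);\s*$")


def _parse_ranges(text: str, sep: str) -> tuple[int, ...]:
    sites: list[int] = []
    for chunk in re.split(r"[,\s]+" if sep == "auto" else re.escape(sep), text):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            a, b = chunk.split("-")
            sites.extend(range(int(a), int(b) + 1))
        else:
            sites.append(int(chunk))
    return tuple(sorted(sites))


def read_scheme(path: str | Path, format: str = "auto") -> PartitionScheme:
    """Parse a partition file written by :func:`write_scheme`."""
    text = Path(path).read_text()
    if format == "auto":
        stripped = text.lstrip().lower()
        if stripped.startswith("#nexus"):
            format = "nexus"
        elif "[data_blocks]" in stripped:
            format = "pfinder"
        else:
            format = "raxml"
    subsets: list[tuple[str, tuple[int, ...], None]] = []
    if format == "raxml":
        for line in text.splitlines():
            m = _RAXML_RE.match(line)
            if m:
                subsets.append((m.group(1), _parse_ranges(m.group(2), "auto"), None))
    elif format == "nexus":
        for m in _CHARSET_RE.finditer(text):
            subsets.append((m.group(1), _parse_ranges(m.group(2), "auto"), None))
    elif format == "pfinder":
        in_blocks = False
        for line in text.splitlines():
            if line.strip().lower() == "[data_blocks]":
                in_blocks = True
                continue
            if in_blocks:
                if line.strip().startswith("["):
                    break
                m = _PF_RE.match(line)
                if m:
                    subsets.append(
                        (m.group(1), _parse_ranges(m.group(2), "auto"), None)
                    )
    else:
        raise ValueError(f"unsupported partition format {format!r}")
    if not subsets:
        raise ValueError(f"no subsets found in {path}")
    total = max(max(sites) for _, sites, _ in subsets)
    return PartitionScheme(tuple(subsets), total)
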