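"""End-to-end orchestration: rates -> scheme, and the simulation benchmark.

``run_rates_partition`` covers the everyday workflow on a user alignment:
compute TIGER rates, build a rate-span scheme for a chosen division
factor, and write the scheme in all three partition-file dialects.

``run_benchmark`` reproduces the simulation study design: for each
requested condition x tree shape, simulate replicates, partition each one
both by the true simulated blocks ("4part") and by TIGER rates plus the
span algorithm ("tiger"), infer an ML tree per strategy, and score the
inferred trees against the generating topology with raw and normalised
Robinson–Foulds distances.  Simulation and partitioning are fully
deterministic given the master seed; per-replicate streams are spawned
from it so any single replicate can be reproduced in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import read_alignment
from .mltree import get_backend
from .ratepartitions import PartitionScheme, build_scheme, write_scheme
from .simulate import (
    CONDITION_IDS,
    get_condition,
    inject_missing,
    simulate_condition,
)
from .tiger import tiger_rates, write_rates
from .treecompare import robinson_foulds, summarize_replicates

__all__ = [
    "DEFAULT_DIVISION_FACTOR",
    "BenchmarkConfig",
    "run_rates_partition",
    "true_block_scheme",
    "run_benchmark",
    "summarize_benchmark",
]

#: Division factor used for the "tiger" benchmark strategy.
DEFAULT_DIVISION_FACTOR = 4.0

_SHAPES = ("asymmetric", "symmetric")
_SHAPE_CODE = {"asymmetric": "AS", "symmetric": "SS"}


@dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration of one benchmark run.

    ``backend`` names an inference backend (see :mod:`tigerpart.mltree`)
    or ``"none"`` to only simulate.  ``strategies`` may contain
    ``"4part"`` (the true simulated blocks) and ``"tiger"`` (TIGER rates
    + rate-span scheme with division factor ``d``).
    """

    conditions: tuple[str, ...] = CONDITION_IDS
    shapes: tuple[str, ...] = _SHAPES
    replicates: int = 10
    seed: int = 0
    strategies: tuple[str, ...] = ("4part", "tiger")
    backend: str = "builtin"
    backend_kwargs: dict = field(default_factory=dict)
    d: float = DEFAULT_DIVISION_FACTOR
    missing_data: bool = False
    missing_taxa: int = 3

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.conditions) - set(CONDITION_IDS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")
        if set(self.shapes) - set(_SHAPES):
            raise ValueError(f"shapes must be drawn from {_SHAPES}")
        bad = set(self.strategies) - {"4part", "tiger"}
        if bad:
            raise ValueError(f"unknown strategies {sorted(bad)}")


def run_rates_partition(
    aln_path: str | Path,
    d: float,
    outdir: str | Path,
    format: str = "phylip",
    remainder_fraction: float = 0.10,
) -> dict:
    """Compute rates and write scheme files for one alignment.

    Returns a log dictionary (also written as JSON next to the outputs)
    recording the division factor, span boundaries and subset sizes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln = read_alignment(aln_path, format=format)
    rates = tiger_rates(aln)
    write_rates(rates, outdir / "rates.txt")
    scheme = build_scheme(rates, d=d, remainder_fraction=remainder_fraction)
    paths = {}
    for fmt, suffix in (("raxml", "txt"), ("nexus", "nex"), ("pfinder", "cfg")):
        p = outdir / f"scheme_{fmt}.{suffix}"
        write_scheme(scheme, fmt, p)
        paths[fmt] = str(p)
    log = {
        "tigerpart_version": __version__,
        "alignment": str(aln_path),
        "n_taxa": aln.n_taxa,
        "n_sites": aln.n_sites,
        "d": d,
        "remainder_fraction": remainder_fraction,
        "subsets": [
            {
                "name": name,
                "n_sites": len(sites),
                "span": None
                if span is None
                else {"upper": span.upper, "lower": span.lower,
                      "remainder": span.is_remainder},
            }
            for name, sites, span in scheme.subsets
        ],
        "scheme_files": paths,
    }
    (outdir / "run.json").write_text(json.dumps(log, indent=2))
    return log


def true_block_scheme(block_boundaries: Sequence[tuple[int, int]],
                      total_sites: int) -> PartitionScheme:
    """Scheme matching the simulated block layout (the "4part" strategy)."""
    subsets = tuple(
        (f"p{k}", tuple(range(start, end + 1)), None)
        for k, (start, end) in enumerate(block_boundaries, start=1)
    )
    return PartitionScheme(subsets, total_sites)


def _replicate_seed(master: int, ci: int, si: int, rep: int,
                    purpose: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master,
                                  spawn_key=(ci, si, rep, purpose))


def run_benchmark(cfg: BenchmarkConfig, outdir: str | Path | None = None
                  ) -> pd.DataFrame:
    """Run the simulation benchmark; one row per replicate x strategy."""
    backend = None if cfg.backend == "none" else get_backend(
        cfg.backend, **cfg.backend_kwargs
    )
    rows = []
    for ci, cond_id in enumerate(cfg.conditions):
        for si, shape in enumerate(cfg.shapes):
            cond = get_condition(cond_id, shape)
            for rep in range(cfg.replicates):
                sim = simulate_condition(
                    cond, _replicate_seed(cfg.seed, ci, si, rep, 0)
                )
                aln = sim.alignment
                if cfg.missing_data:
                    aln = inject_missing(
                        aln,
                        sim.block_boundaries,
                        n_taxa=cfg.missing_taxa,
                        seed=np.random.default_rng(
                            _replicate_seed(cfg.seed, ci, si, rep, 1)
                        ),
                    )
                if backend is None:
                    continue
                true_newick = sim.tree.as_string(schema="newick")
                schemes: dict[str, PartitionScheme] = {}
                if "4part" in cfg.strategies:
                    schemes["4part"] = true_block_scheme(
                        sim.block_boundaries, aln.n_sites
                    )
                if "tiger" in cfg.strategies:
                    rates = tiger_rates(aln)
                    schemes["tiger"] = build_scheme(rates, d=cfg.d)
                for strategy, scheme in schemes.items():
                    inferred = backend.infer(aln, scheme)
                    rf = robinson_foulds(true_newick, inferred)
                    rows.append(
                        {
                            "condition": cond_id,
                            "shape": _SHAPE_CODE[shape],
                            "strategy": strategy,
                            "replicate": rep,
                            "raw_rf": rf.raw,
                            "normalized_rf": rf.normalized,
                        }
                    )
    df = pd.DataFrame(
        rows,
        columns=["condition", "shape", "strategy", "replicate",
                 "raw_rf", "normalized_rf"],
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "replicates.tsv", sep="\t", index=False)
        if len(df):
            summarize_benchmark(df).to_csv(outdir / "summary.tsv", sep="\t")
        sidecar = {
            "tigerpart_version": __version__,
            "seed": cfg.seed,
            "conditions": list(cfg.conditions),
            "shapes": list(cfg.shapes),
            "replicates": cfg.replicates,
            "strategies": list(cfg.strategies),
            "backend": cfg.backend,
            "d": cfg.d,
            "missing_data": cfg.missing_data,
        }
        (outdir / "run.json").write_text(json.dumps(sidecar, indent=2))
    return df


def summarize_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Condition-level mean raw RF per shape x strategy, plus overall rows.

    The layout mirrors the benchmark summary tables: one row per
    condition, then ``mean`` and ``S.D.`` rows computed across the
    per-condition means of each column.
    """
    table = df.pivot_table(
        index="condition",
        columns=["shape", "strategy"],
        values="raw_rf",
        aggfunc="mean",
    )
    order = [c for c in CONDITION_IDS if c in table.index]
    table = table.loc[order]
    summary_rows = {}
    for col in table.columns:
        mean, sd = summarize_replicates(table[col].dropna().tolist())
        summary_rows.setdefault("mean", {})[col] = mean
        summary_rows.setdefault("S.D.", {})[col] = sd
    extra = pd.DataFrame(summary_rows).T
    extra.index.name = table.index.name
    return pd.concat([table, extra])
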