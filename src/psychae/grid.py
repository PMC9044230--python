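"""The factorial simulation experiment: enumerate, run, summarize.

The full study design crosses 3 communality structures x 3 non-normality
scenarios x 27 sample sizes (243 population conditions), with 10
replicates per condition.  Each replicate generates a dataset, splits it
80/20, z-scores by the training statistics, fits every requested reducer
on the training partition, and scores MSE/MAE/NED on the test partition.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fleishman import SCENARIOS
from .metrics import mae, mse, ned
from .reducers import (
    VARIANTS,
    ReducerConfig,
    fit_reducer,
    standardize_apply,
    standardize_fit,
)
from .simulate import STRUCTURE_LABELS, generate, study_structures

__all__ = [
    "GridSpec",
    "Condition",
    "sample_size_ladder",
    "enumerate_conditions",
    "derive_seed",
    "run_condition",
    "run_grid",
    "summarize",
    "SUMMARY_FACTORS",
]

log = logging.getLogger(__name__)

SUMMARY_FACTORS = {
    "communality": "structure",
    "normality": "scenario",
    "sample_size": "n",
    "bottleneck": "bottleneck",
}


def sample_size_ladder() -> list[int]:
    """The 27 sample sizes: 100..190 by 10, then 200..1000 by 50."""
    return list(range(100, 200, 10)) + list(range(200, 1001, 50))


@dataclass(frozen=True)
class Condition:
    structure: str
    scenario: str
    n: int


@dataclass(frozen=True)
class GridSpec:
    """Configuration of one experiment run."""

    structures: tuple[str, ...] = STRUCTURE_LABELS
    scenarios: tuple[str, ...] = ("s1", "s2", "s3")
    sample_sizes: tuple[int, ...] = field(
        default_factory=lambda: tuple(sample_size_ladder())
    )
    replicates: int = 10
    train_fraction: float = 0.8
    master_seed: int = 20210
    algorithms: tuple[str, ...] = VARIANTS
    reducer_configs: dict[str, ReducerConfig] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("structures", "scenarios", "sample_sizes", "algorithms"):
            if not getattr(self, name):
                raise ValueError(f"empty factor: {name}")
        unknown = set(self.structures) - set(STRUCTURE_LABELS)
        if unknown:
            raise ValueError(f"unknown structure(s): {sorted(unknown)}")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenario(s): {sorted(unknown)}")
        unknown = set(self.algorithms) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        sizes = list(self.sample_sizes)
        if sizes != sorted(set(sizes)):
            raise ValueError("sample sizes must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def config_for(self, variant: str, seed: int) -> ReducerConfig:
        base = self.reducer_configs.get(variant, ReducerConfig(variant=variant))
        return replace(base, variant=variant, seed=seed)


def enumerate_conditions(spec: GridSpec) -> list[Condition]:
    """Cartesian product structures x scenarios x sample sizes."""
    for name in ("structures", "scenarios", "sample_sizes"):
        if not getattr(spec, name):
            raise ValueError(f"empty factor: {name}")
    return [
        Condition(st, sc, n)
        for st in spec.structures
        for sc in spec.scenarios
        for n in spec.sample_sizes
    ]


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed from the master seed and any hashable labels."""
    key = "|".join([str(master_seed), *map(str, parts)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_condition(
    condition: Condition,
    spec: GridSpec,
    structures=None,
) -> list[dict]:
    """All replicate x algorithm result rows for one condition."""
    if structures is None:
        structures = study_structures()
    structure = structures[condition.structure]
    moment_spec = SCENARIOS[condition.scenario]
    rows: list[dict] = []
    for rep in range(spec.replicates):
        seed = derive_seed(
            spec.master_seed,
            condition.structure,
            condition.scenario,
            condition.n,
            rep,
        )
        dataset = generate(structure, moment_spec, condition.n, seed)
        rng = np.random.default_rng(derive_seed(seed, "split"))
        perm = rng.permutation(condition.n)
        n_test = round((1 - spec.train_fraction) * condition.n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        scaler = standardize_fit(dataset.data[train_idx])
        train = standardize_apply(scaler, dataset.data[train_idx])
        test = standardize_apply(scaler, dataset.data[test_idx])
        for variant in spec.algorithms:
            config = spec.config_for(variant, derive_seed(seed, variant))
            row = {
                "structure": condition.structure,
                "scenario": condition.scenario,
                "n": condition.n,
                "replicate": rep,
                "algorithm": variant,
                "bottleneck": config.bottleneck,
                "seed": seed,
                "failed": False,
                "mse": np.nan,
                "mae": np.nan,
                "ned": np.nan,
            }
            try:
                model = fit_reducer(train, config)
                recon = model.reconstruct(test)
                row["mse"] = mse(test, recon)
                row["mae"] = mae(test, recon)
                row["ned"] = ned(test, recon)
            except Exception as exc:  # record, do not abort the grid
                log.warning(
                    "fit failed for %s on %s: %s", variant, condition, exc
                )
                row["failed"] = True
            rows.append(row)
    return rows


def run_grid(spec: GridSpec, progress: bool = False) -> pd.DataFrame:
    """Run every condition of the grid; one tidy row per fit."""
    structures = study_structures()
    conditions = enumerate_conditions(spec)
    rows: list[dict] = []
    for i, condition in enumerate(conditions):
        if progress:
            log.info(
                "condition %d/%d: %s", i + 1, len(conditions), condition
            )
        rows.extend(run_condition(condition, spec, structures))
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame, by: str = "communality") -> pd.DataFrame:
    """Mean and SD of each metric per algorithm within each factor level.

    ``by`` is one of communality | normality | sample_size | bottleneck.
    Failed fits are excluded (their count is logged).
    """
    if results.empty:
        raise ValueError("no results to summarize")
    if by not in SUMMARY_FACTORS:
        raise ValueError(
            f"unknown factor {by!r}; expected one of {sorted(SUMMARY_FACTORS)}"
        )
    column = SUMMARY_FACTORS[by]
    n_failed = int(results["failed"].sum())
    if n_failed:
        log.warning("excluding %d failed fit(s) from the summary", n_failed)
    ok = results[~results["failed"]]
    long = ok.melt(
        id_vars=[column, "algorithm"],
        value_vars=["mse", "mae", "ned"],
        var_name="metric",
    )
    out = (
        long.groupby(["metric", "algorithm", column], sort=False)["value"]
        .agg(mean="mean", sd="std")
        .reset_index()
        .rename(columns={column: "level"})
    )
    out.insert(2, "factor", by)
    return out
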