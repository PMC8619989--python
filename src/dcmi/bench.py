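"""Comparative experiment harness for the four G-test configurations.

One experimental unit runs IPC-MB once per feature of a sampled dataset
(every feature in turn as the target) under a given configuration:

* ``default``         — direct counting, no optimization structure;
* ``static-adtree``   — a static AD-tree built once and shared by all runs
                         of the same (dataset, LLT) group;
* ``dynamic-adtree``  — a dynamic AD-tree shared and grown across runs;
* ``dcmi``            — a shared Joint Entropy Table plus DoF cache.

All configurations produce identical blankets, verdict traces and CI-test
counts; they differ only in how sample counts are obtained, which is what
the recorded metrics (test counts, JHT hit rate, structure entry counts)
measure.  Wall-clock time is recorded for orientation but never asserted
on: it is hardware-dependent, unlike counts and rates.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .adtree import ADTree, ADTreeBackend, ADTreeBudgetError
from .bayesnet import BayesianNetwork, sample
from .cache import DcmiBackend, DoFCache, JointEntropyTable, hit_rate
from .citest import CITestConfig, DirectCountBackend
from .ipcmb import GTestTester, find_mb

__all__ = [
    "ExperimentConfig",
    "RunMetrics",
    "derive_seed",
    "run_experiment",
    "summarize",
]

BACKENDS = ("default", "static-adtree", "dynamic-adtree", "dcmi")


def derive_seed(base: int, *keys: int) -> int:
    """Deterministic child seed (splitmix-style mixing), kept below 2**31.

    Any cell of a result table can be recomputed in isolation by deriving
    the same child seed from the experiment seed and the cell coordinates.
    """
    h = (base + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    for k in keys:
        h = (h ^ (k + 0x9E3779B97F4A7C15)) * 0xBF58476D1CE4E5B9
        h &= 0xFFFFFFFFFFFFFFFF
        h ^= h >> 27
        h = (h * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
        h ^= h >> 31
    return int(h & 0x7FFFFFFF)


@dataclass
class ExperimentConfig:
    """What to run: network, sample sizes, backends, LLT grid, significance."""

    network: BayesianNetwork
    sample_sizes: Sequence[int] = (2000,)
    backends: Sequence[str] = BACKENDS
    llt_values: Sequence[float] = (0.0, 5.0, 10.0)
    alpha: float = 0.05
    seed: int = 0
    static_node_budget: int | None = 2_000_000

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        for b in self.backends:
            if b not in BACKENDS:
                raise ValueError(f"unknown backend {b!r}")


@dataclass
class RunMetrics:
    """Aggregated metrics of one (backend, llt, n) experimental unit."""

    backend: str
    llt: float | None
    dataset_id: str
    n: int
    total_ci_tests: int = 0
    jht_hit_rate: float | None = None
    structure_entry_counts: dict[str, int] = field(default_factory=dict)
    per_target_tests: list[int] = field(default_factory=list)
    blankets: dict[int, tuple[int, ...]] = field(default_factory=dict)
    elapsed_seconds: float = 0.0
    skipped: bool = False
    skip_reason: str | None = None

    def to_record(self) -> dict:
        return {
            "backend": self.backend,
            "llt": self.llt,
            "dataset_id": self.dataset_id,
            "n": self.n,
            "total_ci_tests": self.total_ci_tests,
            "jht_hit_rate": self.jht_hit_rate,
            "structure_entry_counts": dict(self.structure_entry_counts),
            "per_target_tests": list(self.per_target_tests),
            "blankets": {str(t): sorted(mb) for t, mb in self.blankets.items()},
            "elapsed_seconds": self.elapsed_seconds,
            "skipped": self.skipped,
            "skip_reason": self.skip_reason,
        }


def _make_backend(name, ds, llt, budget):
    if name == "default":
        return DirectCountBackend(ds)
    if name == "static-adtree":
        tree = ADTree(ds, mode="static", llt_percent=llt, node_budget=budget)
        return ADTreeBackend(tree)
    if name == "dynamic-adtree":
        tree = ADTree(ds, mode="dynamic", llt_percent=llt)
        return ADTreeBackend(tree)
    if name == "dcmi":
        return DcmiBackend(ds, JointEntropyTable(), DoFCache())
    raise ValueError(name)


def _structure_counts(name, backend) -> dict[str, int]:
    if name == "dcmi":
        return {
            "jht_entries": len(backend.jht),
            "dof_entries": len(backend.dof_cache),
        }
    if name.endswith("adtree"):
        return dict(backend.tree.node_counts())
    return {}


def run_experiment(cfg: ExperimentConfig) -> list[RunMetrics]:
    """Run every configured (backend, llt, n) unit over all targets.

    The optimization structure of a unit is built once and shared by the
    per-target runs of that unit; infeasible static builds (node budget
    exceeded) are recorded as skipped rather than failing the experiment.
    Deterministic given ``cfg.seed``.
    """
    results: list[RunMetrics] = []
    test_cfg = CITestConfig(alpha=cfg.alpha)
    for size_idx, n in enumerate(cfg.sample_sizes):
        ds = sample(cfg.network, n, derive_seed(cfg.seed, size_idx, n))
        dataset_id = f"{cfg.network.name}:n{n}"
        for name in cfg.backends:
            llts: Sequence[float | None]
            llts = cfg.llt_values if name.endswith("adtree") else [None]
            for llt in llts:
                metrics = RunMetrics(name, llt, dataset_id, n)
                t0 = time.perf_counter()
                try:
                    backend = _make_backend(
                        name, ds, llt or 0.0, cfg.static_node_budget
                    )
                except ADTreeBudgetError as exc:
                    metrics.skipped = True
                    metrics.skip_reason = str(exc)
                    results.append(metrics)
                    continue
                tester = GTestTester(backend, test_cfg)
                for target in range(ds.M):
                    before = tester.tests_performed
                    res = find_mb(
                        target,
                        tester,
                        spouse_conditioning=test_cfg.spouse_conditioning,
                    )
                    metrics.per_target_tests.append(
                        tester.tests_performed - before
                    )
                    metrics.blankets[target] = tuple(sorted(res.mb))
                metrics.total_ci_tests = tester.tests_performed
                metrics.elapsed_seconds = time.perf_counter() - t0
                metrics.structure_entry_counts = _structure_counts(name, backend)
                if name == "dcmi":
                    metrics.jht_hit_rate = hit_rate(backend.jht)
                results.append(metrics)
    return results


def summarize(metrics: Iterable[RunMetrics]) -> pd.DataFrame:
    """One row per (n, backend, llt), deterministically sorted."""
    metrics = list(metrics)
    if not metrics:
        raise ValueError("no metrics to summarize")
    rows = []
    for m in metrics:
        row = {
            "dataset_id": m.dataset_id,
            "n": m.n,
            "backend": m.backend,
            "llt": m.llt,
            "total_ci_tests": m.total_ci_tests,
            "jht_hit_rate": m.jht_hit_rate,
            "elapsed_seconds": m.elapsed_seconds,
            "skipped": m.skipped,
        }
        for k, v in m.structure_entry_counts.items():
            row[k] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["n", "backend", "llt"], na_position="first", kind="mergesort"
    ).reset_index(drop=True)


def metrics_to_json(metrics: Iterable[RunMetrics]) -> str:
    return json.dumps([m.to_record() for m in metrics], indent=2)
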