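"""Reference benchmark experiments: eFDR calibration and planted recovery.

Two standing experiments quantify the behaviour of the full prioritization
path on synthetic panels with known ground truth:

* **Calibration** — the all-null configuration (every candidate is a decoy,
  exchangeable with the resampled null sets).  Any prioritized gene is a
  false discovery, so the per-replicate false-discovery proportion is 1
  when anything is prioritized and 0 otherwise; averaged over replicates it
  should sit near the eFDR target.
* **Recovery** — candidates planted inside the strongly loaded reference
  module should be prioritized, decoys should not.

Both experiments run the same pipeline a user runs: weights from
per-individual reference matrices, genome-wide |r| cut-off, connectivity,
eFDR resampling, selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coexpression import (
    ThresholdSpec,
    WeightVector,
    combination_weights,
    combine_correlations,
    pairwise_correlation,
    significance_cutoff,
)
from .prioritize import (
    ConnectivityTable,
    EFDRCurve,
    connectivity_table,
    efdr_curve,
    select_prioritized,
)
from .synthetic import BenchmarkData, planted_benchmark

__all__ = [
    "BenchmarkResult",
    "CalibrationResult",
    "RecoveryResult",
    "run_benchmark",
    "efdr_calibration",
    "planted_recovery",
]


@dataclass
class BenchmarkResult:
    bench: BenchmarkData
    weights: WeightVector
    threshold: ThresholdSpec
    table: ConnectivityTable
    curve: EFDRCurve

    @property
    def prioritized(self) -> set[str]:
        return set(self.table.prioritized_genes())


def run_benchmark(
    bench: BenchmarkData,
    *,
    quantile: float = 0.95,
    target: float = 0.25,
    n_resamples: int = 1000,
    n_sampled_pairs: int = 10_000,
    method: str = "pearson",
    seed: int = 0,
) -> BenchmarkResult:
    """Run the full prioritization pipeline on one synthetic benchmark."""
    panels = list(bench.panels)
    if len(panels) > 1:
        per_ind = [pairwise_correlation(p, bench.reference, method=method) for p in panels]
        weights = combination_weights(per_ind, time_period=panels[0].time_period)
    else:
        weights = WeightVector((panels[0].individual_id,), np.array([1.0]),
                               panels[0].time_period)

    child = np.random.SeedSequence(seed).generate_state(2)
    threshold = significance_cutoff(
        panels, weights=weights, quantile=quantile,
        n_sampled_pairs=n_sampled_pairs, seed=int(child[0] & 0x7FFFFFFF), method=method,
    )

    union = list(bench.reference.symbols) + list(bench.candidates.symbols)
    matrices = [pairwise_correlation(p, union, method=method) for p in panels]
    combined = (
        combine_correlations(matrices, weights) if len(matrices) > 1 else matrices[0]
    )
    table = connectivity_table(bench.candidates, bench.reference, combined, threshold.cutoff)
    curve = efdr_curve(
        table, panels, bench.reference, threshold.cutoff,
        weights=weights, n_resamples=n_resamples, target=target,
        method=method, seed=int(child[1] & 0x7FFFFFFF),
    )
    table = select_prioritized(table, curve)
    return BenchmarkResult(bench, weights, threshold, table, curve)


@dataclass
class CalibrationResult:
    fdps: np.ndarray  # per-replicate false-discovery proportions
    target: float

    @property
    def mean_fdp(self) -> float:
        return float(self.fdps.mean())


def efdr_calibration(
    *,
    n_replicates: int = 200,
    n_reference: int = 29,
    n_candidates: int = 50,
    n_resamples: int = 200,
    n_genes: int = 300,
    n_individuals: int = 2,
    n_samples: int = 60,
    n_sampled_pairs: int = 2000,
    target: float = 0.25,
    seed: int = 0,
) -> CalibrationResult:
    """Realized false-discovery proportion under the all-null configuration.

    Candidates are plain background genes, exchangeable with the resampled
    null sets, so every prioritized gene is a false discovery: the FDP of a
    replicate is 1 if anything was prioritized, else 0 (the 0/0 = 0
    convention).  The mean FDP over replicates estimates the realized FDR
    and should land near the nominal target.
    """
    streams = np.random.SeedSequence(seed).generate_state(2 * n_replicates)
    fdps = np.empty(n_replicates)
    for i in range(n_replicates):
        bench = planted_benchmark(
            n_reference=n_reference,
            n_true_candidates=0,
            n_decoys=n_candidates,
            n_genes=n_genes,
            n_individuals=n_individuals,
            n_samples=n_samples,
            seed=int(streams[2 * i] & 0x7FFFFFFF),
        )
        result = run_benchmark(
            bench,
            target=target,
            n_resamples=n_resamples,
            n_sampled_pairs=n_sampled_pairs,
            seed=int(streams[2 * i + 1] & 0x7FFFFFFF),
        )
        fdps[i] = 1.0 if result.prioritized else 0.0
    return CalibrationResult(fdps=fdps, target=target)


@dataclass
class RecoveryResult:
    n_true: int
    n_true_prioritized: int
    n_decoys: int
    n_decoys_prioritized: int

    @property
    def recovery_fraction(self) -> float:
        return self.n_true_prioritized / self.n_true if self.n_true else float("nan")


def planted_recovery(
    *,
    n_reference: int = 29,
    n_true_candidates: int = 10,
    n_decoys: int = 50,
    n_genes: int = 1200,
    n_individuals: int = 4,
    n_samples: int = 100,
    loading: float = 0.9,
    n_resamples: int = 1000,
    n_sampled_pairs: int = 10_000,
    target: float = 0.25,
    seed: int = 0,
) -> RecoveryResult:
    """Prioritization accuracy when true candidates share the reference module."""
    child = np.random.SeedSequence(seed).generate_state(2)
    bench = planted_benchmark(
        n_reference=n_reference,
        n_true_candidates=n_true_candidates,
        n_decoys=n_decoys,
        n_genes=n_genes,
        n_individuals=n_individuals,
        n_samples=n_samples,
        loading=loading,
        seed=int(child[0] & 0x7FFFFFFF),
    )
    result = run_benchmark(
        bench, target=target, n_resamples=n_resamples,
        n_sampled_pairs=n_sampled_pairs, seed=int(child[1] & 0x7FFFFFFF),
    )
    prioritized = result.prioritized
    return RecoveryResult(
        n_true=len(bench.true_candidates),
        n_true_prioritized=len(prioritized & set(bench.true_candidates)),
        n_decoys=len(bench.decoys),
        n_decoys_prioritized=len(prioritized & set(bench.decoys)),
    )
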