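"""Connectivity scoring of candidate genes and empirical-FDR selection.

A candidate's evidence of "guilt by association" is its connectivity to the
reference set: over the reference genes g with |r(candidate, g)| strictly
above the significance cut-off, the discrete score K* counts those edges and
the continuous score K sums their |r|.  Each contributing |r| lies in
(cutoff, 1], so cutoff·K* ≤ K ≤ K*, and both scores are nonincreasing in
the cut-off.

Selection uses a resampling-based empirical false discovery rate: random
gene sets of the same size as the candidate list are drawn from genes that
belong to neither the reference nor the candidate set, scored identically,
and eFDR(T) is the mean number of random genes with K > T divided by the
number of observed candidates with K > T.  Candidates are prioritized at
the smallest threshold whose (monotonized) eFDR drops to the target rate,
0.25 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coexpression import (
    CorrelationMatrix,
    WeightVector,
    combine_cross,
    common_genes,
    cross_correlation,
    _drop_zero_variance,
    _weights_or_default,
)
from .io import ExpressionPanel, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityTable",
    "EFDRCurve",
    "connectivity",
    "connectivity_table",
    "leave_one_out_connectivity",
    "efdr_from_samples",
    "efdr_curve",
    "select_prioritized",
]


@dataclass
class ConnectivityTable:
    """Per-gene connectivity scores, ranks and prioritization flags.

    ``frame`` is indexed by gene symbol with columns ``K_star`` (int),
    ``K`` (float), ``rank`` (1 = best, by descending K, ties broken by gene
    symbol) and ``prioritized`` (bool).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"K_star", "K", "rank", "prioritized"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"connectivity table needs columns {sorted(required)}")
        if self.frame.index.has_duplicates:
            raise ValueError("connectivity table has duplicate gene symbols")

    @classmethod
    def from_scores(
        cls,
        genes: Sequence[str],
        k_star: np.ndarray,
        k: np.ndarray,
        prioritized: np.ndarray | None = None,
    ) -> "ConnectivityTable":
        frame = pd.DataFrame(
            {
                "K_star": np.asarray(k_star, dtype=int),
                "K": np.asarray(k, dtype=float),
                "prioritized": (
                    np.zeros(len(genes), dtype=bool) if prioritized is None
                    else np.asarray(prioritized, dtype=bool)
                ),
            },
            index=pd.Index(genes, name="gene"),
        )
        order = frame.sort_values(["K", "gene"], ascending=[False, True],
                                  kind="mergesort").index
        frame.loc[order, "rank"] = np.arange(1, len(frame) + 1)
        frame["rank"] = frame["rank"].astype(int)
        return cls(frame[["K_star", "K", "rank", "prioritized"]])

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def K(self) -> np.ndarray:
        return self.frame["K"].to_numpy()

    @property
    def K_star(self) -> np.ndarray:
        return self.frame["K_star"].to_numpy()

    def prioritized_genes(self) -> list[str]:
        sub = self.frame[self.frame["prioritized"]]
        return list(sub.sort_values("rank").index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.sort_values("rank").copy()
        out["prioritized"] = out["prioritized"].astype(int)
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class EFDRCurve:
    """Empirical FDR as a function of the connectivity threshold T.

    ``efdr_raw`` holds the raw ratio (may exceed 1; NaN where no observed
    candidate exceeds T, the ratio being undefined there).  ``efdr`` is the
    monotonized curve, built scanning from high thresholds downward so that
    no threshold reports a lower eFDR than any stricter threshold above it;
    it is nonincreasing in T and truncated at 1 for reporting.
    ``chosen_T`` is the smallest threshold with eFDR ≤ target — the point
    where the monotone curve crosses the target coming down from above —
    or None when the target is never reached.
    """

    thresholds: np.ndarray
    efdr_raw: np.ndarray
    efdr: np.ndarray
    target: float
    chosen_T: float | None
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.efdr_raw = np.asarray(self.efdr_raw, dtype=float)
        self.efdr = np.asarray(self.efdr, dtype=float)
        if not (len(self.thresholds) == len(self.efdr_raw) == len(self.efdr)):
            raise ValueError("thresholds and eFDR arrays must be aligned")
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be sorted ascending")

    def chosen_for(self, target: float) -> float | None:
        """Smallest threshold whose monotonized eFDR is at or below target."""
        ok = np.flatnonzero(~np.isnan(self.efdr) & (self.efdr <= target))
        return float(self.thresholds[ok[0]]) if ok.size else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"T": self.thresholds, "efdr_raw": self.efdr_raw, "efdr_monotone": self.efdr}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _scores_from_abs_r(abs_r: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """K* and K per row of an |r| block against the reference genes."""
    edges = abs_r > cutoff  # strict: an edge must exceed the cut-off
    k_star = edges.sum(axis=1)
    k = np.where(edges, abs_r, 0.0).sum(axis=1)
    return k_star, k


def connectivity(
    candidate: str,
    reference: GeneSet,
    combined: CorrelationMatrix,
    cutoff: float,
) -> tuple[int, float]:
    """Discrete (K*) and continuous (K) connectivity of one candidate.

    The candidate must not itself belong to the reference set — a self
    correlation of 1 would otherwise inflate its score.
    """
    if candidate in reference:
        raise ValueError(f"candidate {candidate!r} is in the reference set")
    i = combined.index_of(candidate)
    ref_idx = [combined.index_of(g) for g in reference.symbols]
    abs_r = np.abs(combined.r[i, ref_idx])[None, :]
    k_star, k = _scores_from_abs_r(abs_r, cutoff)
    return int(k_star[0]), float(k[0])


def connectivity_table(
    candidates: GeneSet,
    reference: GeneSet,
    combined: CorrelationMatrix,
    cutoff: float,
) -> ConnectivityTable:
    """Connectivity scores for every candidate against the reference set."""
    overlap = set(candidates.symbols) & set(reference.symbols)
    if overlap:
        raise ValueError(f"candidates overlap the reference set: {sorted(overlap)}")
    cand_idx = [combined.index_of(g) for g in candidates.symbols]
    ref_idx = [combined.index_of(g) for g in reference.symbols]
    abs_r = np.abs(combined.r[np.ix_(cand_idx, ref_idx)])
    k_star, k = _scores_from_abs_r(abs_r, cutoff)
    return ConnectivityTable.from_scores(list(candidates.symbols), k_star, k)


def leave_one_out_connectivity(
    reference: GeneSet,
    combined: CorrelationMatrix,
    cutoff: float,
) -> ConnectivityTable:
    """Score each reference gene against the rest of the reference set.

    Analogous to leave-one-out cross-validation: a coherent reference
    network should score its own members highly when they are held out one
    at a time and treated as candidates.
    """
    if len(reference) < 3:
        raise ValueError("leave-one-out needs at least three reference genes")
    idx = [combined.index_of(g) for g in reference.symbols]
    abs_r = np.abs(combined.r[np.ix_(idx, idx)]).copy()
    np.fill_diagonal(abs_r, 0.0)  # exclude the held-out gene's self edge
    k_star, k = _scores_from_abs_r(abs_r, cutoff)
    return ConnectivityTable.from_scores(list(reference.symbols), k_star, k)


def efdr_from_samples(
    observed_K: np.ndarray,
    resampled_K: np.ndarray,
    *,
    target: float = 0.25,
    thresholds: np.ndarray | None = None,
    seed: int = 0,
) -> EFDRCurve:
    """Empirical FDR curve from observed and resampled connectivity scores.

    ``resampled_K`` has one row per resampled gene set.  For each threshold
    T, eFDR(T) = mean over resamples of #{resampled K > T} divided by
    #{observed K > T} ("exceed" is strict on both sides).  The default
    threshold grid covers the full step function of the curve over
    continuous T: each unique observed K value, plus the floating-point
    value just below it (where the exceedance count includes genes scoring
    exactly that K — the threshold that admits the top m genes lies just
    below the m-th largest score).
    """
    observed_K = np.asarray(observed_K, dtype=float)
    resampled_K = np.atleast_2d(np.asarray(resampled_K, dtype=float))
    if observed_K.size == 0:
        raise ValueError("no observed connectivity scores")
    if thresholds is None:
        uniq = np.unique(observed_K)
        thresholds = np.union1d(uniq, np.nextafter(uniq, -np.inf))
    thresholds = np.sort(np.asarray(thresholds, dtype=float))

    obs_sorted = np.sort(observed_K)
    null_sorted = np.sort(resampled_K.ravel())
    n_resamples = resampled_K.shape[0]

    obs_exceed = observed_K.size - np.searchsorted(obs_sorted, thresholds, side="right")
    null_exceed_mean = (
        null_sorted.size - np.searchsorted(null_sorted, thresholds, side="right")
    ) / n_resamples

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(obs_exceed > 0, null_exceed_mean / np.maximum(obs_exceed, 1), np.nan)

    # Monotonized scanning from high T downward: a threshold's eFDR is never
    # lower than one already seen at a stricter (higher) threshold, so the
    # curve is nonincreasing in T and chosen_T is the point where it crosses
    # the target coming down from above — a noise dip below the target at a
    # lax threshold cannot claim the target rate.
    mono = np.full_like(raw, np.nan)
    running = -np.inf
    for i in range(len(raw) - 1, -1, -1):
        if not np.isnan(raw[i]):
            running = max(running, raw[i])
            mono[i] = min(running, 1.0)  # report at most 1; raw kept unclipped

    curve = EFDRCurve(
        thresholds=thresholds,
        efdr_raw=raw,
        efdr=mono,
        target=target,
        chosen_T=None,
        n_resamples=n_resamples,
        seed=seed,
    )
    curve.chosen_T = curve.chosen_for(target)
    return curve


def efdr_curve(
    observed: ConnectivityTable,
    panels: Sequence[ExpressionPanel],
    reference: GeneSet,
    cutoff: float,
    *,
    weights: WeightVector | None = None,
    set_size: int | None = None,
    n_resamples: int = 1000,
    target: float = 0.25,
    method: str = "pearson",
    seed: int = 0,
    exclude: Sequence[str] = (),
) -> EFDRCurve:
    """Resample random candidate sets and estimate the eFDR curve for K.

    Random sets are the same size as the observed candidate list and are
    drawn without replacement from genes belonging to neither the reference
    nor the candidate set (nor ``exclude``), so the null sets cannot carry
    the signal being tested.
    """
    set_size = set_size or len(observed)
    banned = set(reference.symbols) | set(observed.genes) | set(exclude)
    universe = [g for g in common_genes(panels) if g not in banned]
    for panel in panels:
        universe = _drop_zero_variance(panel, universe)
    if set_size > len(universe):
        raise ValueError(
            f"resample size {set_size} exceeds the {len(universe)} eligible null genes"
        )

    weights = _weights_or_default(panels, weights, "pooled")
    blocks = [
        cross_correlation(p, universe, list(reference.symbols), method=method)
        for p in panels
    ]
    combined_block = combine_cross(blocks, weights) if len(blocks) > 1 else blocks[0]
    _, universe_K = _scores_from_abs_r(np.abs(combined_block), cutoff)

    rng = np.random.default_rng(seed)
    resampled = np.empty((n_resamples, set_size))
    for b in range(n_resamples):
        idx = rng.choice(len(universe), size=set_size, replace=False)
        resampled[b] = universe_K[idx]

    return efdr_from_samples(observed.K, resampled, target=target, seed=seed)


def select_prioritized(
    table: ConnectivityTable,
    curve: EFDRCurve,
    *,
    target: float | None = None,
) -> ConnectivityTable:
    """Flag candidates whose continuous connectivity clears the eFDR threshold.

    A candidate is prioritized iff K > chosen_T, the smallest threshold at
    which the monotonized eFDR drops to the target rate.  If no threshold
    reaches the target, nothing is prioritized (with a logged warning).
    """
    target = curve.target if target is None else target
    chosen = curve.chosen_for(target)
    if chosen is None:
        logger.warning("no connectivity threshold achieves eFDR <= %.3g; "
                       "prioritizing nothing", target)
        flags = np.zeros(len(table), dtype=bool)
    else:
        flags = table.K > chosen
    return ConnectivityTable.from_scores(table.genes, table.K_star, table.K, flags)
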