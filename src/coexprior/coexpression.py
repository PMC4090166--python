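"""Pairwise expression correlation, cross-individual combination, and nulls.

The level of co-expression of two genes is their sample correlation
coefficient r across a panel's samples (Pearson by default; Spearman is
Pearson on within-gene average ranks).  When a resource contributes several
individuals, per-individual correlation matrices are combined within a time
period by a weighted sum, with inverse-variance weights: an individual whose
correlation coefficients are more variable is down-weighted.  Edge
significance is declared against a genome-wide null: the empirical
``quantile``-quantile (default 95th percentile, the "top 5%" rule) of |r|
over randomly sampled gene pairs from the whole dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionPanel, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "WeightVector",
    "ThresholdSpec",
    "EcdfSummary",
    "pairwise_correlation",
    "cross_correlation",
    "combination_weights",
    "combine_correlations",
    "significance_cutoff",
    "null_distribution",
    "nearest_rank_quantile",
    "common_genes",
]

METHODS = ("pearson", "spearman")
_ATOL = 1e-9


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise correlation coefficients for a gene panel.

    ``source`` records provenance: an individual id, or
    ``"combined:<time_period>"`` for a weighted combination.
    """

    genes: tuple[str, ...]
    r: np.ndarray
    method: str
    source: str

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.genes)
        if self.r.shape != (n, n):
            raise ValueError(f"matrix shape {self.r.shape} does not match {n} genes")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.r), initial=0.0) > 1 + 1e-8:
            raise ValueError("correlation coefficients must lie in [-1, 1]")
        # remove numerical fuzz so invariants hold exactly
        self.r = np.clip((self.r + self.r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(self.r, 1.0)

    @property
    def n(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in correlation matrix") from None

    def loc(self, a: str, b: str) -> float:
        return float(self.r[self.index_of(a), self.index_of(b)])

    def submatrix(self, genes: Sequence[str]) -> "CorrelationMatrix":
        idx = [self.index_of(g) for g in genes]
        return CorrelationMatrix(tuple(genes), self.r[np.ix_(idx, idx)], self.method, self.source)

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal entries of the upper triangle (each pair once)."""
        iu = np.triu_indices(self.n, k=1)
        return self.r[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.genes), columns=list(self.genes))

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class WeightVector:
    """Per-individual combination weights, inverse-variance normalized.

    Within a time period the weights are nonnegative and sum to one; the
    individual with the lowest correlation variability receives the largest
    weight.
    """

    individual_ids: tuple[str, ...]
    w: np.ndarray
    time_period: str = "pooled"

    def __post_init__(self) -> None:
        self.individual_ids = tuple(self.individual_ids)
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.individual_ids),):
            raise ValueError("one weight per individual required")
        if (self.w < -_ATOL).any():
            raise ValueError("weights must be nonnegative")
        if not math.isclose(float(self.w.sum()), 1.0, abs_tol=1e-8):
            raise ValueError("weights must sum to one within a time period")

    def __len__(self) -> int:
        return len(self.individual_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual": list(self.individual_ids), "weight": self.w,
             "time_period": self.time_period}
        )


@dataclass(frozen=True)
class ThresholdSpec:
    """An |r| significance cut-off: the empirical quantile of the null |r|."""

    quantile: float
    cutoff: float
    n_sampled_pairs: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must lie in [0, 1]")


@dataclass
class EcdfSummary:
    """|r| samples for reference gene pairs and for a random-gene null.

    Stores sorted |r| values for both groups plus the null medians of the
    signed and absolute coefficient, ready for ECDF comparison plots.
    """

    reference_abs_r: np.ndarray
    null_abs_r: np.ndarray
    median_r_null: float
    median_abs_r_null: float

    def __post_init__(self) -> None:
        self.reference_abs_r = np.sort(np.asarray(self.reference_abs_r, dtype=float))
        self.null_abs_r = np.sort(np.asarray(self.null_abs_r, dtype=float))

    @staticmethod
    def _ecdf(values: np.ndarray) -> np.ndarray:
        n = len(values)
        return np.arange(1, n + 1) / n if n else np.empty(0)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for label, values in (("reference", self.reference_abs_r), ("null", self.null_abs_r)):
            if len(values):
                parts.append(pd.DataFrame(
                    {"group": label, "abs_r": values, "ecdf": self._ecdf(values)}
                ))
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=["group", "abs_r", "ecdf"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _as_symbols(genes: GeneSet | Sequence[str] | None, panel: ExpressionPanel) -> list[str]:
    if genes is None:
        return list(panel.genes)
    if isinstance(genes, GeneSet):
        return list(genes.symbols)
    return list(genes)


def _standardized_rows(panel: ExpressionPanel, genes: Sequence[str], method: str) -> np.ndarray:
    """Rows centred and scaled to unit norm, so r is a plain dot product.

    Spearman replaces each gene's values by average ranks first.  Rows with
    zero variance come back as all-NaN; callers decide how to drop them.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    x = panel.expression(list(genes)).astype(float)
    if method == "spearman":
        x = rankdata(x, axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = x / norms
    z[norms[:, 0] == 0.0] = np.nan
    return z


def _drop_zero_variance(panel: ExpressionPanel, genes: list[str]) -> list[str]:
    x = panel.expression(genes)
    flat = x.std(axis=1) == 0.0
    if flat.any():
        dropped = [g for g, f in zip(genes, flat) if f]
        logger.warning(
            "dropping %d zero-variance gene(s) from panel %r: correlation undefined (%s)",
            len(dropped), panel.individual_id, ", ".join(dropped[:10]),
        )
        genes = [g for g, f in zip(genes, flat) if not f]
    return genes


def pairwise_correlation(
    panel: ExpressionPanel,
    genes: GeneSet | Sequence[str] | None = None,
    *,
    method: str = "pearson",
) -> CorrelationMatrix:
    """All pairwise correlations among ``genes`` across the panel's samples.

    Genes whose expression vector has zero variance have no defined
    correlation; they are excluded from the result with a logged warning.
    """
    symbols = _drop_zero_variance(panel, _as_symbols(genes, panel))
    z = _standardized_rows(panel, symbols, method)
    r = z @ z.T
    return CorrelationMatrix(tuple(symbols), r, method, panel.individual_id)


def cross_correlation(
    panel: ExpressionPanel,
    rows: Sequence[str],
    cols: Sequence[str],
    *,
    method: str = "pearson",
) -> np.ndarray:
    """Rectangular |rows| × |cols| correlation block (no symmetry assumed)."""
    zr = _standardized_rows(panel, list(rows), method)
    zc = _standardized_rows(panel, list(cols), method)
    return np.clip(zr @ zc.T, -1.0, 1.0)


def combination_weights(
    per_individual: Sequence[CorrelationMatrix],
    *,
    time_period: str = "pooled",
) -> WeightVector:
    """Inverse-variance weights from per-individual correlation variability.

    For individual i, v_i is the sample variance of the off-diagonal
    correlation coefficients of that individual's matrix, and
    w_i = (1/v_i) / sum_j (1/v_j).  Individuals with greater correlation
    variability therefore get lower weight, and the weights sum to one.
    """
    if len(per_individual) < 2:
        raise ValueError("weight derivation needs at least two individuals")
    panel_genes = per_individual[0].genes
    for m in per_individual[1:]:
        if m.genes != panel_genes:
            raise ValueError("all correlation matrices must share the same gene panel")
    variances = np.array([m.upper_triangle().var(ddof=1) for m in per_individual])
    if (variances == 0.0).any():
        flat = [m.source for m, v in zip(per_individual, variances) if v == 0.0]
        raise ValueError(f"degenerate panel: zero correlation variance for {flat}")
    inv = 1.0 / variances
    return WeightVector(
        individual_ids=tuple(m.source for m in per_individual),
        w=inv / inv.sum(),
        time_period=time_period,
    )


def combine_correlations(
    per_individual: Sequence[CorrelationMatrix],
    weights: WeightVector,
) -> CorrelationMatrix:
    """Weighted sum of per-individual correlation matrices.

    Raw r values are combined (no Fisher-z transform); with weights summing
    to one the result is a convex combination, so every entry stays within
    [min_i r_i, max_i r_i] and in particular within [-1, 1].
    """
    if len(per_individual) != len(weights):
        raise ValueError("need exactly one weight per correlation matrix")
    panel_genes = per_individual[0].genes
    method = per_individual[0].method
    for m in per_individual[1:]:
        if m.genes != panel_genes:
            raise ValueError("misaligned gene panels: matrices must share the same genes")
        if m.method != method:
            raise ValueError("cannot combine matrices with different correlation methods")
    ids = tuple(m.source for m in per_individual)
    if ids != weights.individual_ids:
        raise ValueError(
            f"weights are for individuals {weights.individual_ids}, matrices are {ids}"
        )
    combined = np.tensordot(weights.w, np.stack([m.r for m in per_individual]), axes=1)
    return CorrelationMatrix(panel_genes, combined, method, f"combined:{weights.time_period}")


def combine_cross(blocks: Sequence[np.ndarray], weights: WeightVector) -> np.ndarray:
    """Weighted sum of rectangular per-individual correlation blocks."""
    if len(blocks) != len(weights):
        raise ValueError("need exactly one weight per block")
    return np.tensordot(weights.w, np.stack(blocks), axes=1)


def nearest_rank_quantile(values: np.ndarray, quantile: float) -> float:
    """Nearest-rank empirical quantile: the ceil(q*n)-th order statistic."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    k = math.ceil(quantile * values.size)
    return float(values[k - 1])


def common_genes(panels: Sequence[ExpressionPanel]) -> list[str]:
    """Genes present in every panel, in the first panel's order."""
    if not panels:
        raise ValueError("at least one panel required")
    shared = set(panels[0].genes)
    for p in panels[1:]:
        shared &= set(p.genes)
    return [g for g in panels[0].genes if g in shared]


def _weights_or_default(
    panels: Sequence[ExpressionPanel],
    weights: WeightVector | None,
    time_period: str,
) -> WeightVector:
    if weights is not None:
        ids = tuple(p.individual_id for p in panels)
        if weights.individual_ids != ids:
            raise ValueError(f"weights are for {weights.individual_ids}, panels are {ids}")
        return weights
    if len(panels) == 1:
        return WeightVector((panels[0].individual_id,), np.array([1.0]), time_period)
    raise ValueError("multi-individual panels require an explicit WeightVector")


def significance_cutoff(
    panels: Sequence[ExpressionPanel],
    *,
    weights: WeightVector | None = None,
    quantile: float = 0.95,
    n_sampled_pairs: int = 100_000,
    seed: int = 0,
    method: str = "pearson",
) -> ThresholdSpec:
    """Genome-wide |r| significance cut-off at the given quantile.

    Estimates the distribution of combined |r| over ``n_sampled_pairs``
    uniformly sampled distinct gene pairs from the whole dataset (sampling
    pairs rather than enumerating all ~n²/2 of them) and returns its
    nearest-rank empirical quantile.  With the default quantile of 0.95 this
    is the "top 5% of |r|" edge-significance rule.
    """
    if n_sampled_pairs < 100:
        raise ValueError("n_sampled_pairs < 100 gives an unstable cut-off estimate")
    universe = common_genes(panels)
    for panel in panels:
        universe = _drop_zero_variance(panel, universe)
    n = len(universe)
    if n < 2:
        raise ValueError("need at least two usable genes to sample pairs")

    rng = np.random.default_rng(seed)
    a = rng.integers(0, n, size=n_sampled_pairs)
    b = rng.integers(0, n, size=n_sampled_pairs)
    clash = a == b
    while clash.any():
        b[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = a == b

    weights = _weights_or_default(panels, weights, "pooled")
    per_panel = []
    for panel in panels:
        z = _standardized_rows(panel, universe, method)
        per_panel.append(np.einsum("ij,ij->i", z[a], z[b]))
    combined = np.tensordot(weights.w, np.stack(per_panel), axes=1)
    cutoff = nearest_rank_quantile(np.abs(combined), quantile)
    return ThresholdSpec(quantile=quantile, cutoff=cutoff,
                         n_sampled_pairs=n_sampled_pairs, seed=seed)


def null_distribution(
    panels: Sequence[ExpressionPanel],
    *,
    weights: WeightVector | None = None,
    n_genes: int = 1000,
    exclude: Sequence[str] = (),
    reference: CorrelationMatrix | None = None,
    method: str = "pearson",
    seed: int = 0,
) -> EcdfSummary:
    """Null |r| distribution from randomly chosen genes, for ECDF comparison.

    Draws ``n_genes`` genes uniformly without replacement from the dataset
    (excluding ``exclude`` — typically the reference and candidate genes, so
    the null is not contaminated by them), computes all pairwise combined
    correlations among them (n_genes·(n_genes−1)/2 pairs), and summarizes
    the |r| ECDF and the null medians.  If a reference correlation matrix is
    supplied, its pairwise |r| values are carried along for comparison.
    """
    universe = [g for g in common_genes(panels) if g not in set(exclude)]
    for panel in panels:
        universe = _drop_zero_variance(panel, universe)
    if n_genes > len(universe):
        raise ValueError(
            f"requested {n_genes} null genes but only {len(universe)} are available"
        )
    rng = np.random.default_rng(seed)
    chosen = [universe[i] for i in rng.choice(len(universe), size=n_genes, replace=False)]

    weights = _weights_or_default(panels, weights, "pooled")
    matrices = [pairwise_correlation(p, chosen, method=method) for p in panels]
    combined = combine_correlations(matrices, weights) if len(matrices) > 1 else matrices[0]
    null_r = combined.upper_triangle()
    reference_abs = reference.upper_triangle() if reference is not None else np.empty(0)
    return EcdfSummary(
        reference_abs_r=np.abs(reference_abs),
        null_abs_r=np.abs(null_r),
        median_r_null=float(np.median(null_r)),
        median_abs_r_null=float(np.median(np.abs(null_r))),
    )
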