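"""Synthetic multi-individual expression panels with planted co-expression.

Every downstream stage consumes only pairwise correlation structure, so a
single-factor-per-module linear model is sufficient to emulate the relevant
features of a real expression resource: modules of positively (or
negatively) co-expressed genes, approximately normal per-gene log
intensities, several individuals sharing the same module structure, and
heterogeneous per-individual noise so that inverse-variance combination
weights genuinely differ.

For a module with latent factor f ~ N(0, 1) per sample, a member gene with
signed loading λ takes the value λ·f + sqrt(1 − λ²)·ε with ε drawn from
N(0, noise_sd) (background genes are pure ε).  At unit noise the population
correlation of two members is exactly λ_i·λ_j — the closed form the tests
check against — while noisier individuals see attenuated and more variable
correlations, which is what drives their lower combination weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ExpressionPanel, GeneSet

__all__ = ["Module", "SyntheticSpec", "BenchmarkData", "generate_panels", "planted_benchmark"]


@dataclass(frozen=True)
class Module:
    """A co-expression module: member gene indices with signed loadings.

    A negative loading plants a gene that is negatively correlated with the
    positively loaded members (a "negative cluster" connected to the module
    through negative co-expression).
    """

    members: tuple[int, ...]
    loadings: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.members) != len(self.loadings):
            raise ValueError("one loading per member gene required")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate gene indices within a module")
        if any(abs(lam) >= 1.0 for lam in self.loadings):
            raise ValueError("loadings must satisfy |lambda| < 1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Panel dimensions, planted modules and per-individual noise levels."""

    n_individuals: int
    n_samples_per_individual: int
    n_genes: int
    modules: tuple[Module, ...] = field(default_factory=tuple)
    noise_sd_per_individual: tuple[float, ...] | None = None
    seed: int = 0
    time_period: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_samples_per_individual < 3 or self.n_genes < 1:
            raise ValueError("need >=1 individual, >=3 samples and >=1 gene")
        taken: set[int] = set()
        for module in self.modules:
            if set(module.members) & taken:
                raise ValueError("module memberships must be disjoint")
            taken |= set(module.members)
            if module.members and (max(module.members) >= self.n_genes or min(module.members) < 0):
                raise ValueError("module gene index out of range")
        if self.noise_sd_per_individual is not None:
            if len(self.noise_sd_per_individual) != self.n_individuals:
                raise ValueError("one noise SD per individual required")
            if any(sd <= 0 for sd in self.noise_sd_per_individual):
                raise ValueError("noise SDs must be positive")

    @property
    def noise_sds(self) -> tuple[float, ...]:
        if self.noise_sd_per_individual is None:
            return (1.0,) * self.n_individuals
        return tuple(self.noise_sd_per_individual)


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_panels(spec: SyntheticSpec) -> list[ExpressionPanel]:
    """Draw one expression panel per individual under the factor model.

    Individuals share the module structure (members and loadings) but have
    independent latent factors, independent noise, and possibly different
    noise SDs.  Output is reproducible for a given spec seed: each
    individual gets an independent child stream of the spec's seed.
    """
    names = gene_names(spec.n_genes)
    samples = [f"S{j:04d}" for j in range(spec.n_samples_per_individual)]
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_individuals)

    panels = []
    for i, (sd, stream) in enumerate(zip(spec.noise_sds, streams)):
        rng = np.random.default_rng(stream)
        values = rng.normal(0.0, sd, size=(spec.n_genes, spec.n_samples_per_individual))
        for module in spec.modules:
            factor = rng.normal(size=spec.n_samples_per_individual)
            lam = np.asarray(module.loadings)[:, None]
            rows = list(module.members)
            values[rows] = lam * factor + np.sqrt(1.0 - lam**2) * values[rows]
        panels.append(
            ExpressionPanel(
                individual_id=f"ind{i + 1}",
                time_period=spec.time_period,
                genes=list(names),
                samples=list(samples),
                values=values,
            )
        )
    return panels


@dataclass(frozen=True)
class BenchmarkData:
    """Panels plus gene sets and ground truth for a planted benchmark."""

    panels: tuple[ExpressionPanel, ...]
    reference: GeneSet
    candidates: GeneSet
    true_candidates: tuple[str, ...]
    decoys: tuple[str, ...]
    spec: SyntheticSpec


def planted_benchmark(
    *,
    n_reference: int = 29,
    n_true_candidates: int = 10,
    n_decoys: int = 50,
    n_genes: int = 1200,
    n_individuals: int = 4,
    n_samples: int = 100,
    loading: float = 0.9,
    noise_sd_per_individual: Sequence[float] | None = None,
    seed: int = 0,
) -> BenchmarkData:
    """A recovery benchmark: reference genes and true candidates share a module.

    The first ``n_reference + n_true_candidates`` genes form one strongly
    loaded module (|λ| = ``loading``); decoys are background genes with no
    planted structure, drawn at random from the remainder.  The candidate
    list interleaves true candidates and decoys in shuffled order, and the
    truth labels are retained so recovery can be scored.  With
    ``n_true_candidates=0`` this is the all-null configuration used for
    eFDR calibration.
    """
    n_module = n_reference + n_true_candidates
    if n_module > n_genes:
        raise ValueError("module larger than the gene universe")
    if n_reference + n_true_candidates + n_decoys > n_genes:
        raise ValueError("not enough genes for reference, candidates and decoys")

    module = Module(members=tuple(range(n_module)), loadings=(loading,) * n_module) \
        if n_module else None
    spec = SyntheticSpec(
        n_individuals=n_individuals,
        n_samples_per_individual=n_samples,
        n_genes=n_genes,
        modules=(module,) if module else (),
        noise_sd_per_individual=(
            tuple(noise_sd_per_individual) if noise_sd_per_individual is not None else None
        ),
        seed=seed,
    )
    panels = generate_panels(spec)
    names = gene_names(n_genes)

    reference = GeneSet("reference", tuple(names[:n_reference]))
    true_cands = tuple(names[n_reference:n_module])
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(spec.n_individuals + 1)[-1])
    background = names[n_module:]
    decoys = tuple(background[i] for i in rng.choice(len(background), n_decoys, replace=False))

    candidate_symbols = list(true_cands) + list(decoys)
    rng.shuffle(candidate_symbols)
    candidates = GeneSet("candidates", tuple(candidate_symbols))

    return BenchmarkData(
        panels=tuple(panels),
        reference=reference,
        candidates=candidates,
        true_candidates=true_cands,
        decoys=decoys,
        spec=spec,
    )
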