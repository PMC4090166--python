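"""End-to-end orchestration: config handling, staged runs, reloadable outputs.

A run is driven by a single YAML config whose defaults match the method's
standard settings (top-5% |r| edge cut-off, eFDR target 0.25, 1000 null
genes, 1000 resamples).  Panels are grouped by time period and each group
is analysed independently, mirroring per-resource analysis; all outputs for
a group land in ``<out_dir>/<time_period>/`` as TSV/YAML so every stage is
individually reloadable and a later stage can resume from an earlier one's
files.  All randomness flows from one master seed via fixed per-stage
derived seeds, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import coexpression, compare, io, network, prioritize

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

STAGES = ("correlate", "prioritize", "network", "compare")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PanelSource:
    path: str
    individual_id: str | None = None
    time_period: str = "pooled"


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run (defaults = standard settings)."""

    panels: list[PanelSource]
    reference: str
    candidates: str
    out_dir: str
    probe_map: str | None = None
    annotations: str | None = None
    method: str = "pearson"
    quantile: float = 0.95
    efdr_target: float = 0.25
    n_null_genes: int = 1000
    n_resamples: int = 1000
    n_sampled_pairs: int = 100_000
    collapse_rule: str = "highest_median"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        panels = [PanelSource(**p) for p in raw.pop("panels", [])]
        if not panels:
            raise ValueError(f"{path}: config lists no expression panels")
        known = {f.name for f in dataclasses.fields(cls)} - {"panels"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(panels=panels, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(4)
        names = ("cutoff", "null", "efdr", "compare")
        return {n: int(s & 0x7FFFFFFF) for n, s in zip(names, state)}


def _load_panels(config: RunConfig) -> dict[str, list[io.ExpressionPanel]]:
    probe_map = io.read_probe_map(config.probe_map) if config.probe_map else None
    groups: dict[str, list[io.ExpressionPanel]] = {}
    for source in config.panels:
        panel = io.read_expression(
            source.path,
            individual_id=source.individual_id,
            time_period=source.time_period,
        )
        if probe_map is not None:
            panel = io.collapse_probes(panel, probe_map, rule=config.collapse_rule)
        groups.setdefault(panel.time_period, []).append(panel)
    return groups


def _write_gene_matching(path: Path, sets: Sequence[io.GeneSet]) -> None:
    rows = []
    for gs in sets:
        rows.append(
            {
                "set": gs.name,
                "requested": len(gs.symbols) + len(gs.missing),
                "matched": len(gs.symbols),
                "missing": len(gs.missing),
                "missing_symbols": ",".join(gs.missing),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _load_weights(path: Path) -> coexpression.WeightVector:
    frame = pd.read_csv(path, sep="\t")
    return coexpression.WeightVector(
        individual_ids=tuple(frame["individual"].astype(str)),
        w=frame["weight"].to_numpy(),
        time_period=str(frame["time_period"].iloc[0]),
    )


def _load_cutoff(path: Path) -> coexpression.ThresholdSpec:
    with open(path) as handle:
        return coexpression.ThresholdSpec(**yaml.safe_load(handle))


def _load_matrix(path: Path, method: str, source: str) -> coexpression.CorrelationMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return coexpression.CorrelationMatrix(
        tuple(frame.index.astype(str)), frame.to_numpy(), method, source
    )


def _load_connectivity(path: Path) -> prioritize.ConnectivityTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame["prioritized"] = frame["prioritized"].astype(bool)
    return prioritize.ConnectivityTable(frame)


class _GroupRun:
    """Analysis state for one time period, resumable from on-disk outputs."""

    def __init__(self, config: RunConfig, time_period: str,
                 panels: list[io.ExpressionPanel], out_dir: Path):
        self.config = config
        self.time_period = time_period
        self.panels = panels
        self.dir = out_dir
        self.dir.mkdir(parents=True, exist_ok=True)
        self.seeds = config.stage_seeds()

        shared = coexpression.common_genes(panels)
        universe_panel = panels[0]
        requested_ref = io.read_gene_list(config.reference, name="reference")
        requested_cand = io.read_gene_list(config.candidates, name="candidates")
        shared_set = set(shared)
        self.reference = io.GeneSet(
            "reference",
            tuple(g for g in requested_ref.symbols if g in shared_set),
            tuple(g for g in requested_ref.symbols if g not in shared_set),
        )
        cand_matched = [g for g in requested_cand.symbols if g in shared_set]
        overlap = [g for g in cand_matched if g in set(self.reference.symbols)]
        if overlap:
            logger.warning("dropping %d candidate(s) already in the reference set: %s",
                           len(overlap), ", ".join(overlap))
        self.candidates = io.GeneSet(
            "candidates",
            tuple(g for g in cand_matched if g not in set(overlap)),
            tuple(g for g in requested_cand.symbols if g not in shared_set),
        )
        logger.info("%s: %d of %d reference and %d of %d candidate genes present",
                    time_period, len(self.reference),
                    len(requested_ref), len(self.candidates), len(requested_cand))
        _write_gene_matching(self.dir / "gene_matching.tsv",
                             [self.reference, self.candidates])
        self._weights: coexpression.WeightVector | None = None
        self._cutoff: coexpression.ThresholdSpec | None = None
        self._reference_matrix: coexpression.CorrelationMatrix | None = None
        self._union_matrix: coexpression.CorrelationMatrix | None = None
        self._table: prioritize.ConnectivityTable | None = None

    # -- reloadable intermediates -------------------------------------------

    def weights(self) -> coexpression.WeightVector:
        if self._weights is None:
            path = self.dir / "weights.tsv"
            if path.exists():
                self._weights = _load_weights(path)
            else:
                if len(self.panels) == 1:
                    self._weights = coexpression.WeightVector(
                        (self.panels[0].individual_id,), np.array([1.0]), self.time_period
                    )
                else:
                    per_ind = [
                        coexpression.pairwise_correlation(
                            p, self.reference, method=self.config.method
                        )
                        for p in self.panels
                    ]
                    self._weights = coexpression.combination_weights(
                        per_ind, time_period=self.time_period
                    )
                self._weights.to_frame().to_csv(
                    path, sep="\t", index=False, float_format="%.6g"
                )
        return self._weights

    def cutoff(self) -> coexpression.ThresholdSpec:
        if self._cutoff is None:
            path = self.dir / "cutoff.yaml"
            if path.exists():
                self._cutoff = _load_cutoff(path)
            else:
                self._cutoff = coexpression.significance_cutoff(
                    self.panels,
                    weights=self.weights(),
                    quantile=self.config.quantile,
                    n_sampled_pairs=self.config.n_sampled_pairs,
                    seed=self.seeds["cutoff"],
                    method=self.config.method,
                )
                with open(path, "w") as handle:
                    yaml.safe_dump(dataclasses.asdict(self._cutoff), handle, sort_keys=True)
        return self._cutoff

    def _combined(self, genes: Sequence[str]) -> coexpression.CorrelationMatrix:
        matrices = [
            coexpression.pairwise_correlation(p, genes, method=self.config.method)
            for p in self.panels
        ]
        if len(matrices) == 1:
            m = matrices[0]
            return coexpression.CorrelationMatrix(
                m.genes, m.r, m.method, f"combined:{self.time_period}"
            )
        return coexpression.combine_correlations(matrices, self.weights())

    def reference_matrix(self) -> coexpression.CorrelationMatrix:
        if self._reference_matrix is None:
            path = self.dir / "reference_matrix.tsv"
            if path.exists():
                self._reference_matrix = _load_matrix(
                    path, self.config.method, f"combined:{self.time_period}"
                )
            else:
                self._reference_matrix = self._combined(list(self.reference.symbols))
                self._reference_matrix.to_tsv(path)
        return self._reference_matrix

    def union_matrix(self) -> coexpression.CorrelationMatrix:
        if self._union_matrix is None:
            union = list(self.reference.symbols) + list(self.candidates.symbols)
            self._union_matrix = self._combined(union)
        return self._union_matrix

    def connectivity(self) -> prioritize.ConnectivityTable:
        if self._table is None:
            path = self.dir / "connectivity.tsv"
            if path.exists():
                self._table = _load_connectivity(path)
            else:
                self.run_prioritize()
        return self._table

    # -- stages --------------------------------------------------------------

    def run_correlate(self) -> None:
        self.weights()
        ref_matrix = self.reference_matrix()
        self.cutoff()
        summary = coexpression.null_distribution(
            self.panels,
            weights=self.weights(),
            n_genes=self.config.n_null_genes,
            exclude=list(self.reference.symbols) + list(self.candidates.symbols),
            reference=ref_matrix,
            method=self.config.method,
            seed=self.seeds["null"],
        )
        summary.to_tsv(self.dir / "ecdf.tsv")
        pd.DataFrame(
            [{"median_r_null": summary.median_r_null,
              "median_abs_r_null": summary.median_abs_r_null}]
        ).to_csv(self.dir / "null_medians.tsv", sep="\t", index=False, float_format="%.6g")

    def run_prioritize(self) -> None:
        cutoff = self.cutoff().cutoff
        table = prioritize.connectivity_table(
            self.candidates, self.reference, self.union_matrix(), cutoff
        )
        curve = prioritize.efdr_curve(
            table,
            self.panels,
            self.reference,
            cutoff,
            weights=self.weights(),
            n_resamples=self.config.n_resamples,
            target=self.config.efdr_target,
            method=self.config.method,
            seed=self.seeds["efdr"],
        )
        table = prioritize.select_prioritized(table, curve)
        loo = prioritize.leave_one_out_connectivity(
            self.reference, self.reference_matrix(), cutoff
        )
        table.to_tsv(self.dir / "connectivity.tsv")
        loo.to_tsv(self.dir / "loo_connectivity.tsv")
        curve.to_tsv(self.dir / "efdr_curve.tsv")
        chosen = curve.chosen_for(self.config.efdr_target)
        with open(self.dir / "efdr_threshold.yaml", "w") as handle:
            yaml.safe_dump(
                {"target": self.config.efdr_target,
                 "chosen_T": None if chosen is None else float(chosen)},
                handle, sort_keys=True,
            )
        with open(self.dir / "prioritized.txt", "w") as handle:
            for gene in table.prioritized_genes():
                handle.write(gene + "\n")
        self._table = table

    def run_network(self) -> None:
        ref_matrix = self.reference_matrix()
        ordering = network.angular_order(ref_matrix)
        ordering.to_frame().to_csv(
            self.dir / "ordering.tsv", sep="\t", index=False, float_format="%.6g"
        )
        network.cross_order(ref_matrix, ordering).to_tsv(self.dir / "ordered_matrix.tsv")

        table = self.connectivity()
        chosen = io.GeneSet("prioritized", tuple(table.prioritized_genes()))
        shown = list(self.reference.symbols) + list(chosen.symbols)
        edges = network.build_network(
            self.union_matrix().submatrix(shown),
            self.cutoff().cutoff,
            self.reference,
            chosen,
        )
        edges.to_tsv(self.dir / "edges.tsv")
        edges.to_graphml(self.dir / "edges.graphml")

    def run_compare(self) -> None:
        if self.config.annotations is None:
            logger.info("%s: no annotation table supplied; skipping comparisons",
                        self.time_period)
            return
        annotations = compare.AnnotationTable.read_tsv(self.config.annotations)
        results = compare.compare_resources(
            self.connectivity(), annotations,
            n_permutations=self.config.n_resamples, seed=self.seeds["compare"],
        )
        results.to_csv(self.dir / "comparisons.tsv", sep="\t",
                       index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, stages: Sequence[str] = STAGES) -> Path:
    """Run the requested stages for every time-period group of panels.

    Returns the output directory.  Any stage failure is re-raised as a
    :class:`PipelineError` naming the stage.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "resolved_config.yaml")

    groups = _load_panels(config)
    for time_period, panels in groups.items():
        run = _GroupRun(config, time_period, panels, out_dir / time_period)
        for stage in STAGES:
            if stage not in stages:
                continue
            try:
                getattr(run, f"run_{stage}")()
            except Exception as exc:
                raise PipelineError(f"stage {stage!r} ({time_period}): {exc}") from exc
    return out_dir
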