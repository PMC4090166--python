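"""Reading expression matrices, probe maps and gene lists.

File conventions
----------------
Expression matrices are plain-text tables, genes (or probes) in rows and
samples in columns: the header row holds sample identifiers and the first
column holds gene/probe identifiers.  Tab- and comma-delimited files are
both accepted (the delimiter is inferred from the file extension unless
given explicitly).  Values are log-scale intensities; empty or non-numeric
cells are a parse error, not missing data — input matrices are expected to
be complete and already normalized.

Probe maps are two- or three-column tab-delimited tables with a header row:
``probe_id``, ``gene_symbol`` and optionally ``transcript_length`` (bp).

Gene lists are plain text, one symbol per line; ``#`` starts a comment and
blank lines are ignored.  Symbols are matched case-sensitively after
whitespace trimming; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ProbeMap",
    "ExpressionPanel",
    "GeneSet",
    "read_expression",
    "read_probe_map",
    "read_gene_list",
    "collapse_probes",
    "match_genes",
]

MIN_SAMPLES = 3  # a sample correlation needs at least three points


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class ProbeMap:
    """Many-to-one map from microarray probes to gene symbols.

    Parameters
    ----------
    frame
        Indexed by ``probe_id``; columns ``gene_symbol`` and, optionally,
        ``transcript_length`` (positive integers, base pairs).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dups = sorted(self.frame.index[self.frame.index.duplicated()].unique())
            raise ValueError(f"duplicate probe ids in probe map: {dups}")
        if "gene_symbol" not in self.frame.columns:
            raise ValueError("probe map needs a gene_symbol column")
        if "transcript_length" in self.frame.columns:
            lengths = self.frame["transcript_length"].dropna()
            if (lengths <= 0).any():
                raise ValueError("transcript_length values must be positive")

    @property
    def has_lengths(self) -> bool:
        return "transcript_length" in self.frame.columns

    def gene_of(self, probe_id: str) -> str:
        return self.frame.at[probe_id, "gene_symbol"]


@dataclass
class ExpressionPanel:
    """One individual's genes × samples log-intensity matrix.

    ``values[i, j]`` is the expression of ``genes[i]`` in ``samples[j]``.
    Gene identifiers must be unique within a panel; at least three samples
    are required so downstream correlations are defined.
    """

    individual_id: str
    time_period: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        seen: set[str] = set()
        dups = sorted({g for g in self.genes if g in seen or seen.add(g)})
        if dups:
            raise ValueError(f"duplicate gene identifiers in panel: {dups}")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.samples) < MIN_SAMPLES:
            raise ValueError(
                f"panel {self.individual_id!r} has {len(self.samples)} samples; "
                f"at least {MIN_SAMPLES} are required"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def expression(self, genes: list[str]) -> np.ndarray:
        """Rows of the value matrix for the requested genes, in order."""
        index = self.gene_index()
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from panel {self.individual_id!r}: {missing}")
        return self.values[[index[g] for g in genes]]

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, index=self.genes, columns=self.samples)
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class GeneSet:
    """A named gene list, optionally recording symbols a dataset lacked."""

    name: str
    symbols: tuple[str, ...]
    missing: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"gene set {self.name!r} contains duplicate symbols")
        overlap = set(self.symbols) & set(self.missing)
        if overlap:
            raise ValueError(f"symbols both matched and missing: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    *,
    delimiter: str | None = None,
    individual_id: str | None = None,
    time_period: str = "pooled",
) -> ExpressionPanel:
    """Parse a genes × samples expression table into a panel.

    Raises :class:`ParseError` (with a line number where applicable) for an
    empty file, duplicate sample or gene identifiers, ragged rows, or
    non-numeric cells.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)

    with open(path) as handle:
        header_line = handle.readline()
    if not header_line.strip():
        raise ParseError(f"{path}: empty file or blank header (line 1)")
    header = [h.strip() for h in header_line.rstrip("\n").split(sep)]
    sample_ids = header[1:]
    if not sample_ids:
        raise ParseError(f"{path}: header has no sample columns (line 1)")
    dup_samples = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dup_samples:
        raise ParseError(f"{path}: duplicate sample ids in header (line 1): {dup_samples}")

    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str, skip_blank_lines=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file (line 1)") from exc
    if frame.empty:
        raise ParseError(f"{path}: no data rows (line 2)")

    genes = [str(g).strip() for g in frame.index]
    dup_genes = sorted({g for g in genes if genes.count(g) > 1})
    if dup_genes:
        raise ParseError(f"{path}: duplicate gene identifiers: {dup_genes}")

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ParseError(
            f"{path}: non-numeric or empty cell at line {i + 2}, "
            f"gene {genes[i]!r}, sample {frame.columns[j]!r}"
        )

    return ExpressionPanel(
        individual_id=individual_id or path.stem,
        time_period=time_period,
        genes=genes,
        samples=[str(c).strip() for c in frame.columns],
        values=numeric.to_numpy(dtype=float),
    )


def read_probe_map(path: str | Path, *, delimiter: str = "\t") -> ProbeMap:
    """Read a probe → gene table (header: probe_id, gene_symbol[, transcript_length])."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty probe map") from exc
    required = {"probe_id", "gene_symbol"}
    if not required <= set(frame.columns):
        raise ParseError(
            f"{path}: probe map header must contain {sorted(required)}, got {list(frame.columns)}"
        )
    frame["probe_id"] = frame["probe_id"].astype(str).str.strip()
    frame["gene_symbol"] = frame["gene_symbol"].astype(str).str.strip()
    return ProbeMap(frame.set_index("probe_id"))


def read_gene_list(path: str | Path, *, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; duplicates are dropped with a warning."""
    path = Path(path)
    symbols: list[str] = []
    seen: set[str] = set()
    with open(path) as handle:
        for raw in handle:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line in seen:
                logger.warning("%s: dropping duplicate gene symbol %r", path, line)
                continue
            seen.add(line)
            symbols.append(line)
    return GeneSet(name=name or path.stem, symbols=tuple(symbols))


def collapse_probes(
    panel: ExpressionPanel,
    probe_map: ProbeMap,
    *,
    rule: str = "highest_median",
) -> ExpressionPanel:
    """Collapse a probe-level panel to one representative row per gene.

    ``rule="highest_median"`` keeps, per gene, the probe with the largest
    median expression across this panel's samples (medians are computed per
    individual panel).  ``rule="longest_transcript"`` keeps the probe whose
    transcript is longest in base pairs and requires the probe map to carry
    transcript lengths.  Ties are broken by the lexicographically smallest
    probe id so the choice is deterministic.
    """
    if rule not in ("highest_median", "longest_transcript"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    if rule == "longest_transcript" and not probe_map.has_lengths:
        raise ValueError("longest_transcript rule requires transcript_length in the probe map")

    mapped = probe_map.frame
    unmapped = [p for p in panel.genes if p not in mapped.index]
    if unmapped:
        raise ValueError(f"probes absent from probe map: {unmapped}")

    if rule == "highest_median":
        keys = np.median(panel.values, axis=1)
    else:
        keys = mapped.loc[panel.genes, "transcript_length"].to_numpy(dtype=float)

    # Per gene, keep the probe with the largest key; ties -> smallest probe id.
    best: dict[str, tuple[float, str, int]] = {}
    gene_order: list[str] = []
    for row, probe in enumerate(panel.genes):
        gene = mapped.at[probe, "gene_symbol"]
        candidate = (keys[row], probe, row)
        if gene not in best:
            best[gene] = candidate
            gene_order.append(gene)
        else:
            key, kept_probe, _ = best[gene]
            if candidate[0] > key or (candidate[0] == key and probe < kept_probe):
                best[gene] = candidate

    rows = [best[g][2] for g in gene_order]
    return ExpressionPanel(
        individual_id=panel.individual_id,
        time_period=panel.time_period,
        genes=gene_order,
        samples=list(panel.samples),
        values=panel.values[rows],
    )


def match_genes(panel: ExpressionPanel, requested: GeneSet) -> GeneSet:
    """Partition a requested gene set into panel-matched and missing symbols.

    Missingness is data, not an error: genes absent from an expression
    resource are simply excluded from analysis there, and the returned set
    records them so the loss can be reported.
    """
    universe = set(panel.genes)
    matched = tuple(g for g in requested.symbols if g in universe)
    missing = tuple(g for g in requested.symbols if g not in universe)
    if missing:
        logger.info(
            "%d of %d genes in set %r absent from panel %r",
            len(missing), len(requested), requested.name, panel.individual_id,
        )
    return GeneSet(name=requested.name, symbols=matched, missing=missing)
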