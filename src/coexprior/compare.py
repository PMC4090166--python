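"""Group comparisons of connectivity scores against external evidence.

Candidates flagged by an independent resource (genic intolerance, prior
neurological-disease evidence, variant deleteriousness predictions, ...)
should, if connectivity carries real signal, score higher than unflagged
candidates.  The comparison is a one-sided two-sample Mann-Whitney rank-sum
test with continuity correction (alternative: flagged group higher),
reported both from the asymptotic normal approximation and from a label
permutation test, which guards the asymptotic p-value against dependence
between data points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .prioritize import ConnectivityTable

__all__ = ["AnnotationTable", "GroupTestResult", "group_test", "compare_resources"]


@dataclass
class AnnotationTable:
    """Per-gene binary evidence flags; NA marks a gene a resource did not assess."""

    frame: pd.DataFrame  # index: gene; columns: boolean flags with NA allowed

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dups = sorted(self.frame.index[self.frame.index.duplicated()].unique())
            raise ValueError(f"duplicate genes in annotation table: {dups}")
        for col in self.frame.columns:
            values = self.frame[col].dropna().unique()
            if not set(values) <= {0, 1, True, False}:
                raise ValueError(f"flag {col!r} has non-binary values: {sorted(values)}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AnnotationTable":
        """Read a TSV with a ``gene`` column and flag columns in {0, 1, NA}."""
        frame = pd.read_csv(path, sep="\t", na_values=["NA", ""])
        if "gene" not in frame.columns:
            raise ValueError(f"{path}: annotation table needs a 'gene' column")
        return cls(frame.set_index("gene"))

    @property
    def flags(self) -> list[str]:
        return list(self.frame.columns)

    def flag(self, name: str) -> pd.Series:
        return self.frame[name]


@dataclass(frozen=True)
class GroupTestResult:
    flag: str
    score_type: str
    n_flagged: int
    n_unflagged: int
    statistic: float  # Mann-Whitney U of the flagged group
    p_asymptotic: float
    p_permutation: float


def _one_sided_u(flagged: np.ndarray, unflagged: np.ndarray) -> tuple[float, float]:
    result = mannwhitneyu(
        flagged, unflagged, alternative="greater", use_continuity=True, method="asymptotic"
    )
    return float(result.statistic), float(result.pvalue)


def group_test(
    scores: Mapping[str, float] | pd.Series,
    flags: Mapping[str, object] | pd.Series,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
    flag_name: str = "flag",
    score_type: str = "K",
) -> GroupTestResult:
    """One-sided Mann-Whitney comparison of flagged vs unflagged scores.

    Genes with a missing flag are excluded (not assessed is not the same as
    unflagged).  The permutation p-value shuffles group labels
    ``n_permutations`` times and uses the add-one estimator
    (1 + #{permuted U ≥ observed U}) / (1 + n_permutations), so it is never
    exactly zero.
    """
    scores = pd.Series(scores, dtype=float)
    flags = pd.Series(flags).reindex(scores.index)
    assessed = flags.notna()
    scores, flags = scores[assessed], flags[assessed].astype(bool)
    n1, n0 = int(flags.sum()), int((~flags).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(
            f"flag {flag_name!r}: both groups must be nonempty (flagged={n1}, unflagged={n0})"
        )

    values = scores.to_numpy()
    labels = flags.to_numpy()
    u_obs, p_asym = _one_sided_u(values[labels], values[~labels])

    # Labels are permuted over fixed scores, so the rank vector is computed
    # once; U = (rank sum of the flagged subset) - n1*(n1+1)/2.
    ranks = rankdata(values)
    offset = n1 * (n1 + 1) / 2.0
    rng = np.random.default_rng(seed)
    n = len(values)
    exceed = 0
    for _ in range(n_permutations):
        idx = rng.choice(n, size=n1, replace=False)
        if ranks[idx].sum() - offset >= u_obs:
            exceed += 1
    p_perm = (1 + exceed) / (1 + n_permutations)

    return GroupTestResult(
        flag=flag_name,
        score_type=score_type,
        n_flagged=n1,
        n_unflagged=n0,
        statistic=u_obs,
        p_asymptotic=p_asym,
        p_permutation=p_perm,
    )


def compare_resources(
    table: ConnectivityTable,
    annotations: AnnotationTable,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the group test for every flag and both connectivity scores.

    Returns a tidy frame (flag, score_type, group sizes, U, both p-values);
    flags with an empty group are skipped with a note in the frame absent.
    """
    rows = []
    for i, flag in enumerate(annotations.flags):
        flag_values = annotations.flag(flag).reindex(table.frame.index)
        for j, score_type in enumerate(("K_star", "K")):
            scores = table.frame[score_type]
            try:
                result = group_test(
                    scores,
                    flag_values,
                    n_permutations=n_permutations,
                    seed=seed + 1000 * i + j,
                    flag_name=flag,
                    score_type=score_type,
                )
            except ValueError:
                continue
            rows.append(result.__dict__)
    return pd.DataFrame(rows)
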