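import numpy as np
import pytest

from coexprior import CorrelationMatrix, ExpressionPanel, GeneSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel(rng):
    """Ten independent genes, 50 samples — no planted structure."""
    genes = [f"G{i}" for i in range(10)]
    return ExpressionPanel(
        individual_id="ind1",
        time_period="pooled",
        genes=genes,
        samples=[f"S{j}" for j in range(50)],
        values=rng.normal(size=(10, 50)),
    )


def make_panel(values, individual_id="ind1", time_period="pooled"):
    values = np.asarray(values, dtype=float)
    return ExpressionPanel(
        individual_id=individual_id,
        time_period=time_period,
        genes=[f"G{i}" for i in range(values.shape[0])],
        samples=[f"S{j}" for j in range(values.shape[1])],
        values=values,
    )


def make_corr(r, genes=None, method="pearson", source="ind1"):
    r = np.asarray(r, dtype=float)
    genes = genes or [f"G{i}" for i in range(r.shape[0])]
    return CorrelationMatrix(tuple(genes), r, method, source)


def two_block_matrix(n1=4, n2=4, within=0.8, between=0.0):
    """Block-diagonal correlation structure: two positive clusters."""
    n = n1 + n2
    r = np.full((n, n), between)
    r[:n1, :n1] = within
    r[n1:, n1:] = within
    np.fill_diagonal(r, 1.0)
    return make_corr(r)


@pytest.fixture
def reference_set():
    return GeneSet("reference", ("R1", "R2", "R3"))
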