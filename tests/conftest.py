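import numpy as np
import pandas as pd
import pytest

from regscreen.preprocess import ExpressionDataset, TimeGrid


@pytest.fixture
def grid():
    return TimeGrid(start_min=0.0, step_min=20.0, n_points=19)


@pytest.fixture
def small_grid():
    return TimeGrid(start_min=0.0, step_min=20.0, n_points=5)


def make_dataset(donor_id, values, grid, ids=None, flags=None, symbols=None):
    """Assemble an ExpressionDataset from a plain array."""
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"T{i:03d}" for i in range(values.shape[0])]
    index = pd.Index(ids, name="transcript_id")
    cols = [f"{t:g}" for t in grid.times]
    vdf = pd.DataFrame(values, index=index, columns=cols)
    fdf = None
    if flags is not None:
        fdf = pd.DataFrame(np.asarray(flags, dtype=object), index=index, columns=cols)
    sser = None
    if symbols is not None:
        sser = pd.Series(list(symbols), index=index, name="gene_symbol")
    return ExpressionDataset(
        donor_id=donor_id, values=vdf, grid=grid, gene_symbols=sser, flags=fdf
    )


@pytest.fixture
def make_ds():
    return make_dataset


def write_expr_tsv(path, ids, values, times, symbols=None):
    """Write an expression table in the dialect read_expression_table expects."""
    with open(path, "w") as fh:
        header = ["transcript_id"]
        if symbols is not None:
            header.append("gene_symbol")
        header += [f"{t:g}" for t in times]
        fh.write("\t".join(header) + "\n")
        for i, tid in enumerate(ids):
            row = [tid]
            if symbols is not None:
                row.append(symbols[i])
            row += [f"{v:.6g}" for v in values[i]]
            fh.write("\t".join(row) + "\n")


@pytest.fixture
def expr_writer():
    return write_expr_tsv
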