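"""Genome-scale all-2-one sweep: every transcript as candidate regulator of
fixed target outputs, per donor, with delay scanning, cross-donor
sign-consistency filtering, descending fitness ranking and a top-percentile
cut.

The sweep fits one delayed first-order model per (input transcript, output
transcript, donor) triple, retaining for each triple only the best delay on
the configured grid. Because every input shares the same output series within
a (donor, output, delay) slice, the ordinary-least-squares fits are solved in
a single batched singular-value decomposition, which keeps a full-genome
sweep (tens of thousands of fits) in the seconds range. The batched path is
numerically identical to :func:`regscreen.dynamics.fit_pairwise` (both are
SVD least squares; a dedicated test pins the equivalence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import ACTIVATOR, REPRESSOR, PairwiseFit, PairwiseModel
from .preprocess import ExpressionDataset

__all__ = [
    "ScreenConfig",
    "ScreenTable",
    "GeneSummary",
    "all2one",
    "consistency_filter",
    "rank_models",
    "top_percentile",
    "collapse_to_genes",
    "candidate_filters",
]

DEFAULT_DELAY_GRID_MIN = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of one all-2-one run.

    ``ranking_donor`` names the donor whose fitness orders the final table
    (None defers to the pipeline default: the second donor supplied).
    ``top_fraction`` is the percentile cut applied after ranking.
    """

    target_output_ids: tuple[str, ...]
    delay_grid_min: tuple[float, ...] = DEFAULT_DELAY_GRID_MIN
    ranking_donor: str | None = None
    top_fraction: float = 0.025
    consistency_mode: str = "per-output-cross-donor"

    def __post_init__(self) -> None:
        if not self.target_output_ids:
            raise ValueError("at least one target output id is required")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        grid = tuple(float(d) for d in self.delay_grid_min)
        if len(grid) == 0 or any(d < 0 for d in grid):
            raise ValueError("delay grid must be non-empty and non-negative")
        if list(grid) != sorted(grid):
            raise ValueError("delay grid must be sorted ascending")
        if self.consistency_mode != "per-output-cross-donor":
            raise ValueError(f"unknown consistency_mode {self.consistency_mode!r}")
        object.__setattr__(self, "target_output_ids", tuple(self.target_output_ids))
        object.__setattr__(self, "delay_grid_min", grid)


# ---------------------------------------------------------------------------
# batched delay-scan fitting


def _batch_fit_single_delay(
    U: np.ndarray, y: np.ndarray, d: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS-fit y[k+1] = a*y[k] + b*u[k-d] + c for every input row of U.

    Returns (theta (n,3), fitness (n,), degenerate (n,)). Fitness of a
    degenerate fit is NaN. Identical estimator to the per-pair path: SVD
    least squares with NumPy's default rank cutoff.
    """
    n_inputs, n = U.shape
    y_win = y[d:]
    m = n - d  # usable window length
    rows = m - 1
    a0 = y_win[:-1]
    z = y_win[1:]
    b = U[:, : rows]  # u[k-d] for k = d .. n-2
    X = np.empty((n_inputs, rows, 3), dtype=float)
    X[:, :, 0] = a0
    X[:, :, 1] = b
    X[:, :, 2] = 1.0
    u_svd, s, vt = np.linalg.svd(X, full_matrices=False)
    # rank cutoff mirroring np.linalg.lstsq(rcond=None)
    tol = s[:, :1] * max(rows, 3) * np.finfo(float).eps
    ok = s > tol
    rank = ok.sum(axis=1)
    s_inv = np.where(ok, 1.0 / np.where(s == 0, 1.0, s), 0.0)
    proj = np.einsum("nri,r->ni", u_svd, z)
    theta = np.einsum("nij,ni->nj", vt, s_inv * proj)

    degenerate = (rank < 3) | (theta[:, 1] == 0.0)
    if np.ptp(y_win) == 0.0:
        degenerate[:] = True

    # free-run simulation from the observed y[d]
    yhat = np.empty((n_inputs, m), dtype=float)
    yhat[:, 0] = y_win[0]
    alpha, beta, gamma = theta[:, 0], theta[:, 1], theta[:, 2]
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(m - 1):
            yhat[:, i + 1] = alpha * yhat[:, i] + beta * b[:, i] + gamma
        denom = np.linalg.norm(y_win - y_win.mean())
        if denom == 0.0:
            fitness = np.full(n_inputs, np.nan)
        else:
            resid = np.linalg.norm(y_win[None, :] - yhat, axis=1)
            fitness = 100.0 * (1.0 - resid / denom)
    fitness = np.where(np.isnan(fitness), -np.inf, fitness)
    fitness = np.where(degenerate, np.nan, fitness)
    return theta, fitness, degenerate


def _batch_delay_scan(
    U: np.ndarray, y: np.ndarray, delays: Sequence[int]
) -> dict[str, np.ndarray]:
    """Best-delay fit per input row; ties broken toward the smallest delay."""
    n_inputs, n = U.shape
    best_fit = np.full(n_inputs, -np.inf)
    best_theta = np.zeros((n_inputs, 3))
    best_delay = np.full(n_inputs, min(delays), dtype=int)
    any_ok = np.zeros(n_inputs, dtype=bool)
    for d in sorted(int(d) for d in delays):
        if not 0 <= d < n - 2 or (n - d) < 4:
            raise ValueError(f"delay of {d} steps is invalid for series length {n}")
        theta, fitness, degenerate = _batch_fit_single_delay(U, y, d)
        cand = ~degenerate & (fitness > best_fit)
        best_fit[cand] = fitness[cand]
        best_theta[cand] = theta[cand]
        best_delay[cand] = d
        any_ok |= ~degenerate
    best_fit[~any_ok] = np.nan
    return {
        "theta": best_theta,
        "fitness": best_fit,
        "delay_steps": best_delay,
        "degenerate": ~any_ok,
        "n_fit_points": n - best_delay,
    }


def all2one(
    datasets: Sequence[ExpressionDataset],
    cfg: ScreenConfig,
) -> list[PairwiseFit]:
    """Fit every (input transcript, target output, donor) triple at its best
    delay.

    All datasets must share the same transcript ids in the same order (use
    :func:`regscreen.preprocess.intersect_donors` first). Target transcripts
    are never used as their own inputs.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    ref_ids = datasets[0].transcript_ids
    for ds in datasets[1:]:
        if ds.transcript_ids != ref_ids:
            raise ValueError(
                "datasets must share an identical transcript-id ordering; "
                "run intersect_donors first"
            )
    for target in cfg.target_output_ids:
        for ds in datasets:
            if target not in ds.values.index:
                raise ValueError(
                    f"target transcript {target!r} absent from donor {ds.donor_id!r}"
                )
    grid = datasets[0].grid
    delays = [grid.delay_min_to_steps(d) for d in cfg.delay_grid_min]
    target_set = set(cfg.target_output_ids)
    input_ids = [t for t in ref_ids if t not in target_set]

    fits: list[PairwiseFit] = []
    for ds in datasets:
        U = ds.values.loc[input_ids].to_numpy(dtype=float)
        for output_id in cfg.target_output_ids:
            y = ds.series(output_id)
            res = _batch_delay_scan(U, y, delays)
            theta = res["theta"]
            for i, input_id in enumerate(input_ids):
                degenerate = bool(res["degenerate"][i])
                d = int(res["delay_steps"][i])
                if degenerate:
                    model = PairwiseModel(0.0, 0.0, 0.0, d, grid.step_min)
                    fit_val, sign = math.nan, None
                else:
                    model = PairwiseModel(
                        float(theta[i, 0]), float(theta[i, 1]), float(theta[i, 2]),
                        d, grid.step_min,
                    )
                    fit_val = float(res["fitness"][i])
                    sign = model.sign
                fits.append(
                    PairwiseFit(
                        model=model,
                        fitness=fit_val,
                        sign=sign,
                        n_fit_points=int(res["n_fit_points"][i]),
                        degenerate=degenerate,
                        input_id=input_id,
                        output_id=output_id,
                        donor_id=ds.donor_id,
                    )
                )
    return fits


def consistency_filter(
    fits: Iterable[PairwiseFit],
    cfg: ScreenConfig,
) -> tuple[list[PairwiseFit], dict[str, str]]:
    """Discard inputs whose activator/repressor role disagrees across donors.

    For every target output transcript separately, the sign of the input gain
    must agree across all donors; one disagreement on any output discards all
    of the input's fits. Inputs with a degenerate fit for any (donor, output)
    are likewise discarded. Returns the retained fits and a map of discarded
    input id -> reason.
    """
    fits = list(fits)
    by_input: dict[str, list[PairwiseFit]] = {}
    for fit in fits:
        by_input.setdefault(fit.input_id, []).append(fit)  # type: ignore[arg-type]
    discarded: dict[str, str] = {}
    for input_id, group in by_input.items():
        if any(f.degenerate for f in group):
            discarded[input_id] = "degenerate fit in at least one donor/output"
            continue
        by_output: dict[str, set[str]] = {}
        for f in group:
            by_output.setdefault(f.output_id, set()).add(f.sign)  # type: ignore[arg-type]
        bad = [out for out, signs in by_output.items() if len(signs) > 1]
        if bad:
            discarded[input_id] = (
                f"activator/repressor sign disagrees across donors for output(s) {sorted(bad)}"
            )
    kept = [f for f in fits if f.input_id not in discarded]
    return kept, discarded


@dataclass(frozen=True)
class ScreenTable:
    """Ranked screen output: one row per retained (input, output) model.

    Columns: rank, input_id, gene_symbol, output_id, delay_min, fitness,
    sign, alpha, beta, gamma, n_fit_points and one ``fitness_<donor>`` column
    per donor. Fitness is non-increasing with rank.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.df):
            fit = self.df["fitness"].to_numpy()
            if np.any(np.diff(fit) > 1e-12):
                raise ValueError("fitness must be non-increasing with rank")
            ranks = self.df["rank"].to_numpy()
            if np.any(np.diff(ranks) <= 0):
                raise ValueError("ranks must be strictly increasing")

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path, decimals: int | None = None) -> None:
        df = self.df
        if decimals is not None:
            df = df.copy()
            for col in df.columns:
                if df[col].dtype.kind == "f":
                    df[col] = df[col].round(decimals)
        df.to_csv(path, sep="\t", index=False)


def rank_models(
    fits: Iterable[PairwiseFit],
    cfg: ScreenConfig,
    gene_symbols: Mapping[str, str] | None = None,
) -> ScreenTable:
    """Rank the retained (input, output) models of the ranking donor by
    descending fitness.

    Ties are broken lexicographically by input id (then output id). Other
    donors' fitness values are carried along as ``fitness_<donor>`` columns.
    """
    fits = [f for f in fits if not f.degenerate]
    donors = sorted({f.donor_id for f in fits if f.donor_id is not None})
    ranking_donor = cfg.ranking_donor
    if ranking_donor is None:
        if len(donors) > 1:
            ranking_donor = donors[1]
        elif donors:
            ranking_donor = donors[0]
    other_fitness: dict[tuple[str, str, str], float] = {
        (f.input_id, f.output_id, f.donor_id): f.fitness for f in fits
    }
    rows = []
    for f in fits:
        if f.donor_id != ranking_donor:
            continue
        symbol = "" if gene_symbols is None else str(gene_symbols.get(f.input_id, ""))
        row = {
            "input_id": f.input_id,
            "gene_symbol": symbol,
            "output_id": f.output_id,
            "delay_min": f.model.delay_min,
            "fitness": f.fitness,
            "sign": f.sign,
            "alpha": f.model.alpha,
            "beta": f.model.beta,
            "gamma": f.model.gamma,
            "n_fit_points": f.n_fit_points,
        }
        for donor in donors:
            row[f"fitness_{donor}"] = other_fitness.get(
                (f.input_id, f.output_id, donor), math.nan
            )
        rows.append(row)
    if not rows:
        return ScreenTable(pd.DataFrame(columns=["rank", "input_id", "gene_symbol",
                                                 "output_id", "delay_min", "fitness", "sign"]))
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["fitness", "input_id", "output_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return ScreenTable(df)


def top_percentile(table: ScreenTable, fraction: float) -> ScreenTable:
    """Keep the top ``ceil(fraction * n_rows)`` rows of a ranked table."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(table))
    return ScreenTable(table.df.head(k).reset_index(drop=True))


@dataclass(frozen=True)
class GeneSummary:
    """Gene-level collapse of a ranked table: best-ranked row per identity."""

    df: pd.DataFrame
    n_rows_in: int
    n_distinct: int

    @property
    def n_collapsed(self) -> int:
        return self.n_rows_in - self.n_distinct


def collapse_to_genes(table: ScreenTable) -> GeneSummary:
    """Collapse a ranked table to distinct gene identities.

    Identity is the annotation symbol when present; rows without a symbol
    (bare probeset ids) count as their own identities. Each gene keeps its
    best-ranked row.
    """
    df = table.df.copy()
    if "gene_symbol" in df.columns:
        symbol = df["gene_symbol"].fillna("").astype(str)
        df["identity"] = np.where(symbol.str.len() > 0, symbol, df["input_id"])
    else:
        df["identity"] = df["input_id"]
    collapsed = df.drop_duplicates(subset="identity", keep="first").reset_index(drop=True)
    return GeneSummary(df=collapsed, n_rows_in=len(df), n_distinct=len(collapsed))


def candidate_filters(
    table: ScreenTable,
    delay_window_min: tuple[float, float] = (20.0, 60.0),
    exclude_multi_gene: bool = True,
) -> ScreenTable:
    """Optional post-hoc shortlist filters on a ranked table.

    Drops rows whose annotation maps to multiple genes (symbols joined by
    ``///``) and rows whose best delay falls outside ``delay_window_min``
    (inclusive). Original ranks are preserved for traceability.
    """
    df = table.df
    keep = pd.Series(True, index=df.index)
    if exclude_multi_gene and "gene_symbol" in df.columns:
        keep &= ~df["gene_symbol"].fillna("").astype(str).str.contains("///", regex=False)
    lo, hi = delay_window_min
    keep &= (df["delay_min"] >= lo) & (df["delay_min"] <= hi)
    return ScreenTable(df[keep].reset_index(drop=True))
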