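"""Pipeline orchestration, run manifests and human-readable report data.

``run_pipeline`` chains the full screen — read, optional back-transform,
flag filter, intensity filter, donor intersection, all-2-one sweep,
cross-donor consistency filter, ranking, percentile cut — and records every
stage's bookkeeping in a :class:`RunManifest` so no row is lost silently.
``fitness_rank_curve`` serialises the fitness-versus-rank profile (the
steep-then-linear decay that motivates a top-percentile cut) as plain TSV
data for plotting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib import metadata, resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import (
    ConfigurationError,
    ExpressionDataset,
    FilterReport,
    TimeGrid,
    delog_transform,
    flag_filter,
    intensity_filter,
    intersect_donors,
    read_expression_table,
    read_flags_table,
)
from .screen import (
    ScreenConfig,
    ScreenTable,
    all2one,
    consistency_filter,
    rank_models,
    top_percentile,
)

__all__ = [
    "RunManifest",
    "StageError",
    "run_pipeline",
    "fitness_rank_curve",
    "load_table1_fixture",
    "FixtureError",
]

_FIXTURE_NAME = "published_ranking_176.tsv"
_FIXTURE_SHA256 = "48e317af27c7f49b950b0f700ad377e8ab13146968af08ef889202342a5fe792"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


class FixtureError(RuntimeError):
    """The packaged reference table is missing or corrupted."""


@dataclass
class RunManifest:
    """Machine-readable provenance of one screen run."""

    config: dict
    inputs: dict[str, str]  # path -> sha256 digest
    filter_counts: dict[str, dict]
    n_common_transcripts: int
    n_inputs: int
    n_outputs: int
    n_fits_before_consistency: int
    n_inputs_after_consistency: int
    n_models_ranked: int
    n_rows_top: int
    version: str
    created_utc: str

    def __post_init__(self) -> None:
        if self.n_models_ranked != self.n_inputs_after_consistency * self.n_outputs:
            raise ValueError(
                "bookkeeping mismatch: ranked models != retained inputs x outputs"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _version() -> str:
    try:
        return metadata.version("regscreen")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_pipeline(
    expr_paths: Sequence[str | Path],
    cfg: ScreenConfig,
    donor_ids: Sequence[str] | None = None,
    flags_paths: Sequence[str | Path] | None = None,
    grid: TimeGrid = TimeGrid(),
    delog: bool = False,
    skip_flag_filter: bool = False,
    mean_min: float = 50.0,
    peak_min: float = 100.0,
    outdir: str | Path | None = None,
) -> tuple[ScreenTable, RunManifest]:
    """Execute the full screen on per-donor expression tables.

    Returns the top-percentile ranked table and the run manifest. When
    ``outdir`` is given, writes the full ranked table (full precision), the
    top table rounded to two decimals, the fitness-rank curve, per-donor
    filter reports and the manifest there. Any stage failure is re-raised as
    :class:`StageError` naming the stage.
    """
    if donor_ids is None:
        donor_ids = [f"donor{i + 1}" for i in range(len(expr_paths))]
    if len(donor_ids) != len(expr_paths):
        raise ValueError("donor_ids must match expr_paths")
    if flags_paths is not None and len(flags_paths) != len(expr_paths):
        raise ValueError("flags_paths must match expr_paths")

    inputs_digest: dict[str, str] = {}
    datasets: list[ExpressionDataset] = []
    try:
        for i, path in enumerate(expr_paths):
            ds = read_expression_table(path, donor_ids[i], grid)
            inputs_digest[str(path)] = _digest(path)
            if flags_paths is not None:
                ds = read_flags_table(flags_paths[i], ds)
                inputs_digest[str(flags_paths[i])] = _digest(flags_paths[i])
            if delog:
                ds = ExpressionDataset(
                    donor_id=ds.donor_id,
                    values=delog_transform(ds.values),
                    grid=ds.grid,
                    gene_symbols=ds.gene_symbols,
                    flags=ds.flags,
                )
            datasets.append(ds)
    except Exception as exc:
        raise StageError("read", exc) from exc

    filter_counts: dict[str, dict] = {}
    filtered: list[ExpressionDataset] = []
    try:
        for ds in datasets:
            if skip_flag_filter:
                flag_rep = FilterReport(n_input=ds.n_transcripts, n_after_flag=ds.n_transcripts)
                after_flag = ds
            else:
                after_flag, flag_rep = flag_filter(ds)
            after_int, int_rep = intensity_filter(after_flag, mean_min, peak_min)
            report = FilterReport.merged(flag_rep, int_rep)
            filter_counts[ds.donor_id] = {
                "n_input": report.n_input,
                "n_after_flag": report.n_after_flag,
                "n_after_intensity": report.n_after_intensity,
            }
            filtered.append(after_int)
            if outdir is not None:
                outdir = Path(outdir)
                outdir.mkdir(parents=True, exist_ok=True)
                report.to_json(outdir / f"filter_report_{ds.donor_id}.json")
    except Exception as exc:
        raise StageError("filter", exc) from exc

    try:
        common = intersect_donors(filtered) if len(filtered) > 1 else list(filtered)
    except Exception as exc:
        raise StageError("intersect", exc) from exc

    try:
        fits = all2one(common, cfg)
    except Exception as exc:
        raise StageError("all2one", exc) from exc

    try:
        kept, discarded = consistency_filter(fits, cfg)
    except Exception as exc:
        raise StageError("consistency", exc) from exc

    try:
        symbols = None
        if common[0].gene_symbols is not None:
            symbols = common[0].gene_symbols.to_dict()
        ranked = rank_models(kept, cfg, gene_symbols=symbols)
        top = top_percentile(ranked, cfg.top_fraction)
    except Exception as exc:
        raise StageError("rank", exc) from exc

    n_outputs = len(cfg.target_output_ids)
    n_inputs = common[0].n_transcripts - len(
        set(cfg.target_output_ids) & set(common[0].transcript_ids)
    )
    manifest = RunManifest(
        config={
            "target_output_ids": list(cfg.target_output_ids),
            "delay_grid_min": list(cfg.delay_grid_min),
            "ranking_donor": cfg.ranking_donor,
            "top_fraction": cfg.top_fraction,
            "consistency_mode": cfg.consistency_mode,
            "delog": delog,
            "skip_flag_filter": skip_flag_filter,
            "mean_min": mean_min,
            "peak_min": peak_min,
        },
        inputs=inputs_digest,
        filter_counts=filter_counts,
        n_common_transcripts=common[0].n_transcripts,
        n_inputs=n_inputs,
        n_outputs=n_outputs,
        n_fits_before_consistency=len(fits),
        n_inputs_after_consistency=n_inputs - len(discarded),
        n_models_ranked=len(ranked),
        n_rows_top=len(top),
        version=_version(),
        created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ranked.to_tsv(outdir / "ranked_models.tsv")
        top.to_tsv(outdir / "top_models_report.tsv", decimals=2)
        fitness_rank_curve(ranked).to_csv(
            outdir / "fitness_rank_curve.tsv", sep="\t", index=False
        )
        manifest.to_json(outdir / "manifest.json")
    return top, manifest


def fitness_rank_curve(table: ScreenTable) -> pd.DataFrame:
    """Cumulative model count against fitness, for plotting the rank decay.

    Row i states: ``cumulative_models`` models reach ``fitness`` or higher.
    """
    df = table.df
    return pd.DataFrame(
        {
            "cumulative_models": np.arange(1, len(df) + 1),
            "fitness": df["fitness"].to_numpy() if len(df) else np.array([]),
        }
    )


_PROBE_SUFFIXES = ("_at",)


def load_table1_fixture() -> ScreenTable:
    """Load the packaged published reference ranking (176 top models).

    Each row carries the printed rank, identity (gene symbol, or bare
    probeset id where the annotation had no symbol), best delay in minutes
    and fitness in percent. The file's checksum is verified on load.
    """
    ref = resources.files("regscreen.data").joinpath(_FIXTURE_NAME)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:  # pragma: no cover
        raise FixtureError("packaged reference ranking is missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureError(
            f"reference ranking checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    import io

    df = pd.read_csv(io.BytesIO(raw), sep="\t")
    is_probe = df["identity"].str.endswith(_PROBE_SUFFIXES)
    out = pd.DataFrame(
        {
            "rank": df["rank"],
            "input_id": df["identity"],
            "gene_symbol": df["identity"].where(~is_probe, ""),
            "output_id": "",
            "delay_min": df["delay_min"].astype(float),
            "fitness": df["fitness"].astype(float),
        }
    )
    return ScreenTable(out)
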