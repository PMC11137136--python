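"""Synthetic two-donor time-series datasets with known ground truth.

The generator emulates the shape of the real screening input: two donors,
19 time points sampled every 20 minutes, strictly positive transcript
intensities in microarray-like arbitrary units, two target probesets
measuring the same underlying target transcript, and a configurable number of
decoy transcripts. Ground truth is a planted co-stimulated regulator module
driving the target through the delayed first-order law

    y[k+1] = alpha * y[k] + sum_r beta_r * u_r[k - d_r] + gamma  (+ noise)

with donor-specific magnitudes but activator/repressor signs shared across
donors, so planted regulators survive the cross-donor consistency filter by
construction.

World design (chosen once; see the package methods note):

* Every transcript has a characteristic response *shape* shared across
  donors — donors are biological replicates of the same stimulation — plus a
  small donor-specific deviation and scale jitter. Without shared shapes the
  cross-donor sign-consistency filter would discard essentially everything,
  which is not how replicate donors behave.
* Planted regulators form a coherent module: each follows a rise-and-fall
  stimulus-response pulse drawn from one kinetic family (time constant and
  shape exponent jittered per transcript), acts with a common sign, and with
  a latency clustered within one sampling step of a module delay. Scattered
  latencies or oscillatory programs make single-input fits of a jointly
  driven target unidentifiable at 19 time points.
* Decoys are independent low-order Fourier series (at most 3 harmonics over
  the 6-h span), mutually independent and independent of the target.

Noise is additive Gaussian on the observations (measurement noise), not on
the process. All randomness flows from one integer seed through
counter-based per-transcript streams, so any single series is reproducible
independently of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dynamics import PairwiseModel, simulate
from .preprocess import ExpressionDataset, TimeGrid

__all__ = [
    "SynthTruth",
    "generate_input_signal",
    "generate_target",
    "generate_screen_dataset",
]

DONOR_IDS = ("donor1", "donor2")
TARGET_IDS = ("TARGET_A", "TARGET_B")
TARGET_SYMBOL = "TARGET"

# world constants (intensity units are the arbitrary linear scale of
# background-corrected microarray intensities)
BASELINE_RANGE = (200.0, 600.0)  # per-transcript baseline intensity
TARGET_SCALE = 500.0             # order of magnitude of the target level
Y0_RANGE = (300.0, 700.0)        # target level at stimulation time
DONOR_SHAPE_DEV = 0.10           # donor-specific shape deviation (SD units)
DONOR_SCALE_JITTER = (0.8, 1.2)  # donor-specific multiplicative scale
KINETIC_JITTER = 0.15            # per-regulator jitter of pulse kinetics
PULSE_TAU_RANGE = (25.0, 55.0)   # module pulse time constant, minutes
PULSE_EXP_RANGE = (1.2, 2.5)     # module pulse shape exponent
REG_AMP_RANGE = (0.25, 0.45)     # regulator response amplitude (rel. baseline)
DECOY_AMP_RANGE = (0.10, 0.45)   # decoy response amplitude (rel. baseline)
INTENSITY_FLOOR = 5.0            # detection floor of the platform


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based stream: one generator per (seed, key) tuple."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _pulse_shape(t: np.ndarray, tau: float, p: float) -> np.ndarray:
    """Rise-and-fall stimulus-response pulse, zero before t=0, unit SD."""
    tp = np.maximum(t, 0.0)
    with np.errstate(invalid="ignore"):
        s = np.where(t > 0, (tp / (p * tau)) ** p * np.exp(p - tp / tau), 0.0)
    s = s - s.mean()
    return s / np.std(s)


def _fourier_shape(rng: np.random.Generator, t: np.ndarray, span: float) -> np.ndarray:
    """Random low-order Fourier series (<= 3 harmonics), unit SD."""
    s = np.zeros_like(t)
    for m in range(1, 4):
        s += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * m * t / span + rng.uniform(0, 2 * np.pi))
    return s / np.std(s)


@dataclass(frozen=True)
class SynthTruth:
    """Ground-truth generative specification of one synthetic screen.

    ``models[donor_id][regulator_id]`` holds the planted
    :class:`~regscreen.dynamics.PairwiseModel`; within a donor all planted
    models share ``alpha`` and ``gamma`` (the target's own dynamics and
    offset), and each regulator contributes its ``beta`` and delay to the
    joint recursion. ``noise_frac_of_sd`` scales observation noise to the
    clean target's standard deviation; ``noise_sd`` gives it in absolute
    intensity units instead (at most one of the two may be nonzero).
    ``inconsistent_regulator_ids`` name planted controls whose gain sign is
    deliberately flipped between donors (they must be discarded by the
    consistency filter).
    """

    true_regulator_ids: tuple[str, ...]
    models: dict[str, dict[str, PairwiseModel]]
    seed: int
    n_decoys: int
    grid: TimeGrid = TimeGrid()
    noise_sd: float = 0.0
    noise_frac_of_sd: float = 0.0
    inconsistent_regulator_ids: tuple[str, ...] = ()
    donor_ids: tuple[str, ...] = DONOR_IDS
    target_ids: tuple[str, ...] = TARGET_IDS

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.noise_frac_of_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.noise_sd > 0 and self.noise_frac_of_sd > 0:
            raise ValueError("specify noise_sd or noise_frac_of_sd, not both")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be non-negative")
        for rid in self.true_regulator_ids:
            signs = {np.sign(self.models[d][rid].beta) for d in self.donor_ids}
            if len(signs) != 1:
                raise ValueError(
                    f"planted regulator {rid!r} has inconsistent beta signs across donors"
                )
        for donor in self.donor_ids:
            donor_models = self.models[donor]
            alphas = {m.alpha for m in donor_models.values()}
            gammas = {m.gamma for m in donor_models.values()}
            if len(alphas) > 1 or len(gammas) > 1:
                raise ValueError(
                    f"donor {donor!r}: planted models must share alpha and gamma"
                )

    @classmethod
    def create(
        cls,
        n_true: int = 5,
        n_decoys: int = 495,
        noise_frac_of_sd: float = 0.10,
        noise_sd: float = 0.0,
        seed: int = 0,
        grid: TimeGrid = TimeGrid(),
        n_inconsistent: int = 0,
        donor_ids: tuple[str, ...] = DONOR_IDS,
    ) -> "SynthTruth":
        """Draw a random but reproducible truth specification.

        Defaults state the baseline world: 5 planted regulators among 495
        decoys, two donors, observation noise at 10% of the clean target's
        standard deviation, delays on the same 0–100 min grid the screen
        scans. Per donor, the target's self-coefficient ``alpha`` is drawn in
        (0.55, 0.80) — a stable self-dynamics with a half-life of a few
        sampling steps — and each regulator's gain is sized so the module
        jointly sustains a target of order 500 intensity units. Module
        latencies cluster within one step of a common module delay.
        """
        meta = _rng(seed, 0)
        module_sign = float(meta.choice([-1.0, 1.0]))
        module_delay = int(meta.integers(1, 5))
        reg_delays = np.clip(
            module_delay + meta.choice([-1, 0, 1], size=n_true), 0, 5
        ).astype(int)
        inc_delays = meta.integers(0, 6, size=n_inconsistent)
        reg_ids = tuple(f"REG_{i + 1:02d}" for i in range(n_true))
        inc_ids = tuple(f"XREG_{i + 1:02d}" for i in range(n_inconsistent))
        n_drivers = max(n_true + n_inconsistent, 1)
        mean_u = float(np.mean(BASELINE_RANGE))
        models: dict[str, dict[str, PairwiseModel]] = {}
        for di, donor in enumerate(donor_ids):
            drng = _rng(seed, 1, di)
            alpha = float(drng.uniform(0.55, 0.80))
            scale = (1 - alpha) * TARGET_SCALE / (n_drivers * mean_u)
            betas: dict[str, float] = {}
            delays_by_id: dict[str, int] = {}
            for j, rid in enumerate(reg_ids):
                betas[rid] = float(module_sign * scale * drng.uniform(0.7, 1.3))
                delays_by_id[rid] = int(reg_delays[j])
            for j, rid in enumerate(inc_ids):
                beta = float(scale * drng.uniform(0.7, 1.3))
                if di % 2 == 1:
                    beta = -beta  # flipped role in every second donor
                betas[rid] = beta
                delays_by_id[rid] = int(inc_delays[j])
            # basal production: keeps the steady-state level near TARGET_SCALE
            # whatever the module sign (a repressor module pulls down from a
            # positive baseline rather than driving expression negative)
            gamma = float(
                (1 - alpha) * TARGET_SCALE * drng.uniform(0.95, 1.10)
                - sum(betas.values()) * mean_u
            )
            models[donor] = {
                rid: PairwiseModel(alpha, b, gamma, delays_by_id[rid], grid.step_min)
                for rid, b in betas.items()
            }
        return cls(
            true_regulator_ids=reg_ids,
            models=models,
            seed=seed,
            n_decoys=n_decoys,
            grid=grid,
            noise_sd=noise_sd,
            noise_frac_of_sd=noise_frac_of_sd,
            inconsistent_regulator_ids=inc_ids,
            donor_ids=donor_ids,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_decoys": self.n_decoys,
            "noise_sd": self.noise_sd,
            "noise_frac_of_sd": self.noise_frac_of_sd,
            "grid": {
                "start_min": self.grid.start_min,
                "step_min": self.grid.step_min,
                "n_points": self.grid.n_points,
            },
            "true_regulator_ids": list(self.true_regulator_ids),
            "inconsistent_regulator_ids": list(self.inconsistent_regulator_ids),
            "target_ids": list(self.target_ids),
            "models": {
                donor: {
                    rid: {
                        "alpha": m.alpha,
                        "beta": m.beta,
                        "gamma": m.gamma,
                        "delay_steps": m.delay_steps,
                        "step_min": m.step_min,
                    }
                    for rid, m in donor_models.items()
                }
                for donor, donor_models in self.models.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def generate_input_signal(
    grid: TimeGrid,
    seed: int,
    kind: Literal["smooth", "noise"] = "smooth",
    n_extra_pre: int = 0,
) -> np.ndarray:
    """One strictly positive input series on the grid, deterministic per seed.

    ``smooth`` draws a baseline in (200, 600) plus up to three random Fourier
    harmonics over the series span (each at most 12% of baseline, so the
    series stays strictly positive and slowly varying); ``noise`` draws
    independent uniform intensities in (100, 500). ``n_extra_pre`` prepends
    that many pre-history samples of the same law (used to drive delayed
    generative models from t=0) — the returned length is
    ``n_points + n_extra_pre`` and entry ``n_extra_pre`` corresponds to t=0.
    """
    rng = _rng(seed, 7)
    n = grid.n_points + n_extra_pre
    if kind == "noise":
        return rng.uniform(100.0, 500.0, size=n)
    if kind != "smooth":
        raise ValueError(f"unknown signal kind {kind!r}")
    baseline = rng.uniform(*BASELINE_RANGE)
    t = (np.arange(n) - n_extra_pre) * grid.step_min + grid.start_min
    span = grid.step_min * (grid.n_points - 1)
    series = np.full(n, baseline)
    for m in range(1, 4):
        amp = rng.uniform(0.0, 0.12) * baseline
        phase = rng.uniform(0.0, 2.0 * np.pi)
        series += amp * np.sin(2.0 * np.pi * m * t / span + phase)
    return series


def generate_target(
    u: np.ndarray,
    model: PairwiseModel,
    y0: float,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Free-run one planted pairwise model and add observation noise.

    Returns the trajectory over the usable window (length ``len(u) - d``,
    aligned with output indices ``d..N-1``). With ``noise_sd=0`` this is the
    exact model trajectory, so fitting it back recovers the parameters to
    machine precision.
    """
    clean = simulate(model, u, y0)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return clean
    rng = _rng(seed, 11)
    return clean + rng.normal(0.0, noise_sd, size=clean.shape)


def _transcript_series(
    truth: SynthTruth, donor_idx: int, transcript_idx: int, is_driver: bool,
    shape: np.ndarray, baseline: float, amp: float, t: np.ndarray, span: float,
) -> np.ndarray:
    """Donor-specific realisation of a transcript's shared response shape."""
    rng = _rng(truth.seed, 4, donor_idx, transcript_idx)
    donor_shape = shape + DONOR_SHAPE_DEV * _fourier_shape(rng, t, span)
    scale = baseline * rng.uniform(*DONOR_SCALE_JITTER)
    return np.maximum(scale * (1.0 + amp * donor_shape), INTENSITY_FLOOR)


def _joint_target(
    truth: SynthTruth,
    donor: str,
    inputs_ext: dict[str, np.ndarray],
    pad: int,
    y0: float,
) -> np.ndarray:
    """Clean target trajectory driven jointly by all planted regulators."""
    n = truth.grid.n_points
    donor_models = truth.models[donor]
    y = np.empty(n)
    y[0] = y0
    if donor_models:
        any_model = next(iter(donor_models.values()))
        alpha, gamma = any_model.alpha, any_model.gamma
    else:  # null world: plain first-order relaxation toward gamma/(1-alpha)
        alpha, gamma = 0.7, 150.0
    for k in range(n - 1):
        drive = sum(
            m.beta * inputs_ext[rid][pad + k - m.delay_steps]
            for rid, m in donor_models.items()
        )
        y[k + 1] = alpha * y[k] + drive + gamma
    return y


def generate_screen_dataset(
    truth: SynthTruth,
) -> tuple[list[ExpressionDataset], SynthTruth]:
    """Generate one full two-donor screening dataset from a truth spec.

    Per donor: planted regulators follow the module's stimulus-response
    pulse (kinetics jittered per transcript), decoys are independent smooth
    Fourier signals, and the two target probesets are independent noisy
    observations of the same clean target trajectory driven by the planted
    module (at zero noise the two outputs coincide). Transcript shapes are
    shared across donors up to a small donor deviation and scale jitter.
    Detection flags are all Present. Row order is identical across donors.
    """
    grid = truth.grid
    driver_ids = list(truth.true_regulator_ids) + list(truth.inconsistent_regulator_ids)
    decoy_ids = [f"DECOY_{i + 1:04d}" for i in range(truth.n_decoys)]
    input_ids = driver_ids + decoy_ids
    pad = max(
        [m.delay_steps for dm in truth.models.values() for m in dm.values()],
        default=0,
    )
    t = (np.arange(grid.n_points + pad) - pad) * grid.step_min + grid.start_min
    span = grid.step_min * (grid.n_points - 1)

    # donor-shared characteristics
    meta = _rng(truth.seed, 6)
    tau0 = meta.uniform(*PULSE_TAU_RANGE)
    p0 = meta.uniform(*PULSE_EXP_RANGE)
    shapes: dict[str, np.ndarray] = {}
    baselines: dict[str, float] = {}
    amps: dict[str, float] = {}
    for ti, tid in enumerate(input_ids):
        srng = _rng(truth.seed, 2, ti)
        baselines[tid] = float(srng.uniform(*BASELINE_RANGE))
        if tid in truth.true_regulator_ids:
            tau = tau0 * srng.uniform(1 - KINETIC_JITTER, 1 + KINETIC_JITTER)
            p = p0 * srng.uniform(1 - KINETIC_JITTER, 1 + KINETIC_JITTER)
            shapes[tid] = _pulse_shape(t, tau, p)
            amps[tid] = float(srng.uniform(*REG_AMP_RANGE))
        elif tid in truth.inconsistent_regulator_ids:
            # own, module-independent pulse so its flipped role is visible
            shapes[tid] = _pulse_shape(
                t, srng.uniform(*PULSE_TAU_RANGE), srng.uniform(*PULSE_EXP_RANGE)
            )
            amps[tid] = float(srng.uniform(*REG_AMP_RANGE))
        else:
            shapes[tid] = _fourier_shape(srng, t, span)
            amps[tid] = float(srng.uniform(*DECOY_AMP_RANGE))

    datasets: list[ExpressionDataset] = []
    for di, donor in enumerate(truth.donor_ids):
        inputs_ext = {
            tid: _transcript_series(
                truth, di, ti, tid in driver_ids,
                shapes[tid], baselines[tid], amps[tid], t, span,
            )
            for ti, tid in enumerate(input_ids)
        }
        y0 = float(_rng(truth.seed, 3, di).uniform(*Y0_RANGE))
        clean = _joint_target(truth, donor, inputs_ext, pad, y0)
        if truth.noise_frac_of_sd > 0:
            sd = truth.noise_frac_of_sd * float(np.std(clean))
        else:
            sd = truth.noise_sd
        rows: dict[str, np.ndarray] = {
            tid: series[pad:] for tid, series in inputs_ext.items()
        }
        for oi, out_id in enumerate(truth.target_ids):
            noise_rng = _rng(truth.seed, 5, di, oi)
            obs = clean if sd == 0 else clean + noise_rng.normal(0.0, sd, size=clean.shape)
            rows[out_id] = obs
        all_ids = input_ids + list(truth.target_ids)
        values = pd.DataFrame(
            np.vstack([rows[tid] for tid in all_ids]),
            index=pd.Index(all_ids, name="transcript_id"),
            columns=[f"{tt:g}" for tt in grid.times],
        )
        symbols = pd.Series(
            [TARGET_SYMBOL if tid in truth.target_ids else tid for tid in all_ids],
            index=values.index,
            name="gene_symbol",
        )
        flags = pd.DataFrame("P", index=values.index, columns=values.columns)
        datasets.append(
            ExpressionDataset(
                donor_id=donor,
                values=values,
                grid=grid,
                gene_symbols=symbols,
                flags=flags,
            )
        )
    return datasets, truth
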