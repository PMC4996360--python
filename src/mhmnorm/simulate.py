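"""Synthetic time-series expression data with array-level "plate" artifacts.

The generator emulates the simulation design used throughout the correlation
benchmarks: a small number of genes with clear temporal patterns (increasing
ramp, decreasing ramp, sinusoid) alongside genes whose expression is a random
constant level plus observation noise, all sampled on a regular time grid.
A *plate effect* — a technical artifact affecting every measurement of one
array — is modeled as a single additive offset or multiplicative factor
applied to one whole column (time point).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .matrix import ExpressionMatrix

__all__ = [
    "PatternSpec",
    "PlateEffectSpec",
    "default_pattern_specs",
    "generate_profiles",
    "apply_plate_effect",
    "large_matrix_standin",
    "load_simulation_config",
]

PATTERN_KINDS = ("increasing", "decreasing", "sinusoidal", "random")
PLATE_MODES = ("additive", "multiplicative")


@dataclass(frozen=True)
class PatternSpec:
    """Temporal pattern of one simulated gene.

    ``increasing``/``decreasing`` genes are monotone ramps ``baseline ±
    amplitude * t/(N-1)``; a ``sinusoidal`` gene is ``baseline + amplitude *
    sin(2*pi*t/period + phase)``; a ``random`` gene is a constant level (drawn
    per gene at generation time).  Gaussian observation noise of standard
    deviation ``noise_sd`` is added to every pattern.
    """

    kind: str
    amplitude: float = 5.0
    baseline: float = 5.0
    period: float | None = None  # sinusoidal only
    phase: float = 0.0  # sinusoidal only
    noise_sd: float | None = None  # default 0.1 * amplitude

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValidationError(
                f"unknown pattern kind {self.kind!r}; expected one of {PATTERN_KINDS}"
            )
        if not self.amplitude > 0:
            raise ValidationError("amplitude must be strictly positive")
        if self.period is not None and not self.period > 0:
            raise ValidationError("period must be strictly positive")
        if self.kind == "sinusoidal" and self.period is None:
            raise ValidationError("sinusoidal pattern requires a period")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    @property
    def effective_noise_sd(self) -> float:
        return 0.1 * self.amplitude if self.noise_sd is None else self.noise_sd


@dataclass(frozen=True)
class PlateEffectSpec:
    """A single-array technical artifact on one time-point column.

    One column receives a shared perturbation drawn once per dataset:
    ``additive`` adds an offset delta ~ Uniform(magnitude_range) to every
    entry of the column, ``multiplicative`` multiplies every entry by such a
    draw.  ``target_column`` is an explicit column index or ``"random"``.
    """

    mode: str = "additive"
    magnitude_range: tuple[float, float] = (0.5, 2.0)
    target_column: int | str = "random"

    def __post_init__(self) -> None:
        if self.mode not in PLATE_MODES:
            raise ValidationError(
                f"unknown plate-effect mode {self.mode!r}; expected one of {PLATE_MODES}"
            )
        low, high = self.magnitude_range
        if low > high:
            raise ValidationError(
                f"magnitude_range is inverted: ({low}, {high})"
            )
        if self.target_column != "random" and not isinstance(self.target_column, (int, np.integer)):
            raise ValidationError("target_column must be an integer index or 'random'")


def default_pattern_specs(n_timepoints: int = 16) -> list[PatternSpec]:
    """The three patterned genes of the simulation design: increasing ramp,
    decreasing ramp, and a sinusoid completing two cycles over the series."""
    return [
        PatternSpec("increasing"),
        PatternSpec("decreasing"),
        PatternSpec("sinusoidal", period=n_timepoints / 2, phase=0.0),
    ]


def generate_profiles(
    pattern_specs: Sequence[PatternSpec],
    n_random: int,
    n_timepoints: int,
    seed: int,
    *,
    level_range: tuple[float, float] = (1.0, 10.0),
    random_noise_sd: float = 0.5,
) -> ExpressionMatrix:
    """Simulate an expression matrix of patterned plus random-level genes.

    Parameters
    ----------
    pattern_specs
        One spec per patterned gene (first rows of the output).
    n_random
        Number of additional genes whose level is drawn per gene from
        ``Uniform(level_range)`` with i.i.d. Gaussian noise of sd
        ``random_noise_sd`` per time point.
    n_timepoints
        Number of columns; the time grid is the integer indices ``0..N-1``.
    seed
        Seed for all random draws; identical seeds give bit-identical output.
    """
    if n_timepoints < 2:
        raise ValidationError("need at least 2 time points")
    if n_random < 0:
        raise ValidationError("n_random must be non-negative")
    n_genes = len(pattern_specs) + n_random
    if n_genes < 1:
        raise ValidationError("need at least one gene")
    if random_noise_sd < 0:
        raise ValidationError("random_noise_sd must be non-negative")
    lo, hi = level_range
    if lo > hi:
        raise ValidationError(f"level_range is inverted: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints, dtype=np.float64)
    values = np.empty((n_genes, n_timepoints))
    for g, spec in enumerate(pattern_specs):
        if spec.kind == "increasing":
            signal = spec.baseline + spec.amplitude * t / (n_timepoints - 1)
        elif spec.kind == "decreasing":
            signal = spec.baseline - spec.amplitude * t / (n_timepoints - 1)
        elif spec.kind == "sinusoidal":
            signal = spec.baseline + spec.amplitude * np.sin(
                2.0 * np.pi * t / spec.period + spec.phase
            )
        else:  # "random" as an explicit spec: level drawn like the bulk genes
            signal = np.full(n_timepoints, rng.uniform(lo, hi))
        sd = spec.effective_noise_sd
        values[g] = signal + (rng.normal(0.0, sd, n_timepoints) if sd > 0 else 0.0)
    for g in range(len(pattern_specs), n_genes):
        level = rng.uniform(lo, hi)
        noise = rng.normal(0.0, random_noise_sd, n_timepoints) if random_noise_sd > 0 else 0.0
        values[g] = level + noise
    return ExpressionMatrix(values)


def apply_plate_effect(
    x: ExpressionMatrix, spec: PlateEffectSpec, seed: int
) -> ExpressionMatrix:
    """Perturb exactly one column of ``x`` per the plate-effect spec.

    All other columns are bit-identical to the input; the affected column and
    the perturbation magnitude are drawn deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    if spec.target_column == "random":
        column = int(rng.integers(x.n_timepoints))
    else:
        column = int(spec.target_column)
        if not 0 <= column < x.n_timepoints:
            raise ValidationError(
                f"target_column {column} out of range [0, {x.n_timepoints})"
            )
    magnitude = rng.uniform(*spec.magnitude_range)
    values = x.values.copy()
    if spec.mode == "additive":
        values[:, column] = values[:, column] + magnitude
    else:
        values[:, column] = values[:, column] * magnitude
    return x.with_values(values)


def large_matrix_standin(
    n_genes: int,
    n_timepoints: int,
    seed: int,
    *,
    amplitude_range: tuple[float, float] = (0.5, 5.0),
    baseline_range: tuple[float, float] = (1.0, 10.0),
) -> ExpressionMatrix:
    """Synthetic stand-in for a genome-wide time-course expression matrix.

    Emulates the feature of real large-scale time-course data that matters for
    subset-correlation analysis: essentially every gene follows some smooth
    temporal trajectory (here a ramp or a sinusoid with per-gene random
    amplitude, baseline, period and phase, plus observation noise at 10% of
    amplitude), so gene-gene correlations are dominated by the temporal
    signal rather than by observation noise.  A matrix of flat noise-only
    genes would not share this property — its correlations would be pure
    noise artifacts, which no real transcriptome resembles.
    """
    if n_genes < 1:
        raise ValidationError("need at least one gene")
    rng = np.random.default_rng(seed)
    kinds = rng.choice(PATTERN_KINDS[:3], size=n_genes)
    specs = []
    for kind in kinds:
        amplitude = float(rng.uniform(*amplitude_range))
        baseline = float(rng.uniform(*baseline_range))
        specs.append(
            PatternSpec(
                str(kind),
                amplitude=amplitude,
                baseline=baseline,
                period=float(rng.uniform(n_timepoints / 2, 2 * n_timepoints))
                if kind == "sinusoidal"
                else None,
                phase=float(rng.uniform(0.0, 2.0 * np.pi)),
            )
        )
    profile_seed = int(rng.integers(2**31 - 1))
    return generate_profiles(specs, 0, n_timepoints, profile_seed)


def _pattern_from_dict(d: dict) -> PatternSpec:
    allowed = {"kind", "amplitude", "baseline", "period", "phase", "noise_sd"}
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"unknown pattern fields: {sorted(unknown)}")
    return PatternSpec(**d)


def load_simulation_config(path: str | Path) -> dict:
    """Load a YAML simulation config.

    Recognized keys: ``patterned`` (list of pattern-spec mappings), ``random``
    (mapping with ``n``, ``level_range``, ``noise_sd``), ``timepoints``, and
    ``plate`` (plate-effect mapping with ``mode``, ``magnitude_range``,
    ``target_column``).  Returns a dict with parsed spec objects under keys
    ``pattern_specs``, ``n_random``, ``level_range``, ``random_noise_sd``,
    ``n_timepoints``, ``plate_spec``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("simulation config must be a mapping")
    n_timepoints = int(raw.get("timepoints", 16))
    patterned = raw.get("patterned")
    if patterned is None:
        pattern_specs = default_pattern_specs(n_timepoints)
    else:
        pattern_specs = [_pattern_from_dict(dict(p)) for p in patterned]
    random_cfg = dict(raw.get("random", {}))
    plate_cfg = raw.get("plate")
    plate_spec = None
    if plate_cfg is not None:
        plate_cfg = dict(plate_cfg)
        if "magnitude_range" in plate_cfg:
            plate_cfg["magnitude_range"] = tuple(plate_cfg["magnitude_range"])
        plate_spec = PlateEffectSpec(**plate_cfg)
    return {
        "pattern_specs": pattern_specs,
        "n_random": int(random_cfg.get("n", 5)),
        "level_range": tuple(random_cfg.get("level_range", (1.0, 10.0))),
        "random_noise_sd": float(random_cfg.get("noise_sd", 0.5)),
        "n_timepoints": n_timepoints,
        "plate_spec": plate_spec,
    }
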