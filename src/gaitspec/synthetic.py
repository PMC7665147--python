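"""Synthetic walking cohorts with known regression structure.

The generator emulates hip-worn accelerometry during steady walking: the
vertical axis carries a constant gravity offset plus a harmonic comb -- a
sum of sinusoids at integer (and optionally half-integer) multiples of the
cadence with random phases -- and independent Gaussian device noise is added
to all three axes.  Half-integer harmonics mimic the stride (two-step)
periodicity of real gait, which places energy at orders 0.5, 1.5, ...

Responses follow the scalar-on-function model: each simulated bout is pushed
through the *actual* pre-processing pipeline to obtain its spectrum,
cadence, and VMC, and

    y_i = g0 + male_i g1 + cadence_i g2 + vmc_i g3
          + delta_s * sum_j w_i(s_j) beta_true(s_j) + eps_i,

with the same Riemann-sum quadrature the estimator uses, so parameter
recovery is exact up to noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import PreprocessConfig, SimulateConfig
from .errors import ParameterError
from .penalty import build_basis
from .preprocess import RawBout, SubjectFeatures, order_grid, process_bout

__all__ = [
    "GaitParams",
    "CohortSpec",
    "Cohort",
    "simulate_bout",
    "simulate_cohort",
    "default_gait_sampler",
    "bump_beta",
]

#: default harmonic comb (fundamental first); amplitudes sum below the
#: gravity offset so the noiseless vertical axis never crosses zero
DEFAULT_AMPLITUDES = (0.40, 0.20, 0.10, 0.06, 0.04)
DEFAULT_HALF_AMPLITUDES = (0.10, 0.06, 0.04, 0.02, 0.01)


@dataclass
class GaitParams:
    """Parameters of one subject's quasi-periodic walking signal."""

    cadence_hz: float = 2.0
    harmonic_amplitudes: Sequence[float] = DEFAULT_AMPLITUDES
    half_harmonics_flag: bool = False
    half_harmonic_amplitudes: Sequence[float] = DEFAULT_HALF_AMPLITUDES
    noise_sd: float = 0.05
    duration_s: float = 60.0
    fs: float = 80.0
    offset_g: float = 1.0       # constant gravity component on axis 3
    window_s: float = 10.0      # minimum usable duration

    def validate(self) -> "GaitParams":
        if not 1.2 <= self.cadence_hz <= 4.0:
            raise ParameterError(f"cadence {self.cadence_hz} outside [1.2, 4.0] Hz")
        amps = np.asarray(self.harmonic_amplitudes, dtype=float)
        if (amps < 0).any():
            raise ParameterError("harmonic amplitudes must be nonnegative")
        if self.half_harmonics_flag:
            half = np.asarray(self.half_harmonic_amplitudes, dtype=float)
            if (half < 0).any():
                raise ParameterError("half-harmonic amplitudes must be nonnegative")
        top = self.cadence_hz * max(
            len(amps),
            (len(self.half_harmonic_amplitudes) - 0.5) if self.half_harmonics_flag else 0,
        )
        if top > 0 and self.fs <= 2 * top:
            raise ParameterError(
                f"fs = {self.fs} Hz cannot resolve the top harmonic at {top} Hz"
            )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")
        if self.duration_s < self.window_s:
            raise ParameterError("bout shorter than one analysis window")
        return self


def _harmonic_series(params: GaitParams, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sum of sinusoids at (half-)integer cadence multiples, random phases."""
    signal = np.zeros_like(t)
    multiples: list[tuple[float, float]] = [
        (k + 1.0, a) for k, a in enumerate(params.harmonic_amplitudes)
    ]
    if params.half_harmonics_flag:
        multiples += [
            (k + 0.5, a) for k, a in enumerate(params.half_harmonic_amplitudes)
        ]
    for mult, amp in multiples:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        signal += amp * np.sin(2.0 * np.pi * mult * params.cadence_hz * t + phase)
    return signal


def simulate_bout(
    params: GaitParams,
    seed: int | np.random.Generator,
    subject_id: str = "sim",
) -> RawBout:
    """One tri-axial walking bout; deterministic given the seed.

    Axis 3 carries gravity plus the harmonic comb; all axes receive
    independent white noise.  The vector magnitude of the noiseless part is
    |offset + comb(t)|, periodic with fundamental ``params.cadence_hz``.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs
    x3 = params.offset_g + _harmonic_series(params, t, rng)
    noise = rng.normal(0.0, params.noise_sd, size=(3, n)) if params.noise_sd > 0 else np.zeros((3, n))
    return RawBout(
        subject_id=subject_id,
        fs=params.fs,
        x1=noise[0],
        x2=noise[1],
        x3=x3 + noise[2],
    )


def default_gait_sampler(sim: SimulateConfig | None = None) -> Callable[[np.random.Generator], GaitParams]:
    """Per-subject gait parameters: cadence ~ U(cadence_min, cadence_max),
    harmonic amplitudes independently jittered by U(0.7, 1.3)."""
    sim = sim or SimulateConfig()

    def sampler(rng: np.random.Generator) -> GaitParams:
        amps = np.asarray(DEFAULT_AMPLITUDES) * rng.uniform(0.7, 1.3, len(DEFAULT_AMPLITUDES))
        half = np.asarray(DEFAULT_HALF_AMPLITUDES) * rng.uniform(0.7, 1.3, len(DEFAULT_HALF_AMPLITUDES))
        return GaitParams(
            cadence_hz=float(rng.uniform(sim.cadence_min, sim.cadence_max)),
            harmonic_amplitudes=tuple(amps),
            half_harmonics_flag=sim.half_harmonics,
            half_harmonic_amplitudes=tuple(half),
            noise_sd=sim.noise_sd,
            duration_s=sim.duration_s,
        )

    return sampler


def bump_beta(
    grid: np.ndarray, center: float = 2.5, height: float = 50.0, sd: float = 0.08
) -> np.ndarray:
    """A single Gaussian bump on the order grid, peak value ``height``.

    Built from the harmonic-basis column at ``center`` so the function lies
    exactly in the informative subspace span(Q) when the basis uses the same
    sd and includes that center.
    """
    basis = build_basis(grid, sd=sd, center_min=center, center_max=center)
    col = basis.Q[:, 0]
    return height * col / col.max()


@dataclass
class CohortSpec:
    """Design of a simulated cohort: gait distribution and true coefficients."""

    n_subjects: int = 46
    gait_params_sampler: Callable[[np.random.Generator], GaitParams] | None = None
    beta_true: np.ndarray | None = None      # on the pipeline's order grid
    gamma_true: Sequence[float] = (65.0, -2.0, -5.0, 10.0)  # intercept, male, cadence, vmc
    sigma_eps: float = 0.5
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def validate(self) -> "CohortSpec":
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be at least 1")
        if self.sigma_eps < 0:
            raise ParameterError("sigma_eps must be nonnegative")
        if self.beta_true is not None and len(self.beta_true) != self.preprocess.order_points:
            raise ParameterError("beta_true must live on the pipeline's order grid")
        return self


@dataclass
class Cohort:
    """A realized synthetic cohort with its generating truth attached."""

    bouts: list[RawBout]
    covariates: pd.DataFrame      # subject_id, male, y
    y: np.ndarray
    features: list[SubjectFeatures]
    beta_true: np.ndarray
    gamma_true: np.ndarray
    spec: CohortSpec


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate bouts and responses from the scalar-on-function model.

    Each subject's spectrum, cadence and VMC are computed by the real
    pre-processing pipeline; the functional term uses the same delta_s
    Riemann quadrature as the estimator.  One global seed expands into
    independent per-subject substreams plus a cohort-level stream for the
    sex indicator and residual noise, so cohorts are bit-reproducible.
    """
    spec.validate()
    cfg = spec.preprocess
    grid = order_grid(cfg)
    beta = np.zeros(cfg.order_points) if spec.beta_true is None else np.asarray(spec.beta_true, float)
    gamma = np.asarray(spec.gamma_true, dtype=float)
    sampler = spec.gait_params_sampler or default_gait_sampler(
        SimulateConfig(n_subjects=spec.n_subjects)
    )
    delta_s = float(grid[1] - grid[0])

    ss = np.random.SeedSequence(spec.seed)
    subject_seeds = ss.spawn(spec.n_subjects)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])

    bouts: list[RawBout] = []
    features: list[SubjectFeatures] = []
    for i, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        params = sampler(rng)
        bout = simulate_bout(params, rng, subject_id=f"s{i:03d}")
        bouts.append(bout)
        features.append(process_bout(bout, cfg))

    male = cohort_rng.integers(0, 2, size=spec.n_subjects).astype(float)
    eps = cohort_rng.normal(0.0, spec.sigma_eps, size=spec.n_subjects) if spec.sigma_eps > 0 else np.zeros(spec.n_subjects)
    y = np.empty(spec.n_subjects)
    for i, f in enumerate(features):
        scalar_part = gamma @ np.array([1.0, male[i], f.cadence_hz, f.vmc])
        functional_part = delta_s * float(f.spectrum @ beta)
        y[i] = scalar_part + functional_part + eps[i]

    covariates = pd.DataFrame(
        {"subject_id": [b.subject_id for b in bouts], "male": male, "y": y}
    )
    return Cohort(
        bouts=bouts, covariates=covariates, y=y, features=features,
        beta_true=beta, gamma_true=gamma, spec=spec,
    )
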