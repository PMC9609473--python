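"""Synthetic dialysis release experiments.

No raw release curves for this system are publicly deposited, so the
pipeline is exercised on simulated experiments: the closed-form
conversion profile plus additive Gaussian measurement noise on the
conversion (clipped to [0, 1]), deterministically seeded.

:func:`reference_presets` enumerates the published condition grid for
doxorubicin release from N-vinyl-2-pyrrolidone/acrylic-acid copolymer
nanoparticles — four copolymer compositions, four mass concentrations,
four temperatures and three pH values — each loaded with its reported
(k1, k_minus1) pair as ground truth.  Conditions repeated across the
published series (310 K / pH 7 / 1e-2 g/mL appears in three of them)
are kept as separate presets so each series stays complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fitting import ReleaseCurve
from .models import ExperimentCondition, RateConstants, conversion_profile

__all__ = [
    "DEFAULT_TIMES",
    "DEFAULT_NOISE_SD",
    "SyntheticSpec",
    "generate_release_experiment",
    "reference_presets",
    "reference_temperature_series",
    "absorbance_view",
    "absorbance_to_conversion",
]

#: Default sampling grid: 0-48 h at 2 h steps, matching the multi-hour
#: equilibration timescale implied by rate constants of order 0.1 1/h.
DEFAULT_TIMES: np.ndarray = np.arange(0.0, 48.0 + 1e-9, 2.0)

#: Default additive noise on conversion (~2% of the largest neutral-pH
#: plateau).
DEFAULT_NOISE_SD: float = 0.002

# Published rate-constant series (1/h) for the four condition sweeps:
# (series label suffix, condition, k1, k_minus1).
_COMPOSITION_SERIES: List[Tuple[str, float, float, float]] = [
    # (x_aa, k1, k_minus1) at 310 K, pH 7, 1e-2 g/mL
    ("x3.9", 0.039, 1.65e-2, 0.153),
    ("x5.6", 0.056, 1.03e-2, 0.118),
    ("x9.8", 0.098, 7.58e-3, 0.101),
    ("x15.8", 0.158, 2.80e-3, 0.053),
]
_CONCENTRATION_SERIES: List[Tuple[str, float, float, float]] = [
    # (conc g/mL, k1, k_minus1) at x_aa=0.039, 310 K, pH 7
    ("c2.5e-3", 2.5e-3, 2.56e-2, 0.113),
    ("c5.0e-3", 5.0e-3, 2.16e-2, 0.133),
    ("c1.0e-2", 1.0e-2, 1.65e-2, 0.153),
    ("c1.5e-2", 1.5e-2, 8.77e-3, 0.186),
]
_TEMPERATURE_SERIES: List[Tuple[str, float, float, float]] = [
    # (T kelvin, k1, k_minus1) at x_aa=0.039, 1e-2 g/mL, pH 7
    ("278K", 278.0, 2.80e-3, 0.119),
    ("298K", 298.0, 1.27e-2, 0.137),
    ("310K", 310.0, 1.65e-2, 0.153),
    ("323K", 323.0, 3.52e-2, 0.166),
]
_PH_SERIES: List[Tuple[str, float, float, float]] = [
    # (pH, k1, k_minus1) at x_aa=0.039, 1e-2 g/mL, 310 K
    ("4", 4.0, 0.123, 0.093),
    ("7", 7.0, 0.0165, 0.153),
    ("9", 9.0, 0.0282, 0.185),
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to simulate one dialysis release experiment.

    The spec is the experiment's full provenance: ground-truth
    constants, condition metadata, sampling grid, noise level and seed.
    Generation is a pure function of the spec.
    """

    truth: RateConstants
    condition: ExperimentCondition
    times: np.ndarray = field(default_factory=lambda: DEFAULT_TIMES.copy())
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing 1-D grid")
        if t[0] < 0:
            raise ValueError("times must start at or after 0")

    @property
    def label(self) -> str:
        return self.condition.label


def generate_release_experiment(spec: SyntheticSpec) -> ReleaseCurve:
    """Simulate one release curve: truth profile + clipped Gaussian noise.

    xi_obs(t) = clip(xi_true(t) + eps_t, 0, 1) with eps_t i.i.d.
    N(0, noise_sd^2) from ``numpy.random.default_rng(spec.seed)``.
    Identical specs produce bit-identical curves.
    """
    xi_true = conversion_profile(spec.truth, spec.times)
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_sd, size=spec.times.size) if spec.noise_sd > 0 else 0.0
    xi_obs = np.clip(xi_true + eps, 0.0, 1.0)
    return ReleaseCurve(times=spec.times.copy(), xi=xi_obs, condition=spec.condition)


def reference_presets(
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    times: Optional[Sequence[float]] = None,
) -> List[SyntheticSpec]:
    """The 15 published study conditions as synthetic experiment specs.

    Four composition presets, four concentration presets, four
    temperature presets and three pH presets (4 + 4 + 4 + 3), labelled
    e.g. ``"composition/x3.9"``, ``"temperature/278K"``, ``"pH/4"``.
    Per-preset seeds are derived as ``seed + index`` so replicate suites
    stay reproducible from a single integer.
    """
    grid = np.asarray(times, dtype=float) if times is not None else DEFAULT_TIMES.copy()
    specs: List[SyntheticSpec] = []

    def add(label: str, cond: ExperimentCondition, k1: float, km1: float) -> None:
        specs.append(
            SyntheticSpec(
                truth=RateConstants(k1=k1, k_minus1=km1),
                condition=cond,
                times=grid.copy(),
                noise_sd=noise_sd,
                seed=seed + len(specs),
            )
        )

    for tag, x_aa, k1, km1 in _COMPOSITION_SERIES:
        cond = ExperimentCondition(
            temperature=310.0, pH=7.0, x_aa=x_aa, copolymer_conc=1e-2,
            label=f"composition/{tag}",
        )
        add(cond.label, cond, k1, km1)
    for tag, conc, k1, km1 in _CONCENTRATION_SERIES:
        cond = ExperimentCondition(
            temperature=310.0, pH=7.0, x_aa=0.039, copolymer_conc=conc,
            label=f"concentration/{tag}",
        )
        add(cond.label, cond, k1, km1)
    for tag, T, k1, km1 in _TEMPERATURE_SERIES:
        cond = ExperimentCondition(
            temperature=T, pH=7.0, x_aa=0.039, copolymer_conc=1e-2,
            label=f"temperature/{tag}",
        )
        add(cond.label, cond, k1, km1)
    for tag, pH, k1, km1 in _PH_SERIES:
        cond = ExperimentCondition(
            temperature=310.0, pH=pH, x_aa=0.039, copolymer_conc=1e-2,
            label=f"pH/{tag}",
        )
        add(cond.label, cond, k1, km1)
    return specs


def reference_temperature_series() -> Tuple[List[Tuple[float, float]], List[Tuple[float, float]]]:
    """Published (T, k1) and (T, k_minus1) series for thermodynamic analysis.

    Four temperatures between 278 K and 323 K at pH 7, 3.9 mol% acrylic
    acid, 1e-2 g/mL copolymer; input to Arrhenius and van't Hoff fits.
    """
    k1 = [(T, k1) for _, T, k1, _ in _TEMPERATURE_SERIES]
    km1 = [(T, km1) for _, T, _, km1 in _TEMPERATURE_SERIES]
    return k1, km1


def absorbance_view(curve: ReleaseCurve, slope: float, offset: float = 0.0) -> np.ndarray:
    """Render conversions as a raw absorbance-like signal A = slope*xi + offset.

    Emulates the 480 nm spectrophotometric readout with a linear
    calibration; :func:`absorbance_to_conversion` is its exact inverse.
    """
    if not slope > 0:
        raise ValueError(f"calibration slope must be positive, got {slope}")
    return slope * curve.xi + offset


def absorbance_to_conversion(absorbance: Sequence[float], slope: float, offset: float = 0.0) -> np.ndarray:
    """Invert the linear calibration: xi = (A - offset) / slope."""
    if not slope > 0:
        raise ValueError(f"calibration slope must be positive, got {slope}")
    return (np.asarray(absorbance, dtype=float) - offset) / slope
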