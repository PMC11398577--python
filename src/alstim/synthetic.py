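"""Synthetic parameter-sweep datasets and LFP-like test signals.

The generators here emulate the statistical structure of three kinds of
stimulation parameter-sweep experiments so every downstream stage (query
strategies, episode harness, statistics) can be exercised end to end:

* a 200-sample random sweep of electrical deep-brain-stimulation
  parameters against a beta-band power biomarker (``pd_sweep``),
* a 100-combination grid (5 amplitudes x 10 frequencies x 2 pulse widths)
  with 4 repeated sessions against theta power (``nhp_grid``),
* a 72-combination optogenetic sweep against slow-gamma power
  (``opto_sweep``), plus a dense 1080-point grid for the closed-loop
  replication preset (``invivo_grid``).

The response surface is a parametric surrogate, not a biophysical
simulation: expected response = baseline - (ga*amplitude + gw*pulse_width)
* S(f), where S is a Gaussian bump in log-frequency.  High-frequency
stimulation near the tuning center suppresses the biomarker most, which
reproduces the qualitative amplitude/frequency/pulse-width structure an
active learner must exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .sweep_data import ParameterSweepTable

__all__ = [
    "SurrogateConfig",
    "GridSpec",
    "make_parameter_grid",
    "expected_surface",
    "simulate_response_surface",
    "simulate_state_dependent",
    "synth_lfp",
    "make_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """Parameters of the surrogate stimulation-response surface.

    ``frequency_center``/``frequency_width`` (Hz) define the suppression
    profile S(f) = exp(-0.5 ((ln f - ln c) / (w/c))^2), a Gaussian bump in
    log-frequency whose relative width is ``width/center``.  ``noise_sd``
    is per-observation (trial) noise, ``session_sd`` the between-session
    offset scale used when several response sessions are generated.
    ``noise_df`` switches trial noise to a Student-t with that many
    degrees of freedom (scaled to the same sd) to emulate outlier-prone
    recordings.
    """

    baseline_power: float = 1.0
    amplitude_gain: float = 0.0
    pulsewidth_gain: float = 0.0
    frequency_center: float = 130.0
    frequency_width: float = 50.0
    state_coupling: float = 0.0
    noise_sd: float = 0.05
    session_sd: float = 0.0
    noise_df: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.session_sd < 0:
            raise ValueError("noise_sd and session_sd must be nonnegative")
        if self.amplitude_gain < 0 or self.pulsewidth_gain < 0:
            raise ValueError("gains must be nonnegative")
        if self.frequency_width <= 0 or self.frequency_center <= 0:
            raise ValueError("frequency tuning must be positive")
        if self.noise_df is not None and self.noise_df <= 2:
            raise ValueError("noise_df must exceed 2 for a finite variance")


@dataclass(frozen=True)
class GridSpec:
    """Ordered factor levels of a full-factorial stimulation grid."""

    amplitude_levels: tuple
    frequency_levels: tuple
    pulsewidth_levels: tuple

    def __post_init__(self) -> None:
        for name in ("amplitude_levels", "frequency_levels", "pulsewidth_levels"):
            levels = np.asarray(getattr(self, name), dtype=float)
            if levels.size == 0:
                raise ValueError(f"{name} is empty")
            if np.any(levels <= 0):
                raise ValueError(f"{name} must be strictly positive")
            if np.any(np.diff(levels) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, tuple(levels))


def make_parameter_grid(spec: GridSpec) -> np.ndarray:
    """Cartesian product of grid levels, amplitude varying slowest.

    Returns an ``(n, 3)`` array in canonical (amplitude, frequency,
    pulse_width) order with deterministic lexicographic row order.
    """
    a, f, w = (
        np.asarray(spec.amplitude_levels),
        np.asarray(spec.frequency_levels),
        np.asarray(spec.pulsewidth_levels),
    )
    A, F, W = np.meshgrid(a, f, w, indexing="ij")
    return np.column_stack([A.ravel(), F.ravel(), W.ravel()])


def expected_surface(parameters: np.ndarray, config: SurrogateConfig) -> np.ndarray:
    """Closed-form expected response for each parameter row (no noise)."""
    P = np.atleast_2d(np.asarray(parameters, dtype=float))
    amp, freq, pw = P[:, 0], P[:, 1], P[:, 2]
    rel_width = config.frequency_width / config.frequency_center
    z = (np.log(freq) - np.log(config.frequency_center)) / rel_width
    S = np.exp(-0.5 * z**2)
    depth = config.amplitude_gain * amp + config.pulsewidth_gain * pw
    return config.baseline_power - depth * S


def _trial_noise(rng: np.random.Generator, shape, config: SurrogateConfig) -> np.ndarray:
    if config.noise_df is None:
        return rng.normal(0.0, config.noise_sd, size=shape)
    df = config.noise_df
    # standard-t rescaled so the sd equals noise_sd
    return rng.standard_t(df, size=shape) * config.noise_sd * np.sqrt((df - 2) / df)


def simulate_response_surface(
    parameters: np.ndarray, config: SurrogateConfig, m: int = 1
) -> np.ndarray:
    """Simulate ``m`` response sessions for each parameter row.

    Each session column adds one shared Gaussian offset (sd
    ``session_sd``) plus independent per-observation noise (sd
    ``noise_sd``); identical configs and seeds give bit-identical output.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    P = np.atleast_2d(np.asarray(parameters, dtype=float))
    mu = expected_surface(P, config)
    rng = np.random.default_rng(config.seed)
    offsets = rng.normal(0.0, config.session_sd, size=m) if config.session_sd > 0 else np.zeros(m)
    noise = _trial_noise(rng, (P.shape[0], m), config) if config.noise_sd > 0 else np.zeros((P.shape[0], m))
    return mu[:, None] + offsets[None, :] + noise


def simulate_state_dependent(
    parameters: np.ndarray, config: SurrogateConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate single-session responses coupled to a pre-stimulation state.

    The pre-stimulation state is i.i.d. standard normal (drawn from a
    stream independent of the surface noise, so ``state_coupling=0``
    reproduces :func:`simulate_response_surface` exactly); the expected
    response is the surface value plus ``state_coupling * state``.
    """
    responses = simulate_response_surface(parameters, config, m=1)
    n = responses.shape[0]
    state_rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 1]))
    state = state_rng.standard_normal(n)
    return responses + config.state_coupling * state[:, None], state


def synth_lfp(
    band_targets: Sequence[tuple[tuple[float, float], float]],
    fs: float,
    duration: float,
    seed: int,
    floor_sd: float = 0.0,
) -> np.ndarray:
    """Band-limited Gaussian noise with prescribed per-band variances.

    Each ``((f_lo, f_hi), power)`` entry contributes an independent
    component whose variance equals ``power`` and whose spectrum is
    confined to the band (FFT masking of white noise); ``floor_sd`` adds
    an optional broadband white floor.  Useful as a controllable fixture
    for spectral-feature code.
    """
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration * fs must be at least 2 samples")
    rng = np.random.default_rng(seed)
    signal = np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    for (f_lo, f_hi), power in band_targets:
        if f_hi > fs / 2:
            raise ValueError(f"band edge {f_hi} Hz above Nyquist {fs / 2} Hz")
        if power < 0:
            raise ValueError("band power must be nonnegative")
        if power == 0:
            continue
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        mask = (freqs >= f_lo) & (freqs <= f_hi)
        spec[~mask] = 0.0
        comp = np.fft.irfft(spec, n)
        sd = comp.std()
        if sd > 0:
            comp *= np.sqrt(power) / sd
        signal += comp
    if floor_sd > 0:
        signal += floor_sd * rng.standard_normal(n)
    return signal


# ---------------------------------------------------------------------------
# Presets: one per emulated dataset


def _pd_sweep(seed: int = 1) -> ParameterSweepTable:
    """200 random electrical-DBS parameter sets vs. beta-band power.

    Ranges cover the therapeutic STN-DBS programming window (amplitudes
    50-500 uA, frequencies 60-185 Hz, pulse widths 50-500 us); the
    suppression profile's relative log-width of 1 gives the graded,
    saturating high-frequency effect seen empirically, and ``noise_sd``
    reflects the large window-to-window variability of bursty beta power
    (CV ~ 40% of the mean response level).
    """
    bounds = {"amplitude": (50.0, 500.0), "frequency": (60.0, 185.0), "pulse_width": (50.0, 500.0)}
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
    n = 200
    params = np.column_stack([rng.uniform(lo, hi, n) for lo, hi in bounds.values()])
    config = SurrogateConfig(
        baseline_power=1.0,
        amplitude_gain=0.0012,
        pulsewidth_gain=0.0006,
        frequency_center=130.0,
        frequency_width=130.0,
        noise_sd=0.25,
        seed=seed,
    )
    responses = simulate_response_surface(params, config, m=1)
    return ParameterSweepTable(
        parameters=params,
        responses=responses,
        metadata={
            "preset": "pd_sweep",
            "units": {"amplitude": "uA", "frequency": "Hz", "pulse_width": "us"},
            "band": "beta 13-30 Hz",
            "bounds": bounds,
            "surrogate": config.__dict__ | {},
        },
    )


#: the 5 x 10 x 2 electrical-stimulation grid (100 combinations)
NHP_GRID = GridSpec(
    amplitude_levels=(100.0, 200.0, 300.0, 400.0, 500.0),
    frequency_levels=(7.0, 12.0, 31.0, 50.0, 65.0, 72.0, 100.0, 130.0, 145.0, 180.0),
    pulsewidth_levels=(200.0, 400.0),
)


def _nhp_grid(seed: int = 1) -> ParameterSweepTable:
    """100-combination grid with 4 repeated sessions vs. theta power."""
    params = make_parameter_grid(NHP_GRID)
    config = SurrogateConfig(
        baseline_power=1.0,
        amplitude_gain=0.0012,
        pulsewidth_gain=0.0008,
        frequency_center=130.0,
        frequency_width=130.0,
        noise_sd=0.2,
        session_sd=0.15,
        seed=seed,
    )
    responses = simulate_response_surface(params, config, m=4)
    _, state = simulate_state_dependent(params, replace(config, state_coupling=0.3))
    return ParameterSweepTable(
        parameters=params,
        responses=responses,
        pre_stim_state=state,
        metadata={
            "preset": "nhp_grid",
            "units": {"amplitude": "uA", "frequency": "Hz", "pulse_width": "us"},
            "band": "theta 5-8 Hz",
            "sessions": 4,
            "surrogate": config.__dict__ | {},
        },
    )


#: admissible 4 x 6 x 3 factorization of the 72-combination optical sweep
OPTO_GRID = GridSpec(
    amplitude_levels=tuple(np.linspace(10.0, 50.0, 4)),
    frequency_levels=tuple(np.linspace(5.0, 42.0, 6)),
    pulsewidth_levels=tuple(np.linspace(2.0, 10.0, 3)),
)

#: 9 x 12 x 10 grid (1080 points) for the closed-loop replication preset
INVIVO_GRID = GridSpec(
    amplitude_levels=tuple(np.linspace(10.0, 50.0, 9)),
    frequency_levels=tuple(np.linspace(5.0, 42.0, 12)),
    pulsewidth_levels=tuple(np.linspace(2.0, 10.0, 10)),
)

_OPTO_CONFIG = dict(
    baseline_power=1.0,
    amplitude_gain=0.01,
    pulsewidth_gain=0.03,
    frequency_center=35.0,
    frequency_width=15.0,
    noise_sd=0.1,
)


def _opto_like(grid: GridSpec, preset: str, seed: int) -> ParameterSweepTable:
    params = make_parameter_grid(grid)
    config = SurrogateConfig(**_OPTO_CONFIG, seed=seed)
    responses = simulate_response_surface(params, config, m=1)
    return ParameterSweepTable(
        parameters=params,
        responses=responses,
        metadata={
            "preset": preset,
            "units": {"amplitude": "mW/mm^2", "frequency": "Hz", "pulse_width": "ms"},
            "band": "slow gamma 31-55 Hz",
            "surrogate": config.__dict__ | {},
        },
    )


def _opto_sweep(seed: int = 1) -> ParameterSweepTable:
    """72-combination optogenetic sweep vs. slow-gamma power."""
    return _opto_like(OPTO_GRID, "opto_sweep", seed)


def _invivo_grid(seed: int = 1) -> ParameterSweepTable:
    """Dense 1080-point optical grid used by the closed-loop preset."""
    return _opto_like(INVIVO_GRID, "invivo_grid", seed)


PRESETS: dict[str, Callable[[int], ParameterSweepTable]] = {
    "pd_sweep": _pd_sweep,
    "nhp_grid": _nhp_grid,
    "opto_sweep": _opto_sweep,
    "invivo_grid": _invivo_grid,
}


def make_preset(name: str, seed: int = 1) -> ParameterSweepTable:
    """Generate one of the named emulated datasets."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return factory(seed)
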