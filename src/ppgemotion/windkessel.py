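"""Dual-windkessel simulation of the arterial pulse wave.

The arterial tree is modelled as a lumped, third-order electrical analog:
a half-sine ejection current ``Q(t)`` feeds a proximal compliance ``C1``
(aortic arch and main branches), blood inertia is a series inductance
``L``, and the distal compartment is a compliance ``C2`` in parallel with
the peripheral resistance ``R``.  The distal pressure ``P2`` is read out
as the surrogate for the photoplethysmographic (PPG) pulse.

State equations (model units are a self-consistent arbitrary system)::

    C1 * dP1/dt = Q(t) - iL
    L  * diL/dt = P1 - P2
    C2 * dP2/dt = iL - P2 / R

Ejection is a half-sine of peak ``Q0`` over the systolic interval
``[0, Ts)`` and zero over diastole ``[Ts, Td)``, repeated with the cardiac
period ``Td``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "WindkesselParams",
    "PulseWave",
    "SimulationError",
    "PARAM_NAMES",
    "BASE_PARAMS",
    "ALT_PARAMS",
    "inflow",
    "simulate",
    "settle_cycles_for",
    "settled_cycle",
    "sweep_parameter",
    "sweep_matrix",
    "PUBLISHED_DIRECTIONS",
    "COMPUTED_DIRECTIONS",
    "KNOWN_DIRECTION_DEVIATIONS",
]

#: The seven tunable circuit parameters, in canonical order.
PARAM_NAMES = ("R", "L", "C1", "C2", "Q0", "Ts", "Td")


class SimulationError(RuntimeError):
    """Raised when the circuit integration fails or diverges."""


@dataclass(frozen=True)
class WindkesselParams:
    """Parameter set of the dual-windkessel circuit.

    Parameters
    ----------
    R : float
        Peripheral vascular resistance.
    L : float
        Blood-flow inertance.
    C1 : float
        Proximal (aortic arch) compliance.
    C2 : float
        Distal (aorta + peripheral vessels) compliance.
    Q0 : float
        Peak ejection flow (extreme point of blood flow).
    Ts : float
        Systole duration in seconds.
    Td : float
        Cardiac cycle duration in seconds.
    max_td : float
        Physiological guard on the cycle length (seconds).
    """

    R: float
    L: float
    C1: float
    C2: float
    Q0: float
    Ts: float
    Td: float
    max_td: float = 2.0

    def __post_init__(self) -> None:
        for name in ("R", "L", "C1", "C2", "Ts", "Td"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not np.isfinite(self.Q0) or self.Q0 < 0:
            raise ValueError(f"Q0 must be non-negative, got {self.Q0!r}")
        if self.Ts >= self.Td:
            raise ValueError(f"systole Ts={self.Ts} must be shorter than cycle Td={self.Td}")
        if self.Td > self.max_td:
            raise ValueError(f"Td={self.Td} exceeds the physiological guard {self.max_td} s")

    def scaled(self, name: str, factor: float) -> "WindkesselParams":
        """Return a copy with one named parameter multiplied by ``factor``."""
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}; expected one of {PARAM_NAMES}")
        return replace(self, **{name: getattr(self, name) * factor})

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}


#: Baseline parameter set (resting-state pulse shape).
BASE_PARAMS = WindkesselParams(R=0.8, L=0.008, C1=0.8, C2=0.18, Q0=395.0, Ts=0.28, Td=0.77)

#: Alternative published parameterization (faster, stiffer circulation).
ALT_PARAMS = WindkesselParams(R=1.2, L=0.012, C1=1.2, C2=0.20, Q0=450.0, Ts=0.25, Td=0.67)


@dataclass(frozen=True)
class PulseWave:
    """A uniformly sampled simulated pulse train."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size < 2:
            raise ValueError("a pulse wave needs at least two samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("pulse wave contains non-finite samples")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


def inflow(params: WindkesselParams, t):
    """Ejection flow at time(s) ``t``: a Td-periodic half-sine burst.

    ``Q(t) = Q0 * sin(pi * phase / Ts)`` for cycle phase in ``[0, Ts)``,
    zero through diastole.  The peak value ``Q0`` occurs at phase ``Ts/2``.
    """
    t = np.asarray(t, dtype=float)
    phase = np.mod(t, params.Td)
    q = np.where(phase < params.Ts,
                 params.Q0 * np.sin(np.pi * phase / params.Ts),
                 0.0)
    # sin can go fractionally negative at the phase == Ts boundary
    return np.maximum(q, 0.0) if q.ndim else float(max(q, 0.0))


def mean_inflow(params: WindkesselParams) -> float:
    """Time-average of the ejection flow over one cardiac cycle.

    Analytically ``Q0 * 2 * Ts / (pi * Td)`` (integral of the half-sine).
    """
    return params.Q0 * 2.0 * params.Ts / (np.pi * params.Td)


def settle_cycles_for(params: WindkesselParams, n_time_constants: float = 8.0) -> int:
    """Cycles needed for start-up transients to decay.

    The slowest mode of the circuit is bounded by the RC product of the
    peripheral resistance with the total compliance; ``n_time_constants``
    of that bound (floor 10 cycles) leaves a relative residual below
    ``exp(-n_time_constants)``.
    """
    tau = params.R * (params.C1 + params.C2)
    return max(10, int(np.ceil(n_time_constants * tau / params.Td)))


def _rhs(t, y, p: WindkesselParams):
    p1, il, p2 = y
    q = p.Q0 * np.sin(np.pi * (t % p.Td) / p.Ts) if (t % p.Td) < p.Ts else 0.0
    return (
        (q - il) / p.C1,
        (p1 - p2) / p.L,
        (il - p2 / p.R) / p.C2,
    )


def simulate(
    params: WindkesselParams,
    fs: float = 125.0,
    n_cycles: int = 26,
    settle_cycles: int = 10,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float | None = None,
) -> PulseWave:
    """Integrate the circuit from rest and return the settled distal pressure.

    The first ``settle_cycles`` cardiac cycles are discarded so transients
    of the zero initial state have decayed; the remaining ``n_cycles``
    cycles of ``P2`` are returned sampled at ``fs`` Hz.
    """
    if fs < 50:
        raise ValueError("fs must be at least 50 Hz to resolve the pulse")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    t_start = settle_cycles * params.Td
    t_end = t_start + n_cycles * params.Td
    n_out = int(round(n_cycles * params.Td * fs))
    t_eval = t_start + np.arange(n_out) / fs
    if max_step is None:
        max_step = params.Ts / 4.0
    sol = solve_ivp(
        _rhs,
        (0.0, t_end),
        (0.0, 0.0, 0.0),
        t_eval=t_eval,
        args=(params,),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        max_step=max_step,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationError(
            f"windkessel integration failed for parameters {params.as_dict()}: {sol.message}"
        )
    return PulseWave(samples=sol.y[2], fs=fs, t0=0.0)


def settled_cycle(
    params: WindkesselParams,
    n_points: int = 2048,
    settle_cycles: int = 10,
    **kwargs,
) -> np.ndarray:
    """One settled cardiac cycle of ``P2`` on a uniform phase grid.

    Convenience for beat-by-beat resynthesis: the returned array holds
    ``n_points`` samples spanning exactly one period ``Td`` (endpoint
    excluded).
    """
    fs = n_points / params.Td
    wave = simulate(params, fs=fs, n_cycles=1, settle_cycles=settle_cycles, **kwargs)
    return wave.samples


def sweep_parameter(
    name: str,
    base: WindkesselParams = BASE_PARAMS,
    rel_step: float = 0.5,
    fs: float = 125.0,
    deadband: float = 0.01,
    target_duration: float = 20.0,
) -> dict[str, int]:
    """Direction of change of the nine harmonic features when one parameter grows.

    Simulates the circuit at ``base`` and with ``name`` multiplied by
    ``1 + rel_step``, extracts the nine frequency-domain features from
    each settled waveform (fundamental at ``1/Td``), and reports the sign
    of the induced relative change per feature: ``+1`` increase, ``-1``
    decrease, ``0`` when the relative change stays inside ``deadband``.
    """
    from .features import band_powers, freq_features

    if name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {name!r}")
    if not 0 < rel_step <= 0.5:
        raise ValueError("rel_step must be in (0, 0.5]")

    def run(p: WindkesselParams) -> dict[str, float]:
        n_cycles = max(2, int(round(target_duration / p.Td)))
        wave = simulate(p, fs=fs, n_cycles=n_cycles)
        bands = band_powers(wave.samples, fs, f0=1.0 / p.Td)
        return freq_features(bands)

    f_base = run(base)
    f_up = run(base.scaled(name, 1.0 + rel_step))
    signs: dict[str, int] = {}
    for feat, v0 in f_base.items():
        rel = (f_up[feat] - v0) / abs(v0) if v0 != 0 else np.inf * np.sign(f_up[feat])
        signs[feat] = 0 if abs(rel) < deadband else (1 if rel > 0 else -1)
    return signs


#: Published direction-of-change matrix for the nine harmonic features under
#: a 50% increase of each circuit parameter (+1 up, -1 down, 0 inside the
#: dead-band), keyed feature -> parameter.
PUBLISHED_DIRECTIONS: dict[str, dict[str, int]] = {
    "BF":     {"R": -1, "C1": -1, "C2": -1, "L": +1, "Q0": +1, "Td": +1, "Ts": +1},
    "BFn":    {"R": -1, "C1": -1, "C2": -1, "L": -1, "Q0": +1, "Td": +1, "Ts": +1},
    "FHF":    {"R": +1, "C1": -1, "C2": +1, "L": +1, "Q0": +1, "Td": +1, "Ts": -1},
    "FHFn":   {"R": +1, "C1": +1, "C2": +1, "L": +1, "Q0": 0,  "Td": -1, "Ts": -1},
    "SHF":    {"R": +1, "C1": -1, "C2": -1, "L": -1, "Q0": 0,  "Td": +1, "Ts": -1},
    "SHFn":   {"R": +1, "C1": -1, "C2": -1, "L": -1, "Q0": 0,  "Td": +1, "Ts": -1},
    "FHFBF":  {"R": +1, "C1": +1, "C2": +1, "L": +1, "Q0": 0,  "Td": -1, "Ts": -1},
    "SHFBF":  {"R": +1, "C1": -1, "C2": -1, "L": -1, "Q0": 0,  "Td": +1, "Ts": -1},
    "SHFFHF": {"R": +1, "C1": -1, "C2": -1, "L": -1, "Q0": 0,  "Td": +1, "Ts": -1},
}

#: Regression fixture: directions this implementation computes around
#: ``BASE_PARAMS`` at rel_step 0.5 with a 1% relative dead-band.
COMPUTED_DIRECTIONS: dict[str, dict[str, int]] = {
    "BF":     {"R": 0,  "L": +1, "C1": -1, "C2": -1, "Q0": +1, "Ts": +1, "Td": +1},
    "BFn":    {"R": 0,  "L": -1, "C1": -1, "C2": -1, "Q0": 0,  "Ts": +1, "Td": -1},
    "FHF":    {"R": 0,  "L": +1, "C1": -1, "C2": +1, "Q0": +1, "Ts": -1, "Td": +1},
    "FHFn":   {"R": 0,  "L": +1, "C1": +1, "C2": +1, "Q0": 0,  "Ts": -1, "Td": +1},
    "SHF":    {"R": +1, "L": +1, "C1": -1, "C2": +1, "Q0": +1, "Ts": -1, "Td": +1},
    "SHFn":   {"R": +1, "L": +1, "C1": +1, "C2": +1, "Q0": 0,  "Ts": -1, "Td": +1},
    "FHFBF":  {"R": 0,  "L": +1, "C1": +1, "C2": +1, "Q0": 0,  "Ts": -1, "Td": +1},
    "SHFBF":  {"R": +1, "L": +1, "C1": +1, "C2": +1, "Q0": 0,  "Ts": -1, "Td": +1},
    "SHFFHF": {"R": +1, "L": +1, "C1": +1, "C2": +1, "Q0": 0,  "Ts": -1, "Td": +1},
}

#: Cells (feature, parameter) where the computed direction persistently
#: differs from the published arrow at these sweep settings.  These are
#: surfaced, not hidden: around the alternative published operating point
#: (:data:`ALT_PARAMS`) all but seven cells agree, and the two Q0-column
#: entries of the published matrix (BFn up, SHF zero) are impossible for any
#: linear time-invariant circuit, since scaling the forcing scales all band
#: powers equally and leaves every ratio unchanged.  See docs/methods.md for
#: the full analysis.
KNOWN_DIRECTION_DEVIATIONS: frozenset[tuple[str, str]] = frozenset(
    (feat, par)
    for feat, row in PUBLISHED_DIRECTIONS.items()
    for par, sign in row.items()
    if COMPUTED_DIRECTIONS[feat][par] != sign
)


def sweep_matrix(
    base: WindkesselParams = BASE_PARAMS,
    rel_step: float = 0.5,
    fs: float = 125.0,
    deadband: float = 0.01,
) -> dict[str, dict[str, int]]:
    """Full 9-feature x 7-parameter direction matrix, keyed by parameter."""
    return {
        name: sweep_parameter(name, base=base, rel_step=rel_step, fs=fs, deadband=deadband)
        for name in PARAM_NAMES
    }
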