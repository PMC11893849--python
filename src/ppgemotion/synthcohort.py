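"""Synthetic multi-subject PPG cohorts with emotion-conditioned physiology.

Each subject gets a personal windkessel parameter set drawn around the
baseline pulse shape with a lognormal spread; an emotion condition is a
set of multiplicative parameter shifts (multiplicative so positivity
invariants hold automatically).  High arousal stiffens the circulation
(higher peripheral resistance, stronger ejection, shorter cycle); high
valence shifts compliance and inertia.  Raw epochs are synthesized
beat-by-beat from the settled simulator cycle with per-beat period
jitter, a respiration-band baseline-wander tone, and broadband sensor
noise, then sampled at the nominal 125 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import Epoch
from .windkessel import BASE_PARAMS, WindkesselParams, settled_cycle

__all__ = [
    "CohortSpec",
    "LabeledCohort",
    "HIGH_AROUSAL_SHIFTS",
    "HIGH_VALENCE_SHIFTS",
    "draw_subject",
    "synth_epoch",
    "generate",
]

#: High-arousal physiology: vasoconstriction and intensified cardiac
#: activity — higher peripheral resistance, stronger ejection, faster beat.
HIGH_AROUSAL_SHIFTS: dict[str, float] = {"R": 1.3, "Q0": 1.15, "Td": 0.87}

#: High-valence physiology: altered proximal compliance and inertia.
HIGH_VALENCE_SHIFTS: dict[str, float] = {"C1": 1.15, "L": 1.2}


@dataclass(frozen=True)
class CohortSpec:
    """Generation recipe for one synthetic cohort.

    Noise amplitudes are fractions of the clean pulse peak-to-peak range;
    the baseline wander is a single tone drawn uniformly from
    ``wander_band`` (respiration range) per epoch.  ``subject_spread`` is
    the lognormal coefficient of variation of the per-subject parameter
    draws.  ``condition_shifts`` maps condition name to per-parameter
    multipliers applied on top of the subject's baseline.
    """

    n_subjects: int = 20
    epochs_per_condition: int = 30
    fs: float = 125.0
    epoch_s: float = 20.0
    base: WindkesselParams = BASE_PARAMS
    subject_spread: float = 0.10
    dimension: str = "arousal"
    condition_shifts: dict = field(default_factory=lambda: {
        "low": {},
        "high": dict(HIGH_AROUSAL_SHIFTS),
    })
    wander_band: tuple[float, float] = (0.2, 0.35)
    wander_amp: float = 0.3
    noise_sd: float = 0.02
    jitter_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.epochs_per_condition < 1:
            raise ValueError("counts must be >= 1")
        if min(self.wander_amp, self.noise_sd, self.jitter_cv,
               self.subject_spread) < 0:
            raise ValueError("spread and noise fractions must be >= 0")

    def manifest(self) -> dict:
        d = asdict(self)
        d["base"] = self.base.as_dict()
        return d


@dataclass(frozen=True)
class LabeledCohort:
    """Generated epochs plus the resolved recipe that produced them."""

    epochs: list[Epoch]
    spec: CohortSpec

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ep in self.epochs:
            lab = ep.meta["condition"]
            out[lab] = out.get(lab, 0) + 1
        return out


_JITTERED = ("R", "L", "C1", "C2", "Q0")  # Ts/Td handled jointly to keep Ts < Td


def draw_subject(spec: CohortSpec, subject_index: int, max_attempts: int = 100) -> WindkesselParams:
    """Per-subject baseline parameters: lognormal spread around the base.

    Deterministic given ``(spec.seed, subject_index)``.  A draw violating
    the parameter invariants is redrawn; generation aborts after
    ``max_attempts`` failures.
    """
    rng = np.random.default_rng([spec.seed, 1000003, subject_index])
    base = spec.base
    if spec.subject_spread == 0:
        return base
    sigma = np.sqrt(np.log1p(spec.subject_spread**2))  # lognormal CV -> sigma
    for _ in range(max_attempts):
        factors = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=6))
        try:
            draw = {n: getattr(base, n) * f for n, f in zip(_JITTERED, factors)}
            # one shared factor for the timing pair preserves Ts < Td
            draw["Ts"] = base.Ts * factors[5]
            draw["Td"] = base.Td * factors[5]
            return WindkesselParams(**draw)
        except ValueError:
            continue
    raise RuntimeError(f"could not draw valid parameters for subject {subject_index}")


def _apply_shifts(params: WindkesselParams, shifts: dict[str, float]) -> WindkesselParams:
    p = params
    for name, factor in shifts.items():
        p = p.scaled(name, factor)
    return p


def synth_epoch(
    params: WindkesselParams,
    condition: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    subject_id: str = "",
    cycle: np.ndarray | None = None,
    start_time: float = 0.0,
) -> Epoch:
    """One raw labelled epoch from a subject's (condition-shifted) physiology.

    The settled simulator cycle is repeated beat by beat; each beat is
    time-stretched by an independent lognormal factor of coefficient of
    variation ``jitter_cv`` (an approximation to re-integrating per beat,
    exact for period changes of a quasi-static circuit).  A respiration
    tone and white noise are then added and the result sampled at
    ``spec.fs``.
    """
    if condition not in spec.condition_shifts:
        raise ValueError(f"condition {condition!r} not defined in spec")
    shifted = _apply_shifts(params, spec.condition_shifts[condition])
    if cycle is None:
        cycle = settled_cycle(shifted)
    n_out = int(round(spec.epoch_s * spec.fs))
    t_grid = np.arange(n_out) / spec.fs

    # beat boundaries with per-beat period jitter
    sigma = np.sqrt(np.log1p(spec.jitter_cv**2)) if spec.jitter_cv > 0 else 0.0
    starts = [0.0]
    periods = []
    while starts[-1] < spec.epoch_s:
        f = np.exp(rng.normal(-sigma**2 / 2.0, sigma)) if sigma else 1.0
        periods.append(shifted.Td * f)
        starts.append(starts[-1] + periods[-1])
    starts = np.asarray(starts)
    beat_idx = np.clip(np.searchsorted(starts, t_grid, side="right") - 1,
                       0, len(periods) - 1)
    phase = (t_grid - starts[beat_idx]) / np.asarray(periods)[beat_idx]
    phase = np.clip(phase, 0.0, 1.0 - 1e-12)
    pos = phase * cycle.size
    samples = np.interp(pos, np.arange(cycle.size + 1),
                        np.r_[cycle, cycle[0]])

    p2p = float(np.ptp(cycle))
    f_w = rng.uniform(*spec.wander_band)
    phi = rng.uniform(0, 2 * np.pi)
    samples = samples + spec.wander_amp * p2p * np.sin(2 * np.pi * f_w * t_grid + phi)
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd * p2p, size=n_out)

    labels = {}
    if spec.dimension in ("arousal", "valence"):
        labels[f"label_{spec.dimension}"] = condition
    return Epoch(
        samples=samples, fs=spec.fs, start_time=start_time,
        subject_id=subject_id,
        label_arousal=labels.get("label_arousal"),
        label_valence=labels.get("label_valence"),
        meta={"condition": condition, "params": shifted.as_dict()},
    )


def generate(spec: CohortSpec) -> LabeledCohort:
    """Full factorial cohort: subjects x conditions x epochs.

    Deterministic for a given spec (including its seed).  One simulator
    run per subject-condition pair provides the settled cycle reused by
    all of that pair's epochs.  Aborts when more than 1% of epochs fail
    to simulate.
    """
    epochs: list[Epoch] = []
    failures = 0
    total = spec.n_subjects * len(spec.condition_shifts) * spec.epochs_per_condition
    for si in range(spec.n_subjects):
        subject_id = f"S{si:03d}"
        base = draw_subject(spec, si)
        for ci, condition in enumerate(spec.condition_shifts):
            shifted = _apply_shifts(base, spec.condition_shifts[condition])
            cycle = settled_cycle(shifted)
            rng = np.random.default_rng([spec.seed, 2000003, si, ci])
            for k in range(spec.epochs_per_condition):
                try:
                    epochs.append(synth_epoch(
                        base, condition, spec, rng, subject_id=subject_id,
                        cycle=cycle, start_time=k * spec.epoch_s,
                    ))
                except Exception:
                    failures += 1
                    if failures > max(1, total // 100):
                        raise
    return LabeledCohort(epochs=epochs, spec=spec)
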