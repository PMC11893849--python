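"""Feature extraction from preprocessed PPG epochs.

Three feature families are computed per 20-s epoch:

* **FREQ9** — nine harmonic frequency-domain features.  The pulse spectrum
  concentrates in narrow bands at the heart-rate fundamental ``f0`` and
  its first two harmonics; band powers BF, FHF, SHF are the spectral mass
  in ``k*f0 ± 0.2 Hz`` for ``k = 1, 2, 3``, and the remaining six features
  are their normalized shares and pairwise ratios.
* **PRV** — pulse-rate-variability statistics over the NN (peak-to-peak)
  interval sequence, in milliseconds, plus approximate entropy, fuzzy
  entropy and Lempel-Ziv complexity of that sequence.
* **MORPH** — per-beat morphology (amplitudes, limb durations, slopes and
  areas) averaged over the beats of the epoch.

Per-subject feature normalization removes inter-individual offsets by a
within-subject z-transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FREQ9",
    "PRV",
    "MORPH",
    "SpectralBands",
    "power_spectrum",
    "mean_hr",
    "band_powers",
    "freq_features",
    "prv_features",
    "morph_features",
    "normalize_by_subject",
    "approximate_entropy",
    "fuzzy_entropy",
    "lempel_ziv_complexity",
]

FREQ9 = ("BF", "BFn", "FHF", "FHFn", "SHF", "SHFn", "FHFBF", "SHFBF", "SHFFHF")

PRV = (
    "MeanNN", "SDNN", "RMSNN", "MedianNN", "RDNN", "IQRNN", "CVNN",
    "SDSD", "RMSSD", "CVSD", "pNN20", "ApEn", "FuzzyEn", "LZC",
)

MORPH = (
    "Amp_Diff", "Interval_Rise", "Interval_Drop", "Slope_Rise",
    "Slope_Max_Rise", "Slope_Drop", "Slope_Min_Drop", "Area_Rise",
    "Area_Drop", "Area_Total", "Area_Rise_rate", "Area_Drop_rate",
    "Area_Total_rate", "Area_RD_rate",
)

FAMILIES = {"freq": FREQ9, "prv": PRV, "morph": MORPH}


class InsufficientBeatsError(ValueError):
    """Raised when a fiducial set has too few beats for the request."""


# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralBands:
    """Harmonic band powers of one epoch.

    ``BF``/``FHF``/``SHF`` are the spectral powers (signal units squared)
    in the bands ``[k*f0 - hw, k*f0 + hw]`` for ``k = 1, 2, 3``.
    """

    BF: float
    FHF: float
    SHF: float
    f0: float
    half_width: float = 0.2

    def __post_init__(self) -> None:
        if min(self.BF, self.FHF, self.SHF) < 0:
            raise ValueError("band powers must be non-negative")
        if self.f0 <= 2 * self.half_width:
            raise ValueError(
                f"f0={self.f0:.3f} Hz too low: harmonic bands of half-width "
                f"{self.half_width} Hz would overlap"
            )


def power_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided discrete power spectrum with an exact Parseval balance.

    The signal mean is removed, so ``power.sum()`` equals the population
    variance of ``x`` to rounding error.  Returns ``(freqs, power)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    spec = np.fft.rfft(x - x.mean())
    power = np.abs(spec) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def mean_hr(peak_indices: np.ndarray, fs: float) -> float:
    """Mean heart rate in beats per minute from accepted systolic peaks."""
    peaks = np.asarray(peak_indices)
    if peaks.size < 2:
        raise InsufficientBeatsError("mean HR needs at least two peaks")
    return 60.0 / (float(np.mean(np.diff(peaks))) / fs)


def band_powers(
    samples: np.ndarray,
    fs: float,
    f0: float,
    half_width: float = 0.2,
) -> SpectralBands:
    """Spectral mass in the fundamental and first two harmonic bands.

    ``f0`` is the heart-rate fundamental in Hz (mean HR / 60).  A bin
    contributes to band ``k`` when its center frequency lies inside the
    closed interval ``[k*f0 - half_width, k*f0 + half_width]``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size / fs < 10.0:
        raise ValueError("epoch shorter than 10 s: frequency resolution too coarse")
    if 3 * f0 + half_width >= fs / 2:
        raise ValueError(f"third harmonic band exceeds Nyquist for f0={f0:.3f} Hz")
    freqs, power = power_spectrum(samples, fs)
    masses = []
    for k in (1, 2, 3):
        sel = (freqs >= k * f0 - half_width) & (freqs <= k * f0 + half_width)
        masses.append(float(power[sel].sum()))
    return SpectralBands(BF=masses[0], FHF=masses[1], SHF=masses[2],
                         f0=f0, half_width=half_width)


def freq_features(bands: SpectralBands) -> dict[str, float]:
    """The nine harmonic features: powers, normalized shares, ratios.

    Returns NaN entries when a ratio denominator vanishes; callers drop
    such epochs.
    """
    bf, fhf, shf = bands.BF, bands.FHF, bands.SHF
    total = bf + fhf + shf
    nan = float("nan")
    return {
        "BF": bf,
        "FHF": fhf,
        "SHF": shf,
        "BFn": bf / total if total > 0 else nan,
        "FHFn": fhf / total if total > 0 else nan,
        "SHFn": shf / total if total > 0 else nan,
        "FHFBF": fhf / bf if bf > 0 else nan,
        "SHFBF": shf / bf if bf > 0 else nan,
        "SHFFHF": shf / fhf if fhf > 0 else nan,
    }


# ---------------------------------------------------------------------------
# pulse rate variability
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int) -> np.ndarray:
    n = x.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) with Chebyshev distance.

    ``r`` defaults to ``0.2`` times the population standard deviation.
    Self-matches are counted, per the original definition.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * float(np.std(x))

    def phi(mm: int) -> float:
        templ = _embed(x, mm)
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
        c = np.mean(d <= r, axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def fuzzy_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Fuzzy entropy with exponential membership ``exp(-d**2 / r)``.

    Templates are baseline-removed (their own mean subtracted) before the
    Chebyshev distance is taken; self-matches are excluded.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * float(np.std(x))

    def phi(mm: int) -> float:
        templ = _embed(x, mm)
        templ = templ - templ.mean(axis=1, keepdims=True)
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
        mu = np.exp(-(d**2) / r)
        np.fill_diagonal(mu, 0.0)
        n = templ.shape[0]
        return float(mu.sum() / (n * (n - 1)))

    return float(np.log(phi(m)) - np.log(phi(m + 1)))


def lempel_ziv_complexity(x: np.ndarray, normalize: bool = True) -> float:
    """Lempel-Ziv (LZ76) complexity of the median-binarized sequence.

    When ``normalize`` is true the raw phrase count ``c`` is scaled by
    ``log2(n) / n`` so values are comparable across sequence lengths.
    """
    x = np.asarray(x, dtype=float)
    s = (x > np.median(x)).astype(np.uint8).tobytes()
    n = len(s)
    # LZ76 parsing: a new phrase ends when its extension no longer occurs
    # anywhere in the history seen so far
    c = 0
    i = 0
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    if not normalize:
        return float(c)
    return float(c * np.log2(n) / n) if n > 1 else float(c)


def prv_features(
    peak_indices: np.ndarray,
    fs: float,
    min_nn: int = 8,
    min_nn_complexity: int = 32,
) -> dict[str, float]:
    """Time-domain and complexity statistics of the NN-interval sequence.

    NN intervals are consecutive peak-to-peak times in milliseconds.
    Statistics need at least ``min_nn`` intervals; the entropy/complexity
    measures need ``min_nn_complexity`` and are returned as NaN below
    that (flagged missing rather than unreliable).
    """
    peaks = np.asarray(peak_indices)
    nn = np.diff(peaks) / fs * 1000.0
    out = dict.fromkeys(PRV, float("nan"))
    if nn.size < min_nn:
        return out
    diffs = np.diff(nn)
    mean_nn = float(np.mean(nn))
    sdnn = float(np.std(nn, ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    out.update(
        MeanNN=mean_nn,
        SDNN=sdnn,
        RMSNN=float(np.sqrt(np.mean(nn**2))),
        MedianNN=float(np.median(nn)),
        RDNN=float(np.max(nn) - np.min(nn)),
        IQRNN=float(np.percentile(nn, 75) - np.percentile(nn, 25)),
        CVNN=sdnn / mean_nn,
        SDSD=float(np.std(diffs, ddof=1)),
        RMSSD=rmssd,
        CVSD=rmssd / mean_nn,
        pNN20=float(np.mean(np.abs(diffs) > 20.0) * 100.0),
    )
    if nn.size >= min_nn_complexity and np.std(nn) > 0:
        out["ApEn"] = approximate_entropy(nn)
        out["FuzzyEn"] = fuzzy_entropy(nn)
        out["LZC"] = lempel_ziv_complexity(nn)
    return out


# ---------------------------------------------------------------------------
# pulse morphology
# ---------------------------------------------------------------------------

def morph_features(
    samples: np.ndarray,
    fs: float,
    peak_indices: np.ndarray,
    trough_indices: np.ndarray,
    agg: str = "mean",
) -> dict[str, float]:
    """Per-beat morphological descriptors, aggregated over the epoch.

    A beat is a trough-peak-trough triplet.  For each beat: rise amplitude
    (peak minus onset trough), limb durations, mean and extreme limb
    slopes, and trapezoidal areas above the beat baseline (the straight
    line joining the two troughs).  ``*_rate`` features divide each area
    by the beat duration; ``Area_RD_rate`` is the rise/drop area ratio.
    Aggregation is the mean over beats (``agg="median"`` available).
    """
    y = np.asarray(samples, dtype=float)
    peaks = np.asarray(peak_indices)
    troughs = np.asarray(trough_indices)
    agg_fn = {"mean": np.mean, "median": np.median}[agg]

    beats: list[dict[str, float]] = []
    for u, v in zip(troughs[:-1], troughs[1:]):
        inner = peaks[(peaks > u) & (peaks < v)]
        if inner.size != 1:
            continue
        p = int(inner[0])
        dur = (v - u) / fs
        amp = y[p] - y[u]
        t_rise = (p - u) / fs
        t_drop = (v - p) / fs
        baseline = np.interp(np.arange(u, v + 1), [u, v], [y[u], y[v]])
        b = y[u : v + 1] - baseline
        area_rise = float(np.trapezoid(b[: p - u + 1], dx=1.0 / fs))
        area_drop = float(np.trapezoid(b[p - u :], dx=1.0 / fs))
        beats.append({
            "Amp_Diff": amp,
            "Interval_Rise": t_rise,
            "Interval_Drop": t_drop,
            "Slope_Rise": amp / t_rise,
            "Slope_Max_Rise": float(np.max(np.diff(y[u : p + 1])) * fs),
            "Slope_Drop": (y[v] - y[p]) / t_drop,
            "Slope_Min_Drop": float(np.min(np.diff(y[p : v + 1])) * fs),
            "Area_Rise": area_rise,
            "Area_Drop": area_drop,
            "Area_Total": area_rise + area_drop,
            "Area_Rise_rate": area_rise / dur,
            "Area_Drop_rate": area_drop / dur,
            "Area_Total_rate": (area_rise + area_drop) / dur,
            "Area_RD_rate": area_rise / area_drop if area_drop != 0 else float("nan"),
        })
    if not beats:
        return dict.fromkeys(MORPH, float("nan"))
    return {name: float(agg_fn([b[name] for b in beats])) for name in MORPH}


# ---------------------------------------------------------------------------
# per-subject normalization
# ---------------------------------------------------------------------------

def normalize_by_subject(
    table: pd.DataFrame,
    feature_cols: list[str] | tuple[str, ...] | None = None,
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Within-subject z-transform of every feature column.

    For feature ``F`` of subject ``S``, each epoch value is replaced by
    ``(F - mean_S(F)) / std_S(F)`` where the mean and (population)
    standard deviation are taken over all of that subject's epochs.  A
    feature constant within a subject becomes NaN (flagged, not dropped
    here).
    """
    if feature_cols is None:
        meta = {subject_col, "epoch_id", "label_arousal", "label_valence", "condition"}
        feature_cols = [c for c in table.columns if c not in meta]
    out = table.copy()
    grouped = table.groupby(subject_col, sort=False)[list(feature_cols)]
    mean = grouped.transform("mean")
    std = grouped.transform(lambda s: np.std(s.to_numpy(), ddof=0))
    std = std.mask(std == 0)
    out[list(feature_cols)] = (table[list(feature_cols)] - mean) / std
    return out
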