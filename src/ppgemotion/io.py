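"""Readers, writers, run configuration, and the end-to-end pipeline.

All artifacts are plain delimited text or JSON/YAML: waveforms as
two-column ``time_s,amplitude`` files with a ``# fs=<Hz>`` header, labels
and feature tables as CSV, run configuration as YAML.  ``run_pipeline``
ties the stages together: synthesize (optional) -> preprocess -> extract
features -> screen + evaluate, writing every table, the resolved
configuration and a rejects log beside the results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Protocol

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import correlation_matrix, screen_features, svm_protocol
from .features import FAMILIES, band_powers, freq_features, mean_hr, morph_features, \
    normalize_by_subject, prv_features
from .preprocess import DegenerateSignalError, Epoch, PPGRecord, preprocess_record
from .synthcohort import CohortSpec, LabeledCohort, generate

__all__ = [
    "RunConfig",
    "RecordAdapter",
    "read_record",
    "write_record",
    "read_labels",
    "write_cohort",
    "feature_table",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

def read_record(path: str | Path, fs: float | None = None,
                subject_id: str | None = None) -> PPGRecord:
    """Read a delimited-text PPG record.

    Accepts one column (amplitude; requires ``fs``) or two columns
    (``time_s,amplitude``).  The sampling rate is taken from a ``# fs=``
    header comment first, the time-column spacing second, the ``fs``
    argument last; a conflict between header and argument is an error.
    """
    path = Path(path)
    header_fs = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "fs=" in line:
                    header_fs = float(line.split("fs=")[1].split()[0])
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                if not rows:
                    continue  # column-header line
                raise ValueError(f"{path}:{ln}: unparseable record line: {line!r}") from exc
    if not rows:
        raise ValueError(f"{path}: empty record")
    arr = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr).all(axis=1))[0]) + 1
        raise ValueError(f"{path}: non-finite sample near data line {bad}")
    if arr.shape[1] == 1:
        samples = arr[:, 0]
        eff_fs = header_fs if header_fs is not None else fs
        if eff_fs is None:
            raise ValueError(f"{path}: single-column record requires a sampling rate")
    else:
        t, samples = arr[:, 0], arr[:, 1]
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.flatnonzero(dt <= 0)[0]) + 2
            raise ValueError(f"{path}: non-monotone time column at data line {bad}")
        spacing_fs = 1.0 / float(np.median(dt))
        eff_fs = header_fs if header_fs is not None else spacing_fs
    if header_fs is not None and fs is not None and abs(header_fs - fs) > 1e-9:
        raise ValueError(f"{path}: header fs={header_fs} conflicts with override fs={fs}")
    return PPGRecord(samples=samples, fs=float(eff_fs),
                     subject_id=subject_id or path.stem)


def write_record(path: str | Path, record: PPGRecord) -> None:
    """Write a record as ``time_s,amplitude`` text with a ``# fs=`` header."""
    t = np.arange(record.n) / record.fs
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        fh.write("time_s,amplitude\n")
        for ti, yi in zip(t, record.samples):
            fh.write(f"{ti:.17g},{yi:.17g}\n")


def read_labels(path: str | Path, score_threshold: float = 5.0) -> pd.DataFrame:
    """Read a label sidecar table.

    Columns ``subject_id,stimulus_id,arousal,valence`` where the emotion
    columns hold either ``low``/``high`` or 1-9 self-report scores
    (binarized at ``score >= score_threshold`` -> ``high``).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "stimulus_id": str})
    for col in ("arousal", "valence"):
        vals = df[col]
        if vals.dtype.kind in "if":
            df[col] = np.where(vals >= score_threshold, "high", "low")
        else:
            bad = set(vals.unique()) - {"low", "high"}
            if bad:
                raise ValueError(f"{path}: invalid {col} labels {sorted(bad)}")
    return df


def write_cohort(cohort: LabeledCohort, outdir: str | Path) -> Path:
    """Write one record file per subject-condition plus labels and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups: dict[tuple[str, str], list[Epoch]] = {}
    for ep in cohort.epochs:
        groups.setdefault((ep.subject_id, ep.meta["condition"]), []).append(ep)
    labels = []
    for (subject, condition), eps in groups.items():
        samples = np.concatenate([ep.samples for ep in eps])
        rec = PPGRecord(samples=samples, fs=cohort.spec.fs, subject_id=subject)
        name = f"{subject}_{condition}.csv"
        write_record(outdir / name, rec)
        first = eps[0]
        labels.append({
            "subject_id": subject, "stimulus_id": condition,
            "arousal": first.label_arousal or "",
            "valence": first.label_valence or "",
            "file": name,
        })
    pd.DataFrame(labels).to_csv(outdir / "labels.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cohort.spec.manifest(), fh, indent=2, default=str)
    return outdir


# ---------------------------------------------------------------------------
# third-party dataset adapters
# ---------------------------------------------------------------------------

class RecordAdapter(Protocol):
    """Import hook for external affect datasets.

    An adapter is any callable that yields ``(record, arousal, valence)``
    triples — one validated :class:`PPGRecord` per subject-stimulus plus
    its ``"low"``/``"high"`` labels (``None`` when unlabeled).  Pass the
    yielded records through :func:`ppgemotion.preprocess.preprocess_record`
    and :func:`ppgemotion.preprocess.segment` to obtain epochs compatible
    with :func:`feature_table`.  No parser for any proprietary binary
    layout is included; adapters for such datasets live with their users.
    """

    def __call__(self) -> Iterator[tuple[PPGRecord, str | None, str | None]]:
        ...


# ---------------------------------------------------------------------------
# feature extraction over epochs
# ---------------------------------------------------------------------------

def feature_table(
    epochs: list[Epoch],
    families: tuple[str, ...] = ("freq",),
    normalize: bool = True,
    rejects: list | None = None,
) -> pd.DataFrame:
    """Preprocess each epoch and assemble the per-epoch feature table.

    Each raw epoch runs through the full conditioning chain (bandpass,
    smoothing, fiducial detection, baseline removal, z-score); requested
    feature families are computed from the cleaned signal and fiducials.
    Epochs without a detectable pulse are skipped and logged to
    ``rejects``.  With ``normalize`` the within-subject z-transform is
    applied to every feature column.
    """
    rows = []
    for idx, ep in enumerate(epochs):
        rec = PPGRecord(samples=ep.samples, fs=ep.fs, subject_id=ep.subject_id)
        try:
            clean, fid = preprocess_record(rec)
            hr = mean_hr(fid.peak_indices, ep.fs)
        except (DegenerateSignalError, ValueError) as exc:
            if rejects is not None:
                rejects.append({"epoch": idx, "subject_id": ep.subject_id,
                                "reason": str(exc)})
            continue
        row: dict = {
            "subject_id": ep.subject_id,
            "epoch_id": idx,
            "label_arousal": ep.label_arousal,
            "label_valence": ep.label_valence,
        }
        if "freq" in families:
            row.update(freq_features(band_powers(clean.samples, ep.fs, hr / 60.0)))
        if "prv" in families:
            row.update(prv_features(fid.peak_indices, ep.fs))
        if "morph" in families:
            row.update(morph_features(clean.samples, ep.fs,
                                      fid.peak_indices, fid.trough_indices))
        rows.append(row)
    table = pd.DataFrame(rows)
    if normalize and len(table):
        cols = [c for fam in families for c in FAMILIES[fam] if c in table.columns]
        table = normalize_by_subject(table, cols)
    return table


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (serialized beside outputs)."""

    seed: int = 0
    dimension: str = "arousal"
    families: tuple[str, ...] = ("freq",)
    iterations: int = 100
    alpha: float = 0.05
    normalize: bool = True
    epoch_s: float = 20.0
    fs: float = 125.0
    n_subjects: int = 20
    epochs_per_condition: int = 30
    effect_scale: float = 1.0
    out_dir: str = "results"
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("package_version", None)  # provenance stamp, not a knob
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}")
        if "families" in data:
            data["families"] = tuple(data["families"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        d["package_version"] = __version__
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _scaled_shifts(shifts: dict[str, float], scale: float) -> dict[str, float]:
    return {k: 1.0 + (v - 1.0) * scale for k, v in shifts.items()}


def run_pipeline(config: RunConfig) -> Path:
    """Synthesize a cohort and run it through the full analysis.

    Writes to ``config.out_dir``: the metrics table, the U-test screening
    table, ROC coordinates of the reported iteration, the feature
    correlation matrix and family summary, the resolved configuration,
    and a rejects log.  Deterministic for a fixed configuration.
    """
    from .synthcohort import HIGH_AROUSAL_SHIFTS, HIGH_VALENCE_SHIFTS

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_shift = (HIGH_AROUSAL_SHIFTS if config.dimension == "arousal"
                  else HIGH_VALENCE_SHIFTS)
    spec = CohortSpec(
        n_subjects=config.n_subjects,
        epochs_per_condition=config.epochs_per_condition,
        fs=config.fs,
        epoch_s=config.epoch_s,
        dimension=config.dimension,
        condition_shifts={
            "low": {},
            "high": _scaled_shifts(base_shift, config.effect_scale),
        },
        seed=config.seed,
    )
    cohort = generate(spec)
    rejects: list = []
    table = feature_table(cohort.epochs, families=config.families,
                          normalize=config.normalize, rejects=rejects)
    table.to_csv(out / "features.csv", index=False)

    feature_cols = [c for fam in config.families for c in FAMILIES[fam]
                    if c in table.columns and not table[c].isna().all()]
    retained, comparisons = screen_features(
        table, config.dimension, feature_cols, alpha=config.alpha)
    pd.DataFrame([{
        "feature": c.feature, "U": c.u_stat, "p_value": c.p_value,
        "n_low": c.n_a, "n_high": c.n_b, "stars": c.stars,
        "retained": c.feature in retained, "method": c.method,
    } for c in comparisons]).to_csv(out / "utest.csv", index=False)

    cols = retained if retained else feature_cols
    result = svm_protocol(table, config.dimension, cols,
                          iterations=config.iterations, seed=config.seed)
    pd.DataFrame([{"dimension": config.dimension,
                   "features": "+".join(config.families),
                   **result.as_dict()}]).to_csv(out / "metrics.csv", index=False)
    pd.DataFrame({"fpr": result.roc_fpr, "tpr": result.roc_tpr}).to_csv(
        out / "roc.csv", index=False)

    corr, summary = correlation_matrix(
        table, {fam: FAMILIES[fam] for fam in config.families})
    corr.to_csv(out / "correlation.csv")
    summary.to_csv(out / "correlation_families.csv")

    with open(out / "rejects.json", "w") as fh:
        json.dump(rejects, fh, indent=2)
    config.to_yaml(out / "resolved_config.yaml")
    return out
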