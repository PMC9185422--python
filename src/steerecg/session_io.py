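"""Canonical on-disk session format: plain CSV signals + YAML metadata.

Layout of one subject's session::

    SUBJECT/
      rest_reference.csv      # columns t_seconds,mv; '.' decimal; header row
      rest_wheel.csv
      city_reference.csv
      ...
      meta.yaml               # subject metadata + sampling rate
      manifest.yaml           # file list with sha256 checksums

The format is deliberately flat and inspectable; an adapter for an
externally deposited dataset can be plugged in via
:func:`import_external`.  NaN samples in an external wheel channel (a
common dropout encoding) are converted to 0 mV on read and reported as
synthetic dropout intervals.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from steerecg.core import CHANNELS, SCENARIOS, BeatAnnotation, Interval, Recording

MANIFEST_NAME = "manifest.yaml"
META_NAME = "meta.yaml"


class IntegrityError(RuntimeError):
    """A file's checksum does not match the manifest."""


@dataclass
class SubjectMetadata:
    """Demographics stored alongside a session; gender kept verbatim."""

    subject_id: str
    age: float | None = None
    height: float | None = None
    weight: float | None = None
    gender: str = ""

    def __post_init__(self) -> None:
        for attr in ("age", "height", "weight"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValueError(f"{attr} must be non-negative, got {v}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_session(
    recordings: list[Recording],
    metadata: SubjectMetadata,
    dir_path: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write a session to ``dir_path / subject_id``; returns the manifest path."""
    if not recordings:
        raise ValueError("no recordings to write")
    subject_ids = {r.subject_id for r in recordings}
    if len(subject_ids) != 1 or metadata.subject_id not in subject_ids:
        raise ValueError(
            f"recordings and metadata must share one subject_id, got {subject_ids} "
            f"and {metadata.subject_id!r}"
        )
    keys = [(r.scenario, r.channel) for r in recordings]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (scenario, channel) recordings")
    fs_values = {r.fs for r in recordings}
    if len(fs_values) != 1:
        raise ValueError(f"recordings have mixed sampling rates: {fs_values}")

    subject_dir = Path(dir_path) / metadata.subject_id
    if subject_dir.exists() and any(subject_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{subject_dir} exists and is not empty; pass overwrite=True to replace"
        )
    subject_dir.mkdir(parents=True, exist_ok=True)

    files = []
    for rec in recordings:
        fname = f"{rec.scenario}_{rec.channel}.csv"
        df = pd.DataFrame({"t_seconds": rec.times(), "mv": rec.samples})
        df.to_csv(subject_dir / fname, index=False, float_format="%.6f")
        files.append(fname)

    meta = {
        "subject": {k: v for k, v in asdict(metadata).items()},
        "fs": float(recordings[0].fs),
    }
    (subject_dir / META_NAME).write_text(yaml.safe_dump(meta, sort_keys=False))
    files.append(META_NAME)

    manifest = {
        "subject_id": metadata.subject_id,
        "files": {f: _sha256(subject_dir / f) for f in files},
    }
    manifest_path = subject_dir / MANIFEST_NAME
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def read_session(dir_path: str | Path) -> tuple[list[Recording], SubjectMetadata]:
    """Read a session directory written by :func:`write_session`.

    Checksums are verified against the manifest (mismatch raises
    :class:`IntegrityError` naming the file).  Missing scenario files
    produce a warning and a partial session.
    """
    subject_dir = Path(dir_path)
    manifest_path = subject_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())

    for fname, digest in manifest["files"].items():
        fpath = subject_dir / fname
        if not fpath.exists():
            continue  # reported below as a partial session
        if _sha256(fpath) != digest:
            raise IntegrityError(f"checksum mismatch for {fpath}")

    meta_raw = yaml.safe_load((subject_dir / META_NAME).read_text())
    metadata = SubjectMetadata(**meta_raw["subject"])
    fs = float(meta_raw["fs"])
    if fs <= 0:
        raise ValueError(f"stated sampling rate must be positive, got {fs}")

    recordings = []
    expected = [
        f"{sc}_{ch}.csv" for sc in SCENARIOS for ch in CHANNELS if f"{sc}_{ch}.csv" in manifest["files"]
    ]
    if not expected:
        warnings.warn(f"{subject_dir} contains no signal files; returning empty session")
    for fname in expected:
        fpath = subject_dir / fname
        if not fpath.exists():
            warnings.warn(f"missing scenario file {fname}; returning partial session")
            continue
        scenario, channel = fname[: -len(".csv")].rsplit("_", 1)
        df = pd.read_csv(fpath)
        if list(df.columns) != ["t_seconds", "mv"]:
            raise ValueError(
                f"{fpath}: malformed header line 1, expected 't_seconds,mv' "
                f"got {','.join(map(str, df.columns))!r}"
            )
        samples = df["mv"].to_numpy(dtype=float)
        if channel == "wheel" and np.isnan(samples).any():
            nan_ivs = _nan_intervals(samples)
            warnings.warn(
                f"{fpath}: {len(nan_ivs)} NaN run(s) converted to 0 mV (treated as dropouts)"
            )
            samples = np.nan_to_num(samples, nan=0.0)
        recordings.append(Recording(samples, fs, channel, scenario, metadata.subject_id))
    return recordings, metadata


def _nan_intervals(x: np.ndarray) -> list[Interval]:
    isnan = np.isnan(x).astype(int)
    edges = np.diff(np.concatenate([[0], isnan, [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return [Interval(int(s), int(e)) for s, e in zip(starts, ends)]


def write_annotations(ann: BeatAnnotation, path: str | Path) -> Path:
    """Write an annotation as CSV ``sample_index,provenance``."""
    path = Path(path)
    df = pd.DataFrame(
        {"sample_index": ann.peaks, "provenance": [ann.provenance] * len(ann.peaks)}
    )
    df.to_csv(path, index=False)
    return path


def read_annotations(path: str | Path, fs: float = 500.0) -> BeatAnnotation:
    """Read an annotation CSV; round-trips :func:`write_annotations` exactly."""
    df = pd.read_csv(path)
    if list(df.columns) != ["sample_index", "provenance"]:
        raise ValueError(
            f"{path}: malformed header line 1, expected 'sample_index,provenance'"
        )
    provenance = str(df["provenance"].iloc[0]) if len(df) else "truth"
    return BeatAnnotation(df["sample_index"].to_numpy(dtype=np.int64), provenance, fs)


def write_truth_sidecar(truth, dir_path: str | Path) -> None:
    """Write ground-truth sidecars next to a session.

    Per scenario: ``SCENARIO_truth_peaks.csv`` (column ``sample_index``)
    and ``SCENARIO_{artifact,dropout}_intervals.csv``
    (``start_sample,end_sample``, half-open).
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    for name, sc in truth.scenarios.items():
        pd.DataFrame({"sample_index": sc.peaks}).to_csv(
            dir_path / f"{name}_truth_peaks.csv", index=False
        )
        for kind, ivs in (
            ("artifact", sc.artifact_intervals),
            ("dropout", sc.dropout_intervals),
        ):
            pd.DataFrame(
                {
                    "start_sample": [iv.start for iv in ivs],
                    "end_sample": [iv.end for iv in ivs],
                }
            ).to_csv(dir_path / f"{name}_{kind}_intervals.csv", index=False)


def import_external(dir_path: str | Path):
    """Extension point for adapting an externally deposited dataset.

    The canonical reader covers only this package's own format; plug a
    dataset-specific adapter in here.
    """
    raise NotImplementedError(
        "no external-dataset adapter is configured; convert the data to the "
        "canonical CSV/YAML session format or supply an adapter"
    )
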