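"""Readers and writers for every artifact the pipeline touches.

Audio travels as 16-bit PCM WAV (the format the clinical recordings used);
tabular artifacts (the plosive data matrix, feature matrices, reports) are
comma-separated UTF-8 text with an explicit header, and trained models are
stored in a single versioned JSON file.  All round-trips are lossless up to
the documented 16-bit quantization of audio samples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioRecord",
    "DataMatrix",
    "DATA_MATRIX_COLUMNS",
    "read_wav",
    "write_wav",
    "write_data_matrix",
    "read_data_matrix",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

# Health status coding used in files, exactly as stored in the data matrix:
# 1 = depression, 2 = healthy control.  The +1/-1 coding used at the network
# boundary lives in neural_models; files never see it.
HEALTH_DEPRESSION = 1
HEALTH_CONTROL = 2


@dataclass
class AudioRecord:
    """A mono waveform with its sample rate and subject/laugh metadata.

    ``samples`` are float64 normalized to [-1, 1]; this is the unit every
    downstream stage (segmentation, feature extraction) consumes.
    """

    samples: np.ndarray
    sample_rate_hz: int
    subject_id: str = ""
    class_label: Optional[str] = None  # "depression" | "control" | None
    laugh_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioRecord holds mono audio (1-D samples)")
        if self.samples.size == 0:
            raise ValueError("AudioRecord must be non-empty")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        peak = float(np.max(np.abs(self.samples)))
        if peak > 1.0 + 2.0 ** -15:
            raise ValueError(f"samples exceed [-1, 1] (peak {peak:.4f})")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


# Column layout of the plosive data matrix: one row per plosive, the six
# sound variables (formants as three numbers), plosive placement within the
# laugh, timing, identifiers, and the dichotomous health status {1, 2}.
DATA_MATRIX_COLUMNS = [
    "subject_id",
    "laugh_id",
    "placement",
    "onset_ms",
    "duration_ms",
    "f0_mean_hz",
    "f1_hz",
    "f2_hz",
    "f3_hz",
    "avg_power",
    "entropy_bits",
    "voiced_pct",
    "health_status",
]

_ACOUSTIC_COLUMNS = [
    "duration_ms",
    "f0_mean_hz",
    "f1_hz",
    "f2_hz",
    "f3_hz",
    "avg_power",
    "entropy_bits",
    "voiced_pct",
]


@dataclass
class DataMatrix:
    """The per-plosive data matrix: plosive rows, variable columns.

    The seventh, dichotomous variable ``health_status`` codes the subject's
    condition as 1 (depression) or 2 (healthy control).  Missing acoustic
    values (e.g. F0 of a fully unvoiced plosive) are NaN and are handled
    explicitly by the feature-schema builder; ``validate`` can be asked to
    reject them for strictly complete matrices.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DATA_MATRIX_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in DATA_MATRIX_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"data matrix missing columns: {missing}")
        self.table = self.table[DATA_MATRIX_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self, require_complete: bool = False) -> None:
        if len(self.table) == 0:
            return
        status = self.table["health_status"].to_numpy()
        if not np.isin(status, [HEALTH_DEPRESSION, HEALTH_CONTROL]).all():
            bad = sorted(set(status) - {HEALTH_DEPRESSION, HEALTH_CONTROL})
            raise ValueError(f"health_status must be 1 or 2, found {bad}")
        if (self.table["placement"].to_numpy() < 1).any():
            raise ValueError("placement is 1-based and must be >= 1")
        if require_complete:
            acoustic = self.table[_ACOUSTIC_COLUMNS]
            if acoustic.isna().any().any():
                raise ValueError("acoustic columns contain missing values")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def read_wav(path, subject_id: str = "", class_label: Optional[str] = None,
             laugh_id: str = "") -> AudioRecord:
    """Read a PCM WAV file into an :class:`AudioRecord`.

    Integer PCM is scaled to [-1, 1] by the type's full scale (2^15 for
    16-bit); stereo input is downmixed to mono by channel averaging.
    Compressed/non-WAV files raise a format error naming the problem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise ValueError(f"{path} is not an uncompressed PCM WAV file: {exc}") from exc
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    if samples.ndim == 2:  # stereo -> mono
        samples = samples.mean(axis=1)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioRecord(samples=samples, sample_rate_hz=int(rate),
                       subject_id=subject_id, class_label=class_label,
                       laugh_id=laugh_id or path.stem)


def write_wav(record: AudioRecord, path) -> None:
    """Write an :class:`AudioRecord` as mono 16-bit PCM WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scaled = np.clip(record.samples, -1.0, 32767.0 / 32768.0)
    ints = np.round(scaled * 32768.0).astype(np.int16)
    wavfile.write(str(path), int(record.sample_rate_hz), ints)


# ---------------------------------------------------------------------------
# Data matrix I/O
# ---------------------------------------------------------------------------

def write_data_matrix(matrix: DataMatrix, path) -> None:
    """Write the plosive data matrix as CSV (comma, '.' decimal, header)."""
    matrix.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.table.to_csv(path, index=False, float_format="%.8g")


def read_data_matrix(path) -> DataMatrix:
    path = Path(path)
    table = pd.read_csv(path)
    unknown = [c for c in table.columns if c not in DATA_MATRIX_COLUMNS]
    missing = [c for c in DATA_MATRIX_COLUMNS if c not in table.columns]
    if unknown or missing:
        raise ValueError(
            f"{path}: schema mismatch (unknown columns {unknown}, missing "
            f"{missing}); expected header: {','.join(DATA_MATRIX_COLUMNS)}"
        )
    if len(table):
        table["subject_id"] = table["subject_id"].astype(str)
        table["laugh_id"] = table["laugh_id"].astype(str)
    return DataMatrix(table=table)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj.get("dtype", "float64"))
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def save_model(model, path) -> None:
    """Persist a trained model (MLP or RBFN) to a single versioned file.

    The payload is JSON with full-precision weights plus a checksum; loading
    verifies both the format version and the checksum so truncated or edited
    files fail loudly instead of silently corrupting predictions.
    """
    state = _encode(model.get_state())
    body = json.dumps({"model_class": type(model).__name__, "state": state},
                      sort_keys=True)
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "checksum": hashlib.sha256(body.encode()).hexdigest(),
        "body": body,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload))


def load_model(path):
    from . import neural_models  # late import: avoids a module cycle

    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: corrupt or truncated model file: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path}: not a laughdx model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {payload['format_version']} "
            f"!= supported {MODEL_FORMAT_VERSION}"
        )
    body = payload["body"]
    if hashlib.sha256(body.encode()).hexdigest() != payload.get("checksum"):
        raise ValueError(f"{path}: checksum mismatch (truncated or edited file)")
    doc = json.loads(body)
    state = _decode(doc["state"])
    cls = getattr(neural_models, doc["model_class"], None)
    if cls is None:
        raise ValueError(f"{path}: unknown model class {doc['model_class']!r}")
    return cls.from_state(state)
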