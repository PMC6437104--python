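"""The six sound variables of a laughter plosive, and the network schemas.

Per plosive the pipeline measures: time duration, fundamental-frequency
mean (autocorrelation tracking in 10 ms frames), the first three formants
(LPC root finding), average power per sample, spectral Shannon entropy over
the 50-10,000 Hz analysis band, and the voiced fraction of the
plosive-to-next-plosive interval.  The per-plosive rows form the data
matrix; laughs with at least five plosives are then folded into the three
network input schemas:

* ``ANN40`` (p=40): eight channels for each of the first five plosives —
  duration, F0 mean, F1, F2, average power, entropy, placement index, and
  onset time.  An optional label-channel variant swaps onset for the health
  label to demonstrate why a class-label input channel is target leakage.
* ``EANN5`` (p=5): average power of plosives 1-5 only.
* ``P5ANN6`` (p=6): the six acoustic numbers of the fifth plosive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import solve_toeplitz
from scipy.signal import find_peaks

from .soundio import AudioRecord, DataMatrix, DATA_MATRIX_COLUMNS, HEALTH_DEPRESSION
from .plosive_segmenter import PlosiveSegment

__all__ = [
    "F0Track",
    "PlosiveFeatures",
    "FeatureSchema",
    "FeatureMatrix",
    "SCHEMAS",
    "f0_track",
    "f0_mean",
    "formants_lpc",
    "average_power",
    "spectral_entropy",
    "voiced_fraction",
    "extract_plosive_features",
    "features_to_data_matrix",
    "build_feature_matrix",
]


# ---------------------------------------------------------------------------
# F0 tracking
# ---------------------------------------------------------------------------

@dataclass
class F0Track:
    f0_hz: np.ndarray        # per-frame estimate, NaN where unvoiced
    voiced: np.ndarray       # per-frame bool
    frame_ms: float
    empty: bool = False      # segment shorter than one analysis window

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())


def f0_track(samples: np.ndarray, sample_rate_hz: float, frame_ms: float = 10.0,
             window_ms: float = 30.0, f0_band: Tuple[float, float] = (75.0, 600.0),
             voicing_threshold: float = 0.65, peak_tolerance: float = 0.85) -> F0Track:
    """Frame-wise F0 by normalized autocorrelation, one estimate per 10 ms.

    A frame is voiced iff the normalized autocorrelation has a local peak
    >= ``voicing_threshold`` at a lag inside the F0 band.  Among candidate
    peaks within ``peak_tolerance`` of the best one, the smallest lag wins
    — the period is the *smallest* interval of vocal-fold oscillation, and
    this rejects the classic subharmonic (period-doubling) errors.  The
    pitch is the sample rate over that lag, refined by parabolic
    interpolation.
    """
    x = np.asarray(samples, dtype=np.float64)
    win = int(round(window_ms * 1e-3 * sample_rate_hz))
    hop = int(round(frame_ms * 1e-3 * sample_rate_hz))
    if x.size < win:
        return F0Track(f0_hz=np.empty(0), voiced=np.empty(0, bool),
                       frame_ms=frame_ms, empty=True)
    lag_min = max(2, int(math.floor(sample_rate_hz / f0_band[1])))
    lag_max = min(win - 2, int(math.ceil(sample_rate_hz / f0_band[0])))
    f0s, voiced = [], []
    for start in range(0, x.size - win + 1, hop):
        frame = x[start:start + win]
        frame = frame - frame.mean()
        energy = float(frame @ frame)
        if energy <= 0.0:
            f0s.append(np.nan)
            voiced.append(False)
            continue
        # full autocorrelation via FFT, then lag-dependent normalization
        n_fft = 1 << int(np.ceil(np.log2(2 * win)))
        spec = np.fft.rfft(frame, n_fft)
        ac = np.fft.irfft(spec * np.conj(spec))[:win]
        lags = np.arange(win)
        cum = np.concatenate(([0.0], np.cumsum(frame ** 2)))
        norm = np.sqrt(cum[win - lags] * (cum[win] - cum[lags]))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(norm > 0, ac / norm, 0.0)
        cand, _ = find_peaks(r[lag_min:lag_max + 1])
        cand = cand + lag_min
        if cand.size == 0 or r[cand].max() < voicing_threshold:
            f0s.append(np.nan)
            voiced.append(False)
            continue
        best = float(r[cand].max())
        k = int(cand[r[cand] >= peak_tolerance * best][0])
        peak = r[k]
        # parabolic lag interpolation
        if 1 <= k < win - 1:
            a, b, c = r[k - 1], r[k], r[k + 1]
            denom = a - 2 * b + c
            delta = 0.5 * (a - c) / denom if abs(denom) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f0s.append(sample_rate_hz / (k + delta))
        voiced.append(True)
    f0_arr = np.array(f0s)
    voiced_arr = np.array(voiced, bool)
    # octave correction against the track median: residual subharmonic /
    # harmonic frames are snapped back when an integer multiple or divisor
    # lands within 20% of the median
    if voiced_arr.sum() >= 3:
        med = float(np.median(f0_arr[voiced_arr]))
        for i in np.flatnonzero(voiced_arr):
            f = f0_arr[i]
            if f < 0.75 * med:
                mult = round(med / f)
                if mult >= 2 and abs(mult * f - med) / med < 0.2:
                    f0_arr[i] = mult * f
            elif f > 1.5 * med:
                div = round(f / med)
                if div >= 2 and abs(f / div - med) / med < 0.2:
                    f0_arr[i] = f / div
    return F0Track(f0_hz=f0_arr, voiced=voiced_arr, frame_ms=frame_ms)


def f0_mean(track: F0Track) -> float:
    """Arithmetic mean over voiced frames; NaN sentinel if none are voiced."""
    if track.empty or track.n_voiced == 0:
        return float("nan")
    return float(np.nanmean(track.f0_hz[track.voiced]))


# ---------------------------------------------------------------------------
# Formants
# ---------------------------------------------------------------------------

def lpc_coefficients(samples: np.ndarray, order: int) -> np.ndarray:
    """LPC by the autocorrelation (Levinson/Toeplitz) method: [1, a1..ap]."""
    x = np.asarray(samples, dtype=np.float64)
    r = np.correlate(x, x, mode="full")[x.size - 1:x.size + order]
    if r[0] <= 0:
        raise ValueError("zero-energy frame has no LPC representation")
    r = r / r[0]
    r[0] *= 1.0 + 1e-9  # white-noise floor keeps the Toeplitz system regular
    a = solve_toeplitz((r[:order], r[:order]), -r[1:order + 1])
    return np.concatenate(([1.0], a))


def lpc_roots_to_formants(coeffs: np.ndarray, sample_rate_hz: float,
                          freq_range: Tuple[float, float] = (90.0, 5000.0),
                          max_bandwidth_hz: float = 400.0
                          ) -> List[Tuple[float, float]]:
    """(frequency, bandwidth) of qualifying LPC pole pairs, ascending."""
    roots = np.roots(coeffs)
    roots = roots[np.imag(roots) > 0]
    out = []
    for z in roots:
        freq = float(np.angle(z) * sample_rate_hz / (2 * np.pi))
        mag = abs(z)
        if mag >= 1.0 or mag <= 0.0:
            continue
        bw = float(-sample_rate_hz / np.pi * np.log(mag))
        if freq_range[0] <= freq <= freq_range[1] and bw < max_bandwidth_hz:
            out.append((freq, bw))
    out.sort(key=lambda fb: fb[0])
    return out


def _formants_lpc_frame(x: np.ndarray, sample_rate_hz: float,
                        pre_emphasis: float) -> Tuple[float, float, float]:
    x = np.append(x[0], x[1:] - pre_emphasis * x[:-1])
    x = x * np.hamming(x.size)
    order = 2 + int(round(sample_rate_hz / 1000.0))
    try:
        coeffs = lpc_coefficients(x, order)
    except ValueError:
        return (float("nan"),) * 3
    pairs = lpc_roots_to_formants(coeffs, sample_rate_hz)
    freqs = [f for f, _ in pairs[:3]]
    while len(freqs) < 3:
        freqs.append(float("nan"))
    return tuple(freqs)  # type: ignore[return-value]


def formants_lpc(samples: np.ndarray, sample_rate_hz: float,
                 pre_emphasis: float = 0.6,
                 frame_ms: float = 30.0) -> Tuple[float, float, float]:
    """First three formants from LPC roots; NaN for missing formants.

    Each analysis frame is pre-emphasized and Hamming-windowed; the LPC
    order is 2 + sample_rate/1000 (rounded).  Qualifying roots lie inside
    the unit circle with frequency in 90-5,000 Hz and bandwidth under
    400 Hz.  Segments long enough for it are analyzed in up to three
    ``frame_ms`` frames (centered at 30/50/70% of the segment) and the
    per-formant median is returned, which suppresses single-frame outliers
    from the onset transient and the release tail.

    The default pre-emphasis is moderate (0.6): laughter plosives already
    carry the +6 dB/oct radiation tilt, and a full 0.97 pre-emphasis
    over-tilts the spectrum enough to bias the first formant toward the
    nearest strong harmonic.
    """
    x = np.asarray(samples, dtype=np.float64)
    min_len = int(0.025 * sample_rate_hz)
    if x.size < min_len:
        return (float("nan"),) * 3
    win = int(round(frame_ms * 1e-3 * sample_rate_hz))
    estimates = []
    for center_frac in (0.3, 0.5, 0.7):
        mid = int(center_frac * x.size)
        frame = x[max(0, mid - win // 2): mid + win - win // 2]
        if frame.size >= min_len:
            estimates.append(_formants_lpc_frame(frame, sample_rate_hz, pre_emphasis))
    if not estimates:
        estimates.append(_formants_lpc_frame(x, sample_rate_hz, pre_emphasis))
    arr = np.asarray(estimates, dtype=np.float64)
    med = [np.median(col[~np.isnan(col)]) if (~np.isnan(col)).any() else float("nan")
           for col in arr.T]
    return tuple(float(v) for v in med)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Power, entropy, voicing
# ---------------------------------------------------------------------------

def average_power(samples: np.ndarray) -> float:
    """Mean squared amplitude per sample (normalized audio, dimensionless)."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("average_power of an empty segment")
    return float(np.mean(x ** 2))


def spectral_entropy(samples: np.ndarray, sample_rate_hz: float,
                     n_fft: Optional[int] = None,
                     band_hz: Tuple[float, float] = (50.0, 10_000.0)) -> float:
    """Shannon entropy (bits) of the normalized power spectrum in the band.

    The power spectrum of the (rectangular-windowed) segment is restricted
    to the analysis band and normalized to a probability vector p;
    H = -sum p_i log2 p_i, so 0 <= H <= log2(n_bins).  An all-zero segment
    has entropy 0 by convention.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("spectral_entropy of an empty segment")
    n = n_fft or x.size
    power = np.abs(np.fft.rfft(x, n)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    hi = min(band_hz[1], sample_rate_hz / 2.0)
    mask = (freqs >= band_hz[0]) & (freqs <= hi)
    power = power[mask]
    total = power.sum()
    if total <= 0.0:
        return 0.0
    p = power / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def voiced_fraction(track: F0Track, interval_ms: float) -> float:
    """Voiced time over the plosive-to-next-plosive interval, clamped [0,1].

    ``interval_ms`` runs from this plosive's onset to the next plosive's
    onset (or to the plosive's own end for the last plosive in the laugh).
    """
    if interval_ms <= 0:
        raise ValueError("interval_ms must be positive")
    if track.empty:
        return 0.0
    return float(np.clip(track.n_voiced * track.frame_ms / interval_ms, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Per-plosive assembly
# ---------------------------------------------------------------------------

@dataclass
class PlosiveFeatures:
    """A detected plosive's six-variable acoustic description."""

    duration_ms: float
    f0_mean_hz: float           # NaN when no frame is voiced
    f1_hz: float
    f2_hz: float
    f3_hz: float
    avg_power: float
    entropy_bits: float
    voiced_pct: float
    placement: int
    onset_ms: float
    flags: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if not (0.0 <= self.voiced_pct <= 1.0):
            raise ValueError("voiced_pct must lie in [0, 1]")
        if self.avg_power < 0:
            raise ValueError("avg_power must be >= 0")


def extract_plosive_features(record: AudioRecord, segment: PlosiveSegment,
                             next_segment: Optional[PlosiveSegment] = None,
                             frame_ms: float = 10.0) -> PlosiveFeatures:
    """Measure all six sound variables on one detected plosive.

    Unmeasurable quantities (no voiced frame, missing formants, silence)
    are NaN with an explicit flag — never a silently substituted default.
    """
    fs = record.sample_rate_hz
    x = record.samples[segment.start_sample:segment.end_sample]
    flags: Set[str] = set()
    track = f0_track(x, fs, frame_ms=frame_ms)
    if track.empty:
        flags.add("short_for_f0")
    f0 = f0_mean(track)
    if math.isnan(f0):
        flags.add("no_voiced_frames")
    f1, f2, f3 = formants_lpc(x, fs)
    if any(math.isnan(v) for v in (f1, f2, f3)):
        flags.add("missing_formants")
    power = average_power(x)
    entropy = spectral_entropy(x, fs)
    if power == 0.0:
        flags.add("silent")
    onset_ms = segment.onset_ms(fs)
    if next_segment is not None:
        interval_ms = next_segment.onset_ms(fs) - onset_ms
    else:
        interval_ms = segment.duration_ms(fs)
    return PlosiveFeatures(
        duration_ms=segment.duration_ms(fs),
        f0_mean_hz=f0, f1_hz=f1, f2_hz=f2, f3_hz=f3,
        avg_power=power, entropy_bits=entropy,
        voiced_pct=voiced_fraction(track, interval_ms),
        placement=segment.placement, onset_ms=onset_ms, flags=flags,
    )


def features_to_data_matrix(rows: Sequence[Tuple[str, str, int, PlosiveFeatures]]
                            ) -> DataMatrix:
    """Assemble (subject_id, laugh_id, health_status, features) rows into the
    plosive data matrix."""
    records = []
    for subject_id, laugh_id, health, pf in rows:
        records.append({
            "subject_id": subject_id, "laugh_id": laugh_id,
            "placement": pf.placement, "onset_ms": pf.onset_ms,
            "duration_ms": pf.duration_ms, "f0_mean_hz": pf.f0_mean_hz,
            "f1_hz": pf.f1_hz, "f2_hz": pf.f2_hz, "f3_hz": pf.f3_hz,
            "avg_power": pf.avg_power, "entropy_bits": pf.entropy_bits,
            "voiced_pct": pf.voiced_pct, "health_status": health,
        })
    table = pd.DataFrame.from_records(records, columns=DATA_MATRIX_COLUMNS)
    return DataMatrix(table=table)


# ---------------------------------------------------------------------------
# Network input schemas
# ---------------------------------------------------------------------------

N_PLOSIVES_REQUIRED = 5

# the six acoustic numbers fed to the networks (formant set reduced to
# F1/F2 so the eight-channel-per-plosive layout closes at p = 40)
_SIX_ACOUSTIC = ["duration_ms", "f0_mean_hz", "f1_hz", "f2_hz",
                 "avg_power", "entropy_bits"]


@dataclass(frozen=True)
class FeatureSchema:
    schema_id: str            # ANN40 | EANN5 | P5ANN6
    p: int
    column_names: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.column_names) != self.p:
            raise ValueError(f"{self.schema_id}: {len(self.column_names)} columns != p={self.p}")


def _ann40_columns(label_channel: bool) -> Tuple[str, ...]:
    eighth = "health" if label_channel else "onset_ms"
    cols = []
    for k in range(1, N_PLOSIVES_REQUIRED + 1):
        for name in _SIX_ACOUSTIC + ["placement", eighth]:
            cols.append(f"p{k}_{name}")
    return tuple(cols)


SCHEMAS = {
    "ANN40": FeatureSchema("ANN40", 40, _ann40_columns(label_channel=False)),
    "EANN5": FeatureSchema("EANN5", 5,
                           tuple(f"p{k}_avg_power" for k in range(1, 6))),
    "P5ANN6": FeatureSchema("P5ANN6", 6, tuple(f"p5_{n}" for n in _SIX_ACOUSTIC)),
}


@dataclass
class FeatureMatrix:
    """Laugh-level network exemplars: one row per laugh, schema columns,
    labels +1 (depression) / -1 (control)."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    laugh_ids: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != self.schema.p:
            raise ValueError(
                f"feature matrix must be (n, {self.schema.p}) for {self.schema.schema_id}, "
                f"got {self.X.shape}")
        if not np.isin(self.y, [-1.0, 1.0]).all():
            raise ValueError("labels must be +1 (depression) or -1 (control)")

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X[idx], self.y[idx], self.subject_ids[idx],
                             self.laugh_ids[idx], self.schema)


def build_feature_matrix(matrix: DataMatrix, schema_id: str,
                         label_channel: bool = False
                         ) -> Tuple[FeatureMatrix, List[Tuple[str, str]]]:
    """Fold the per-plosive data matrix into laugh-level network exemplars.

    Laughs contribute their first five plosives.  Laughs with fewer than
    five plosives are excluded, as are laughs with unmeasurable channels
    the schema needs (EANN5 needs energy only, so unvoiced plosives do not
    exclude a laugh there).  Returns the matrix and an exclusion log of
    (laugh_id, reason).  ``label_channel`` reproduces the literal leaky
    layout whose eighth channel is the health label itself.
    """
    if schema_id not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_id!r}; choose from {sorted(SCHEMAS)}")
    if label_channel and schema_id != "ANN40":
        raise ValueError("label_channel layout applies to ANN40 only")
    schema = SCHEMAS[schema_id]
    if schema_id == "ANN40" and label_channel:
        schema = FeatureSchema("ANN40", 40, _ann40_columns(label_channel=True))

    rows, labels, subj, lids = [], [], [], []
    excluded: List[Tuple[str, str]] = []
    for laugh_id, grp in matrix.table.groupby("laugh_id", sort=True):
        grp = grp.sort_values("placement")
        if len(grp) < N_PLOSIVES_REQUIRED:
            excluded.append((str(laugh_id), f"only {len(grp)} plosives (<5)"))
            continue
        grp = grp.iloc[:N_PLOSIVES_REQUIRED]
        health = int(grp["health_status"].iloc[0])
        label = 1.0 if health == HEALTH_DEPRESSION else -1.0
        if schema_id == "EANN5":
            vec = grp["avg_power"].to_numpy(dtype=np.float64)
        elif schema_id == "P5ANN6":
            vec = grp.iloc[-1][_SIX_ACOUSTIC].to_numpy(dtype=np.float64)
        else:  # ANN40
            parts = []
            for _, prow in grp.iterrows():
                eighth = label if label_channel else prow["onset_ms"]
                parts.extend([prow[c] for c in _SIX_ACOUSTIC]
                             + [prow["placement"], eighth])
            vec = np.asarray(parts, dtype=np.float64)
        if np.isnan(vec).any():
            excluded.append((str(laugh_id), "unmeasured channel (NaN) in schema"))
            continue
        rows.append(vec)
        labels.append(label)
        subj.append(str(grp["subject_id"].iloc[0]))
        lids.append(str(laugh_id))

    X = np.asarray(rows, dtype=np.float64) if rows else np.empty((0, schema.p))
    fm = FeatureMatrix(X=X, y=np.asarray(labels), subject_ids=np.asarray(subj, dtype=object),
                       laugh_ids=np.asarray(lids, dtype=object), schema=schema)
    return fm, excluded
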