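"""Plosive automatic detector.

Laughter bouts appear in the time domain as isolated energy bursts
(plosives) separated by short silences.  The detector band-limits the
recording to the analysis band, computes a sliding-RMS amplitude envelope,
and segments the envelope at a threshold relative to its global peak; a
clarity filter then rejects segments that cannot be laughter plosives
(over-long events, sustained plateaus such as hums or exclamations).

The envelope is RMS rather than Hilbert because plosives are defined by
energy peaks; the threshold is relative to the per-recording peak because
recording gain is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal

from .soundio import AudioRecord

__all__ = [
    "SegmenterConfig",
    "PlosiveSegment",
    "Rejection",
    "band_filter",
    "amplitude_envelope",
    "detect_plosives",
    "clarity_filter",
]


@dataclass(frozen=True)
class SegmenterConfig:
    band_hz: Tuple[float, float] = (50.0, 10_000.0)
    envelope_window_ms: float = 5.0
    onset_threshold_rel: float = 0.1  # fraction of the global envelope peak
    min_plosive_ms: float = 30.0
    max_plosive_ms: float = 350.0
    min_silence_ms: float = 20.0
    # peak picking runs on a longer-window envelope so noisy bursts stay
    # unimodal; boundaries are refined on a sharper envelope
    detect_window_ms: float = 60.0
    boundary_window_ms: float = 15.0
    # candidate peaks closer than this keep only the larger; just under the
    # shortest plosive repetition period seen in laughter bouts
    min_peak_gap_ms: float = 150.0

    def __post_init__(self) -> None:
        if not 0.0 < self.onset_threshold_rel < 1.0:
            raise ValueError("onset_threshold_rel must lie in (0, 1)")
        if not self.min_plosive_ms < self.max_plosive_ms:
            raise ValueError("min_plosive_ms must be < max_plosive_ms")
        if self.band_hz[0] >= self.band_hz[1]:
            raise ValueError("band_hz must be (low, high) with low < high")


@dataclass(frozen=True)
class PlosiveSegment:
    start_sample: int
    end_sample: int
    placement: int  # 1-based index within the laugh
    peak_envelope: float

    def __post_init__(self) -> None:
        if self.start_sample >= self.end_sample:
            raise ValueError("start_sample must be < end_sample")

    def duration_ms(self, sample_rate_hz: float) -> float:
        return 1000.0 * (self.end_sample - self.start_sample) / sample_rate_hz

    def onset_ms(self, sample_rate_hz: float) -> float:
        return 1000.0 * self.start_sample / sample_rate_hz


@dataclass(frozen=True)
class Rejection:
    segment: PlosiveSegment
    code: str  # "duration_long" | "duration_short" | "plateau"
    detail: str


def band_filter(record: AudioRecord, band_hz: Tuple[float, float] = (50.0, 10_000.0),
                order: int = 8) -> AudioRecord:
    """Zero-phase Butterworth band-pass onto the analysis band.

    Forward-backward filtering keeps onsets in place (no group delay) and
    doubles the stop-band attenuation of the underlying order-``order``
    design, comfortably past 40 dB one octave outside the band.
    """
    nyq = record.sample_rate_hz / 2.0
    lo, hi = band_hz
    if hi >= nyq:
        raise ValueError(
            f"band edge {hi} Hz >= Nyquist {nyq} Hz; raise the sample rate or lower the band"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=record.sample_rate_hz,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, record.samples)
    peak = np.max(np.abs(filtered))
    if peak > 1.0:  # filtering ripple can overshoot full scale marginally
        filtered = filtered / peak
    return replace(record, samples=filtered)


def amplitude_envelope(record: AudioRecord, window_ms: float = 5.0) -> np.ndarray:
    """Sliding-RMS amplitude envelope, one value per sample."""
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    n = max(1, int(round(window_ms * 1e-3 * record.sample_rate_hz)))
    kernel = np.ones(n) / n
    power = np.convolve(record.samples ** 2, kernel, mode="same")
    return np.sqrt(np.maximum(power, 0.0))


def _nearest_local_min(env: np.ndarray, idx: int, direction: int, stop: int,
                       floor: float = 0.0) -> int:
    """Walk from idx in direction until the envelope stops decreasing.

    The walk also stops once the envelope drops below ``floor``: past that
    point it is tracing the silence noise floor, whose micro-minima would
    only jitter the boundary.
    """
    i = idx
    while 0 < i < len(env) - 1 and i != stop:
        j = i + direction
        if j == stop or j <= 0 or j >= len(env) - 1:
            return j if 0 <= j < len(env) else i
        if env[j] > env[i] or env[j] < floor:
            return i
        i = j
    return i


def detect_plosives(record: AudioRecord, config: SegmenterConfig = SegmenterConfig()
                    ) -> List[PlosiveSegment]:
    """Segment a laugh into plosives: energy peaks separated by silence.

    Candidate plosives are local maxima of a smoothed
    (``detect_window_ms``) envelope above ``onset_threshold_rel`` x its
    global peak, kept at least ``min_peak_gap_ms`` apart (the smaller of
    two close peaks is dropped, which keeps the detection count monotone
    non-increasing in the threshold).  Boundaries are the threshold
    crossings around each peak on a sharper (``boundary_window_ms``)
    envelope, extended outward to the nearest envelope local minimum; the
    inter-peak envelope minimum caps both sides so segments stay disjoint.
    Segments shorter than ``min_plosive_ms`` are discarded; over-long
    segments are left for ``clarity_filter`` to reject with a logged
    reason.
    """
    if record.samples.size == 0:
        return []
    fs = record.sample_rate_hz
    env_det = amplitude_envelope(record, config.detect_window_ms)
    env = amplitude_envelope(record, config.boundary_window_ms)
    if float(env_det.max()) <= 0.0:
        return []
    thr_det = config.onset_threshold_rel * float(env_det.max())
    thr = config.onset_threshold_rel * float(env.max())
    min_dist = max(1, int(round(config.min_peak_gap_ms * 1e-3 * fs)))
    peaks, _ = signal.find_peaks(env_det, height=thr_det, distance=min_dist)
    if peaks.size == 0:
        return []

    min_silence = int(round(config.min_silence_ms * 1e-3 * fs))
    segments: List[PlosiveSegment] = []
    bounds = []
    for k, p in enumerate(peaks):
        # threshold crossings around the peak
        left_stop = 0 if k == 0 else int(peaks[k - 1])
        right_stop = len(env) - 1 if k == len(peaks) - 1 else int(peaks[k + 1])
        i = p
        while i > left_stop and env[i] >= thr:
            i -= 1
        j = p
        while j < right_stop and env[j] >= thr:
            j += 1
        # extend outward to the nearest envelope local minimum
        i = _nearest_local_min(env, i, -1, left_stop, floor=0.5 * thr)
        j = _nearest_local_min(env, j, +1, right_stop, floor=0.5 * thr)
        # cap at the inter-peak minimum so neighbours stay disjoint
        if k > 0:
            lo_cap = int(peaks[k - 1]) + np.argmin(env[peaks[k - 1]:p + 1])
            i = max(i, int(lo_cap))
        if k < len(peaks) - 1:
            hi_cap = p + np.argmin(env[p:peaks[k + 1] + 1])
            j = min(j, int(hi_cap))
        bounds.append([int(i), int(j)])

    # enforce the minimum silence gap by trimming at the separating minimum
    for a, b in zip(bounds, bounds[1:]):
        gap = b[0] - a[1]
        if gap < min_silence:
            need = min_silence - gap
            a[1] -= (need + 1) // 2
            b[0] += need // 2

    placement = 1
    for i, j in bounds:
        if j <= i:
            continue
        if 1000.0 * (j - i) / fs < config.min_plosive_ms:
            continue
        segments.append(PlosiveSegment(start_sample=i, end_sample=j,
                                       placement=placement,
                                       peak_envelope=float(env[i:j].max())))
        placement += 1
    return segments


def clarity_filter(segments: Sequence[PlosiveSegment], record: AudioRecord,
                   config: SegmenterConfig = SegmenterConfig()
                   ) -> Tuple[List[PlosiveSegment], List[Rejection]]:
    """Reject segments that cannot be clean laughter plosives.

    Rules (each rejection logged with a reason code):

    * ``duration_long`` / ``duration_short`` — outside the plosive duration
      bounds; laughter calls are short percussive events.  Duration is
      judged on *coalesced* events: consecutive segments whose separating
      gap never falls to silence (below the detection threshold) are one
      sustained vocalization, however the detector happened to carve it.
    * ``plateau`` — the envelope stays within 15% of the segment peak for
      longer than ``max_plosive_ms``: the signature of a sustained
      vocalization (hum, exclamation) rather than a burst.

    Survivors are renumbered so placements stay consecutive from 1.
    """
    fs = record.sample_rate_hz
    env = amplitude_envelope(record, config.boundary_window_ms)
    thr = config.onset_threshold_rel * float(env.max()) if env.size else 0.0

    # coalesce runs of segments with no true silence between them
    event_of = {}
    event_spans: List[List[int]] = []
    for seg in segments:
        if (event_spans
                and env[event_spans[-1][1]:seg.start_sample + 1].min() >= thr):
            event_spans[-1][1] = seg.end_sample
        else:
            event_spans.append([seg.start_sample, seg.end_sample])
        event_of[seg] = len(event_spans) - 1

    accepted: List[PlosiveSegment] = []
    rejections: List[Rejection] = []
    for seg in segments:
        span = event_spans[event_of[seg]]
        event_dur = 1000.0 * (span[1] - span[0]) / fs
        dur = seg.duration_ms(fs)
        if event_dur > config.max_plosive_ms:
            detail = (f"{dur:.1f} ms segment" if event_dur == dur else
                      f"part of a {event_dur:.1f} ms sustained event")
            rejections.append(Rejection(seg, "duration_long",
                                        f"{detail} > {config.max_plosive_ms} ms"))
            continue
        if dur < config.min_plosive_ms:
            rejections.append(Rejection(seg, "duration_short",
                                        f"{dur:.1f} ms < {config.min_plosive_ms} ms"))
            continue
        seg_env = env[seg.start_sample:seg.end_sample]
        plateau = seg_env >= 0.85 * seg_env.max()
        # longest run of near-peak envelope
        run = best = 0
        for flag in plateau:
            run = run + 1 if flag else 0
            best = max(best, run)
        if 1000.0 * best / fs > config.max_plosive_ms:
            rejections.append(Rejection(seg, "plateau",
                                        f"near-peak plateau {1000.0 * best / fs:.1f} ms"))
            continue
        accepted.append(seg)
    accepted = [replace(s, placement=k + 1) for k, s in enumerate(accepted)]
    return accepted, rejections
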