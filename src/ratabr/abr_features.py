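"""Feature extraction from averaged auditory brainstem response (ABR) traces.

An ABR trace is a short averaged evoked potential recorded after a tone-burst
stimulus.  In the rat it contains four to five biphasic waves (I–V) within
~6 ms of stimulus onset, each generated by a successive station of the
auditory brainstem.  This module extracts, per recording:

* the background activity SD from the pre-stimulus segment,
* per-wave features: positive peak, subsequent negative trough, peak-to-peak
  amplitude, and transit-corrected latencies,
* interpeak latencies (I-II, II-IV, I-IV, positive and negative),
* the auditory threshold from a descending intensity series, defined as the
  lowest stimulus intensity whose response peak-to-peak voltage exceeds twice
  the background SD (and does so at every higher tested intensity).

Latency conventions: wave times are in ms after stimulus onset; reported
latencies add a fixed acoustic transit time (default 0.5 ms, the travel time
from the speaker diaphragm to the tympanic membrane).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigurationError, InputError

WAVE_IDS: Tuple[str, ...] = ("I", "II", "III", "IV", "V")

#: Per-wave peak search windows, ms post-onset.  Disjoint by construction so
#: that each wave's trough (which follows its peak and precedes the next
#: window) has an unambiguous home.  Chosen to bracket typical rat ABR
#: latencies at 80 dB SPL including age-related delays.
DEFAULT_SEARCH_WINDOWS: Dict[str, Tuple[float, float]] = {
    "I": (0.5, 1.7),
    "II": (1.8, 2.5),
    "III": (2.6, 3.3),
    "IV": (3.4, 4.4),
    "V": (4.5, 6.2),
}

#: Acoustic transit time added to every reported latency, ms.
DEFAULT_TRANSIT_MS = 0.5

#: Peak-to-peak analysis window for threshold detection, ms post-onset.
DEFAULT_ANALYSIS_WINDOW: Tuple[float, float] = (0.0, 8.0)

#: Sentinel for a series in which no intensity satisfies the criterion.
NO_RESPONSE = "no-response"


@dataclass
class ABRRecording:
    """One averaged evoked-potential trace plus its stimulus metadata."""

    samples: np.ndarray          # voltage, μV
    sampling_rate: float         # Hz
    onset_index: int             # sample index of stimulus onset
    freq_khz: float
    intensity_db: float
    subject: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InputError("samples must be a 1-D voltage series")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("samples contain non-finite values")
        if not (0 <= self.onset_index < self.samples.size):
            raise InputError("onset_index outside the recording")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def time_ms(self) -> np.ndarray:
        """Time axis in ms relative to stimulus onset."""
        return (np.arange(self.n_samples) - self.onset_index) * 1000.0 / self.sampling_rate

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms post-onset."""
        return self.onset_index + int(round(t_ms * self.sampling_rate / 1000.0))

    def post_segment(self, start_ms: float, end_ms: float) -> np.ndarray:
        i0 = max(self.index_at(start_ms), 0)
        i1 = min(self.index_at(end_ms), self.n_samples - 1)
        if i1 < i0:
            raise InputError("empty analysis window")
        return self.samples[i0 : i1 + 1]


@dataclass
class IntensitySeries:
    """Descending-intensity recordings of one subject at one frequency.

    The grid must descend in constant 5 dB steps starting at 80 dB SPL,
    mirroring the acquisition protocol.
    """

    recordings: List[ABRRecording]

    def __post_init__(self) -> None:
        if not self.recordings:
            raise InputError("empty intensity series")
        ints = [r.intensity_db for r in self.recordings]
        if ints[0] != 80:
            raise InputError("intensity series must start at 80 dB SPL")
        steps = np.diff(ints)
        if len(ints) > 1 and not np.allclose(steps, -5.0):
            raise InputError("intensity grid must descend in constant 5 dB steps")
        subjects = {r.subject for r in self.recordings}
        freqs = {r.freq_khz for r in self.recordings}
        if len(subjects) > 1 or len(freqs) > 1:
            raise InputError("series mixes subjects or frequencies")

    @property
    def intensities(self) -> List[float]:
        return [r.intensity_db for r in self.recordings]

    @property
    def subject(self) -> str:
        return self.recordings[0].subject

    @property
    def freq_khz(self) -> float:
        return self.recordings[0].freq_khz


@dataclass
class WaveFeature:
    """Peak/trough times (ms post-onset) and amplitude (μV) of one ABR wave."""

    wave_id: str
    peak_time: float
    trough_time: float
    peak_voltage: float
    trough_voltage: float
    amplitude: float
    positive_latency: float
    negative_latency: float


@dataclass
class InterpeakLatencies:
    """Pairwise latency differences (ms); ``None`` where a wave was absent."""

    PI_PII: Optional[float] = None
    PII_PIV: Optional[float] = None
    PI_PIV: Optional[float] = None
    NI_NII: Optional[float] = None
    NII_NIV: Optional[float] = None
    NI_NIV: Optional[float] = None
    missing_waves: Tuple[str, ...] = ()


@dataclass
class ThresholdResult:
    """Detected auditory threshold for one subject × frequency."""

    threshold: Optional[float]           # dB SPL, or None for no-response
    criterion_sd: Dict[float, float]     # intensity -> 2 × background SD (μV)
    per_intensity_pp: Dict[float, float]  # intensity -> peak-to-peak (μV)
    subject: str = ""
    freq_khz: float = float("nan")

    @property
    def is_no_response(self) -> bool:
        return self.threshold is None

    @property
    def label(self) -> str:
        return NO_RESPONSE if self.threshold is None else f"{self.threshold:g}"


def background_sd(recording: ABRRecording, pre_window_ms: Optional[float] = None) -> float:
    """Sample SD (denominator n−1) of the pre-stimulus background segment.

    Parameters
    ----------
    pre_window_ms:
        Length of the pre-stimulus window to use, ending at stimulus onset.
        Defaults to the entire available pre-stimulus segment.  At least 1 ms
        of background is required.
    """
    fs = recording.sampling_rate
    avail_ms = recording.onset_index * 1000.0 / fs
    if pre_window_ms is None:
        pre_window_ms = avail_ms
    if pre_window_ms > avail_ms + 1e-9:
        raise InputError(
            f"requested {pre_window_ms:g} ms of background but only {avail_ms:g} ms precede onset"
        )
    n = int(round(pre_window_ms * fs / 1000.0))
    if n < max(2, int(round(1.0 * fs / 1000.0))):
        raise InputError("pre-stimulus segment shorter than 1 ms")
    seg = recording.samples[recording.onset_index - n : recording.onset_index]
    return float(np.std(seg, ddof=1))


def peak_to_peak(
    recording: ABRRecording, analysis_window: Tuple[float, float] = DEFAULT_ANALYSIS_WINDOW
) -> float:
    """Whole-response peak-to-peak voltage (max − min) over a post-onset window."""
    w0, w1 = analysis_window
    if w1 <= w0:
        raise InputError("empty analysis window")
    seg = recording.post_segment(w0, w1)
    return float(seg.max() - seg.min())


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima, including plateau left edges."""
    idx, _ = find_peaks(x)
    return idx


def _validate_windows(windows: Mapping[str, Tuple[float, float]]) -> List[Tuple[str, float, float]]:
    ordered = []
    for wid in WAVE_IDS:
        if wid not in windows:
            continue
        a, b = windows[wid]
        if b <= a or a < 0:
            raise ConfigurationError(f"malformed window for wave {wid}: ({a}, {b})")
        ordered.append((wid, float(a), float(b)))
    if not ordered:
        raise ConfigurationError("no wave windows supplied")
    starts = [a for _, a, _ in ordered]
    ends = [b for _, _, b in ordered]
    if any(s2 < e1 for (_, _, e1), (_, s2, _) in zip(ordered, ordered[1:])):
        raise ConfigurationError("wave windows must be ordered and non-overlapping")
    del starts, ends
    return ordered


def detect_waves(
    recording: ABRRecording,
    search_windows: Mapping[str, Tuple[float, float]] = DEFAULT_SEARCH_WINDOWS,
    transit_ms: float = DEFAULT_TRANSIT_MS,
    pre_window_ms: Optional[float] = None,
    criterion_multiplier: float = 2.0,
) -> List[WaveFeature]:
    """Identify ABR waves I–V and measure their amplitudes and latencies.

    Per wave the peak is the tallest local maximum inside the wave's search
    window (earliest wins a tie), required to exceed ``criterion_multiplier``
    × background SD; the trough is the deepest local minimum after the peak
    and before the next wave's window starts (or the window end, for the last
    wave).  Waves with no qualifying peak are omitted from the result.
    """
    ordered = _validate_windows(search_windows)
    if recording.onset_index >= recording.n_samples - 1:
        raise InputError("empty post-onset segment")
    sd = background_sd(recording, pre_window_ms)
    criterion = criterion_multiplier * sd

    x = recording.samples
    fs = recording.sampling_rate
    maxima = _local_maxima(x)
    minima = _local_maxima(-x)

    features: List[WaveFeature] = []
    for k, (wid, a, b) in enumerate(ordered):
        i0, i1 = recording.index_at(a), recording.index_at(b)
        cand = maxima[(maxima >= i0) & (maxima <= i1)]
        cand = cand[x[cand] > criterion]
        if cand.size == 0:
            continue
        # tallest local maximum; earliest index on ties
        peak_idx = int(cand[np.argmax(x[cand])])
        ties = cand[x[cand] == x[peak_idx]]
        peak_idx = int(ties.min())

        if k + 1 < len(ordered):
            trough_end = recording.index_at(ordered[k + 1][1])  # next window start
        else:
            trough_end = i1  # last wave: its own window end
        tcand = minima[(minima > peak_idx) & (minima < trough_end)]
        if tcand.size:
            trough_idx = int(tcand[np.argmin(x[tcand])])
            tties = tcand[x[tcand] == x[trough_idx]]
            trough_idx = int(tties.min())
        else:
            # monotone tail: fall back to the lowest sample strictly after the peak
            if peak_idx + 1 >= trough_end:
                continue
            span = x[peak_idx + 1 : trough_end]
            trough_idx = peak_idx + 1 + int(np.argmin(span))

        peak_t = (peak_idx - recording.onset_index) * 1000.0 / fs
        trough_t = (trough_idx - recording.onset_index) * 1000.0 / fs
        features.append(
            WaveFeature(
                wave_id=wid,
                peak_time=peak_t,
                trough_time=trough_t,
                peak_voltage=float(x[peak_idx]),
                trough_voltage=float(x[trough_idx]),
                amplitude=float(x[peak_idx] - x[trough_idx]),
                positive_latency=peak_t + transit_ms,
                negative_latency=trough_t + transit_ms,
            )
        )
    return features


def interpeak(features: Sequence[WaveFeature]) -> InterpeakLatencies:
    """Interpeak latencies I-II, II-IV, I-IV from positive and negative latencies.

    The fixed acoustic transit correction cancels in every difference.  Waves
    that were not detected leave their dependent fields ``None`` and are
    listed in ``missing_waves``.
    """
    by_id = {f.wave_id: f for f in features}
    missing = tuple(w for w in ("I", "II", "IV") if w not in by_id)

    def pdiff(a: str, b: str) -> Optional[float]:
        if a in by_id and b in by_id:
            return by_id[b].positive_latency - by_id[a].positive_latency
        return None

    def ndiff(a: str, b: str) -> Optional[float]:
        if a in by_id and b in by_id:
            return by_id[b].negative_latency - by_id[a].negative_latency
        return None

    return InterpeakLatencies(
        PI_PII=pdiff("I", "II"),
        PII_PIV=pdiff("II", "IV"),
        PI_PIV=pdiff("I", "IV"),
        NI_NII=ndiff("I", "II"),
        NII_NIV=ndiff("II", "IV"),
        NI_NIV=ndiff("I", "IV"),
        missing_waves=missing,
    )


def detect_threshold(
    series: IntensitySeries,
    pre_window_ms: Optional[float] = None,
    analysis_window: Tuple[float, float] = DEFAULT_ANALYSIS_WINDOW,
    criterion_multiplier: float = 2.0,
    criterion_mode: str = "whole-trace",
    search_windows: Mapping[str, Tuple[float, float]] = DEFAULT_SEARCH_WINDOWS,
) -> ThresholdResult:
    """Auditory threshold of a descending intensity series.

    The response criterion at one intensity is, per the acquisition protocol:
    peak-to-peak voltage strictly greater than ``criterion_multiplier`` × the
    background SD of that same recording.  The threshold is the lowest tested
    intensity at which the criterion holds there *and* at every higher tested
    intensity; if it already fails at 80 dB SPL the result is no-response.

    ``criterion_mode`` selects the response statistic: ``"whole-trace"``
    (default) uses the peak-to-peak over ``analysis_window``; ``"any-wave"``
    uses the largest single-wave amplitude returned by :func:`detect_waves`.
    """
    if criterion_mode not in ("whole-trace", "any-wave"):
        raise ConfigurationError(f"unknown criterion mode: {criterion_mode!r}")
    per_pp: Dict[float, float] = {}
    per_crit: Dict[float, float] = {}
    passes: List[bool] = []
    for rec in series.recordings:  # descending intensities
        sd = background_sd(rec, pre_window_ms)
        if criterion_mode == "whole-trace":
            pp = peak_to_peak(rec, analysis_window)
        else:
            waves = detect_waves(
                rec, search_windows, pre_window_ms=pre_window_ms,
                criterion_multiplier=criterion_multiplier,
            )
            pp = max((w.amplitude for w in waves), default=0.0)
        per_pp[rec.intensity_db] = pp
        per_crit[rec.intensity_db] = criterion_multiplier * sd
        passes.append(pp > criterion_multiplier * sd)

    threshold: Optional[float] = None
    for rec, ok in zip(series.recordings, passes):
        if ok:
            threshold = rec.intensity_db
        else:
            break
    return ThresholdResult(
        threshold=threshold,
        criterion_sd=per_crit,
        per_intensity_pp=per_pp,
        subject=series.subject,
        freq_khz=series.freq_khz,
    )
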