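"""Synthetic ABR cohorts and DAB micrograph fields with known ground truth.

The waveform generator emulates averaged rat ABR traces: a sum of biphasic
waves I–V (derivative-of-Gaussian bumps) whose amplitudes grow with stimulus
level above the subject's threshold and whose latencies shorten with
increasing intensity, plus Gaussian post-averaging residual noise.  Age
effects enter as per-frequency threshold shifts, amplitude attenuation
factors and latency delays, so every downstream quantity (threshold,
amplitude, latency, interpeak latency) has an exact ground truth.

The micrograph generator emulates DAB immunostaining fields: a Gaussian
background plus perisomatic rings and small neuropil puncta elevated by a
signal gain, with an age-dependent condition factor scaling both the number
of profiles and the gain.  The drawn signal pixels are recorded exactly in a
ground-truth mask and placement log.

All randomness derives from a single master seed through documented
``numpy.random.SeedSequence`` children, so any individual trace or field is
reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .abr_features import ABRRecording, IntensitySeries, WAVE_IDS
from .densitometry import POSITIONS, SUBDIVISIONS, MicrographField
from .errors import ConfigurationError, GenerationError

DEFAULT_FREQUENCIES: Tuple[float, ...] = (0.5, 1, 2, 4, 8, 16, 32)
DEFAULT_INTENSITIES: Tuple[float, ...] = tuple(range(80, 25, -5))  # 80 … 30 dB SPL

#: Young-group auditory thresholds (dB SPL) per frequency (kHz), i.e. the
#: baseline the age-related shifts are added to.  These are the young-group
#: means rounded to the 5 dB acquisition grid (45 dB at 0.5 kHz declining to
#: 30 dB at 32 kHz).
DEFAULT_BASELINE_THRESHOLDS: Dict[float, float] = {
    0.5: 45, 1: 45, 2: 40, 4: 40, 8: 35, 16: 35, 32: 30,
}

#: Level above threshold (dB) at which wave amplitude growth saturates.
GROWTH_SATURATION_DB = 40.0


@dataclass(frozen=True)
class WaveTemplate:
    """Shape parameters of one ABR wave at 80 dB SPL in a young subject."""

    wave_id: str
    base_amplitude: float      # peak-to-peak μV at 80 dB SPL, full growth
    base_peak_latency: float   # ms post-onset at 80 dB SPL
    width: float = 0.25        # ms; trough follows the peak by this much
    latency_slope: float = 0.10   # ms of latency added per 10 dB of attenuation
    growth_exponent: float = 1.0  # shape of amplitude growth with level

    def __post_init__(self) -> None:
        if self.wave_id not in WAVE_IDS:
            raise ConfigurationError(f"unknown wave id {self.wave_id!r}")
        if self.base_amplitude <= 0 or self.width <= 0:
            raise ConfigurationError("base_amplitude and width must be positive")
        if self.latency_slope < 0:
            raise ConfigurationError("latency_slope must be non-negative")

    def peak_latency(self, intensity_db: float, delay_ms: float = 0.0) -> float:
        return self.base_peak_latency + self.latency_slope * (80.0 - intensity_db) / 10.0 + delay_ms

    def trough_latency(self, intensity_db: float, delay_ms: float = 0.0) -> float:
        return self.peak_latency(intensity_db, delay_ms) + self.width


#: Default wave templates.  Peak-to-peak amplitudes ordered II > I > IV > V > III,
#: the canonical rat ABR amplitude ordering; latencies within ~5 ms of onset.
DEFAULT_TEMPLATES: Tuple[WaveTemplate, ...] = (
    WaveTemplate("I", base_amplitude=2.6, base_peak_latency=1.3),
    WaveTemplate("II", base_amplitude=3.5, base_peak_latency=2.1),
    WaveTemplate("III", base_amplitude=0.9, base_peak_latency=2.9),
    WaveTemplate("IV", base_amplitude=1.9, base_peak_latency=3.7),
    WaveTemplate("V", base_amplitude=1.3, base_peak_latency=4.8),
)


def _log_interp(frequencies: Sequence[float], lo: float, hi: float) -> Dict[float, float]:
    """Linear interpolation in log2(frequency) between two range endpoints."""
    f = np.asarray(sorted(frequencies), dtype=float)
    x = np.log2(f)
    vals = lo + (hi - lo) * (x - x[0]) / (x[-1] - x[0]) if f.size > 1 else np.array([lo])
    return {float(k): float(v) for k, v in zip(f, vals)}


@dataclass(frozen=True)
class AgeEffect:
    """Per-frequency age effects applied on top of the young baseline."""

    group: str
    threshold_shift: Mapping[float, float]   # kHz -> dB
    amplitude_factor: Mapping[float, float]  # kHz -> fraction in (0, 1]
    latency_delay: Mapping[float, float]     # kHz -> ms

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.threshold_shift.values()):
            raise ConfigurationError("threshold shifts must be non-negative")
        if any(not (0 < v <= 1) for v in self.amplitude_factor.values()):
            raise ConfigurationError("amplitude factors must lie in (0, 1]")
        if any(v < 0 for v in self.latency_delay.values()):
            raise ConfigurationError("latency delays must be non-negative")

    @classmethod
    def young(cls, frequencies: Sequence[float] = DEFAULT_FREQUENCIES) -> "AgeEffect":
        """No shifts, no attenuation, no delay: the reference group."""
        z = {float(f): 0.0 for f in frequencies}
        one = {float(f): 1.0 for f in frequencies}
        return cls("young", threshold_shift=z, amplitude_factor=one, latency_delay=dict(z))

    @classmethod
    def middle(cls, frequencies: Sequence[float] = DEFAULT_FREQUENCIES) -> "AgeEffect":
        """12–14-month-like effects: shifts 24.38→33.75 dB low→high frequency."""
        return cls(
            "middle",
            threshold_shift=_log_interp(frequencies, 24.38, 33.75),
            amplitude_factor=_log_interp(frequencies, 0.75, 0.55),
            latency_delay=_log_interp(frequencies, 0.0, 0.14),
        )

    @classmethod
    def old(cls, frequencies: Sequence[float] = DEFAULT_FREQUENCIES) -> "AgeEffect":
        """18–20-month-like effects: shifts 30.63→46.25 dB low→high frequency."""
        return cls(
            "old",
            threshold_shift=_log_interp(frequencies, 30.63, 46.25),
            amplitude_factor=_log_interp(frequencies, 0.50, 0.15),
            latency_delay=_log_interp(frequencies, 0.0, 0.20),
        )


def default_age_effects(
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
) -> Tuple[AgeEffect, AgeEffect, AgeEffect]:
    return AgeEffect.young(frequencies), AgeEffect.middle(frequencies), AgeEffect.old(frequencies)


@dataclass
class CohortDesign:
    """Design of a full ABR cohort: groups × subjects × frequencies × intensities."""

    groups: List[Tuple[AgeEffect, int]] = field(default_factory=lambda: [
        (AgeEffect.young(), 8), (AgeEffect.middle(), 8), (AgeEffect.old(), 8),
    ])
    frequencies: Tuple[float, ...] = DEFAULT_FREQUENCIES
    intensities: Tuple[float, ...] = DEFAULT_INTENSITIES
    noise_sd: float = 0.35          # μV, post-averaging residual (10% of wave-II base)
    sampling_rate: float = 25_000.0  # Hz
    window_ms: Tuple[float, float] = (-5.0, 10.0)
    seed: int = 0
    templates: Tuple[WaveTemplate, ...] = DEFAULT_TEMPLATES
    baseline_thresholds: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("cohort needs at least one group")
        if any(n <= 0 for _, n in self.groups):
            raise ConfigurationError("group sizes must be positive")
        _validate_grid(self.intensities)
        if -self.window_ms[0] < 2.0:
            raise ConfigurationError("pre-stimulus window must be at least 2 ms")
        for f in self.frequencies:
            if f not in self.baseline_thresholds:
                raise ConfigurationError(f"no baseline threshold for {f} kHz")


def _validate_grid(intensities: Sequence[float]) -> None:
    if not intensities:
        raise ConfigurationError("empty intensity grid")
    if intensities[0] != 80:
        raise ConfigurationError("intensity grid must start at 80 dB SPL")
    if len(intensities) > 1 and not np.allclose(np.diff(intensities), -5.0):
        raise ConfigurationError("intensity grid must descend in 5 dB steps")


def effective_level(
    intensity_db: float,
    freq_khz: float,
    effect: AgeEffect,
    baseline_thresholds: Mapping[float, float] = DEFAULT_BASELINE_THRESHOLDS,
) -> float:
    """Stimulus level relative to the subject's threshold at this frequency."""
    return intensity_db - baseline_thresholds[freq_khz] - effect.threshold_shift[freq_khz]


def amplitude_growth(level_db: float, exponent: float = 1.0) -> float:
    """Monotone growth of wave amplitude with level above threshold.

    Zero at and below threshold, linear up to saturation 40 dB above
    threshold (raised to ``exponent`` for non-default growth shapes).
    """
    return float(np.clip(level_db / GROWTH_SATURATION_DB, 0.0, 1.0) ** exponent)


def _biphasic_bump(t_ms: np.ndarray, peak_ms: float, width_ms: float, pp_amplitude: float) -> np.ndarray:
    """Derivative-of-Gaussian bump: positive peak at ``peak_ms``, trough at
    ``peak_ms + width_ms``, peak-to-peak voltage ``pp_amplitude``."""
    sigma = width_ms / 2.0
    center = peak_ms + sigma
    z = (center - t_ms) / sigma
    raw = z * np.exp(-0.5 * z**2)           # extrema ±e^{-1/2} at t = peak, peak+width
    return pp_amplitude / (2.0 * math.exp(-0.5)) * raw


def _trace_seed(master_seed: int, subject_idx: int, freq_khz: float, intensity_db: float) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=[int(master_seed), int(subject_idx), int(round(freq_khz * 1000)), int(round(intensity_db))]
    )
    return np.random.default_rng(ss)


def simulate_abr(
    templates: Sequence[WaveTemplate],
    effect: AgeEffect,
    freq_khz: float,
    intensity_db: float,
    noise_sd: float = 0.0,
    sampling_rate: float = 25_000.0,
    window_ms: Tuple[float, float] = (-5.0, 10.0),
    seed: int = 0,
    subject_idx: int = 0,
    baseline_thresholds: Mapping[float, float] = DEFAULT_BASELINE_THRESHOLDS,
    subject: str = "",
) -> ABRRecording:
    """Simulate one averaged ABR trace.

    The trace is the sum of the per-wave biphasic bumps, scaled by the wave's
    age amplitude factor and the growth function of the effective level
    (intensity − baseline threshold − age shift), with latencies shifted by
    the intensity slope and the age delay.  Gaussian noise of SD ``noise_sd``
    is added everywhere; the pre-stimulus segment carries noise only.
    """
    if not templates:
        raise ConfigurationError("need at least one wave template")
    if sampling_rate <= 0:
        raise ConfigurationError("sampling rate must be positive")
    if not (0 <= intensity_db <= 80):
        raise ConfigurationError("intensity must lie in [0, 80] dB SPL")
    delay = effect.latency_delay[freq_khz]
    latest = max(tpl.trough_latency(intensity_db, delay) for tpl in templates)
    if window_ms[1] < latest:
        raise ConfigurationError(
            f"post-stimulus window ends at {window_ms[1]} ms but the latest wave extends to {latest:.2f} ms"
        )
    if window_ms[0] > -1.0:
        raise ConfigurationError("window must include at least 1 ms of pre-stimulus baseline")

    n = int(round((window_ms[1] - window_ms[0]) * sampling_rate / 1000.0)) + 1
    onset_index = int(round(-window_ms[0] * sampling_rate / 1000.0))
    t = (np.arange(n) - onset_index) * 1000.0 / sampling_rate

    level = effective_level(intensity_db, freq_khz, effect, baseline_thresholds)
    amp_factor = effect.amplitude_factor[freq_khz]
    signal = np.zeros(n)
    if level > 0:
        for tpl in templates:
            a = tpl.base_amplitude * amp_factor * amplitude_growth(level, tpl.growth_exponent)
            if a > 0:
                signal += _biphasic_bump(t, tpl.peak_latency(intensity_db, delay), tpl.width, a)
        signal[t < 0] = 0.0  # stimulus-locked activity only after onset

    rng = _trace_seed(seed, subject_idx, freq_khz, intensity_db)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    return ABRRecording(
        samples=signal + noise,
        sampling_rate=sampling_rate,
        onset_index=onset_index,
        freq_khz=freq_khz,
        intensity_db=intensity_db,
        subject=subject or f"{effect.group}-{subject_idx:02d}",
        group=effect.group,
    )


def simulate_series(
    templates: Sequence[WaveTemplate],
    effect: AgeEffect,
    freq_khz: float,
    intensities: Sequence[float] = DEFAULT_INTENSITIES,
    noise_sd: float = 0.0,
    sampling_rate: float = 25_000.0,
    window_ms: Tuple[float, float] = (-5.0, 10.0),
    seed: int = 0,
    subject_idx: int = 0,
    baseline_thresholds: Mapping[float, float] = DEFAULT_BASELINE_THRESHOLDS,
    subject: str = "",
) -> IntensitySeries:
    """One descending intensity series; per-trace seeds derive from ``seed``."""
    _validate_grid(tuple(intensities))
    recs = [
        simulate_abr(
            templates, effect, freq_khz, i, noise_sd, sampling_rate, window_ms,
            seed=seed, subject_idx=subject_idx,
            baseline_thresholds=baseline_thresholds, subject=subject,
        )
        for i in intensities
    ]
    return IntensitySeries(recs)


@dataclass
class CohortDataset:
    """Simulated cohort: all series plus the exact ground-truth thresholds."""

    design: CohortDesign
    series: Dict[Tuple[str, str, float], IntensitySeries]  # (group, subject, freq) -> series
    truth: pd.DataFrame  # columns: group, subject, freq_khz, true_threshold_db (NaN = no response)

    @property
    def n_recordings(self) -> int:
        return sum(len(s.recordings) for s in self.series.values())


def true_threshold(
    effect: AgeEffect,
    freq_khz: float,
    intensities: Sequence[float],
    baseline_thresholds: Mapping[float, float] = DEFAULT_BASELINE_THRESHOLDS,
) -> Optional[float]:
    """Lowest grid intensity with positive effective level (None if none)."""
    audible = [
        i for i in intensities
        if effective_level(i, freq_khz, effect, baseline_thresholds) > 0
    ]
    return min(audible) if audible else None


def simulate_cohort(design: CohortDesign) -> CohortDataset:
    """Simulate every subject × frequency series of a cohort design."""
    series: Dict[Tuple[str, str, float], IntensitySeries] = {}
    rows = []
    subject_counter = 0
    for effect, n_subj in design.groups:
        for s in range(n_subj):
            subject_counter += 1
            name = f"{effect.group}-{s + 1:02d}"
            for f in design.frequencies:
                series[(effect.group, name, f)] = simulate_series(
                    design.templates, effect, f, design.intensities,
                    noise_sd=design.noise_sd, sampling_rate=design.sampling_rate,
                    window_ms=design.window_ms, seed=design.seed,
                    subject_idx=subject_counter, subject=name,
                    baseline_thresholds=design.baseline_thresholds,
                )
                t = true_threshold(effect, f, design.intensities, design.baseline_thresholds)
                rows.append(
                    {"group": effect.group, "subject": name, "freq_khz": f,
                     "true_threshold_db": np.nan if t is None else t}
                )
    truth = pd.DataFrame(rows, columns=["group", "subject", "freq_khz", "true_threshold_db"])
    return CohortDataset(design=design, series=series, truth=truth)


# ---------------------------------------------------------------------------
# Synthetic DAB micrograph fields
# ---------------------------------------------------------------------------

@dataclass
class FieldDesign:
    """Design of one synthetic immunostaining field.

    ``condition_factor`` scales both the number of profiles and the signal
    gain, emulating the age-related decline in staining density and
    intensity; 1.0 is the young condition.
    """

    image_size: Tuple[int, int] = (256, 256)
    background_mean: float = 40.0
    background_sd: float = 8.0
    n_rings: int = 12
    n_puncta: int = 150
    ring_radius: int = 9
    ring_thickness: int = 3
    punctum_radius: int = 1
    signal_gain: float = 120.0
    condition_factor: float = 1.0
    pixel_size_um: Optional[float] = 0.25

    def __post_init__(self) -> None:
        if self.n_rings < 0 or self.n_puncta < 0:
            raise ConfigurationError("profile counts must be non-negative")
        if not (0 < self.condition_factor <= 1):
            raise ConfigurationError("condition_factor must lie in (0, 1]")
        if min(self.image_size) < 64:
            raise ConfigurationError("field must be at least 64×64 pixels")
        if not (0 < self.ring_thickness <= self.ring_radius):
            raise ConfigurationError("ring thickness must lie in (0, ring_radius]")

    @property
    def effective_counts(self) -> Tuple[int, int]:
        return (
            int(round(self.n_rings * self.condition_factor)),
            int(round(self.n_puncta * self.condition_factor)),
        )


def _element_pixels(kind: str, center: Tuple[int, int], design: FieldDesign,
                    shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    if kind == "ring":
        rr_o, cc_o = draw_disk(center, design.ring_radius + 1, shape=shape)
        inner = design.ring_radius + 1 - design.ring_thickness
        rr_i, cc_i = draw_disk(center, inner, shape=shape)
        outer = set(zip(rr_o.tolist(), cc_o.tolist()))
        hole = set(zip(rr_i.tolist(), cc_i.tolist()))
        pts = sorted(outer - hole)
    else:
        rr, cc = draw_disk(center, design.punctum_radius + 0.5, shape=shape)
        pts = sorted(zip(rr.tolist(), cc.tolist()))
    arr = np.array(pts, dtype=int)
    return arr[:, 0], arr[:, 1]


def simulate_micrograph(design: FieldDesign, seed: int = 0,
                        max_tries_per_element: int = 1000) -> MicrographField:
    """One synthetic field with an exact ground-truth mask and placement log.

    Background pixels are Normal(background_mean, background_sd) clipped to
    [0, 255]; signal pixels are additionally elevated by signal_gain ×
    condition_factor.  Profiles are placed by rejection sampling so no two
    overlap; exceeding the retry budget raises :class:`GenerationError`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), 0xD0B]))
    h, w = design.image_size
    occupied = np.zeros((h, w), dtype=bool)
    log: List[dict] = []

    n_rings, n_puncta = design.effective_counts
    margin_ring = design.ring_radius + 1
    margin_punct = design.punctum_radius + 1
    for kind, count, margin in (("ring", n_rings, margin_ring),
                                ("punctum", n_puncta, margin_punct)):
        for _ in range(count):
            for attempt in range(max_tries_per_element):
                r = int(rng.integers(margin, h - margin))
                c = int(rng.integers(margin, w - margin))
                rr, cc = _element_pixels(kind, (r, c), design, (h, w))
                if not occupied[rr, cc].any():
                    occupied[rr, cc] = True
                    log.append({"kind": kind, "row": r, "col": c, "n_pixels": int(rr.size)})
                    break
            else:
                raise GenerationError(
                    f"could not place {kind} after {max_tries_per_element} tries"
                )

    gain = design.signal_gain * design.condition_factor
    img = rng.normal(design.background_mean, design.background_sd, size=(h, w))
    img[occupied] += gain
    img = np.clip(img, 0, 255).round().astype(np.uint8)
    return MicrographField(
        pixels=img,
        truth_mask=occupied,
        pixel_size_um=design.pixel_size_um,
        placement_log=log,
    )


@dataclass
class HistologyCohort:
    """Simulated histology dataset with per-group ground truth."""

    fields: List[MicrographField]
    truth: pd.DataFrame  # per group: expected labeled-area fraction and pixel count


def simulate_histology_cohort(
    designs: Mapping[str, FieldDesign],
    n_subjects: int = 8,
    sections_per_subject: int = 4,
    fields_per_section: int = 3,
    subdivision: str = "AVCN",
    seed: int = 0,
) -> HistologyCohort:
    """Simulate group-tagged fields: subjects × sections × (dorsal/middle/ventral).

    ``fields_per_section`` must be 3 so each section contributes one field at
    each sampling position, matching the dorsal/middle/ventral protocol.
    """
    if subdivision not in SUBDIVISIONS:
        raise ConfigurationError(f"unknown subdivision {subdivision!r}")
    if fields_per_section != len(POSITIONS):
        raise ConfigurationError("fields_per_section must equal the 3 sampling positions")
    fields: List[MicrographField] = []
    rows = []
    for g_idx, (group, design) in enumerate(designs.items()):
        signal_px = []
        for s in range(n_subjects):
            name = f"{group}-{s + 1:02d}"
            for sec in range(sections_per_subject):
                for p_idx, pos in enumerate(POSITIONS):
                    child = np.random.SeedSequence(
                        entropy=[int(seed), g_idx, s, sec, p_idx]
                    ).generate_state(1)[0]
                    fld = simulate_micrograph(design, seed=int(child))
                    fld.subject = name
                    fld.group = group
                    fld.subdivision = subdivision
                    fld.position = pos
                    fields.append(fld)
                    signal_px.append(int(fld.truth_mask.sum()))
        area = design.image_size[0] * design.image_size[1]
        rows.append({
            "group": group,
            "condition_factor": design.condition_factor,
            "expected_signal_px": float(np.mean(signal_px)),
            "expected_area_fraction": float(np.mean(signal_px)) / area,
            "n_fields": len(signal_px),
        })
    truth = pd.DataFrame(rows)
    return HistologyCohort(fields=fields, truth=truth)
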