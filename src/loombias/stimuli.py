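"""Synthesis of looming/receding/static stimuli with distance cues.

The carrier is a harmonic tone complex (F0 = 100 Hz, partials spanning
1-16 kHz, generalized Schroeder phases) of 1.2 s with 10 ms squared-sine
edge ramps. Moving trials crossfade (linear, 10 ms) between two renderings
of the carrier at the jittered change time:

* intensity cue — identical spectra, broadband level stepped between
  +2.5 dB (near) and -2.5 dB (far) around the static reference; looming
  goes far -> near.
* spectral-shape cue — crossfade between the native HRTF-filtered rendering
  (far, externalized) and a flat-spectrum rendering (near, internalized),
  both normalized to equal broadband RMS so the overall intensity is
  constant; looming goes native -> flat.

Static trials hold the onset-position rendering throughout. A template HRTF
can be individualized for listeners without measured HRTFs by frequency
scaling driven by two anthropometric measures (pinna-cavity height and head
width; template: 44 mm / 134 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.io import wavfile

from .trial_design import TrialSpec

TEMPLATE_PINNA_HEIGHT_MM = 44.0
TEMPLATE_HEAD_WIDTH_MM = 134.0


@dataclass(frozen=True)
class StimulusSpec:
    """Carrier and cue parameters of the stimulus family."""

    f0: float = 100.0
    band_lo: float = 1000.0
    band_hi: float = 16000.0
    phase_curvature: float = 0.5
    duration: float = 1.2
    edge_ramp: float = 0.010
    transition_ramp: float = 0.010
    intensity_step_db: float = 2.5
    sample_rate: float = 48000.0

    def __post_init__(self) -> None:
        if not self.band_lo < self.band_hi:
            raise ValueError("band_lo must be below band_hi")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.duration <= 2 * self.edge_ramp:
            raise ValueError("duration must exceed both edge ramps")
        if min(self.edge_ramp, self.transition_ramp) < 0:
            raise ValueError("ramps must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


@dataclass
class Waveform:
    """Audio samples with their rate; mono (n,) or stereo (n, 2)."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sample_rate

    def to_wav(self, path: str | Path) -> None:
        wavfile.write(
            str(path), int(self.sample_rate), self.samples.astype(np.float32)
        )

    @classmethod
    def from_wav(cls, path: str | Path) -> "Waveform":
        rate, data = wavfile.read(str(path))
        return cls(samples=np.asarray(data, dtype=float), sample_rate=float(rate))


@dataclass
class HRTFSet:
    """Per-ear magnitude responses for a source at +/-90 deg azimuth, 0 deg elevation.

    ``magnitude_db`` has shape (2, n_freq); row 0 is the ear ipsilateral to
    the source, row 1 the contralateral (head-shadowed) ear — lateral sources
    are symmetric, so one pair serves both sides. ``anthropometrics`` records
    the pinna-cavity height and head width (mm) of the listener the set
    belongs to.
    """

    frequencies: np.ndarray
    magnitude_db: np.ndarray
    anthropometrics: dict = field(
        default_factory=lambda: {
            "pinna_height_mm": TEMPLATE_PINNA_HEIGHT_MM,
            "head_width_mm": TEMPLATE_HEAD_WIDTH_MM,
        }
    )

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitude_db = np.atleast_2d(
            np.asarray(self.magnitude_db, dtype=float)
        )
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(self.magnitude_db)):
            raise ValueError("magnitudes must be finite")
        if self.magnitude_db.shape[0] == 1:  # mono set applies to both ears
            self.magnitude_db = np.vstack([self.magnitude_db] * 2)
        if self.magnitude_db.shape != (2, self.frequencies.size):
            raise ValueError("magnitude_db must be (2, n_freq)")

    def ear_db(self, ear: Literal["ipsi", "contra"]) -> np.ndarray:
        return self.magnitude_db[0 if ear == "ipsi" else 1]

    def to_tables(self, stem: str | Path) -> None:
        """Write one two-column (frequency_hz, magnitude_db) file per ear."""
        stem = Path(stem)
        for i, ear in enumerate(("ipsi", "contra")):
            np.savetxt(
                stem.with_name(f"{stem.name}_{ear}.tsv"),
                np.column_stack([self.frequencies, self.magnitude_db[i]]),
                delimiter="\t",
                header="frequency_hz\tmagnitude_db",
                comments="",
            )

    @classmethod
    def from_tables(
        cls,
        left: str | Path,
        right: str | Path,
        anthropometrics: dict | None = None,
    ) -> "HRTFSet":
        tabs = [np.loadtxt(p, delimiter="\t", skiprows=1) for p in (left, right)]
        if not np.allclose(tabs[0][:, 0], tabs[1][:, 0]):
            raise ValueError("ears must share one frequency grid")
        kwargs = {}
        if anthropometrics is not None:
            kwargs["anthropometrics"] = anthropometrics
        return cls(
            frequencies=tabs[0][:, 0],
            magnitude_db=np.vstack([tabs[0][:, 1], tabs[1][:, 1]]),
            **kwargs,
        )


def synthetic_template_hrtf(
    n_freq: int = 256,
    f_max: float = 20000.0,
    notch_hz: float = 8000.0,
    notch_depth_db: float = 15.0,
    notch_width_hz: float = 1500.0,
    shelf_db: float = 6.0,
) -> HRTFSet:
    """A synthetic stand-in for a measured template HRTF at +/-90 deg azimuth.

    Synthetic: a real measured set cannot ship with the package. The shape is
    a plausible lateral-incidence magnitude profile — a gentle high-frequency
    concha shelf with a pinna notch on the ipsilateral ear and a head-shadowed
    (low-passed, attenuated) contralateral ear. It carries the template
    anthropometrics (44 mm pinna height, 134 mm head width).
    """
    f = np.linspace(20.0, f_max, n_freq)
    notch = -notch_depth_db * np.exp(-0.5 * ((f - notch_hz) / notch_width_hz) ** 2)
    shelf = shelf_db / (1.0 + np.exp(-(f - 4000.0) / 800.0))
    ipsi = shelf + notch
    # Head shadow: broadband attenuation growing with frequency.
    contra = -3.0 - 12.0 / (1.0 + np.exp(-(f - 2000.0) / 600.0))
    return HRTFSet(frequencies=f, magnitude_db=np.vstack([ipsi, contra]))


def harmonic_complex(spec: StimulusSpec) -> Waveform:
    """Sum of equal-amplitude cosine partials at k*f0 within the band.

    Phases follow a generalized Schroeder rule, phi_k = c * pi * k (k + 1) / K
    over the K in-band partials with curvature c in [-1, 1]; c = 0 gives a
    cosine-phase (high-crest) complex, |c| = 1 the classical Schroeder
    phases. Isolated here so an alternative phase rule can be substituted.
    """
    k_lo = int(np.ceil(spec.band_lo / spec.f0 - 1e-9))
    k_hi = int(np.floor(spec.band_hi / spec.f0 + 1e-9))
    if k_hi < k_lo:
        raise ValueError("band excludes every multiple of f0")
    k = np.arange(k_lo, k_hi + 1)
    K = k.size
    idx = np.arange(1, K + 1)
    phases = spec.phase_curvature * np.pi * idx * (idx + 1) / K
    t = np.arange(spec.n_samples) / spec.sample_rate
    wave = np.cos(
        2 * np.pi * np.outer(k * spec.f0, t) + phases[:, None]
    ).sum(axis=0)
    wave /= K  # unit per-partial amplitude scale
    return Waveform(samples=_apply_edge_ramps(wave, spec), sample_rate=spec.sample_rate)


def _apply_edge_ramps(wave: np.ndarray, spec: StimulusSpec) -> np.ndarray:
    n_ramp = int(round(spec.edge_ramp * spec.sample_rate))
    if n_ramp == 0:
        return wave
    wave = wave.copy()
    ramp = np.sin(0.5 * np.pi * np.arange(n_ramp) / n_ramp) ** 2
    wave[:n_ramp] *= ramp
    wave[-n_ramp:] *= ramp[::-1]
    return wave


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def rms_db(x: np.ndarray, ref: float = 1.0) -> float:
    return 20.0 * np.log10(rms(x) / ref)


def _interp_mag_db(hrtf_f: np.ndarray, hrtf_db: np.ndarray,
                   f: np.ndarray) -> np.ndarray:
    # Edge-hold extrapolation outside the tabulated support.
    return np.interp(f, hrtf_f, hrtf_db)


def apply_magnitude_filter(
    wave: np.ndarray, sample_rate: float, frequencies: np.ndarray,
    magnitude_db: np.ndarray,
) -> np.ndarray:
    """Zero-phase magnitude filtering via the real FFT.

    Only the magnitude profile carries the spectral-shape cue, so phase is
    left untouched (minimum-phase reconstruction is deliberately not done).
    """
    n = wave.shape[0]
    spectrum = np.fft.rfft(wave)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    gain = 10.0 ** (_interp_mag_db(frequencies, magnitude_db, f) / 20.0)
    return np.fft.irfft(spectrum * gain, n=n)


def flat_reference(hrtf: HRTFSet,
                   band: tuple[float, float] = (1000.0, 16000.0)) -> HRTFSet:
    """Flat-spectrum counterpart of ``hrtf``, energy-matched per ear.

    The output magnitude is constant over the grid, set per ear so the mean
    linear power over the stimulus band equals that of the native set.
    Applying it twice is idempotent.
    """
    in_band = (hrtf.frequencies >= band[0]) & (hrtf.frequencies <= band[1])
    if not np.any(in_band):
        in_band = np.ones_like(hrtf.frequencies, dtype=bool)
    level = 10.0 * np.log10(
        np.mean(10.0 ** (hrtf.magnitude_db[:, in_band] / 10.0), axis=1)
    )
    flat = np.repeat(level[:, None], hrtf.frequencies.size, axis=1)
    return HRTFSet(
        frequencies=hrtf.frequencies.copy(),
        magnitude_db=flat,
        anthropometrics=dict(hrtf.anthropometrics),
    )


def scale_hrtf(
    template: HRTFSet,
    pinna_height_mm: float,
    head_width_mm: float,
    weights: tuple[float, float] = (0.5, 0.5),
) -> HRTFSet:
    """Individualize a template HRTF by anthropometric frequency scaling.

    The frequency axis is scaled by s, the weighted geometric mean of the
    template/listener ratios of pinna-cavity height and head width
    (default weights 0.5/0.5). A listener larger than the template gives
    s < 1: spectral features move to proportionally lower frequencies. The
    scaled magnitude is resampled onto the template grid with edge-hold
    extrapolation.
    """
    if pinna_height_mm <= 0 or head_width_mm <= 0:
        raise ValueError("anthropometric measurements must be positive")
    t_pinna = template.anthropometrics["pinna_height_mm"]
    t_head = template.anthropometrics["head_width_mm"]
    w_p, w_h = weights
    s = ((t_pinna / pinna_height_mm) ** w_p) * ((t_head / head_width_mm) ** w_h)
    s **= 1.0 / (w_p + w_h)
    scaled = np.vstack([
        _interp_mag_db(template.frequencies * s, template.magnitude_db[i],
                       template.frequencies)
        for i in range(2)
    ])
    return HRTFSet(
        frequencies=template.frequencies.copy(),
        magnitude_db=scaled,
        anthropometrics={
            "pinna_height_mm": pinna_height_mm,
            "head_width_mm": head_width_mm,
        },
    )


def _crossfade(a: np.ndarray, b: np.ndarray, sample_rate: float,
               change_time: float, ramp: float) -> np.ndarray:
    """Linear crossfade a -> b starting at change_time; weights sum to 1."""
    n = a.shape[0]
    w = np.zeros(n)
    start = int(round(change_time * sample_rate))
    n_ramp = max(int(round(ramp * sample_rate)), 1)
    stop = min(start + n_ramp, n)
    w[start:stop] = (np.arange(stop - start) + 0.5) / n_ramp
    w[stop:] = 1.0
    return (1.0 - w) * a + w * b


def synthesize_trial(
    trial: TrialSpec, spec: StimulusSpec, hrtf: HRTFSet
) -> Waveform:
    """Render one trial as a stereo waveform.

    The ipsilateral ear (the one facing the source at +/-90 deg) carries the
    ear-0 (ipsi) response of ``hrtf``; the other ear the contralateral
    response — both ears are always rendered. For the intensity cue the
    unstepped native rendering defines the 0 dB reference around which the
    near/far segments sit at +2.5 / -2.5 dB.
    """
    carrier = harmonic_complex(spec)
    if trial.side == "left":
        ear_rows = (0, 1)  # left ear ipsilateral
    else:
        ear_rows = (1, 0)
    flat = flat_reference(hrtf, band=(spec.band_lo, spec.band_hi))

    channels = []
    for out_ch, row in enumerate(ear_rows):
        native = apply_magnitude_filter(
            carrier.samples, spec.sample_rate, hrtf.frequencies,
            hrtf.magnitude_db[row],
        )
        flatw = apply_magnitude_filter(
            carrier.samples, spec.sample_rate, hrtf.frequencies,
            flat.magnitude_db[row],
        )
        # Equal broadband RMS between the two spectral renderings.
        flatw *= rms(native) / rms(flatw)

        step = 10.0 ** (spec.intensity_step_db / 20.0)
        if trial.cue == "intensity":
            near, far = native * step, native / step
        else:
            near, far = flatw, native

        if trial.motion == "looming":
            sig = _crossfade(far, near, spec.sample_rate, trial.change_time,
                             spec.transition_ramp)
        elif trial.motion == "receding":
            sig = _crossfade(near, far, spec.sample_rate, trial.change_time,
                             spec.transition_ramp)
        elif trial.motion == "static_near_onset":
            sig = near
        elif trial.motion == "static_far_onset":
            sig = far
        else:
            raise ValueError(f"static trial with undefined onset: {trial.motion}")
        channels.append(sig)

    stereo = np.column_stack(channels)
    return Waveform(samples=stereo, sample_rate=spec.sample_rate)


def render_schedule(
    trials, spec: StimulusSpec, hrtf: HRTFSet, out_dir: str | Path
) -> list[Path]:
    """Render every trial of a schedule to WAV files in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, trial in enumerate(trials):
        wav = synthesize_trial(trial, spec, hrtf)
        path = out_dir / f"trial_{i:05d}_{trial.cue}_{trial.motion}_{trial.side}.wav"
        wav.to_wav(path)
        paths.append(path)
    return paths
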