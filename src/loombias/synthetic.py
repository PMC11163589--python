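"""Ground-truth synthetic behavioral and EEG data generators.

Every pipeline stage in this package is testable without the study's
recordings: behavioral choice/RT datasets are generated from the
hierarchical LBA itself (participant parameters drawn from truncated-normal
group distributions, trials simulated by the accumulator race), and EEG
epochs are built from a stereotypical N1/P2 template (windowed Gaussians)
plus a condition-dependent looming-bias deflection embedded in spatially
correlated, 1/f-shaped noise. The generators' defaults mirror the study
conditions (4 cue x motion cells, drift-rate structure favoring correct
responses, N1/P2 latencies inside the peak-search windows); what they do
not emulate is documented in docs/methods.md.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import lba
from .cluster_stats import SensorLayout, build_adjacency
from .erp import Epochs
from .lba import (
    CUES,
    MOTIONS,
    PARAM_NAMES,
    BehavioralDataset,
    GroupHyper,
    LBAParams,
    _sample_truncnorm,
)


def default_behavior_truth() -> GroupHyper:
    """Ground-truth group distribution used by the generator.

    Shared-parameter locations follow the group-level values reported for
    the adult listener pool (A = 0.573, b = 1.694, t0 = 0.139 s); drift
    locations sit at the model's prior centers (correct 3, error 1, giving
    realistic ~80% discrimination accuracy). Between-participant scales are
    kept moderate so simulated samples of a dozen participants remain
    informative about the group locations.
    """
    mu = {"A": 0.573, "b": 1.694, "t0": 0.139}
    sigma = {"A": 0.35, "b": 0.35, "t0": 0.08}
    for name in PARAM_NAMES[3:]:
        mu[name] = 3.0 if name.endswith("_correct") else 1.0
        sigma[name] = 0.3
    return GroupHyper(mu=mu, sigma=sigma)


@dataclass
class BehaviorTruth:
    """Generator configuration for synthetic choice/RT data."""

    hyper: GroupHyper = field(default_factory=default_behavior_truth)
    n_participants: int = 12
    trials_per_condition: int = 50
    seed: int = 0
    catch_trials_per_cue: int = 0
    catch_accuracy: float = 0.97


def _generate_table(truth: BehaviorTruth) -> tuple[pd.DataFrame, dict[str, LBAParams]]:
    rng = np.random.default_rng(truth.seed)
    frames = []
    params_by_part: dict[str, LBAParams] = {}
    for p in range(truth.n_participants):
        pid = f"P{p:02d}"
        while True:
            x = np.array([
                _sample_truncnorm(rng, truth.hyper.mu[n], truth.hyper.sigma[n])
                for n in PARAM_NAMES
            ])
            if x[1] > x[0]:  # b > A, matching the model's support
                break
        params = LBAParams.from_vector(x)
        params_by_part[pid] = params
        for cue in CUES:
            for motion in MOTIONS:
                sim = lba.simulate_lba(
                    params, (cue, motion), truth.trials_per_condition, rng
                )
                sim.insert(0, "participant", pid)
                frames.append(sim)
        if truth.catch_trials_per_cue:
            rt_ref = (params.b / 2.0) + params.t0
            for cue in CUES:
                n_catch = truth.catch_trials_per_cue
                correct = rng.random(n_catch) < truth.catch_accuracy
                frames.append(pd.DataFrame({
                    "participant": pid,
                    "cue": cue,
                    "motion": rng.choice(
                        ["static_near_onset", "static_far_onset"], n_catch
                    ),
                    "response": np.where(correct, "correct", "incorrect"),
                    "rt": rng.uniform(0.6 * rt_ref, 1.4 * rt_ref, n_catch),
                }))
    return pd.concat(frames, ignore_index=True), params_by_part


def gen_behavior(
    truth: BehaviorTruth,
) -> tuple[BehavioralDataset, dict[str, LBAParams]]:
    """Simulate a hierarchical LBA dataset with recorded per-participant truth.

    Participant parameters are drawn from the positive-truncated-normal
    group distributions (redrawn until b > A); each of the 4 cue x motion
    conditions gets ``trials_per_condition`` simulated races. Optional
    static catch trials (uniform RTs around the typical decision time, the
    configured accuracy) are generated for the descriptive summary but
    excluded from the returned motion-trial dataset. Deterministic given
    the seed.
    """
    table, params_by_part = _generate_table(truth)
    motion_only = table[~table["motion"].astype(str).str.startswith("static")]
    return (
        BehavioralDataset(table=motion_only.reset_index(drop=True)),
        params_by_part,
    )


def full_table(truth: BehaviorTruth) -> pd.DataFrame:
    """Full trial table including static catch trials (for the summary)."""
    if not truth.catch_trials_per_cue:
        truth = BehaviorTruth(
            hyper=truth.hyper, n_participants=truth.n_participants,
            trials_per_condition=truth.trials_per_condition, seed=truth.seed,
            catch_trials_per_cue=20, catch_accuracy=truth.catch_accuracy,
        )
    table, _ = _generate_table(truth)
    return table


# ---------------------------------------------------------------------------
# Synthetic EEG
# ---------------------------------------------------------------------------

def ring_layout(n_channels: int = 16, radius: float = 0.09) -> SensorLayout:
    """Synthetic cap: channels on a ring plus a vertex channel ("Cz").

    Positions are 3D (meters, head-sized) so distance-threshold adjacency
    behaves like a real montage.
    """
    names = ["Cz"] + [f"E{i:02d}" for i in range(1, n_channels)]
    angles = np.linspace(0, 2 * np.pi, n_channels - 1, endpoint=False)
    ring = np.column_stack([
        radius * np.cos(angles),
        radius * np.sin(angles),
        np.full(n_channels - 1, 0.02),
    ])
    pos = np.vstack([[0.0, 0.0, radius], ring])
    return SensorLayout(channel_names=names, positions=pos)


@dataclass
class ERPTemplate:
    """N1/P2 template: windowed-Gaussian deflections (s, uV)."""

    n1_latency: float = 0.120
    n1_amplitude: float = -3.0
    n1_width: float = 0.030
    p2_latency: float = 0.220
    p2_amplitude: float = 2.5
    p2_width: float = 0.050

    def waveform(self, times: np.ndarray) -> np.ndarray:
        n1 = self.n1_amplitude * np.exp(
            -0.5 * ((times - self.n1_latency) / self.n1_width) ** 2
        )
        p2 = self.p2_amplitude * np.exp(
            -0.5 * ((times - self.p2_latency) / self.p2_width) ** 2
        )
        return n1 + p2


@dataclass
class EEGTruth:
    """Generator configuration for synthetic change-locked EEG epochs."""

    layout: SensorLayout = field(default_factory=ring_layout)
    template: ERPTemplate = field(default_factory=ERPTemplate)
    bias_channels: tuple[str, ...] = ("Cz", "E01", "E02", "E03")
    bias_onset: float = 0.100
    bias_offset: float = 0.250
    bias_amplitude: float = 1.5
    noise_sd: float = 8.0
    noise_correlation_length: float = 0.05
    noise_exponent: float = 1.0
    amplitude_jitter_sd: float = 0.15
    sample_rate: float = 250.0
    tmin: float = -0.1
    tmax: float = 0.5
    n_participants: int = 12
    trials_per_condition: int = 60
    seed: int = 0

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.tmax - self.tmin) * self.sample_rate)) + 1
        return self.tmin + np.arange(n) / self.sample_rate


def _spatial_cholesky(layout: SensorLayout, corr_length: float) -> np.ndarray:
    d = np.linalg.norm(
        layout.positions[:, None, :] - layout.positions[None, :, :], axis=-1
    )
    cov = np.exp(-d / corr_length)
    # jitter for numerical positive-definiteness
    return np.linalg.cholesky(cov + 1e-9 * np.eye(cov.shape[0]))


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_time: int,
    sample_rate: float, exponent: float,
) -> np.ndarray:
    """White noise shaped to a 1/f^exponent power spectrum along time."""
    white = rng.standard_normal(shape + (n_time,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_time, d=1.0 / sample_rate)
    gain = np.ones_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    gain[0] = gain[1]
    shaped = np.fft.irfft(spec * gain, n=n_time, axis=-1)
    shaped /= shaped.std(axis=-1, keepdims=True).mean() or 1.0
    return shaped


def gen_eeg(truth: EEGTruth) -> dict[str, list[Epochs]]:
    """Per-participant looming/receding Epochs with an embedded bias.

    Every epoch carries the shared N1/P2 template on all channels, the
    looming condition additionally a negative bias deflection (half-sine
    over [onset, offset]) on the affected channels, plus spatially
    correlated 1/f noise; participants get multiplicative amplitude jitter.
    Returns {"looming": [Epochs per participant], "receding": [...]}.
    """
    rng = np.random.default_rng(truth.seed)
    times = truth.times
    n_time = times.size
    n_ch = len(truth.layout.channel_names)
    chol = _spatial_cholesky(truth.layout, truth.noise_correlation_length)
    template = truth.template.waveform(times)
    bias_idx = [truth.layout.channel_names.index(c) for c in truth.bias_channels]
    in_bias = (times >= truth.bias_onset) & (times <= truth.bias_offset)
    bias_shape = np.zeros(n_time)
    if in_bias.any():
        span = times[in_bias]
        bias_shape[in_bias] = np.sin(
            np.pi * (span - span[0]) / max(span[-1] - span[0], 1e-9)
        )
    out: dict[str, list[Epochs]] = {"looming": [], "receding": []}
    for p in range(truth.n_participants):
        amp = 1.0 + truth.amplitude_jitter_sd * rng.standard_normal()
        for condition in ("looming", "receding"):
            signal = np.tile(amp * template, (n_ch, 1))
            if condition == "looming":
                bias = np.zeros((n_ch, n_time))
                bias[bias_idx] = -truth.bias_amplitude * bias_shape
                signal = signal + amp * bias
            noise = _one_over_f_noise(
                rng, (truth.trials_per_condition, n_ch), n_time,
                truth.sample_rate, truth.noise_exponent,
            )
            noise = np.einsum("ij,tjk->tik", chol, noise) * truth.noise_sd
            data = signal[None, :, :] + noise
            out[condition].append(Epochs(
                data=data,
                sample_rate=truth.sample_rate,
                tmin=truth.tmin,
                channel_names=list(truth.layout.channel_names),
                labels=pd.DataFrame({
                    "participant": [f"P{p:02d}"] * truth.trials_per_condition,
                    "condition": [condition] * truth.trials_per_condition,
                }),
                reference="average",
            ))
    return out


# ---------------------------------------------------------------------------
# Canned tiny fixtures
# ---------------------------------------------------------------------------

def _digest(arr: np.ndarray) -> str:
    a = np.ascontiguousarray(np.round(np.asarray(arr, dtype=float), 10))
    return hashlib.sha256(a.tobytes()).hexdigest()[:16]


def fixture_suite() -> dict:
    """Tiny hand-checkable datasets regenerated from fixed seeds.

    behavior: 2 participants x 8 trials (2 per condition); eeg: 6 epochs of
    4 channels x 50 samples. Digests of the regenerated arrays accompany
    the data so byte-stability across runs is checkable.
    """
    b_truth = BehaviorTruth(n_participants=2, trials_per_condition=2, seed=11)
    behavior, params = gen_behavior(b_truth)
    e_truth = EEGTruth(
        layout=ring_layout(4), bias_channels=("Cz", "E01"),
        n_participants=1, trials_per_condition=6,
        sample_rate=100.0, tmin=-0.1, tmax=0.39, seed=13,
    )
    eeg = gen_eeg(e_truth)
    return {
        "behavior": behavior,
        "behavior_params": params,
        "behavior_digest": _digest(behavior.table["rt"].to_numpy()),
        "eeg": eeg,
        "eeg_digest": _digest(eeg["looming"][0].data),
        "seeds": {"behavior": 11, "eeg": 13},
    }
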