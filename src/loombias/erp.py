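"""ERP preprocessing, N1/P2 peak extraction, and peak-bias statistics.

Two preprocessing recipes are provided. Adults: 0.5-100 Hz bandpass (Kaiser
window, beta = 7.2, order 462) -> onset epochs [-200, 1500] ms -> hard
threshold -200..800 uV -> average reference -> re-epoch to the change event
[-550, 850] ms -> per-participant trial-count equalization -> 20 Hz low-pass
smoothing (Hamming FIR, order 150) -> 100-ms pre-event baseline. Newborns:
0.05 Hz high-pass (Hamming, order 33000) and 80 Hz low-pass (Hamming, order
84) at 500 Hz -> average reference -> change epochs [-100, 800] ms ->
baseline -> threshold -100..100 uV -> equalization -> 20 Hz smoothing
(Hamming, order 140); participants keeping < 60% of designed trials in any
condition are excluded.

The N1 peak is the largest-magnitude local negative extremum in its search
window (82-182 ms post-change at the scalp; 77-177 ms for source-style
series); P2 is the largest local positive extremum within 150 ms after the
found N1. A 2x2 repeated-measures ANOVA on the looming-minus-receding peak
biases with paired follow-up contrasts completes the statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

#: Component search windows in seconds post change event.
N1_WINDOW_SCALP = (0.082, 0.182)
N1_WINDOW_SOURCE = (0.077, 0.177)
P2_SEARCH_SPAN = 0.150

#: Frontocentral electrode cluster used for newborn scalp ERPs.
NEWBORN_FRONTOCENTRAL = (
    "Fp1", "AF7", "AF3", "AFz", "AF4", "F5", "F3", "F1", "Fz", "F2",
    "F4", "F6", "FC3", "FC1", "FC2", "FC4", "C1", "C2", "C4",
)


@dataclass
class FilterSpec:
    """Linear-phase FIR design: windowed sinc with the named window.

    ``order`` is the filter order (taps = order + 1), matching the
    convention in which a high-pass must have even order for a valid
    type-I linear-phase design.
    """

    kind: Literal["bandpass", "lowpass", "highpass"]
    cutoffs: tuple[float, ...]
    window: Literal["kaiser", "hamming"] = "hamming"
    beta: float | None = None
    order: int = 100

    def __post_init__(self) -> None:
        if self.order <= 0:
            raise ValueError("order must be positive")
        if isinstance(self.cutoffs, (int, float)):
            self.cutoffs = (float(self.cutoffs),)
        self.cutoffs = tuple(float(c) for c in self.cutoffs)

    def design(self, sample_rate: float) -> np.ndarray:
        nyq = sample_rate / 2.0
        if any(c <= 0 or c >= nyq for c in self.cutoffs):
            raise ValueError(
                f"cutoffs {self.cutoffs} outside (0, Nyquist={nyq})"
            )
        win = ("kaiser", self.beta) if self.window == "kaiser" else "hamming"
        numtaps = self.order + 1
        if self.kind == "lowpass":
            return signal.firwin(numtaps, self.cutoffs[0], window=win, fs=sample_rate)
        if self.kind == "highpass":
            return signal.firwin(numtaps, self.cutoffs[0], window=win,
                                 pass_zero=False, fs=sample_rate)
        return signal.firwin(numtaps, list(self.cutoffs), window=win,
                             pass_zero=False, fs=sample_rate)


# Paper-recipe filter presets.
ADULT_BANDPASS = FilterSpec("bandpass", (0.5, 100.0), "kaiser", beta=7.2, order=462)
ADULT_SMOOTH = FilterSpec("lowpass", (20.0,), "hamming", order=150)
NEWBORN_HIGHPASS = FilterSpec("highpass", (0.05,), "hamming", order=33000)
NEWBORN_LOWPASS = FilterSpec("lowpass", (80.0,), "hamming", order=84)
NEWBORN_SMOOTH = FilterSpec("lowpass", (20.0,), "hamming", order=140)


def fir_filter(data: np.ndarray, spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Apply a linear-phase FIR along the last axis, delay-compensated.

    The group delay of order/2 samples is removed so the output is
    zero-phase; edges are reflect-padded over half the filter length.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    if n <= spec.order:
        raise ValueError("data must be longer than the filter order")
    taps = spec.design(sample_rate)
    half = spec.order // 2
    pad = min(half, n - 1)
    padded = np.concatenate(
        [data[..., 1 : pad + 1][..., ::-1], data, data[..., -pad - 1 : -1][..., ::-1]],
        axis=-1,
    )
    taps_nd = taps.reshape((1,) * (data.ndim - 1) + (-1,))
    full = signal.fftconvolve(padded, taps_nd, axes=-1, mode="full")
    start = pad + half
    return full[..., start : start + n]


@dataclass
class Epochs:
    """Trials x channels x time container of potentials in microvolts."""

    data: np.ndarray
    sample_rate: float
    tmin: float
    channel_names: list[str]
    labels: pd.DataFrame | None = None
    reference: Literal["Cz", "average"] = "Cz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length mismatch")
        if self.labels is not None and len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length mismatch")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sample_rate

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "Epochs":
        return Epochs(
            data=self.data.copy(), sample_rate=self.sample_rate,
            tmin=self.tmin, channel_names=list(self.channel_names),
            labels=None if self.labels is None else self.labels.copy(),
            reference=self.reference,
        )

    def average(self, condition: str = "") -> "Evoked":
        return Evoked(
            data=self.data.mean(axis=0),
            sample_rate=self.sample_rate,
            tmin=self.tmin,
            channel_names=list(self.channel_names),
            n_trials=self.n_trials,
            condition=condition,
        )

    def save_h5(self, path: str | Path) -> None:
        """Self-describing structured container (HDF5: array + metadata)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["sample_rate"] = self.sample_rate
            f.attrs["tmin"] = self.tmin
            f.attrs["reference"] = self.reference
            f.attrs["channel_names"] = [str(c) for c in self.channel_names]
            if self.labels is not None:
                f.create_dataset(
                    "labels_json",
                    data=np.bytes_(self.labels.to_json(orient="records")),
                )

    @classmethod
    def load_h5(cls, path: str | Path) -> "Epochs":
        import h5py

        with h5py.File(path, "r") as f:
            labels = None
            if "labels_json" in f:
                from io import StringIO

                labels = pd.read_json(
                    StringIO(f["labels_json"][()].decode()), orient="records"
                )
            return cls(
                data=f["data"][()],
                sample_rate=float(f.attrs["sample_rate"]),
                tmin=float(f.attrs["tmin"]),
                channel_names=[str(c) for c in f.attrs["channel_names"]],
                labels=labels,
                reference=str(f.attrs["reference"]),
            )


@dataclass
class Evoked:
    """Channels x time average of epochs."""

    data: np.ndarray
    sample_rate: float
    tmin: float
    channel_names: list[str]
    n_trials: int
    condition: str = ""

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[1]) / self.sample_rate

    def pick(self, channels: str | Sequence[str]) -> np.ndarray:
        """Single-channel trace or mean over a channel cluster."""
        if isinstance(channels, str):
            channels = [channels]
        idx = [self.channel_names.index(c) for c in channels]
        return self.data[idx].mean(axis=0)


def read_continuous(path: str | Path):
    """Optional reader for BrainVision (.vhdr) / EDF continuous recordings.

    Returns (data uV [channels x time], sample_rate, channel_names).
    Requires :mod:`mne`.
    """
    import mne  # deferred: optional dependency

    path = Path(path)
    if path.suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported format: {path.suffix}")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def epoch_and_baseline(
    continuous: np.ndarray,
    sample_rate: float,
    events: Sequence[int],
    window: tuple[float, float],
    baseline: tuple[float, float] | None,
    channel_names: Sequence[str] | None = None,
    labels: pd.DataFrame | None = None,
) -> Epochs:
    """Cut epochs around event samples and subtract the baseline mean.

    The window is a closed interval on the sample grid: an adult change
    epoch [-550, 850] ms at 1000 Hz holds 1401 samples. Events too close to
    a recording edge are dropped with a warning (and their label rows with
    them).
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_ch, n_time = continuous.shape
    i_lo = int(round(window[0] * sample_rate))
    i_hi = int(round(window[1] * sample_rate))
    epochs, kept = [], []
    for j, ev in enumerate(events):
        a, b = ev + i_lo, ev + i_hi
        if a < 0 or b >= n_time:
            warnings.warn(f"event at sample {ev} too close to an edge; dropped")
            continue
        epochs.append(continuous[:, a : b + 1])
        kept.append(j)
    if not epochs:
        raise ValueError("no epoch fits within the recording")
    data = np.stack(epochs)
    out = Epochs(
        data=data,
        sample_rate=sample_rate,
        tmin=i_lo / sample_rate,
        channel_names=(
            list(channel_names) if channel_names is not None
            else [f"ch{i}" for i in range(n_ch)]
        ),
        labels=None if labels is None else labels.iloc[kept].reset_index(drop=True),
    )
    if baseline is not None:
        out = apply_baseline(out, baseline)
    return out


def apply_baseline(epochs: Epochs, interval: tuple[float, float]) -> Epochs:
    """Subtract the per-epoch, per-channel mean over ``interval`` (s)."""
    t = epochs.times
    mask = (t >= interval[0] - 1e-12) & (t <= interval[1] + 1e-12)
    if not mask.any():
        raise ValueError("baseline interval outside the epoch")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def reject_by_threshold(
    epochs: Epochs, lo: float, hi: float
) -> tuple[Epochs, np.ndarray]:
    """Drop epochs with any sample outside [lo, hi] uV on any channel.

    Returns the kept epochs and a boolean mask (True = rejected).
    """
    if lo >= hi:
        raise ValueError("need lo < hi")
    bad = np.any((epochs.data < lo) | (epochs.data > hi), axis=(1, 2))
    kept = epochs.copy()
    kept.data = kept.data[~bad]
    if kept.labels is not None:
        kept.labels = kept.labels[~bad].reset_index(drop=True)
    return kept, bad


def equalization_removal_indices(y: int, x: int) -> list[int]:
    """1-based indices removed when dropping x of y trials: round(k*y/x).

    Round-half-up on the index positions spreads the removals evenly over
    the recording; e.g. y=10, x=2 removes the 5th and 10th trials.
    """
    if x <= 0:
        return []
    step = y / x
    return [int(np.floor(k * step + 0.5)) for k in range(1, x + 1)]


def equalize_trials(
    per_condition: dict[str, Epochs]
) -> dict[str, Epochs]:
    """Reduce every condition to the minimum per-condition trial count.

    From a condition with y trials, the x = y - m removals (m the minimum
    count) are taken at 1-based positions round(k*y/x), preserving the
    relative order of survivors.
    """
    counts = {c: e.n_trials for c, e in per_condition.items()}
    if min(counts.values()) < 1:
        raise ValueError("every condition needs at least one trial")
    m = min(counts.values())
    out = {}
    for cond, ep in per_condition.items():
        y = ep.n_trials
        x = y - m
        if x == 0:
            out[cond] = ep
            continue
        remove = set(i - 1 for i in equalization_removal_indices(y, x))
        keep = [i for i in range(y) if i not in remove]
        new = ep.copy()
        new.data = new.data[keep]
        if new.labels is not None:
            new.labels = new.labels.iloc[keep].reset_index(drop=True)
        out[cond] = new
    return out


def include_participant(
    kept_counts: dict[str, int] | Sequence[int],
    design_count: int,
    min_fraction: float = 0.6,
) -> bool:
    """True iff every condition keeps >= min_fraction of its designed trials.

    The boundary is inclusive: exactly 60 of 100 kept is still included.
    """
    counts = (
        list(kept_counts.values()) if isinstance(kept_counts, dict)
        else list(kept_counts)
    )
    return all(c >= min_fraction * design_count - 1e-12 for c in counts)


def rereference(epochs: Epochs, scheme: Literal["average"] = "average") -> Epochs:
    """Re-reference to the channel average; channel sum becomes ~0."""
    if scheme != "average":
        raise ValueError(f"unknown scheme: {scheme}")
    if epochs.data.shape[1] < 2:
        raise ValueError("average reference needs >= 2 channels")
    out = epochs.copy()
    out.data -= out.data.mean(axis=1, keepdims=True)
    out.reference = "average"
    return out


@dataclass
class PeakMeasure:
    """One component peak; ``found=False`` carries no amplitude/latency."""

    component: Literal["N1", "P2"]
    amplitude: float | None
    latency: float | None
    found: bool


def _local_extrema(trace: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of ``trace`` (endpoints excluded)."""
    if trace.size < 3:
        return np.array([], dtype=int)
    inner = (trace[1:-1] > trace[:-2]) & (trace[1:-1] > trace[2:])
    return np.flatnonzero(inner) + 1


def find_component_peak(
    evoked: Evoked,
    pick: str | Sequence[str],
    component: Literal["N1", "P2"],
    window_set: Literal["scalp", "source"] = "scalp",
    n1_latency: float | None = None,
) -> PeakMeasure:
    """Locate the N1 or P2 peak on a channel (or channel-cluster mean) trace.

    N1 is the largest-magnitude strict local negative extremum within its
    search window; P2 the largest strict local positive extremum within
    150 ms after the found N1 latency (``n1_latency`` required for P2).
    Window endpoints never qualify as peaks. ``found=False`` when no strict
    local extremum exists in the window.
    """
    trace = evoked.pick(pick)
    t = evoked.times
    if component == "N1":
        w = N1_WINDOW_SCALP if window_set == "scalp" else N1_WINDOW_SOURCE
        sign = -1.0
    else:
        if n1_latency is None:
            raise ValueError("P2 search requires the found N1 latency")
        w = (n1_latency, n1_latency + P2_SEARCH_SPAN)
        sign = 1.0
    if w[0] < t[0] or w[1] > t[-1] + 1e-12:
        raise ValueError(f"window {w} outside the epoch [{t[0]}, {t[-1]}]")
    mask = (t >= w[0] - 1e-12) & (t <= w[1] + 1e-12)
    idx = np.flatnonzero(mask)
    # Window endpoints are excluded by convention: only interior strict
    # local extrema of the windowed trace qualify.
    sub = sign * trace[idx]
    candidates = [idx[e] for e in _local_extrema(sub)]
    if not candidates:
        return PeakMeasure(component=component, amplitude=None, latency=None,
                           found=False)
    best = max(candidates, key=lambda i: sign * trace[i])
    return PeakMeasure(
        component=component,
        amplitude=float(trace[best]),
        latency=float(t[best]),
        found=True,
    )


def bias_peak_table(
    peaks: pd.DataFrame,
    component: Literal["N1", "P2"],
    value: Literal["amplitude", "latency"] = "amplitude",
) -> tuple[pd.DataFrame, int]:
    """Looming-minus-receding peak bias per participant x attention x cue.

    ``peaks`` needs columns participant, attention, cue, motion, component,
    amplitude, latency, found. Participants missing any required peak for
    this component are dropped listwise (complete-case table); the drop
    count is returned alongside.
    """
    sub = peaks[peaks["component"] == component]
    n_cells = (
        sub.groupby(["attention", "cue", "motion"], observed=True)
        .ngroups
    )
    good, dropped = [], []
    for pid, g in sub.groupby("participant"):
        complete = (
            len(g) == n_cells
            and g["found"].all()
            and g[value].notna().all()
        )
        (good if complete else dropped).append(pid)
    kept = sub[sub["participant"].isin(good)]
    pivot = kept.pivot_table(
        index=["participant", "attention", "cue"],
        columns="motion",
        values=value,
        aggfunc="first",
    ).reset_index()
    pivot["bias"] = pivot["looming"] - pivot["receding"]
    out = pivot[["participant", "attention", "cue", "bias"]]
    return out.reset_index(drop=True), len(dropped)


def _paired_cohens_d(diff: np.ndarray) -> float:
    return float(np.mean(diff) / np.std(diff, ddof=1))


def cohens_d_ci(
    diff: np.ndarray, n_boot: int = 10000, seed: int = 0,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """BCa bootstrap CI of the paired Cohen's d (seeded)."""
    res = stats.bootstrap(
        (np.asarray(diff, dtype=float),),
        lambda d, axis=-1: np.mean(d, axis=axis) / np.std(d, ddof=1, axis=axis),
        n_resamples=n_boot,
        confidence_level=confidence,
        method="BCa",
        random_state=np.random.default_rng(seed),
        vectorized=True,
    )
    return float(res.confidence_interval.low), float(res.confidence_interval.high)


def rm_anova_2x2(
    table: pd.DataFrame,
    factors: tuple[str, str] = ("attention", "cue"),
    value: str = "bias",
    ci_seed: int = 0,
    n_boot: int = 10000,
) -> dict:
    """Two-way fully-within-participant ANOVA on a complete-case 2x2 table.

    Standard participant-by-condition sums-of-squares decomposition with
    generalized eta squared (additive-SS definition: effect SS over effect
    SS plus all subject-related error SS). Mauchly sphericity is trivially
    satisfied with 2-level factors and is therefore report-only; a
    Shapiro-Wilk normality check per effect is included the same way.
    Follow-up paired t contrasts per factor carry paired Cohen's d with a
    seeded BCa bootstrap CI.
    """
    f1, f2 = factors
    wide = table.pivot_table(index="participant", columns=[f1, f2],
                             values=value)
    if wide.isna().any().any():
        raise ValueError("missing cells: complete-case input required")
    n = wide.shape[0]
    a_levels = sorted({c[0] for c in wide.columns})
    b_levels = sorted({c[1] for c in wide.columns})
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    cube = np.empty((n, 2, 2))
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            cube[:, i, j] = wide[(a, b)].to_numpy()

    grand = cube.mean()
    subj = cube.mean(axis=(1, 2))
    mean_a = cube.mean(axis=(0, 2))
    mean_b = cube.mean(axis=(0, 1))
    mean_ab = cube.mean(axis=0)
    mean_sa = cube.mean(axis=2)
    mean_sb = cube.mean(axis=1)

    # Each factor-level mean pools n subjects x 2 levels of the other factor.
    ss_a = 2 * n * np.sum((mean_a - grand) ** 2)
    ss_b = 2 * n * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum(
        (mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2
    )
    ss_subj = 4 * np.sum((subj - grand) ** 2)
    ss_sa = 2 * np.sum(
        (mean_sa - subj[:, None] - mean_a[None, :] + grand) ** 2
    )
    ss_sb = 2 * np.sum(
        (mean_sb - subj[:, None] - mean_b[None, :] + grand) ** 2
    )
    ss_total = np.sum((cube - grand) ** 2)
    ss_sab = ss_total - ss_a - ss_b - ss_ab - ss_subj - ss_sa - ss_sb

    df_effect = 1
    df_error = n - 1
    ss_error_all = ss_subj + ss_sa + ss_sb + ss_sab

    def effect(name, ss_eff, ss_err):
        ms_eff = ss_eff / df_effect
        ms_err = ss_err / df_error
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(stats.f.sf(F, df_effect, df_error)) if ms_err > 0 else 1.0
        ges = float(ss_eff / (ss_eff + ss_error_all)) if (
            ss_eff + ss_error_all
        ) > 0 else 0.0
        return {"F": float(F), "df": (df_effect, df_error), "p": p, "ges": ges}

    effects = {
        f1: effect(f1, ss_a, ss_sa),
        f2: effect(f2, ss_b, ss_sb),
        f"{f1}:{f2}": effect("ixn", ss_ab, ss_sab),
    }

    contrasts = {}
    for name, axis_means in ((f1, mean_sa), (f2, mean_sb)):
        diff = axis_means[:, 1] - axis_means[:, 0]
        if np.allclose(diff.std(ddof=1), 0):
            contrasts[name] = {
                "diff": float(diff.mean()), "t": np.nan, "p": np.nan,
                "d": np.nan, "d_ci": (np.nan, np.nan),
            }
            continue
        t_res = stats.ttest_rel(axis_means[:, 1], axis_means[:, 0])
        d = _paired_cohens_d(diff)
        d_ci = cohens_d_ci(diff, n_boot=n_boot, seed=ci_seed)
        contrasts[name] = {
            "diff": float(diff.mean()), "t": float(t_res.statistic),
            "p": float(t_res.pvalue), "d": d, "d_ci": d_ci,
        }

    normality = {}
    for name, eff in (("grand", cube.reshape(n, -1).mean(axis=1)),):
        if n >= 3:
            w = stats.shapiro(eff)
            normality[name] = {"W": float(w.statistic), "p": float(w.pvalue)}

    return {
        "effects": effects,
        "contrasts": contrasts,
        "n": n,
        "levels": {f1: a_levels, f2: b_levels},
        "sphericity": "trivial (2-level factors)",
        "normality": normality,
    }


# ---------------------------------------------------------------------------
# Recipe pipelines with an execution recorder
# ---------------------------------------------------------------------------

@dataclass
class PipelineRecord:
    """Names of executed stages, in order, for pipeline-order assertions."""

    steps: list[str] = field(default_factory=list)

    def log(self, name: str) -> None:
        self.steps.append(name)


ADULT_PIPELINE_ORDER = (
    "bandpass", "onset_epochs", "threshold", "average_reference",
    "change_epochs", "equalize", "smooth", "baseline",
)


def adult_pipeline(
    continuous: np.ndarray,
    sample_rate: float,
    onset_events: Sequence[int],
    change_events: Sequence[int],
    labels: pd.DataFrame,
    channel_names: Sequence[str] | None = None,
    condition_column: str = "condition",
    record: PipelineRecord | None = None,
    bandpass: FilterSpec = ADULT_BANDPASS,
    smooth: FilterSpec = ADULT_SMOOTH,
    threshold: tuple[float, float] = (-200.0, 800.0),
) -> dict[str, Epochs]:
    """Adult preprocessing recipe, stage order as documented in the module.

    Onset epochs span [-200, 1500] ms; the threshold verdicts computed there
    are applied when re-epoching to the change events ([-550, 850] ms),
    mirroring a workflow in which artifact screening happens on the onset
    epochs. Returns baseline-corrected, equalized per-condition epochs.
    """
    rec = record if record is not None else PipelineRecord()
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    filtered = fir_filter(continuous, bandpass, sample_rate)
    rec.log("bandpass")
    onset = epoch_and_baseline(
        filtered, sample_rate, onset_events, (-0.2, 1.5), (-0.1, 0.0),
        channel_names=channel_names, labels=labels,
    )
    rec.log("onset_epochs")
    _, bad = reject_by_threshold(onset, *threshold)
    rec.log("threshold")
    referenced = filtered - filtered.mean(axis=0, keepdims=True)
    rec.log("average_reference")
    keep_events = [e for e, b in zip(change_events, bad) if not b]
    keep_labels = labels[~bad].reset_index(drop=True)
    change = epoch_and_baseline(
        referenced, sample_rate, keep_events, (-0.55, 0.85), None,
        channel_names=onset.channel_names, labels=keep_labels,
    )
    rec.log("change_epochs")
    per_cond = {}
    for cond, sub in change.labels.groupby(condition_column):
        e = change.copy()
        idx = sub.index.to_numpy()
        e.data = e.data[idx]
        e.labels = sub.reset_index(drop=True)
        per_cond[str(cond)] = e
    per_cond = equalize_trials(per_cond)
    rec.log("equalize")
    for cond, e in per_cond.items():
        e.data = fir_filter(e.data, smooth, sample_rate)
    rec.log("smooth")
    per_cond = {
        c: apply_baseline(e, (-0.1, 0.0)) for c, e in per_cond.items()
    }
    rec.log("baseline")
    return per_cond


def newborn_pipeline(
    continuous: np.ndarray,
    sample_rate: float,
    change_events: Sequence[int],
    labels: pd.DataFrame,
    channel_names: Sequence[str] | None = None,
    condition_column: str = "condition",
    record: PipelineRecord | None = None,
    highpass: FilterSpec = NEWBORN_HIGHPASS,
    lowpass: FilterSpec = NEWBORN_LOWPASS,
    smooth: FilterSpec = NEWBORN_SMOOTH,
    threshold: tuple[float, float] = (-100.0, 100.0),
) -> dict[str, Epochs]:
    """Newborn preprocessing recipe (500 Hz, Cz-referenced input)."""
    rec = record if record is not None else PipelineRecord()
    x = fir_filter(continuous, highpass, sample_rate)
    rec.log("highpass")
    x = fir_filter(x, lowpass, sample_rate)
    rec.log("lowpass")
    ref = x - x.mean(axis=0, keepdims=True)
    rec.log("average_reference")
    change = epoch_and_baseline(
        ref, sample_rate, change_events, (-0.1, 0.8), (-0.1, 0.0),
        channel_names=channel_names, labels=labels,
    )
    rec.log("change_epochs+baseline")
    kept, _ = reject_by_threshold(change, *threshold)
    rec.log("threshold")
    per_cond = {}
    for cond, sub in kept.labels.groupby(condition_column):
        e = kept.copy()
        idx = sub.index.to_numpy()
        e.data = e.data[idx]
        e.labels = sub.reset_index(drop=True)
        per_cond[str(cond)] = e
    per_cond = equalize_trials(per_cond)
    rec.log("equalize")
    for cond, e in per_cond.items():
        e.data = fir_filter(e.data, smooth, sample_rate)
    rec.log("smooth")
    return per_cond
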