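"""Hierarchical Bayesian linear ballistic accumulator (LBA) modeling.

The LBA treats a two-alternative forced choice as a race: each response
option accumulates evidence linearly from a start point drawn from U[0, A]
toward a threshold b, at a drift rate drawn per trial from N(v_i, s_v); the
first accumulator to reach b produces the response, and a non-decision time
t0 is added to the threshold-crossing time. Per participant the model holds
8 drift rates — one per (cue x motion x correct/incorrect) cell — plus
A, b, t0 shared across conditions (11 free parameters). Participant-level
parameters are drawn from positive-truncated normal group distributions
whose locations and scales carry truncated-normal and gamma hyperpriors.

Inference uses differential-evolution MCMC (DE-MCMC): each chain's proposal
is its state plus a scaled difference of two other chains' states, which
adapts the proposal geometry to the correlated posterior. The looming-bias
statistic r is the fraction of posterior-predictive drift samples in which
the looming drift exceeds the receding drift; r = 0.5 means no bias.

The drift-rate scale s_v is fixed to 1 (the conventional LBA scaling
constraint). All "N(m, s)" prior notations are read as (mean, standard
deviation), never (mean, variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr, ndtr

S_V = 1.0  # fixed drift-rate standard deviation (scaling constraint)

CUES = ("intensity", "spectral")
MOTIONS = ("looming", "receding")
RESPONSES = ("correct", "incorrect")

#: Names of the 8 drift-rate parameters, in canonical order.
DRIFT_NAMES = tuple(
    f"v_{cue}_{motion}_{resp}"
    for cue in CUES
    for motion in MOTIONS
    for resp in RESPONSES
)
#: The 11 participant-level parameter names, canonical order.
PARAM_NAMES = ("A", "b", "t0") + DRIFT_NAMES

_SQRT2PI = math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------------------
# First-passage density / CDF (single accumulator)
# ---------------------------------------------------------------------------

def _phi(x):
    return np.exp(-0.5 * np.square(x)) / _SQRT2PI


def lba_pdf(t, A, b, v, s_v=S_V):
    """First-passage time density of a single LBA accumulator.

    f(t) = (1/A) [ -v Phi(z2) + s_v phi(z2) + v Phi(z1) - s_v phi(z1) ],
    z1 = (b - t v) / (t s_v), z2 = (b - A - t v) / (t s_v), with Phi/phi the
    unit-normal CDF/PDF. The density is defective: it integrates to the
    probability that the accumulator ever finishes. ``A -> 0`` falls back to
    the degenerate fixed-start-point limit.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = np.zeros_like(t)
    pos = t > 0
    ts = np.where(pos, t, 1.0)
    if A < 1e-10:
        # Degenerate limit: start point fixed at 0, first passage at b/d
        # with d ~ N(v, s_v); density of t = b/d.
        z = (b - ts * v) / (ts * s_v)
        out = np.where(pos, b / (np.square(ts) * s_v) * _phi(z), 0.0)
        return out
    z1 = (b - ts * v) / (ts * s_v)
    z2 = (b - A - ts * v) / (ts * s_v)
    dens = (-v * ndtr(z2) + s_v * _phi(z2) + v * ndtr(z1) - s_v * _phi(z1)) / A
    return np.where(pos, np.maximum(dens, 0.0), 0.0)


def lba_cdf(t, A, b, v, s_v=S_V):
    """Defective first-passage CDF of a single LBA accumulator.

    F(t) = 1 + ((b - A - t v)/A) Phi(z2) - ((b - t v)/A) Phi(z1)
             + (t s_v / A) (phi(z2) - phi(z1)).
    lim_{t->inf} F(t) = P(drift > 0) when A > 0, so slow accumulators may
    never finish.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    pos = t > 0
    ts = np.where(pos, t, 1.0)
    if A < 1e-10:
        z = (b - ts * v) / (ts * s_v)
        return np.where(pos, ndtr(-z), 0.0)
    z1 = (b - ts * v) / (ts * s_v)
    z2 = (b - A - ts * v) / (ts * s_v)
    cdf = (
        1.0
        + (b - A - ts * v) / A * ndtr(z2)
        - (b - ts * v) / A * ndtr(z1)
        + ts * s_v / A * (_phi(z2) - _phi(z1))
    )
    return np.where(pos, np.clip(cdf, 0.0, 1.0), 0.0)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class LBAParams:
    """One participant's 11 LBA parameters."""

    A: float
    b: float
    t0: float
    v: dict[str, float]
    s_v: float = S_V

    def __post_init__(self) -> None:
        missing = set(DRIFT_NAMES) - set(self.v)
        if missing:
            raise ValueError(f"missing drift entries: {sorted(missing)}")
        if len(self.v) != 8:
            raise ValueError("exactly 8 drift entries required")

    @property
    def valid(self) -> bool:
        return (
            self.A > 0
            and self.b > self.A
            and self.t0 > 0
            and all(np.isfinite(list(self.v.values())))
            and all(x > 0 for x in self.v.values())
        )

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.A, self.b, self.t0] + [self.v[n] for n in DRIFT_NAMES]
        )

    @classmethod
    def from_vector(cls, x: Sequence[float]) -> "LBAParams":
        x = np.asarray(x, dtype=float)
        return cls(
            A=float(x[0]), b=float(x[1]), t0=float(x[2]),
            v=dict(zip(DRIFT_NAMES, x[3:].tolist())),
        )


@dataclass
class GroupHyper:
    """Group-level truncated-normal location and scale per parameter."""

    mu: dict[str, float]
    sigma: dict[str, float]

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.mu or name not in self.sigma:
                raise ValueError(f"missing hyperparameter for {name}")
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("scales must be positive")

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            [self.mu[n] for n in PARAM_NAMES],
            [self.sigma[n] for n in PARAM_NAMES],
        ])

    @classmethod
    def from_vector(cls, x: Sequence[float]) -> "GroupHyper":
        x = np.asarray(x, dtype=float)
        k = len(PARAM_NAMES)
        return cls(
            mu=dict(zip(PARAM_NAMES, x[:k].tolist())),
            sigma=dict(zip(PARAM_NAMES, x[k:].tolist())),
        )


# Hyperprior settings: location priors are positive-truncated normals
# (mean, sd); scale priors are Gamma(shape, scale). Drift locations use the
# correct-response prior N+(3, 1) or the error prior N+(1, 1).
def _location_prior(name: str) -> tuple[float, float]:
    if name == "A":
        return (2.0, 1.0)
    if name == "b":
        return (2.0, 1.0)
    if name == "t0":
        return (0.2, 0.1)
    return (3.0, 1.0) if name.endswith("_correct") else (1.0, 1.0)


def _scale_prior(name: str) -> tuple[float, float]:
    return (1.0, 3.0) if name == "t0" else (1.0, 1.0)


# Chain start distributions, positive-truncated N(mean, sd).
def _start_distribution(name: str) -> tuple[float, float]:
    starts = {"A": (2.0, 0.2), "b": (1.0, 0.1), "t0": (0.2, 0.02)}
    if name in starts:
        return starts[name]
    return (3.0, 0.3) if name.endswith("_correct") else (1.0, 0.1)


def _log_truncnorm(x, mu, sigma):
    """Log density of N(mu, sigma) truncated to x > 0 (vectorized)."""
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    log_norm = log_ndtr(mu / sigma)  # P(X > 0) for X ~ N(mu, sigma)
    out = -0.5 * np.square(z) - math.log(_SQRT2PI) - np.log(sigma) - log_norm
    return np.where(x > 0, out, -np.inf)


def _sample_truncnorm(rng, mu, sigma, size=None):
    a = (0.0 - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=size,
                               random_state=rng)


# ---------------------------------------------------------------------------
# Dataset and likelihood
# ---------------------------------------------------------------------------

@dataclass
class BehavioralDataset:
    """Motion-trial choice/RT table.

    Columns: participant, cue, motion, response ("correct"/"incorrect"),
    rt (s). Static/catch trials are excluded before fitting; the descriptive
    summary keeps them (see :func:`behavior_summary`).
    """

    table: pd.DataFrame

    REQUIRED = ("participant", "cue", "motion", "response", "rt")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.table["rt"] <= 0).any():
            raise ValueError("all response times must be positive")

    @property
    def participants(self) -> list:
        return sorted(self.table["participant"].unique().tolist())

    def for_participant(self, participant) -> pd.DataFrame:
        return self.table[self.table["participant"] == participant]

    def to_tsv(self, path: str | Path) -> None:
        cols = ["participant", "cue", "motion", "response", "rt"]
        out = self.table[cols].rename(columns={"rt": "rt_s"})
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BehavioralDataset":
        df = pd.read_csv(path, sep="\t").rename(columns={"rt_s": "rt"})
        return cls(table=df)


def _accumulator_names(cue: str, motion: str) -> tuple[str, str]:
    return (
        f"v_{cue}_{motion}_correct",
        f"v_{cue}_{motion}_incorrect",
    )


def race_likelihood(trial, params: LBAParams) -> float:
    """Log defective density of one trial under a two-accumulator race.

    log [ f_winner(rt - t0) * (1 - F_loser(rt - t0)) ]; the winner is the
    accumulator matching the observed response. Returns -inf for rt <= t0.
    """
    name_c, name_e = _accumulator_names(trial.cue, trial.motion)
    winner, loser = (
        (name_c, name_e) if trial.response == "correct" else (name_e, name_c)
    )
    td = trial.rt - params.t0
    if td <= 0:
        return -np.inf
    f = lba_pdf(td, params.A, params.b, params.v[winner], params.s_v)
    surv = 1.0 - lba_cdf(td, params.A, params.b, params.v[loser], params.s_v)
    with np.errstate(divide="ignore"):
        return float(np.log(f) + np.log(np.maximum(surv, 0.0)))


def _loglik_participant(rt, v_winner, v_loser, A, b, t0, s_v=S_V) -> float:
    """Vectorized sum of trial log-likelihoods for one participant."""
    td = rt - t0
    if np.any(td <= 0):
        return -np.inf
    f = lba_pdf(td, A, b, v_winner, s_v)
    surv = 1.0 - lba_cdf(td, A, b, v_loser, s_v)
    if np.any(f <= 0) or np.any(surv <= 0):
        return -np.inf
    return float(np.sum(np.log(f)) + np.sum(np.log(surv)))


def _index_participant(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map a participant's trials to (rt, winner drift index, loser drift index)."""
    name_to_idx = {n: i for i, n in enumerate(PARAM_NAMES)}
    rt = df["rt"].to_numpy(dtype=float)
    w_idx = np.empty(len(df), dtype=int)
    l_idx = np.empty(len(df), dtype=int)
    for j, row in enumerate(df.itertuples(index=False)):
        name_c, name_e = _accumulator_names(row.cue, row.motion)
        if row.response == "correct":
            w, l = name_c, name_e
        else:
            w, l = name_e, name_c
        w_idx[j] = name_to_idx[w]
        l_idx[j] = name_to_idx[l]
    return rt, w_idx, l_idx


def log_posterior(
    data: BehavioralDataset,
    participant_params: dict[object, LBAParams],
    hyper: GroupHyper,
) -> float:
    """Joint log posterior of the hierarchical LBA.

    Sum of trial log-likelihoods, positive-truncated-normal participant-level
    priors under ``hyper``, and the hyperpriors (truncated-normal locations,
    gamma scales). -inf outside the support, including b <= A.
    """
    total = 0.0
    for pid in data.participants:
        if pid not in participant_params:
            raise ValueError(f"no parameters for participant {pid}")
    for pid, params in participant_params.items():
        if not params.valid:
            return -np.inf
        x = params.to_vector()
        for i, name in enumerate(PARAM_NAMES):
            lp = _log_truncnorm(x[i], hyper.mu[name], hyper.sigma[name])
            if not np.isfinite(lp):
                return -np.inf
            total += float(lp)
        df = data.for_participant(pid)
        if len(df):
            rt, w_idx, l_idx = _index_participant(df)
            ll = _loglik_participant(
                rt, x[w_idx], x[l_idx], params.A, params.b, params.t0,
                params.s_v,
            )
            if not np.isfinite(ll):
                return -np.inf
            total += ll
    lp_hyper = _log_hyperprior(hyper.to_vector())
    if not np.isfinite(lp_hyper):
        return -np.inf
    return total + lp_hyper


def _log_hyperprior(hyper_vec: np.ndarray) -> float:
    k = len(PARAM_NAMES)
    total = 0.0
    for i, name in enumerate(PARAM_NAMES):
        mu, sigma = hyper_vec[i], hyper_vec[k + i]
        if sigma <= 0 or mu <= 0:
            return -np.inf
        m0, s0 = _location_prior(name)
        total += float(_log_truncnorm(mu, m0, s0))
        shape, scale = _scale_prior(name)
        total += float(stats.gamma.logpdf(sigma, a=shape, scale=scale))
    return total


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_lba(
    params: LBAParams,
    condition: tuple[str, str],
    n_trials: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate (response, rt) pairs for one (cue, motion) condition.

    Start points ~ U[0, A], drifts ~ N(v, s_v) per accumulator; finish time
    (b - start)/drift for positive drifts; winner takes the trial and t0 is
    added. Races in which no accumulator finishes (all drifts <= 0) are
    redrawn, i.e. the simulator conditions on a response occurring, matching
    the defective-density renormalization implicit in the likelihood.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cue, motion = condition
    name_c, name_e = _accumulator_names(cue, motion)
    v = np.array([params.v[name_c], params.v[name_e]])
    responses = np.empty(n_trials, dtype=object)
    rts = np.empty(n_trials, dtype=float)
    todo = np.arange(n_trials)
    while todo.size:
        m = todo.size
        starts = rng.uniform(0.0, params.A, size=(m, 2))
        drifts = rng.normal(v, params.s_v, size=(m, 2))
        with np.errstate(divide="ignore"):
            finish = np.where(drifts > 0, (params.b - starts) / drifts, np.inf)
        win = np.argmin(finish, axis=1)
        t_win = finish[np.arange(m), win]
        done = np.isfinite(t_win)
        idx = todo[done]
        responses[idx] = np.where(win[done] == 0, "correct", "incorrect")
        rts[idx] = t_win[done] + params.t0
        todo = todo[~done]
    return pd.DataFrame({
        "cue": cue, "motion": motion, "response": responses, "rt": rts,
    })


# ---------------------------------------------------------------------------
# DE-MCMC sampler
# ---------------------------------------------------------------------------

@dataclass
class PosteriorChains:
    """DE-MCMC output: participant- and group-level samples.

    ``participant_samples``: (chain, draw, participant, 11);
    ``group_samples``: (chain, draw, 22) laid out as 11 locations then 11
    scales, both in :data:`PARAM_NAMES` order. Draws are post burn-in and
    post thinning.
    """

    participant_samples: np.ndarray
    group_samples: np.ndarray
    participants: list
    config: dict

    @property
    def n_chains(self) -> int:
        return self.group_samples.shape[0]

    @property
    def n_draws(self) -> int:
        return self.group_samples.shape[1]

    def group_location(self, name: str) -> np.ndarray:
        return self.group_samples[:, :, PARAM_NAMES.index(name)]

    def group_scale(self, name: str) -> np.ndarray:
        return self.group_samples[:, :, len(PARAM_NAMES) + PARAM_NAMES.index(name)]

    def flat_group(self) -> np.ndarray:
        return self.group_samples.reshape(-1, self.group_samples.shape[-1])

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            participant_samples=self.participant_samples,
            group_samples=self.group_samples,
            participants=np.asarray(self.participants, dtype=object),
            config=np.array([repr(self.config)], dtype=object),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorChains":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                participant_samples=z["participant_samples"],
                group_samples=z["group_samples"],
                participants=z["participants"].tolist(),
                config=eval(z["config"][0]),  # noqa: S307 - own repr round-trip
            )


def _participant_loglik(x, rt, w_idx, l_idx) -> float:
    """Likelihood part of the participant block (-inf outside support)."""
    A, b, t0 = x[0], x[1], x[2]
    if A <= 0 or b <= A or t0 <= 0 or np.any(x[3:] <= 0):
        return -np.inf
    return _loglik_participant(rt, x[w_idx], x[l_idx], A, b, t0)


def _participant_prior(x, hyper_vec) -> float:
    k = len(PARAM_NAMES)
    lp = float(np.sum(_log_truncnorm(x, hyper_vec[:k], hyper_vec[k:])))
    return lp


def _participant_block_logp(x, rt, w_idx, l_idx, hyper_vec) -> float:
    """Participant-level conditional: likelihood + prior under hyper."""
    ll = _participant_loglik(x, rt, w_idx, l_idx)
    if not np.isfinite(ll):
        return -np.inf
    lp = _participant_prior(x, hyper_vec)
    if not np.isfinite(lp):
        return -np.inf
    return lp + ll


def _group_block_logp(hyper_vec, part_matrix) -> float:
    """Group-level conditional: participant priors + hyperprior."""
    k = len(PARAM_NAMES)
    mu, sigma = hyper_vec[:k], hyper_vec[k:]
    if np.any(mu <= 0) or np.any(sigma <= 0):
        return -np.inf
    lp = _log_hyperprior(hyper_vec)
    if not np.isfinite(lp):
        return -np.inf
    lp += float(np.sum(_log_truncnorm(part_matrix, mu[None, :], sigma[None, :])))
    return lp


def _group_pair_logp(mu_j, sigma_j, name, part_col) -> float:
    """Conditional of one (location, scale) hyperparameter pair.

    Involves only that parameter's participant column and its own
    hyperprior, so the group level can be updated in 11 cheap 2-dim
    sub-blocks with far better acceptance than one 22-dim joint move.
    """
    if mu_j <= 0 or sigma_j <= 0:
        return -np.inf
    m0, s0 = _location_prior(name)
    z = (mu_j - m0) / s0
    lp = (
        -0.5 * z * z - math.log(_SQRT2PI) - math.log(s0)
        - float(log_ndtr(m0 / s0))
    )
    # Scale hyperprior is Gamma(shape=1, scale): an exponential density.
    _, scale = _scale_prior(name)
    lp += -sigma_j / scale - math.log(scale)
    zc = (part_col - mu_j) / sigma_j
    lp += float(
        np.sum(-0.5 * zc * zc)
        - part_col.size * (
            math.log(_SQRT2PI) + math.log(sigma_j) + float(log_ndtr(mu_j / sigma_j))
        )
    )
    return lp


def de_mcmc_fit(
    data: BehavioralDataset,
    n_chains: int = 32,
    n_iter: int = 8000,
    n_burn: int = 6000,
    thin: int = 5,
    seed: int = 0,
    gamma: float | None = None,
    jitter: float = 1e-3,
    group_sweeps: int = 5,
    max_start_retries: int = 100,
) -> PosteriorChains:
    """Fit the hierarchical LBA by blocked DE-MCMC.

    Per iteration every chain updates each participant's 11-parameter block
    and then the 22-parameter group block with the crossover proposal
    theta* = theta + gamma (theta_m - theta_n) + U(-jitter, jitter), m != n
    both different from the proposing chain, accepted by Metropolis on the
    block's conditional posterior. gamma defaults to 2.38 / sqrt(2 d) for a
    d-dimensional block. The study configuration is 32 chains x 8000
    iterations, 6000 burn-in, thinning 5; reduced settings are appropriate
    for desk-scale work. Deterministic given ``seed``.
    """
    if n_chains < 4:
        raise ValueError("DE-MCMC needs at least 4 chains for distinct donors")
    rng = np.random.default_rng(seed)
    participants = data.participants
    n_part = len(participants)
    k = len(PARAM_NAMES)

    trial_index = {}
    for pid in participants:
        df = data.for_participant(pid)
        for cue in CUES:
            for motion in MOTIONS:
                if not len(df[(df["cue"] == cue) & (df["motion"] == motion)]):
                    raise ValueError(
                        f"participant {pid} lacks condition ({cue}, {motion})"
                    )
        trial_index[pid] = _index_participant(df)

    gamma_part = gamma if gamma is not None else 2.38 / math.sqrt(2 * k)
    gamma_group = gamma if gamma is not None else 2.38 / math.sqrt(2 * 2)  # 2-dim sub-blocks

    # --- starting values --------------------------------------------------
    part_state = np.empty((n_chains, n_part, k))
    group_state = np.empty((n_chains, 2 * k))
    part_ll = np.full((n_chains, n_part), -np.inf)  # likelihood-only cache
    group_logp = np.full(n_chains, -np.inf)

    start_mu = np.array([_start_distribution(n)[0] for n in PARAM_NAMES])
    start_sd = np.array([_start_distribution(n)[1] for n in PARAM_NAMES])

    for c in range(n_chains):
        for attempt in range(max_start_retries):
            for p in range(n_part):
                x = _sample_truncnorm(rng, start_mu, start_sd)
                # The nominal start distributions propose b < A almost
                # surely; condition the b start on the drawn A so the race
                # is well-defined from the first iteration.
                a_lo = (x[0] - start_mu[1]) / start_sd[1]
                x[1] = stats.truncnorm.rvs(
                    a_lo, np.inf, loc=start_mu[1], scale=start_sd[1],
                    random_state=rng,
                )
                # The non-decision time must undercut the participant's
                # fastest response for the likelihood to be finite.
                min_rt = float(trial_index[participants[p]][0].min())
                x[2] = min(x[2], 0.9 * min_rt)
                part_state[c, p] = x
            group_state[c, :k] = _sample_truncnorm(rng, start_mu, start_sd)
            group_state[c, k:] = rng.gamma(
                shape=1.0, scale=[_scale_prior(n)[1] for n in PARAM_NAMES]
            )
            ok = True
            for p, pid in enumerate(participants):
                rt, w_idx, l_idx = trial_index[pid]
                ll = _participant_loglik(part_state[c, p], rt, w_idx, l_idx)
                if not np.isfinite(ll) or not np.isfinite(
                    _participant_prior(part_state[c, p], group_state[c])
                ):
                    ok = False
                    break
                part_ll[c, p] = ll
            if ok:
                glp = _group_block_logp(group_state[c], part_state[c])
                ok = np.isfinite(glp)
            if ok:
                group_logp[c] = glp
                break
        else:
            raise RuntimeError(
                "could not find a finite-posterior start after retries"
            )

    # --- sampling ---------------------------------------------------------
    keep = [
        i for i in range(n_iter)
        if i >= n_burn and (i - n_burn) % thin == 0
    ]
    n_keep = len(keep)
    part_out = np.empty((n_chains, n_keep, n_part, k))
    group_out = np.empty((n_chains, n_keep, 2 * k))
    keep_pos = {it: j for j, it in enumerate(keep)}

    chain_ids = np.arange(n_chains)
    for it in range(n_iter):
        # donor pairs per chain, m != n != self
        donors = np.empty((n_chains, 2), dtype=int)
        for c in range(n_chains):
            m, n = rng.choice(np.delete(chain_ids, c), size=2, replace=False)
            donors[c] = (m, n)
        u_accept_part = rng.random((n_chains, n_part))
        u_accept_single = rng.random((n_chains, n_part))
        single_dim = rng.integers(0, k, size=(n_chains, n_part))
        u_accept_group = rng.random((n_chains, group_sweeps, k))
        noise_part = rng.uniform(-jitter, jitter, size=(n_chains, n_part, k))
        noise_single = rng.uniform(-jitter, jitter, size=(n_chains, n_part))
        noise_group = rng.uniform(
            -jitter, jitter, size=(n_chains, group_sweeps, 2 * k)
        )

        for c in range(n_chains):
            m, n = donors[c]
            for p, pid in enumerate(participants):
                prop = (
                    part_state[c, p]
                    + gamma_part * (part_state[m, p] - part_state[n, p])
                    + noise_part[c, p]
                )
                rt, w_idx, l_idx = trial_index[pid]
                prop_ll = _participant_loglik(prop, rt, w_idx, l_idx)
                if not np.isfinite(prop_ll):
                    continue
                cur = part_ll[c, p] + _participant_prior(
                    part_state[c, p], group_state[c]
                )
                prop_lp = prop_ll + _participant_prior(prop, group_state[c])
                if np.log(u_accept_part[c, p]) < prop_lp - cur:
                    part_state[c, p] = prop
                    part_ll[c, p] = prop_ll
                # Random-scan single-parameter DE move: weakly identified
                # dimensions (notably A) mix poorly under the joint block
                # move alone, because acceptance is governed by the
                # well-identified dimensions.
                j = single_dim[c, p]
                prop = part_state[c, p].copy()
                prop[j] += (
                    2.38 / math.sqrt(2)
                    * (part_state[m, p, j] - part_state[n, p, j])
                    + noise_single[c, p]
                )
                prop_ll = _participant_loglik(prop, rt, w_idx, l_idx)
                if np.isfinite(prop_ll):
                    cur = part_ll[c, p] + _participant_prior(
                        part_state[c, p], group_state[c]
                    )
                    prop_lp = prop_ll + _participant_prior(prop, group_state[c])
                    if np.log(u_accept_single[c, p]) < prop_lp - cur:
                        part_state[c, p] = prop
                        part_ll[c, p] = prop_ll
            # Group level: 11 independent (mu_j, sigma_j) sub-block moves.
            # These conditionals never touch the likelihood, so several
            # sweeps per iteration are nearly free and sharpen group-level
            # mixing considerably.
            for sweep in range(group_sweeps):
                for j, name in enumerate(PARAM_NAMES):
                    col = part_state[c, :, j]
                    cur = _group_pair_logp(
                        group_state[c, j], group_state[c, k + j], name, col
                    )
                    mu_p = (
                        group_state[c, j]
                        + gamma_group * (group_state[m, j] - group_state[n, j])
                        + noise_group[c, sweep, j]
                    )
                    sd_p = (
                        group_state[c, k + j]
                        + gamma_group
                        * (group_state[m, k + j] - group_state[n, k + j])
                        + noise_group[c, sweep, k + j]
                    )
                    lp_g = _group_pair_logp(mu_p, sd_p, name, col)
                    if np.log(u_accept_group[c, sweep, j]) < lp_g - cur:
                        group_state[c, j] = mu_p
                        group_state[c, k + j] = sd_p

        if it in keep_pos:
            j = keep_pos[it]
            part_out[:, j] = part_state
            group_out[:, j] = group_state

    return PosteriorChains(
        participant_samples=part_out,
        group_samples=group_out,
        participants=list(participants),
        config={
            "n_chains": n_chains, "n_iter": n_iter, "n_burn": n_burn,
            "thin": thin, "seed": seed, "gamma": gamma, "jitter": jitter,
        },
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(samples: np.ndarray) -> float | np.ndarray:
    """Potential scale reduction factor (classical between/within form).

    ``samples`` has shape (chain, draw) or (chain, draw, parameter).
    Zero-variance (degenerate) chains yield NaN rather than an error.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
        squeeze = True
    else:
        squeeze = False
    m, n = x.shape[0], x.shape[1]
    if m < 2 or n < 2:
        raise ValueError("need >= 2 chains with >= 2 retained draws")
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    rhat = np.where(W > 0, rhat, np.nan)
    return float(rhat[0]) if squeeze else rhat


def gelman_rubin_report(chains: PosteriorChains) -> pd.DataFrame:
    """R-hat for every group-level parameter (locations and scales)."""
    rhat = gelman_rubin(chains.group_samples)
    names = [f"mu_{n}" for n in PARAM_NAMES] + [f"sigma_{n}" for n in PARAM_NAMES]
    return pd.DataFrame({"parameter": names, "rhat": rhat})


# ---------------------------------------------------------------------------
# Posterior predictive checks
# ---------------------------------------------------------------------------

def posterior_predictive_check(
    chains: PosteriorChains,
    data: BehavioralDataset,
    draws_per_chain: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Quartile-coverage and accuracy PPC per condition.

    For each posterior draw (``draws_per_chain`` random retained draws per
    chain) the model simulates a dataset matching the observed per-condition
    trial counts. The RT statistic is the proportion of simulated RTs inside
    the observed interquartile range [q1, q3] (reference 0.5); the accuracy
    statistic is the simulated hit rate minus the observed one (reference 0).
    Both come with a 95% credible interval and a two-sided Monte-Carlo
    p-value of the reference value.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_chains, n_draws = chains.n_chains, chains.n_draws
    draw_idx = [
        (c, int(i))
        for c in range(n_chains)
        for i in rng.integers(0, n_draws, size=draws_per_chain)
    ]
    for cue in CUES:
        for motion in MOTIONS:
            obs = data.table[
                (data.table["cue"] == cue) & (data.table["motion"] == motion)
            ]
            if not len(obs):
                import warnings

                warnings.warn(f"condition ({cue}, {motion}) absent; skipped")
                continue
            q1, q3 = np.quantile(obs["rt"], [0.25, 0.75])
            obs_acc = float((obs["response"] == "correct").mean())
            per_part_counts = obs.groupby("participant").size()
            stat_rt, stat_acc = [], []
            for c, i in draw_idx:
                sim_rt, sim_corr = [], []
                for p, pid in enumerate(chains.participants):
                    if pid not in per_part_counts.index:
                        continue
                    params = LBAParams.from_vector(
                        chains.participant_samples[c, i, p]
                    )
                    sim = simulate_lba(
                        params, (cue, motion),
                        int(per_part_counts.loc[pid]), rng,
                    )
                    sim_rt.append(sim["rt"].to_numpy())
                    sim_corr.append((sim["response"] == "correct").to_numpy())
                sim_rt = np.concatenate(sim_rt)
                sim_corr = np.concatenate(sim_corr)
                stat_rt.append(float(np.mean((sim_rt >= q1) & (sim_rt <= q3))))
                stat_acc.append(float(sim_corr.mean()) - obs_acc)
            for name, vals, ref in (
                ("rt_quartile_coverage", np.array(stat_rt), 0.5),
                ("accuracy_diff", np.array(stat_acc), 0.0),
            ):
                lo, hi = np.quantile(vals, [0.025, 0.975])
                p_two = 2 * min(
                    (np.sum(vals >= ref) + 1) / (vals.size + 1),
                    (np.sum(vals <= ref) + 1) / (vals.size + 1),
                )
                rows.append({
                    "cue": cue, "motion": motion, "statistic": name,
                    "mean": float(vals.mean()), "ci_lo": float(lo),
                    "ci_hi": float(hi), "reference": ref,
                    "p_two_sided": min(float(p_two), 1.0),
                    "n_draws": vals.size,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Looming-bias ratio statistic
# ---------------------------------------------------------------------------

@dataclass
class RatioResult:
    """Posterior-predictive drift-rate ratio statistic.

    ``r_draws`` holds one r per repetition; r is the fraction of paired
    drift samples with looming drift exceeding receding drift, so r in
    [0, 1] and 0.5 is chance.
    """

    r_draws: np.ndarray
    point: float
    ci89_low: float
    p_gt_chance: float
    cue: str

    def as_dict(self) -> dict:
        return {
            "cue": self.cue, "r": self.point, "ci89_low": self.ci89_low,
            "p_gt_chance": self.p_gt_chance,
        }


def looming_ratio(
    chains: PosteriorChains,
    n_samples: int = 10000,
    n_reps: int = 10000,
    cue: Literal["pooled", "intensity", "spectral"] = "pooled",
    seed: int = 0,
) -> RatioResult:
    """Ratio of posterior-predictive drift samples favoring looming.

    Per repetition one joint posterior draw of the group-level (location,
    scale) pair is taken for the looming-correct and receding-correct
    accumulators; ``n_samples`` Gaussian drifts are generated per motion
    direction and r = mean(1[v_L - v_R > 0]). In pooled mode both cues'
    accumulators are sampled from the same posterior draw and concatenated
    before pairing. Returns the r distribution over ``n_reps`` repetitions,
    its one-tailed 89% credible interval (lower bound), and p(r > 0.5).
    """
    cues = CUES if cue == "pooled" else (cue,)
    for c in cues:
        for motion in MOTIONS:
            name = f"v_{c}_{motion}_correct"
            if name not in PARAM_NAMES:
                raise ValueError(f"missing accumulator {name}")
    rng = np.random.default_rng(seed)
    flat = chains.flat_group()
    k = len(PARAM_NAMES)
    idx = rng.integers(0, flat.shape[0], size=n_reps)
    r = np.empty(n_reps)
    for j, i in enumerate(idx):
        draw = flat[i]
        vl_parts, vr_parts = [], []
        for c in cues:
            il = PARAM_NAMES.index(f"v_{c}_looming_correct")
            ir = PARAM_NAMES.index(f"v_{c}_receding_correct")
            vl_parts.append(
                rng.normal(draw[il], draw[k + il], size=n_samples)
            )
            vr_parts.append(
                rng.normal(draw[ir], draw[k + ir], size=n_samples)
            )
        v_l = np.concatenate(vl_parts)
        v_r = np.concatenate(vr_parts)
        r[j] = float(np.mean(v_l - v_r > 0))
    point = float(np.mean(r))
    ci89_low = float(np.quantile(r, 0.11))
    p_gt = float(np.mean(r > 0.5))
    return RatioResult(r_draws=r, point=point, ci89_low=ci89_low,
                       p_gt_chance=p_gt, cue=cue)


def ratio_closed_form(mu_l: float, sigma_l: float, mu_r: float,
                      sigma_r: float) -> float:
    """P(X > Y) for independent X ~ N(mu_l, sigma_l), Y ~ N(mu_r, sigma_r).

    Independent oracle for :func:`looming_ratio` at fixed group parameters:
    Phi((mu_l - mu_r) / sqrt(sigma_l^2 + sigma_r^2)).
    """
    return float(ndtr((mu_l - mu_r) / math.hypot(sigma_l, sigma_r)))


# ---------------------------------------------------------------------------
# Descriptive behavioral summary
# ---------------------------------------------------------------------------

def behavior_summary(
    table: pd.DataFrame, catch_error_criterion: float = 0.2
) -> dict:
    """Descriptive report over a table that still includes static trials.

    Static (catch) trials are identified by motion starting with "static".
    Reports per-participant hit-rate quartiles and RT mean +/- SD for static
    and motion trials, a paired Wilcoxon signed-rank comparison between
    them, and the catch-error exclusion flags (> 20% errors on catch
    trials excludes a participant).
    """
    is_static = table["motion"].astype(str).str.startswith("static")
    static = table[is_static]
    motion = table[~is_static]
    if not len(static):
        return {"applicable": False}

    def per_part(df):
        hit = df.groupby("participant")["response"].apply(
            lambda r: float((r == "correct").mean())
        )
        rt = df[df["response"] == "correct"].groupby("participant")["rt"]
        return hit, rt.mean()

    static_hit, static_rt = per_part(static)
    motion_hit, motion_rt = per_part(motion)
    excluded = static_hit.index[
        (1.0 - static_hit) > catch_error_criterion
    ].tolist()

    common = static_hit.index.intersection(motion_hit.index)
    if len(common) >= 2:
        wil_hit = stats.wilcoxon(static_hit.loc[common], motion_hit.loc[common])
        wil_rt = stats.wilcoxon(
            static_rt.reindex(common), motion_rt.reindex(common),
            nan_policy="omit",
        )
        signed_rank = {
            "hit_rate": {"V": float(wil_hit.statistic), "p": float(wil_hit.pvalue)},
            "rt": {"V": float(wil_rt.statistic), "p": float(wil_rt.pvalue)},
            "n": int(len(common)),
        }
    else:
        signed_rank = None

    def quartiles(s):
        return [float(x) for x in np.quantile(s, [0.25, 0.5, 0.75])]

    return {
        "applicable": True,
        "static_hit_rate_quartiles": quartiles(static_hit),
        "motion_hit_rate_quartiles": quartiles(motion_hit),
        "static_rt_mean_sd": [
            float(static_rt.mean()), float(static_rt.std(ddof=1)),
        ],
        "motion_rt_mean_sd": [
            float(motion_rt.mean()), float(motion_rt.std(ddof=1)),
        ],
        "signed_rank": signed_rank,
        "excluded_participants": excluded,
        "catch_error_criterion": catch_error_criterion,
    }
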