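"""End-to-end orchestration with reproducibility metadata.

A run is described by a structured YAML/dict config with per-stage blocks
and one global seed; every stochastic stage receives an explicit child seed
derived from it. The "study" profile carries the full-scale settings
(32 chains x 8000 iterations, 500 permutations, ...); the bundled "desk"
profile scales everything down to minutes on one CPU.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import cluster_stats, erp, lba, stimuli, synthetic, trial_design
from ._version import __version__

STAGES = ("schedule", "stimuli", "behavior", "lba", "ratio", "eeg", "cluster")

#: Full study-scale defaults per stage.
STUDY_PROFILE = {
    "schedule": {"design": "adult", "trials_per_condition": 100},
    "stimuli": {"n_example_trials": 8},
    "behavior": {"n_participants": 28, "trials_per_condition": 100},
    "lba": {"n_chains": 32, "n_iter": 8000, "n_burn": 6000, "thin": 5},
    "ratio": {"n_samples": 10000, "n_reps": 10000},
    "eeg": {"n_participants": 28, "trials_per_condition": 92},
    "cluster": {"n_permutations": 500, "alpha": 0.05},
}

#: Reduced profile for desk-scale runs (minutes on one CPU).
DESK_PROFILE = {
    "schedule": {"design": "adult", "trials_per_condition": 4},
    "stimuli": {"n_example_trials": 4},
    "behavior": {"n_participants": 6, "trials_per_condition": 40},
    "lba": {"n_chains": 8, "n_iter": 800, "n_burn": 500, "thin": 3},
    "ratio": {"n_samples": 2000, "n_reps": 1000},
    "eeg": {"n_participants": 10, "trials_per_condition": 40},
    "cluster": {"n_permutations": 200, "alpha": 0.05},
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run configuration."""

    stages: dict
    seed: int = 0
    out_dir: str = "run"
    profile: str = "desk"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        profile = raw.get("profile", "desk")
        base = DESK_PROFILE if profile == "desk" else STUDY_PROFILE
        requested = raw.get("stages")
        if requested is None:
            raise ValueError("config missing required 'stages' block")
        stages = {}
        for name in requested:
            if name not in STAGES:
                raise ValueError(f"unknown stage '{name}'")
            block = dict(base[name])
            block.update(raw.get(name, {}))
            stages[name] = block
        return cls(
            stages=stages,
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "run")),
            profile=profile,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        # Explicit child seed per stochastic stage, derived from the global
        # seed; kept below 2^31.
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def digest(self) -> str:
        blob = json.dumps(
            {"stages": self.stages, "seed": self.seed, "profile": self.profile},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in declared order.

    Writes per-stage outputs plus a provenance manifest (package version,
    config hash, per-stage seeds, output digests) into the run directory.
    Deterministic stages reproduce identical outputs under identical
    configs. A stage failure aborts with :class:`StageError` naming the
    stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "profile": config.profile,
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        seed = config.stage_seed(stage)
        try:
            outputs = _STAGE_RUNNERS[stage](config.stages[stage], seed, out, state)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {
            "seed": seed,
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": {
                k: _file_digest(v) for k, v in outputs.items()
            },
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _file_digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# --- stage runners ---------------------------------------------------------

def _run_schedule(block, seed, out, state):
    builder = (
        trial_design.build_adult_schedule
        if block.get("design", "adult") == "adult"
        else trial_design.build_newborn_schedule
    )
    schedule = builder(seed=seed, trials_per_condition=block["trials_per_condition"])
    state["schedule"] = schedule
    path = out / "schedule.tsv"
    schedule.to_tsv(path)
    report = trial_design.validate_schedule(schedule)
    rep_path = out / "schedule_report.json"
    rep_path.write_text(json.dumps({
        "passed": report.passed,
        "balance_violations": report.balance_violations,
    }, indent=2))
    return {"schedule": path, "report": rep_path}


def _run_stimuli(block, seed, out, state):
    schedule = state.get("schedule")
    if schedule is None:
        raise ValueError("stimuli stage requires the schedule stage")
    hrtf = stimuli.synthetic_template_hrtf()
    spec = stimuli.StimulusSpec()
    n = min(block.get("n_example_trials", 4), len(schedule.trials))
    paths = stimuli.render_schedule(
        schedule.trials[:n], spec, hrtf, out / "stimuli"
    )
    index = out / "stimuli_index.tsv"
    index.write_text("\n".join(str(p.name) for p in paths))
    return {"index": index}


def _run_behavior(block, seed, out, state):
    truth = synthetic.BehaviorTruth(
        n_participants=block["n_participants"],
        trials_per_condition=block["trials_per_condition"],
        seed=seed,
    )
    data, params = synthetic.gen_behavior(truth)
    state["behavior"] = data
    state["behavior_truth"] = truth
    path = out / "behavior.tsv"
    data.to_tsv(path)
    return {"behavior": path}


def _run_lba(block, seed, out, state):
    data = state.get("behavior")
    if data is None:
        raise ValueError("lba stage requires the behavior stage")
    chains = lba.de_mcmc_fit(
        data,
        n_chains=block["n_chains"], n_iter=block["n_iter"],
        n_burn=block["n_burn"], thin=block["thin"], seed=seed,
    )
    state["chains"] = chains
    path = out / "chains.npz"
    chains.save(path)
    diag = lba.gelman_rubin_report(chains)
    diag_path = out / "gelman_rubin.tsv"
    diag.to_csv(diag_path, sep="\t", index=False)
    return {"chains": path, "gelman_rubin": diag_path}


def _run_ratio(block, seed, out, state):
    chains = state.get("chains")
    if chains is None:
        raise ValueError("ratio stage requires the lba stage")
    rows = []
    for cue in ("pooled", "intensity", "spectral"):
        res = lba.looming_ratio(
            chains, n_samples=block["n_samples"], n_reps=block["n_reps"],
            cue=cue, seed=seed,
        )
        rows.append(res.as_dict())
    import pandas as pd

    path = out / "looming_ratio.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    state["ratio"] = rows
    return {"ratio": path}


def _run_eeg(block, seed, out, state):
    truth = synthetic.EEGTruth(
        n_participants=block["n_participants"],
        trials_per_condition=block["trials_per_condition"],
        seed=seed,
    )
    state["eeg"] = synthetic.gen_eeg(truth)
    state["eeg_truth"] = truth
    path = out / "eeg_meta.json"
    path.write_text(json.dumps({
        "n_participants": truth.n_participants,
        "trials_per_condition": truth.trials_per_condition,
        "sample_rate": truth.sample_rate,
    }, indent=2))
    return {"eeg_meta": path}


def _run_cluster(block, seed, out, state):
    eeg = state.get("eeg")
    truth = state.get("eeg_truth")
    if eeg is None:
        raise ValueError("cluster stage requires the eeg stage")
    looming = np.stack([e.average().data for e in eeg["looming"]])
    receding = np.stack([e.average().data for e in eeg["receding"]])
    layout = cluster_stats.build_adjacency(truth.layout)
    result = cluster_stats.permutation_test(
        looming - receding,
        adjacency=layout.adjacency,
        n_permutations=block["n_permutations"],
        alpha=block["alpha"],
        seed=seed,
        times=truth.times,
        channel_names=truth.layout.channel_names,
    )
    path = out / "clusters.tsv"
    result.to_frame().to_csv(path, sep="\t", index=False)
    state["clusters"] = result
    return {"clusters": path}


_STAGE_RUNNERS = {
    "schedule": _run_schedule,
    "stimuli": _run_stimuli,
    "behavior": _run_behavior,
    "lba": _run_lba,
    "ratio": _run_ratio,
    "eeg": _run_eeg,
    "cluster": _run_cluster,
}
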