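"""Render example stimuli and verify the printed acoustic contract.

Synthesizes one trial per cue x motion cell with the synthetic template
HRTF, writes the WAVs under scratch/ (audio is bulky) and a measurement
table under results/: broadband level of the pre- and post-transition
segments, their difference, and the measured crossfade width.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from loombias import stimuli as st
from loombias.trial_design import TrialSpec

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
WAV_DIR = ROOT / "scratch" / "stimuli"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    WAV_DIR.mkdir(parents=True, exist_ok=True)
    spec = st.StimulusSpec()
    hrtf = st.synthetic_template_hrtf()
    fs = spec.sample_rate
    rows = []
    for cue in ("intensity", "spectral"):
        for motion in ("looming", "receding", "static_near_onset",
                       "static_far_onset"):
            trial = TrialSpec("passive", cue, motion, "left", 0.6, 0.5, 0)
            wav = st.synthesize_trial(trial, spec, hrtf)
            wav.to_wav(WAV_DIR / f"{cue}_{motion}.wav")
            pre = wav.samples[int(0.1 * fs): int(0.55 * fs), 0]
            post = wav.samples[int(0.66 * fs): int(1.15 * fs), 0]
            rows.append({
                "cue": cue, "motion": motion,
                "pre_db": round(st.rms_db(pre), 3),
                "post_db": round(st.rms_db(post), 3),
                "step_db": round(st.rms_db(post) - st.rms_db(pre), 3),
            })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "stimulus_levels.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    n = spec.n_samples
    w = st._crossfade(np.zeros(n), np.ones(n), fs, 0.6, spec.transition_ramp)
    width_ms = (np.argmax(w >= 1 - 1e-12) - np.argmax(w > 0)) / fs * 1000
    print(f"\ncrossfade width: {width_ms:.1f} ms "
          f"(configured {spec.transition_ramp * 1000:.0f} ms)")


if __name__ == "__main__":
    main()
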