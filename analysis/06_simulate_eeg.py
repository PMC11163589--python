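"""Generate synthetic change-locked EEG epochs with an embedded looming bias.

Builds a 16-channel synthetic cap, embeds a 1.5 uV negative looming-minus-
receding deflection over 100-250 ms on a frontocentral channel group inside
spatially correlated 1/f noise, and writes per-participant grand averages
plus the generator configuration under results/. The raw epoch files go to
scratch/ (bulky HDF5).
"""

import json
from pathlib import Path

import numpy as np

from loombias import synthetic

SEED = 20240905
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
EPOCH_DIR = ROOT / "scratch" / "eeg"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    EPOCH_DIR.mkdir(parents=True, exist_ok=True)
    truth = synthetic.EEGTruth(
        layout=synthetic.ring_layout(16),
        bias_channels=("Cz", "E01", "E02", "E03"),
        n_participants=12, trials_per_condition=60, seed=SEED,
    )
    eeg = synthetic.gen_eeg(truth)
    for cond, per_part in eeg.items():
        stack = np.stack([e.average().data for e in per_part])
        np.save(EPOCH_DIR / f"evoked_{cond}.npy", stack)
        for p, epochs in enumerate(per_part):
            epochs.save_h5(EPOCH_DIR / f"{cond}_P{p:02d}.h5")
    truth.layout.to_tsv(OUT / "eeg_layout.tsv")
    (OUT / "eeg_truth.json").write_text(json.dumps({
        "n_participants": truth.n_participants,
        "trials_per_condition": truth.trials_per_condition,
        "sample_rate_hz": truth.sample_rate,
        "bias_amplitude_uv": truth.bias_amplitude,
        "bias_window_s": [truth.bias_onset, truth.bias_offset],
        "bias_channels": list(truth.bias_channels),
        "noise_sd_uv": truth.noise_sd,
        "seed": SEED,
    }, indent=2))
    print(f"wrote {2 * truth.n_participants} epoch files -> {EPOCH_DIR}")


if __name__ == "__main__":
    main()
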