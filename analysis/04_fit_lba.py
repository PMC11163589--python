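"""Fit the hierarchical LBA to the simulated behavior by DE-MCMC.

Reads results/behavior_motion.tsv (run 03 first), fits at a desk scale
(8 chains x 2000 iterations, 1000 burn-in, thinning 5 — the full study
configuration of 32 chains x 8000 with 6000 burn-in is a config change
away), then writes the chains, the Gelman-Rubin table, and the posterior
predictive check report under results/.
"""

from pathlib import Path

from loombias import lba

SEED = 20240903
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = lba.BehavioralDataset.from_tsv(OUT / "behavior_motion.tsv")
    chains = lba.de_mcmc_fit(
        data, n_chains=8, n_iter=2000, n_burn=1000, thin=5, seed=SEED
    )
    chains.save(OUT / "lba_chains.npz")
    diag = lba.gelman_rubin_report(chains)
    diag.to_csv(OUT / "gelman_rubin.tsv", sep="\t", index=False)
    print(f"max group-level R-hat: {diag['rhat'].max():.3f}")
    ppc = lba.posterior_predictive_check(
        chains, data, draws_per_chain=10, seed=SEED + 1
    )
    ppc.to_csv(OUT / "ppc.tsv", sep="\t", index=False)
    rt = ppc[ppc.statistic == "rt_quartile_coverage"]
    ok = ((rt.ci_lo <= 0.5) & (rt.ci_hi >= 0.5)).sum()
    print(f"RT quartile-coverage CrIs containing 0.5: {ok}/{len(rt)}")


if __name__ == "__main__":
    main()
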