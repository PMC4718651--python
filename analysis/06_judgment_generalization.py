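#!/usr/bin/env python
"""Observed vs predicted probability judgments (generalisation test).

Simulates an urn cohort that overweights private information
(beta_soc = 0.78 < 1), fits the influence model to its *choices only*,
and predicts mean probability judgments per posterior level from the
fitted group medians.  Finding: the choice-fitted model reproduces the
compression of judgments — above 0.50 at the indifference level, below
the normative value at the 0.89 level — without ever seeing a judgment.
Writes results/judgment_generalization.csv and a comparison figure.
"""

from pathlib import Path

from socialcascade.fitting import ChainConfig, fit_cohort, pool_group
from socialcascade.influence import InfluenceParams
from socialcascade.report import judgment_comparison
from socialcascade.scenarios import load_scenarios
from socialcascade.simulate import CohortSpec, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    design = load_scenarios("study1", with_mirrors=True)
    truth = InfluenceParams(beta_bias=-0.12, beta_soc=0.78, theta=6.08)
    records, _ = simulate_cohort(
        CohortSpec(design=design, n_participants=40, params=truth,
                   repeats=2, seed=seed)
    )
    group = pool_group(fit_cohort(records, design, config=ChainConfig.desk(seed=seed)))
    fitted = InfluenceParams(
        beta_bias=group.medians["beta_bias"],
        beta_soc=group.medians["beta_soc"],
        theta=group.medians["theta"],
    )
    table = judgment_comparison(records, fitted, design)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "judgment_generalization.csv", index=False, float_format="%.6g")
    print(table.to_string(index=False))

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(table.posterior_level, table.observed_mean_judgment, "o-", label="observed")
    ax.plot(table.posterior_level, table.predicted_mean_judgment, "s-", label="predicted")
    ax.plot([0.5, 0.9], [0.5, 0.9], "k--", lw=0.8, label="normative")
    ax.set_xlabel("normative posterior level")
    ax.set_ylabel("mean probability judgment")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "judgment_generalization.png", dpi=150)
    print(f"figure -> {OUT / 'judgment_generalization.png'}")


if __name__ == "__main__":
    main()
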