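"""Descriptive and inferential result surfaces of the cascade analyses.

Scenario groups are derived, never hand-assigned: the normative posterior
level (0.50 / 0.67 / 0.80 / 0.89) comes from the scenario engine, and the
authority condition from whether a higher-ranked (HR) predecessor is
present and whether their decision matches the option favoured by the
focal private signal (baseline / md_supports / md_opposes).

Aggregates are unweighted means over scenario-level proportions, which is
how the published tables summarise them.  The inferential layer is
deliberately standard: Wilcoxon signed-rank tests on per-participant
choice proportions and paired t tests on mean judgments.  Because the
per-participant condition means are coarse (averages of three to seven
binary trials), the asymptotic normal p-value of the signed-rank test is
anticonservative here; p-values are therefore computed from the exact
sign-flip permutation null of the signed-rank statistic (zeros ranked but
contributing nothing, Pratt-style), while the z statistic of the normal
approximation is still reported for comparability with published values.
"""

from __future__ import annotations

import io
import zlib
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from socialcascade.influence import InfluenceParams, predict
from socialcascade.scenarios import DecisionScenario, scenario_posterior

_LEVELS = (0.50, 0.67, 0.80, 0.89)

_OBSERVED_FILES = {"study1": "study1_observed.csv", "study2": "study2_observed.csv"}


def load_observed(study: str) -> pd.DataFrame:
    """Published per-scenario outcome columns (choice %, mean judgment)."""
    if study not in _OBSERVED_FILES:
        raise ValueError(f"unknown study {study!r}")
    text = resources.files("socialcascade.data").joinpath(_OBSERVED_FILES[study]).read_text()
    return pd.read_csv(io.StringIO(text))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_scenarios(scenarios: Sequence[DecisionScenario]) -> pd.DataFrame:
    """Scenario group labels derived from the normative engine.

    Columns: posterior of A, posterior level (of the favoured option),
    favoured option ('none' at indifference), whether the private signal
    backs the favoured option, and the authority condition.
    """
    rows = []
    for s in scenarios:
        post_a = scenario_posterior(s)
        level = round(max(post_a, 1.0 - post_a), 2)
        if abs(post_a - 0.5) < 1e-9:
            favored = "none"
        else:
            favored = "A" if post_a > 0.5 else "B"
        private_option = "A" if s.private_signal == "a" else "B"
        hr_decisions = {d for d, r in s.predecessors if r == "HR"}
        if not hr_decisions:
            condition = "baseline"
        elif hr_decisions == {private_option}:
            condition = "md_supports"
        elif private_option not in hr_decisions and len(hr_decisions) == 1:
            condition = "md_opposes"
        else:
            condition = "mixed"
        rows.append(
            {
                "scenario_id": s.scenario_id,
                "study": s.study,
                "posterior_A": post_a,
                "posterior_level": level,
                "favored": favored,
                "private_option": private_option,
                "private_favored": favored == private_option,
                "condition": condition,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# choice aggregates
# ---------------------------------------------------------------------------


def _consistency(records: pd.DataFrame, classes: pd.DataFrame, rule: str) -> pd.Series:
    merged = records.merge(classes, on="scenario_id", how="left", validate="m:1")
    if merged["posterior_A"].isna().any():
        bad = sorted(set(merged.loc[merged["posterior_A"].isna(), "scenario_id"]))
        raise ValueError(f"records reference unknown scenarios: {bad}")
    if rule == "bayes_consistent":
        if (merged["favored"] == "none").any():
            raise ValueError(
                "bayes_consistent is undefined for indifference (0.50) scenarios"
            )
        return merged["choice"] == merged["favored"]
    if rule == "private_consistent":
        return merged["choice"] == merged["private_option"]
    raise ValueError(f"unknown rule {rule!r}")


def aggregate_choices(
    records: pd.DataFrame,
    scenarios: Sequence[DecisionScenario],
    rule: str = "bayes_consistent",
) -> tuple[pd.DataFrame, float]:
    """Per-scenario consistency proportions and their unweighted mean.

    ``rule`` is ``bayes_consistent`` (choice matches the Bayesian-favoured
    option; undefined for 0.50 scenarios) or ``private_consistent``.
    """
    classes = classify_scenarios(scenarios)
    work = records.copy()
    work["consistent"] = _consistency(records, classes, rule)
    per_scenario = (
        work.groupby("scenario_id", sort=False)["consistent"].mean().rename("proportion")
    ).reset_index()
    return per_scenario, float(per_scenario["proportion"].mean())


def printed_aggregates(study: str) -> dict[str, float]:
    """Recompute the published aggregate percentages from table cells.

    Unweighted means of the printed per-scenario proportions, grouped by
    derived scenario class:

    * ``bayes_all`` — all scenarios with a favoured option;
    * ``bayes_private_favored`` — those where the favoured option matches
      the private signal;
    * ``cascade`` — those where it opposes the private signal (cascade
      scenarios);
    * ``indifference_private`` — 0.50 scenarios, proportion of choices
      following the private signal.
    """
    from socialcascade.scenarios import load_scenarios

    observed = load_observed(study)
    classes = classify_scenarios(load_scenarios(study))
    df = observed.merge(classes, on="scenario_id", validate="1:1")
    nonhalf = df[df["favored"] != "none"]
    out = {
        "bayes_all": float(nonhalf["pct_choices"].mean()),
        "bayes_private_favored": float(
            nonhalf.loc[nonhalf["private_favored"], "pct_choices"].mean()
        ),
        "cascade": float(nonhalf.loc[~nonhalf["private_favored"], "pct_choices"].mean()),
        "indifference_private": float(
            df.loc[df["favored"] == "none", "pct_choices"].mean()
        ),
    }
    return out


# ---------------------------------------------------------------------------
# authority contrasts
# ---------------------------------------------------------------------------


def _participant_condition_means(
    records: pd.DataFrame, classes: pd.DataFrame, level: float
) -> pd.DataFrame:
    merged = records.merge(classes, on="scenario_id", validate="m:1")
    sub = merged[np.isclose(merged["posterior_level"], level)]
    sub = sub.assign(private_consistent=(sub["choice"] == sub["private_option"]))
    return (
        sub.groupby(["participant_id", "condition"])
        .agg(prop_private=("private_consistent", "mean"), mean_judgment=("judgment", "mean"))
        .reset_index()
    )


def signed_rank_permutation_p(diffs: np.ndarray, n_resamples: int = 4000) -> float:
    """Sign-flip permutation p-value of the signed-rank statistic.

    Exact-level under the symmetric null even with heavy ties and zeros
    (zeros are ranked but contribute nothing).  The resampling seed is
    derived from the data, so the result is deterministic.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0 or np.allclose(d, 0.0):
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    contrib = np.where(d == 0.0, 0.0, ranks)
    observed = float(np.sum(np.sign(d) * ranks))
    rng = np.random.default_rng(zlib.crc32(d.tobytes()))
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, d.size))
    null = signs @ contrib
    hits = int(np.sum(np.abs(null) >= abs(observed) - 1e-9))
    return (hits + 1) / (n_resamples + 1)


def authority_tests(
    records: pd.DataFrame,
    scenarios: Sequence[DecisionScenario],
    alpha: float = 0.05,
    levels: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Baseline-vs-MD condition tests within each posterior level.

    Per participant, condition means are computed first; then paired
    Wilcoxon signed-rank tests (choice proportions; sign-flip permutation
    p-value, z statistic from the normal approximation) and paired t
    tests (judgments) compare md_supports and md_opposes against
    baseline.  Degenerate all-zero differences are flagged undefined.
    """
    if records["participant_id"].nunique() < 2:
        raise ValueError("authority tests need at least 2 participants")
    classes = classify_scenarios(scenarios)
    rows = []
    for level in (levels if levels is not None else _LEVELS):
        if not np.isclose(classes["posterior_level"], level).any():
            continue
        means = _participant_condition_means(records, classes, level)
        wide_p = means.pivot(index="participant_id", columns="condition", values="prop_private")
        wide_j = means.pivot(index="participant_id", columns="condition", values="mean_judgment")
        for cond in ("md_supports", "md_opposes"):
            if cond not in wide_p.columns or "baseline" not in wide_p.columns:
                continue
            dp = (wide_p[cond] - wide_p["baseline"]).dropna()
            dj = (wide_j[cond] - wide_j["baseline"]).dropna()
            row = {
                "posterior_level": level,
                "comparison": f"{cond}_vs_baseline",
                "n": int(len(dp)),
                "mean_diff_prop": float(dp.mean()),
                "mean_diff_judgment": float(dj.mean()),
            }
            if np.allclose(dp, 0.0):
                row.update(wilcoxon_z=0.0, wilcoxon_p=1.0, wilcoxon_defined=False)
            else:
                res = stats.wilcoxon(dp[dp != 0], method="approx")
                row.update(
                    wilcoxon_z=float(res.zstatistic),
                    wilcoxon_p=signed_rank_permutation_p(dp.to_numpy()),
                    wilcoxon_defined=True,
                )
            if len(dj) < 2 or float(dj.std(ddof=0)) == 0.0:
                row.update(t_stat=np.nan, t_p=np.nan, t_defined=False)
            else:
                t = stats.ttest_rel(wide_j[cond].dropna(), wide_j["baseline"].dropna())
                row.update(t_stat=float(t.statistic), t_p=float(t.pvalue), t_defined=True)
            row["significant"] = bool(row["wilcoxon_p"] < alpha) if row["wilcoxon_defined"] else False
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# observed vs predicted judgments (generalisation test)
# ---------------------------------------------------------------------------


def judgment_comparison(
    records: pd.DataFrame,
    params: InfluenceParams,
    scenarios: Sequence[DecisionScenario],
    judgment_rule: str = "expected",
) -> pd.DataFrame:
    """Observed vs model-predicted mean judgments per posterior level.

    Predictions come from the influence model under choice-fitted
    parameters; the observed judgment column is never consulted when
    producing them.
    """
    classes = classify_scenarios(scenarios)
    by_id = {s.scenario_id: s for s in scenarios}
    classes["predicted_judgment"] = [
        predict(by_id[sid], params, judgment_rule=judgment_rule).predicted_judgment
        for sid in classes["scenario_id"]
    ]
    merged = records.merge(classes, on="scenario_id", validate="m:1")
    obs = merged.groupby("posterior_level")["judgment"].mean()
    pred = classes.groupby("posterior_level")["predicted_judgment"].mean()
    out = pd.DataFrame(
        {"observed_mean_judgment": obs, "predicted_mean_judgment": pred}
    ).reset_index()
    return out
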