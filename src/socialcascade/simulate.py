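"""Synthetic participant cohorts with known influence parameters.

Each synthetic participant answers a fixed list of scenarios (as in the
questionnaire designs packaged with this project): choices are Bernoulli
draws from the influence model's choice rule, and probability judgments
are the subjective posterior of the drawn choice plus truncated Gaussian
noise on the probability scale, clamped to the 50-100% response scale.

Defaults emulate the published cohorts: 40 participants on the packaged
designs, with mean parameters at the group medians estimated from the
urn experiment (beta_bias = -0.12, beta_soc = 0.78, theta = 6.08) and
modest between-participant heterogeneity.  Fixed-parameter cohorts (every
participant at the same truth) are used for parameter-recovery work.

Reproducibility: one master seed; per-participant generators are spawned
from it deterministically, so enlarging a cohort never reshuffles the
records of existing participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from socialcascade.influence import (
    BETA_RANGE,
    BIAS_RANGE,
    THETA_RANGE,
    InfluenceParams,
    batch_log_odds,
    evidence_matrix,
)
from socialcascade.scenarios import DecisionScenario, validate_scenario

_PARAM_BOUNDS = {
    "beta_bias": BIAS_RANGE,
    "beta_soc": BETA_RANGE,
    "beta_HR": BETA_RANGE,
    "beta_ER": BETA_RANGE,
    "theta": THETA_RANGE,
}

_FORM_PARAMS = {
    "study1": ("beta_bias", "beta_soc", "theta"),
    "study2": ("beta_bias", "beta_HR", "beta_ER", "theta"),
}

#: group medians from the urn experiment; default generator means
DEFAULT_MEANS = {
    "study1": {"beta_bias": -0.12, "beta_soc": 0.78, "theta": 6.08},
    "study2": {"beta_bias": 0.06, "beta_HR": 1.12, "beta_ER": 0.85, "theta": 7.37},
}

#: default between-participant sd (log-odds weights; theta on its own scale)
DEFAULT_SDS = {
    "beta_bias": 0.1,
    "beta_soc": 0.15,
    "beta_HR": 0.15,
    "beta_ER": 0.15,
    "theta": 1.0,
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    ``params`` is either a fixed :class:`InfluenceParams` (every
    participant identical) or a mapping parameter -> (mean, sd) of
    truncated Gaussians; ``None`` selects the default heterogeneous
    population for ``form``.
    """

    design: Sequence[DecisionScenario]
    n_participants: int = 40
    form: str = "study1"
    params: InfluenceParams | Mapping[str, tuple[float, float]] | None = None
    judgment_noise_sd: float = 0.05
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.judgment_noise_sd < 0:
            raise ValueError("judgment_noise_sd must be non-negative")
        if self.repeats <= 0:
            raise ValueError("repeats must be positive")
        if self.form not in _FORM_PARAMS:
            raise ValueError(f"unknown model form {self.form!r}")
        for s in self.design:
            v = validate_scenario(s)
            if not v.valid:
                raise ValueError(f"invalid design scenario {s.scenario_id}: {v.reason}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if not lo <= mean <= hi:
        raise ValueError(f"mean {mean} outside legal range ({lo}, {hi})")
    if sd == 0.0:
        return mean
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampler failed to accept")


def _draw_params(rng: np.random.Generator, spec: CohortSpec) -> dict[str, float]:
    names = _FORM_PARAMS[spec.form]
    if isinstance(spec.params, InfluenceParams):
        if spec.params.form != spec.form:
            raise ValueError("params.form does not match cohort form")
        return {name: getattr(spec.params, name) for name in names}
    dists = dict(spec.params) if spec.params is not None else {
        name: (DEFAULT_MEANS[spec.form][name], DEFAULT_SDS[name]) for name in names
    }
    unknown = set(dists) - set(names)
    if unknown:
        raise ValueError(f"parameters {sorted(unknown)} not part of form {spec.form!r}")
    out = {}
    for name in names:
        mean, sd = dists[name]
        lo, hi = _PARAM_BOUNDS[name]
        out[name] = _truncated_normal(rng, mean, sd, lo, hi)
    return out


def _param_vector(params: dict[str, float], form: str) -> np.ndarray:
    return np.array([params[name] for name in _FORM_PARAMS[form]], dtype=float)


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (records, truth).

    ``records`` has one row per participant x trial with columns
    ``participant_id, scenario_id, choice, judgment``; ``truth`` holds
    each participant's generating parameters.
    """
    design = list(spec.design) * spec.repeats
    X = evidence_matrix(design, form=spec.form)
    theta_idx = len(_FORM_PARAMS[spec.form]) - 1
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_participants)

    rec_rows: list[dict] = []
    truth_rows: list[dict] = []
    for p_idx, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        pid = f"p{p_idx + 1:04d}"
        params = _draw_params(rng, spec)
        vec = _param_vector(params, spec.form)
        l = batch_log_odds(vec, X, form=spec.form)
        p_subj = 1.0 / (1.0 + np.exp(-l))
        # choice rule: logistic in the subjective posterior difference
        pc_a = 1.0 / (1.0 + np.exp(vec[theta_idx] * ((1.0 - p_subj) - p_subj)))
        chose_a = rng.random(len(design)) < pc_a
        base = np.where(chose_a, p_subj, 1.0 - p_subj)
        noise = rng.normal(0.0, spec.judgment_noise_sd, len(design)) if spec.judgment_noise_sd > 0 else 0.0
        judgment = np.clip(base + noise, 0.5, 1.0)
        for t, scenario in enumerate(design):
            rec_rows.append(
                {
                    "participant_id": pid,
                    "scenario_id": scenario.scenario_id,
                    "choice": "A" if chose_a[t] else "B",
                    "judgment": float(judgment[t]) if np.ndim(judgment) else float(judgment),
                }
            )
        truth_rows.append({"participant_id": pid, **params})

    records = pd.DataFrame(rec_rows)
    truth = pd.DataFrame(truth_rows)
    return records, truth


def simulate_bayesian_cohort(
    n: int,
    design: Sequence[DecisionScenario],
    theta: float,
    seed: int = 0,
    form: str = "study1",
    judgment_noise_sd: float = 0.05,
    repeats: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort at the Bayesian point (equal weights, zero bias).

    Convenience wrapper used for model-recovery null checks.
    """
    spec = CohortSpec(
        design=design,
        n_participants=n,
        form=form,
        params=InfluenceParams.bayesian(theta=theta, form=form),
        judgment_noise_sd=judgment_noise_sd,
        repeats=repeats,
        seed=seed,
    )
    return simulate_cohort(spec)


def write_cohort(records: pd.DataFrame, truth: pd.DataFrame, records_path, truth_path) -> None:
    """Write records/truth CSVs with stable formatting."""
    records.to_csv(records_path, index=False, float_format="%.6g", lineterminator="\n")
    truth.to_csv(truth_path, index=False, float_format="%.6g", lineterminator="\n")
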