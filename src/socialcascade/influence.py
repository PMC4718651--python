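"""The social influence model: differential weighting of evidence sources.

The normative observer adds the log-likelihood ratios ``f(x)`` of all
signals with equal weight.  The social influence model relaxes this by
re-weighting the sources while conserving total weight:

* two-source form (``study1``): subjective log odds
  ``beta_bias + beta_soc * sum_public f(x) + (2 - beta_soc) * sum_private f(x)``
  with ``beta_soc`` in (0, 2).  ``beta_soc > 1`` means social information
  is overweighted, ``beta_soc < 1`` that private information is.
* three-source form (``study2``): the public component is split by the
  source's hierarchical rank,
  ``beta_bias + beta_HR * sum_HR f(x) + beta_ER * sum_ER f(x)
  + (3 - beta_HR - beta_ER) * sum_private f(x)``,
  separating authority (higher-ranked, HR) from peer (equally ranked, ER)
  influence.

At ``beta_soc = 1`` (resp. ``beta_HR = beta_ER = 1``) and ``beta_bias = 0``
both forms reduce to the Bayesian solution.  Choices follow a logistic
response rule on the subjective posterior difference with sensitivity
``theta``: ``p(choose A) = 1 / (1 + exp(theta * (p_B - p_A)))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from socialcascade.scenarios import (
    DecisionScenario,
    LikelihoodSpec,
    SignalLedger,
    infer_public_signals,
)

#: log-odds are clipped here before exponentiation
LOG_ODDS_CLIP = 50.0

THETA_RANGE = (0.0, 10.0)
BETA_RANGE = (0.0, 2.0)
BIAS_RANGE = (-1.0, 1.0)


@dataclass(frozen=True)
class InfluenceParams:
    """Free parameters of the social influence model.

    ``form`` selects the two-source (``"study1"``: ``beta_soc``) or
    three-source (``"study2"``: ``beta_HR``, ``beta_ER``) weighting;
    ``theta`` is the choice sensitivity.  The Bayesian observer is the
    special case ``bayesian(theta)``.
    """

    beta_bias: float = 0.0
    beta_soc: float | None = None
    beta_HR: float | None = None
    beta_ER: float | None = None
    theta: float = 5.0
    form: str = "study1"

    def __post_init__(self) -> None:
        if self.form not in ("study1", "study2"):
            raise ValueError(f"unknown model form {self.form!r}")
        if self.form == "study1":
            if self.beta_soc is None:
                raise ValueError("study1 form requires beta_soc")
            if not BETA_RANGE[0] < self.beta_soc < BETA_RANGE[1]:
                raise ValueError(f"beta_soc must be in (0, 2), got {self.beta_soc}")
        else:
            if self.beta_HR is None or self.beta_ER is None:
                raise ValueError("study2 form requires beta_HR and beta_ER")
            for name, b in (("beta_HR", self.beta_HR), ("beta_ER", self.beta_ER)):
                if not BETA_RANGE[0] < b < BETA_RANGE[1]:
                    raise ValueError(f"{name} must be in (0, 2), got {b}")
        if not THETA_RANGE[0] < self.theta < THETA_RANGE[1]:
            raise ValueError(f"theta must be in (0, 10), got {self.theta}")

    @property
    def private_weight(self) -> float:
        """Weight on private signals (total weight is conserved)."""
        if self.form == "study1":
            return 2.0 - self.beta_soc
        return 3.0 - self.beta_HR - self.beta_ER

    @classmethod
    def bayesian(cls, theta: float = 5.0, form: str = "study1") -> "InfluenceParams":
        """Parameters at which the model equals the Bayesian solution."""
        if form == "study1":
            return cls(beta_bias=0.0, beta_soc=1.0, theta=theta, form=form)
        return cls(beta_bias=0.0, beta_HR=1.0, beta_ER=1.0, theta=theta, form=form)


@dataclass(frozen=True)
class ModelPrediction:
    """Model outputs for one scenario."""

    subjective_log_odds: float
    subjective_posterior_A: float
    choice_prob_A: float
    predicted_judgment: float


def weighted_log_odds(
    ledger: SignalLedger, params: InfluenceParams, spec: LikelihoodSpec
) -> float:
    """Subjective log odds of A under the influence model (clipped)."""
    sum_private = sum(spec.f(s) for s in ledger.private_signals)
    if params.form == "study1":
        sum_public = sum(spec.f(s) for s, _ in ledger.public_signals)
        l = (
            params.beta_bias
            + params.beta_soc * sum_public
            + (2.0 - params.beta_soc) * sum_private
        )
    else:
        sum_hr = sum(spec.f(s) for s, r in ledger.public_signals if r == "HR")
        sum_er = sum(spec.f(s) for s, r in ledger.public_signals if r == "EQ")
        l = (
            params.beta_bias
            + params.beta_HR * sum_hr
            + params.beta_ER * sum_er
            + (3.0 - params.beta_HR - params.beta_ER) * sum_private
        )
    return float(np.clip(l, -LOG_ODDS_CLIP, LOG_ODDS_CLIP))


def choice_probability(posterior_A: float, posterior_B: float, theta: float) -> float:
    """Logistic choice rule on the posterior difference.

    ``1 / (1 + exp(theta * (p_B - p_A)))``; complementary in the two
    options and strictly increasing in ``p_A`` for ``theta > 0``.
    """
    if not math.isclose(posterior_A + posterior_B, 1.0, abs_tol=1e-9):
        raise ValueError("posterior_A and posterior_B must sum to 1")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return float(1.0 / (1.0 + np.exp(np.clip(theta * (posterior_B - posterior_A), -LOG_ODDS_CLIP, LOG_ODDS_CLIP))))


def predicted_judgment_from(
    posterior_A: float, choice_prob_A: float, rule: str = "expected"
) -> float:
    """Model-predicted probability judgment (confidence in the choice).

    A respondent who chose option X reports the subjective posterior of
    X.  Because the model is probabilistic about the choice itself, the
    scenario-level prediction averages over the choice distribution
    (``rule="expected"``), matching how observed judgments are averaged
    over participants who chose either side.  ``rule="argmax"`` instead
    reports the subjective posterior of the modal choice.  Either way the
    result is clamped to the response scale [0.5, 1].
    """
    if rule == "expected":
        j = choice_prob_A * posterior_A + (1.0 - choice_prob_A) * (1.0 - posterior_A)
    elif rule == "argmax":
        j = posterior_A if choice_prob_A >= 0.5 else 1.0 - posterior_A
    else:
        raise ValueError(f"unknown judgment rule {rule!r}")
    return float(min(1.0, max(0.5, j)))


def predict(
    scenario: DecisionScenario,
    params: InfluenceParams,
    judgment_rule: str = "expected",
) -> ModelPrediction:
    """Full model prediction for one scenario.

    Pipes signal inference -> weighted log odds -> subjective posterior
    -> choice probability -> predicted judgment.
    """
    ledger = infer_public_signals(scenario)
    l = weighted_log_odds(ledger, params, scenario.likelihood)
    p_a = float(1.0 / (1.0 + np.exp(-l)))
    choice_p = choice_probability(p_a, 1.0 - p_a, params.theta)
    judgment = predicted_judgment_from(p_a, choice_p, rule=judgment_rule)
    return ModelPrediction(
        subjective_log_odds=l,
        subjective_posterior_A=p_a,
        choice_prob_A=choice_p,
        predicted_judgment=judgment,
    )


def evidence_matrix(scenarios, form: str = "study1") -> np.ndarray:
    """Per-scenario evidence sums as a dense design matrix.

    Rows follow ``scenarios``; columns are the summed log-likelihood
    ratios entering the weighted log odds: ``[public, private]`` for the
    two-source form and ``[HR, ER, private]`` for the three-source form.
    This is the vectorisation backbone for cohort simulation and the
    MCMC likelihood.
    """
    rows = []
    for s in scenarios:
        ledger = infer_public_signals(s)
        spec = s.likelihood
        sum_priv = sum(spec.f(x) for x in ledger.private_signals)
        if form == "study1":
            sum_pub = sum(spec.f(x) for x, _ in ledger.public_signals)
            rows.append([sum_pub, sum_priv])
        elif form == "study2":
            sum_hr = sum(spec.f(x) for x, r in ledger.public_signals if r == "HR")
            sum_er = sum(spec.f(x) for x, r in ledger.public_signals if r == "EQ")
            rows.append([sum_hr, sum_er, sum_priv])
        else:
            raise ValueError(f"unknown model form {form!r}")
    return np.asarray(rows, dtype=float)


def batch_log_odds(theta_free: np.ndarray, X: np.ndarray, form: str = "study1") -> np.ndarray:
    """Subjective log odds for arrays of parameter vectors.

    ``theta_free`` has trailing dimension ``[beta_bias, beta_soc, theta]``
    (study1) or ``[beta_bias, beta_HR, beta_ER, theta]`` (study2); ``X``
    is an :func:`evidence_matrix`.  Returns an array with shape
    ``theta_free.shape[:-1] + (n_scenarios,)``, clipped to the numerical
    guard range.
    """
    theta_free = np.asarray(theta_free, dtype=float)
    bias = theta_free[..., :1]
    if form == "study1":
        b_soc = theta_free[..., 1:2]
        coef = np.concatenate([b_soc, 2.0 - b_soc], axis=-1)
    elif form == "study2":
        b_hr = theta_free[..., 1:2]
        b_er = theta_free[..., 2:3]
        coef = np.concatenate([b_hr, b_er, 3.0 - b_hr - b_er], axis=-1)
    else:
        raise ValueError(f"unknown model form {form!r}")
    l = bias + coef @ X.T
    return np.clip(l, -LOG_ODDS_CLIP, LOG_ODDS_CLIP)


def batch_choice_prob(theta_free: np.ndarray, X: np.ndarray, form: str = "study1") -> np.ndarray:
    """Choice probabilities for option A under arrays of parameters."""
    from scipy.special import expit as _expit

    l = batch_log_odds(theta_free, X, form=form)
    p_a = _expit(l)
    theta = np.asarray(theta_free, dtype=float)[..., -1:]
    return _expit(theta * (2.0 * p_a - 1.0))


def predictions_frame(scenarios, params, judgment_rule: str = "expected"):
    """Predictions for many scenarios as a DataFrame keyed by scenario_id."""
    import pandas as pd

    rows = []
    for s in scenarios:
        pred = predict(s, params, judgment_rule=judgment_rule)
        rows.append(
            {
                "scenario_id": s.scenario_id,
                "subjective_log_odds": pred.subjective_log_odds,
                "subjective_posterior_A": pred.subjective_posterior_A,
                "choice_prob_A": pred.choice_prob_A,
                "predicted_judgment": pred.predicted_judgment,
            }
        )
    return pd.DataFrame(rows)
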