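"""Bayesian estimation of influence parameters by MCMC.

Each participant is fitted separately: the likelihood is the Bernoulli
probability of their observed choices under the influence model's choice
rule (probability judgments are deliberately *not* part of the
likelihood — predicting them later is a generalisation test), and the
priors are

* ``beta_bias`` — normal(0, sd 10) truncated at -1 and +1 (effectively
  uniform on the truncation interval),
* ``beta_soc`` / ``beta_HR`` / ``beta_ER`` — uniform on (0, 2),
* ``theta`` — uniform on (0, 10).

Sampling uses component-wise adaptive random-walk Metropolis.  Proposal
scales adapt toward a 40% acceptance rate during burn-in only, so the
post-burn-in chain is a valid fixed-kernel Markov chain.  Chains for all
participants and chain replicates advance in lock-step through a single
vectorised likelihood evaluation, which is what makes desk-scale
parameter-recovery studies (hundreds of fits) cheap.

Group-level estimates follow the chain-averaging convention: sample *i*
of the group chain is the mean over participants of their sample *i*;
medians, 95% highest-density intervals and contrasts are then read off
the averaged chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from socialcascade.influence import (
    BETA_RANGE,
    BIAS_RANGE,
    THETA_RANGE,
    InfluenceParams,
    batch_choice_prob,
    evidence_matrix,
)
from socialcascade.scenarios import DecisionScenario

_FORM_PARAMS = {
    "study1": ("beta_bias", "beta_soc", "theta"),
    "study2": ("beta_bias", "beta_HR", "beta_ER", "theta"),
}

RHAT_THRESHOLD = 1.01


class FitError(RuntimeError):
    """Raised for unusable fit configurations or inputs."""


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Prior distributions for one model form.

    ``bias_sd`` is the standard deviation of the (truncated) normal prior
    on ``beta_bias``; with the default of 10 the prior is near-uniform on
    the truncation interval, so the exact value is inconsequential.
    """

    form: str = "study1"
    bias_mean: float = 0.0
    bias_sd: float = 10.0
    bias_bounds: tuple[float, float] = BIAS_RANGE
    beta_bounds: tuple[float, float] = BETA_RANGE
    theta_bounds: tuple[float, float] = THETA_RANGE

    def __post_init__(self) -> None:
        if self.form not in _FORM_PARAMS:
            raise FitError(f"unknown model form {self.form!r}")
        if self.bias_sd <= 0:
            raise FitError("bias_sd must be positive")

    @property
    def param_names(self) -> tuple[str, ...]:
        return _FORM_PARAMS[self.form]

    def _bounds(self) -> list[tuple[float, float]]:
        n_betas = len(self.param_names) - 2
        return [self.bias_bounds] + [self.beta_bounds] * n_betas + [self.theta_bounds]

    def log_prob(self, x: np.ndarray) -> np.ndarray:
        """Unnormalised log prior density for parameter vectors ``x``."""
        x = np.asarray(x, dtype=float)
        lp = np.zeros(x.shape[:-1])
        inside = np.ones(x.shape[:-1], dtype=bool)
        for j, (lo, hi) in enumerate(self._bounds()):
            inside &= (x[..., j] > lo) & (x[..., j] < hi)
        z = (x[..., 0] - self.bias_mean) / self.bias_sd
        lp = -0.5 * z * z
        return np.where(inside, lp, -np.inf)

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        """Draw parameter vectors from the prior (truncation by rejection)."""
        size = tuple(np.atleast_1d(size))
        bounds = self._bounds()
        out = np.empty(size + (len(bounds),))
        lo, hi = bounds[0]
        draws = rng.normal(self.bias_mean, self.bias_sd, size)
        bad = (draws <= lo) | (draws >= hi)
        while bad.any():  # near-uniform: acceptance per draw ~ (hi-lo)/sd terms
            draws[bad] = rng.normal(self.bias_mean, self.bias_sd, int(bad.sum()))
            bad = (draws <= lo) | (draws >= hi)
        out[..., 0] = draws
        for j, (lo, hi) in enumerate(bounds[1:], start=1):
            out[..., j] = rng.uniform(lo, hi, size)
        return out

    def median_vector(self) -> np.ndarray:
        """Analytic prior medians (symmetric truncation => bias median 0)."""
        meds = [self.bias_mean]
        for lo, hi in self._bounds()[1:]:
            meds.append(0.5 * (lo + hi))
        return np.array(meds)


# ---------------------------------------------------------------------------
# chain configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainConfig:
    """MCMC schedule.

    Defaults mirror the published estimation protocol (burn-in 10,000,
    thinning 100, ~50,000 iterations of kept chain mass); the desk-scale
    profile keeps 5,000 samples across 4 chains with a short burn-in and
    is what tests and recovery studies use.
    """

    n_chains: int = 4
    burn_in: int = 10_000
    thin: int = 100
    n_kept: int = 125  # per chain; 4 x 125 x 100 = 50,000 post-burn iterations
    seed: int = 0
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        for name in ("n_chains", "thin", "n_kept"):
            if getattr(self, name) <= 0:
                raise FitError(f"{name} must be positive")
        if self.burn_in < 0:
            raise FitError("burn_in must be non-negative")

    @classmethod
    def desk(cls, seed: int = 0) -> "ChainConfig":
        return cls(n_chains=4, burn_in=500, thin=4, n_kept=1250, seed=seed)

    @property
    def total_iterations(self) -> int:
        return self.burn_in + self.thin * self.n_kept


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval holding ``mass`` of the samples.

    Sorted-window algorithm: over all windows of ``ceil(mass * n)``
    consecutive order statistics, take the shortest.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise FitError(f"hdi needs at least 100 samples, got {n}")
    if not 0.0 < mass < 1.0:
        raise FitError("mass must be in (0, 1)")
    k = int(math.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat convergence diagnostic for one parameter.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    before the classic between/within variance ratio is formed.  Returns
    1.0 for degenerate (zero-variance) samples.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise FitError("split_rhat expects (n_chains, n_draws)")
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    if n < 2 or m < 2:
        raise FitError("too few draws for split_rhat")
    within = halves.var(axis=1, ddof=1).mean()
    if within == 0:
        return 1.0
    between = n * halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


@dataclass(frozen=True)
class PosteriorSummary:
    """Kept samples plus medians, 95% HDIs and convergence diagnostics."""

    param_names: tuple[str, ...]
    samples: Mapping[str, np.ndarray]  # each (n_chains, n_kept)
    medians: Mapping[str, float]
    hdis: Mapping[str, tuple[float, float]]
    rhats: Mapping[str, float]
    converged: bool
    hdi_mass: float = 0.95
    n_records: int = 0
    participant_id: str = ""

    @classmethod
    def from_samples(
        cls,
        samples: Mapping[str, np.ndarray],
        hdi_mass: float = 0.95,
        n_records: int = 0,
        participant_id: str = "",
    ) -> "PosteriorSummary":
        names = tuple(samples)
        medians, hdis, rhats = {}, {}, {}
        for name, chain in samples.items():
            chain = np.asarray(chain, dtype=float)
            medians[name] = float(np.median(chain))
            hdis[name] = hdi(chain, hdi_mass)
            rhats[name] = split_rhat(chain)
        converged = all(r < RHAT_THRESHOLD for r in rhats.values())
        return cls(
            param_names=names,
            samples={k: np.asarray(v, dtype=float) for k, v in samples.items()},
            medians=medians,
            hdis=hdis,
            rhats=rhats,
            converged=converged,
            hdi_mass=hdi_mass,
            n_records=n_records,
            participant_id=participant_id,
        )

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "n_records": self.n_records,
            "converged": self.converged,
            "parameters": {
                name: {
                    "median": self.medians[name],
                    "hdi_low": self.hdis[name][0],
                    "hdi_high": self.hdis[name][1],
                    "rhat": self.rhats[name],
                }
                for name in self.param_names
            },
        }


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _scenario_index(scenarios: Sequence[DecisionScenario]) -> dict[str, int]:
    return {s.scenario_id: i for i, s in enumerate(scenarios)}


def _records_matrix(
    records: pd.DataFrame, scenarios: Sequence[DecisionScenario]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Map a records table to (trial scenario rows X, choice matrix Y).

    Every participant must have answered the same trial list (as in the
    questionnaire designs); Y is (n_participants, n_trials) with 1 for
    option A.
    """
    idx = _scenario_index(scenarios)
    unknown = set(records["scenario_id"]) - set(idx)
    if unknown:
        raise FitError(f"records reference unknown scenarios: {sorted(unknown)}")
    pids = list(dict.fromkeys(records["participant_id"]))
    groups = records.groupby("participant_id", sort=False)
    trial_ids = None
    rows_y = []
    for pid in pids:
        g = groups.get_group(pid)
        ids = list(g["scenario_id"])
        if trial_ids is None:
            trial_ids = ids
        elif ids != trial_ids:
            raise FitError("participants answered different trial lists")
        rows_y.append([1.0 if c == "A" else 0.0 for c in g["choice"]])
    scen_rows = [scenarios[idx[i]] for i in trial_ids]
    return scen_rows, np.asarray(rows_y), pids


def _batched_loglik(
    theta_free: np.ndarray, X: np.ndarray, Y: np.ndarray, form: str
) -> np.ndarray:
    """Bernoulli log likelihood, broadcast over leading parameter axes.

    ``theta_free``: (..., n_participants, k); ``Y``: (n_participants,
    n_trials); returns (..., n_participants).
    """
    pc = batch_choice_prob(theta_free, X, form=form)
    pc = np.clip(pc, 1e-300, 1.0 - 1e-16)
    return (Y * np.log(pc) + (1.0 - Y) * np.log1p(-pc)).sum(axis=-1)


def log_likelihood(
    records: pd.DataFrame,
    params: InfluenceParams,
    scenarios: Sequence[DecisionScenario],
) -> float:
    """Choice log likelihood of one participant's records.

    Judgments are ignored by contract: the model is estimated from
    choices alone.
    """
    if records.empty:
        return 0.0
    idx = _scenario_index(scenarios)
    unknown = set(records["scenario_id"]) - set(idx)
    if unknown:
        raise FitError(f"records reference unknown scenarios: {sorted(unknown)}")
    scen_rows = [scenarios[idx[i]] for i in records["scenario_id"]]
    X = evidence_matrix(scen_rows, form=params.form)
    names = _FORM_PARAMS[params.form]
    vec = np.array([[getattr(params, n) for n in names]])
    y = np.asarray([1.0 if c == "A" else 0.0 for c in records["choice"]])[None, :]
    return float(_batched_loglik(vec, X, y, params.form)[0])


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

_INIT_SCALES = {"beta_bias": 0.08, "beta_soc": 0.12, "beta_HR": 0.12,
                "beta_ER": 0.12, "theta": 0.6}


def _run_metropolis(
    X: np.ndarray,
    Y: np.ndarray,
    prior: PriorSpec,
    config: ChainConfig,
) -> np.ndarray:
    """Component-wise adaptive RWM; returns (n_chains, n_kept, n_part, k)."""
    rng = np.random.default_rng(config.seed)
    n_part = Y.shape[0]
    names = prior.param_names
    k = len(names)
    shape = (config.n_chains, n_part)

    state = prior.sample(rng, shape)  # (chains, part, k)
    lp = prior.log_prob(state) + _batched_loglik(state, X, Y, prior.form)

    scales = np.tile(
        np.array([_INIT_SCALES[n] for n in names]), (config.n_chains, n_part, 1)
    )
    accepts = np.zeros((config.n_chains, n_part, k))
    kept = np.empty((config.n_chains, config.n_kept, n_part, k))
    kept_i = 0

    total = config.total_iterations
    for it in range(total):
        for j in range(k):
            prop = state.copy()
            prop[..., j] += scales[..., j] * rng.standard_normal(shape)
            lp_prop = prior.log_prob(prop) + _batched_loglik(prop, X, Y, prior.form)
            accept = np.log(rng.random(shape)) < lp_prop - lp
            state[accept] = prop[accept]
            lp = np.where(accept, lp_prop, lp)
            accepts[..., j] += accept
        in_burn = it < config.burn_in
        if in_burn and (it + 1) % config.adapt_interval == 0:
            rate = accepts / config.adapt_interval
            scales *= np.exp(1.2 * (rate - 0.40))
            accepts[:] = 0.0
        if not in_burn:
            post = it - config.burn_in
            if (post + 1) % config.thin == 0 and kept_i < config.n_kept:
                kept[:, kept_i] = state
                kept_i += 1
    if kept_i != config.n_kept:
        raise FitError("sampler schedule did not produce the requested draws")
    return kept


def fit_cohort(
    records: pd.DataFrame,
    scenarios: Sequence[DecisionScenario],
    prior: PriorSpec | None = None,
    config: ChainConfig | None = None,
) -> list[PosteriorSummary]:
    """Fit every participant in a records table (vectorised across them).

    All participants must share the same trial list; the sampler advances
    all chains for all participants in lock-step.
    """
    prior = prior or PriorSpec()
    config = config or ChainConfig.desk()
    if records.empty:
        raise FitError("no records to fit")
    scen_rows, Y, pids = _records_matrix(records, scenarios)
    X = evidence_matrix(scen_rows, form=prior.form)
    kept = _run_metropolis(X, Y, prior, config)  # (chains, kept, part, k)
    summaries = []
    for p, pid in enumerate(pids):
        samples = {
            name: kept[:, :, p, j] for j, name in enumerate(prior.param_names)
        }
        summaries.append(
            PosteriorSummary.from_samples(
                samples, n_records=Y.shape[1], participant_id=pid
            )
        )
    return summaries


def fit_participant(
    records: pd.DataFrame,
    scenarios: Sequence[DecisionScenario],
    prior: PriorSpec | None = None,
    config: ChainConfig | None = None,
) -> PosteriorSummary:
    """Fit a single participant; with zero trials the posterior is the prior."""
    prior = prior or PriorSpec()
    config = config or ChainConfig.desk()
    if records.empty:
        X = np.zeros((0, len(prior.param_names) - 1))
        Y = np.zeros((1, 0))
        kept = _run_metropolis(X, Y, prior, config)
        samples = {n: kept[:, :, 0, j] for j, n in enumerate(prior.param_names)}
        return PosteriorSummary.from_samples(samples, n_records=0)
    if records["participant_id"].nunique() > 1:
        raise FitError("fit_participant expects records of a single participant")
    return fit_cohort(records, scenarios, prior, config)[0]


# ---------------------------------------------------------------------------
# pooling and contrasts
# ---------------------------------------------------------------------------


def _common_length(arrays: list[np.ndarray]) -> list[np.ndarray]:
    n = min(a.shape[1] for a in arrays)
    out = []
    for a in arrays:
        if a.shape[1] == n:
            out.append(a)
        else:  # deterministic strided resample to the common length
            idx = np.linspace(0, a.shape[1] - 1, n).round().astype(int)
            out.append(a[:, idx])
    return out


def pool_group(summaries: Sequence[PosteriorSummary]) -> PosteriorSummary:
    """Group-level posterior by element-wise chain averaging.

    Sample *i* of the group chain is the mean over participants of their
    sample *i* (chains aligned by chain index and draw index).  Pooling a
    single summary is the identity; participant order is irrelevant.
    """
    if not summaries:
        raise FitError("pool_group needs at least one summary")
    names = summaries[0].param_names
    for s in summaries:
        if s.param_names != names:
            raise FitError("summaries have mismatched parameters")
    pooled = {}
    for name in names:
        arrays = _common_length([np.asarray(s.samples[name]) for s in summaries])
        pooled[name] = np.mean(arrays, axis=0)
    return PosteriorSummary.from_samples(
        pooled,
        n_records=sum(s.n_records for s in summaries),
        participant_id="group",
    )


_CONTRASTS = {
    "private_minus_public_s1": (
        ("beta_soc",),
        lambda s: (2.0 - s["beta_soc"]) - s["beta_soc"],
    ),
    "HR_minus_ER": (
        ("beta_HR", "beta_ER"),
        lambda s: s["beta_HR"] - s["beta_ER"],
    ),
    "private_minus_ER": (
        ("beta_HR", "beta_ER"),
        lambda s: (3.0 - s["beta_HR"] - s["beta_ER"]) - s["beta_ER"],
    ),
    "private_minus_HR": (
        ("beta_HR", "beta_ER"),
        lambda s: (3.0 - s["beta_HR"] - s["beta_ER"]) - s["beta_HR"],
    ),
    "private_weight_s2": (
        ("beta_HR", "beta_ER"),
        lambda s: 3.0 - s["beta_HR"] - s["beta_ER"],
    ),
}


def contrast(summary: PosteriorSummary, expression: str) -> PosteriorSummary:
    """Posterior of a derived weight difference, sample-wise on the chains."""
    if expression not in _CONTRASTS:
        raise FitError(
            f"unknown contrast {expression!r}; choose from {sorted(_CONTRASTS)}"
        )
    needed, fn = _CONTRASTS[expression]
    missing = [n for n in needed if n not in summary.param_names]
    if missing:
        raise FitError(
            f"contrast {expression!r} needs parameters {missing} absent from this fit"
        )
    derived = fn({n: np.asarray(summary.samples[n]) for n in needed})
    return PosteriorSummary.from_samples(
        {expression: derived},
        n_records=summary.n_records,
        participant_id=summary.participant_id,
    )


def group_summary_frame(summaries: Sequence[PosteriorSummary]) -> pd.DataFrame:
    """Flat table of per-participant medians/HDIs/diagnostics."""
    rows = []
    for s in summaries:
        for name in s.param_names:
            lo, hi = s.hdis[name]
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "parameter": name,
                    "median": s.medians[name],
                    "hdi_low": lo,
                    "hdi_high": hi,
                    "rhat": s.rhats[name],
                    "converged": s.converged,
                }
            )
    return pd.DataFrame(rows)
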