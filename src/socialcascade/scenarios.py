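"""Sequential-decision scenarios and the normative Bayesian observer.

A scenario describes the situation of a focal decision maker at the end of
a short decision sequence: an ordered list of predecessors who each
publicly announced a binary decision (option ``A`` or ``B``), and one
private signal (``a`` or ``b``) observed only by the focal actor.  Signals
are informative but noisy: the option-consistent signal is observed with
probability ``p_signal_given_match`` (2/3 in the urn and clinical designs
packaged here) when that option is the true state.

The key inferential step is reading predecessors' *private signals* off
their *public decisions*.  A rational predecessor chooses the option
favoured by all evidence available to them; their decision therefore
reveals their signal exactly as long as the already-public evidence does
not dominate it.  Running the public evidence count ``net`` (inferred
a-signals minus inferred b-signals) forward through the sequence:

* ``|net| <= 1`` — the decision is *informative*: with balanced evidence a
  rational actor follows their own signal (ties broken by the private
  draw), and with ``|net| == 1`` an opposing signal would swing them to
  indifference and hence to their own signal.  Either way the announced
  option equals the private signal.
* ``|net| >= 2`` — the decision is *uninformative*: the actor is inside an
  information cascade and would announce the majority option under either
  signal.  No signal can be inferred.

Two packaged fixtures, ``"study1"`` (12 urn tasks) and ``"study2"``
(40 clinical scenarios with equal-rank and higher-rank predecessors),
cover every sequence of up to three predecessors that contains no
unreasonable decision.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.special import expit

OPTIONS = ("A", "B")
SIGNALS = ("a", "b")
RANKS = ("EQ", "HR")  # equal-ranked peer / higher-ranked authority

_OTHER_OPTION = {"A": "B", "B": "A"}
_OTHER_SIGNAL = {"a": "b", "b": "a"}
_SIGNAL_FOR_OPTION = {"A": "a", "B": "b"}


class ScenarioError(ValueError):
    """Raised for malformed or invalid scenarios and scenario files."""


@dataclass(frozen=True)
class LikelihoodSpec:
    """Signal reliabilities and option prior of the generating process.

    Parameters
    ----------
    p_signal_given_match:
        Probability of observing the option-consistent signal given that
        option is the true state, i.e. ``p(a|A) = p(b|B)``.  Must differ
        from 0.5, otherwise signals carry no information.
    prior_A:
        A-priori probability that option A is the true state.
    """

    p_signal_given_match: float = 2.0 / 3.0
    prior_A: float = 0.5

    def __post_init__(self) -> None:
        p = self.p_signal_given_match
        if not 0.0 < p < 1.0:
            raise ScenarioError(f"p_signal_given_match must be in (0, 1), got {p}")
        if p == 0.5:
            raise ScenarioError("p_signal_given_match = 0.5 makes signals uninformative")
        if not 0.0 < self.prior_A < 1.0:
            raise ScenarioError(f"prior_A must be in (0, 1), got {self.prior_A}")

    def f(self, signal: str) -> float:
        """Log-likelihood ratio ln p(x|A)/p(x|B) of a single signal."""
        p = self.p_signal_given_match
        if signal == "a":
            return math.log(p / (1.0 - p))
        if signal == "b":
            return math.log((1.0 - p) / p)
        raise ScenarioError(f"unknown signal {signal!r}")

    @property
    def prior_log_odds(self) -> float:
        return math.log(self.prior_A / (1.0 - self.prior_A))


@dataclass(frozen=True)
class DecisionScenario:
    """One focal decision situation within a sequential decision task."""

    scenario_id: str
    predecessors: tuple[tuple[str, str], ...]  # (decision, rank) in order
    private_signal: str
    likelihood: LikelihoodSpec = field(default_factory=LikelihoodSpec)
    study: str = ""

    def __post_init__(self) -> None:
        for i, (decision, rank) in enumerate(self.predecessors, start=1):
            if decision not in OPTIONS:
                raise ScenarioError(
                    f"{self.scenario_id}: predecessor {i} decision {decision!r} "
                    f"not one of {OPTIONS}"
                )
            if rank not in RANKS:
                raise ScenarioError(
                    f"{self.scenario_id}: predecessor {i} rank {rank!r} not one of {RANKS}"
                )
        if self.private_signal not in SIGNALS:
            raise ScenarioError(
                f"{self.scenario_id}: private signal {self.private_signal!r} "
                f"not one of {SIGNALS}"
            )

    @property
    def has_authority(self) -> bool:
        return any(rank == "HR" for _, rank in self.predecessors)


@dataclass(frozen=True)
class SignalLedger:
    """Signals available to the focal actor after observational inference.

    ``public_signals`` are those read off predecessors' decisions, tagged
    with the rank of the source; ``private_signals`` were observed
    directly.  Uninformative (cascade-following) decisions leave no entry.
    """

    public_signals: tuple[tuple[str, str], ...] = ()
    private_signals: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for signal, rank in self.public_signals:
            if signal not in SIGNALS or rank not in RANKS:
                raise ScenarioError(f"bad public ledger entry ({signal!r}, {rank!r})")
        for signal in self.private_signals:
            if signal not in SIGNALS:
                raise ScenarioError(f"bad private ledger entry {signal!r}")

    @property
    def all_signals(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.public_signals) + self.private_signals

    @property
    def n_a(self) -> int:
        return sum(1 for s in self.all_signals if s == "a")

    @property
    def n_b(self) -> int:
        return sum(1 for s in self.all_signals if s == "b")


@dataclass(frozen=True)
class ScenarioValidity:
    valid: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.valid and self.reason:
            raise ScenarioError("valid scenarios carry no reason")
        if not self.valid and not self.reason:
            raise ScenarioError("invalid scenarios must state a reason")


def validate_scenario(scenario: DecisionScenario) -> ScenarioValidity:
    """Check that every predecessor decision is rationally explicable.

    A decision is *unreasonable* when it opposes a public evidence state
    with ``|net| >= 2`` at that position: inside a cascade a rational
    actor announces the majority option under either private signal, so
    the opposing announcement is inconsistent with Bayesian behaviour.
    """
    net = 0
    for i, (decision, _rank) in enumerate(scenario.predecessors, start=1):
        if abs(net) >= 2:
            majority = "A" if net > 0 else "B"
            if decision != majority:
                return ScenarioValidity(
                    valid=False,
                    reason=(
                        f"predecessor {i} decided {decision} against a settled "
                        f"public evidence state (net {net:+d} favouring {majority}); "
                        "no private signal can rationalise this"
                    ),
                )
            # cascade follower: no signal inferred, net unchanged
        else:
            net += 1 if decision == "A" else -1
    return ScenarioValidity(valid=True)


def infer_public_signals(scenario: DecisionScenario) -> SignalLedger:
    """Infer predecessors' private signals from their public decisions.

    Forward-simulates the public evidence state (see module docstring):
    while ``|net| <= 1`` a decision reveals the matching signal, which is
    appended with the rank of its source; once ``|net| >= 2`` decisions
    are cascade-following and contribute nothing.  The focal actor's own
    signal is appended to the private side of the ledger.
    """
    validity = validate_scenario(scenario)
    if not validity.valid:
        raise ScenarioError(f"{scenario.scenario_id}: {validity.reason}")
    public: list[tuple[str, str]] = []
    net = 0
    for decision, rank in scenario.predecessors:
        if abs(net) <= 1:
            signal = _SIGNAL_FOR_OPTION[decision]
            public.append((signal, rank))
            net += 1 if signal == "a" else -1
        # else: uninformative, skip
    return SignalLedger(
        public_signals=tuple(public), private_signals=(scenario.private_signal,)
    )


def log_odds(ledger: SignalLedger, spec: LikelihoodSpec) -> float:
    """Natural-log posterior odds of A over B given all ledger signals.

    Sum of per-signal log-likelihood ratios plus the prior log odds (zero
    for the symmetric 0.5 prior used in all packaged designs).  With
    symmetric reliabilities this is ``(n_a - n_b) * ln(p/(1-p))``: only
    the signal difference matters, not the total count.
    """
    return spec.prior_log_odds + sum(spec.f(s) for s in ledger.all_signals)


def posterior_from_log_odds(l: float) -> float:
    """Map log odds of A to the posterior probability of A (logistic)."""
    if not math.isfinite(l):
        raise ScenarioError(f"log odds must be finite, got {l}")
    return float(expit(l))


def bayes_posterior_bruteforce(ledger: SignalLedger, spec: LikelihoodSpec) -> float:
    """Posterior of A by direct likelihood products (Bayes's theorem).

    Independent of the log-odds route; used as its oracle in tests.
    """
    p = spec.p_signal_given_match
    n_a, n_b = ledger.n_a, ledger.n_b
    like_A = p**n_a * (1.0 - p) ** n_b
    like_B = (1.0 - p) ** n_a * p**n_b
    num = like_A * spec.prior_A
    return num / (num + like_B * (1.0 - spec.prior_A))


def scenario_posterior(scenario: DecisionScenario) -> float:
    """Normative posterior probability of option A for a scenario."""
    ledger = infer_public_signals(scenario)
    return posterior_from_log_odds(log_odds(ledger, scenario.likelihood))


def mirror_scenario(scenario: DecisionScenario, id_suffix: str = "m") -> DecisionScenario:
    """Swap the roles of the two options (A<->B, a<->b) everywhere.

    Mirroring is an involution and flips the posterior:
    ``posterior_A(mirror(s)) == 1 - posterior_A(s)`` under a symmetric
    prior.  Mirrored ids toggle the suffix so that mirroring twice
    restores the original id.
    """
    if scenario.scenario_id.endswith(id_suffix):
        new_id = scenario.scenario_id[: -len(id_suffix)]
    else:
        new_id = scenario.scenario_id + id_suffix
    return replace(
        scenario,
        scenario_id=new_id,
        predecessors=tuple(
            (_OTHER_OPTION[d], r) for d, r in scenario.predecessors
        ),
        private_signal=_OTHER_SIGNAL[scenario.private_signal],
    )


# ---------------------------------------------------------------------------
# scenario I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "scenario_id",
    "study",
    "predecessors",
    "private_signal",
    "reliability",
    "prior_A",
]

_FIXTURES = {"study1": "study1_scenarios.csv", "study2": "study2_scenarios.csv"}


def _parse_probability(value, row: int, fieldname: str) -> float:
    # accept decimal floats and exact fractions like "2/3"
    try:
        if isinstance(value, str) and "/" in value:
            return float(Fraction(value))
        return float(value)
    except (ValueError, ZeroDivisionError) as exc:
        raise ScenarioError(f"row {row}: bad {fieldname} value {value!r}") from exc


def _parse_predecessors(token: str, row: int) -> tuple[tuple[str, str], ...]:
    token = "" if token is None else str(token).strip()
    if not token or token.lower() == "nan":
        return ()
    out = []
    for i, item in enumerate(token.split(";"), start=1):
        parts = item.strip().split(":")
        if len(parts) != 2:
            raise ScenarioError(
                f"row {row}: field 'predecessors' token {i} ({item!r}) is not RANK:DECISION"
            )
        rank, decision = parts[0].strip().upper(), parts[1].strip().upper()
        if rank not in RANKS:
            raise ScenarioError(f"row {row}: field 'predecessors' has unknown rank {rank!r}")
        if decision not in OPTIONS:
            raise ScenarioError(
                f"row {row}: field 'predecessors' has unknown decision {decision!r}"
            )
        out.append((decision, rank))
    return tuple(out)


def _scenarios_from_frame(
    df: pd.DataFrame, max_predecessors: int | None = 3
) -> list[DecisionScenario]:
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ScenarioError(f"scenario table is missing columns {missing}")
    scenarios = []
    for idx, rec in enumerate(df.to_dict("records"), start=1):
        predecessors = _parse_predecessors(rec["predecessors"], idx)
        if max_predecessors is not None and len(predecessors) > max_predecessors:
            raise ScenarioError(
                f"row {idx}: field 'predecessors' has {len(predecessors)} entries, "
                f"limit is {max_predecessors} (pass max_predecessors=None to relax)"
            )
        signal = str(rec["private_signal"]).strip().lower()
        if signal not in SIGNALS:
            raise ScenarioError(f"row {idx}: field 'private_signal' value {signal!r} invalid")
        spec = LikelihoodSpec(
            p_signal_given_match=_parse_probability(rec["reliability"], idx, "reliability"),
            prior_A=_parse_probability(rec["prior_A"], idx, "prior_A"),
        )
        scenarios.append(
            DecisionScenario(
                scenario_id=str(rec["scenario_id"]),
                predecessors=predecessors,
                private_signal=signal,
                likelihood=spec,
                study=str(rec["study"]),
            )
        )
    return scenarios


def load_scenarios(
    source: str | Path,
    with_mirrors: bool = False,
    max_predecessors: int | None = 3,
) -> list[DecisionScenario]:
    """Load scenarios from a packaged fixture name or a CSV/JSON file.

    ``source`` may be ``"study1"`` (12 urn tasks), ``"study2"`` (40
    clinical scenarios) or a path.  ``with_mirrors=True`` appends the
    option-swapped presentation of every scenario (the two presentations
    each participant saw of the same task).
    """
    if str(source) in _FIXTURES:
        text = (
            resources.files("socialcascade.data")
            .joinpath(_FIXTURES[str(source)])
            .read_text()
        )
        df = pd.read_csv(io.StringIO(text), dtype=str)
    else:
        path = Path(source)
        if not path.exists():
            raise ScenarioError(f"no such scenario file or fixture: {source}")
        if path.suffix.lower() == ".json":
            payload = json.loads(path.read_text() or "[]")
            df = pd.DataFrame(payload, columns=_CSV_COLUMNS)
        else:
            try:
                df = pd.read_csv(path, dtype=str)
            except pd.errors.EmptyDataError:
                df = pd.DataFrame(columns=_CSV_COLUMNS)
    scenarios = _scenarios_from_frame(df, max_predecessors=max_predecessors)
    if with_mirrors:
        scenarios = scenarios + [mirror_scenario(s) for s in scenarios]
    return scenarios


def scenarios_to_frame(scenarios: Sequence[DecisionScenario]) -> pd.DataFrame:
    rows = []
    for s in scenarios:
        rows.append(
            {
                "scenario_id": s.scenario_id,
                "study": s.study,
                "predecessors": ";".join(f"{r}:{d}" for d, r in s.predecessors),
                "private_signal": s.private_signal,
                "reliability": f"{s.likelihood.p_signal_given_match:.6g}",
                "prior_A": f"{s.likelihood.prior_A:.6g}",
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_scenarios(
    scenarios: Sequence[DecisionScenario], path: str | Path, fmt: str | None = None
) -> None:
    """Write scenarios to CSV or JSON; output is byte-stable for fixed input."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    df = scenarios_to_frame(scenarios)
    if fmt == "json":
        records = [
            {k: row[k] for k in sorted(_CSV_COLUMNS)} for row in df.to_dict("records")
        ]
        path.write_text(json.dumps(records, indent=1, sort_keys=True) + "\n")
    else:
        path.write_text(df.to_csv(index=False, lineterminator="\n"))


def enumerate_ledgers(
    max_signals: int, ranks: Iterable[str] = ("EQ",)
) -> list[SignalLedger]:
    """All ledgers with up to ``max_signals`` signals (public EQ + private).

    Exhaustive-enumeration helper for oracle tests of the two posterior
    code paths.
    """
    ledgers = []
    rank = next(iter(ranks))
    for total in range(max_signals + 1):
        for n_a in range(total + 1):
            n_b = total - n_a
            for n_priv_a in range(n_a + 1):
                for n_priv_b in range(n_b + 1):
                    public = tuple(
                        [("a", rank)] * (n_a - n_priv_a) + [("b", rank)] * (n_b - n_priv_b)
                    )
                    private = tuple(["a"] * n_priv_a + ["b"] * n_priv_b)
                    ledgers.append(SignalLedger(public, private))
    return ledgers
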