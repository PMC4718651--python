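"""Scenario engine: signal inference, normative posteriors, fixtures, I/O."""

import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialcascade.report import load_observed
from socialcascade.scenarios import (
    DecisionScenario,
    LikelihoodSpec,
    ScenarioError,
    SignalLedger,
    bayes_posterior_bruteforce,
    enumerate_ledgers,
    infer_public_signals,
    load_scenarios,
    log_odds,
    mirror_scenario,
    posterior_from_log_odds,
    scenario_posterior,
    validate_scenario,
    write_scenarios,
)

LN2 = math.log(2.0)


def scen(predecessors, private, ranks=None, sid="s", p=2 / 3, prior=0.5):
    ranks = ranks or ["EQ"] * len(predecessors)
    return DecisionScenario(
        scenario_id=sid,
        predecessors=tuple(zip(predecessors, ranks)),
        private_signal=private,
        likelihood=LikelihoodSpec(p_signal_given_match=p, prior_A=prior),
    )


class TestSignalInference:
    def test_worked_example_two_followers(self):
        # two A-decisions reveal two a-signals; the focal b-draw stays private
        ledger = infer_public_signals(scen(["A", "A"], "b"))
        assert ledger.public_signals == (("a", "EQ"), ("a", "EQ"))
        assert ledger.private_signals == ("b",)
        assert (ledger.n_a, ledger.n_b) == (2, 1)

    def test_third_cascading_decision_is_uninformative(self):
        ledger = infer_public_signals(scen(["A", "A", "A"], "b"))
        assert len(ledger.public_signals) == 2
        # posterior identical to the two-predecessor sequence
        assert scenario_posterior(scen(["A", "A", "A"], "b")) == pytest.approx(
            scenario_posterior(scen(["A", "A"], "b"))
        )

    def test_empty_history(self):
        ledger = infer_public_signals(scen([], "a"))
        assert ledger.public_signals == ()
        assert ledger.private_signals == ("a",)

    def test_tie_break_reveals_signal_at_net_zero(self):
        # A, B cancels; the third decision at net 0 follows its own draw
        ledger = infer_public_signals(scen(["A", "B", "A"], "a"))
        assert [s for s, _ in ledger.public_signals] == ["a", "b", "a"]

    def test_ranks_carried_through(self):
        ledger = infer_public_signals(scen(["A", "B"], "b", ranks=["HR", "EQ"]))
        assert ledger.public_signals == (("a", "HR"), ("b", "EQ"))

    @pytest.mark.parametrize("fixture", ["study1", "study2"])
    def test_never_more_public_signals_than_predecessors(self, fixture):
        for s in load_scenarios(fixture):
            ledger = infer_public_signals(s)
            assert len(ledger.public_signals) <= len(s.predecessors)
            assert ledger.private_signals == (s.private_signal,)

    def test_invalid_scenario_rejected_with_index(self):
        with pytest.raises(ScenarioError, match="predecessor 3"):
            infer_public_signals(scen(["A", "A", "B"], "a"))


class TestLogOddsAndPosteriors:
    def test_worked_example_log_odds(self, spec23):
        ledger = SignalLedger((("a", "EQ"), ("a", "EQ")), ("b",))
        assert round(log_odds(ledger, spec23), 2) == 0.69

    def test_balanced_ledger_is_indifferent(self, spec23):
        ledger = SignalLedger((("a", "EQ"), ("b", "EQ")), ())
        assert log_odds(ledger, spec23) == pytest.approx(0.0, abs=1e-12)

    def test_three_one_ledger_against_both_oracles(self, spec23):
        ledger = SignalLedger((("a", "EQ"),) * 3, ("b",))
        l = log_odds(ledger, spec23)
        assert l == pytest.approx(2 * LN2, abs=1e-12)
        # independent route: direct Bayes on likelihood products
        assert posterior_from_log_odds(l) == pytest.approx(
            bayes_posterior_bruteforce(ledger, spec23), abs=1e-12
        )

    @pytest.mark.parametrize(
        "l,expected", [(0.0, 0.50), (LN2, 0.67), (2 * LN2, 0.80), (3 * LN2, 0.89)]
    )
    def test_posterior_levels(self, l, expected):
        assert round(posterior_from_log_odds(l), 2) == expected

    def test_posterior_requires_finite_log_odds(self):
        with pytest.raises(ScenarioError):
            posterior_from_log_odds(float("nan"))

    def test_bruteforce_single_signal_and_empty(self, spec23):
        assert bayes_posterior_bruteforce(
            SignalLedger((), ("a",)), spec23
        ) == pytest.approx(2 / 3)
        assert bayes_posterior_bruteforce(SignalLedger(), spec23) == pytest.approx(0.5)
        skewed = LikelihoodSpec(p_signal_given_match=2 / 3, prior_A=0.3)
        assert bayes_posterior_bruteforce(SignalLedger(), skewed) == pytest.approx(0.3)

    @pytest.mark.parametrize("p", [0.6, 2 / 3, 0.75])
    def test_pipeline_equals_bruteforce_exhaustively(self, p):
        """Log-odds + logistic equals direct Bayes on every ledger <= 5 signals."""
        spec = LikelihoodSpec(p_signal_given_match=p)
        for ledger in enumerate_ledgers(5):
            via_log_odds = posterior_from_log_odds(log_odds(ledger, spec))
            assert via_log_odds == pytest.approx(
                bayes_posterior_bruteforce(ledger, spec), abs=1e-12
            )

    def test_posterior_depends_only_on_signal_difference(self, spec23):
        by_diff = {}
        for ledger in enumerate_ledgers(5):
            by_diff.setdefault(ledger.n_a - ledger.n_b, []).append(
                posterior_from_log_odds(log_odds(ledger, spec23))
            )
        for values in by_diff.values():
            assert max(values) - min(values) < 1e-12

    @given(
        st.integers(0, 4),
        st.integers(0, 4),
        st.floats(0.55, 0.95),
        st.floats(0.05, 0.95),
    )
    @settings(derandomize=True, max_examples=60)
    def test_pipeline_equals_bruteforce_random(self, n_a, n_b, p, prior):
        spec = LikelihoodSpec(p_signal_given_match=p, prior_A=prior)
        ledger = SignalLedger(tuple([("a", "EQ")] * n_a), tuple(["b"] * n_b))
        assert posterior_from_log_odds(log_odds(ledger, spec)) == pytest.approx(
            bayes_posterior_bruteforce(ledger, spec), abs=1e-10
        )


class TestValidation:
    def test_opposing_a_settled_cascade_is_unreasonable(self):
        v = validate_scenario(scen(["A", "A", "B"], "a"))
        assert not v.valid
        assert "predecessor 3" in v.reason

    @pytest.mark.parametrize("preds", [["A", "B"], []])
    def test_reasonable_sequences(self, preds):
        assert validate_scenario(scen(preds, "a")).valid

    def test_validity_reason_contract(self):
        from socialcascade.scenarios import ScenarioValidity

        with pytest.raises(ScenarioError):
            ScenarioValidity(valid=False, reason="")
        with pytest.raises(ScenarioError):
            ScenarioValidity(valid=True, reason="something")


class TestFixtures:
    def test_fixture_sizes(self, study1, study2):
        assert len(study1) == 12
        assert len(study2) == 40
        assert len(load_scenarios("study1", with_mirrors=True)) == 24

    @pytest.mark.parametrize("fixture", ["study1", "study2"])
    def test_all_printed_posteriors_reproduced(self, fixture):
        """Every published posterior level (incl. 0.50 rows) to 2 d.p."""
        observed = load_observed(fixture).set_index("scenario_id")
        for s in load_scenarios(fixture):
            post_a = scenario_posterior(s)
            level = round(max(post_a, 1 - post_a), 2)
            assert level == pytest.approx(observed.loc[s.scenario_id, "printed_posterior"])
            favored = observed.loc[s.scenario_id, "printed_favored"]
            if favored == "none":
                assert post_a == pytest.approx(0.5, abs=1e-9)
            else:
                assert (post_a > 0.5) == (favored == "A")

    def test_all_fixture_scenarios_valid(self, study1, study2):
        assert all(validate_scenario(s).valid for s in study1 + study2)


class TestMirroring:
    def test_definition(self):
        m = mirror_scenario(scen(["A", "A"], "b"))
        assert [d for d, _ in m.predecessors] == ["B", "B"]
        assert m.private_signal == "a"

    def test_involution_and_posterior_flip(self, study1, study2):
        for s in study1 + study2:
            m = mirror_scenario(s)
            assert mirror_scenario(m) == s
            assert scenario_posterior(m) == pytest.approx(
                1.0 - scenario_posterior(s), abs=1e-12
            )


class TestIO:
    @staticmethod
    def _structurally_equal(loaded, original):
        assert [s.scenario_id for s in loaded] == [s.scenario_id for s in original]
        for a, b in zip(loaded, original):
            assert a.predecessors == b.predecessors
            assert a.private_signal == b.private_signal
            # writer keeps 6 significant digits
            assert a.likelihood.p_signal_given_match == pytest.approx(
                b.likelihood.p_signal_given_match, abs=1e-6
            )
            assert a.likelihood.prior_A == pytest.approx(b.likelihood.prior_A, abs=1e-6)

    def test_csv_roundtrip_and_byte_stability(self, study2, tmp_path):
        p1, p2, p3 = (tmp_path / n for n in ("a.csv", "b.csv", "c.csv"))
        write_scenarios(study2, p1)
        write_scenarios(study2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        loaded = load_scenarios(p1)
        self._structurally_equal(loaded, study2)
        # a second write/load cycle is exactly idempotent
        write_scenarios(loaded, p3)
        assert load_scenarios(p3) == loaded

    def test_json_roundtrip(self, study1, tmp_path):
        p = tmp_path / "s.json"
        write_scenarios(study1, p)
        assert json.loads(p.read_text())  # sorted-key JSON payload
        self._structurally_equal(load_scenarios(p), study1)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        assert load_scenarios(p) == []

    def test_schema_violation_names_row_and_field(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "scenario_id,study,predecessors,private_signal,reliability,prior_A\n"
            "x1,t,EQ:A,a,2/3,0.5\n"
            "x2,t,EQ:A;XX:B,a,2/3,0.5\n"
        )
        with pytest.raises(ScenarioError, match="row 2.*predecessors"):
            load_scenarios(p)

    def test_predecessor_limit_relaxable(self, tmp_path):
        p = tmp_path / "long.csv"
        p.write_text(
            "scenario_id,study,predecessors,private_signal,reliability,prior_A\n"
            "x1,t,EQ:A;EQ:A;EQ:A;EQ:A,b,2/3,0.5\n"
        )
        with pytest.raises(ScenarioError, match="row 1"):
            load_scenarios(p)
        assert len(load_scenarios(p, max_predecessors=None)) == 1

    def test_uninformative_spec_rejected(self):
        with pytest.raises(ScenarioError):
            LikelihoodSpec(p_signal_given_match=0.5)
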