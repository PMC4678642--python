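"""Data-model and SBML-qual I/O tests: interval grammar, logic
evaluation against a truth-table oracle, and file round-trips."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qualflux.fixtures import make_random_boolean_network
from qualflux.qualio import (
    And,
    Cmp,
    Interval,
    Lit,
    Not,
    Or,
    QualModelError,
    QualSpecies,
    RegulatoryNetwork,
    Transition,
    apply_transition,
    evaluate_expr,
    format_equivalence_note,
    parse_equivalence_note,
    read_sbml_qual,
    write_sbml_qual,
)
from qualflux.rsa import all_states


class TestInterval:
    def test_openness_and_membership(self):
        iv = Interval(0, 8.8, lower_open=True)
        assert not iv.contains(0)
        assert iv.contains(8.8) and iv.contains(0.001)
        assert not iv.contains(8.81)

    def test_unbounded_upper_is_open(self):
        iv = Interval(0, math.inf, lower_open=True)
        assert iv.upper_open
        assert iv.contains(1e12) and not iv.contains(0)

    def test_invalid_intervals_rejected(self):
        with pytest.raises(QualModelError):
            Interval(5, 3)
        with pytest.raises(QualModelError):
            Interval(2, 2, lower_open=True)


class TestEquivalenceNote:
    def test_basic_grammar(self):
        eqs = parse_equivalence_note("STATE 0:[0,0]\nSTATE 1:]0,+inf[")
        assert eqs[0] == Interval(0, 0)
        assert eqs[1] == Interval(0, math.inf, lower_open=True)

    def test_paren_dialect_and_comments(self):
        eqs = parse_equivalence_note("# thresholds\nSTATE 0 : [0, 0]\nSTATE 1 : (0, 8.8]")
        assert eqs[1].lower_open and not eqs[1].upper_open

    def test_overlap_rejected(self):
        with pytest.raises(QualModelError, match="overlap"):
            parse_equivalence_note("STATE 0:[0,5]\nSTATE 1:[3,9]")

    def test_duplicate_level_rejected(self):
        with pytest.raises(QualModelError, match="duplicate"):
            parse_equivalence_note("STATE 0:[0,1]\nSTATE 0:[2,3]")

    def test_malformed_line_names_line_number(self):
        with pytest.raises(QualModelError, match="line 2"):
            parse_equivalence_note("STATE 0:[0,1]\nSTATE nonsense")

    def test_three_state_partition_of_half_line(self):
        # brute-force membership over a grid: each point belongs to exactly
        # one interval, so the three intervals partition [0, +inf)
        eqs = parse_equivalence_note(
            "STATE 0:[0,0]\nSTATE 1:]0,8.8]\nSTATE 2:]8.8,+inf["
        )
        grid = [0.0, 1e-9, 0.5, 8.79, 8.8, 8.800001, 100.0, 1e9]
        for x in grid:
            assert sum(iv.contains(x) for iv in eqs.values()) == 1

    def test_round_trip_through_formatter(self):
        eqs = parse_equivalence_note("STATE 0:[0,0]\nSTATE 1:]0,0.6]\nSTATE 2:]0.6,+inf[")
        assert parse_equivalence_note(format_equivalence_note(eqs)) == eqs


# --------------------------------------------------------------------------
# Logic expressions


def _oracle_eval(expr, state):
    """Independent evaluator: compile the tree to a Python expression."""
    def src(e):
        if isinstance(e, Lit):
            return repr(e.value)
        if isinstance(e, Cmp):
            return f"(state[{e.species!r}] {e.op} {e.const})"
        if isinstance(e, And):
            return "(" + (" and ".join(src(a) for a in e.args) or "True") + ")"
        if isinstance(e, Or):
            return "(" + (" or ".join(src(a) for a in e.args) or "False") + ")"
        if isinstance(e, Not):
            return f"(not {src(e.arg)})"
        raise AssertionError(e)
    return eval(src(expr), {}, {"state": state})


def _expr_strategy(species):
    leaf = st.one_of(
        st.booleans().map(Lit),
        st.tuples(
            st.sampled_from(species),
            st.sampled_from(["==", "!=", ">=", "<=", ">", "<"]),
            st.integers(0, 1),
        ).map(lambda t: Cmp(*t)),
    )
    return st.recursive(
        leaf,
        lambda children: st.one_of(
            st.tuples(children, children).map(lambda t: And(*t)),
            st.tuples(children, children).map(lambda t: Or(*t)),
            children.map(Not),
        ),
        max_leaves=8,
    )


class TestEvaluateExpr:
    def test_literals(self):
        assert evaluate_expr(Lit(True), {}) is True
        assert evaluate_expr(Lit(False), {}) is False

    def test_catabolite_repression_clause(self):
        expr = And(Cmp("glucose", ">=", 1), Not(Cmp("lactose", ">=", 1)))
        assert evaluate_expr(expr, {"glucose": 1, "lactose": 1}) is False
        assert evaluate_expr(expr, {"glucose": 1, "lactose": 0}) is True

    def test_missing_species_raises(self):
        with pytest.raises(QualModelError, match="glucose"):
            evaluate_expr(Cmp("glucose", ">=", 1), {"lactose": 1})

    @settings(derandomize=True, max_examples=200)
    @given(expr=_expr_strategy(["a", "b", "c", "d"]))
    def test_agrees_with_truth_table_oracle(self, expr):
        # all 2^4 Boolean assignments of the four possible leaves
        for levels in itertools.product((0, 1), repeat=4):
            state = dict(zip(["a", "b", "c", "d"], levels))
            assert evaluate_expr(expr, state) == _oracle_eval(expr, state)


class TestApplyTransition:
    def test_no_terms_gives_default(self):
        t = Transition("x", [], 0)
        assert apply_transition(t, {"x": 1}) == 0

    def test_first_match_wins(self):
        t = Transition("x", [(Cmp("glucose", ">=", 1), 0), (Lit(True), 1)])
        assert apply_transition(t, {"glucose": 1}) == 0
        assert apply_transition(t, {"glucose": 0}) == 1

    @settings(derandomize=True, max_examples=100)
    @given(
        results=st.lists(st.integers(0, 3), min_size=0, max_size=4),
        default=st.integers(0, 3),
        state=st.fixed_dictionaries({"a": st.integers(0, 1), "b": st.integers(0, 1)}),
        conds=st.lists(_expr_strategy(["a", "b"]), min_size=4, max_size=4),
    )
    def test_matches_naive_scan(self, results, default, state, conds):
        terms = list(zip(conds, results))
        t = Transition("x", terms, default)
        # independent naive scan
        expected = default
        for cond, res in terms:
            if _oracle_eval(cond, state):
                expected = res
                break
        assert apply_transition(t, state) == expected


# --------------------------------------------------------------------------
# SBML-qual round trips


def _transition_semantics_equal(a: RegulatoryNetwork, b: RegulatoryNetwork) -> bool:
    if a.n_states() > 2 ** 10:
        raise AssertionError("state space too large for exhaustive comparison")
    for state in all_states(a):
        for sid in a.transitions:
            if apply_transition(a.transitions[sid], state) != apply_transition(
                b.transitions[sid], state
            ):
                return False
    return True


class TestSbmlQualRoundTrip:
    def test_lac_fixture_round_trip(self, lac_pair, tmp_path):
        net = lac_pair.regulatory
        path = tmp_path / "lac.xml"
        write_sbml_qual(net, str(path))
        back = read_sbml_qual(str(path))
        assert set(back.species) == set(net.species)
        for sid in net.species:
            assert back.species[sid].max_level == net.species[sid].max_level
            assert back.species[sid].initial_level == net.species[sid].initial_level
            assert back.species[sid].equivalences == net.species[sid].equivalences
        assert set(back.transitions) == set(net.transitions)
        assert _transition_semantics_equal(net, back)

    def test_species_without_rule_is_constant_input(self, lac_pair, tmp_path):
        path = tmp_path / "lac.xml"
        write_sbml_qual(lac_pair.regulatory, str(path))
        back = read_sbml_qual(str(path))
        assert "M_glc_b" in back.inputs and "M_lcts_b" in back.inputs

    def test_equivalence_note_survives_round_trip(self, tmp_path):
        net = RegulatoryNetwork()
        net.add_species(
            QualSpecies("R1", max_level=1, initial_level=0,
                        equivalences={0: Interval(0, 0),
                                      1: Interval(2, 10)})
        )
        path = tmp_path / "r1.xml"
        write_sbml_qual(net, str(path))
        back = read_sbml_qual(str(path))
        assert back.species["R1"].equivalences[1] == Interval(2, 10)

    def test_empty_network_round_trip(self, tmp_path):
        path = tmp_path / "empty.xml"
        write_sbml_qual(RegulatoryNetwork(), str(path))
        back = read_sbml_qual(str(path))
        assert back.species == {} and back.transitions == {}

    @pytest.mark.parametrize("seed", range(6))
    def test_random_boolean_networks_round_trip(self, seed, tmp_path):
        net = make_random_boolean_network(n=6, k=3, seed=seed)
        path = tmp_path / f"rand{seed}.xml"
        write_sbml_qual(net, str(path))
        back = read_sbml_qual(str(path))
        assert set(back.species) == set(net.species)
        assert _transition_semantics_equal(net, back)

    def test_missing_initial_level_rejected(self, tmp_path):
        text = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:qual="http://www.sbml.org/sbml/level3/version1/qual/version1"
      level="3" version="1" qual:required="true">
  <model id="m">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <qual:listOfQualitativeSpecies>
      <qual:qualitativeSpecies qual:id="A" qual:compartment="c"
          qual:constant="true" qual:maxLevel="1"/>
    </qual:listOfQualitativeSpecies>
  </model>
</sbml>"""
        path = tmp_path / "noinit.xml"
        path.write_text(text)
        with pytest.raises(QualModelError, match="A"):
            read_sbml_qual(str(path))

    def test_unsupported_mathml_rejected(self, tmp_path):
        text = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:qual="http://www.sbml.org/sbml/level3/version1/qual/version1"
      level="3" version="1" qual:required="true">
  <model id="m">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <qual:listOfQualitativeSpecies>
      <qual:qualitativeSpecies qual:id="A" qual:compartment="c"
          qual:constant="false" qual:maxLevel="1" qual:initialLevel="0"/>
    </qual:listOfQualitativeSpecies>
    <qual:listOfTransitions>
      <qual:transition qual:id="t">
        <qual:listOfOutputs>
          <qual:output qual:qualitativeSpecies="A"
              qual:transitionEffect="assignmentLevel"/>
        </qual:listOfOutputs>
        <qual:listOfFunctionTerms>
          <qual:functionTerm qual:resultLevel="1">
            <math xmlns="http://www.w3.org/1998/Math/MathML">
              <apply><gt/>
                <apply><plus/><ci>A</ci><cn type="integer">1</cn></apply>
                <cn type="integer">1</cn>
              </apply>
            </math>
          </qual:functionTerm>
          <qual:defaultTerm qual:resultLevel="0"/>
        </qual:listOfFunctionTerms>
      </qual:transition>
    </qual:listOfTransitions>
  </model>
</sbml>"""
        path = tmp_path / "badmath.xml"
        path.write_text(text)
        with pytest.raises(QualModelError):
            read_sbml_qual(str(path))


class TestNetworkInvariants:
    def test_duplicate_species_rejected(self):
        net = RegulatoryNetwork()
        net.add_species(QualSpecies("A"))
        with pytest.raises(QualModelError):
            net.add_species(QualSpecies("A"))

    def test_transition_to_undeclared_species_rejected(self):
        net = RegulatoryNetwork()
        net.add_species(QualSpecies("A"))
        net.add_transition(Transition("B", [(Lit(True), 1)]))
        with pytest.raises(QualModelError, match="B"):
            net.validate()

    def test_initial_level_out_of_range_rejected(self):
        with pytest.raises(QualModelError):
            QualSpecies("A", max_level=1, initial_level=2)
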