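"""Microcosting engine: annualization, personnel rules, roll-ups, scenarios."""

import io
from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhealthecon import (
    CostItem,
    CostLedger,
    CostModelError,
    ScenarioSpec,
    StaffingRule,
    annualize_item,
    apply_scenario,
    case_manager_hours,
    coordinator_hours,
    personnel_cost,
    read_ledger,
    round_money,
    standard_scenarios,
    summarize,
    write_ledger,
)


def _item(**kw):
    base = dict(
        name="x",
        phase="recurring",
        category="participant",
        unit_cost=Decimal("1"),
        quantity_rule="per_participant_once",
    )
    base.update(kw)
    return CostItem(**base)


class TestAnnualize:
    @pytest.mark.parametrize(
        "kw, n, expected",
        [
            # monthly bus pass, 60 participants
            (
                dict(unit_cost=Decimal("41.25"), quantity_rule="per_participant_per_month"),
                60,
                Decimal("29700"),
            ),
            # phone plan billed per 6 months
            (
                dict(
                    unit_cost=Decimal("210"),
                    quantity_rule="per_participant_per_period",
                    period_months=6,
                ),
                60,
                Decimal("25200"),
            ),
            # one-time supply per participant
            (
                dict(unit_cost=Decimal("149.99"), quantity_rule="per_participant_once"),
                60,
                Decimal("8999.40"),
            ),
            # program rules ignore n
            (
                dict(
                    unit_cost=Decimal("99"),
                    quantity_rule="per_program_per_month",
                    category="program",
                ),
                7,
                Decimal("1188"),
            ),
            (
                dict(
                    unit_cost=Decimal("3588.00"),
                    quantity_rule="per_program_once",
                    category="program",
                    phase="startup",
                ),
                123,
                Decimal("3588.00"),
            ),
            # hourly rules: unit cost × annual hours
            (
                dict(
                    unit_cost=Decimal("32.44"),
                    quantity=Decimal("2500"),
                    quantity_rule="per_program_per_hour",
                    category="personnel",
                ),
                60,
                Decimal("81100.00"),
            ),
            # zero quantity → zero cost
            (dict(quantity=Decimal("0")), 60, Decimal("0")),
        ],
    )
    def test_annualized_cost(self, kw, n, expected):
        assert annualize_item(_item(**kw), n) == expected

    def test_unknown_rule_names_item(self):
        with pytest.raises(CostModelError, match="widget.*quantity rule"):
            _item(name="widget", quantity_rule="per_decade")

    def test_per_participant_rule_requires_participants(self):
        with pytest.raises(CostModelError, match="n_participants"):
            annualize_item(_item(), 0)

    def test_period_rule_requires_period(self):
        with pytest.raises(CostModelError, match="period_months"):
            _item(quantity_rule="per_participant_per_period")


class TestPersonnel:
    @pytest.mark.parametrize(
        "n, weeks, expected",
        [(60, 52, 224), (0, 0, 0), (10, 52, 124)],
    )
    def test_coordinator_hours(self, n, weeks, expected):
        # 1 h setup + 1 h training per participant + 2 h/week maintenance
        assert coordinator_hours(n, weeks) == expected

    def test_case_manager_trial_staffing(self):
        # the observed trial staffing total overrides the caseload rule at n=60
        assert case_manager_hours(60) == 2500
        assert case_manager_hours(60, trial_override=False) == 2600
        # pure rule: 20 h/wk per 24 participants
        assert case_manager_hours(24, trial_override=False) == 20 * 52

    def test_case_manager_salary(self):
        rule = StaffingRule("case_manager", Decimal("32.44"))
        assert personnel_cost(rule, 60) == Decimal("81100.00")

    def test_coordinator_salary(self):
        rule = StaffingRule("program_coordinator", Decimal("17"))
        assert personnel_cost(rule, 60) == Decimal("3808")

    def test_coordinator_zero_participants_zero_weeks(self):
        rule = StaffingRule("program_coordinator", Decimal("17"), weeks_per_year=0)
        assert personnel_cost(rule, 0) == 0

    def test_negative_wage_rejected(self):
        with pytest.raises(CostModelError, match="wage"):
            StaffingRule("case_manager", Decimal("-1"))


class TestSummarize:
    def test_reproduces_startup_table(self, trial_ledger):
        s = summarize(trial_ledger)
        assert s.startup_total == Decimal("15924.59")
        assert round_money(s.startup_pppy) == Decimal("265.41")
        assert s.by_category[("startup", "participant")] == Decimal("11718.00")
        assert s.by_category[("startup", "program")] == Decimal("4206.59")

    def test_reproduces_recurring_table(self, trial_ledger):
        s = summarize(trial_ledger)
        assert s.recurring_total == Decimal("155996.00")
        assert s.by_category[("recurring", "participant")] == Decimal("54900.00")
        assert s.by_category[("recurring", "program")] == Decimal("16188")
        assert s.by_category[("recurring", "personnel")] == Decimal("84908.00")

    def test_reproduces_pppy_table(self, trial_ledger):
        s = summarize(trial_ledger)
        n = Decimal(60)
        assert round_money(s.total_pppy) == Decimal("2865.34")
        assert round_money(s.recurring_pppy) == Decimal("2599.93")
        per_cell = {
            ("startup", "participant"): "195.30",
            ("startup", "program"): "70.11",
            ("recurring", "participant"): "915.00",
            ("recurring", "program"): "269.80",
            ("recurring", "personnel"): "1415.13",
        }
        for cell, expected in per_cell.items():
            assert round_money(s.by_category[cell] / n) == Decimal(expected)

    def test_single_item_roll_up(self):
        ledger = CostLedger(items=(_item(unit_cost=Decimal("100")),), n_participants=10)
        s = summarize(ledger)
        assert s.grand_total == Decimal("1000")
        assert s.total_pppy == Decimal("100")

    def test_empty_ledger_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="empty ledger"):
            s = summarize(CostLedger(items=(), n_participants=5))
        assert s.grand_total == 0 and s.total_pppy == 0

    def test_grand_total_is_phase_sum(self, trial_ledger):
        s = summarize(trial_ledger)
        assert s.grand_total == s.startup_total + s.recurring_total
        assert s.grand_total == Decimal("171920.59")


class TestScenarios:
    def test_exclude_startup_leaves_recurring(self, trial_ledger):
        scenario = apply_scenario(trial_ledger, standard_scenarios()["A"])
        s = summarize(scenario)
        assert round_money(s.total_pppy) == Decimal("2599.93")
        assert s.startup_total == 0

    def test_lowest_cost_scenario(self, trial_ledger):
        scenario = apply_scenario(trial_ledger, standard_scenarios()["D"])
        s = summarize(scenario)
        assert round_money(s.total_pppy, 0) == Decimal("2120")

    def test_empty_exclusion_is_identity(self, trial_ledger):
        assert apply_scenario(trial_ledger, ScenarioSpec("base")) == trial_ledger

    def test_base_ledger_unmodified(self, trial_ledger):
        before = trial_ledger.items
        apply_scenario(trial_ledger, standard_scenarios()["D"])
        assert trial_ledger.items == before

    def test_unknown_exclusion_lists_valid_names(self, trial_ledger):
        spec = ScenarioSpec("bad", excluded_items=frozenset({"helicopter"}))
        with pytest.raises(CostModelError, match="helicopter.*valid names.*bus pass"):
            apply_scenario(trial_ledger, spec)


class TestLedgerIO:
    def test_round_trip(self, trial_ledger):
        buf = io.StringIO()
        write_ledger(trial_ledger, buf)
        buf.seek(0)
        assert read_ledger(buf, n_participants=60) == trial_ledger

    def test_bad_header_rejected(self):
        with pytest.raises(CostModelError, match="header"):
            read_ledger(io.StringIO("a,b,c\n1,2,3\n"))

    def test_duplicate_names_rejected(self):
        with pytest.raises(CostModelError, match="duplicate"):
            CostLedger(items=(_item(), _item()), n_participants=5)


# --- property tests ---------------------------------------------------------

_names = st.lists(
    st.text(st.characters(categories=("L", "Nd")), min_size=1, max_size=8),
    min_size=1,
    max_size=8,
    unique=True,
)
_cents = st.integers(min_value=0, max_value=10_000_000).map(
    lambda c: Decimal(c).scaleb(-2)
)


@st.composite
def ledgers(draw):
    names = draw(_names)
    items = []
    for name in names:
        rule = draw(st.sampled_from(["per_participant_once", "per_participant_per_month", "per_program_once", "per_program_per_month", "per_hour_total"]))
        items.append(
            CostItem(
                name=name,
                phase=draw(st.sampled_from(["startup", "recurring"])),
                category=draw(st.sampled_from(["participant", "program", "personnel"])),
                unit_cost=draw(_cents),
                quantity_rule=rule,
                quantity=Decimal(draw(st.integers(min_value=0, max_value=5000))),
            )
        )
    return CostLedger(items=tuple(items), n_participants=draw(st.integers(1, 500)))


@given(ledgers())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_totals_are_additive_over_items(ledger):
    s = summarize(ledger)
    item_sum = sum(
        (annualize_item(it, ledger.n_participants) for it in ledger.items), Decimal(0)
    )
    assert s.grand_total == item_sum
    # PPPY consistency holds to far better than a cent per participant
    assert abs(s.total_pppy * ledger.n_participants - s.grand_total) < Decimal("0.01")


@given(ledgers(), st.data())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_scenario_difference_equals_excluded_costs(ledger, data):
    excluded = data.draw(
        st.sets(st.sampled_from(sorted(ledger.item_names)), max_size=len(ledger.items))
    )
    spec = ScenarioSpec("s", excluded_items=frozenset(excluded))
    reduced = summarize(apply_scenario(ledger, spec))
    base = summarize(ledger)
    removed = sum(
        (
            annualize_item(it, ledger.n_participants)
            for it in ledger.items
            if it.name in excluded
        ),
        Decimal(0),
    )
    assert base.grand_total - reduced.grand_total == removed
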