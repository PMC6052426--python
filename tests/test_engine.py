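"""Cohort engine: odds transform, per-state event risks, event resolution,
single steps, full traces, and a brute-force path-enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vtece import (apply_odds_ratio, event_probabilities,
                   resolve_event_consequences, run_cohort, sequela_incidence,
                   step)
from vtece.engine import derive_inputs
from vtece.parameters import Param, with_params


class TestOddsTransform:
    def test_worked_example(self):
        # OR 0.83 on a monthly probability of 1.8%
        assert apply_odds_ratio(0.018, 0.83) == pytest.approx(0.0149858, abs=1e-6)

    def test_identity_at_or_one(self):
        assert apply_odds_ratio(0.018, 1.0) == 0.018

    def test_zero_probability(self):
        assert apply_odds_ratio(0.0, 7.3) == 0.0

    def test_p_one_rejected(self):
        with pytest.raises(ValueError):
            apply_odds_ratio(1.0, 0.5)

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            apply_odds_ratio(0.1, 0.0)

    @given(p=st.floats(min_value=1e-6, max_value=0.99),
           orv=st.floats(min_value=1e-3, max_value=100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_stays_a_probability_and_is_monotone(self, p, orv):
        q = apply_odds_ratio(p, orv)
        assert 0.0 < q < 1.0
        assert (q > p) == (orv > 1) or q == p
        # odds ratio recovered exactly
        assert (q / (1 - q)) / (p / (1 - p)) == pytest.approx(orv)


class TestEventProbabilities:
    def test_warfarin_first_stratum_matches_inputs(self, base_params):
        probs = event_probabilities("on_treatment_iVTE", 3, "warfarin",
                                    base_params)
        assert probs == {"vte_recurrence": 0.018, "crnmb": 0.017,
                         "non_ich_mb": 0.0016, "ich": 0.0003}

    def test_warfarin_later_stratum(self, base_params):
        probs = event_probabilities("on_treatment_iVTE", 9, "warfarin",
                                    base_params)
        assert probs["vte_recurrence"] == 0.002

    def test_edoxaban_uses_odds_transform(self, base_params):
        probs = event_probabilities("on_treatment_iVTE", 2, "edoxaban",
                                    base_params)
        assert probs["ich"] == pytest.approx(apply_odds_ratio(0.0003, 0.23))

    def test_off_treatment(self, base_params):
        probs = event_probabilities("off_treatment", 1, "warfarin", base_params)
        assert probs == {"vte_recurrence": 0.0042}

    def test_death_is_empty(self, base_params):
        assert event_probabilities("death", 1, "warfarin", base_params) == {}

    def test_unknown_state(self, base_params):
        with pytest.raises(ValueError, match="unknown state"):
            event_probabilities("limbo", 1, "warfarin", base_params)


class TestEventResolution:
    def test_rvte_immediate_death_fraction(self, base_params):
        branches = resolve_event_consequences("vte_recurrence", base_params)
        assert branches["death"] == pytest.approx(0.061 * 0.565)
        # survivors split 28% lifelong / 72% six-month
        surv = 1 - branches["death"]
        assert branches["on_treatment_rVTE_lifelong"] == pytest.approx(surv * 0.28)
        assert branches["on_treatment_rVTE_6mo"] == pytest.approx(surv * 0.72)

    def test_ich_disability_share(self, base_params):
        branches = resolve_event_consequences("ich", base_params)
        assert branches["death"] == 0.261
        surv = 1 - 0.261
        assert branches["off_treatment_disabled"] == pytest.approx(surv * 0.65)

    def test_crnmb_continues_treatment(self, base_params):
        assert resolve_event_consequences("crnmb", base_params) == {
            "continue_treatment": 1.0}

    def test_non_ich_mb_discontinues(self, base_params):
        branches = resolve_event_consequences("non_ich_mb", base_params)
        assert branches == {"death": 0.061, "off_treatment": 1 - 0.061}

    def test_unknown_event(self, base_params):
        with pytest.raises(ValueError, match="unknown event"):
            resolve_event_consequences("nosebleed", base_params)


class TestSequelae:
    def test_index_mix_product(self, base_params):
        out = sequela_incidence(0.401, 0.7758, base_params)
        assert out["p_cteph"] == pytest.approx(0.048 * 0.401)
        assert out["p_pts"] == pytest.approx(0.027 * 0.7758)

    def test_recurrence_mix_product(self, base_params):
        out = sequela_incidence(0.565, 0.435, base_params)
        assert out["p_cteph"] == pytest.approx(0.02712)

    def test_bad_fraction(self, base_params):
        with pytest.raises(ValueError):
            sequela_incidence(1.2, 0.1, base_params)


class TestStep:
    def test_death_is_absorbing(self, base_params, flat_life_table):
        layout_n = 24  # 6+6+6 episode months + late/off/3 tunnels + dead
        x = np.zeros(layout_n)
        x[-1] = 1.0
        new, trackers = step(base_params, "warfarin", x, (0.0, 0.0, 0.0), 10,
                             life_table=flat_life_table)
        assert new[-1] == 1.0
        assert new[:-1].sum() == 0.0

    def test_mass_conserved(self, base_params, flat_life_table):
        x = np.zeros(24)
        x[0] = 0.6   # on treatment, month 1
        x[19] = 0.3  # off treatment
        x[23] = 0.1  # dead
        new, _ = step(base_params, "edoxaban", x, (0.01, 0.02, 0.0), 3,
                      life_table=flat_life_table)
        assert new.sum() == pytest.approx(1.0, abs=1e-12)
        assert (new >= -1e-15).all()

    def test_zero_rates_only_advance_clock(self, base_params):
        p = base_params.copy()
        for risk in p.risks.values():
            risk.p_first6 = Param(0.0)
            risk.p_later = Param(0.0)
        p.clinical.p_recur_off_treatment = Param(0.0)
        rows = [(a, s, 0.0) for a in range(18, 111) for s in ("M", "F")]
        from vtece import make_life_table
        table = make_life_table(rows=rows)
        x = np.zeros(24)
        x[0] = 1.0
        new, _ = step(p, "warfarin", x, (0.0, 0.0, 0.0), 0, life_table=table)
        assert new[1] == 1.0          # month 1 -> month 2, nothing else
        assert new.sum() == pytest.approx(1.0)


class TestRunCohort:
    def test_trace_shape_and_start(self, base_params):
        p = base_params.copy()
        p.settings.horizon_months = 24
        t = run_cohort(p, "warfarin")
        assert t.occupancy.shape[0] == 25
        assert t.occupancy[0, t.layout.ON_I[0]] == pytest.approx(
            1.0, abs=1e-3)   # minus index perioperative deaths
        assert t.occupancy[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_horizon_zero(self, base_params):
        p = base_params.copy()
        p.settings.horizon_months = 0
        t = run_cohort(p, "edoxaban")
        assert t.occupancy.shape[0] == 1

    def test_mass_conservation_every_cycle(self, base_params):
        t = run_cohort(base_params, "edoxaban")
        assert np.allclose(t.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_death_and_counters_monotone(self, base_params):
        t = run_cohort(base_params, "warfarin")
        dead = t.occupancy[:, t.layout.DEAD]
        assert (np.diff(dead) >= -1e-15).all()
        for name, c in t.counters.items():
            assert (np.diff(c) >= -1e-15).all(), name

    def test_trackers_bounded_by_alive(self, base_params):
        t = run_cohort(base_params, "warfarin")
        alive = t.alive()
        for prev in (t.pts, t.cteph, t.disabled):
            assert (prev <= alive + 1e-12).all()
            assert (prev >= -1e-15).all()

    def test_lifetime_recurrences_can_exceed_one(self, base_params):
        """Events per cohort member accumulate beyond 100% over a lifetime."""
        t = run_cohort(base_params, "warfarin")
        assert t.counters["rvte"][-1] > 1.0

    def test_or_one_equalises_clinical_trajectories(self, base_params):
        p = with_params(base_params, {
            f"risks.{ev}.{f}": 1.0 for ev in p_events()
            for f in ("or_first6", "or_later")})
        te = run_cohort(p, "edoxaban")
        tw = run_cohort(p, "warfarin")
        assert np.allclose(te.occupancy, tw.occupancy, atol=1e-12)
        for k in te.counters:
            assert np.allclose(te.counters[k], tw.counters[k], atol=1e-12)

    def test_higher_ich_fatality_increases_deaths(self, base_params):
        worse = with_params(base_params, {"clinical.cfr_ich": 0.44})
        d_base = run_cohort(base_params, "warfarin").occupancy[-1, -1]
        d_worse = run_cohort(worse, "warfarin").occupancy[-1, -1]
        assert d_worse >= d_base

    def test_unknown_arm(self, base_params):
        with pytest.raises(ValueError, match="unknown arm"):
            run_cohort(base_params, "aspirin")


def p_events():
    return ("vte_recurrence", "crnmb", "non_ich_mb", "ich")


# ---------------------------------------------------------------------------
# brute-force oracle: exhaustive 3-cycle path enumeration

def _enumerate_three_cycles(params, arm, q_annual):
    """Independent expected-occupancy computation over 3 monthly cycles.

    Tracks individual-level probability mass over named states using the
    documented conventions (one-cycle tunnels, CRNMB as an overlay on the
    continuing state, competing categorical draws, additive mortality).
    Tracker-specific mortality must be zero for occupancies to be exact.
    """
    c = params.clinical
    bg = 1.0 - (1.0 - q_annual) ** (1.0 / 12.0)

    def orp(p, orv):
        return orv * p / (1 - p + orv * p)

    probs = {}
    for ev in p_events():
        risk = params.risks[ev]
        p = risk.p_first6.value
        probs[ev] = orp(p, risk.or_first6.value) if arm == "edoxaban" else p
    er, ec, em, ei = (probs["vte_recurrence"], probs["crnmb"],
                      probs["non_ich_mb"], probs["ich"])

    cfr_rvte = c.cfr_pe_recurrence.value * c.prop_recurrence_pe.value
    p_pe_rec = c.prop_recurrence_pe.value
    p_ct_rec = c.p_cteph_after_pe.value * p_pe_rec
    periop = c.prop_cteph_endarterectomy.value * c.cfr_endarterectomy.value
    p_life = c.prop_lifelong_after_recurrence.value
    p_off = c.p_recur_off_treatment.value

    p_pe = c.prop_index_pe.value
    onset0 = c.p_cteph_after_pe.value * p_pe
    dead0 = onset0 * periop

    states = {"i1": 1.0 - dead0, "dead": dead0}
    trace = [dict(states)]
    crnmb_trace = [0.0]

    for _ in range(3):
        nxt = {}
        crnmb_next = 0.0

        def add(s, v):
            nxt[s] = nxt.get(s, 0.0) + v

        for s, v in states.items():
            if v == 0.0:
                continue
            if (s[0] == "i" and s[1:].isdigit()) or s.startswith(("r6_", "rl_")):
                add("rvte", v * er)
                add("mb", v * em)
                add("ich", v * ei)
                add("dead", v * bg)
                crnmb_next += v * ec
                stay = v * (1 - er - em - ei - bg)
                m = int(s[1:]) if s[0] == "i" else int(s.split("_")[1])
                if s[0] == "i":
                    add(f"i{m+1}" if m < 6 else "off", stay)
                elif s.startswith("r6"):
                    add(f"r6_{m+1}" if m < 6 else "off", stay)
                else:
                    add(f"rl_{m+1}" if m < 6 else "rl_late", stay)
            elif s == "off":
                add("rvte", v * p_off)
                add("dead", v * bg)
                add("off", v * (1 - p_off - bg))
            elif s == "rvte":
                add("dead", v * (bg + cfr_rvte))
                surv = v * (1 - bg - cfr_rvte)
                pdead = surv * p_ct_rec * periop
                add("dead", pdead)
                surv -= pdead
                add("rl_1", surv * p_life)
                add("r6_1", surv * (1 - p_life))
            elif s == "mb":
                add("dead", v * (bg + c.cfr_non_ich_mb.value))
                add("off", v * (1 - bg - c.cfr_non_ich_mb.value))
            elif s == "ich":
                add("dead", v * (bg + c.cfr_ich.value))
                add("off", v * (1 - bg - c.cfr_ich.value))
            elif s == "dead":
                add("dead", v)
        states = nxt
        trace.append(dict(states))
        crnmb_trace.append(crnmb_next)
    return trace, crnmb_trace


@pytest.mark.parametrize("arm", ["warfarin", "edoxaban"])
def test_three_cycle_trace_matches_enumeration(base_params, arm):
    """The engine reproduces an exhaustive path enumeration to 1e-12."""
    p = base_params.copy()
    p.settings.horizon_months = 3
    # tracker-specific mortality off: occupancy then has an exact
    # individual-level counterpart
    p.clinical.p_monthly_death_post_ich_disability = Param(0.0)
    p.clinical.p_monthly_death_cteph = Param(0.0)
    from vtece import make_life_table
    q = 0.012
    p.life_table = make_life_table(
        rows=[(a, s, q) for a in range(18, 111) for s in ("M", "F")])

    t = run_cohort(p, arm)
    expected, crnmb = _enumerate_three_cycles(p, arm, q)

    L = t.layout
    name_to_idx = {"i1": L.ON_I[0], "i2": L.ON_I[1], "i3": L.ON_I[2],
                   "i4": L.ON_I[3], "r6_1": L.ON_R6[0], "r6_2": L.ON_R6[1],
                   "rl_1": L.ON_RL[0], "rl_2": L.ON_RL[1], "off": L.OFF,
                   "rvte": L.RVTE, "mb": L.MB, "ich": L.ICH, "dead": L.DEAD}
    for cyc, exp in enumerate(expected):
        got = t.occupancy[cyc]
        for name, v in exp.items():
            assert got[name_to_idx[name]] == pytest.approx(v, abs=1e-12), \
                f"cycle {cyc}, state {name}"
        # no mass anywhere the enumeration does not place it
        covered = sum(exp.values())
        assert got.sum() == pytest.approx(covered, abs=1e-12)
        assert t.crnmb_overlay[cyc] == pytest.approx(crnmb[cyc], abs=1e-12)


def test_tracker_closed_forms(base_params):
    """With event risks off, tracker prevalences follow exact geometric decay."""
    p = base_params.copy()
    for risk in p.risks.values():
        risk.p_first6 = Param(0.0)
        risk.p_later = Param(0.0)
    p.clinical.p_recur_off_treatment = Param(0.0)
    p.settings.horizon_months = 24
    from vtece import make_life_table
    q = 0.06
    p.life_table = make_life_table(
        rows=[(a, s, q) for a in range(18, 111) for s in ("M", "F")])
    t = run_cohort(p, "warfarin")

    bg = 1 - (1 - q) ** (1 / 12)
    d = derive_inputs(p, "warfarin")
    p_ct_m = p.clinical.p_monthly_death_cteph.value
    for cyc in range(25):
        assert t.pts[cyc] == pytest.approx(
            d.p_pts_index * (1 - bg) ** cyc, rel=1e-9)
        assert t.cteph[cyc] == pytest.approx(
            t.cteph[0] * ((1 - bg) * (1 - p_ct_m)) ** cyc, rel=1e-9)
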