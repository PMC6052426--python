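"""Markov cohort engine for anticoagulated VTE patients.

The cohort moves monthly between mutually exclusive states: on treatment
after the index VTE (with a month-on-treatment clock), off treatment, three
one-cycle event tunnels (recurrent VTE, non-ICH major bleed, ICH), treatment
after a recurrence (a 6-month stratum and a lifelong stratum, each with its
own clock), and death.  Clinically relevant non-major bleeds do not interrupt
anticoagulation, so they are carried as a one-cycle *overlay* on the
continuing treatment state rather than a separate exclusive state.

Three long-term conditions are tracked as concomitant prevalences alongside
the exclusive states: severe post-thrombotic syndrome (PTS), chronic
thromboembolic pulmonary hypertension (CTEPH) and disability following ICH.
Tracker members are assumed spread proportionally over the alive states, die
of other causes at the population-average rate, and additionally face their
own monthly disease-specific mortality (CTEPH, post-ICH disability).

Event risks while on treatment are time-stratified: the elevated rates of
the first six months after first anticoagulant initiation (the clock of the
underlying trial analysis) apply during calendar months 1-6 of the model,
and the lower "following months" rates thereafter, irrespective of later
re-treatment episodes.  Episode-month clocks are still tracked, but only
for treatment duration and first-cycle costs (heparin lead-in, INR
titration).  Edoxaban risks are obtained from the warfarin baselines
through the odds transform.  Competing risks within a cycle are mutually
exclusive categorical draws; an error is raised if they sum above 1.
No half-cycle correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lifetables import LifeTable, make_life_table, monthly_background_mortality
from .parameters import EVENTS, ModelParameters

FIRST6_MONTHS = 6   # length of the elevated-risk stratum within an episode

COUNTERS = ("rvte", "crnmb", "non_ich_mb", "ich", "pts", "cteph",
            "specific_death")


def apply_odds_ratio(p: float, or_value: float) -> float:
    """Convert a baseline probability through an odds ratio.

    Odds ratios act on odds: p' = OR*p / (1 - p + OR*p).  Identity at OR=1,
    and approximately a rate ratio for small p.
    """
    if or_value <= 0:
        raise ValueError("odds ratio must be > 0")
    if p >= 1.0:
        if or_value != 1.0:
            raise ValueError("cannot apply an odds ratio to p = 1")
        return p
    return or_value * p / (1.0 - p + or_value * p)


# ---------------------------------------------------------------------------
# derived per-run constants

@dataclass(frozen=True)
class DerivedInputs:
    """Quantities computed once per (params, arm) and reused every cycle."""

    arm: str
    # event probabilities by stratum, (rvte, crnmb, mb, ich); apply to all
    # on-treatment episode states (odds ratios applied for edoxaban)
    probs_first6: tuple[float, float, float, float]
    probs_later: tuple[float, float, float, float]
    p_recur_off: float
    # recurrence tunnel resolution
    cfr_rvte: float               # immediate death fraction of an rVTE
    p_lifelong: float
    # sequela incidence per event context
    p_pts_index: float
    p_cteph_index: float
    p_pts_rec: float
    p_cteph_rec: float
    frac_dvt_index: float
    frac_dvt_rec: float
    # other branch parameters
    cfr_mb: float
    cfr_ich: float
    p_disabled: float
    prop_endarterectomy: float
    cfr_endarterectomy: float
    p_death_dis: float
    p_death_cteph: float


def sequela_incidence(pe_fraction: float, dvt_fraction: float,
                      params: ModelParameters) -> dict[str, float]:
    """Per-event probabilities of the chronic sequelae for a given event mix.

    CTEPH can follow a PE, severe PTS a DVT; an event carrying both
    contributes to both.  Fractions must be probabilities.
    """
    if not (0 <= pe_fraction <= 1 and 0 <= dvt_fraction <= 1):
        raise ValueError("event-mix fractions must lie in [0,1]")
    return {
        "p_cteph": params.clinical.p_cteph_after_pe.value * pe_fraction,
        "p_pts": params.clinical.p_pts_after_dvt.value * dvt_fraction,
    }


def derive_inputs(params: ModelParameters, arm: str) -> DerivedInputs:
    c = params.clinical

    def stratum_probs(stratum: str) -> tuple[float, ...]:
        out = []
        for ev in EVENTS:
            risk = params.risks[ev]
            p = (risk.p_first6 if stratum == "first6" else risk.p_later).value
            if arm == "edoxaban":
                orv = (risk.or_first6 if stratum == "first6" else risk.or_later).value
                p = apply_odds_ratio(p, orv)
            out.append(p)
        return tuple(out)

    p_pe_idx = c.prop_index_pe.value
    p_pe_dvt = c.prop_index_pe_with_dvt.value
    frac_dvt_idx = (1.0 - p_pe_idx) + p_pe_idx * p_pe_dvt
    p_pe_rec = c.prop_recurrence_pe.value
    frac_dvt_rec = (1.0 - p_pe_rec) + p_pe_rec * p_pe_dvt

    seq_idx = sequela_incidence(p_pe_idx, frac_dvt_idx, params)
    seq_rec = sequela_incidence(p_pe_rec, frac_dvt_rec, params)

    return DerivedInputs(
        arm=arm,
        probs_first6=stratum_probs("first6"),
        probs_later=stratum_probs("later"),
        p_recur_off=c.p_recur_off_treatment.value,
        cfr_rvte=c.cfr_pe_recurrence.value * p_pe_rec,
        p_lifelong=c.prop_lifelong_after_recurrence.value,
        p_pts_index=seq_idx["p_pts"], p_cteph_index=seq_idx["p_cteph"],
        p_pts_rec=seq_rec["p_pts"], p_cteph_rec=seq_rec["p_cteph"],
        frac_dvt_index=frac_dvt_idx, frac_dvt_rec=frac_dvt_rec,
        cfr_mb=c.cfr_non_ich_mb.value,
        cfr_ich=c.cfr_ich.value,
        p_disabled=c.p_disabled_after_ich.value,
        prop_endarterectomy=c.prop_cteph_endarterectomy.value,
        cfr_endarterectomy=c.cfr_endarterectomy.value,
        p_death_dis=c.p_monthly_death_post_ich_disability.value,
        p_death_cteph=c.p_monthly_death_cteph.value,
    )


def event_probabilities(state: str, months_on_treatment: int, arm: str,
                        params: ModelParameters) -> dict[str, float]:
    """Monthly event probabilities for an exclusive state (background
    mortality excluded; it is added per-cycle from the life table).

    ``months_on_treatment`` counts months since first anticoagulant
    initiation (months <= 6 use the elevated stratum)."""
    if state in ("on_treatment_iVTE", "on_treatment_rVTE"):
        if months_on_treatment < 1:
            raise ValueError("months_on_treatment must be >= 1")
        d = derive_inputs(params, arm)
        first6 = months_on_treatment <= FIRST6_MONTHS
        probs = d.probs_first6 if first6 else d.probs_later
        return dict(zip(EVENTS, probs))
    if state == "off_treatment":
        return {"vte_recurrence": params.clinical.p_recur_off_treatment.value}
    if state in ("rVTE", "non_ICH_MB", "ICH"):
        return {}    # tunnels resolve through resolve_event_consequences
    if state == "death":
        return {}
    raise ValueError(f"unknown state {state!r}")


def resolve_event_consequences(event: str, params: ModelParameters) -> dict[str, float]:
    """Branch distribution applied when a one-cycle event resolves."""
    c = params.clinical
    if event == "vte_recurrence":
        death = c.cfr_pe_recurrence.value * c.prop_recurrence_pe.value
        surv = 1.0 - death
        p_life = c.prop_lifelong_after_recurrence.value
        return {"death": death,
                "on_treatment_rVTE_lifelong": surv * p_life,
                "on_treatment_rVTE_6mo": surv * (1.0 - p_life)}
    if event == "crnmb":
        return {"continue_treatment": 1.0}   # no discontinuation
    if event == "non_ich_mb":
        death = c.cfr_non_ich_mb.value
        return {"death": death, "off_treatment": 1.0 - death}
    if event == "ich":
        death = c.cfr_ich.value
        surv = 1.0 - death
        p_dis = c.p_disabled_after_ich.value
        return {"death": death,
                "off_treatment_disabled": surv * p_dis,
                "off_treatment": surv * (1.0 - p_dis)}
    raise ValueError(f"unknown event {event!r}")


# ---------------------------------------------------------------------------
# state layout and trace

class StateLayout:
    """Index map of the exclusive-state vector for given episode durations."""

    def __init__(self, initial_months: int, recurrence_months: int):
        self.n_i = int(initial_months)
        self.n_r = int(recurrence_months)
        i = 0
        self.ON_I = list(range(i, i + self.n_i)); i += self.n_i
        self.ON_R6 = list(range(i, i + self.n_r)); i += self.n_r
        self.ON_RL = list(range(i, i + FIRST6_MONTHS)); i += FIRST6_MONTHS
        self.RL_LATE = i; i += 1
        self.OFF = i; i += 1
        self.RVTE = i; i += 1
        self.MB = i; i += 1
        self.ICH = i; i += 1
        self.DEAD = i; i += 1
        self.n_states = i

    def names(self) -> list[str]:
        out = [f"on_iVTE_m{m+1}" for m in range(self.n_i)]
        out += [f"on_rVTE6_m{m+1}" for m in range(self.n_r)]
        out += [f"on_rVTE_life_m{m+1}" for m in range(FIRST6_MONTHS)]
        out += ["on_rVTE_life_late", "off_treatment", "rVTE", "non_ICH_MB",
                "ICH", "death"]
        return out


@dataclass
class CohortTrace:
    """Per-cycle record of a deterministic cohort run.

    ``occupancy[c]`` is the exclusive-state distribution at the start of
    cycle ``c``; overlays and tracker prevalences apply *during* cycle ``c``.
    ``counters`` are cumulative incidences (events per initial cohort member;
    can exceed 1 over a lifetime).
    """

    layout: StateLayout
    arm: str
    occupancy: np.ndarray        # (H+1, n_states)
    crnmb_overlay: np.ndarray    # (H+1,)
    pts: np.ndarray              # prevalences (H+1,)
    cteph: np.ndarray
    disabled: np.ndarray
    pts_new: np.ndarray          # incident fractions entering during cycle c
    cteph_new: np.ndarray
    counters: dict[str, np.ndarray]   # cumulative, each (H+1,)
    age: np.ndarray              # (H+1,)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, self.layout.DEAD]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.occupancy, columns=self.layout.names())
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df.insert(1, "age", self.age)
        df["crnmb_overlay"] = self.crnmb_overlay
        df["prev_pts"] = self.pts
        df["prev_cteph"] = self.cteph
        df["prev_disabled"] = self.disabled
        for k, v in self.counters.items():
            df[f"cum_{k}"] = v
        return df


# ---------------------------------------------------------------------------
# the step and the cohort loop

def _check_probability_budget(d: DerivedInputs, bg_max: float) -> None:
    for name, probs in (("first6", d.probs_first6), ("later", d.probs_later)):
        if sum(probs) + bg_max > 1.0:
            raise ValueError(
                f"event probabilities + background mortality exceed 1 in "
                f"on-treatment stratum '{name}' ({d.arm})")
    if d.p_recur_off + bg_max > 1.0:
        raise ValueError("off-treatment probabilities exceed 1")


def _step(layout: StateLayout, d: DerivedInputs, x: list[float], pts: float,
          cteph: float, dis: float, bg: float, probs):
    """One monthly transition.  Returns (x_next, trackers_next, flows).

    Operates on plain Python lists: the state space is small and scalar
    arithmetic on lists is several times faster than numpy element access,
    which matters for the 2,000-draw probabilistic sensitivity analysis.
    """
    L = layout
    new = [0.0] * L.n_states
    crnmb_next = 0.0
    f_rvte = f_mb = f_ich = f_spec = 0.0

    # --- on-treatment episode states ------------------------------------
    # risk stratum is supplied per cycle (time since first initiation);
    # the within-episode month index m only drives duration bookkeeping
    er, ec, em, ei = probs
    stay_frac = 1.0 - er - em - ei - bg
    for idx, next_of_last in ((L.ON_I, L.OFF), (L.ON_R6, L.OFF),
                              (L.ON_RL, L.RL_LATE)):
        n = len(idx)
        for m0 in range(n):
            v = x[idx[m0]]
            if v == 0.0:
                continue
            m = m0 + 1
            new[L.RVTE] += v * er
            new[L.MB] += v * em
            new[L.ICH] += v * ei
            new[L.DEAD] += v * bg
            crnmb_next += v * ec
            nxt = idx[m] if m < n else next_of_last
            new[nxt] += v * stay_frac
            f_rvte += v * er
            f_mb += v * em
            f_ich += v * ei

    # --- lifelong maintenance -------------------------------------------
    # beyond the trial-informed 6-month window of a tertiary episode,
    # lifelong anticoagulation is treated as fully protective: no further
    # recurrences or bleeds are modelled, only background and concomitant
    # condition mortality
    v = x[L.RL_LATE]
    if v:
        new[L.DEAD] += v * bg
        new[L.RL_LATE] += v * (1.0 - bg)

    # --- off treatment ---------------------------------------------------
    v = x[L.OFF]
    if v:
        new[L.RVTE] += v * d.p_recur_off
        new[L.DEAD] += v * bg
        new[L.OFF] += v * (1.0 - d.p_recur_off - bg)
        f_rvte += v * d.p_recur_off

    # --- tunnel resolutions ---------------------------------------------
    pts_in = 0.0
    cteph_in = 0.0
    dis_in = 0.0
    f_cteph = 0.0

    v = x[L.RVTE]
    if v:
        new[L.DEAD] += v * (bg + d.cfr_rvte)
        f_spec += v * d.cfr_rvte
        surv = v * (1.0 - bg - d.cfr_rvte)
        pts_in += surv * d.p_pts_rec
        onset = surv * d.p_cteph_rec
        periop = onset * d.prop_endarterectomy * d.cfr_endarterectomy
        new[L.DEAD] += periop
        f_spec += periop
        f_cteph += onset
        cteph_in += onset - periop
        surv -= periop
        new[L.ON_RL[0]] += surv * d.p_lifelong
        new[L.ON_R6[0]] += surv * (1.0 - d.p_lifelong)

    v = x[L.MB]
    if v:
        new[L.DEAD] += v * (bg + d.cfr_mb)
        f_spec += v * d.cfr_mb
        new[L.OFF] += v * (1.0 - bg - d.cfr_mb)

    v = x[L.ICH]
    if v:
        new[L.DEAD] += v * (bg + d.cfr_ich)
        f_spec += v * d.cfr_ich
        surv = v * (1.0 - bg - d.cfr_ich)
        new[L.OFF] += surv
        dis_in += surv * d.p_disabled

    new[L.DEAD] += x[L.DEAD]

    # --- concomitant trackers -------------------------------------------
    alive_old = 1.0 - x[L.DEAD]
    deaths = new[L.DEAD] - x[L.DEAD]
    r = deaths / alive_old if alive_old > 0 else 0.0
    pts_n = pts * (1.0 - r) + pts_in
    cteph_n = cteph * (1.0 - r) + cteph_in
    dis_n = dis * (1.0 - r) + dis_in

    d_dis = dis_n * d.p_death_dis
    d_ct = cteph_n * d.p_death_cteph
    extra = d_dis + d_ct
    alive_new = 1.0 - new[L.DEAD]
    if extra > 0.0 and alive_new > 0.0:
        scale = (alive_new - extra) / alive_new
        for i in range(L.DEAD):
            new[i] *= scale
        new[L.DEAD] += extra
        f_spec += extra
        alive_new -= extra
    dis_n -= d_dis
    cteph_n -= d_ct
    pts_n = min(pts_n, alive_new)
    cteph_n = min(cteph_n, alive_new)
    dis_n = min(dis_n, alive_new)

    total = sum(new)
    if abs(total - 1.0) > 1e-9:
        raise ArithmeticError(f"mass not conserved: sum = {total!r}")

    flows = {"rvte": f_rvte, "crnmb": crnmb_next, "non_ich_mb": f_mb,
             "ich": f_ich, "pts": pts_in, "cteph": f_cteph,
             "specific_death": f_spec}
    return new, (pts_n, cteph_n, dis_n), (crnmb_next, pts_in, cteph_in), flows


def step(params: ModelParameters, arm: str, x: np.ndarray,
         trackers: tuple[float, float, float], cycle: int,
         life_table: LifeTable | None = None):
    """Public single-step wrapper (builds the per-run context each call)."""
    s = params.settings
    layout = StateLayout(s.initial_treatment_months, s.recurrence_treatment_months)
    d = derive_inputs(params, arm)
    table = life_table or params.life_table or make_life_table()
    bg = monthly_background_mortality(table, s.start_age + cycle / 12.0, s.prop_male)
    _check_probability_budget(d, bg)
    probs = d.probs_first6 if cycle < FIRST6_MONTHS else d.probs_later
    new, tr, _, _ = _step(layout, d, [float(v) for v in x], *trackers, bg=bg,
                          probs=probs)
    return np.array(new), tr


def run_cohort(params: ModelParameters, arm: str | None = None) -> CohortTrace:
    """Roll the cohort from 100% on-treatment (month 1) to the horizon.

    Deterministic: the cohort model contains no randomness.
    """
    s = params.settings
    arm = arm or s.arm
    if arm not in ("edoxaban", "warfarin"):
        raise ValueError(f"unknown arm {arm!r}")
    H = int(s.horizon_months)
    layout = StateLayout(s.initial_treatment_months, s.recurrence_treatment_months)
    d = derive_inputs(params, arm)
    table = params.life_table or make_life_table()

    ages = s.start_age + np.arange(H + 1) / 12.0
    bg = np.array([monthly_background_mortality(table, a, s.prop_male)
                   for a in ages])
    _check_probability_budget(d, float(bg[:max(H, 1)].max()))

    occ = np.zeros((H + 1, layout.n_states))
    crnmb = np.zeros(H + 1)
    pts = np.zeros(H + 1)
    cteph = np.zeros(H + 1)
    dis = np.zeros(H + 1)
    pts_new = np.zeros(H + 1)
    cteph_new = np.zeros(H + 1)
    counters = {k: np.zeros(H + 1) for k in COUNTERS}

    # index-event sequelae apply at entry (cycle 0)
    occ[0, layout.ON_I[0]] = 1.0
    pts[0] = pts_new[0] = d.p_pts_index
    onset0 = d.p_cteph_index
    periop0 = onset0 * d.prop_endarterectomy * d.cfr_endarterectomy
    occ[0, layout.ON_I[0]] -= periop0
    occ[0, layout.DEAD] += periop0
    cteph[0] = cteph_new[0] = onset0 - periop0
    counters["pts"][0] = d.p_pts_index
    counters["cteph"][0] = onset0
    counters["specific_death"][0] = periop0

    x = [float(v) for v in occ[0]]
    tr = (pts[0], cteph[0], dis[0])
    bgl = [float(b) for b in bg]
    for c in range(H):
        probs = d.probs_first6 if c < FIRST6_MONTHS else d.probs_later
        x, tr, inflows, flows = _step(layout, d, x, *tr, bg=bgl[c],
                                      probs=probs)
        occ[c + 1] = x
        crnmb[c + 1], pts_new[c + 1], cteph_new[c + 1] = inflows
        pts[c + 1], cteph[c + 1], dis[c + 1] = tr
        for k in COUNTERS:
            counters[k][c + 1] = counters[k][c] + flows[k]

    return CohortTrace(layout=layout, arm=arm, occupancy=occ,
                       crnmb_overlay=crnmb, pts=pts, cteph=cteph, disabled=dis,
                       pts_new=pts_new, cteph_new=cteph_new,
                       counters=counters, age=ages)
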