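"""Model inputs: efficacy/safety risks, clinical fractions, utilities, costs, run settings.

Every quantity that enters the cohort model lives here as a :class:`Param`
(base value plus optional deterministic-sensitivity bounds), grouped into the
blocks that mirror the published input tables.  Transformations (scenarios,
subgroups, single-parameter overrides for sensitivity analyses) are pure: they
return new objects and never mutate their input.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Iterator

import yaml

log = logging.getLogger("vtece")

#: exclusive adverse-event ids, in the order risks are evaluated each cycle
EVENTS = ("vte_recurrence", "crnmb", "non_ich_mb", "ich")

ARMS = ("edoxaban", "warfarin")
SUBGROUPS = ("all", "dvt_only", "pe_any", "pe_only", "pe_plus_dvt")
SCENARIOS = ("or_nonsig_to_one", "horizon_1y", "horizon_5y")


@dataclass(frozen=True)
class Param:
    """A scalar model input with optional low/high sensitivity bounds.

    Parameters without bounds are treated as fixed (excluded from DSA/PSA).
    """

    value: float
    low: float | None = None
    high: float | None = None

    @property
    def has_bounds(self) -> bool:
        return self.low is not None and self.high is not None

    def with_value(self, value: float) -> "Param":
        return Param(value, self.low, self.high)


def _p(value, low=None, high=None) -> Param:
    return Param(float(value), None if low is None else float(low),
                 None if high is None else float(high))


@dataclass
class TimeStratifiedRisk:
    """Baseline monthly probability (warfarin arm) and edoxaban odds ratio,
    each on two time strata: months 1-6 of a treatment episode vs. months 7+.

    ``or_significant_*`` flags odds ratios whose 95% CI excludes 1; the
    non-significant ones are the targets of the OR→1 scenario analysis.
    """

    p_first6: Param
    p_later: Param
    or_first6: Param
    or_later: Param
    or_significant_first6: bool = True
    or_significant_later: bool = True


@dataclass
class ClinicalParams:
    prop_index_pe: Param          # fraction of index events that are PE (±DVT)
    prop_index_pe_with_dvt: Param  # fraction of index PE that also carry DVT
    prop_recurrence_pe: Param     # fraction of recurrences that are PE
    p_recur_off_treatment: Param  # monthly recurrence probability off treatment
    p_cteph_after_pe: Param       # per-PE-event probability of CTEPH
    p_pts_after_dvt: Param        # per-DVT-event probability of severe PTS
    p_disabled_after_ich: Param   # ICH survivors left disabled
    cfr_pe_recurrence: Param      # case fatality of a PE recurrence
    cfr_non_ich_mb: Param
    cfr_ich: Param
    cfr_endarterectomy: Param     # perioperative mortality of endarterectomy
    p_monthly_death_post_ich_disability: Param
    p_monthly_death_cteph: Param
    prop_lifelong_after_recurrence: Param  # recurrence survivors treated lifelong
    prop_cteph_endarterectomy: Param       # CTEPH patients undergoing surgery


@dataclass
class UtilityParams:
    u_pe: Param
    u_dvt: Param
    du_warfarin: Param        # relative decrement on warfarin vs. edoxaban
    du_crnmb: Param           # one-cycle relative decrements for acute events
    du_non_ich_mb: Param
    du_ich: Param
    du_ich_disability: Param  # while disabled post-ICH (permanent)
    du_cteph: Param           # while CTEPH prevalent (permanent)
    du_pts: Param             # while severe PTS prevalent (permanent)
    du_rvte_first_month: Param


@dataclass
class CostParams:
    # per-cycle treatment cost primitives (drug + heparin lead-in + INR where
    # applicable); stored as printed because their components do not reconcile
    # exactly -- component fields below are used only to *perturb* them.
    c_warfarin_cycle_first: Param
    c_warfarin_cycle_later: Param
    c_edoxaban_cycle_first: Param
    c_edoxaban_cycle_later: Param
    # components (sensitivity handles rebuild cycle costs from these)
    c_heparin_daily: Param
    heparin_days_warfarin: Param
    heparin_days_edoxaban: Param
    c_warfarin_drug_monthly: Param
    c_edoxaban_drug_first: Param
    c_edoxaban_drug_later: Param
    c_inr_first: Param
    c_inr_subsequent: Param
    n_inr_titration: Param
    n_inr_monthly: Param
    # acute event costs
    c_pe_event: Param
    c_dvt_event: Param
    c_ich_acute: Param
    c_non_ich_mb: Param
    c_crnmb: Param
    # long-term costs
    c_ich_disability_monthly: Param
    c_pts_first_month: Param
    c_pts_monthly: Param
    c_endarterectomy: Param
    c_cteph_drugs_monthly: Param


@dataclass
class RunSettings:
    arm: str = "edoxaban"
    horizon_months: int = 600           # 50-year lifetime horizon
    discount_rate_annual: float = 0.035
    wtp: float = 20_000.0               # £ per QALY
    start_age: float = 56.0             # cohort entry age (not reported; see docs)
    prop_male: float = 0.57
    initial_treatment_months: int = 6
    recurrence_treatment_months: int = 6
    subgroup: str = "all"
    or_nonsig_to_one: bool = False
    rng_seed: int = 20180717

    def defaults_applied(self, provided: dict) -> list[str]:
        return [f.name for f in fields(self) if f.name not in provided]


@dataclass
class ModelParameters:
    """Complete, validated input set: one instance fully determines a run."""

    risks: dict[str, TimeStratifiedRisk]
    clinical: ClinicalParams
    utilities: UtilityParams
    costs: CostParams
    settings: RunSettings
    life_table: Any = None  # LifeTable; defaults to the synthetic table on use

    def copy(self) -> "ModelParameters":
        new = copy.deepcopy(self)
        new.life_table = self.life_table  # life table is read-only; share it
        return new


# ---------------------------------------------------------------------------
# parameter tree walking

def iter_params(params: ModelParameters) -> Iterator[tuple[str, Param]]:
    """Yield ``(dotted_path, Param)`` for every scalar input in the set."""
    for ev, risk in params.risks.items():
        for f in fields(risk):
            v = getattr(risk, f.name)
            if isinstance(v, Param):
                yield f"risks.{ev}.{f.name}", v
    for block in ("clinical", "utilities", "costs"):
        obj = getattr(params, block)
        for f in fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, Param):
                yield f"{block}.{f.name}", v


def get_param(params: ModelParameters, path: str) -> Param:
    parts = path.split(".")
    if parts[0] == "risks":
        return getattr(params.risks[parts[1]], parts[2])
    return getattr(getattr(params, parts[0]), parts[1])


def with_params(params: ModelParameters, overrides: dict[str, float]) -> ModelParameters:
    """Return a copy with the given parameter *values* replaced (bounds kept)."""
    new = params.copy()
    for path, value in overrides.items():
        parts = path.split(".")
        if parts[0] == "risks":
            obj, name = new.risks[parts[1]], parts[2]
        else:
            obj, name = getattr(new, parts[0]), parts[1]
        setattr(obj, name, getattr(obj, name).with_value(float(value)))
    return new


def distribution_family(path: str) -> str:
    """PSA distribution family implied by a parameter's role."""
    leaf = path.rsplit(".", 1)[-1]
    if leaf.startswith("or_"):
        return "lognormal"
    if path.startswith("costs.") or leaf.startswith(("n_", "heparin_days")):
        return "gamma"
    return "beta"   # probabilities, proportions, utilities, decrements


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Violation:
    path: str
    value: float
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path} = {self.value}: violates '{self.rule}'"


def validate(params: ModelParameters) -> list[Violation]:
    """Check every type invariant; violations are returned, never raised."""
    out: list[Violation] = []

    def check(path: str, p: Param, lo: float | None, hi: float | None, rule: str):
        if lo is not None and p.value < lo or hi is not None and p.value > hi:
            out.append(Violation(path, p.value, rule))
        if p.has_bounds and not (p.low <= p.value <= p.high):
            out.append(Violation(path, p.value, "low <= base <= high"))

    for path, p in iter_params(params):
        leaf = path.rsplit(".", 1)[-1]
        if leaf.startswith("or_"):
            check(path, p, 1e-12, None, "odds ratio > 0")
        elif path.startswith("costs.") or leaf.startswith(("n_", "heparin_days")):
            check(path, p, 0.0, None, "cost/count >= 0")
        elif path.startswith("utilities.u_"):
            check(path, p, 0.0, 1.0, "utility in [0,1]")
        elif path.startswith("utilities.du_"):
            check(path, p, 0.0, 1.0, "decrement in [0,1]")
        else:
            check(path, p, 0.0, 1.0, "probability in [0,1]")

    s = params.settings
    if s.arm not in ARMS:
        out.append(Violation("settings.arm", float("nan"), f"arm in {ARMS}"))
    if s.subgroup not in SUBGROUPS:
        out.append(Violation("settings.subgroup", float("nan"), f"subgroup in {SUBGROUPS}"))
    if s.horizon_months < 1:
        out.append(Violation("settings.horizon_months", s.horizon_months, "horizon >= 1"))
    if s.discount_rate_annual < 0:
        out.append(Violation("settings.discount_rate_annual", s.discount_rate_annual,
                             "discount rate >= 0"))
    if not 0.0 <= s.prop_male <= 1.0:
        out.append(Violation("settings.prop_male", s.prop_male, "proportion in [0,1]"))
    return out


class ParameterError(ValueError):
    pass


def validate_or_raise(params: ModelParameters) -> ModelParameters:
    violations = validate(params)
    if violations:
        raise ParameterError(
            "invalid parameters:\n" + "\n".join(str(v) for v in violations))
    return params


# ---------------------------------------------------------------------------
# scenarios & subgroups

def apply_scenario(params: ModelParameters, scenario: str) -> ModelParameters:
    """Return a new parameter set with a named scenario applied.

    ``or_nonsig_to_one`` replaces exactly the odds ratios whose confidence
    intervals include 1 (flagged non-significant) by 1.0; the horizon
    scenarios truncate the time horizon.  Idempotent; input untouched.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {SCENARIOS}")
    new = params.copy()
    if scenario == "or_nonsig_to_one":
        for risk in new.risks.values():
            if not risk.or_significant_first6:
                risk.or_first6 = risk.or_first6.with_value(1.0)
            if not risk.or_significant_later:
                risk.or_later = risk.or_later.with_value(1.0)
        new.settings.or_nonsig_to_one = True
    elif scenario == "horizon_1y":
        new.settings.horizon_months = 12
    elif scenario == "horizon_5y":
        new.settings.horizon_months = 60
    return new


def subgroup_parameters(params: ModelParameters, subgroup: str) -> ModelParameters:
    """Restrict the index-event composition to a named subgroup.

    Only the index PE / PE-with-DVT fractions change; event risks, utilities
    per event type and costs stay pooled.
    """
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}; valid: {SUBGROUPS}")
    new = params.copy()
    c = new.clinical
    # overridden index-mix fractions drop their sensitivity bounds: the
    # pooled DSA range no longer applies to a restricted population
    if subgroup == "dvt_only":
        c.prop_index_pe = Param(0.0)
    elif subgroup == "pe_any":
        c.prop_index_pe = Param(1.0)
    elif subgroup == "pe_only":
        c.prop_index_pe = Param(1.0)
        c.prop_index_pe_with_dvt = Param(0.0)
    elif subgroup == "pe_plus_dvt":
        c.prop_index_pe = Param(1.0)
        c.prop_index_pe_with_dvt = Param(1.0)
    new.settings.subgroup = subgroup
    return new


# ---------------------------------------------------------------------------
# (de)serialisation

def _param_to_yaml(p: Param):
    if p.has_bounds:
        return [p.value, p.low, p.high]
    return p.value


def _param_from_yaml(path: str, raw) -> Param:
    if isinstance(raw, (int, float)):
        return Param(float(raw))
    if isinstance(raw, (list, tuple)) and len(raw) == 3:
        return Param(float(raw[0]), float(raw[1]), float(raw[2]))
    raise ParameterError(f"{path}: expected scalar or [value, low, high], got {raw!r}")


def params_to_dict(params: ModelParameters) -> dict:
    out: dict[str, Any] = {"risks": {}, "clinical": {}, "utilities": {},
                           "costs": {}, "settings": {}}
    for ev, risk in params.risks.items():
        d = {}
        for f in fields(risk):
            v = getattr(risk, f.name)
            d[f.name] = _param_to_yaml(v) if isinstance(v, Param) else v
        out["risks"][ev] = d
    for block in ("clinical", "utilities", "costs"):
        obj = getattr(params, block)
        out[block] = {f.name: _param_to_yaml(getattr(obj, f.name)) for f in fields(obj)}
    out["settings"] = {f.name: getattr(params.settings, f.name)
                       for f in fields(RunSettings)}
    return out


def params_from_dict(data: dict) -> ModelParameters:
    for section in ("risks", "clinical", "utilities", "costs"):
        if section not in data:
            raise ParameterError(f"missing section {section!r}")
    risks = {}
    for ev in EVENTS:
        if ev not in data["risks"]:
            raise ParameterError(f"missing risk block risks.{ev}")
        raw = data["risks"][ev]
        kwargs: dict[str, Any] = {}
        for f in fields(TimeStratifiedRisk):
            if f.name not in raw:
                raise ParameterError(f"missing field risks.{ev}.{f.name}")
            v = raw[f.name]
            kwargs[f.name] = bool(v) if f.name.startswith("or_significant") \
                else _param_from_yaml(f"risks.{ev}.{f.name}", v)
        risks[ev] = TimeStratifiedRisk(**kwargs)

    def build(cls, section):
        raw = data[section]
        kwargs = {}
        for f in fields(cls):
            if f.name not in raw:
                raise ParameterError(f"missing field {section}.{f.name}")
            kwargs[f.name] = _param_from_yaml(f"{section}.{f.name}", raw[f.name])
        return cls(**kwargs)

    provided = data.get("settings") or {}
    unknown = set(provided) - {f.name for f in fields(RunSettings)}
    if unknown:
        raise ParameterError(f"unknown settings fields: {sorted(unknown)}")
    settings = RunSettings(**provided)
    for name in settings.defaults_applied(provided):
        log.info("settings.%s not in file; default %r applied",
                 name, getattr(settings, name))

    return ModelParameters(risks=risks, clinical=build(ClinicalParams, "clinical"),
                           utilities=build(UtilityParams, "utilities"),
                           costs=build(CostParams, "costs"), settings=settings)


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a parameter file (YAML)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: not a mapping")
    return validate_or_raise(params_from_dict(data))


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=True)
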