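"""Named, reproducible experiment bundles: base case, the three scenario
analyses (non-significant ORs set to 1; 1-year and 5-year horizons) and the
four index-event subgroups."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .model import MarkovCohortModel
from .outcomes import CEResult, COST_CATEGORIES
from .parameters import (ModelParameters, apply_scenario, subgroup_parameters)


@dataclass(frozen=True)
class ExperimentSpec:
    """A parameter-transformation chain plus the threshold to evaluate at."""

    id: str
    scenarios: tuple[str, ...] = ()
    subgroup: str | None = None
    wtp: float | None = None    # None -> settings.wtp

    def transform(self, params: ModelParameters) -> ModelParameters:
        out = params
        if self.subgroup is not None:
            out = subgroup_parameters(out, self.subgroup)
        for sc in self.scenarios:
            out = apply_scenario(out, sc)
        return out


EXPERIMENTS: dict[str, ExperimentSpec] = {
    "base": ExperimentSpec("base"),
    "dvt_only": ExperimentSpec("dvt_only", subgroup="dvt_only"),
    "pe_any": ExperimentSpec("pe_any", subgroup="pe_any"),
    "pe_only": ExperimentSpec("pe_only", subgroup="pe_only"),
    "pe_plus_dvt": ExperimentSpec("pe_plus_dvt", subgroup="pe_plus_dvt"),
    "or_nonsig_to_one": ExperimentSpec("or_nonsig_to_one",
                                       scenarios=("or_nonsig_to_one",)),
    "horizon_1y": ExperimentSpec("horizon_1y", scenarios=("horizon_1y",)),
    "horizon_5y": ExperimentSpec("horizon_5y", scenarios=("horizon_5y",)),
}


def run_experiment(spec: ExperimentSpec | str,
                   params: ModelParameters) -> CEResult:
    """Run one named experiment.  Pure: same spec + params -> same result."""
    if isinstance(spec, str):
        if spec not in EXPERIMENTS:
            raise KeyError(f"unknown experiment {spec!r}; "
                           f"valid: {sorted(EXPERIMENTS)}")
        spec = EXPERIMENTS[spec]
    model = MarkovCohortModel(spec.transform(params))
    return model.evaluate(wtp=spec.wtp)


def run_all(params: ModelParameters,
            ids: list[str] | None = None) -> dict[str, CEResult]:
    return {i: run_experiment(i, params) for i in (ids or EXPERIMENTS)}


def export_result(result: CEResult, outdir: str | Path) -> Path:
    """Write one experiment's results as JSON + a CSV shaped like the
    published results table (clinical incidences, health outcomes, costs,
    CE statistics)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "result.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)

    rows = []
    e, w = result.edoxaban, result.warfarin
    for k in e.cumulative_incidence:
        rows.append((f"cum_{k}", e.cumulative_incidence[k],
                     w.cumulative_incidence[k]))
    rows.append(("life_years", e.ly, w.ly))
    rows.append(("total_qalys", e.qaly, w.qaly))
    for cat in COST_CATEGORIES:
        rows.append((f"cost_{cat}", e.ledger.cost_totals()[cat],
                     w.ledger.cost_totals()[cat]))
    rows.append(("total_costs", e.cost, w.cost))
    with open(outdir / "table.csv", "w") as fh:
        fh.write("quantity,edoxaban,warfarin\n")
        for name, ev, wv in rows:
            fh.write(f"{name},{ev:.6f},{wv:.6f}\n")
        fh.write(f"incremental_qalys,{result.delta_qaly:.6f},\n")
        fh.write(f"incremental_costs,{result.delta_cost:.6f},\n")
        fh.write(f"icer,{result.status if result.icer is None else result.icer},\n")
        fh.write(f"nmb,{result.nmb():.6f},\n")
    return outdir
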