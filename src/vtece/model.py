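"""High-level modelling object tying the pieces together.

``MarkovCohortModel`` is built from a validated :class:`ModelParameters`
set; ``evaluate()`` runs the deterministic cohort for both treatment arms
and returns a :class:`CEResult` carrying incremental QALYs/costs, dominance
classification, net monetary benefit and a ``summary()`` table.  Sensitivity
analyses (tornado, probabilistic) operate on the same object.
"""

from __future__ import annotations

from .engine import CohortTrace, run_cohort
from .outcomes import ArmOutcomes, CEResult, accumulate, compare
from .parameters import ModelParameters, validate_or_raise


class MarkovCohortModel:
    """Deterministic monthly-cycle cohort model of VTE anticoagulation."""

    def __init__(self, params: ModelParameters, validate: bool = True):
        if validate:
            validate_or_raise(params)
        self.params = params
        self._traces: dict[str, CohortTrace] = {}

    def trace(self, arm: str) -> CohortTrace:
        """The cohort trace for one arm (cached; the model is deterministic)."""
        if arm not in self._traces:
            self._traces[arm] = run_cohort(self.params, arm)
        return self._traces[arm]

    def arm_outcomes(self, arm: str) -> ArmOutcomes:
        return accumulate(self.trace(arm), self.params)

    def evaluate(self, wtp: float | None = None) -> CEResult:
        """Run both arms and compare at the willingness-to-pay threshold."""
        lam = self.params.settings.wtp if wtp is None else wtp
        return compare(self.arm_outcomes("edoxaban"),
                       self.arm_outcomes("warfarin"), lam)

    # alias used by callers that think of evaluation as a 'run'
    run = evaluate
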