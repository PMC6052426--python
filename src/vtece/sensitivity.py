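"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way DSA reruns the full two-arm model at each parameter's low and high
bound; the probabilistic analysis samples every parameter that carries a
sensitivity range from a moment-matched distribution (beta for
probabilities/proportions/utilities, log-normal for odds ratios with the
printed interval as the 95% CI, gamma for costs and resource counts),
independently across parameters, and reruns the model per draw.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .model import MarkovCohortModel
from .outcomes import CEResult
from .parameters import (ModelParameters, Param, distribution_family,
                         get_param, iter_params, with_params)

log = logging.getLogger("vtece")


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis

@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    low: float
    high: float
    nmb_low: float
    nmb_high: float

    @property
    def span(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def _nmb_at(params: ModelParameters, overrides: dict[str, float],
            wtp: float) -> float:
    model = MarkovCohortModel(with_params(params, overrides), validate=False)
    return model.evaluate(wtp=wtp).nmb()


def one_way_dsa(params: ModelParameters,
                parameters: list[str] | None = None,
                wtp: float | None = None) -> list[TornadoRow]:
    """Tornado analysis: NMB at each parameter's low/high bound, all else at
    base.  Rows sorted by span descending, ties by parameter id."""
    lam = params.settings.wtp if wtp is None else wtp
    if parameters is None:
        parameters = [p for p, v in iter_params(params) if v.has_bounds]
    rows = []
    for path in parameters:
        p = get_param(params, path)
        if not p.has_bounds:
            log.warning("DSA: %s has no bounds; skipped", path)
            continue
        nmb_lo = _nmb_at(params, {path: p.low}, lam)
        nmb_hi = _nmb_at(params, {path: p.high}, lam)
        rows.append(TornadoRow(path, p.low, p.high, nmb_lo, nmb_hi))
    rows.sort(key=lambda r: (-r.span, r.parameter))
    return rows


def tornado_to_csv(rows: list[TornadoRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("parameter,low,high,nmb_low,nmb_high,span\n")
        for r in rows:
            fh.write(f"{r.parameter},{r.low:.6g},{r.high:.6g},"
                     f"{r.nmb_low:.4f},{r.nmb_high:.4f},{r.span:.4f}\n")


# ---------------------------------------------------------------------------
# distributions

@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution matched to a base value and DSA bounds."""

    family: str               # beta | lognormal | gamma | point
    args: tuple[float, ...]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point":
            return np.full(size, self.args[0])
        if self.family == "beta":
            a, b = self.args
            return rng.beta(a, b, size)
        if self.family == "lognormal":
            mu, sigma = self.args
            return rng.lognormal(mu, sigma, size)
        if self.family == "gamma":
            shape, scale = self.args
            return rng.gamma(shape, scale, size)
        raise ValueError(self.family)

    def mean(self) -> float:
        if self.family == "point":
            return self.args[0]
        if self.family == "beta":
            a, b = self.args
            return a / (a + b)
        if self.family == "lognormal":
            mu, sigma = self.args
            return math.exp(mu + sigma ** 2 / 2)
        shape, scale = self.args
        return shape * scale


def assign_distribution(path: str, base: float, low: float,
                        high: float) -> DistributionSpec:
    """Pick and moment-match the sampling family for one parameter.

    The spread is set so the central ~95% interval approximates [low, high]
    (sd = range/3.92); the mean is the base value (log-normal: median).
    """
    if not low <= base <= high:
        raise ValueError(f"{path}: bounds [{low}, {high}] do not bracket {base}")
    if high == low:
        return DistributionSpec("point", (base,))
    family = distribution_family(path)
    sd = (high - low) / 3.92

    if family == "lognormal":
        if low <= 0:
            raise ValueError(f"{path}: log-normal requires positive bounds")
        sigma = (math.log(high) - math.log(low)) / 3.92
        return DistributionSpec("lognormal", (math.log(base), sigma))

    if family == "gamma":
        if base <= 0:
            return DistributionSpec("point", (base,))
        shape = (base / sd) ** 2
        return DistributionSpec("gamma", (shape, sd ** 2 / base))

    # beta: mean = base, sd from the range; clip sd to keep the family valid
    m = base
    if m <= 0.0 or m >= 1.0:
        return DistributionSpec("point", (base,))
    var = min(sd ** 2, 0.97 * m * (1 - m))
    nu = m * (1 - m) / var - 1.0
    return DistributionSpec("beta", (m * nu, (1 - m) * nu))


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass
class PSADraw:
    index: int
    overrides: dict[str, float]
    delta_qaly: float
    delta_cost: float
    nmb: float

    @property
    def quadrant(self) -> str:
        if self.delta_qaly > 0 and self.delta_cost < 0:
            return "dominant"
        if self.delta_qaly < 0 and self.delta_cost > 0:
            return "dominated"
        return "trade_off_ne" if self.delta_qaly > 0 else "trade_off_sw"


@dataclass
class PSAResult:
    draws: list[PSADraw]
    wtp: float
    seed: int

    @property
    def n(self) -> int:
        return len(self.draws)

    @property
    def fraction_dominant(self) -> float:
        return sum(d.quadrant == "dominant" for d in self.draws) / self.n

    @property
    def fraction_cost_effective(self) -> float:
        return sum(d.nmb > 0 for d in self.draws) / self.n

    def summary(self) -> dict:
        de = np.array([d.delta_qaly for d in self.draws])
        dc = np.array([d.delta_cost for d in self.draws])
        nmb = np.array([d.nmb for d in self.draws])
        return {
            "n": self.n,
            "seed": self.seed,
            "wtp": self.wtp,
            "fraction_dominant": self.fraction_dominant,
            "fraction_cost_effective": self.fraction_cost_effective,
            "mean_delta_qaly": float(de.mean()),
            "mean_delta_cost": float(dc.mean()),
            "nmb_ci95": [float(np.percentile(nmb, 2.5)),
                         float(np.percentile(nmb, 97.5))],
        }

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("draw,delta_qaly,delta_cost,nmb,quadrant\n")
            for d in self.draws:
                fh.write(f"{d.index},{d.delta_qaly:.8f},{d.delta_cost:.4f},"
                         f"{d.nmb:.4f},{d.quadrant}\n")


def psa_distributions(params: ModelParameters) -> dict[str, DistributionSpec]:
    """Distributions for every parameter carrying a sensitivity range."""
    return {path: assign_distribution(path, p.value, p.low, p.high)
            for path, p in iter_params(params) if p.has_bounds}


def _draw_valid(overrides: dict[str, float]) -> bool:
    for path, v in overrides.items():
        leaf = path.rsplit(".", 1)[-1]
        if leaf.startswith("or_"):
            ok = v > 0
        elif path.startswith("costs.") or leaf.startswith(("n_", "heparin_days")):
            ok = v >= 0
        else:
            ok = 0.0 <= v <= 1.0
        if not ok:
            return False
    return True


def run_psa(params: ModelParameters, n: int = 2000,
            seed: int | None = None, wtp: float | None = None,
            max_retries: int = 100) -> PSAResult:
    """Monte-Carlo resampling of all uncertain parameters, jointly and
    independently, rerunning both arms per draw.  Reproducible given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lam = params.settings.wtp if wtp is None else wtp
    seed = params.settings.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    dists = psa_distributions(params)
    paths = sorted(dists)   # fixed sampling order for reproducibility

    samples = {p: dists[p].sample(rng, n) for p in paths}
    draws: list[PSADraw] = []
    retried = 0
    for i in range(n):
        overrides = {p: float(samples[p][i]) for p in paths}
        tries = 0
        while not _draw_valid(overrides):
            tries += 1
            if tries > max_retries:
                raise RuntimeError(f"draw {i}: no valid sample in "
                                   f"{max_retries} retries")
            overrides = {p: float(dists[p].sample(rng, 1)[0]) for p in paths}
        retried += tries
        model = MarkovCohortModel(with_params(params, overrides),
                                  validate=False)
        res = model.evaluate(wtp=lam)
        draws.append(PSADraw(index=i, overrides=overrides,
                             delta_qaly=res.delta_qaly,
                             delta_cost=res.delta_cost, nmb=res.nmb()))
    if retried:
        log.info("PSA: %d resamples due to invalid draws", retried)
    return PSAResult(draws=draws, wtp=lam, seed=seed)


def ceac(result: PSAResult, lambdas: np.ndarray) -> np.ndarray:
    """Cost-effectiveness acceptability curve: P(dE*lambda - dC > 0)."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0 or result.n == 0:
        raise ValueError("need non-empty draws and lambda grid")
    de = np.array([d.delta_qaly for d in result.draws])
    dc = np.array([d.delta_cost for d in result.draws])
    return (de[None, :] * lambdas[:, None] - dc[None, :] > 0).mean(axis=1)


def ceac_to_csv(lambdas, probs, path) -> None:
    with open(path, "w") as fh:
        fh.write("lambda,probability\n")
        for lam, p in zip(lambdas, probs):
            fh.write(f"{lam:.2f},{p:.6f}\n")
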