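"""Human-readable markdown report assembled from experiment output files."""

from __future__ import annotations

import json
from pathlib import Path

SUBGROUP_IDS = ("dvt_only", "pe_any", "pe_only", "pe_plus_dvt")


def _fmt_gbp(x: float) -> str:
    return f"£{x:,.0f}"


def _load(path: Path) -> dict | None:
    try:
        with open(path) as fh:
            return json.load(fh)
    except (OSError, json.JSONDecodeError):
        return None


def _ce_row(name: str, d: dict) -> str:
    icer = "Dominant" if d["status"] == "dominant" else (
        "Dominated" if d["status"] == "dominated" else _fmt_gbp(d["icer"]))
    return (f"| {name} | {d['delta_qaly']:.3f} | {_fmt_gbp(d['delta_cost'])} "
            f"| {icer} | {_fmt_gbp(d['nmb'])} |")


def render_report(results_dir: str | Path) -> str:
    """One markdown document: base case, subgroups, scenarios, tornado
    top-10 and PSA summary.  Missing pieces produce warnings, not errors."""
    root = Path(results_dir)
    lines = ["# Cost-effectiveness of edoxaban vs. warfarin for VTE", ""]
    warnings = []

    header = ("| Analysis | ΔQALY | ΔCost | ICER | NMB @ £20k |",
              "|---|---|---|---|---|")

    base = _load(root / "base" / "result.json")
    lines += ["## Base case", ""]
    if base:
        lines += [*header, _ce_row("Base case", base), ""]
    else:
        warnings.append("base-case results missing")

    rows = [(sg, _load(root / sg / "result.json")) for sg in SUBGROUP_IDS]
    if any(d for _, d in rows):
        lines += ["## Subgroups (index event)", "", *header]
        for sg, d in rows:
            if d:
                lines.append(_ce_row(sg, d))
            else:
                warnings.append(f"subgroup {sg} missing")
        lines.append("")

    scen = [(s, _load(root / s / "result.json"))
            for s in ("or_nonsig_to_one", "horizon_1y", "horizon_5y")]
    if any(d for _, d in scen):
        lines += ["## Scenarios", "", *header]
        for s, d in scen:
            if d:
                lines.append(_ce_row(s, d))
            else:
                warnings.append(f"scenario {s} missing")
        lines.append("")

    tornado = root / "tornado.csv"
    if tornado.exists():
        lines += ["## One-way sensitivity (top 10 by NMB span)", "",
                  "| Parameter | NMB low | NMB high | Span |", "|---|---|---|---|"]
        with open(tornado) as fh:
            next(fh)
            for i, line in enumerate(fh):
                if i >= 10:
                    break
                p, lo, hi, nlo, nhi, span = line.strip().split(",")
                lines.append(f"| {p} | {_fmt_gbp(float(nlo))} | "
                             f"{_fmt_gbp(float(nhi))} | {_fmt_gbp(float(span))} |")
        lines.append("")
    else:
        warnings.append("tornado.csv missing")

    psa = _load(root / "psa_summary.json")
    if psa:
        lines += ["## Probabilistic sensitivity analysis", "",
                  f"- draws: {psa['n']} (seed {psa['seed']})",
                  f"- dominant (more QALYs, lower cost): "
                  f"{100 * psa['fraction_dominant']:.1f}%",
                  f"- cost-effective at £{psa['wtp']:,.0f}/QALY: "
                  f"{100 * psa['fraction_cost_effective']:.1f}%",
                  f"- NMB 95% CI: {_fmt_gbp(psa['nmb_ci95'][0])} to "
                  f"{_fmt_gbp(psa['nmb_ci95'][1])}", ""]
    else:
        warnings.append("psa_summary.json missing")

    if warnings:
        lines += ["## Warnings", ""] + [f"- {w}" for w in warnings] + [""]
    return "\n".join(lines)
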