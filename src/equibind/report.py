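"""The Equilibrium Binding Checklist as a machine-readable report.

A reported K_D is only an equilibrium constant when the supporting
controls say so. ``build_checklist`` turns fit results and control
verdicts into a structured pass/fail/not-done record and gates the final
K_D on it: the value is reported as an equality only when both the
equilibration and titration controls passed; otherwise it is downgraded
to an explicit bound (a hyperbolic fit under titration, or an
un-equilibrated incubation, can only set an upper limit on the true K_D).
The apparent K_D is multiplied by the active protein fraction when one
was determined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .diagnose import ControlVerdict, RegimeAssessment
from .fit import ActiveFractionResult, FitResult

__all__ = ["CHECKLIST_ITEMS", "ChecklistItem", "ChecklistReport",
           "build_checklist", "render_report"]

#: the required-control item set, in report order
CHECKLIST_ITEMS = (
    ("time-varied",
     "Incubation time varied (>= 10-fold span) to demonstrate equilibration?"),
    ("titration-varied",
     "Limiting-species concentration varied to rule out titration?"),
    ("regime-classified",
     "Concentration regime (binding/intermediate/titration) classified?"),
    ("model-stated",
     "Binding model and fitted equation stated?"),
    ("fit-quality",
     "Fit quality over the full concentration range assessed?"),
    ("independent-approach",
     "K_D cross-checked by an independent approach?"),
    ("active-fraction",
     "Active protein fraction determined and disclosed?"),
    ("conditions-recorded",
     "Conditions (temperature, buffer, salt, pH) recorded?"),
    ("molar-units",
     "All concentrations reported in molar units?"),
)

_STATUSES = ("pass", "fail", "not-done", "n/a")


@dataclass(frozen=True)
class ChecklistItem:
    item_id: str
    question: str
    status: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"invalid status {self.status!r}")


@dataclass
class ChecklistReport:
    """Structured record of a binding-measurement campaign."""

    items: list
    metadata: dict
    kd_final: float | None = None
    kd_qualifier: str = "="        # "=", "<=" or ">="
    kd_ci95: tuple | None = None
    kd_reason: str = ""
    active_fraction: float | None = None
    regime: str | None = None

    def status(self, item_id: str) -> str:
        for it in self.items:
            if it.item_id == item_id:
                return it.status
        raise KeyError(item_id)

    @property
    def validated(self) -> bool:
        return (self.status("time-varied") == "pass"
                and self.status("titration-varied") == "pass")

    def to_dict(self) -> dict:
        d = {
            "schema": "equilibrium-binding-checklist/1",
            "metadata": dict(self.metadata),
            "items": [
                {"item_id": it.item_id, "question": it.question,
                 "status": it.status,
                 **({"evidence": it.evidence} if it.evidence else {})}
                for it in self.items
            ],
            "kd": {
                "qualifier": self.kd_qualifier,
                "value_M": self.kd_final,
                **({"ci95_M": list(self.kd_ci95)} if self.kd_ci95 else {}),
                **({"reason": self.kd_reason} if self.kd_reason else {}),
            },
        }
        if self.active_fraction is not None:
            d["active_fraction"] = self.active_fraction
        if self.regime is not None:
            d["regime"] = self.regime
        return d


def _verdict_status(verdict: ControlVerdict | None) -> tuple[str, str]:
    if verdict is None:
        return "not-done", ""
    note = "; ".join(verdict.messages)
    if verdict.status == "pass":
        return "pass", note
    if verdict.status == "fail":
        return "fail", note
    # insufficient-design cannot certify the control
    return "fail", ("design insufficient" + (": " + note if note else ""))


def build_checklist(fits, verdicts, metadata: dict,
                    regime: RegimeAssessment | None = None,
                    active_fraction: ActiveFractionResult | float | None = None,
                    primary: FitResult | None = None) -> ChecklistReport:
    """Assemble the checklist from fits, control verdicts and metadata.

    ``fits`` is a non-empty list of FitResult (the first converged one is
    the primary K_D route unless ``primary`` is given); ``verdicts`` holds
    at most one ControlVerdict per control. Duplicate verdicts for the
    same control with conflicting statuses are a validation error.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("at least one FitResult is required")

    by_control: dict[str, ControlVerdict] = {}
    conflicts = []
    for v in verdicts:
        if v.control in by_control and by_control[v.control].status != v.status:
            conflicts.append(
                f"{v.control}: {by_control[v.control].status} vs {v.status}")
        by_control.setdefault(v.control, v)
    if conflicts:
        raise ValueError("conflicting duplicate evidence: "
                         + "; ".join(conflicts))

    if primary is None:
        primary = next((f for f in fits if f.converged), fits[0])

    f_active = None
    if isinstance(active_fraction, ActiveFractionResult):
        f_active = active_fraction.active_fraction
    elif active_fraction is not None:
        f_active = float(active_fraction)

    eq_status, eq_note = _verdict_status(by_control.get("equilibration"))
    ti_status, ti_note = _verdict_status(by_control.get("titration"))

    statuses = {
        "time-varied": (eq_status, eq_note),
        "titration-varied": (ti_status, ti_note),
        "regime-classified": (
            ("fail", f"titration regime (excess {regime.excess_ratio:.3g})")
            if regime is not None and regime.regime == "titration"
            else ("pass", f"{regime.regime} regime "
                          f"(excess {regime.excess_ratio:.3g})")
            if regime is not None else ("not-done", "")),
        "model-stated": ("pass", "model: "
                         + ", ".join(sorted({f.model_id for f in fits}))),
        "fit-quality": (
            ("pass", f"primary fit converged, {primary.identifiability}")
            if primary.converged and primary.identifiability == "well-defined"
            else ("fail", f"primary fit: converged={primary.converged}, "
                          f"{primary.identifiability}")),
        "independent-approach": _independent_check(fits),
        "active-fraction": (
            ("pass", f"active fraction {f_active:.3g}")
            if f_active is not None else ("not-done", "")),
        "conditions-recorded": (
            ("pass", "") if all(k in metadata
                                for k in ("temperature", "buffer"))
            else ("fail", "temperature and buffer description required")),
        "molar-units": ("pass", "all concentrations handled in molar (M)"),
    }
    items = [ChecklistItem(item_id=i, question=q, status=statuses[i][0],
                           evidence=statuses[i][1])
             for i, q in CHECKLIST_ITEMS]

    kd_app = primary.estimates.get("kd")
    report = ChecklistReport(items=items, metadata=dict(metadata),
                             regime=regime.regime if regime else None,
                             active_fraction=f_active)
    if kd_app is None or not math.isfinite(kd_app):
        report.kd_final = None
        report.kd_qualifier = "="
        report.kd_reason = "no usable K_D estimate"
        return report

    corr = f_active if f_active is not None else 1.0
    kd_final = kd_app * corr
    ci = primary.ci95.get("kd")
    ci = (tuple(c * corr for c in ci)
          if ci and all(math.isfinite(c) for c in ci) else None)
    report.kd_final = kd_final
    report.kd_ci95 = ci
    if eq_status == "pass" and ti_status == "pass":
        report.kd_qualifier = "="
        report.kd_reason = ("validated equilibrium constant"
                            + ("" if f_active is None
                               else f"; corrected by active fraction {corr:g}"))
    else:
        # an un-equilibrated or titration-limited apparent K_D can only
        # bound the true affinity from above
        report.kd_qualifier = "<="
        reasons = []
        if eq_status != "pass":
            reasons.append(f"equilibration control: {eq_status}")
        if ti_status != "pass":
            reasons.append(f"titration control: {ti_status}")
        report.kd_reason = ("upper limit only (" + "; ".join(reasons) + ")")
    return report


def _independent_check(fits) -> tuple[str, str]:
    routes = {f.model_id for f in fits if f.converged}
    kinetic = {"exponential", "linear"} & routes
    equilibrium = {"hyperbolic", "quadratic", "competition"} & routes
    if kinetic and equilibrium:
        return "pass", ("independent routes: "
                        + ", ".join(sorted(kinetic | equilibrium)))
    if len(routes) >= 2:
        return "pass", "multiple models: " + ", ".join(sorted(routes))
    return "not-done", ""


def render_report(report: ChecklistReport, format: str = "json") -> str:
    """Render a checklist report as lossless JSON or readable markdown/text."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=False)
    if format in ("markdown", "text"):
        d = report.to_dict()
        lines = ["# Equilibrium Binding Checklist", ""]
        for k, v in d["metadata"].items():
            lines.append(f"- {k}: {v}")
        lines.append("")
        lines.append("| item | status | evidence |")
        lines.append("|---|---|---|")
        for it in d["items"]:
            lines.append(f"| {it['question']} | {it['status'].upper()} | "
                         f"{it.get('evidence', '')} |")
        lines.append("")
        kd = d["kd"]
        if kd["value_M"] is not None:
            lines.append(f"**K_D {kd['qualifier']} {kd['value_M']:.3g} M**"
                         + (f" ({kd['reason']})" if kd.get("reason") else ""))
        fails = [it for it in d["items"] if it["status"] == "fail"]
        if fails:
            lines.append("")
            lines.append("## Warnings")
            for it in fails:
                lines.append(f"- FAILED: {it['question']}"
                             + (f" — {it['evidence']}"
                                if it.get("evidence") else ""))
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")
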