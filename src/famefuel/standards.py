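"""Fuel-standard compliance evaluation.

Compares a computed property record against configurable fuel-quality
standards. Two standards ship with the package as YAML configs: the
European biodiesel standard EN 14214 (IV ≤ 120, CN ≥ 51, OS ≥ 6 h, plus a
climate-class CFPP range) and the US ASTM D6751-02 (CN ≥ 47, OS ≥ 3 h).
The CFPP entry of EN 14214 is a national climate-class choice, not a
single limit, so it ships as an *informational* criterion: reported, but
never counted in the overall verdict unless a user configures a concrete
limit.

Boundary comparisons are inclusive (a value exactly at a ≤/≥ limit
passes). A criterion whose property is undefined for the given profile
(e.g. OS for an all-saturated feedstock) is reported ``not-evaluated``
and makes the overall verdict ``not-evaluated`` — fail-safe, never a
silent pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .properties import BiodieselProperties

__all__ = [
    "Criterion",
    "FuelStandard",
    "Verdict",
    "ComplianceReport",
    "evaluate",
    "load_standard",
    "bundled_standards",
]

PASS = "pass"
FAIL = "fail"
NOT_EVALUATED = "not-evaluated"

_BOUND_KINDS = {"min", "max", "range", "informational"}

#: report-level property names accepted in standards configs
_PROPERTY_FIELDS = {
    "sv", "iv", "du", "sfa_percent", "mufa_percent", "pufa_percent",
    "lcsf", "cfpp", "cfpp_cascade", "cn", "os_hours", "x_linoleic_linolenic",
}


@dataclass(frozen=True)
class Criterion:
    """One limit of a fuel standard.

    ``bound`` is ``min``, ``max``, ``range`` or ``informational``; a range
    (and an informational range) carries ``(lo, hi)`` in ``threshold``.
    Informational criteria are evaluated and reported but never affect
    the overall verdict.
    """

    property: str
    bound: str
    threshold: float | tuple[float, float] | None
    units: str = ""

    def __post_init__(self) -> None:
        if self.property not in _PROPERTY_FIELDS:
            raise ValueError(f"unknown property {self.property!r} in standard")
        if self.bound not in _BOUND_KINDS:
            raise ValueError(f"unknown bound kind {self.bound!r}")


@dataclass(frozen=True)
class FuelStandard:
    name: str
    criteria: tuple[Criterion, ...]


@dataclass(frozen=True)
class Verdict:
    property: str
    verdict: str
    detail: str


@dataclass
class ComplianceReport:
    standard: str
    verdicts: list[Verdict] = field(default_factory=list)

    @property
    def overall(self) -> str:
        """``pass`` iff every non-informational criterion passed;
        ``not-evaluated`` if any could not be evaluated; else ``fail``."""
        effective = [v for v in self.verdicts if not v.detail.startswith("informational")]
        if any(v.verdict == NOT_EVALUATED for v in effective):
            return NOT_EVALUATED
        if any(v.verdict == FAIL for v in effective):
            return FAIL
        return PASS

    def verdict_for(self, prop: str) -> str:
        for v in self.verdicts:
            if v.property == prop:
                return v.verdict
        raise KeyError(prop)

    def to_dict(self) -> dict:
        return {
            "standard": self.standard,
            "overall": self.overall,
            "verdicts": [asdict(v) for v in self.verdicts],
        }


def _check(value: float, crit: Criterion) -> bool:
    if crit.bound == "min":
        return value >= float(crit.threshold)  # inclusive
    if crit.bound == "max":
        return value <= float(crit.threshold)
    lo, hi = crit.threshold  # range / informational range
    return lo <= value <= hi


def evaluate(properties: BiodieselProperties, standard: FuelStandard) -> ComplianceReport:
    """Evaluate every criterion of ``standard`` against one record."""
    report = ComplianceReport(standard=standard.name)
    for crit in standard.criteria:
        value = getattr(properties, crit.property)
        prefix = "informational: " if crit.bound == "informational" else ""
        if value is None:
            report.verdicts.append(Verdict(
                crit.property, NOT_EVALUATED,
                f"{prefix}property undefined for this profile"))
            continue
        if crit.bound == "informational" and crit.threshold is None:
            report.verdicts.append(Verdict(
                crit.property, PASS, f"informational: value {value:g} (no limit)"))
            continue
        ok = _check(value, crit)
        detail = f"{prefix}value {value:g} vs {crit.bound} {crit.threshold}"
        report.verdicts.append(Verdict(crit.property, PASS if ok else FAIL, detail))
    return report


# ---------------------------------------------------------------------------
# Config loading

def _criterion_from_config(entry: dict) -> Criterion:
    threshold = entry.get("threshold")
    if isinstance(threshold, (list, tuple)):
        threshold = (float(threshold[0]), float(threshold[1]))
    elif threshold is not None:
        threshold = float(threshold)
    return Criterion(
        property=entry["property"],
        bound=entry["bound"],
        threshold=threshold,
        units=entry.get("units", ""),
    )


def load_standard(source: str | Path | dict) -> FuelStandard:
    """Load a fuel standard from a YAML file (or pre-parsed mapping)."""
    if isinstance(source, dict):
        cfg = source
    else:
        cfg = yaml.safe_load(Path(source).read_text())
    return FuelStandard(
        name=cfg["name"],
        criteria=tuple(_criterion_from_config(e) for e in cfg["criteria"]),
    )


def bundled_standards() -> dict[str, FuelStandard]:
    """The standards shipped with the package, keyed by short name."""
    out: dict[str, FuelStandard] = {}
    pkg = resources.files("famefuel").joinpath("data")
    for res in pkg.iterdir():
        if res.name.endswith(".yaml"):
            std = load_standard(yaml.safe_load(res.read_text()))
            out[std.name] = std
    return out


def get_standard(name: str) -> FuelStandard:
    """Look up a bundled standard by name (case/punctuation-insensitive)."""
    stds = bundled_standards()
    if name in stds:
        return stds[name]
    norm = name.replace(" ", "").replace("-", "").lower()
    for key, std in stds.items():
        if key.replace(" ", "").replace("-", "").lower() == norm:
            return std
    raise KeyError(f"no bundled standard named {name!r}; available: {sorted(stds)}")
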