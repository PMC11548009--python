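"""FAME composition tables: the pipeline's entry format.

A profile is an ordered list of (fatty acid, mass % of total FAMEs) pairs,
as produced by GC-MS FAME quantification. Percentages are used as given —
no renormalisation to 100 unless explicitly requested — because published
profiles are routinely reported with rounding so that totals land slightly
off 100 (e.g. 100.04), and the downstream empirical correlations were
applied to the printed values.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import pandas as pd

from .registry import FattyAcid, parse_shorthand

if TYPE_CHECKING:  # pragma: no cover
    from .properties import BiodieselProperties
    from .standards import ComplianceReport

__all__ = ["FameProfile", "ProfileError", "read_profile", "write_report", "read_report"]

#: Tolerance above 100% allowed for rounding in published tables.
TOTAL_UPPER = 100.5
#: Below this total the profile is flagged as partial (but accepted).
TOTAL_PARTIAL = 95.0

_CLASS_TOTAL_RE = re.compile(r"^\s*total\b", re.IGNORECASE)

_FA_COLUMN_ALIASES = {"fatty_acid", "fatty acid", "component", "fame", "acid"}
_PCT_COLUMN_ALIASES = {"mass_percent", "mass percent", "content (%)", "content",
                       "percent", "%", "mass %", "area %"}


class ProfileError(ValueError):
    """A FAME table violates the compositional contract."""


@dataclass
class FameProfile:
    """An ordered FAME composition with validation on construction.

    Parameters
    ----------
    components : sequence of (FattyAcid, mass_percent) pairs. Percentages
        are of total FAMEs (symbol N in the property formulas).
    source_id : free-text sample or strain identifier.
    partial : set automatically when the total falls below 95%.
    renormalized_by : factor recorded when :meth:`renormalize` was applied.
    """

    components: list[tuple[FattyAcid, float]]
    source_id: str = ""
    partial: bool = field(default=False)
    renormalized_by: float | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, str]] = set()
        for fa, pct in self.components:
            if pct < 0:
                raise ProfileError(f"negative mass percent {pct} for {fa.label}")
            if fa.key in seen:
                raise ProfileError(f"duplicate fatty-acid key {fa.label}")
            seen.add(fa.key)
        total = self.total_percent
        if total > TOTAL_UPPER:
            raise ProfileError(
                f"component total {total:.2f}% exceeds {TOTAL_UPPER}%"
            )
        if total < TOTAL_PARTIAL:
            self.partial = True

    @property
    def total_percent(self) -> float:
        return float(sum(pct for _, pct in self.components))

    def __len__(self) -> int:
        return len(self.components)

    def percent_of(self, n_carbons: int, n_double_bonds: int) -> float:
        """Total mass % of components with the given chain/double-bond count,
        summed across ω-classes."""
        return float(sum(
            pct for fa, pct in self.components
            if fa.n_carbons == n_carbons and fa.n_double_bonds == n_double_bonds
        ))

    def renormalize(self) -> "FameProfile":
        """Return a copy scaled so components sum to exactly 100%.

        The applied factor is recorded in ``renormalized_by``. Opt-in:
        the default pipeline uses percentages as printed.
        """
        total = self.total_percent
        if total <= 0:
            raise ProfileError("cannot renormalize an empty or zero-total profile")
        factor = 100.0 / total
        return FameProfile(
            components=[(fa, pct * factor) for fa, pct in self.components],
            source_id=self.source_id,
            renormalized_by=factor,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fatty_acid": [fa.label for fa, _ in self.components],
                "mass_percent": [pct for _, pct in self.components],
            }
        )


def _find_column(columns: Sequence[str], aliases: set[str], what: str) -> str:
    for col in columns:
        if str(col).strip().lower() in aliases:
            return col
    raise ProfileError(f"no {what} column found among {list(columns)!r}")


def read_profile(source: str | Path | io.TextIOBase, source_id: str = "",
                 sep: str | None = None) -> FameProfile:
    """Read a delimited FAME table into a validated :class:`FameProfile`.

    Expects a header naming a fatty-acid column (``fatty_acid`` or
    ``Component``) and a mass-percent column (``mass_percent`` or
    ``Content (%)``). The delimiter is sniffed among comma, tab and
    semicolon unless given. Rows whose label starts with "Total"
    (published class-total rows) are excluded from the components and
    cross-checked against the recomputed class sums; a mismatch beyond
    0.5 percentage points raises :class:`ProfileError`.
    """
    df = pd.read_csv(source, sep=sep, engine="python", comment="#",
                     skip_blank_lines=True)
    fa_col = _find_column(df.columns, _FA_COLUMN_ALIASES, "fatty-acid")
    pct_col = _find_column(df.columns, _PCT_COLUMN_ALIASES, "mass-percent")

    components: list[tuple[FattyAcid, float]] = []
    stated_totals: list[tuple[str, float]] = []
    for _, row in df.iterrows():
        label = str(row[fa_col]).strip()
        if not label or label.lower() == "nan":
            continue
        pct = float(row[pct_col])
        if _CLASS_TOTAL_RE.match(label):
            stated_totals.append((label.lower(), pct))
            continue
        components.append((parse_shorthand(label), pct))

    profile = FameProfile(components=components, source_id=source_id)
    _crosscheck_class_totals(profile, stated_totals)
    return profile


def _crosscheck_class_totals(profile: FameProfile,
                             stated: list[tuple[str, float]]) -> None:
    from .properties import class_percents  # local import to avoid a cycle

    if not stated:
        return
    sfa, mufa, pufa = class_percents(profile)
    # order matters: "saturated" is a substring of the other two class names
    computed = [("monounsaturated", mufa), ("polyunsaturated", pufa),
                ("saturated", sfa)]
    for label, value in stated:
        for key, ours in computed:
            if key in label:
                if abs(ours - value) > 0.5:
                    raise ProfileError(
                        f"stated class total {label!r} = {value} disagrees with "
                        f"recomputed {ours:.2f}"
                    )
                break


# ---------------------------------------------------------------------------
# Structured pipeline reports

def write_report(path: str | Path, profile: FameProfile,
                 properties: "BiodieselProperties | None" = None,
                 compliance: "Sequence[ComplianceReport] | ComplianceReport | None" = None,
                 ) -> dict:
    """Write a machine-readable JSON report of one pipeline run.

    Floats are serialised via ``repr`` round-trip semantics, so re-reading
    the report reproduces every value bit-identically. The compliance
    block is omitted entirely when no standard was evaluated. Returns the
    document that was written.
    """
    from .standards import ComplianceReport as _CR

    doc: dict = {
        "schema": "famefuel/report/1",
        "source_id": profile.source_id,
        "profile": {
            "components": [
                {"fatty_acid": fa.label, "n_carbons": fa.n_carbons,
                 "n_double_bonds": fa.n_double_bonds, "omega_class": fa.omega_class,
                 "molar_mass": fa.molar_mass, "mass_percent": pct}
                for fa, pct in profile.components
            ],
            "total_percent": profile.total_percent,
            "partial": profile.partial,
            "renormalized_by": profile.renormalized_by,
        },
    }
    if properties is not None:
        doc["properties"] = properties.to_dict()
    if compliance is not None:
        reports = [compliance] if isinstance(compliance, _CR) else list(compliance)
        if reports:
            doc["compliance"] = [r.to_dict() for r in reports]
    Path(path).write_text(json.dumps(doc, indent=2, ensure_ascii=False))
    return doc


def read_report(path: str | Path) -> dict:
    """Read a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())


def report_table(doc: dict) -> str:
    """Human-readable rendering of a report document."""
    lines = [f"Sample: {doc.get('source_id') or '(unnamed)'}"]
    prof = pd.DataFrame(doc["profile"]["components"])
    lines.append(prof[["fatty_acid", "mass_percent"]].to_string(index=False))
    lines.append(f"Total: {doc['profile']['total_percent']:.2f} %")
    if "properties" in doc:
        props = pd.Series(doc["properties"], name="value")
        lines.append("")
        lines.append(props.to_string())
    for block in doc.get("compliance", []):
        lines.append("")
        lines.append(f"Standard {block['standard']}: {block['overall']}")
        for v in block["verdicts"]:
            lines.append(f"  {v['property']:>12} {v['verdict']:<14} ({v['detail']})")
    return "\n".join(lines)
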