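"""Fatty-acid identity resolution.

Maps free-text fatty-acid labels in lipidomics shorthand ("C16:0",
"C18:3 n-3", "α-linolenic acid (C18:3 n-3)") to a chemical identity:
carbon count, double-bond count, ω-class and molar mass. Downstream
empirical fuel-property formulas consume these as their N/M/D symbols.

Molar masses are those of the *free fatty acid* (formula C_n H_{2n-2d} O_2),
not the methyl ester; the empirical property correlations used here were
calibrated on that convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "FattyAcid",
    "parse_shorthand",
    "molar_mass",
    "ShorthandError",
    "builtin_registry",
    "load_registry",
]

# Standard atomic masses, g/mol
_MASS_C = 12.011
_MASS_H = 1.008
_MASS_O = 15.999

SATURATED = "saturated"
UNKNOWN = "unknown"
_OMEGA_CLASSES = {"n-3": "n-3", "n-6": "n-6", "n-9": "n-9"}


class ShorthandError(ValueError):
    """A fatty-acid label could not be resolved to a chemical identity."""


@dataclass(frozen=True)
class FattyAcid:
    """Chemical identity of one FAME component (as the free acid).

    Attributes
    ----------
    n_carbons : total carbon count of the acyl chain.
    n_double_bonds : number of C=C double bonds (symbol D).
    omega_class : "n-3", "n-6", "n-9", "saturated", or "unknown".
        Taken from the label suffix only — double-bond positions are
        never inferred.
    molar_mass : g/mol of the free fatty acid (symbol M).
    trivial_name : common name if known (e.g. "palmitic acid").
    """

    n_carbons: int
    n_double_bonds: int
    omega_class: str = UNKNOWN
    trivial_name: str | None = None
    molar_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        n, d = self.n_carbons, self.n_double_bonds
        if n < 2:
            raise ShorthandError(f"chain length {n} below the C2 minimum")
        if d < 0 or d > (n - 2) // 2:
            raise ShorthandError(
                f"C{n}:{d} exceeds the chemical maximum of {(n - 2) // 2} "
                f"double bonds for a C{n} chain"
            )
        if d == 0:
            object.__setattr__(self, "omega_class", SATURATED)
        elif self.omega_class not in _OMEGA_CLASSES:
            # unsaturated with no (or a non-3/6/9) suffix
            object.__setattr__(self, "omega_class", UNKNOWN)
        if self.molar_mass == 0.0:
            object.__setattr__(self, "molar_mass", molar_mass((n, d)))

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.n_carbons, self.n_double_bonds, self.omega_class)

    @property
    def label(self) -> str:
        """Canonical shorthand, e.g. ``C18:3 n-3``."""
        base = f"C{self.n_carbons}:{self.n_double_bonds}"
        if self.omega_class in _OMEGA_CLASSES:
            return f"{base} {self.omega_class}"
        return base


def molar_mass(key: tuple[int, int]) -> float:
    """Molar mass (g/mol) of the free fatty acid C_n H_{2n-2d} O_2.

    >>> round(molar_mass((16, 0)), 2)
    256.43
    """
    n, d = key
    if n < 2 or d < 0 or d > (n - 2) // 2:
        raise ShorthandError(f"({n}, {d}) is not a chemically valid fatty-acid key")
    return n * _MASS_C + (2 * n - 2 * d) * _MASS_H + 2 * _MASS_O


# Label grammar: an optional trivial-name prefix, then the chain spec
# "C16:0" / "18:3" possibly parenthesised, then an optional ω suffix
# "n-3" / "n3" / "(n-3)" / "ω-3".
_CHAIN_RE = re.compile(r"[Cc]?\s*(\d{1,2})\s*:\s*(\d{1,2})")
_OMEGA_RE = re.compile(r"[(\s]*(?:n|ω|omega)\s*[-–]?\s*(\d{1,2})[)\s]*", re.IGNORECASE)


def parse_shorthand(label: str) -> FattyAcid:
    """Resolve a free-text fatty-acid label to a :class:`FattyAcid`.

    Accepted dialects include ``C16:0``, ``C18:1 n-9``, ``C18:1n9``,
    ``18:3 (n-3)`` and any of these with a trivial-name prefix such as
    ``"Palmitic acid (C16:0)"``.

    Raises
    ------
    ShorthandError
        If no chain token is found, or the double-bond count exceeds the
        chemical maximum for the chain length.
    """
    if not label or not label.strip():
        raise ShorthandError("empty fatty-acid label")
    m = _CHAIN_RE.search(label)
    if m is None:
        raise ShorthandError(f"no Cn:d chain token found in label {label!r}")
    n, d = int(m.group(1)), int(m.group(2))

    omega = SATURATED if d == 0 else UNKNOWN
    if d > 0:
        om = _OMEGA_RE.search(label, m.end())
        if om is not None:
            omega = _OMEGA_CLASSES.get(f"n-{om.group(1)}", UNKNOWN)

    trivial = label[: m.start()].strip(" (,-–")
    trivial = trivial if trivial else None
    fa = FattyAcid(n, d, omega, trivial_name=trivial)

    # prefer registry entry (carries the curated trivial name)
    entry = builtin_registry().get(fa.key)
    if entry is not None and trivial is None:
        return entry
    return fa


_BUILTIN: dict[tuple[int, int, str], FattyAcid] | None = None

# Acids named in the source profile plus the C20–C24 saturates the
# long-chain saturation factor weights.
_BUILTIN_ROWS: list[tuple[int, int, str, str]] = [
    (16, 0, SATURATED, "palmitic acid"),
    (18, 0, SATURATED, "stearic acid"),
    (18, 1, "n-9", "oleic acid"),
    (18, 2, "n-6", "linoleic acid"),
    (18, 3, "n-3", "α-linolenic acid"),
    (18, 3, "n-6", "γ-linolenic acid"),
    (20, 0, SATURATED, "arachidic acid"),
    (22, 0, SATURATED, "behenic acid"),
    (24, 0, SATURATED, "lignoceric acid"),
]


def builtin_registry() -> dict[tuple[int, int, str], FattyAcid]:
    """The shipped registry of named fatty acids, keyed by (n, d, ω-class)."""
    global _BUILTIN
    if _BUILTIN is None:
        _BUILTIN = {}
        for n, d, omega, name in _BUILTIN_ROWS:
            fa = FattyAcid(n, d, omega, trivial_name=name)
            _BUILTIN[fa.key] = fa
    return _BUILTIN


def load_registry(path: str | Path) -> dict[tuple[int, int, str], FattyAcid]:
    """Load a user registry overlaying the built-in one.

    One record per non-blank, non-``#`` line:
    ``label, n_carbons, n_double_bonds, omega, [molar_mass]``.
    An explicit molar mass overrides the computed free-acid mass.
    """
    registry = dict(builtin_registry())
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) not in (4, 5):
            raise ShorthandError(
                f"{path}:{lineno}: expected 4 or 5 comma-separated fields, got {len(parts)}"
            )
        label, n_s, d_s, omega = parts[:4]
        mass = float(parts[4]) if len(parts) == 5 else 0.0
        fa = FattyAcid(int(n_s), int(d_s), omega, trivial_name=label or None,
                       molar_mass=mass)
        registry[fa.key] = fa
    return registry


def resolve_all(labels: Iterable[str]) -> list[FattyAcid]:
    """Parse a sequence of labels, reporting every failure at once."""
    out, errors = [], []
    for lab in labels:
        try:
            out.append(parse_shorthand(lab))
        except ShorthandError as exc:
            errors.append(str(exc))
    if errors:
        raise ShorthandError("; ".join(errors))
    return out
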