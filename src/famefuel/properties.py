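"""Empirical biodiesel property suite computed from a FAME profile.

Nine quantities routinely used to screen oil feedstocks, all estimated
from composition alone via published empirical correlations:

* saponification value         SV  = Σ 560·Nᵢ/Mᵢ                (mg KOH/g)
* iodine value                 IV  = Σ 254·Dᵢ·Nᵢ/Mᵢ             (g I₂/100 g)
* class totals                 SFA/MUFA/PUFA mass-% by double-bond count
* degree of unsaturation       DU  = MUFA + 2·PUFA
* long-chain saturation factor LCSF = 0.1·C16:0 + 0.5·C18:0 + C20:0
                                      + 1.5·C22:0 + 2·C24:0
* cold filter plugging point   CFPP = 3.1417·LCSF − 16.477      (°C)
* cetane number                CN  = 46.3 + 5458/SV − 0.225·IV
* oxidative stability          OS  = 117.9295/X + 2.5905        (h),
                               X = C18:2 + C18:3 mass share

Nᵢ is the mass % of component i, Mᵢ its free-fatty-acid molar mass and
Dᵢ its double-bond count. OS is undefined (not zero) when X = 0.

Published property tables often apply the CFPP correlation to an LCSF
already rounded to two decimals; the record therefore carries both the
full-precision CFPP and the rounded-cascade value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .profiles import FameProfile, ProfileError

__all__ = [
    "BiodieselProperties",
    "saponification_value",
    "iodine_value",
    "class_percents",
    "degree_of_unsaturation",
    "long_chain_saturation_factor",
    "cold_filter_plugging_point",
    "cetane_number",
    "oxidative_stability",
    "compute_all",
]

#: LCSF weights per saturated chain length; absent components contribute 0.
LCSF_WEIGHTS = {16: 0.1, 18: 0.5, 20: 1.0, 22: 1.5, 24: 2.0}

CFPP_SLOPE = 3.1417
CFPP_INTERCEPT = -16.477


@dataclass(frozen=True)
class BiodieselProperties:
    """One feedstock's nine-quantity property record.

    ``os_hours`` is ``None`` when the profile contains no C18:2/C18:3
    (the OS correlation is undefined there). ``cfpp_cascade`` is the
    CFPP computed from LCSF rounded to 2 decimals, matching the rounding
    convention of published comparison tables; ``cfpp`` is full precision.
    """

    sv: float
    iv: float
    du: float
    sfa_percent: float
    mufa_percent: float
    pufa_percent: float
    lcsf: float
    cfpp: float
    cfpp_cascade: float
    cn: float
    os_hours: float | None
    x_linoleic_linolenic: float

    def to_dict(self) -> dict:
        return asdict(self)


def _require_nonempty(profile: FameProfile) -> None:
    if len(profile) == 0:
        raise ProfileError("property computation requires a non-empty profile")


def saponification_value(profile: FameProfile) -> float:
    """SV in mg KOH/g: Σ 560·Nᵢ/Mᵢ over components."""
    _require_nonempty(profile)
    return sum(560.0 * pct / fa.molar_mass for fa, pct in profile.components)


def iodine_value(profile: FameProfile) -> float:
    """IV in g I₂/100 g: Σ 254·Dᵢ·Nᵢ/Mᵢ over components."""
    _require_nonempty(profile)
    return sum(254.0 * fa.n_double_bonds * pct / fa.molar_mass
               for fa, pct in profile.components)


def class_percents(profile: FameProfile) -> tuple[float, float, float]:
    """(SFA %, MUFA %, PUFA %) as mass-percent sums by double-bond count
    (0 / 1 / ≥2)."""
    sfa = mufa = pufa = 0.0
    for fa, pct in profile.components:
        if fa.n_double_bonds == 0:
            sfa += pct
        elif fa.n_double_bonds == 1:
            mufa += pct
        else:
            pufa += pct
    return sfa, mufa, pufa


def degree_of_unsaturation(mufa_percent: float, pufa_percent: float) -> float:
    """DU = MUFA + 2·PUFA (mass-percent weighted double-bond index)."""
    if mufa_percent < 0 or pufa_percent < 0:
        raise ValueError("class percents must be non-negative")
    return mufa_percent + 2.0 * pufa_percent


def long_chain_saturation_factor(profile: FameProfile) -> float:
    """LCSF from the C16–C24 saturate contents; absent chains contribute 0."""
    _require_nonempty(profile)
    return sum(
        weight * profile.percent_of(n, 0) for n, weight in LCSF_WEIGHTS.items()
    )


def cold_filter_plugging_point(lcsf: float) -> float:
    """CFPP (°C) from the linear LCSF correlation."""
    if lcsf < 0:
        raise ValueError("LCSF must be non-negative")
    return CFPP_SLOPE * lcsf + CFPP_INTERCEPT


def cetane_number(sv: float, iv: float) -> float:
    """CN = 46.3 + 5458/SV − 0.225·IV."""
    if sv <= 0:
        raise ValueError("cetane number requires SV > 0")
    return 46.3 + 5458.0 / sv - 0.225 * iv


def oxidative_stability(profile: FameProfile) -> float | None:
    """OS induction time (h) from X = C18:2 + C18:3 mass share.

    Returns ``None`` when X = 0 (all-saturated or C18:2/C18:3-free
    profiles): the correlation diverges there and reporting a number
    would be misleading. The formula is positional-isomer-blind, so
    γ-linolenic (C18:3 n-6) counts toward X alongside α-linolenic.
    """
    _require_nonempty(profile)
    x = profile.percent_of(18, 2) + profile.percent_of(18, 3)
    if x == 0.0:
        return None
    return 117.9295 / x + 2.5905


def compute_all(profile: FameProfile) -> BiodieselProperties:
    """Compute the full property record from one profile.

    The record satisfies, by construction, the algebraic identities
    ``cn + 0.225·iv − 5458/sv = 46.3``, ``du = mufa + 2·pufa`` and
    ``sfa + mufa + pufa = total_percent``.
    """
    _require_nonempty(profile)
    sv = saponification_value(profile)
    iv = iodine_value(profile)
    sfa, mufa, pufa = class_percents(profile)
    lcsf = long_chain_saturation_factor(profile)
    x = profile.percent_of(18, 2) + profile.percent_of(18, 3)
    return BiodieselProperties(
        sv=sv,
        iv=iv,
        du=degree_of_unsaturation(mufa, pufa),
        sfa_percent=sfa,
        mufa_percent=mufa,
        pufa_percent=pufa,
        lcsf=lcsf,
        cfpp=cold_filter_plugging_point(lcsf),
        cfpp_cascade=cold_filter_plugging_point(round(lcsf, 2)),
        cn=cetane_number(sv, iv),
        os_hours=oxidative_stability(profile),
        x_linoleic_linolenic=x,
    )


def check_identities(props: BiodieselProperties, total_percent: float,
                     atol: float = 1e-9) -> None:
    """Raise if a record violates its defining algebraic identities."""
    if not math.isclose(props.cn + 0.225 * props.iv - 5458.0 / props.sv, 46.3,
                        abs_tol=atol):
        raise AssertionError("CN/SV/IV identity violated")
    if props.du != props.mufa_percent + 2.0 * props.pufa_percent:
        raise AssertionError("DU identity violated")
    if not math.isclose(props.sfa_percent + props.mufa_percent + props.pufa_percent,
                        total_percent, abs_tol=atol):
        raise AssertionError("class-sum identity violated")
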