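"""Synthetic FAME profiles and growth plates.

Two generators provide inputs with the statistical structure the
pipeline assumes, so every stage is exercisable without laboratory data.

Compositions are drawn by the Dirichlet construction — independent gamma
variables normalised to the target total — which is the simplest
mechanism guaranteeing nonnegativity and compositional closure. The
concentration weights double as expected shares: with weights w the
long-run mean share of component i is wᵢ/Σw.

Growth plates follow a separable response surface: a Gaussian thermal
performance curve times a Monod (saturating) light term with an optional
exponential photoinhibition penalty above the light optimum,

    μ(T, L) = μmax · exp(−(T−T*)²/(2σ_T²)) · L/(L+K_L) · exp(−β·max(0, L−L*)),

which reproduces the qualitative shape of microalgal plate screens:
unimodal in temperature, saturating then declining in light. Noise is
multiplicative lognormal on the final OD. Defaults emulate a screen of
a eurythermal green microalga with its optimum at 24 °C and
88 µmol m⁻² s⁻¹ on an 8 × 12 (96-well) gradient plate spanning 5–40 °C
and 0–350 µmol m⁻² s⁻¹; none of the parameter values is claimed to be
any particular strain's.

All randomness flows from one ``numpy.random.default_rng`` (PCG64)
generator per call, seeded explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth import GrowthPlate
from .profiles import FameProfile
from .registry import FattyAcid, builtin_registry

__all__ = [
    "ProfileGeneratorSpec",
    "GrowthGeneratorSpec",
    "generate_fame_profile",
    "generate_growth_plate",
    "noiseless_mu",
    "TABLE_POOL",
]

#: Default component pool: the five majors of a green-algal FAME profile,
#: weighted by typical shares (palmitic, stearic, oleic, linoleic,
#: α-linolenic).
TABLE_POOL: tuple[tuple[tuple[int, int, str], float], ...] = (
    ((16, 0, "saturated"), 25.5),
    ((18, 0, "saturated"), 0.87),
    ((18, 1, "n-9"), 13.3),
    ((18, 2, "n-6"), 5.98),
    ((18, 3, "n-3"), 54.39),
)


@dataclass
class ProfileGeneratorSpec:
    """Recipe for random FAME compositions.

    ``weights`` are Dirichlet concentration parameters per pool entry
    (> 0); expected shares are weights normalised to 1. ``total`` is the
    exact component sum of every draw (compositional closure).
    """

    pool: tuple[tuple[int, int, str], ...] = tuple(k for k, _ in TABLE_POOL)
    weights: tuple[float, ...] = tuple(w for _, w in TABLE_POOL)
    total: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pool:
            raise ValueError("component pool must be non-empty")
        if len(self.weights) != len(self.pool):
            raise ValueError("one weight per pool entry required")
        if any(w <= 0 for w in self.weights):
            raise ValueError("concentration weights must be positive")
        if not 0 < self.total <= 100.5:
            raise ValueError("total mass percent must lie in (0, 100.5]")


def generate_fame_profile(spec: ProfileGeneratorSpec) -> FameProfile:
    """Draw one composition: total × normalised independent gammas."""
    rng = np.random.default_rng(spec.seed)
    draws = rng.gamma(shape=np.asarray(spec.weights, dtype=float), scale=1.0)
    shares = draws / draws.sum()
    registry = builtin_registry()
    components = []
    for (n, d, omega), share in zip(spec.pool, shares):
        fa = registry.get((n, d, omega)) or FattyAcid(n, d, omega)
        components.append((fa, float(share * spec.total)))
    return FameProfile(components=components,
                       source_id=f"synthetic-{spec.seed}")


@dataclass
class GrowthGeneratorSpec:
    """Recipe for synthetic temperature × light growth plates."""

    temperatures: tuple[float, ...] = (8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0, 36.0)
    light_levels: tuple[float, ...] = (0.0, 10.0, 22.0, 35.0, 53.0, 70.0, 88.0,
                                       110.0, 140.0, 180.0, 260.0, 350.0)
    optimum_temperature: float = 24.0   # degC (T*)
    optimum_light: float = 88.0         # umol m-2 s-1 (L*)
    mu_max: float = 0.03                # per hour (~0.72 per day)
    thermal_breadth: float = 6.0        # degC (Gaussian sigma)
    light_half_saturation: float = 30.0  # umol m-2 s-1 (K_L)
    photoinhibition: float = 0.006      # per (umol m-2 s-1) above L*
    noise_sigma: float = 0.05           # lognormal sigma on final OD
    initial_od: float = 0.05
    duration_h: float = 72.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("temperatures", "light_levels"):
            ax = np.asarray(getattr(self, name), dtype=float)
            if ax.size == 0 or not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly increasing and non-empty")
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.initial_od <= 0 or self.duration_h <= 0:
            raise ValueError("initial OD and duration must be positive")


def noiseless_mu(spec: GrowthGeneratorSpec) -> np.ndarray:
    """The generator's deterministic μ(T, L) grid (per hour)."""
    t = np.asarray(spec.temperatures, dtype=float)[:, None]
    light = np.asarray(spec.light_levels, dtype=float)[None, :]
    thermal = np.exp(-((t - spec.optimum_temperature) ** 2)
                     / (2.0 * spec.thermal_breadth ** 2))
    monod = light / (light + spec.light_half_saturation)
    inhibition = np.exp(-spec.photoinhibition
                        * np.maximum(0.0, light - spec.optimum_light))
    return spec.mu_max * thermal * monod * inhibition


def generate_growth_plate(spec: GrowthGeneratorSpec) -> GrowthPlate:
    """Simulate one plate: od_final = od_initial·exp(μ·Δt)·noise."""
    rng = np.random.default_rng(spec.seed)
    mu = noiseless_mu(spec)
    od0 = np.full_like(mu, spec.initial_od)
    noise = (np.exp(rng.normal(0.0, spec.noise_sigma, size=mu.shape))
             if spec.noise_sigma > 0 else np.ones_like(mu))
    od1 = od0 * np.exp(mu * spec.duration_h) * noise
    return GrowthPlate(
        temperatures=np.asarray(spec.temperatures, dtype=float),
        light_levels=np.asarray(spec.light_levels, dtype=float),
        od_initial=od0,
        od_final=od1,
        t1=0.0,
        t2=spec.duration_h,
        replicate_id=f"synthetic-{spec.seed}",
    )
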