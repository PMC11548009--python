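"""Temperature × light growth-screen analysis.

Turns two-timepoint plate-reader optical densities (OD600) measured over
a temperature × photon-flux-density grid into a specific-growth-rate
surface, μ = (ln A₂ − ln A₁)/(t₂ − t₁), locates the optimum and exports
the surface as a CSV matrix or heat-map image.

Cells with non-positive OD (a background-subtraction artifact) are
flagged as undefined (NaN) rather than failing the whole plate. μ is
per hour internally; human-facing reports multiply by 24 to per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GrowthPlate",
    "GrowthSurface",
    "specific_growth_rate",
    "growth_surface",
    "find_optimum",
    "read_plate_long",
    "export_surface_csv",
    "export_heatmap",
]

HOURS_PER_DAY = 24.0


def specific_growth_rate(a1, a2, t1: float, t2: float):
    """μ = (ln A₂ − ln A₁)/(t₂ − t₁), per hour.

    Accepts scalars or arrays. Cells where either OD is non-positive
    come back NaN (undefined), not an exception — a blanked well can
    legitimately read ≤ 0 without invalidating the rest of the plate.
    """
    if not t2 > t1:
        raise ValueError(f"t2 ({t2}) must exceed t1 ({t1})")
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    ok = (a1 > 0) & (a2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(ok, (np.log(np.where(ok, a2, 1.0))
                           - np.log(np.where(ok, a1, 1.0))) / (t2 - t1), np.nan)
    if mu.ndim == 0:
        return float(mu)
    return mu


@dataclass
class GrowthPlate:
    """Two-timepoint OD600 readings on a temperature × light grid.

    ``od_initial``/``od_final`` are (n_temperatures × n_lights) grids of
    A₁ and A₂; ``t1``/``t2`` are the read times in hours.
    """

    temperatures: np.ndarray  # degC, one per grid row
    light_levels: np.ndarray  # umol m-2 s-1 (PFD), one per grid column
    od_initial: np.ndarray
    od_final: np.ndarray
    t1: float = 0.0
    t2: float = 72.0
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.light_levels = np.asarray(self.light_levels, dtype=float)
        self.od_initial = np.asarray(self.od_initial, dtype=float)
        self.od_final = np.asarray(self.od_final, dtype=float)
        shape = (self.temperatures.size, self.light_levels.size)
        if self.od_initial.shape != shape or self.od_final.shape != shape:
            raise ValueError(
                f"OD grids must be {shape}, got {self.od_initial.shape} "
                f"and {self.od_final.shape}"
            )
        if not self.t2 > self.t1:
            raise ValueError("t2 must exceed t1")
        if not (np.isfinite(self.od_initial).all() and np.isfinite(self.od_final).all()):
            raise ValueError("OD grids must be finite")


@dataclass
class GrowthSurface:
    """Specific growth rate μ (per hour) on the plate's grid."""

    temperatures: np.ndarray
    light_levels: np.ndarray
    mu: np.ndarray
    viability_fraction: float = 0.05
    optimum: tuple[float, float] | None = field(default=None)

    @property
    def viable_region(self) -> np.ndarray:
        """Boolean grid: μ above ``viability_fraction`` of the maximum."""
        mx = np.nanmax(self.mu)
        with np.errstate(invalid="ignore"):
            return self.mu > self.viability_fraction * mx

    @property
    def mu_per_day(self) -> np.ndarray:
        return self.mu * HOURS_PER_DAY

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mu, index=pd.Index(self.temperatures, name="temperature"),
                            columns=pd.Index(self.light_levels, name="light"))


def growth_surface(plate: GrowthPlate, viability_fraction: float = 0.05) -> GrowthSurface:
    """Cell-wise μ over a plate; undefined cells propagate as NaN."""
    mu = specific_growth_rate(plate.od_initial, plate.od_final, plate.t1, plate.t2)
    surface = GrowthSurface(plate.temperatures, plate.light_levels,
                            np.asarray(mu), viability_fraction)
    if np.isfinite(surface.mu).any():
        surface.optimum = find_optimum(surface)
    return surface


def _mean_filter(mu: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware mean filter with edge truncation (window × window)."""
    if window == 1:
        return mu
    half = window // 2
    vals = np.where(np.isfinite(mu), mu, 0.0)
    cnts = np.isfinite(mu).astype(float)
    out = np.full_like(mu, np.nan, dtype=float)
    nrow, ncol = mu.shape
    for i in range(nrow):
        i0, i1 = max(0, i - half), min(nrow, i + half + 1)
        for j in range(ncol):
            j0, j1 = max(0, j - half), min(ncol, j + half + 1)
            c = cnts[i0:i1, j0:j1].sum()
            if c > 0:
                out[i, j] = vals[i0:i1, j0:j1].sum() / c
    return out


def find_optimum(surface: GrowthSurface, smoothing_window: int = 1
                 ) -> tuple[float, float]:
    """(temperature, PFD) of the μ-surface maximum.

    ``smoothing_window`` ∈ {1, 3, 5} applies an edge-truncated mean
    filter before the argmax (window 1 = none). Exact ties break toward
    the lower temperature, then the lower light level.
    """
    if smoothing_window not in (1, 3, 5):
        raise ValueError("smoothing window must be 1, 3 or 5")
    mu = _mean_filter(surface.mu, smoothing_window)
    if not np.isfinite(mu).any():
        raise ValueError("all cells undefined; cannot locate an optimum")
    best = np.nanmax(mu)
    ti, li = np.nonzero(mu == best)
    # rows/cols may be listed in any axis order; tie-break on axis values
    order = np.lexsort((surface.light_levels[li], surface.temperatures[ti]))
    k = order[0]
    return float(surface.temperatures[ti[k]]), float(surface.light_levels[li[k]])


# ---------------------------------------------------------------------------
# I/O

def read_plate_long(source: str | Path, t1: float = 0.0, t2: float = 72.0,
                    replicate_id: str = "") -> GrowthPlate:
    """Read a long-format plate CSV: columns temperature, light, od_t0, od_t1.

    The grid is reconstructed from the sorted unique axis values; every
    (temperature, light) combination must appear exactly once.
    """
    df = pd.read_csv(source)
    required = {"temperature", "light", "od_t0", "od_t1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV is missing columns {sorted(missing)}")
    temps = np.sort(df["temperature"].unique())
    lights = np.sort(df["light"].unique())
    if len(df) != temps.size * lights.size:
        raise ValueError("plate CSV does not cover a complete grid")
    piv0 = df.pivot(index="temperature", columns="light", values="od_t0")
    piv1 = df.pivot(index="temperature", columns="light", values="od_t1")
    return GrowthPlate(temps, lights, piv0.to_numpy(), piv1.to_numpy(),
                       t1=t1, t2=t2, replicate_id=replicate_id)


def export_surface_csv(surface: GrowthSurface, path: str | Path,
                       per_day: bool = False) -> None:
    """Write the μ matrix (temperature rows × light columns) as CSV."""
    frame = surface.to_frame()
    if per_day:
        frame = frame * HOURS_PER_DAY
    frame.to_csv(path)


def export_heatmap(surface: GrowthSurface, path: str | Path,
                   per_day: bool = True) -> None:
    """Render the μ surface as a heat-map image with the optimum marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mu = surface.mu_per_day if per_day else surface.mu
    fig, ax = plt.subplots(figsize=(7, 4.5))
    im = ax.pcolormesh(surface.light_levels, surface.temperatures, mu,
                       shading="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax,
                 label="specific growth rate " + ("(d$^{-1}$)" if per_day else "(h$^{-1}$)"))
    if surface.optimum is not None:
        t_opt, l_opt = surface.optimum
        ax.plot(l_opt, t_opt, "r*", markersize=14, label=f"optimum ({t_opt:g} °C, {l_opt:g})")
        ax.legend(loc="upper right")
    ax.set_xlabel("photon flux density (µmol m$^{-2}$ s$^{-1}$)")
    ax.set_ylabel("temperature (°C)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
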