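"""Trichome-density arithmetic and type-VI storage-cavity geometry.

Leaf-disc counts (r = 2 mm discs, abaxial + adaxial surfaces) become summed
per-disc totals and per-mm² densities; plants are grouped into equal-width
density classes.  Storage cavities, measured as width (transverse plane)
and height (medial plane) in µm, are modelled as prolate spheroids; volumes
convert to picolitres (1 pl = 1000 µm³).

Note on the spheroid volume: the default formula is (4/3)·a²·b with a,b the
semi-axes, i.e. WITHOUT the factor π of the geometric spheroid volume
(4/3)·π·a²·b.  Both conventions are supported (``include_pi``); every
ratio-based summary (fold changes, percent reductions) is invariant to the
choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TrichomeCount",
    "CavityMeasurement",
    "summed_density",
    "summed_density_table",
    "assign_density_classes",
    "cavity_volume",
    "um3_to_picolitre",
    "picolitre_to_um3",
    "density_terpene_correlation",
    "CorrelationResult",
    "DEFAULT_DISC_RADIUS_MM",
]

DEFAULT_DISC_RADIUS_MM = 2.0
TRICHOME_TYPES = ("typeVI", "typeI_IV", "NG")


@dataclass(frozen=True)
class TrichomeCount:
    """Counts of one trichome type on one leaf disc."""

    plant_id: str
    side: str
    trichome_type: str
    count: int
    disc_radius_mm: float = DEFAULT_DISC_RADIUS_MM

    def __post_init__(self) -> None:
        if self.side not in ("abaxial", "adaxial"):
            raise ValueError(f"side must be abaxial/adaxial, got {self.side!r}")
        if self.count < 0:
            raise ValueError("count must be ≥ 0")
        if self.disc_radius_mm <= 0:
            raise ValueError("disc radius must be > 0")


@dataclass(frozen=True)
class CavityMeasurement:
    """Width (transverse plane) and height (medial plane) of one cavity, µm."""

    trichome_id: str
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("cavity dimensions must be > 0")


def summed_density(
    abaxial: float, adaxial: float, disc_radius_mm: float = DEFAULT_DISC_RADIUS_MM
) -> tuple[float, float]:
    """Two-sided summed count per leaf disc and the per-mm² density.

    ``abaxial``/``adaxial`` are the mean counts over the discs taken on
    that surface.  Returns ``(summed_per_disc, per_mm2)``; the per-mm²
    figure divides the two-sided sum by one disc area π·r².
    """
    if disc_radius_mm <= 0:
        raise ValueError("disc radius must be > 0")
    total = abaxial + adaxial
    area = math.pi * disc_radius_mm**2
    return total, total / area


def summed_density_table(
    counts: pd.DataFrame, trichome_type: str = "typeVI"
) -> pd.DataFrame:
    """Per-plant summed density from a tidy counts table.

    ``counts`` needs columns ``plant_id, side, disc_radius_mm,
    trichome_type, count`` with one row per disc.  Mean over discs is taken
    per side first, then sides are summed.  A plant missing one of the two
    surfaces is an error.
    """
    sub = counts[counts["trichome_type"] == trichome_type]
    if sub.empty:
        raise ValueError(f"no rows for trichome type {trichome_type!r}")
    per_side = (
        sub.groupby(["plant_id", "side"])
        .agg(count=("count", "mean"), disc_radius_mm=("disc_radius_mm", "first"))
        .reset_index()
    )
    side_counts = per_side.groupby("plant_id")["side"].nunique()
    incomplete = side_counts[side_counts < 2]
    if not incomplete.empty:
        raise ValueError(
            f"missing leaf surface for plants: {list(incomplete.index)}"
        )
    wide = per_side.pivot(index="plant_id", columns="side", values="count")
    radius = per_side.groupby("plant_id")["disc_radius_mm"].first()
    total = wide["abaxial"] + wide["adaxial"]
    area = math.pi * radius**2
    return pd.DataFrame(
        {
            "plant_id": wide.index,
            "summed_per_disc": total.values,
            "per_mm2": (total / area).values,
        }
    ).reset_index(drop=True)


def assign_density_classes(
    summed: pd.DataFrame, k: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Group plants into ``k`` equal-width classes of summed trichome count.

    Bins span [min, max] of ``summed_per_disc`` and are right-closed; the
    minimum belongs to class 1 and the maximum to class ``k``.  Returns the
    assignments (``plant_id, summed_count, class_index``) and the ``k+1``
    bin edges for audit.
    """
    if k < 1:
        raise ValueError("need ≥1 class")
    x = summed["summed_per_disc"].to_numpy(dtype=float)
    lo, hi = x.min(), x.max()
    if lo == hi:
        warnings.warn("all summed counts equal; assigning a single class")
        edges = np.array([lo, hi])
        idx = np.ones(x.size, dtype=int)
    else:
        edges = np.linspace(lo, hi, k + 1)
        idx = np.searchsorted(edges[1:], x, side="left") + 1
        idx = np.clip(idx, 1, k)
    out = pd.DataFrame(
        {
            "plant_id": summed["plant_id"].values,
            "summed_count": x,
            "class_index": idx,
        }
    )
    return out, edges


def cavity_volume(
    width_um: float, height_um: float, include_pi: bool = False
) -> float:
    """Prolate-spheroid storage-cavity volume in µm³.

    a = width/2, b = height/2.  Default is the convention (4/3)·a²·b;
    ``include_pi`` gives the geometric spheroid volume (4/3)·π·a²·b (see
    module note).
    """
    if width_um <= 0 or height_um <= 0:
        raise ValueError("cavity dimensions must be > 0")
    a = width_um / 2.0
    b = height_um / 2.0
    v = (4.0 / 3.0) * a**2 * b
    return v * math.pi if include_pi else v


def um3_to_picolitre(v_um3: float) -> float:
    """µm³ → picolitre (1 pl = 10³ µm³)."""
    if np.any(np.asarray(v_um3) < 0):
        raise ValueError("volume must be ≥ 0")
    return v_um3 / 1000.0


def picolitre_to_um3(v_pl: float) -> float:
    """Inverse of :func:`um3_to_picolitre`."""
    if np.any(np.asarray(v_pl) < 0):
        raise ValueError("volume must be ≥ 0")
    return v_pl * 1000.0


@dataclass(frozen=True)
class CorrelationResult:
    """OLS fit of terpene total on trichome density."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    #: x grid, fitted line and 95% confidence band for the mean response
    line: pd.DataFrame

    def summary(self) -> str:
        return (
            f"density–terpene OLS (n={self.n}): total = "
            f"{self.intercept:.4g} + {self.slope:.4g}·density, "
            f"r² = {self.r_squared:.3f}, p = {self.p_value:.3g}"
        )


def density_terpene_correlation(
    density_per_mm2, total_ng_per_mg, n_grid: int = 100
) -> CorrelationResult:
    """Linear association between type-VI density and leaf terpene total.

    Ordinary least squares of total terpenes (ng/mg FW) on density
    (trichomes/mm²); r² is the squared Pearson correlation, p the two-sided
    test of zero slope.  The returned line carries a 95% confidence band
    for the mean response, as drawn on density-vs-terpene scatterplots.
    """
    x = np.asarray(density_per_mm2, dtype=float)
    y = np.asarray(total_ng_per_mg, dtype=float)
    if x.size != y.size:
        raise ValueError("paired arrays required")
    if x.size < 3:
        raise ValueError("need ≥3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), n_grid)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    line = pd.DataFrame(
        {
            "density": grid,
            "fitted": pred["mean"].values,
            "ci_low": pred["mean_ci_lower"].values,
            "ci_high": pred["mean_ci_upper"].values,
        }
    )
    return CorrelationResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=int(x.size),
        line=line,
    )
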