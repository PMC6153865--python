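"""First-arrival-time regression, ANCOVA and odour-plume density inversion.

The time for the first fish to reach a baited camera grows log-linearly
with depth,

    log10(t_arr [min]) = a + b * depth [m],

and under the odour-plume model the first arriver is the nearest fish,
alerted by a plume advected at the current speed ``V_w`` and swimming to
the bait at speed ``V_f``. With t_arr in *seconds*,

    r = t_arr / (1/V_f + 1/V_w)        (radius of the space per fish, m)
    A = 10^6 / (3 r^2)                 (fish per km^2).

Both speeds default to 0.05 m/s, typical of deep-ocean conditions. The
published Atlantic and Eastern-Mediterranean regression coefficients are
bundled as :data:`ATLANTIC` and :data:`MEDITERRANEAN`.

Arrival times are *recorded* in minutes (one image interval); the
minute-to-second conversion for the plume inversion is owned by this
module (:func:`density_at_depth`). Zero arrival times are rejected rather
than jittered — floor recorded times at one image interval upstream.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as scipy_stats

from .errors import DegenerateModelError, ValidationError

__all__ = [
    "ArrivalRegression",
    "AncovaResult",
    "DensityEstimate",
    "ATLANTIC",
    "MEDITERRANEAN",
    "DEFAULT_V_F",
    "DEFAULT_V_W",
    "fit_arrival_regression",
    "predict_t_arr",
    "ancova_compare",
    "density_from_arrival",
    "density_at_depth",
    "arrival_time_for_density",
    "density_line_from_arrival_line",
    "intersection_depth",
]

#: Assumed fish swimming speed and odour-plume advection speed (m/s).
DEFAULT_V_F = 0.05
DEFAULT_V_W = 0.05


@dataclasses.dataclass(frozen=True)
class ArrivalRegression:
    """log10(t_arr [min]) = a + b * depth [m]."""

    a: float
    b: float
    n: int
    r_squared: float | None = None
    basin: str | None = None


#: Published Atlantic first-fish arrival line (83 deployments).
ATLANTIC = ArrivalRegression(a=0.0386, b=0.000331, n=83, r_squared=0.613, basin="atlantic")
#: Published Eastern Mediterranean first-fish arrival line (28 deployments).
MEDITERRANEAN = ArrivalRegression(a=0.892, b=0.000200, n=28, r_squared=None, basin="mediterranean")


@dataclasses.dataclass(frozen=True)
class AncovaResult:
    """Sequential (type-I) ANCOVA of log10(t_arr) on depth and basin.

    F statistics are reported for the depth covariate, the basin main
    effect and the depth x basin interaction, entered in that order, plus
    the overall regression F. ``df_resid = n - 4`` for the two-basin
    interaction model.
    """

    f_model: float
    p_model: float
    f_depth: float
    p_depth: float
    f_location: float
    p_location: float
    f_interaction: float
    p_interaction: float
    df_resid: int
    n: int
    by_basin: Mapping[str, ArrivalRegression]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["by_basin"] = {k: dataclasses.asdict(v) for k, v in self.by_basin.items()}
        return d


@dataclasses.dataclass(frozen=True)
class DensityEstimate:
    """Odour-plume inversion output: r in metres, A in fish per km^2."""

    r: float
    A: float
    v_f: float = DEFAULT_V_F
    v_w: float = DEFAULT_V_W


def _validated_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        depth = records["depth_m"].to_numpy(dtype=float)
        t = records["t_arr_min"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(records), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError("records must be (depth_m, t_arr_min) pairs")
        depth, t = arr[:, 0], arr[:, 1]
    if (t <= 0).any():
        raise ValidationError(
            "t_arr must be > 0 for a log fit; floor recorded times at one image interval (1 min)"
        )
    return depth, t


def fit_arrival_regression(records, basin: str | None = None) -> ArrivalRegression:
    """OLS of log10(t_arr [min]) on depth (>= 3 points, all t_arr > 0).

    *records* is a DataFrame with ``depth_m``/``t_arr_min`` columns or an
    iterable of (depth, t_arr) pairs.
    """
    depth, t = _validated_arrays(records)
    if depth.size < 3:
        raise ValidationError(f"need at least 3 records to fit, got {depth.size}")
    y = np.log10(t)
    model = sm.OLS(y, sm.add_constant(depth)).fit()
    return ArrivalRegression(
        a=float(model.params[0]),
        b=float(model.params[1]),
        n=int(depth.size),
        r_squared=float(model.rsquared),
        basin=basin,
    )


def predict_t_arr(reg: ArrivalRegression, depth: float) -> float:
    """Predicted first-arrival time in minutes at *depth* metres (>= 0)."""
    if depth < 0:
        raise ValidationError("depth must be >= 0")
    return float(10.0 ** (reg.a + reg.b * depth))


def ancova_compare(records: pd.DataFrame, max_f: float = 1e12) -> AncovaResult:
    """Two-basin ANCOVA: log10(t_arr) ~ depth + basin + depth:basin.

    *records* needs columns ``depth_m, t_arr_min, basin`` with exactly two
    basin labels, each observed at least 3 times. Sums of squares are
    sequential (type I) with depth entered first. A zero-residual
    (noise-free) fit is flagged as degenerate rather than reporting an
    infinite F.
    """
    df = records.copy()
    for col in ("depth_m", "t_arr_min", "basin"):
        if col not in df.columns:
            raise ValidationError(f"records missing column {col!r}")
    basins = sorted(df["basin"].astype(str).unique())
    if len(basins) != 2:
        raise ValidationError(f"ancova_compare requires exactly two basins, got {basins}")
    counts = df["basin"].value_counts()
    if (counts < 3).any():
        raise ValidationError("each basin needs at least 3 records")
    if (df["t_arr_min"] <= 0).any():
        raise ValidationError("t_arr must be > 0 for a log fit")
    y = np.log10(df["t_arr_min"].to_numpy(dtype=float))
    depth = df["depth_m"].to_numpy(dtype=float)
    dummy = (df["basin"].astype(str) == basins[1]).to_numpy(dtype=float)

    # nested fits for the sequential (type I) decomposition, depth first
    full = sm.OLS(y, sm.add_constant(np.column_stack([depth, dummy, depth * dummy]))).fit()
    if full.ssr <= 1e-12 * max(1.0, float(full.centered_tss)):
        raise DegenerateModelError("zero residual variance: interaction F is unbounded (noise-free input)")
    ssr_depth = sm.OLS(y, sm.add_constant(depth)).fit().ssr
    ssr_loc = sm.OLS(y, sm.add_constant(np.column_stack([depth, dummy]))).fit().ssr
    mse = full.ssr / full.df_resid

    def seq_f(drop: float) -> tuple[float, float]:
        f = drop / mse
        return float(f), float(scipy_stats.f.sf(f, 1, full.df_resid))

    f_depth, p_depth = seq_f(float(full.centered_tss) - ssr_depth)
    f_location, p_location = seq_f(ssr_depth - ssr_loc)
    f_interaction, p_interaction = seq_f(ssr_loc - full.ssr)
    by_basin = {
        b: fit_arrival_regression(df[df["basin"].astype(str) == b], basin=b) for b in basins
    }
    return AncovaResult(
        f_model=float(full.fvalue),
        p_model=float(full.f_pvalue),
        f_depth=f_depth,
        p_depth=p_depth,
        f_location=f_location,
        p_location=p_location,
        f_interaction=f_interaction,
        p_interaction=p_interaction,
        df_resid=int(full.df_resid),
        n=int(len(df)),
        by_basin=by_basin,
    )


def density_from_arrival(t_arr_s: float, v_f: float = DEFAULT_V_F, v_w: float = DEFAULT_V_W) -> DensityEstimate:
    """Invert a first-arrival time (in *seconds*) to a fish density.

    r = t_arr / (1/v_f + 1/v_w); A = 10^6 / (3 r^2) fish per km^2.
    """
    if t_arr_s <= 0 or v_f <= 0 or v_w <= 0:
        raise ValidationError("t_arr and both speeds must be > 0")
    r = t_arr_s / (1.0 / v_f + 1.0 / v_w)
    return DensityEstimate(r=r, A=1e6 / (3.0 * r * r), v_f=v_f, v_w=v_w)


def density_at_depth(
    reg: ArrivalRegression, depth: float, v_f: float = DEFAULT_V_F, v_w: float = DEFAULT_V_W
) -> DensityEstimate:
    """Predicted density at *depth*: regression minutes -> seconds -> inversion."""
    t_min = predict_t_arr(reg, depth)
    return density_from_arrival(t_min * 60.0, v_f=v_f, v_w=v_w)


def arrival_time_for_density(A: float, v_f: float = DEFAULT_V_F, v_w: float = DEFAULT_V_W) -> float:
    """Algebraic inverse of :func:`density_from_arrival`: seconds for density *A*."""
    if A <= 0 or v_f <= 0 or v_w <= 0:
        raise ValidationError("A and both speeds must be > 0")
    r = math.sqrt(1e6 / (3.0 * A))
    return r * (1.0 / v_f + 1.0 / v_w)


def density_line_from_arrival_line(
    reg: ArrivalRegression, v_f: float = DEFAULT_V_F, v_w: float = DEFAULT_V_W
) -> tuple[float, float]:
    """Coefficients (intercept, slope) of log10(A [km^-2]) vs depth implied
    by an arrival line plus the plume inversion; the slope is always -2b."""
    c = 1.0 / v_f + 1.0 / v_w
    intercept = 6.0 - math.log10(3.0) - 2.0 * (math.log10(60.0) + reg.a - math.log10(c))
    return intercept, -2.0 * reg.b


def intersection_depth(reg1: ArrivalRegression, reg2: ArrivalRegression) -> float:
    """Depth (m) at which two arrival lines predict equal t_arr."""
    if math.isclose(reg1.b, reg2.b, rel_tol=0.0, abs_tol=1e-15):
        raise ValidationError("regression lines are parallel: no intersection")
    return (reg1.a - reg2.a) / (reg2.b - reg1.b)
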