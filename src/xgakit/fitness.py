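"""Competitive-fitness estimation from barcode counts.

The growth model: a strain's abundance in a pool follows
A_t = A_0 * 2^(g t), with t counted in pool generations (doublings of the
whole pool) so that a strain with g = 1 exactly tracks the pool. Observed
frequencies f_t, rescaled by the pool expansion 2^t, give an observed
area under the growth curve

    AUC = integral_0^T f(t) 2^t dt   (f piecewise-linear between timepoints)

which is matched against the model prediction
f_0 (2^(g T) - 1) / (g ln 2) by bounded 1-D least squares to estimate g.
Resistance is r = g_drug / g_solvent; per-drug normalized resistance is
r / max(r).

Also houses the liquid-growth helpers (saturation-time detection, OD-ratio
resistance, linear IC50 interpolation) and the qPCR relative-expression
calculation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import CountMatrix, FrequencyTable

LN2 = np.log(2.0)

#: numerical floor applied to growth rates and normalized resistance
GROWTH_FLOOR = 1e-10

#: search interval for the growth-rate solver (doublings per pool generation)
GROWTH_BOUNDS = (-10.0, 10.0)


class ZeroTotalSampleError(ValueError):
    """A sample had zero total counts and cannot be normalized."""


@dataclass
class PlateGrowthCurve:
    """One well's optical-density time series."""

    times: np.ndarray  # minutes, strictly increasing
    od: np.ndarray
    condition: str = ""
    concentration: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise ValueError("times and od must be matching 1-D arrays")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if (self.od < 0).any():
            raise ValueError("od must be non-negative")


@dataclass
class GrowthResult:
    """Per-strain growth, resistance and filter flags.

    ``g`` is strain x condition (doublings per pool generation, clipped to
    [1e-10, 10]); ``r`` is g_drug / g_solvent for unfiltered strains;
    ``r_norm`` is r / max over strains per drug, floored at 1e-10.
    ``flags`` carries boolean columns low_count and slow_baseline.
    """

    g: pd.DataFrame
    r: pd.DataFrame
    r_norm: pd.DataFrame
    flags: pd.DataFrame
    solvent: str = "DMSO"
    settings: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# frequencies


def counts_to_frequencies(counts: CountMatrix) -> FrequencyTable:
    """Per-sample normalization, averaging frequencies across tag kinds.

    Within each (tag, generation, condition) sample, counts (runs summed)
    are divided by the sample total; a strain's frequency is the mean of
    its per-tag frequencies over the tags available for it, renormalized
    so each sample's frequencies sum to exactly 1 (a no-op when every
    strain carries both tags).
    """
    df = counts.summed_over_runs()
    totals = df.groupby(["tag", "generation", "condition"])["count"].transform("sum")
    bad = totals == 0
    if bad.any():
        sample = df.loc[bad, ["tag", "generation", "condition"]].iloc[0]
        raise ZeroTotalSampleError(
            f"sample tag={sample['tag']} generation={sample['generation']} "
            f"condition={sample['condition']} has zero total counts"
        )
    df = df.assign(f=df["count"] / totals)
    avg = (
        df.groupby(["strain_id", "generation", "condition"], as_index=False)["f"].mean()
    )
    sample_sum = avg.groupby(["generation", "condition"])["f"].transform("sum")
    avg["f"] = avg["f"] / sample_sum
    tags_per_strain = df.groupby("strain_id")["tag"].agg(lambda s: tuple(sorted(set(s))))
    return FrequencyTable(f=avg, provenance={"tags": tags_per_strain.to_dict()})


# ---------------------------------------------------------------------------
# AUC and growth solver


def observed_auc(f_series: np.ndarray, timepoints: np.ndarray) -> float:
    """Closed-form integral of the piecewise-linear frequency curve times 2^t.

    Each segment uses the antiderivative
    integral (a + b t) 2^t dt = 2^t ((a + b t)/ln2 - b/ln2^2).
    """
    f = np.asarray(f_series, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if f.shape != t.shape or f.ndim != 1 or len(f) < 2:
        raise ValueError("need matching 1-D series with >= 2 timepoints")
    if not np.all(np.diff(t) > 0):
        raise ValueError("timepoints must be strictly increasing")
    if t[0] != 0:
        raise ValueError("first timepoint must be 0")
    total = 0.0
    for i in range(len(t) - 1):
        t0, t1 = t[i], t[i + 1]
        b = (f[i + 1] - f[i]) / (t1 - t0)
        a = f[i] - b * t0

        def F(x: float) -> float:
            return 2.0**x * ((a + b * x) / LN2 - b / LN2**2)

        total += F(t1) - F(t0)
    return float(total)


def predicted_auc(f0: float, g: float, T: float) -> float:
    """Model AUC: f0 (2^(gT) - 1) / (g ln2), with the g -> 0 limit f0*T."""
    if abs(g) < 1e-12:
        return f0 * T
    return f0 * (2.0 ** (g * T) - 1.0) / (g * LN2)


def estimate_growth(
    f_series: np.ndarray,
    timepoints: np.ndarray,
    bounds: tuple[float, float] = GROWTH_BOUNDS,
) -> float:
    """Solve the AUC-matching equation for the relative growth rate g.

    Bounded scalar minimization of the squared AUC residual; the match is
    strictly monotone in g so the minimum is unique. The returned value is
    clipped to the search bounds; downstream use applies the 1e-10 floor.
    """
    f = np.asarray(f_series, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if f[0] <= 0:
        raise ValueError("frequency at t=0 must be positive")
    auc = observed_auc(f, t)
    T = float(t[-1])
    f0 = float(f[0])

    def sq_resid(g: float) -> float:
        return (predicted_auc(f0, g, T) - auc) ** 2

    res = minimize_scalar(sq_resid, bounds=bounds, method="bounded", options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"growth solver failed (residual {res.fun:.3g})")
    return float(res.x)


# ---------------------------------------------------------------------------
# filters, resistance, pooling


def apply_filters(
    counts: CountMatrix,
    g_solvent: pd.Series,
    min_t0_count: float = 30.0,
    baseline_fraction: float = 0.7,
    solvent: str = "DMSO",
) -> pd.DataFrame:
    """Flag strains to exclude from resistance outputs.

    low_count: mean t=0 solvent count over the strain's available tags is
    below ``min_t0_count`` (mean >= 30 passes). slow_baseline: solvent
    growth below ``baseline_fraction`` of the median over strains passing
    the count filter.
    """
    df = counts.summed_over_runs()
    t0 = df[(df["generation"] == 0) & (df["condition"] == solvent)]
    mean_t0 = t0.groupby("strain_id")["count"].mean()
    strains = g_solvent.index
    low = pd.Series(
        [mean_t0.get(s, 0.0) < min_t0_count for s in strains], index=strains, dtype=bool
    )
    unfiltered = g_solvent[~low]
    median_g = float(unfiltered.median()) if len(unfiltered) else np.nan
    slow = g_solvent < baseline_fraction * median_g
    return pd.DataFrame({"low_count": low, "slow_baseline": slow.astype(bool)})


def compute_resistance(g_drug, g_solvent):
    """r = g_drug / g_solvent (inputs already floored at 1e-10)."""
    return np.asarray(g_drug, dtype=float) / np.asarray(g_solvent, dtype=float)


def normalize_resistance(r) -> np.ndarray:
    """r / max(r) per drug, floored at 1e-10."""
    r = np.asarray(r, dtype=float)
    return np.clip(r / r.max(axis=0), GROWTH_FLOOR, None)


def estimate_growth_table(freqs: FrequencyTable) -> pd.DataFrame:
    """Per-strain, per-condition growth rates (strain x condition frame)."""
    out: dict[str, pd.Series] = {}
    for cond in sorted(freqs.f["condition"].unique()):
        mat = freqs.pivot(cond)
        t = np.array(sorted(mat.columns), dtype=float)
        mat = mat[sorted(mat.columns)]
        vals = {}
        for sid, row in mat.iterrows():
            f = row.to_numpy(dtype=float)
            if f[0] <= 0:
                vals[sid] = np.nan
                continue
            vals[sid] = estimate_growth(f, t)
        out[cond] = pd.Series(vals)
    return pd.DataFrame(out)


def growth_and_resistance(
    counts: CountMatrix,
    solvent: str = "DMSO",
    min_t0_count: float = 30.0,
    baseline_fraction: float = 0.7,
) -> GrowthResult:
    """Counts -> frequencies -> growth -> filters -> resistance, end to end."""
    freqs = counts_to_frequencies(counts)
    g = estimate_growth_table(freqs)
    if solvent not in g.columns:
        raise ValueError(f"solvent condition {solvent!r} absent from counts")
    g_floored = g.clip(lower=GROWTH_FLOOR)
    flags = apply_filters(
        counts, g_floored[solvent], min_t0_count, baseline_fraction, solvent
    )
    keep = ~(flags["low_count"] | flags["slow_baseline"])
    drugs = [c for c in g.columns if c != solvent]
    kept = g_floored.loc[keep[keep].index]
    r = kept[drugs].div(kept[solvent], axis=0)
    r_norm = pd.DataFrame(
        normalize_resistance(r.to_numpy()), index=r.index, columns=r.columns
    )
    return GrowthResult(
        g=g_floored,
        r=r,
        r_norm=r_norm,
        flags=flags,
        solvent=solvent,
        settings={
            "min_t0_count": min_t0_count,
            "baseline_fraction": baseline_fraction,
            "growth_bounds": list(GROWTH_BOUNDS),
            "growth_floor": GROWTH_FLOOR,
        },
    )


def rescale_pools(
    r_a: pd.DataFrame,
    masks_a: pd.DataFrame,
    r_alpha: pd.DataFrame,
    masks_alpha: pd.DataFrame,
    grouping_loci: list[int],
):
    """Affine-align MATa resistance onto the MATalpha scale, then merge.

    Strains are not shared between pools, so the line of best fit is
    computed per drug over the 2^k genotype-group means at the grouping
    loci (ordinary least squares of alpha means on a means); all MATa
    values are passed through the fitted line. Returns (merged frame with
    a ``pool`` column, dict drug -> (slope, intercept)).
    """
    drugs = [c for c in r_a.columns if c in r_alpha.columns]
    if not drugs:
        raise ValueError("pools share no drugs")

    def group_key(masks: pd.DataFrame) -> pd.Series:
        sub = masks.iloc[:, grouping_loci].astype(int).astype(str)
        return sub.apply("".join, axis=1)

    key_a = group_key(masks_a.loc[r_a.index])
    key_al = group_key(masks_alpha.loc[r_alpha.index])
    coeffs: dict[str, tuple[float, float]] = {}
    r_a_out = r_a.copy()
    for drug in drugs:
        means_a = r_a[drug].groupby(key_a).mean()
        means_al = r_alpha[drug].groupby(key_al).mean()
        shared = means_a.index.intersection(means_al.index)
        if len(shared) < 3:
            warnings.warn(
                f"{drug}: fewer than 3 shared genotype groups; passing through unscaled"
            )
            coeffs[drug] = (1.0, 0.0)
            continue
        slope, intercept = np.polyfit(means_a[shared], means_al[shared], 1)
        coeffs[drug] = (float(slope), float(intercept))
        r_a_out[drug] = slope * r_a[drug] + intercept
    merged = pd.concat(
        [r_a_out[drugs].assign(pool="a"), r_alpha[drugs].assign(pool="alpha")]
    )
    return merged, coeffs


# ---------------------------------------------------------------------------
# plate growth (IC50) helpers


def _window_slope(y: np.ndarray, t: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window difference quotient; returns (slopes, window-mid times)."""
    d = (y[window:] - y[:-window]) / (t[window:] - t[:-window])
    mid = 0.5 * (t[window:] + t[:-window])
    return d, mid


def plate_saturation_time(
    curve: PlateGrowthCurve, window: int = 4, literal_argmax: bool = False
) -> float:
    """Time at which the culture saturates, from curvature of OD(t).

    First and second derivatives by sliding-window differencing (window of
    4 readings). Saturation is the extreme-magnitude curvature in the
    deceleration phase (after peak growth rate); ``literal_argmax`` instead
    returns the global argmax of the second derivative.
    """
    t, y = curve.times, curve.od
    if len(t) < 2 * window + 2:
        raise ValueError(f"need at least {2 * window + 2} readings")
    d1, t1 = _window_slope(y, t, window)
    d2, t2 = _window_slope(d1, t1, window)
    if np.allclose(d1, 0.0, atol=1e-12):
        warnings.warn("flat growth curve; returning last timepoint")
        return float(t[-1])
    if literal_argmax:
        return float(t2[int(np.argmax(d2))])
    peak = int(np.argmax(d1))
    # second-derivative samples centred after the growth-rate peak
    decel = np.nonzero(t2 >= t1[peak])[0]
    if len(decel) == 0:
        warnings.warn("no deceleration phase detected; returning last timepoint")
        return float(t[-1])
    idx = decel[int(np.argmin(d2[decel]))]
    return float(t2[idx])


def plate_resistance(
    od_drug: PlateGrowthCurve, od_solvent: PlateGrowthCurve, t_sat: float
) -> float:
    """OD_drug(t_sat) / OD_solvent(t_sat), linearly interpolating readings."""
    for c in (od_drug, od_solvent):
        if not (c.times[0] <= t_sat <= c.times[-1]):
            raise ValueError("t_sat outside curve time range")
    num = float(np.interp(t_sat, od_drug.times, od_drug.od))
    den = float(np.interp(t_sat, od_solvent.times, od_solvent.od))
    return num / den


class IC50Result(NamedTuple):
    value: float
    censored: str  # "none", "low" (below grid) or "high" (above grid)


def interpolate_ic50(resistance_by_concentration: dict[float, float]) -> IC50Result:
    """Concentration at which the resistance profile crosses 0.5.

    Linear interpolation between measured concentrations; if 0.5 is not
    bracketed, the estimate is censored at the grid boundary.
    """
    items = sorted(resistance_by_concentration.items())
    if len(items) < 2:
        raise ValueError("need >= 2 concentrations")
    conc = np.array([c for c, _ in items], dtype=float)
    res = np.array([r for _, r in items], dtype=float)
    if res[0] < 0.5:
        return IC50Result(float(conc[0]), "low")
    for i in range(len(conc) - 1):
        r0, r1 = res[i], res[i + 1]
        if (r0 - 0.5) * (r1 - 0.5) <= 0 and r0 != r1:
            frac = (r0 - 0.5) / (r0 - r1)
            return IC50Result(float(conc[i] + frac * (conc[i + 1] - conc[i])), "none")
    return IC50Result(float(conc[-1]), "high")


def relative_expression(cq_target, cq_control) -> float:
    """Fold expression 2^(Cq_control - Cq_target), replicates averaged first."""
    tgt = float(np.mean(np.asarray(cq_target, dtype=float)))
    ctl = float(np.mean(np.asarray(cq_control, dtype=float)))
    if not (np.isfinite(tgt) and np.isfinite(ctl)):
        raise ValueError("Cq values must be finite")
    return float(2.0 ** (ctl - tgt))
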