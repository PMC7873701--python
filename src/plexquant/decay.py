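"""Photoconversion pulse-chase analysis: RFP/CFP time courses and two-phase
exponential decay fits.

A photoconvertible fluorophore (Dendra2-style) fused to a protein of
interest is pulse-converted from green to red; the red signal then decays as
the tagged protein is degraded, while a co-expressed CFP reports expression.
The gated per-event RFP/CFP ratio therefore traces the degradation of the
converted pool.  The decay model is

    R(t) = span_fast * exp(-k_fast t) + span_slow * exp(-k_slow t) + plateau

with nonnegative spans/plateau and k_fast > k_slow >= 0.  Fitting is
weighted least squares (inverse variance by the per-timepoint SE when
available) with a multi-start over a log-spaced rate grid; when the best
two-phase fit is degenerate (rate ratio < 3, or a span below 2% of R(0))
the model collapses to a single exponential and is reported as such.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


def half_life(k: float) -> float:
    """ln(2)/k, hours for a rate per hour."""
    if k <= 0:
        raise ValueError("rate must be positive")
    return math.log(2) / k


@dataclass
class TimeCoursePoint:
    time: float
    mean_ratio: float
    n_events: int
    ratio_se: float


def mean_ratio_timecourse(events: pd.DataFrame) -> list[TimeCoursePoint]:
    """Per-timepoint mean of per-event RFP/CFP ratios with standard errors.

    ``events`` has columns time_h, rfp, cfp for the gated RFP-positive
    population (gating is input metadata, not recomputed here).  Timepoints
    are returned sorted; a timepoint with no events is simply absent.
    """
    if (events["cfp"] <= 0).any():
        raise ValueError("CFP must be positive for every event")
    ratio = events["rfp"] / events["cfp"]
    points = []
    for t, grp in ratio.groupby(events["time_h"]):
        n = len(grp)
        se = float(grp.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        points.append(TimeCoursePoint(float(t), float(grp.mean()), n, se))
    return sorted(points, key=lambda p: p.time)


@dataclass
class BiphasicFit:
    span_fast: float
    k_fast: float
    span_slow: float
    k_slow: float
    plateau: float
    rss: float
    model: str  # "biphasic" | "monophasic"
    converged: bool

    @property
    def half_life_fast(self) -> float:
        return half_life(self.k_fast) if self.k_fast > 0 else math.inf

    @property
    def half_life_slow(self) -> float:
        return half_life(self.k_slow) if self.k_slow > 0 else math.inf

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return (
            self.span_fast * np.exp(-self.k_fast * t)
            + self.span_slow * np.exp(-self.k_slow * t)
            + self.plateau
        )


def _weights(points: list[TimeCoursePoint]) -> np.ndarray:
    se = np.array([p.ratio_se for p in points])
    if np.all(se > 0):
        return 1.0 / se
    return np.ones(len(points))


def _fit_curve(t, y, w, n_exp, pin_plateau, k_starts):
    """Best weighted LSQ fit with ``n_exp`` exponentials over multi-starts."""
    y0 = max(y.max(), 1e-12)
    best = None
    for ks in k_starts:
        if n_exp == 2:
            kf, ksl = ks
            x0 = [0.5 * y0, kf, 0.5 * y0, ksl] + ([] if pin_plateau else [max(y.min(), 0.0)])

            def resid(x):
                sf, kf_, ss, ks_ = x[:4]
                pl = 0.0 if pin_plateau else x[4]
                return w * (sf * np.exp(-kf_ * t) + ss * np.exp(-ks_ * t) + pl - y)

            lb = [0.0, 0.0, 0.0, 0.0] + ([] if pin_plateau else [0.0])
            ub = [np.inf] * len(x0)
        else:
            (k1,) = ks
            x0 = [y0, k1] + ([] if pin_plateau else [max(y.min(), 0.0)])

            def resid(x):
                s, k = x[:2]
                pl = 0.0 if pin_plateau else x[2]
                return w * (s * np.exp(-k * t) + pl - y)

            lb = [0.0, 0.0] + ([] if pin_plateau else [0.0])
            ub = [np.inf] * len(x0)
        try:
            sol = least_squares(
                resid, x0, bounds=(lb, ub), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        rss = float(np.sum((resid(sol.x) / w) ** 2))
        if best is None or rss < best[1]:
            best = (sol, rss)
    return best


def fit_biphasic(
    points: list[TimeCoursePoint],
    pin_plateau: bool = False,
    n_starts: int = 16,
    min_rate_ratio: float = 3.0,
    min_span_fraction: float = 0.02,
) -> BiphasicFit:
    """Fit the two-phase decay, falling back to one phase when degenerate.

    Requires >= 5 timepoints for the two-phase model.  Multi-start initial
    rates are log-spaced over scales implied by the sampled time range.
    """
    if len(points) < 5:
        raise ValueError("need at least 5 timepoints for a biphasic fit")
    t = np.array([p.time for p in points])
    y = np.array([p.mean_ratio for p in points])
    w = _weights(points)
    t_span = max(t.max() - t.min(), 1e-6)

    # constant data: plateau-only
    if np.allclose(y, y[0], rtol=1e-12, atol=1e-12 * max(1.0, abs(y[0]))):
        return BiphasicFit(0.0, 0.0, 0.0, 0.0, float(y[0]), 0.0, "monophasic", True)

    k_grid = np.geomspace(0.05 / t_span, 50.0 / t_span, max(4, int(round(math.sqrt(n_starts)))))
    bi_starts = [(kf, ksl) for kf in k_grid for ksl in k_grid if kf > ksl]
    if not bi_starts:
        bi_starts = [(k_grid[-1], k_grid[0])]
    best_bi = _fit_curve(t, y, w, 2, pin_plateau, bi_starts)
    mono_starts = [(k,) for k in np.geomspace(0.05 / t_span, 50.0 / t_span, n_starts)]
    best_mono = _fit_curve(t, y, w, 1, pin_plateau, mono_starts)

    if best_bi is None and best_mono is None:
        warnings.warn("decay fit failed to converge from every start", stacklevel=2)
        return BiphasicFit(0.0, 0.0, 0.0, 0.0, float(y.mean()), float(np.sum((y - y.mean()) ** 2)), "monophasic", False)

    def unpack_bi(sol):
        sf, kf, ss, ksl = sol.x[:4]
        pl = 0.0 if pin_plateau else sol.x[4]
        if kf < ksl:  # enforce fast/slow ordering
            sf, ss = ss, sf
            kf, ksl = ksl, kf
        return sf, kf, ss, ksl, pl

    use_mono = best_bi is None
    if not use_mono:
        sf, kf, ss, ksl, pl = unpack_bi(best_bi[0])
        r0 = sf + ss + pl
        ratio = kf / ksl if ksl > 0 else math.inf
        if ratio < min_rate_ratio or min(sf, ss) < min_span_fraction * max(r0, 1e-12):
            use_mono = True

    if use_mono and best_mono is not None:
        sol, rss = best_mono
        s, k = sol.x[:2]
        pl = 0.0 if pin_plateau else sol.x[2]
        return BiphasicFit(float(s), float(k), 0.0, 0.0, float(pl), rss, "monophasic", bool(sol.success))
    sol, rss = best_bi
    sf, kf, ss, ksl, pl = unpack_bi(sol)
    return BiphasicFit(
        float(sf), float(kf), float(ss), float(ksl), float(pl), rss, "biphasic", bool(sol.success)
    )


def fit_decay_table(
    events: pd.DataFrame,
    by: list[str] = ("construct", "genotype"),
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit one decay curve per group of a long-format event table."""
    by = [c for c in by if c in events.columns]
    rows = []
    groups = events.groupby(by) if by else [((), events)]
    for key, grp in groups:
        if not isinstance(key, tuple):
            key = (key,)
        fit = fit_biphasic(mean_ratio_timecourse(grp), **fit_kwargs)
        rows.append(
            dict(zip(by, key))
            | {
                "model": fit.model,
                "span_fast": fit.span_fast,
                "k_fast": fit.k_fast,
                "half_life_fast_h": fit.half_life_fast,
                "span_slow": fit.span_slow,
                "k_slow": fit.k_slow,
                "half_life_slow_h": fit.half_life_slow,
                "plateau": fit.plateau,
                "rss": fit.rss,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
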