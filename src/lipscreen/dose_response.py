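"""Four-parameter log-logistic (LL.4) dose-response fitting per precursor.

The model is f(x) = c + (d - c) / (1 + (x/e)^b) on the dose domain, with the
zero-dose control handled by the continuous limit (f(0) = d for b > 0,
f(0) = c for b < 0).  Parameters are estimated by bounded least squares with
multi-start initialization; the sigmoid-trend strength is the Pearson
correlation r between observed responses and model predictions at the same
doses, computed on replicate-level values.  The half-maximal response
concentration is e: f(e) = (c + d) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .preprocess import NormalizedMatrix
from .stats import bh_adjust, one_way_anova_f, pearson_r

__all__ = [
    "DoseResponseFit",
    "ll4",
    "fit_ll4",
    "correlation_to_fit",
    "fit_screen",
    "anova_by_dose",
    "call_dose_responsive_peptides",
]

_B_MAX = 50.0


@dataclass
class DoseResponseFit:
    b: float  # slope (signed)
    c: float  # lower asymptote (scaled units)
    d: float  # upper asymptote (scaled units)
    e: float  # half-maximal response concentration (dose units)
    r: float = math.nan  # Pearson correlation observed vs fitted
    anova_p: float = math.nan
    anova_q: float = math.nan
    converged: bool = False
    rss: float = math.inf


def ll4(x, b: float, c: float, d: float, e: float):
    """Evaluate the LL.4 model; x = 0 is mapped to the limit value."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x > 0
    out[pos] = c + (d - c) / (1.0 + (x[pos] / e) ** b)
    out[~pos] = d if b > 0 else c
    return out


def _residual_factory(x, y, sign: int):
    xp = x[x > 0]
    yp = y[x > 0]
    y0 = y[x <= 0]
    n0 = y0.size
    lnx = np.log(xp)

    def resid(theta):
        b, c, d, loge = theta
        u = np.exp(np.clip(b * (lnx - loge), -300.0, 300.0))
        pred_pos = c + (d - c) / (1.0 + u)
        pred0 = d if sign > 0 else c
        return np.concatenate([pred_pos - yp, np.full(n0, pred0) - y0])

    def jac(theta):
        b, c, d, loge = theta
        u = np.exp(np.clip(b * (lnx - loge), -300.0, 300.0))
        denom = 1.0 + u
        dpred_du = -(d - c) / denom**2
        J = np.zeros((xp.size + n0, 4))
        J[: xp.size, 0] = dpred_du * u * (lnx - loge)
        J[: xp.size, 1] = u / denom
        J[: xp.size, 2] = 1.0 / denom
        J[: xp.size, 3] = dpred_du * (-b * u)
        if sign > 0:
            J[xp.size :, 2] = 1.0
        else:
            J[xp.size :, 1] = 1.0
        return J

    return resid, jac


def fit_ll4(doses, responses) -> DoseResponseFit:
    """Least-squares LL.4 fit with multi-start initialization.

    Starts: c0 = min response, d0 = max response, e0 on a geometric grid
    spanning the positive doses, b0 in {-2, -1, 1, 2}; slope sign is fixed
    per start (the model is discontinuous in b at 0 when x = 0 data are
    present).  Best start by RSS, ties by smaller |b|.  ``converged`` is
    False when every start fails or the fitted e leaves
    [min positive dose / 100, max dose * 100].
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if np.unique(x).size < 5:
        raise ValueError("need >= 5 distinct dose conditions with data")
    pos = np.unique(x[x > 0])
    if pos.size < 2 or np.ptp(y) == 0:
        return DoseResponseFit(math.nan, float(y.mean()), float(y.mean()),
                               math.nan, converged=False)
    c0, d0 = float(y.min()), float(y.max())
    e_grid = np.geomspace(pos.min(), pos.max(), 3)
    e_lo, e_hi = pos.min() / 100.0, pos.max() * 100.0
    span = d0 - c0
    best: tuple[float, float, np.ndarray] | None = None  # (rss, |b|, theta)
    for b0 in (-2.0, -1.0, 1.0, 2.0):
        sign = 1 if b0 > 0 else -1
        resid, jac = _residual_factory(x, y, sign)
        b_bounds = (1e-3, _B_MAX) if sign > 0 else (-_B_MAX, -1e-3)
        bounds = (
            [b_bounds[0], c0 - abs(span) - 1.0, c0 - abs(span) - 1.0, math.log(e_lo)],
            [b_bounds[1], d0 + abs(span) + 1.0, d0 + abs(span) + 1.0, math.log(e_hi)],
        )
        for e0 in e_grid:
            theta0 = np.array([b0, c0, d0, math.log(e0)])
            try:
                sol = least_squares(resid, theta0, jac=jac, bounds=bounds,
                                    method="trf", xtol=1e-9, ftol=1e-9,
                                    max_nfev=150)
            except Exception:
                continue
            if not sol.success and not np.isfinite(sol.cost):
                continue
            rss = float(2.0 * sol.cost)
            cand = (rss, abs(float(sol.x[0])), sol.x)
            if best is None or cand[:2] < best[:2]:
                best = cand
    if best is None:
        return DoseResponseFit(math.nan, math.nan, math.nan, math.nan, converged=False)
    rss, _, theta = best
    b, c, d, loge = (float(v) for v in theta)
    e = math.exp(loge)
    converged = bool(np.isfinite([b, c, d, e]).all()) and e_lo <= e <= e_hi
    if abs(d - c) < 1e-9:  # degenerate flat fit: no dose response signal
        converged = False
    fit = DoseResponseFit(b, c, d, e, converged=converged, rss=rss)
    fit.r = correlation_to_fit(fit, x, y) if converged else math.nan
    return fit


def correlation_to_fit(fit: DoseResponseFit, doses, responses) -> float:
    """Pearson r between observed replicate-level responses and the model
    predictions at the same doses; NaN for degenerate fits."""
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    pred = ll4(x, fit.b, fit.c, fit.d, fit.e)
    return pearson_r(y, pred)


def anova_by_dose(matrix: NormalizedMatrix) -> pd.DataFrame:
    """One-way ANOVA across dose conditions per precursor on the normalized
    *unscaled* abundances, BH-adjusted over precursors."""
    rows = []
    dose_cols = {d: matrix.runs_at_dose(d) for d in matrix.doses}
    for prec in matrix.values.index:
        row = matrix.values.loc[prec]
        groups = [row[cols].to_numpy(dtype=float) for cols in dose_cols.values()]
        groups = [g[np.isfinite(g)] for g in groups]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2 or sum(g.size for g in groups) - len(groups) < 1:
            rows.append((prec, math.nan, math.nan))
            continue
        res = one_way_anova_f(groups)
        rows.append((prec, res.f, res.p))
    out = pd.DataFrame(rows, columns=["precursor_id", "anova_f", "anova_p"]).set_index(
        "precursor_id"
    )
    out["anova_q"] = bh_adjust(out["anova_p"].to_numpy())
    return out


def fit_screen(
    scaled: NormalizedMatrix, unscaled: NormalizedMatrix | None = None
) -> pd.DataFrame:
    """Fit LL.4 per precursor of a unit-scaled matrix.

    Returns a frame indexed by precursor with columns b, c, d, e, r, rss,
    converged (+ anova_p/q merged from ``unscaled`` when given).
    """
    doses_per_run = scaled.runs["dose"].to_numpy(dtype=float)
    records = {}
    for prec in scaled.values.index:
        if prec in scaled.constant:
            records[prec] = DoseResponseFit(math.nan, math.nan, math.nan, math.nan,
                                            converged=False)
            continue
        y = scaled.values.loc[prec].to_numpy(dtype=float)
        try:
            records[prec] = fit_ll4(doses_per_run, y)
        except ValueError:
            records[prec] = DoseResponseFit(math.nan, math.nan, math.nan, math.nan,
                                            converged=False)
    out = pd.DataFrame(
        {
            "b": {k: f.b for k, f in records.items()},
            "c": {k: f.c for k, f in records.items()},
            "d": {k: f.d for k, f in records.items()},
            "e": {k: f.e for k, f in records.items()},
            "r": {k: f.r for k, f in records.items()},
            "rss": {k: f.rss for k, f in records.items()},
            "converged": {k: f.converged for k, f in records.items()},
        }
    ).loc[list(scaled.values.index)]
    out.index.name = "precursor_id"
    if unscaled is not None:
        an = anova_by_dose(unscaled)
        out = out.join(an[["anova_p", "anova_q"]], how="left")
    return out


def call_dose_responsive_peptides(
    fits: pd.DataFrame,
    anova_q: pd.Series | None = None,
    r_threshold: float = 0.85,
    anova_q_threshold: float = 0.01,
) -> set[str]:
    """Precursors with a converged fit, r > ``r_threshold`` and
    ANOVA q < ``anova_q_threshold``."""
    if anova_q is None:
        if "anova_q" not in fits.columns:
            raise ValueError("anova q-values missing from fits frame")
        anova_q = fits["anova_q"]
    if not fits.index.equals(anova_q.index):
        anova_q = anova_q.reindex(fits.index)
        if anova_q.isna().all():
            raise ValueError("ANOVA q-values cover none of the fitted precursors")
    ok = (
        fits["converged"].fillna(False).astype(bool)
        & (fits["r"] > r_threshold)
        & (anova_q < anova_q_threshold)
    )
    return set(fits.index[ok])
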