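"""Normalization, outlier removal, coverage filtering and unit scaling.

The working container is :class:`NormalizedMatrix`: a precursor x run matrix
of log2-scale abundances with per-run dose/replicate metadata.  Statistical
testing downstream uses the normalized *unscaled* values; only curve fitting
and sigmoid correlation use the [0, 1]-scaled view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .report_io import REPORT_COLUMNS

__all__ = [
    "NormalizedMatrix",
    "matrix_from_records",
    "normalize_intensities",
    "remove_outliers_iqr",
    "filter_precursors",
    "scale_unit_interval",
]


@dataclass
class NormalizedMatrix:
    """Precursor x run abundance matrix plus run and precursor metadata.

    values: DataFrame indexed by precursor_id, columns are run ids.
    runs: DataFrame indexed by run id with columns ``dose`` and ``replicate``.
    precursors: DataFrame indexed by precursor_id with ``protein_id``,
        ``peptide_seq`` and ``tryptic_type``.
    scaled: True for a unit-interval view; constant: precursors flagged as
        constant (excluded from dose-response fitting).
    provenance: method name and fitted per-run calibration parameters.
    """

    values: pd.DataFrame
    runs: pd.DataFrame
    precursors: pd.DataFrame
    scaled: bool = False
    constant: set[str] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.runs["dose"].unique())

    def runs_at_dose(self, dose: float) -> list[str]:
        return list(self.runs.index[np.isclose(self.runs["dose"], dose)])

    def subset(self, precursor_ids) -> "NormalizedMatrix":
        ids = [p for p in self.values.index if p in set(precursor_ids)]
        return replace(
            self,
            values=self.values.loc[ids],
            precursors=self.precursors.loc[ids],
            constant={c for c in self.constant if c in set(ids)},
        )


def matrix_from_records(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pivot a long-format report into (raw matrix, run metadata, precursor metadata)."""
    df = records.copy()
    df["run_id"] = (
        df["dose"].map(lambda d: format(float(d), "g")) + "_r" + df["replicate"].astype(str)
    )
    mat = df.pivot_table(
        index="precursor_id", columns="run_id", values="intensity", aggfunc="first"
    )
    runs = (
        df[["run_id", "dose", "replicate"]]
        .drop_duplicates("run_id")
        .set_index("run_id")
        .loc[mat.columns]
    )
    prec_cols = ["precursor_id", "protein_id", "peptide_seq"]
    if "tryptic_type" in df.columns:
        prec_cols.append("tryptic_type")
    prec = df[prec_cols].drop_duplicates("precursor_id").set_index("precursor_id").loc[mat.index]
    return mat, runs, prec


def _irls_affine(run: np.ndarray, ref: np.ndarray, n_iter: int = 20) -> tuple[float, float]:
    """Robust (Huber-weighted IRLS) fit of run ~ a*ref + b on complete pairs."""
    mask = np.isfinite(run) & np.isfinite(ref)
    x, y = ref[mask], run[mask]
    if x.size < 3 or np.ptp(x) == 0:
        return 1.0, 0.0
    w = np.ones_like(x)
    a, b = 1.0, 0.0
    for _ in range(n_iter):
        sw = w.sum()
        xm, ym = (w * x).sum() / sw, (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 0:
            break
        a_new = (w * (x - xm) * (y - ym)).sum() / sxx
        b_new = ym - a_new * xm
        resid = y - (a_new * x + b_new)
        scale = 1.4826 * np.median(np.abs(resid)) + 1e-12
        u = np.abs(resid) / (1.345 * scale)
        w = np.where(u <= 1.0, 1.0, 1.0 / u)
        if abs(a_new - a) < 1e-10 and abs(b_new - b) < 1e-10:
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    if not np.isfinite(a) or a <= 0:
        a, b = float(np.median(y) / max(np.median(x), 1e-12)), 0.0
    return float(a), float(b)


def _glog_param(cal: np.ndarray) -> float:
    """Additive-noise scale for the generalized log, estimated by regressing
    per-precursor replicate variance on squared mean (var = sa2 + sm2*mean^2)."""
    means = np.nanmean(cal, axis=1)
    vars_ = np.nanvar(cal, axis=1, ddof=1)
    ok = np.isfinite(means) & np.isfinite(vars_)
    m, v = means[ok], vars_[ok]
    if m.size < 5:
        return float(np.nanmedian(cal) / 10.0 + 1e-9)
    X = np.column_stack([np.ones_like(m), m**2])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    sa2, sm2 = max(coef[0], 0.0), max(coef[1], 0.0)
    if sm2 <= 0 or sa2 <= 0:
        return float(np.nanmedian(cal) / 10.0 + 1e-9)
    return float(np.sqrt(sa2 / sm2))


def normalize_intensities(records: pd.DataFrame, method: str = "median_log2") -> NormalizedMatrix:
    """Normalize raw intensities to log2-scale abundances.

    ``median_log2``: log2 transform, then shift every run's median to the
    grand median.  ``vst``: per-run affine calibration (scale + offset,
    robust IRLS against a row-median reference run) followed by a
    generalized-log transform ``log2((y + sqrt(y^2 + c^2)) / 2)`` that
    agrees with log2 at high intensity.  Both methods preserve rank order
    within each run.
    """
    raw, runs, prec = matrix_from_records(records)
    if raw.shape[1] < 2:
        raise ValueError("need at least 2 runs to normalize")
    vals = raw.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise ValueError("intensities must be positive")
    if method == "median_log2":
        log2 = np.log2(vals)
        run_medians = np.nanmedian(log2, axis=0)
        grand = np.nanmedian(log2)
        out = log2 - run_medians[None, :] + grand
        provenance = {
            "method": "median_log2",
            "run_offsets": dict(zip(raw.columns, (run_medians - grand).tolist())),
        }
    elif method == "vst":
        ref = np.nanmedian(vals, axis=1)
        cal = np.empty_like(vals)
        params = {}
        for j, col in enumerate(raw.columns):
            a, b = _irls_affine(vals[:, j], ref)
            cal[:, j] = (vals[:, j] - b) / a
            params[col] = {"scale": a, "offset": b}
        c = _glog_param(cal)
        out = np.log2((cal + np.sqrt(cal**2 + c**2)) / 2.0)
        provenance = {"method": "vst", "glog_c": c, "run_calibration": params}
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    values = pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return NormalizedMatrix(values=values, runs=runs, precursors=prec, provenance=provenance)


def remove_outliers_iqr(matrix: NormalizedMatrix, multiplier: float = 1.5) -> NormalizedMatrix:
    """Mask per-(precursor, dose condition) values outside the Tukey fences.

    Values below Q1 - multiplier*IQR or above Q3 + multiplier*IQR are set to
    missing.  Quartiles use linear interpolation (type 7).  Condition groups
    with fewer than 3 present values pass through untouched.  Applied once.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    vals = matrix.values.to_numpy(dtype=float).copy()
    for dose in matrix.doses:
        cols = [matrix.values.columns.get_loc(r) for r in matrix.runs_at_dose(dose)]
        block = vals[:, cols]
        n_present = np.isfinite(block).sum(axis=1)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q1 = np.nanquantile(block, 0.25, axis=1)
            q3 = np.nanquantile(block, 0.75, axis=1)
        iqr = q3 - q1
        lo = q1 - multiplier * iqr
        hi = q3 + multiplier * iqr
        eligible = n_present >= 3
        mask = eligible[:, None] & ((block < lo[:, None]) | (block > hi[:, None]))
        block[mask] = np.nan
        vals[:, cols] = block
    values = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    out = NormalizedMatrix(
        values=values, runs=matrix.runs, precursors=matrix.precursors,
        scaled=matrix.scaled, constant=set(matrix.constant),
        provenance={**matrix.provenance, "outlier_multiplier": multiplier},
    )
    return out


def filter_precursors(
    matrix: NormalizedMatrix,
    min_precursors_per_protein: int = 2,
    min_replicates: int = 3,
    min_conditions: int = 5,
    coverage_scope: str = "per_condition",
) -> NormalizedMatrix:
    """Coverage filter: keep precursors measured in >= ``min_replicates``
    replicates in each of >= ``min_conditions`` dose conditions, then keep
    proteins with >= ``min_precursors_per_protein`` surviving precursors.

    ``coverage_scope="global"`` instead requires >= ``min_replicates``
    present values in total while still covering >= ``min_conditions``
    conditions with any data.
    """
    present = np.isfinite(matrix.values.to_numpy(dtype=float))
    doses = matrix.doses
    per_dose_counts = np.column_stack(
        [
            present[:, [matrix.values.columns.get_loc(r) for r in matrix.runs_at_dose(d)]].sum(axis=1)
            for d in doses
        ]
    )
    if coverage_scope == "per_condition":
        cond_ok = (per_dose_counts >= min_replicates).sum(axis=1)
        keep = cond_ok >= min_conditions
    elif coverage_scope == "global":
        keep = (present.sum(axis=1) >= min_replicates) & (
            (per_dose_counts >= 1).sum(axis=1) >= min_conditions
        )
    else:
        raise ValueError(f"unknown coverage_scope {coverage_scope!r}")
    ids = matrix.values.index[keep]
    prot = matrix.precursors.loc[ids, "protein_id"]
    counts = prot.value_counts()
    good_proteins = set(counts.index[counts >= min_precursors_per_protein])
    ids = [p for p in ids if prot.loc[p] in good_proteins]
    return matrix.subset(ids)


def scale_unit_interval(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Per-precursor min-max scaling of present values to [0, 1].

    Precursors with fewer than 2 distinct present values are flagged as
    constant; their scaled values are NaN and they are excluded from
    dose-response fitting (not fatal).
    """
    vals = matrix.values.to_numpy(dtype=float)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mins = np.nanmin(vals, axis=1)
        maxs = np.nanmax(vals, axis=1)
    rng = maxs - mins
    const_mask = ~np.isfinite(rng) | (rng <= 0)
    scaled = (vals - mins[:, None]) / np.where(const_mask, np.nan, rng)[:, None]
    values = pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.values.columns)
    constant = set(matrix.values.index[const_mask])
    return NormalizedMatrix(
        values=values, runs=matrix.runs, precursors=matrix.precursors,
        scaled=True, constant=constant,
        provenance={**matrix.provenance, "scaled": True},
    )
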