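"""Differential testing, scoring and candidate-interactor assembly.

A peptide precursor is a *hit* when it is both dose-responsive (sigmoid
correlation r above threshold, ANOVA q below threshold) and differentially
abundant between the contrast conditions (|log2 FC| and moderated-t q
thresholds, mode-dependent).  Hits are grouped by protein; the protein-level
half-maximal response concentration is the minimum EC50 among its
significant precursors.  The FT/ST identity of a peptide together with the
sign of its fold change encodes whether the underlying region gained or
lost protease protection when the bait was added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix
from .report_io import SiteAnnotation, TrypticType
from .stats import VariancePrior, bh_adjust, fit_variance_prior, moderated_t_test, wilcoxon_rank_sum

__all__ = [
    "DifferentialResult",
    "CandidateInteractor",
    "MODE_THRESHOLDS",
    "Q_FLOOR",
    "differential_contrast",
    "compute_score",
    "protection_direction",
    "map_peptides_to_sites",
    "assemble_candidates",
    "top_hits_by_correlation",
    "compare_ec50_distributions",
]

#: (|log2 FC| threshold, q threshold) per screening mode.
MODE_THRESHOLDS = {
    "lysate": (0.75, 0.01),
    "purified": (1.0, 0.01),
    "protein_abundance": (math.log2(1.5), 0.05),
}

Q_FLOOR = 1e-15


@dataclass
class DifferentialResult:
    unit_id: str
    log2_fc: float
    p: float
    q: float
    score: float = math.nan
    significant: bool = False


@dataclass
class CandidateInteractor:
    protein_id: str
    significant_precursors: pd.DataFrame  # per-precursor fit + differential columns
    protein_ec50: float  # minimum e among significant precursors
    best_r: float  # r of the lowest-EC50 precursor
    best_score: float  # highest score among significant precursors
    directions: dict[str, str] = field(default_factory=dict)
    site_calls: dict[str, str] = field(default_factory=dict)


def differential_contrast(
    matrix: NormalizedMatrix,
    contrast: tuple[float, float],
    prior: VariancePrior | None = None,
    mode: str = "lysate",
) -> pd.DataFrame:
    """Moderated-t contrast of two dose conditions.

    Units are precursors, or proteins in ``protein_abundance`` mode (raw
    intensities summed over each protein's precursors before log2).  The
    variance prior is fitted across all tested units when not supplied.
    Returns a frame with log2_fc, t, p, q, score and significance at the
    mode's thresholds.
    """
    if mode not in MODE_THRESHOLDS:
        raise ValueError(f"unknown mode {mode!r}")
    dose_a, dose_b = contrast
    cols_a = matrix.runs_at_dose(dose_a)
    cols_b = matrix.runs_at_dose(dose_b)
    if not cols_a or not cols_b:
        raise ValueError(f"contrast condition missing from matrix: {contrast}")
    values = matrix.values
    if mode == "protein_abundance":
        raw = np.power(2.0, values)
        grouped = raw.groupby(matrix.precursors["protein_id"]).sum(min_count=1)
        values = np.log2(grouped)
    a = values[cols_a].to_numpy(dtype=float)
    b = values[cols_b].to_numpy(dtype=float)
    testable = (np.isfinite(a).sum(axis=1) >= 2) & (np.isfinite(b).sum(axis=1) >= 2)
    units = values.index[testable]
    a, b = a[testable], b[testable]
    if prior is None:
        na = np.isfinite(a).sum(axis=1)
        nb = np.isfinite(b).sum(axis=1)
        df = na + nb - 2
        s2 = (
            (na - 1) * np.nanvar(a, axis=1, ddof=1)
            + (nb - 1) * np.nanvar(b, axis=1, ddof=1)
        ) / df
        try:
            prior = fit_variance_prior(s2, df)
        except ValueError:
            # degenerate screen (e.g. noiseless synthetic data): shrink
            # completely to a vanishing variance floor
            prior = VariancePrior(math.inf, 1e-12)
    rows = []
    for i, unit in enumerate(units):
        res = moderated_t_test(a[i], b[i], prior)
        rows.append((unit, res.effect, res.t_mod, res.p))
    out = pd.DataFrame(rows, columns=["unit_id", "log2_fc", "t", "p"]).set_index("unit_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["score"] = np.abs(out["log2_fc"]) / np.maximum(out["q"], Q_FLOOR)
    fc_thr, q_thr = MODE_THRESHOLDS[mode]
    out["significant"] = (np.abs(out["log2_fc"]) > fc_thr) & (out["q"] < q_thr)
    out.attrs["prior"] = prior
    out.attrs["contrast"] = (dose_a, dose_b)
    out.attrs["mode"] = mode
    return out


def compute_score(log2_fc: float, q: float, q_floor: float = Q_FLOOR) -> float:
    """score = |log2 FC| / adjusted p, with the q-value floored at
    ``q_floor`` to keep the score finite."""
    return abs(log2_fc) / max(q, q_floor)


def protection_direction(tryptic_type: TrypticType | str, log2_fc: float) -> str | None:
    """Map peptide class and fold-change sign to a protection call.

    A semi-tryptic peptide arises from a protease cut inside the region:
    less cutting (protection by the bound bait) means less of it, so
    ST + decrease = increased protection.  A fully tryptic peptide survives
    when the internal cut does NOT happen, so FT + increase = increased
    protection.  Returns None (undefined) for a zero fold change.
    """
    tt = TrypticType(tryptic_type)
    if tt not in (TrypticType.FT, TrypticType.ST):
        raise ValueError(f"direction undefined for tryptic type {tt}")
    if log2_fc == 0 or not np.isfinite(log2_fc):
        return None
    if tt is TrypticType.ST:
        return "increased_protection" if log2_fc < 0 else "decreased_protection"
    return "increased_protection" if log2_fc > 0 else "decreased_protection"


def map_peptides_to_sites(
    peptide_interval: tuple[int, int],
    sites: list[SiteAnnotation],
    near_window: int = 10,
    mode: str = "overlap",
    protein_id: str | None = None,
) -> str:
    """Classify a localized peptide relative to annotated sites.

    ``at``: the peptide interval overlaps a site (``mode="containment"``
    instead requires the peptide to contain the full site, the strict
    direct-mapping notion); ``near``: gap to the closest site is at most
    ``near_window`` residues; ``distant`` otherwise.  1-based inclusive
    coordinates.  Ties between equally close sites go to the smaller start.
    """
    if not sites:
        return "unannotated"
    if protein_id is not None:
        wrong = [s for s in sites if s.protein_id != protein_id]
        if wrong:
            raise ValueError(
                f"site {wrong[0].site_name!r} annotated on {wrong[0].protein_id!r}, "
                f"peptide is on {protein_id!r}"
            )
    ps, pe = peptide_interval
    if not (1 <= ps <= pe):
        raise ValueError(f"invalid peptide interval [{ps}, {pe}]")
    best_gap, best_start, best_at = None, None, False
    for s in sorted(sites, key=lambda s: (s.start, s.end)):
        overlaps = ps <= s.end and s.start <= pe
        if mode == "containment":
            is_at = ps <= s.start and s.end <= pe
        elif mode == "overlap":
            is_at = overlaps
        else:
            raise ValueError(f"unknown site mode {mode!r}")
        # residues strictly between the intervals (adjacent intervals: gap 0)
        gap = 0 if overlaps else max(s.start - pe, ps - s.end) - 1
        if best_gap is None or (gap, s.start) < (best_gap, best_start):
            best_gap, best_start, best_at = gap, s.start, is_at
    if best_at:
        return "at"
    if best_gap <= near_window:
        return "near"
    return "distant"


def assemble_candidates(
    dose_hits: set[str],
    diff_results: pd.DataFrame,
    fits: pd.DataFrame,
    precursors: pd.DataFrame,
    sites: dict[str, list[SiteAnnotation]] | None = None,
    peptide_intervals: dict[str, tuple[int, int]] | None = None,
    near_window: int = 10,
    site_mode: str = "overlap",
) -> list[CandidateInteractor]:
    """Group hit precursors into protein-level candidate interactors.

    A precursor qualifies when it is in ``dose_hits`` (dose-responsive) and
    significant in ``diff_results``.  The protein EC50 is the minimum e of
    its significant precursors; candidates are sorted by their best
    precursor score (descending), ties by protein id.
    """
    sig = diff_results.index[diff_results["significant"].astype(bool)]
    hit_ids = sorted(dose_hits & set(sig) & set(fits.index))
    out: list[CandidateInteractor] = []
    if not hit_ids:
        return out
    table = fits.loc[hit_ids].join(
        diff_results.loc[hit_ids, ["log2_fc", "p", "q", "score"]]
    )
    table = table.join(precursors[["protein_id", "peptide_seq", "tryptic_type"]], how="left")
    for protein_id, sub in table.groupby("protein_id", sort=True):
        ec = sub["e"].astype(float)
        protein_ec50 = float(ec.min())
        best_prec = ec.idxmin()
        directions = {}
        site_calls = {}
        for prec, row in sub.iterrows():
            try:
                directions[prec] = protection_direction(row["tryptic_type"], row["log2_fc"])
            except ValueError:
                directions[prec] = None
            call = "unannotated"
            if sites is not None and peptide_intervals is not None:
                prot_sites = sites.get(protein_id, [])
                interval = peptide_intervals.get(prec)
                if prot_sites and interval is not None:
                    call = map_peptides_to_sites(
                        interval, prot_sites, near_window=near_window, mode=site_mode,
                        protein_id=protein_id,
                    )
            site_calls[prec] = call
        out.append(
            CandidateInteractor(
                protein_id=str(protein_id),
                significant_precursors=sub,
                protein_ec50=protein_ec50,
                best_r=float(sub.loc[best_prec, "r"]),
                best_score=float(sub["score"].max()),
                directions=directions,
                site_calls=site_calls,
            )
        )
    out.sort(key=lambda cand: (-cand.best_score, cand.protein_id))
    return out


def top_hits_by_correlation(
    candidates: list[CandidateInteractor], max_dose: float = 2.0, n: int = 50
) -> list[CandidateInteractor]:
    """Keep candidates with 0 < protein EC50 <= ``max_dose`` and return the
    ``n`` with the highest sigmoid correlation of their lowest-EC50
    precursor; ties by higher score, then protein id."""
    kept = [c for c in candidates if 0 < c.protein_ec50 <= max_dose]
    kept.sort(key=lambda c: (-c.best_r, -c.best_score, c.protein_id))
    return kept[:n]


def compare_ec50_distributions(group_a, group_b) -> float:
    """Two-sided rank-sum p comparing protein-level EC50 distributions."""
    return wilcoxon_rank_sum(group_a, group_b)


def candidates_to_frame(candidates: list[CandidateInteractor]) -> pd.DataFrame:
    """Flatten candidates to the report table written by the screen."""
    rows = []
    for c in candidates:
        n_inc = sum(1 for v in c.directions.values() if v == "increased_protection")
        rows.append(
            {
                "protein_id": c.protein_id,
                "ec50": c.protein_ec50,
                "best_r": c.best_r,
                "best_score": c.best_score,
                "n_sig_peptides": len(c.significant_precursors),
                "n_increased_protection": n_inc,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "ec50", "best_r", "best_score",
            "n_sig_peptides", "n_increased_protection",
        ],
    )
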