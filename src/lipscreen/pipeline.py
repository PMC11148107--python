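"""End-to-end dose-response screen: report in, candidate interactors out.

Pipeline stages, in order: normalization -> per-condition IQR outlier
masking -> coverage filtering -> ANOVA across doses (on unscaled
abundances) -> unit-interval scaling -> per-precursor LL.4 fitting and
sigmoid correlation -> moderated-t differential contrast (default: highest
dose vs zero-dose control) -> protein-level candidate assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import call_dose_responsive_peptides, fit_screen
from .hits import (
    CandidateInteractor,
    assemble_candidates,
    candidates_to_frame,
    differential_contrast,
)
from .preprocess import (
    NormalizedMatrix,
    filter_precursors,
    normalize_intensities,
    remove_outliers_iqr,
    scale_unit_interval,
)
from .report_io import ScreenConfig, SiteAnnotation

__all__ = ["ScreenResult", "run_screen"]


@dataclass
class ScreenResult:
    """All intermediate and final tables of one screening run."""

    config: ScreenConfig
    matrix: NormalizedMatrix  # normalized, outlier-masked, filtered (unscaled)
    scaled: NormalizedMatrix
    fits: pd.DataFrame  # per-precursor LL.4 parameters, r, ANOVA p/q
    dose_hits: set[str]  # dose-responsive precursors
    differential: pd.DataFrame  # per-precursor moderated-t results
    candidates: list[CandidateInteractor] = field(default_factory=list)

    @property
    def hit_precursors(self) -> set[str]:
        sig = set(self.differential.index[self.differential["significant"]])
        return self.dose_hits & sig

    @property
    def candidate_proteins(self) -> set[str]:
        return {c.protein_id for c in self.candidates}

    @property
    def detected_proteins(self) -> set[str]:
        return set(self.matrix.precursors["protein_id"])

    def candidates_table(self) -> pd.DataFrame:
        return candidates_to_frame(self.candidates)

    def write_tables(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.fits.to_csv(directory / "peptide_fits.tsv", sep="\t", na_rep=".")
        self.differential.to_csv(directory / "differential.tsv", sep="\t", na_rep=".")
        self.candidates_table().to_csv(
            directory / "candidates.tsv", sep="\t", index=False, na_rep="."
        )


def run_screen(
    records: pd.DataFrame,
    config: ScreenConfig | None = None,
    contrast: tuple[float, float] | None = None,
    sites: dict[str, list[SiteAnnotation]] | None = None,
    peptide_intervals: dict[str, tuple[int, int]] | None = None,
) -> ScreenResult:
    """Run the full dose-response screen on a long-format peptide report.

    ``contrast`` defaults to (highest dose, 0): maximal bait occupancy
    yields the largest fold changes.  Statistical testing (ANOVA and the
    moderated t) uses normalized unscaled abundances; curve fitting and the
    sigmoid correlation use the unit-scaled values.
    """
    config = config or ScreenConfig()
    matrix = normalize_intensities(records, method=config.normalization)
    matrix = remove_outliers_iqr(matrix, multiplier=config.outlier_multiplier)
    matrix = filter_precursors(
        matrix,
        min_precursors_per_protein=config.min_precursors_per_protein,
        min_replicates=config.min_replicates,
        min_conditions=config.min_conditions,
        coverage_scope=config.coverage_scope,
    )
    scaled = scale_unit_interval(matrix)
    fits = fit_screen(scaled, unscaled=matrix)
    dose_hits = call_dose_responsive_peptides(
        fits,
        r_threshold=config.r_threshold,
        anova_q_threshold=config.anova_q_threshold,
    )
    if contrast is None:
        doses = matrix.doses
        contrast = (float(doses.max()), 0.0)
    mode = "purified" if config.mode == "single_dose" else "lysate"
    differential = differential_contrast(matrix, contrast, mode=mode)
    if config.mode == "single_dose":
        # no dose series: hits are defined by the differential test alone
        dose_hits = set(differential.index)
    candidates = assemble_candidates(
        dose_hits,
        differential,
        fits,
        matrix.precursors,
        sites=sites,
        peptide_intervals=peptide_intervals,
        near_window=config.near_window,
        site_mode=config.site_mode,
    )
    return ScreenResult(
        config=config,
        matrix=matrix,
        scaled=scaled,
        fits=fits,
        dose_hits=dose_hits,
        differential=differential,
        candidates=candidates,
    )
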