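import math

import numpy as np
import pandas as pd
import pytest

from lipscreen.hits import (
    MODE_THRESHOLDS,
    Q_FLOOR,
    assemble_candidates,
    compare_ec50_distributions,
    compute_score,
    differential_contrast,
    map_peptides_to_sites,
    protection_direction,
    top_hits_by_correlation,
)
from lipscreen.preprocess import NormalizedMatrix
from lipscreen.report_io import SiteAnnotation


def two_condition_matrix(effects, sd=0.05, n_rep=4, seed=0):
    """Matrix with planted log2 differences (dose 4 vs control) per precursor."""
    rng = np.random.default_rng(seed)
    n = len(effects)
    cols, doses, reps = [], [], []
    for d in (0.0, 4.0):
        for r in range(1, n_rep + 1):
            cols.append(f"{d:g}_r{r}")
            doses.append(d)
            reps.append(r)
    base = rng.normal(20, 2, n)
    data = np.empty((n, len(cols)))
    for j, d in enumerate(doses):
        data[:, j] = base + (np.asarray(effects) if d > 0 else 0.0) + rng.normal(0, sd, n)
    idx = [f"PEP{i}/2" for i in range(n)]
    values = pd.DataFrame(data, index=idx, columns=cols)
    runs = pd.DataFrame({"dose": doses, "replicate": reps}, index=cols)
    prec = pd.DataFrame(
        {
            "protein_id": [f"P{i // 2}" for i in range(n)],
            "peptide_seq": [f"PEP{i}" for i in range(n)],
            "tryptic_type": ["ST" if i % 2 else "FT" for i in range(n)],
        },
        index=idx,
    )
    return NormalizedMatrix(values=values, runs=runs, precursors=prec)


class TestDifferentialContrast:
    def test_recovers_planted_fold_changes(self):
        effects = [0.0, 0.0, 2.0, -2.0, 0.0, 0.0, 0.0, 0.0]
        nm = two_condition_matrix(effects)
        res = differential_contrast(nm, (4.0, 0.0), mode="lysate")
        assert np.allclose(res["log2_fc"], effects, atol=0.15)
        assert set(res.index[res["significant"]]) == {"PEP2/2", "PEP3/2"}

    def test_purified_mode_needs_larger_fold_change(self):
        effects = [0.0] * 6 + [0.8, 2.0]
        nm = two_condition_matrix(effects, sd=0.03)
        lys = differential_contrast(nm, (4.0, 0.0), mode="lysate")
        pur = differential_contrast(nm, (4.0, 0.0), mode="purified")
        assert "PEP6/2" in set(lys.index[lys["significant"]])
        assert "PEP6/2" not in set(pur.index[pur["significant"]])
        assert "PEP7/2" in set(pur.index[pur["significant"]])

    def test_equal_means_never_significant(self):
        nm = two_condition_matrix([0.0] * 10, sd=0.05)
        res = differential_contrast(nm, (4.0, 0.0))
        assert not res["significant"].any()

    def test_unknown_condition_rejected(self):
        nm = two_condition_matrix([0.0] * 4)
        with pytest.raises(ValueError, match="contrast"):
            differential_contrast(nm, (3.0, 0.0))

    def test_protein_abundance_mode_aggregates_precursors(self):
        effects = [1.0, 1.0, 0.0, 0.0]  # P0 shifts, P1 does not
        nm = two_condition_matrix(effects, sd=0.02)
        res = differential_contrast(nm, (4.0, 0.0), mode="protein_abundance")
        assert set(res.index) == {"P0", "P1"}
        assert res.loc["P0", "log2_fc"] == pytest.approx(1.0, abs=0.1)
        assert bool(res.loc["P0", "significant"])
        assert not bool(res.loc["P1", "significant"])


class TestScore:
    def test_direct_formula(self):
        assert compute_score(1.5, 0.001) == pytest.approx(1500.0)

    def test_zero_fold_change(self):
        assert compute_score(0.0, 0.5) == 0.0

    def test_floor_guards_tiny_q(self):
        assert compute_score(1.0, 0.0) == pytest.approx(1.0 / Q_FLOOR)


class TestProtectionDirection:
    @pytest.mark.parametrize(
        "tt, fc, expected",
        [
            ("ST", -1.2, "increased_protection"),
            ("ST", +0.8, "decreased_protection"),
            ("FT", +1.0, "increased_protection"),
            ("FT", -1.0, "decreased_protection"),
        ],
    )
    def test_rule(self, tt, fc, expected):
        assert protection_direction(tt, fc) == expected

    def test_zero_fold_change_is_undefined(self):
        assert protection_direction("FT", 0.0) is None

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            protection_direction("unknown", 1.0)

    def test_planted_protected_st_responders_recovered(self, seeded_screen, screen_result):
        """Planted protected (ST, negative effect) responders that become
        hits are called increased_protection in > 95% of cases."""
        _, truth = seeded_screen
        diff = screen_result.differential
        calls = []
        for prec, params in truth.responder_precursors.items():
            if params["tryptic_type"] != "ST" or prec not in diff.index:
                continue
            calls.append(
                protection_direction("ST", diff.loc[prec, "log2_fc"])
                == "increased_protection"
            )
        assert calls
        assert sum(calls) / len(calls) > 0.95


class TestSiteMapping:
    SITES = [SiteAnnotation("P1", "site0", 62, 69)]

    def test_overlap_is_at(self):
        assert map_peptides_to_sites((62, 75), self.SITES) == "at"

    def test_boundary_gap_is_near(self):
        assert map_peptides_to_sites((80, 95), self.SITES, near_window=10) == "near"

    def test_far_is_distant(self):
        assert map_peptides_to_sites((200, 210), self.SITES, near_window=10) == "distant"

    def test_containment_mode_requires_full_site(self):
        # overlapping but not containing the whole site: near, not at
        assert map_peptides_to_sites((65, 75), self.SITES, mode="containment") == "near"
        assert map_peptides_to_sites((60, 70), self.SITES, mode="containment") == "at"

    def test_closest_site_wins_ties_by_start(self):
        sites = [
            SiteAnnotation("P1", "far", 200, 210),
            SiteAnnotation("P1", "near", 100, 110),
        ]
        assert map_peptides_to_sites((95, 98), sites, near_window=5) == "near"

    def test_sites_on_other_protein_rejected(self):
        with pytest.raises(ValueError, match="P2"):
            map_peptides_to_sites((1, 10), self.SITES, protein_id="P2")


def _fits_frame(rows):
    return pd.DataFrame(rows).set_index("precursor_id")


class TestAssembly:
    def _inputs(self):
        fits = _fits_frame(
            [
                {"precursor_id": "A1/2", "e": 2.7, "r": 0.95, "converged": True},
                {"precursor_id": "A2/2", "e": 1.2, "r": 0.90, "converged": True},
                {"precursor_id": "A3/2", "e": 3.3, "r": 0.99, "converged": True},
                {"precursor_id": "B1/2", "e": 0.8, "r": 0.92, "converged": True},
                {"precursor_id": "C1/2", "e": 0.9, "r": 0.97, "converged": True},
            ]
        )
        diff = pd.DataFrame(
            {
                "log2_fc": [1.0, -1.5, 2.0, 1.1, 1.2],
                "p": [1e-5] * 5,
                "q": [1e-4, 1e-4, 1e-4, 1e-4, 1e-3],
                "score": [1e4, 1.5e4, 2e4, 1.1e4, 1.2e3],
                "significant": [True, True, True, True, False],
            },
            index=fits.index,
        )
        prec = pd.DataFrame(
            {
                "protein_id": ["PA", "PA", "PA", "PB", "PC"],
                "peptide_seq": ["A1", "A2", "A3", "B1", "C1"],
                "tryptic_type": ["FT", "ST", "FT", "FT", "FT"],
            },
            index=fits.index,
        )
        hits = {"A1/2", "A2/2", "A3/2", "B1/2", "C1/2"}
        return hits, diff, fits, prec

    def test_protein_ec50_is_minimum(self):
        hits, diff, fits, prec = self._inputs()
        cands = assemble_candidates(hits, diff, fits, prec)
        pa = next(c for c in cands if c.protein_id == "PA")
        assert pa.protein_ec50 == pytest.approx(1.2)

    def test_protein_without_significant_precursors_absent(self):
        hits, diff, fits, prec = self._inputs()
        cands = assemble_candidates(hits, diff, fits, prec)
        assert "PC" not in {c.protein_id for c in cands}

    def test_sorted_by_best_score_then_id(self):
        hits, diff, fits, prec = self._inputs()
        cands = assemble_candidates(hits, diff, fits, prec)
        assert [c.protein_id for c in cands] == ["PA", "PB"]

    def test_directions_follow_tryptic_rule(self):
        hits, diff, fits, prec = self._inputs()
        pa = next(
            c for c in assemble_candidates(hits, diff, fits, prec) if c.protein_id == "PA"
        )
        assert pa.directions["A2/2"] == "increased_protection"  # ST, fc < 0
        assert pa.directions["A1/2"] == "increased_protection"  # FT, fc > 0


class TestTopHits:
    def _candidates(self, n):
        from lipscreen.hits import CandidateInteractor

        out = []
        for i in range(n):
            out.append(
                CandidateInteractor(
                    protein_id=f"P{i:03d}",
                    significant_precursors=pd.DataFrame(),
                    protein_ec50=0.5 + (i % 5) * 0.6,
                    best_r=0.86 + 0.001 * (i % 90),
                    best_score=float(i),
                )
            )
        return out

    def test_ec50_window_filter(self):
        cands = self._candidates(10)
        kept = top_hits_by_correlation(cands, max_dose=2.0, n=50)
        assert all(c.protein_ec50 <= 2.0 for c in kept)
        assert any(c.protein_ec50 > 2.0 for c in cands)

    def test_returns_exactly_n(self):
        cands = self._candidates(90)
        assert len(top_hits_by_correlation(cands, max_dose=10.0, n=50)) == 50

    def test_ranked_by_r_then_score(self):
        cands = self._candidates(30)
        kept = top_hits_by_correlation(cands, max_dose=10.0, n=30)
        rs = [c.best_r for c in kept]
        assert rs == sorted(rs, reverse=True)


class TestEC50Comparison:
    def test_identical_groups(self):
        assert compare_ec50_distributions([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(1.0, 0.3, 30)
        b = rng.normal(2.5, 0.3, 30)
        assert compare_ec50_distributions(a, b) < 0.01
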