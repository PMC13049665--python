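"""Compartment derivation, density computation, immunotype classification."""

import numpy as np
import pandas as pd
import pytest

from spatialimc import (
    ClassifierThresholds,
    CompartmentMap,
    ImageStack,
    Panel,
    assign_compartment,
    classify_immunotype,
    compute_density,
    derive_compartments,
)
from spatialimc.spatial import BACKGROUND, PARENCHYMA, STROMA


def brute_force_immunotype(density, ratio, density_thr=200.0, ratio_thr=0.6):
    """Independent transcription of the prose rule, used as the oracle."""
    if density < density_thr:
        return "depleted"
    if ratio > ratio_thr:
        return "enriched"
    return "compartmentalized"


class TestClassifyImmunotype:
    @pytest.mark.parametrize(
        "whole,par,stro,expected",
        [
            # the published patient regimes: two depleted, one enriched
            (98.46, 30.0, 120.0, "depleted"),
            (117.09, 40.0, 130.0, "depleted"),
            (252.08, 280.0, 230.0, "enriched"),
            (0.0, 0.0, 0.0, "depleted"),
            (250.0, 100.0, 200.0, "compartmentalized"),  # ratio 0.5
            (200.0, 200.0, 100.0, "enriched"),  # exactly at density threshold -> stage 2
        ],
    )
    def test_rule_examples(self, whole, par, stro, expected):
        res = classify_immunotype(whole, par, stro)
        assert res.label == expected
        assert res.whole_density == whole

    def test_ratio_exactly_at_threshold_is_compartmentalized(self):
        with pytest.warns(UserWarning, match="threshold"):
            res = classify_immunotype(300.0, 60.0, 100.0)
        assert res.ratio == pytest.approx(0.6)
        assert res.label == "compartmentalized"

    def test_zero_stromal_density_is_enriched_with_warning(self):
        with pytest.warns(UserWarning, match="inf"):
            res = classify_immunotype(250.0, 50.0, 0.0)
        assert res.label == "enriched"
        assert np.isinf(res.ratio)

    def test_no_compartment_cells_above_threshold_is_error(self):
        with pytest.raises(ValueError, match="compartment"):
            classify_immunotype(250.0, 0.0, 0.0)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            classify_immunotype(-1.0, 0.0, 0.0)

    def test_custom_thresholds_respected(self):
        thr = ClassifierThresholds(density=100.0, ratio=1.5)
        assert classify_immunotype(150.0, 160.0, 100.0, thr).label == "enriched"
        assert classify_immunotype(150.0, 140.0, 100.0, thr).label == "compartmentalized"
        assert classify_immunotype(90.0, 160.0, 100.0, thr).label == "depleted"

    def test_decision_trace_reproduces_label(self):
        res = classify_immunotype(250.0, 280.0, 230.0)
        assert res.decision_trace[0]["outcome"] is False  # not depleted
        assert res.decision_trace[1]["outcome"] is True  # enriched
        assert res.label == "enriched"

    def test_grid_agreement_with_oracle(self):
        # full grid: density 0..400 step 1, ratio 0..2 step 0.01, off the
        # exact-0.6 tie line
        for di in range(0, 401, 7):
            for ri in range(0, 201, 3):
                if ri == 60:
                    continue
                ratio = ri / 100.0
                res = classify_immunotype(float(di), ratio * 100.0, 100.0)
                assert res.label == brute_force_immunotype(di, ratio)

    def test_monotone_in_whole_density(self):
        # raising whole density can only move depleted -> {enriched, comp.}
        for ratio in (0.2, 0.9):
            labels = [
                classify_immunotype(d, ratio * 100.0, 100.0).label
                for d in (0, 100, 199, 200, 300)
            ]
            seen_non_depleted = False
            for lab in labels:
                if lab != "depleted":
                    seen_non_depleted = True
                assert not (seen_non_depleted and lab == "depleted")

    def test_precomputed_ratio_mode(self):
        res = classify_immunotype(250.0, 10.0, 100.0, precomputed_ratio=0.9)
        assert res.label == "enriched"
        assert res.ratio == 0.9


class TestComputeDensity:
    @staticmethod
    def _table(counts_by_roi_phenotype):
        rows = []
        for (roi, ph), n in counts_by_roi_phenotype.items():
            for i in range(n):
                rows.append(
                    {
                        "cell_id": len(rows) + 1,
                        "roi_id": roi,
                        "centroid_x_um": 1.0,
                        "centroid_y_um": 1.0,
                        "area_um2": 50.0,
                        "phenotype": ph,
                    }
                )
        return pd.DataFrame(rows)

    def test_hundred_cells_per_mm2(self):
        t = self._table({("r1", "CD8_T"): 100})
        rep = compute_density(t, {"r1": 1.0})
        assert rep.density_of("CD8_T", "r1") == 100.0

    def test_mean_across_rois(self):
        t = self._table(
            {("r1", "CD8_T"): 100, ("r2", "CD8_T"): 200, ("r3", "CD8_T"): 300, ("r4", "CD8_T"): 400}
        )
        rep = compute_density(t, {f"r{i}": 1.0 for i in range(1, 5)})
        assert rep.mean_density["CD8_T"] == 250.0

    def test_rois_without_cells_count_as_zero(self):
        t = self._table({("r1", "CD8_T"): 100})
        rep = compute_density(t, {"r1": 1.0, "r2": 1.0})
        assert rep.mean_density["CD8_T"] == 50.0

    def test_zero_area_rejected(self):
        t = self._table({("r1", "CD8_T"): 1})
        with pytest.raises(ValueError, match="area"):
            compute_density(t, {"r1": 0.0})

    def test_density_is_count_over_area_exactly(self):
        t = self._table({("r1", "CD8_T"): 37, ("r1", "B"): 13})
        rep = compute_density(t, {"r1": 0.731})
        row = rep.per_roi.set_index("phenotype")
        assert row.loc["CD8_T", "density"] == 37 / 0.731
        assert row.loc["B", "count"] == 13

    def test_conservation_sum_of_counts(self):
        t = self._table({("r1", "CD8_T"): 37, ("r1", "B"): 13, ("r1", "other"): 5})
        rep = compute_density(t, {"r1": 0.9})
        per_roi = rep.per_roi
        assert per_roi["count"].sum() == len(t)
        recon = (per_roi["density"] * per_roi["area_mm2"]).sum()
        assert recon == pytest.approx(len(t), abs=1e-9)


class TestCompartments:
    @staticmethod
    def _panel():
        return Panel.from_records(
            [
                (0, "Nd142", "CA19-9", "tumor"),
                (1, "Pr141", "aSMA", "stroma"),
            ]
        )

    def _stack(self, tumor_left=True):
        # left half tumor signal, right half stroma signal
        px = np.zeros((2, 60, 60), dtype=np.float32)
        px[0, :, :30] = 0.8
        px[1, :, 30:] = 0.8
        return ImageStack(pixels=px, panel=self._panel(), roi_id="r1")

    def test_two_band_geometry_recovered(self):
        cmap = derive_compartments(self._stack())
        assert cmap.labels[30, 10] == PARENCHYMA
        assert cmap.labels[30, 50] == STROMA
        frac = cmap.parenchyma_area_mm2 / cmap.tissue_area_mm2
        assert frac == pytest.approx(0.5, abs=0.1)

    def test_missing_stroma_signal_degenerate(self):
        px = np.zeros((2, 60, 60), dtype=np.float32)
        px[0, :, :] = 0.8  # tumor everywhere, no stroma
        with pytest.raises(ValueError, match="degenerate"):
            derive_compartments(ImageStack(pixels=px, panel=self._panel(), roi_id="r"))

    def test_all_background_rejected(self):
        px = np.zeros((2, 60, 60), dtype=np.float32)
        with pytest.raises(ValueError, match="no tissue|degenerate"):
            derive_compartments(ImageStack(pixels=px, panel=self._panel(), roi_id="r"))

    def test_agreement_with_synthetic_truth(self, small_sample, small_results):
        _, _, gt = small_sample
        for rid, cm_true in gt.compartment_maps.items():
            cm_est = small_results.compartment_maps[rid]
            agreement = (cm_true.labels == cm_est.labels).mean()
            assert agreement >= 0.9

    def test_area_accounting(self):
        labels = np.full((10, 10), STROMA, dtype=np.int8)
        labels[:5] = PARENCHYMA
        labels[9, 9] = BACKGROUND
        cmap = CompartmentMap(labels=labels, roi_id="r", pixel_size_um=1000.0)  # 1 mm px
        assert cmap.parenchyma_area_mm2 == 50.0
        assert cmap.stroma_area_mm2 == 49.0
        assert cmap.tissue_area_mm2 == 99.0


class TestAssignCompartment:
    def test_centroid_lookup(self):
        labels = np.zeros((20, 20), dtype=np.int8)
        labels[:, :10] = PARENCHYMA
        labels[:, 10:] = STROMA
        labels[0, 0] = BACKGROUND
        cmap = CompartmentMap(labels=labels, roi_id="r1")
        t = pd.DataFrame(
            {
                "cell_id": [1, 2, 3],
                "roi_id": ["r1"] * 3,
                "centroid_x_um": [5.0, 15.0, 0.2],
                "centroid_y_um": [5.0, 5.0, 0.2],
                "area_um2": [10.0] * 3,
            }
        )
        out = assign_compartment(t, cmap)
        assert out["compartment"].tolist() == ["parenchyma", "stroma", "unassigned"]

    def test_other_rois_untouched(self):
        labels = np.full((5, 5), PARENCHYMA, dtype=np.int8)
        cmap = CompartmentMap(labels=labels, roi_id="r1")
        t = pd.DataFrame(
            {
                "cell_id": [1],
                "roi_id": ["r9"],
                "centroid_x_um": [1.0],
                "centroid_y_um": [1.0],
                "area_um2": [10.0],
            }
        )
        out = assign_compartment(t, cmap)
        assert out["compartment"].isna().all()

    def test_counts_conserved(self, small_results):
        cells = small_results.cell_table
        assert cells["compartment"].notna().all()
        by_comp = cells.groupby("compartment").size().sum()
        assert by_comp == len(cells)
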