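"""Volumetry: segmentation recovery, population split, compartment arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wntquant import synthetic as synth
from wntquant import volumes as vol


def _segment_all(stack, **kwargs):
    opts = vol.SegmentationOptions(**kwargs)
    return {role: vol.segment_channel(stack, role, opts)
            for role in vol.CHANNEL_ROLES}


class TestSegmentation:
    def test_uniform_zero_image_yields_no_objects(self, iso_calibration):
        zeros = np.zeros((20, 20, 20))
        stack = vol.ImageStack(
            {r: zeros for r in vol.CHANNEL_ROLES}, iso_calibration
        )
        labels = vol.segment_channel(stack, "calcein")
        assert labels.max() == 0

    def test_two_disjoint_spheres_recovered(self, iso_calibration):
        cells = (
            synth.CellPhantom(center=(7, 7, 7), cell_semiaxes=(4, 4, 4),
                              nucleus_semiaxes=(2, 2, 2), shell_thickness=0.5),
            synth.CellPhantom(center=(7, 7, 22), cell_semiaxes=(5, 5, 5),
                              nucleus_semiaxes=(2.5, 2.5, 2.5), shell_thickness=0.5),
        )
        stack, truth = synth.render_image_stack(
            synth.PhantomSpec(cells=cells), iso_calibration
        )
        labels = vol.segment_channel(stack, "calcein")
        assert labels.max() == 2
        voxel_pl = iso_calibration.voxel_volume_pl
        measured = sorted(
            np.bincount(labels.ravel())[1:] * voxel_pl
        )
        expected = sorted(truth.true_calcein_pl)
        np.testing.assert_allclose(measured, expected, rtol=0.03)

    def test_border_touching_object_excluded(self, iso_calibration):
        cell = synth.CellPhantom(center=(1.0, 8, 8), cell_semiaxes=(4, 4, 4),
                                 nucleus_semiaxes=(2, 2, 2), shell_thickness=0.0)
        stack, _ = synth.render_image_stack(
            synth.PhantomSpec(cells=(cell,)), iso_calibration,
            shape=(60, 80, 80), allow_truncation=True,
        )
        labels = vol.segment_channel(
            stack, "calcein", vol.SegmentationOptions(exclude_border=True)
        )
        assert labels.max() == 0
        labels = vol.segment_channel(
            stack, "calcein", vol.SegmentationOptions(exclude_border=False)
        )
        assert labels.max() == 1

    def test_min_volume_filter(self, iso_calibration):
        big = synth.CellPhantom(center=(8, 8, 8), cell_semiaxes=(4, 4, 4),
                                nucleus_semiaxes=(2, 2, 2), shell_thickness=0.0)
        stack, _ = synth.render_image_stack(
            synth.PhantomSpec(cells=(big,)), iso_calibration
        )
        labels = vol.segment_channel(
            stack, "calcein", vol.SegmentationOptions(min_volume_pl=1.0)
        )
        assert labels.max() == 0  # 0.268 pL sphere removed by a 1 pL floor


class TestMeasurement:
    def test_voxel_count_arithmetic(self):
        # 1000 voxels at 0.2 x 0.2 x 0.5 um (0.02 um^3) = 20 um^3 = 0.020 pL
        cal = vol.VoxelCalibration(dx=0.2, dy=0.2, dz=0.5)
        shape = (30, 30, 30)
        hoechst = np.zeros(shape, dtype=np.int32)
        hoechst[10:20, 10:20, 10:20] = 1  # 1000 voxels
        calcein = np.zeros(shape, dtype=np.int32)
        calcein[8:22, 8:22, 8:22] = 1
        dii = np.zeros(shape, dtype=np.int32)
        dii[6:24, 6:24, 6:24] = 1
        records, issues = vol.measure_cell_volumes(
            {"calcein": calcein, "hoechst": hoechst, "dii": dii}, cal
        )
        assert not issues
        (rec,) = records
        assert rec.v_hoechst == pytest.approx(0.020, abs=1e-12)
        assert rec.v_calcein == pytest.approx(14**3 * 0.02 / 1000, abs=1e-12)

    def test_zero_noise_phantom_recovery_within_3_percent(self, iso_calibration):
        cell = synth.CellPhantom(center=(9, 9, 9), cell_semiaxes=(6, 6.5, 7),
                                 nucleus_semiaxes=(4, 4, 4.5), shell_thickness=1.0)
        stack, truth = synth.render_image_stack(
            synth.PhantomSpec(cells=(cell,)), iso_calibration
        )
        masks = _segment_all(stack)
        records, issues = vol.measure_cell_volumes(masks, iso_calibration)
        assert not issues
        (rec,) = records
        assert rec.v_calcein == pytest.approx(truth.true_calcein_pl[1], rel=0.03)
        assert rec.v_hoechst == pytest.approx(truth.true_hoechst_pl[1], rel=0.03)
        assert rec.v_dii == pytest.approx(truth.true_dii_pl[1], rel=0.03)

    def test_orphan_nucleus_excluded_and_reported(self):
        cal = vol.VoxelCalibration(dx=0.2, dy=0.2, dz=0.2)
        shape = (30, 30, 30)
        hoechst = np.zeros(shape, dtype=np.int32)
        hoechst[2:6, 2:6, 2:6] = 1  # no calcein anywhere near
        calcein = np.zeros(shape, dtype=np.int32)
        calcein[15:25, 15:25, 15:25] = 1
        dii = np.zeros(shape, dtype=np.int32)
        dii[14:26, 14:26, 14:26] = 1
        records, issues = vol.measure_cell_volumes(
            {"calcein": calcein, "hoechst": hoechst, "dii": dii}, cal
        )
        assert records == []
        assert any(i["kind"] == "orphan_nucleus" for i in issues)

    def test_binucleate_cell_flagged_and_excluded(self):
        cal = vol.VoxelCalibration(dx=0.2, dy=0.2, dz=0.2)
        shape = (30, 30, 30)
        hoechst = np.zeros(shape, dtype=np.int32)
        hoechst[10:13, 10:13, 8:11] = 1
        hoechst[10:13, 10:13, 16:19] = 2
        calcein = np.zeros(shape, dtype=np.int32)
        calcein[8:16, 8:16, 5:22] = 1
        dii = np.zeros(shape, dtype=np.int32)
        dii[7:17, 7:17, 4:23] = 1
        records, issues = vol.measure_cell_volumes(
            {"calcein": calcein, "hoechst": hoechst, "dii": dii}, cal
        )
        assert records == []
        assert any(i["kind"] == "multinucleate" for i in issues)

    def test_nucleus_growth_never_shrinks_hoechst_volume(self, iso_calibration):
        previous = 0.0
        for r in (2.0, 3.0, 4.0):
            cell = synth.CellPhantom(center=(8, 8, 8), cell_semiaxes=(5, 5, 5),
                                     nucleus_semiaxes=(r, r, r),
                                     shell_thickness=0.5)
            stack, _ = synth.render_image_stack(
                synth.PhantomSpec(cells=(cell,)), iso_calibration
            )
            masks = _segment_all(stack, min_volume_pl=0.01)
            records, _ = vol.measure_cell_volumes(masks, iso_calibration)
            assert records[0].v_hoechst >= previous
            previous = records[0].v_hoechst


class TestPopulationSplit:
    def test_zero_noise_classification_matches_hidden_labels(self):
        params = synth.PopulationParams(
            n_cells=300, dividing_fraction=0.1, cv=0.0, ratio_noise_sd=0.0, seed=2
        )
        df = synth.generate_cell_population(params)
        split = vol.split_populations(df.drop(columns="true_label"))
        assert (split.labels == df.true_label).all()

    def test_realistic_mixture_recovers_dividing_fraction(self):
        # pooled study proportions: n = 469 cells, dividing fraction 8.5%
        params = synth.PopulationParams(
            n_cells=469, dividing_fraction=0.085, cv=0.15, ratio_noise_sd=0.1,
            seed=20,
        )
        df = synth.generate_cell_population(params)
        split = vol.split_populations(df.drop(columns="true_label"))
        recovered = split.n_dividing / len(df)
        assert recovered == pytest.approx(0.085, abs=0.03)

    def test_small_n_labels_everything_nondividing(self):
        params = synth.PopulationParams(n_cells=5, seed=0)
        df = synth.generate_cell_population(params)
        with pytest.warns(UserWarning, match="too few"):
            split = vol.split_populations(df.drop(columns="true_label"))
        assert (split.labels == "ND").all()

    def test_degenerate_volumes_rejected(self):
        params = synth.PopulationParams(n_cells=50, cv=0.0, ratio_noise_sd=0.0,
                                        dividing_fraction=0.0, seed=0)
        df = synth.generate_cell_population(params)
        with pytest.raises(ValueError, match="degenerate"):
            vol.split_populations(df.drop(columns="true_label"))

    def test_relabelling_is_idempotent_and_r2_bounded(self):
        params = synth.PopulationParams(n_cells=400, seed=8)
        df = synth.generate_cell_population(params).drop(columns="true_label")
        s1 = vol.split_populations(df)
        s2 = vol.split_populations(df)
        assert (s1.labels == s2.labels).all()
        assert 0.0 <= s1.r_squared <= 1.0
        assert 0.0 <= s1.r_squared_nd <= 1.0


class TestCompartments:
    def test_subtraction_identities(self):
        rec = vol.CellVolumeRecord(1, v_calcein=2.08, v_hoechst=0.74, v_dii=2.61)
        c = vol.compartment_volumes(rec)
        assert c.nuclei == pytest.approx(0.74)
        assert c.cytosol == pytest.approx(1.34)
        assert c.membrane_outer == pytest.approx(0.53)

    def test_unrounded_inputs_differ_from_rounded_print(self):
        rec = vol.CellVolumeRecord(1, v_calcein=1.27, v_hoechst=0.36, v_dii=1.50)
        c = vol.compartment_volumes(rec)
        assert c.cytosol == pytest.approx(0.91)
        assert c.membrane_outer == pytest.approx(0.23)

    def test_equal_calcein_hoechst_gives_zero_cytosol(self):
        c = vol.compartment_volumes(vol.CellVolumeRecord(1, 1.0, 1.0, 1.4))
        assert c.cytosol == 0.0

    def test_ordering_violation_is_an_error(self):
        with pytest.raises(ValueError, match="hoechst"):
            vol.compartment_volumes(vol.CellVolumeRecord(1, 0.5, 0.7, 1.0))
        with pytest.raises(ValueError, match="dii"):
            vol.compartment_volumes(vol.CellVolumeRecord(1, 1.2, 0.7, 1.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        h=st.floats(0.01, 5.0),
        dc=st.floats(0.0, 5.0),
        dd=st.floats(0.0, 5.0),
    )
    def test_compartments_conserve_whole_cell_volume(self, h, dc, dd):
        rec = vol.CellVolumeRecord(1, v_calcein=h + dc, v_hoechst=h,
                                   v_dii=h + dc + dd)
        c = vol.compartment_volumes(rec)
        assert c.total == pytest.approx(rec.v_dii, rel=1e-12)


class TestRatioStats:
    def test_single_record_ratio(self):
        stats = vol.normalized_ratio_stats(
            [vol.CellVolumeRecord(1, 1.44, 0.65, 1.82)]
        )
        assert stats["mean"] == pytest.approx(2.215, abs=5e-4)
        assert stats["sd"] == 0.0

    def test_population_mean_ratio_recovered(self):
        # generator mean ratio 2.90 with relative spread 0.2 (SD ~ 0.58)
        params = synth.PopulationParams(
            n_cells=469, dividing_fraction=0.0,
            mean_volumes_nd=(2.90 * 0.53, 0.53, 1.89),
            cv=0.25, ratio_noise_sd=0.2, seed=31,
        )
        df = synth.generate_cell_population(params)
        stats = vol.normalized_ratio_stats(df)
        assert stats["mean"] == pytest.approx(2.90, abs=0.1)

    def test_identical_ratios_have_zero_sd(self):
        recs = [vol.CellVolumeRecord(i, 2.0, 1.0, 2.5) for i in range(1, 6)]
        stats = vol.normalized_ratio_stats(recs)
        assert stats["sd"] == 0.0

    def test_zero_hoechst_cells_excluded_with_warning(self):
        recs = [
            vol.CellVolumeRecord(1, 2.0, 1.0, 2.5),
            vol.CellVolumeRecord(2, 2.0, 0.0, 2.5),
        ]
        with pytest.warns(UserWarning, match="zero Hoechst"):
            stats = vol.normalized_ratio_stats(recs)
        assert stats["n"] == 1
        assert stats["n_excluded"] == 1


class TestSummaries:
    def test_single_cell_summary(self):
        recs = [vol.CellVolumeRecord(1, 1.4, 0.6, 1.8)]
        with pytest.warns(UserWarning):
            split = vol.split_populations(recs)
        summary = vol.summarize_population(recs, split)
        stats = summary.marker_stats
        assert stats.loc["calcein", "mean_total"] == pytest.approx(1.4)
        assert stats.loc["calcein", "mean_nd"] == pytest.approx(1.4)
        assert stats.loc["calcein", "sd_total"] == 0.0
        assert summary.d_over_nd["calcein"] is None  # no dividing cells

    def test_d_over_nd_recovered_on_quantified_population(self):
        params = synth.PopulationParams(n_cells=500, dividing_fraction=0.1,
                                        d_over_nd_ratio=2.0, seed=17)
        df = synth.generate_cell_population(params).drop(columns="true_label")
        split = vol.split_populations(df)
        summary = vol.summarize_population(df, split)
        for marker in ("calcein", "hoechst", "dii"):
            assert summary.d_over_nd[marker] == pytest.approx(2.0, rel=0.05)

    def test_ncm_ratio_from_nd_means(self, cell_lines):
        nd = cell_lines["HEK293T"]["volumes_pl"]
        rec = vol.CellVolumeRecord(
            1, v_calcein=nd["calcein"]["nd"][0], v_hoechst=nd["hoechst"]["nd"][0],
            v_dii=nd["dii"]["nd"][0],
        )
        n, c, m = vol.compartment_volumes(rec).ncm_ratio()
        assert (round(n, 1), round(c, 1), round(m, 1)) == (1.0, 1.2, 0.6)

    def test_aggregate_d_over_nd_averages_lines(self):
        summaries = [
            {"calcein": 1.9, "hoechst": 1.7, "dii": 2.0},
            {"calcein": 2.1, "hoechst": 2.1, "dii": 2.0},
        ]
        agg = vol.aggregate_d_over_nd(summaries)
        assert agg["calcein"] == pytest.approx(2.0)
        assert agg["hoechst"] == pytest.approx(1.9)
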