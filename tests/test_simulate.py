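"""Synthetic cohort generator: geometry, covariance, motion, signal, cohort."""

import numpy as np
import pytest

import fcpipe as fp
from fcpipe.preprocess import build_censor_mask, compute_framewise_displacement
from fcpipe.simulate import CovarianceSpec, sample_phenotype


# ---------------------------------------------------------------------------
# parcellation geometry
# ---------------------------------------------------------------------------
class TestSymmetricParcellation:
    def test_eight_per_hemisphere_gives_one_roi_per_network_per_side(self, small_atlas):
        table = small_atlas.roi_table
        assert len(table) == 16
        for net in fp.NETWORKS_8:
            sub = table[table["merged_network"] == net]
            assert sorted(sub["hemisphere"]) == ["L", "R"]

    def test_mirroring_label_volume_reproduces_it_exactly(self, small_atlas):
        """Flipping x and remapping ids through the mirror table is an identity."""
        labels = small_atlas.labels
        mirror = dict(
            zip(small_atlas.roi_table["id"], small_atlas.roi_table["mirror_id"])
        )
        mirror[0] = 0
        flipped = labels[::-1, :, :]
        remapped = np.vectorize(mirror.get)(flipped)
        assert np.array_equal(remapped, labels)

    def test_mirror_centroids_negate_world_x(self, small_atlas):
        t = small_atlas.roi_table.set_index("id")
        for rid, row in t.iterrows():
            m = t.loc[row["mirror_id"]]
            assert m["x"] == pytest.approx(-row["x"], abs=1e-9)
            assert m["y"] == pytest.approx(row["y"])
            assert m["z"] == pytest.approx(row["z"])

    def test_twenty_rois_no_overlap_and_min_size(self):
        params = fp.SimParams(grid_shape=(40, 40, 24), n_rois_per_hemisphere=20)
        atlas = fp.build_symmetric_parcellation(params)
        labels = atlas.labels
        # exhaustive voxel-label check: every ROI >= 8 voxels, labels partition
        counts = np.bincount(labels.ravel())
        assert len(counts) == 41
        assert (counts[1:] >= 8).all()
        assert counts[1:].sum() == (labels > 0).sum()  # no overlap by construction

    def test_too_many_rois_names_limiting_axis(self):
        params = fp.SimParams(grid_shape=(12, 14, 8), n_rois_per_hemisphere=8)
        with pytest.raises(ValueError, match="axis is limiting"):
            fp.build_symmetric_parcellation(
                fp.SimParams(**{**params.__dict__, "n_rois_per_hemisphere": 500})
            )

    def test_odd_first_axis_rejected(self):
        with pytest.raises(ValueError, match="even"):
            fp.SimParams(grid_shape=(13, 14, 8))

    def test_masks_disjoint_and_thick(self, small_params):
        masks = fp.build_tissue_masks(small_params)
        overlap = (
            masks["wm"].astype(int) + masks["csf"].astype(int) + masks["face"].astype(int)
        )
        assert overlap.max() == 1
        assert not (masks["face"] & masks["brain"]).any()
        # each tissue block survives one-voxel erosion
        for name in ("wm", "csf", "face"):
            assert not fp.erode_mask(masks[name]).empty


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------
class TestRoiCovariance:
    def test_zero_coupling_gives_identity(self, small_params, small_atlas):
        params = fp.SimParams(
            **{**small_params.__dict__, "within_z": 0.0, "between_z": 0.0, "homotopic_z": 0.0}
        )
        spec = fp.build_roi_covariance(params, small_atlas)
        assert np.allclose(spec.matrix, np.eye(small_atlas.n_rois))
        assert not spec.repaired

    def test_within_cell_equals_tanh_of_z(self, small_params, small_atlas):
        wz = {n: 0.0 for n in fp.NETWORKS_8}
        wz["default"] = 0.4
        spec = fp.build_roi_covariance(
            small_params, small_atlas, within_z=wz,
            between_z=np.zeros((8, 8)), homotopic_z=0.0,
        )
        members = small_atlas.network_members("default")
        i, j = members[:2]
        assert spec.matrix[i, j] == pytest.approx(np.tanh(0.4), abs=1e-12)
        assert spec.matrix[i, j] == pytest.approx(0.3799, abs=5e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_positive_definite(self, small_params, small_atlas, seed):
        rng = np.random.default_rng(seed)
        bz = rng.normal(0, 0.2, (8, 8))
        bz = (bz + bz.T) / 2
        spec = fp.build_roi_covariance(
            small_params, small_atlas,
            within_z={n: rng.uniform(0, 0.8) for n in fp.NETWORKS_8},
            between_z=bz, homotopic_z=rng.uniform(0, 0.5),
        )
        assert np.linalg.eigvalsh(spec.matrix).min() > 0

    def test_repair_reported_when_needed(self, small_params, small_atlas):
        # strong homotopic coupling on top of strong anticorrelation breaks PD
        bz = np.full((8, 8), -0.9)
        spec = fp.build_roi_covariance(
            small_params, small_atlas,
            within_z={n: 2.0 for n in fp.NETWORKS_8}, between_z=bz, homotopic_z=0.0,
        )
        assert spec.repaired
        assert spec.repair_magnitude > 0
        assert np.linalg.eigvalsh(spec.matrix).min() > 0
        assert np.allclose(np.diag(spec.matrix), 1.0)

    def test_infinite_z_rejected(self, small_params, small_atlas):
        with pytest.raises(ValueError, match="finite"):
            fp.build_roi_covariance(
                small_params, small_atlas,
                within_z={n: np.inf for n in fp.NETWORKS_8},
                between_z=np.zeros((8, 8)), homotopic_z=0.0,
            )


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------
class TestSimulateMotion:
    def test_null_motion_keeps_everything(self, small_params):
        params = fp.SimParams(
            **{**small_params.__dict__, "spike_rate": 0.0, "drift_mm": 0.0}
        )
        motion, truth = fp.simulate_motion(params, "NT", rng=0)
        fd = compute_framewise_displacement(motion)
        assert np.allclose(fd, 0.0)
        assert truth["supra_threshold_frames"].size == 0
        assert build_censor_mask(fd).n_motion_free == params.n_frames_per_run

    def test_censored_fraction_matches_analytic_expectation(self):
        """Poisson spikes each censor ~3 frames: retained ~ n exp(-3 rate)."""
        n = 400
        rate = np.log(2) / 3  # expected retained fraction ~ 0.5
        params = fp.SimParams(
            n_frames_per_run=n, spike_rate=rate, spike_dispersion=0.0, drift_mm=0.0
        )
        kept = []
        for seed in range(100):
            motion, _ = fp.simulate_motion(params, "NT", rng=seed)
            fd = compute_framewise_displacement(motion)
            kept.append(build_censor_mask(fd).n_motion_free)
        expected = n * np.exp(-3 * rate)
        assert abs(np.mean(kept) - expected) < 0.10 * expected

    def test_truth_records_exactly_supra_threshold_frames(self, small_params):
        motion, truth = fp.simulate_motion(small_params, "LVCP", rng=3)
        fd = compute_framewise_displacement(motion)
        assert np.array_equal(truth["supra_threshold_frames"], np.flatnonzero(fd > 0.2))

    def test_lvcp_retains_fewer_volumes_than_nt(self):
        """Group spike rates reproduce the observed motion ordering."""
        params = fp.SimParams(n_frames_per_run=620, spike_dispersion=0.0)
        kept = {}
        for group in ("LVCP", "NT"):
            totals = []
            for seed in range(30):
                motion, _ = fp.simulate_motion(params, group, rng=1000 + seed)
                fd = compute_framewise_displacement(motion)
                totals.append(build_censor_mask(fd).n_motion_free)
            kept[group] = np.mean(totals)
        assert kept["LVCP"] < kept["NT"]


# ---------------------------------------------------------------------------
# subject signal
# ---------------------------------------------------------------------------
class TestSimulateSubject:
    def test_same_seed_is_bit_identical(self, small_params, small_atlas, small_cov, nt_phenotype):
        a = fp.simulate_subject(small_params, nt_phenotype, small_atlas, small_cov, seed=9)
        b = fp.simulate_subject(small_params, nt_phenotype, small_atlas, small_cov, seed=9)
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra.data, rb.data)
        for ma, mb in zip(a.motion, b.motion):
            assert np.array_equal(ma.params, mb.params)

    def test_empirical_correlation_converges_to_target(self, small_atlas):
        """With noise and confounds off, the seed-averaged empirical ROI
        correlation approaches the generating matrix (Monte-Carlo over 40
        seeds at 1240 frames; sampling error of the mean < 0.05)."""
        params = fp.SimParams(
            grid_shape=(12, 14, 8), n_rois_per_hemisphere=8, n_runs=1,
            n_frames_per_run=1240, noise_sd=0.0, global_amp=0.0, confound_amp=0.0,
        )
        cov = fp.build_roi_covariance(params, small_atlas)
        ph = fp.SubjectPhenotype("s", "NT", 10.0, "M", 110.0)

        def mean_abs_err(T, n_seeds):
            p = fp.SimParams(**{**params.__dict__, "n_frames_per_run": T})
            errs = []
            for s in range(n_seeds):
                sub = fp.simulate_subject(p, ph, small_atlas, cov, seed=s)
                r = np.corrcoef(sub.truth["runs"][0]["roi_ts"], rowvar=False)
                errs.append(r - cov.matrix)
            mean_err = np.abs(np.mean(errs, axis=0))
            iu = np.triu_indices(small_atlas.n_rois, 1)
            return mean_err[iu]

        assert mean_abs_err(1240, 40).max() < 0.05
        # monotone decay of estimation error with run length
        decay = [mean_abs_err(T, 10).mean() for T in (300, 620, 1240)]
        assert decay[0] > decay[1] > decay[2]

    def test_global_amp_raises_mean_pairwise_correlation(self, small_atlas):
        ph = fp.SubjectPhenotype("s", "NT", 10.0, "M", 110.0)
        means = []
        for amp in (0.0, 0.5, 1.0):
            params = fp.SimParams(
                grid_shape=(12, 14, 8), n_rois_per_hemisphere=8, n_runs=1,
                n_frames_per_run=400, global_amp=amp,
            )
            cov = fp.build_roi_covariance(params, small_atlas)
            vals = []
            for seed in range(20):
                sub = fp.simulate_subject(params, ph, small_atlas, cov, seed=200 + seed)
                ts = np.column_stack(
                    [sub.runs[0].data[small_atlas.labels == rid, :].mean(axis=0)
                     for rid in small_atlas.roi_ids]
                )
                r = np.corrcoef(ts, rowvar=False)
                vals.append(r[np.triu_indices(small_atlas.n_rois, 1)].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_covariance_dimension_checked(self, small_params, small_atlas, nt_phenotype):
        with pytest.raises(ValueError, match="dimension"):
            fp.simulate_subject(
                small_params, nt_phenotype, small_atlas,
                CovarianceSpec(matrix=np.eye(3)), seed=0,
            )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------
class TestSimulateCohort:
    def test_default_group_sizes_total_56(self):
        params = fp.SimParams(
            grid_shape=(12, 14, 8), n_rois_per_hemisphere=8,
            n_frames_per_run=20, n_runs=1,
        )
        cohort = fp.simulate_cohort(params, group_effects=None, seed=1)
        assert len(cohort.subjects) == 56
        groups = [s.phenotype.group for s in cohort.subjects]
        assert (groups.count("LVCP"), groups.count("HVCP"), groups.count("NT")) == (17, 20, 19)

    def test_phenotype_invariants_hold(self):
        rng = np.random.default_rng(0)
        for group in fp.GROUPS:
            for i in range(50):
                ph = sample_phenotype(group, i, rng)
                if group == "LVCP":
                    assert ph.iq_composite <= 79
                else:
                    assert ph.iq_composite >= 80
                assert 7 <= ph.age_years <= 17

    def test_null_cohort_has_identical_group_coupling(self):
        params = fp.SimParams(
            grid_shape=(12, 14, 8), n_rois_per_hemisphere=8,
            n_frames_per_run=20, n_runs=1, subject_sd=0.0,
        )
        cohort = fp.simulate_cohort(
            params, group_sizes={"LVCP": 2, "HVCP": 2, "NT": 2},
            group_effects=None, seed=2,
        )
        covs = [s.truth["covariance"] for s in cohort.subjects]
        for c in covs[1:]:
            assert np.allclose(c, covs[0])

    def test_identical_seed_reproduces_cohort(self):
        params = fp.SimParams(
            grid_shape=(12, 14, 8), n_rois_per_hemisphere=8,
            n_frames_per_run=30, n_runs=1,
        )
        sizes = {"LVCP": 2, "HVCP": 2, "NT": 2}
        a = fp.simulate_cohort(params, group_sizes=sizes, seed=5)
        b = fp.simulate_cohort(params, group_sizes=sizes, seed=5)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.phenotype == sb.phenotype
            assert np.array_equal(sa.runs[0].data, sb.runs[0].data)
            assert np.array_equal(sa.motion[0].params, sb.motion[0].params)

    def test_planted_within_default_deficit_recovered_in_expectation(self):
        """A 0.15 z deficit planted in the LVCP default network appears in
        the empirical within-default Fisher z at the planted size (mean over
        50 replicate cohorts within 2 SE)."""
        params = fp.SimParams(
            grid_shape=(12, 14, 8), n_rois_per_hemisphere=8,
            n_frames_per_run=400, n_runs=1,
            noise_sd=0.0, global_amp=0.0, confound_amp=0.0, subject_sd=0.0,
        )
        effects = {"LVCP": {"within_z_delta": {"default": -0.15}}}
        atlas = fp.build_symmetric_parcellation(params)
        members = atlas.network_members("default")
        iu = np.triu_indices(len(members), 1)
        diffs = []
        for seed in range(50):
            cohort = fp.simulate_cohort(
                params, group_sizes={"LVCP": 5, "HVCP": 2, "NT": 5},
                group_effects=effects, seed=seed,
            )
            vals = {"LVCP": [], "NT": []}
            for s in cohort.subjects:
                if s.phenotype.group not in vals:
                    continue
                r = np.corrcoef(s.truth["runs"][0]["roi_ts"], rowvar=False)
                sub = np.arctanh(r[np.ix_(members, members)][iu])
                vals[s.phenotype.group].append(sub.mean())
            diffs.append(np.mean(vals["NT"]) - np.mean(vals["LVCP"]))
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - 0.15) < 2 * se + 1e-9

    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fp.simulate_cohort(group_sizes={"LVCP": 1}, seed=0)
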