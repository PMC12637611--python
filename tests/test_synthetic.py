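"""Generator-level checks: reproducibility, moments, planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lesiontrack as lt
from lesiontrack.synthetic import (
    BehaviorConfig,
    CohortConfig,
    DSPConfig,
    HotspotSpec,
    LesionSpec,
    MyeloidSpec,
    NoiseSpec,
    PhantomConfig,
    RecruitmentConfig,
    generate_behavior_sequences,
    generate_dsp_counts,
    generate_recruitment_series,
    generate_trajectory_cohort,
    generate_voxel_phantom,
)


class TestTrajectoryCohort:
    def test_empty_cohort(self):
        traj, truth = generate_trajectory_cohort(CohortConfig(n_mice=0))
        assert traj.empty and truth.empty

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(weekly_growth_mean=float("nan"))
        with pytest.raises(ValueError):
            CohortConfig(session_interval=0)
        with pytest.raises(ValueError):
            CohortConfig(endpoint_week=10, onset_window=(4, 12))

    def test_growth_defaults_match_cohort_conditions(self):
        cfg = CohortConfig()
        assert cfg.weekly_growth_mean == 24.0 and cfg.weekly_growth_sd == 10.0

    def test_progressing_growth_moment(self):
        """Sample mean of per-lesion weekly growth within 3 SE of the config mean."""
        cfg = CohortConfig(n_mice=250, lesions_per_mouse_by_fate=(4.0, 0.0, 0.0), seed=11)
        _, truth = generate_trajectory_cohort(cfg)
        g = truth["true_weekly_growth_pct"]
        assert len(g) >= 1000
        se = g.std(ddof=1) / np.sqrt(len(g))
        assert abs(g.mean() - cfg.weekly_growth_mean) <= 3 * se

    def test_regressing_endpoint_invariant(self):
        """Every regressing lesion ends <= 25% of its observed peak; complete ones are censored."""
        cfg = CohortConfig(n_mice=40, lesions_per_mouse_by_fate=(0.0, 2.0, 0.0), seed=3)
        traj, truth = generate_trajectory_cohort(cfg)
        for (_, lesion), grp in traj.groupby(["mouse_id", "lesion_id"]):
            grp = grp.sort_values("week")
            fate = truth.set_index("lesion_id").loc[lesion, "fate"]
            assert fate.startswith("regressing")
            vols = np.where(grp["censored"], 0.0, grp["volume_um3"])
            assert vols[-1] <= 0.25 * vols.max() + 1e-9
            if fate == "regressing_complete":
                assert bool(grp["censored"].iloc[-1])

    def test_bit_reproducible(self):
        cfg = CohortConfig(n_mice=4, seed=42)
        a, ta = generate_trajectory_cohort(cfg)
        b, tb = generate_trajectory_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_censoring_reported_at_floor(self):
        cfg = CohortConfig(n_mice=30, lesions_per_mouse_by_fate=(0.0, 2.0, 0.0), seed=9)
        traj, _ = generate_trajectory_cohort(cfg)
        cens = traj[traj["censored"]]
        assert not cens.empty
        assert (cens["volume_um3"] == cfg.detection_floor).all()


class TestBehaviorSequences:
    def test_zero_change_probability_means_constant(self):
        cfg = BehaviorConfig(
            change_prob_by_state=dict.fromkeys(lt.MYELOID_STATES, 0.0),
            n_lesions=10,
            sequence_length=6,
            seed=1,
        )
        seqs, _ = generate_behavior_sequences(cfg)
        assert (seqs.groupby("lesion_id")["state"].nunique() == 1).all()

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="unknown state"):
            BehaviorConfig(change_prob_by_state={"spiral": 0.5})

    def test_scattered_change_fraction_in_binomial_ci(self):
        """>= 10,000 transitions from scattered: change fraction within the 99% CI."""
        cfg = BehaviorConfig(n_lesions=5000, sequence_length=10, seed=2)
        seqs, _ = generate_behavior_sequences(cfg)
        changed = n = 0
        for _, grp in seqs.groupby("lesion_id"):
            s = grp.sort_values("session")["state"].to_numpy()
            frm = s[:-1] == "scattered"
            n += frm.sum()
            changed += (s[1:][frm] != "scattered").sum()
        assert n >= 10_000
        p = cfg.change_prob_by_state["scattered"]
        half = stats.norm.ppf(0.995) * np.sqrt(p * (1 - p) / n)
        assert abs(changed / n - p) <= half

    def test_transition_matrix_rows_stochastic(self):
        P = BehaviorConfig().transition_matrix()
        assert np.allclose(P.sum(axis=1), 1.0)
        assert (P.to_numpy() >= 0).all()


class TestVoxelPhantom:
    def test_zero_myeloid_gfp_background_only(self):
        cfg = PhantomConfig(myeloid_spec=(MyeloidSpec(state="scattered", count=0),), seed=1)
        channels, truth = generate_voxel_phantom(cfg)
        assert truth["components"].empty
        assert channels["gfp"].values.max() <= 1.0

    def test_default_acquisition_geometry(self):
        cfg = PhantomConfig()
        depth = cfg.grid_shape[0] * cfg.voxel_size[0]
        assert depth == 150.0 and cfg.voxel_size[0] == 2.0

    def test_lesion_mask_matches_analytic_ellipsoid(self):
        cfg = PhantomConfig(seed=1)
        _, truth = generate_voxel_phantom(cfg)
        les = cfg.lesion_spec[0]
        analytic = 4.0 / 3.0 * np.pi * np.prod(les.semi_axes_um)
        voxvol = np.prod(cfg.voxel_size)
        measured = truth["lesion_mask"].sum() * voxvol
        assert abs(measured / analytic - 1.0) < 0.05

    def test_component_volumes_exact(self):
        cfg = PhantomConfig(myeloid_spec=(MyeloidSpec(state="multifocal"),), seed=4)
        _, truth = generate_voxel_phantom(cfg)
        comp = truth["components"]
        voxvol = np.prod(cfg.voxel_size)
        assert np.array_equal(
            comp["volume_um3"].to_numpy(), comp["voxel_count"].to_numpy() * voxvol
        )
        labels = truth["myeloid_labels"]
        counts = np.bincount(labels.ravel())[1:]
        assert np.array_equal(np.sort(counts[counts > 0]), np.sort(comp["voxel_count"]))

    def test_lesion_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            PhantomConfig(
                lesion_spec=(LesionSpec(center_um=(30.0, 10.0, 64.0), semi_axes_um=(25.0, 55.0, 55.0)),)
            )

    def test_noise_keeps_values_nonnegative(self):
        cfg = PhantomConfig(noise_spec=NoiseSpec(gaussian_sd=5.0, poisson_scale=0.5), seed=2)
        channels, _ = generate_voxel_phantom(cfg)
        for vol in channels.values():
            assert vol.values.min() >= 0


class TestRecruitmentSeries:
    def test_zero_hotspots_index_unity(self):
        cfg = RecruitmentConfig(hotspots=(), seed=1)
        stack, mask, _ = generate_recruitment_series(cfg)
        for cy, cx in [(500.0, 700.0), (450.0, 650.0)]:
            idx = lt.recruitment_index(stack[0], (cy, cx), mask, cfg.pixel_size_um)
            assert idx == pytest.approx(1.0, abs=1e-12)

    def test_default_lead_time_two_weeks(self):
        assert RecruitmentConfig().lead_time_weeks == 2.0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            HotspotSpec(center_um=(500.0, 700.0), amplitude=-1.0)

    def test_hotspot_matches_closed_form_disk_average(self):
        """Measured index equals the analytic disk-averaged Gaussian within 2%."""
        cfg = RecruitmentConfig(seed=3)
        stack, mask, _ = generate_recruitment_series(cfg)
        h = cfg.hotspots[0]
        frame = stack[list(cfg.weeks).index(h.onset_week)]
        idx = lt.recruitment_index(frame, h.center_um, mask, cfg.pixel_size_um)
        R, s = 250.0, h.sigma_um
        disk_mean = cfg.background + h.amplitude * (2 * s**2 / R**2) * (1 - np.exp(-(R**2) / (2 * s**2)))
        tongue_mean = cfg.background + h.amplitude * 2 * np.pi * s**2 / (mask.sum() * cfg.pixel_size_um**2)
        assert idx == pytest.approx(disk_mean / tongue_mean, rel=0.02)

    def test_ramp_starts_at_lead_time(self):
        cfg = RecruitmentConfig(seed=1)
        stack, mask, _ = generate_recruitment_series(cfg)
        h = cfg.hotspots[0]
        weeks = list(cfg.weeks)
        at_ramp_start = stack[weeks.index(h.onset_week - cfg.lead_time_weeks)]
        at_onset = stack[weeks.index(h.onset_week)]
        i_start = lt.recruitment_index(at_ramp_start, h.center_um, mask, cfg.pixel_size_um)
        i_onset = lt.recruitment_index(at_onset, h.center_um, mask, cfg.pixel_size_um)
        assert i_start == pytest.approx(1.0, abs=1e-9)
        assert i_onset > 1.02


class TestDSPCounts:
    def test_no_enrichment_means_chance_assignment(self):
        cfg = DSPConfig(compartment_enrichment=1.0, seed=8)
        counts, annot, truth = generate_dsp_counts(cfg)
        # exclude planted DE genes, which remain informative in myeloid AOIs
        keep = ~counts.index.isin(list(cfg.de_log2fc))
        comp = lt.assign_compartments(counts, annot["class"])
        acc = (comp.loc[keep, "compartment"] == truth["compartments"][keep]).mean()
        assert abs(acc - 1 / 3) < 0.1

    def test_planted_de_genes_present_with_sign(self):
        cfg = DSPConfig()
        assert cfg.de_log2fc["Cxcl9"] > 0 and cfg.de_log2fc["Cxcl10"] > 0
        for g in ("Mmp12", "Apoe", "Lipa"):
            assert cfg.de_log2fc[g] < 0

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            DSPConfig(nb_dispersion=0.0)
        with pytest.raises(ValueError, match="enrichment"):
            DSPConfig(compartment_enrichment=0.5)

    def test_negative_binomial_moments(self):
        """Per-gene sample mean/variance match NB moments m and m + m^2/k."""
        cfg = DSPConfig(
            n_genes={"myeloid": 30, "epithelial": 30, "other": 30},
            n_aois_per_class=220,
            compartment_enrichment=1.0,
            gene_mean_log2_sd=0.0,
            aoi_size_log2_sd=0.0,
            de_log2fc={},
            seed=6,
        )
        counts, _, _ = generate_dsp_counts(cfg)
        m, k = cfg.nb_mean, cfg.nb_dispersion
        n = counts.shape[1]
        sample_mean = counts.mean(axis=1)
        sample_var = counts.var(axis=1, ddof=1)
        var = m + m**2 / k
        # Monte-Carlo error bands: 4 SE of the mean / of the variance estimate
        se_mean = np.sqrt(var / n)
        assert (np.abs(sample_mean - m) < 4 * se_mean).mean() > 0.95
        assert np.abs(sample_var.mean() - var) / var < 0.1

    def test_reproducible(self):
        a = generate_dsp_counts(DSPConfig(seed=3))[0]
        b = generate_dsp_counts(DSPConfig(seed=3))[0]
        pd.testing.assert_frame_equal(a, b)
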