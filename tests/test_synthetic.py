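"""Phantom voxelisation, the rotational beam simulator, BMI and cohorts."""

import math

import numpy as np
import pytest

import cbctrisk as cr


class TestGeneratePhantom:
    def test_sphere_volume_within_ten_percent(self):
        spec = cr.PhantomSpec(
            10, 10, 30, organs=(cr.OrganSpec("liver", (0, 0, 0), (5, 5, 5)),),
            include_skin=False,
        )
        _, structures = cr.generate_phantom(spec, voxel_size_mm=2.5)
        volume = structures["liver"].sum() * 2.5**3 / 1000.0
        analytic = 4.0 / 3.0 * math.pi * 5.0**3
        assert volume == pytest.approx(analytic, rel=0.10)

    def test_empty_organ_list_gives_body_only(self):
        spec = cr.PhantomSpec(8, 6, 20, organs=(), include_skin=False)
        phantom, structures = cr.generate_phantom(spec, 5.0)
        assert len(structures) == 0
        assert phantom.material_mask("tissue").any()
        assert phantom.material_mask("air").any()

    def test_disjoint_organs_have_disjoint_masks(self):
        spec = cr.PhantomSpec(
            10, 8, 30,
            organs=(
                cr.OrganSpec("kidney", (-4, 0, 0), (2, 2, 2)),
                cr.OrganSpec("spleen", (4, 0, 0), (2, 2, 2)),
            ),
            include_skin=False,
        )
        _, structures = cr.generate_phantom(spec, 2.5)
        assert not (structures["kidney"] & structures["spleen"]).any()

    def test_organ_outside_body_rejected(self):
        spec = cr.PhantomSpec(
            8, 8, 20, organs=(cr.OrganSpec("liver", (7, 0, 0), (3, 3, 3)),)
        )
        with pytest.raises(ValueError, match="outside the body"):
            cr.generate_phantom(spec, 5.0)

    def test_shared_organ_id_components_merge(self):
        layout = cr.default_organ_layout(15, 10, 48)
        spec = cr.PhantomSpec(15, 10, 48, organs=layout)
        _, structures = cr.generate_phantom(spec, 5.0)
        # two lungs, one mask, both sides populated
        lung = structures["lung"]
        nx = lung.shape[0]
        assert lung[: nx // 2].any() and lung[nx // 2 :].any()


class TestSimulator:
    def test_central_axis_depth_curve_decreases(self, water_cylinder):
        """Single anterior beam in homogeneous tissue: primary-only model
        gives a strictly decreasing central-axis depth dose."""
        beam = cr.BeamModel(bowtie_strength=0.0, heel_strength=0.0)
        grid = cr.simulate_rotational_dose(
            water_cylinder, beam, cr.AcquisitionProtocol.thorax(), [0.0]
        )
        nx, ny, nz = grid.shape
        body = water_cylinder.labels[nx // 2, :, nz // 2] > 0
        depth_curve = grid.values[nx // 2, body, nz // 2]
        assert (np.diff(depth_curve) < 0).all()

    def test_full_rotation_symmetric_beam_is_rotationally_symmetric(
        self, water_cylinder, symmetric_beam
    ):
        """Full rotation over a centred cylinder with bowtie/heel disabled:
        the dose field is symmetric under 90-degree rotation within
        discretisation tolerance."""
        angles = np.arange(-180.0, 180.0, 10.0)
        grid = cr.simulate_rotational_dose(
            water_cylinder, symmetric_beam, cr.AcquisitionProtocol.thorax(), angles
        )
        rotated = np.rot90(grid.values, k=1, axes=(0, 1))
        body = water_cylinder.labels > 0
        sel = body & np.rot90(body, k=1, axes=(0, 1))
        rel = np.abs(grid.values - rotated)[sel] / grid.values[sel].max()
        assert np.quantile(rel, 0.95) < 0.02

    def test_protocol_mas_ratio_is_exact_per_voxel(self, water_cylinder):
        """Pelvis vs thorax on the same phantom: every voxel scales by
        exactly 1440/360 = 4."""
        beam = cr.BeamModel()
        angles = np.arange(-180.0, 180.0, 30.0)
        thorax = cr.simulate_rotational_dose(
            water_cylinder, beam, cr.AcquisitionProtocol.thorax(), angles
        )
        pelvis = cr.simulate_rotational_dose(
            water_cylinder, beam, cr.AcquisitionProtocol.pelvis(), angles
        )
        nonzero = thorax.values > 0
        np.testing.assert_allclose(
            pelvis.values[nonzero] / thorax.values[nonzero], 4.0, rtol=1e-12
        )

    def test_bowtie_and_heel_produce_measurable_asymmetry(self, water_cylinder):
        """With the half-bowtie and heel enabled, mirrored lateral and axial
        profiles at depth disagree by more than 2%."""
        beam = cr.BeamModel()  # defaults: bowtie 0.4, heel 0.15
        grid = cr.simulate_rotational_dose(
            water_cylinder, beam, cr.AcquisitionProtocol.thorax(), [0.0]
        )
        nx, ny, nz = grid.shape
        body_rows = np.where(water_cylinder.labels.any(axis=(0, 2)))[0]
        iy = body_rows.min() + 10  # ~5 cm depth at 5 mm voxels
        lateral = grid.values[:, iy, nz // 2]
        in_body = water_cylinder.labels[:, iy, nz // 2] > 0
        mirrored = lateral[::-1]
        lateral_mismatch = np.abs(lateral - mirrored)[in_body] / lateral[in_body].max()
        assert lateral_mismatch.max() > 0.02
        axial = grid.values[nx // 2, iy, :]
        in_body_z = water_cylinder.labels[nx // 2, iy, :] > 0
        axial_mismatch = np.abs(axial - axial[::-1])[in_body_z] / axial[in_body_z].max()
        assert axial_mismatch.max() > 0.02

    def test_deeper_organ_gets_less_dose(self):
        """Two identical tissue spheres, one nearer the anterior entrance:
        the deeper one receives less dose from an anterior beam."""
        spec = cr.PhantomSpec(
            12, 10, 24,
            organs=(
                cr.OrganSpec("stomach", (0, -5, 0), (2, 2, 2)),
                cr.OrganSpec("pancreas", (0, 5, 0), (2, 2, 2)),
            ),
            include_skin=False,
        )
        phantom, structures = cr.generate_phantom(spec, 5.0)
        beam = cr.BeamModel(bowtie_strength=0.0, heel_strength=0.0)
        grid = cr.simulate_rotational_dose(
            phantom, beam, cr.AcquisitionProtocol.thorax(), [0.0]
        )
        shallow = cr.mean_organ_dose(grid, structures["stomach"])
        deep = cr.mean_organ_dose(grid, structures["pancreas"])
        assert deep < shallow

    def test_angle_outside_range_rejected(self, water_cylinder):
        beam = cr.BeamModel()
        with pytest.raises(ValueError, match="-180"):
            cr.simulate_rotational_dose(
                water_cylinder, beam, cr.AcquisitionProtocol.thorax(), [190.0]
            )

    def test_empty_angle_list_rejected(self, water_cylinder):
        with pytest.raises(ValueError, match="non-empty"):
            cr.simulate_rotational_dose(
                water_cylinder, cr.BeamModel(), cr.AcquisitionProtocol.thorax(), []
            )

    def test_deterministic(self, water_cylinder, symmetric_beam):
        protocol = cr.AcquisitionProtocol.fourd()
        a = cr.simulate_rotational_dose(
            water_cylinder, symmetric_beam, protocol, [0.0, 90.0]
        )
        b = cr.simulate_rotational_dose(
            water_cylinder, symmetric_beam, protocol, [0.0, 90.0]
        )
        assert np.array_equal(a.values, b.values)


class TestPipelinePhysicsTrends:
    def _effective_dose_for_radius(self, radius_cm):
        organs = (
            cr.OrganSpec("lung", (0, -0.2 * radius_cm, 0), (2.5, 2.5, 3.0), "lung"),
            cr.OrganSpec("stomach", (-0.3 * radius_cm, 0, -2), (2, 2, 2)),
            cr.OrganSpec("liver", (0.3 * radius_cm, 0, -2), (2.5, 2.5, 2.5)),
        )
        spec = cr.PhantomSpec(radius_cm, radius_cm * 0.8, 18, organs=organs,
                              include_skin=True)
        phantom, structures = cr.generate_phantom(spec, 5.0)
        beam = cr.BeamModel()
        grid = cr.simulate_rotational_dose(
            phantom, beam, cr.AcquisitionProtocol.fourd(),
            np.arange(-180.0, 180.0, 30.0),
        )
        table = cr.mean_organ_doses(grid, structures)
        return cr.effective_dose(table, cr.TissueWeightingScheme.study_subset())

    def test_effective_dose_decreases_with_body_radius(self):
        """Same organ layout inside growing bodies: effective dose falls as
        the trunk gets larger (the BMI trend, qualitatively)."""
        doses = [self._effective_dose_for_radius(r) for r in (10.0, 13.0, 16.0)]
        assert doses[0] > doses[1] > doses[2]

    def test_end_to_end_linearity_in_total_mas(self):
        """Doubling total mAs (via N) doubles every mean organ dose, the
        effective dose and the EAR exactly."""
        spec = cr.PhantomSpec(
            10, 8, 16,
            organs=(cr.OrganSpec("lung", (0, -2, 0), (3, 2, 3), "lung"),),
            include_skin=False,
        )
        phantom, structures = cr.generate_phantom(spec, 5.0)
        beam = cr.BeamModel()
        protocol = cr.AcquisitionProtocol.fourd()
        doubled = protocol.replace(n_acquisitions=2)
        angles = [0.0, 120.0, -120.0]
        g1 = cr.simulate_rotational_dose(phantom, beam, protocol, angles)
        g2 = cr.simulate_rotational_dose(phantom, beam, doubled, angles)
        scheme = cr.TissueWeightingScheme.study_subset()
        beir = cr.BEIRParameterSet.default()
        t1 = cr.mean_organ_doses(g1, structures)
        t2 = cr.mean_organ_doses(g2, structures)
        assert t2.dose("lung") == pytest.approx(2 * t1.dose("lung"), rel=1e-12)
        assert cr.effective_dose(t2, scheme) == pytest.approx(
            2 * cr.effective_dose(t1, scheme), rel=1e-12
        )
        q = cr.EARQuery("lung", "female", 30, 70)
        assert cr.excess_absolute_risk(t2.dose("lung"), beir, q).value == pytest.approx(
            2 * cr.excess_absolute_risk(t1.dose("lung"), beir, q).value, rel=1e-12
        )


class TestBMI:
    @pytest.mark.parametrize(
        "height,weight,bmi,category",
        [
            (138.6, 31.4, 16.3, "underweight"),
            (147.3, 49.2, 22.7, "normal"),
            (146.0, 55.0, 25.8, "overweight"),
            (157.0, 45.6, 18.5, "normal"),  # exactly on the 18.50 floor
        ],
    )
    def test_published_patients(self, height, weight, bmi, category):
        result = cr.bmi_class(height, weight)
        assert round(result.value, 1) == bmi
        assert result.category == category

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            cr.bmi_class(0.0, 50.0)
        with pytest.raises(ValueError):
            cr.bmi_class(160.0, -1.0)


class TestSampleCohort:
    def test_deterministic_given_seed(self):
        spec = cr.CohortSpec.for_site("liver", 6, seed=42)
        a = cr.sample_cohort(spec)
        b = cr.sample_cohort(spec)
        assert [(p.sex, p.height_cm, p.weight_kg) for p in a] == [
            (p.sex, p.height_cm, p.weight_kg) for p in b
        ]

    def test_cohort_size(self):
        assert len(cr.sample_cohort(cr.CohortSpec.for_site("lung", 15, 0))) == 15

    def test_default_lung_ranges_span_all_bmi_classes(self):
        """1000 draws from the lung-site defaults cover underweight through
        overweight (the study cohort spans 16.3-25.8 kg/m^2)."""
        patients = cr.sample_cohort(cr.CohortSpec.for_site("lung", 1000, seed=1))
        bmis = np.array([p.bmi for p in patients])
        assert bmis.min() < 18.5
        assert bmis.max() >= 25.0

    def test_heights_within_configured_range(self):
        spec = cr.CohortSpec.for_site("lung", 200, seed=2)
        patients = cr.sample_cohort(spec)
        lo, hi = spec.height_range_cm
        assert all(lo <= p.height_cm <= hi for p in patients)

    def test_impossible_distribution_rejected(self):
        with pytest.raises(ValueError):
            cr.CohortSpec.for_site("lung", 5, 0, height_range_cm=(180.0, 120.0))
        spec = cr.CohortSpec.for_site("lung", 5, 0, height_mean_cm=400.0,
                                      height_sd_cm=0.001)
        with pytest.raises(ValueError):
            cr.sample_cohort(spec)

    def test_phantoms_scale_with_weight(self):
        heavy = cr.synthetic.body_radii_from_anthropometry(160.0, 90.0)
        light = cr.synthetic.body_radii_from_anthropometry(160.0, 45.0)
        assert heavy[0] > light[0] and heavy[1] > light[1]
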