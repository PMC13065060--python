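"""Material table, layout generation and scan rendering."""

import numpy as np
import pytest

from spectraseg.materials import (CONFUSABLE_PAIRS, default_materials,
                                  material_by_name)
from spectraseg.phantom import (AcquisitionParams, CoverageError,
                                PhantomLayout, make_layouts, render_scan,
                                standard_positions)


@pytest.fixture(scope="module")
def materials():
    return default_materials()


class TestMaterials:
    def test_twelve_materials_with_unique_class_ids(self, materials):
        assert len(materials) == 12
        assert sorted(m.class_id for m in materials) == list(range(1, 13))
        # deterministic construction
        again = default_materials()
        for a, b in zip(materials, again):
            assert a.name == b.name and np.array_equal(a.mu, b.mu)

    def test_ha_attenuation_linear_in_concentration(self, materials):
        water = material_by_name(materials, "water").mu
        ha200 = material_by_name(materials, "HA200").mu
        ha400 = material_by_name(materials, "HA400").mu
        assert np.allclose(ha400 - water, 2 * (ha200 - water))
        # strictly increasing coefficient along the HA family
        coeffs = [(material_by_name(materials, n).mu - water).sum()
                  for n in ("HA50", "HA100", "HA200", "HA400", "HA800")]
        assert np.all(np.diff(coeffs) > 0)

    def test_engineered_band_integral_ties(self, materials):
        for iod, ha in CONFUSABLE_PAIRS:
            si = material_by_name(materials, iod).mu.sum()
            sh = material_by_name(materials, ha).mu.sum()
            assert abs(si - sh) < 1e-6

    def test_spectral_shapes_differ(self, materials):
        water = material_by_name(materials, "water").mu
        sh = material_by_name(materials, "HA100").mu - water
        si = material_by_name(materials, "I5").mu - water
        cos = sh @ si / (np.linalg.norm(sh) * np.linalg.norm(si))
        assert cos < 0.99

    def test_confusable_profiles_separated_beyond_noise(self, materials):
        """At default noise, the tied pairs differ by >= 5 sigma in some bin."""
        acq = AcquisitionParams()
        sigmas = acq.bin_sigmas()
        for iod, ha in CONFUSABLE_PAIRS:
            diff = np.abs(material_by_name(materials, iod).mu
                          - material_by_name(materials, ha).mu)
            assert np.any(diff >= 5 * sigmas)


class TestLayouts:
    def test_five_scans_cover_all_materials(self, materials):
        layouts = make_layouts(5, materials, rng_seed=0)
        assert len(layouts) == 5
        names = {m.name for lay in layouts for m in lay.assignment.values()}
        assert len(names) == 12
        for lay in layouts:
            assert len(lay.assignment) == 8
            names_in_scan = [m.name for m in lay.assignment.values()]
            assert len(set(names_in_scan)) == 8

    def test_coverage_impossible_raises(self, materials):
        with pytest.raises(CoverageError):
            make_layouts(1, materials, rng_seed=0)

    def test_single_scan_without_coverage(self, materials):
        (lay,) = make_layouts(1, materials, rng_seed=3, ensure_coverage=False)
        assert len(lay.assignment) == 8

    def test_seed_determinism(self, materials):
        a = make_layouts(5, materials, rng_seed=11)
        b = make_layouts(5, materials, rng_seed=11)
        for la, lb in zip(a, b):
            assert {k: m.name for k, m in la.assignment.items()} == \
                   {k: m.name for k, m in lb.assignment.items()}

    def test_geometry_validation(self, materials):
        pos = list(standard_positions(100.0))
        pos[1] = (49.0, 0.0)  # rod crosses the phantom boundary
        with pytest.raises(ValueError):
            PhantomLayout(100.0, 10.0, tuple(pos), {})


class TestRenderScan:
    def test_rasterized_rod_area_matches_analytic_disk(self, materials):
        """Central 10 mm rod at 0.1 mm voxels: ~pi*50^2 labeled voxels/slice."""
        mat = material_by_name(materials, "HA800")
        lay = PhantomLayout(100.0, 10.0, standard_positions(100.0), {0: mat})
        acq = AcquisitionParams(voxel_size_mm=0.1, image_size=128, n_slices=1,
                                noise_sigma0=0.0, bias_amplitude=0.0)
        _, lab = render_scan(lay, acq)
        count = int((lab.labels[0] == mat.class_id).sum())
        expected = np.pi * 50.0 ** 2
        assert abs(count - expected) / expected < 0.02

    def test_noiseless_rod_voxels_equal_signature(self, materials):
        mat = material_by_name(materials, "I10")
        lay = PhantomLayout(100.0, 10.0, standard_positions(100.0), {0: mat})
        acq = AcquisitionParams(image_size=64, n_slices=2, noise_sigma0=0.0,
                                bias_amplitude=0.0)
        vol, lab = render_scan(lay, acq)
        mask = lab.labels[0] == mat.class_id
        for f in range(vol.n_bins):
            assert np.allclose(vol.values[0, f][mask], mat.mu[f], atol=1e-6)

    def test_rods_traverse_all_slices_and_labels_inside_radius(self, materials):
        layouts = make_layouts(1, materials, rng_seed=0, ensure_coverage=False)
        acq = AcquisitionParams(image_size=64, n_slices=3, seed=5)
        vol, lab = render_scan(layouts[0], acq)
        assert np.array_equal(lab.labels[0], lab.labels[2])
        vox = vol.voxel_size_mm
        n = acq.image_size
        coords = (np.arange(n) - (n - 1) / 2.0) * vox
        xx, yy = np.meshgrid(coords, coords, indexing="xy")
        for pos_idx, mat in layouts[0].assignment.items():
            cx, cy = layouts[0].positions[pos_idx]
            mask = lab.labels[0] == mat.class_id
            r = np.hypot(xx[mask] - cx, yy[mask] - cy)
            assert r.max() <= layouts[0].rod_diameter_mm / 2 + 1e-9

    def test_seeded_determinism_and_noise_independence(self, materials):
        layouts = make_layouts(1, materials, rng_seed=0, ensure_coverage=False)
        acq1 = AcquisitionParams(image_size=32, n_slices=2, seed=9)
        v1, l1 = render_scan(layouts[0], acq1)
        v2, l2 = render_scan(layouts[0], acq1)
        assert np.array_equal(v1.values, v2.values)
        acq2 = AcquisitionParams(image_size=32, n_slices=2, seed=10)
        v3, l3 = render_scan(layouts[0], acq2)
        assert not np.array_equal(v1.values, v3.values)
        assert np.array_equal(l1.labels, l3.labels)

    def test_ha_family_mean_intensity_monotone(self, materials):
        """Noiseless mean rod intensity rises with HA concentration."""
        means = []
        for name in ("HA50", "HA100", "HA200", "HA400", "HA800"):
            mat = material_by_name(materials, name)
            lay = PhantomLayout(100.0, 10.0, standard_positions(100.0),
                                {0: mat})
            acq = AcquisitionParams(image_size=48, n_slices=1,
                                    noise_sigma0=0.0, bias_amplitude=0.0)
            vol, lab = render_scan(lay, acq)
            mask = lab.labels[0] == mat.class_id
            means.append(vol.values[0, :, mask].mean())
        assert np.all(np.diff(means) > 0)
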