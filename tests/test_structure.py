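"""Volume-fraction slab models: profiles, symmetry, inventories, APM."""

import numpy as np
import pytest

from nrpore.materials import D2O, SI_MW, material_sld, solvent_sld
from nrpore.structure import (
    Layer,
    area_per_molecule,
    build_membrane_model,
    lipid_inventory,
    sld_profile,
    volume_fraction_profile,
)

BEFORE_10 = {
    "head_in_thickness": 5.7,
    "head_in_lipid": 0.83,
    "tail_thickness": 29.8,
    "tail_lipid": 0.98,
    "head_out_thickness": 5.7,
    "head_out_lipid": 0.83,
}


class TestBuildMembraneModel:
    def test_published_before_structure(self, materials):
        m = build_membrane_model(0.10, BEFORE_10, materials=materials)
        tails = m.layer("tails")
        assert tails.thickness == pytest.approx(29.8)
        assert tails.components["lipid_tail"] == pytest.approx(0.98)
        assert tails.solvent_fraction == pytest.approx(0.02)

    def test_pure_popc_tail_sld_at_zero_cl(self, materials):
        m = build_membrane_model(0.0, BEFORE_10, materials=materials)
        assert material_sld(m.materials["lipid_tail"], D2O) == pytest.approx(
            material_sld(materials["popc_tail"], D2O), rel=1e-12
        )

    def test_rejects_oversummed_fractions(self, materials):
        bad = dict(BEFORE_10, tail_lipid=1.1)
        with pytest.raises(ValueError):
            build_membrane_model(0.10, bad, materials=materials)

    def test_rejects_bad_x_cl(self, materials):
        with pytest.raises(ValueError):
            build_membrane_model(1.5, BEFORE_10, materials=materials)


class TestProfiles:
    def test_fractions_sum_to_one_everywhere(self, catalog):
        z = np.linspace(-30.0, 180.0, 700)
        for name in ("10CL_before", "10CL_after"):
            prof = volume_fraction_profile(catalog[name], z)
            total = sum(prof.values())
            np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_sld_profile_consistent_with_fraction_mixture(self, catalog):
        """rho(z) equals the pointwise fraction-weighted slab SLD mixture."""
        m = catalog["10CL_after"]
        z = np.linspace(-20.0, 160.0, 400)
        rho = sld_profile(m, SI_MW, z)
        slds, _, _ = m.slab_arrays(SI_MW, "h")
        from nrpore.structure import _layer_weights

        weights, _ = _layer_weights(m, z)
        expected = (slds[:, None] * weights).sum(axis=0)
        np.testing.assert_allclose(rho, expected, atol=1e-12 * abs(slds).max())

    def test_zero_roughness_gives_step_profile(self, materials):
        m = build_membrane_model(0.10, BEFORE_10, materials=materials)
        m.substrate_roughness = 0.0
        for layer in m.layers:
            layer.roughness = 0.0
        z = np.linspace(-10.0, 60.0, 1000)
        rho = sld_profile(m, D2O, z)
        # piecewise constant: derivative is zero except at interfaces
        levels = np.unique(np.round(rho, 12))
        assert len(levels) <= len(m.layers) + 2

    def test_tail_trough_between_headgroup_shoulders(self, catalog):
        """In D2O the hydrogenous tail region is a deep SLD trough."""
        m = catalog["10CL_before"]
        z = np.linspace(0.0, 60.0, 600)
        rho = sld_profile(m, D2O, z)
        core = (z > 25) & (z < 40)  # inside tail region
        assert rho[core].min() < 1.0e-6
        assert rho.max() > 3.0e-6

    def test_pure_solvent_region(self, catalog):
        prof = volume_fraction_profile(catalog["10CL_before"], np.array([500.0]))
        assert prof["solvent"][0] == pytest.approx(1.0, abs=1e-9)

    def test_after_model_has_protein_in_tails_and_three_lobes(self, catalog):
        m = catalog["10CL_after"]
        z = np.linspace(0.0, 160.0, 2000)
        prof = volume_fraction_profile(m, z)
        tails_start = 12.0 + 4.0 + 6.5
        core = (z > tails_start + 5) & (z < tails_start + 20)
        assert prof["protein"][core].min() > 0.03
        # three protein-bearing layers above the bilayer: wing plateaus near
        # 12% flanking a core peak near 30%
        complex_start = tails_start + 27.6 + 6.5
        wing1 = complex_start + 23.4 / 2
        core_z = complex_start + 23.4 + 29.7 / 2
        wing2 = complex_start + 23.4 + 29.7 + 23.4 / 2
        p_at = lambda zz: np.interp(zz, z, prof["protein"])
        assert p_at(wing1) == pytest.approx(0.12, abs=0.02)
        assert p_at(core_z) == pytest.approx(0.30, abs=0.02)
        assert p_at(wing2) == pytest.approx(0.12, abs=0.02)

    def test_symmetric_complex_mirror(self, catalog):
        """Wing layers of the symmetric complex are mirror images."""
        m = catalog["10CL_after"]
        c1, c3 = m.layer("cluster1"), m.layer("cluster3")
        assert c1.thickness == c3.thickness
        assert c1.components == c3.components
        # setting through either name updates both
        m2 = m.copy()
        m2.set("cluster3.thickness", 25.0)
        assert m2.layer("cluster1").thickness == 25.0

    def test_lipid_profile_integral_matches_inventory(self, catalog):
        """Numeric quadrature of the lipid profile equals the slab inventory."""
        m = catalog["10CL_after"]
        z = np.linspace(-60.0, 260.0, 6000)
        prof = volume_fraction_profile(m, z)
        integral = np.trapezoid(prof["lipid"], z)
        inv = lipid_inventory(m)
        expected = inv["bilayer"]["lipid"] + inv["complex"]["lipid"]
        assert integral == pytest.approx(expected, rel=1e-6)


class TestAreaPerMolecule:
    def test_doubling_thickness_halves_apm(self):
        a1 = area_per_molecule(30.0, 0.98, 0.1, v_tails=941.7)
        a2 = area_per_molecule(60.0, 0.98, 0.1, v_tails=941.7)
        assert a2 == pytest.approx(a1 / 2)

    def test_published_back_calculation(self):
        # APM = 2 V / (t phi): 2*941.7/(29.8*0.98)
        assert area_per_molecule(29.8, 0.98, 0.1, v_tails=941.7) == pytest.approx(
            64.5, abs=0.05
        )

    def test_apm_increases_with_cardiolipin(self, materials):
        """Four-chain cardiolipin is bulkier, so the mole-average area grows."""
        a0 = area_per_molecule(29.8, 0.98, 0.0, materials=materials)
        a15 = area_per_molecule(29.8, 0.98, 0.15, materials=materials)
        assert a15 > a0

    def test_rejects_degenerate_geometry(self):
        with pytest.raises(ValueError):
            area_per_molecule(0.0, 0.98, 0.1, v_tails=941.7)
        with pytest.raises(ValueError):
            area_per_molecule(29.8, 0.0, 0.1, v_tails=941.7)


class TestLipidInventory:
    def test_empty_complex_zero_inventory(self, catalog):
        inv = lipid_inventory(catalog["10CL_before"])
        assert inv["complex"]["lipid"] == 0.0
        assert inv["complex"]["protein"] == 0.0

    def test_core_layer_hand_arithmetic(self, catalog):
        # complex core: 29.7 A x 0.17 lipid
        inv = lipid_inventory(catalog["10CL_after"])
        assert inv["complex"]["lipid"] == pytest.approx(29.7 * 0.17, rel=1e-9)

    def test_invariant_under_layer_split(self, catalog):
        """Splitting a layer into two identical halves preserves Gamma."""
        m = catalog["10CL_before"].copy()
        inv0 = lipid_inventory(m)["bilayer"]["lipid"]
        tails = m.layer("tails")
        idx = m.layers.index(tails)
        halves = [
            Layer("tails", tails.thickness / 2, tails.roughness, dict(tails.components)),
            Layer("tails_b", tails.thickness / 2, 0.0, dict(tails.components)),
        ]
        m.layers[idx : idx + 1] = halves
        # region membership is by name; count the second half explicitly
        split = lipid_inventory(m)["bilayer"]["lipid"] + (
            halves[1].thickness * halves[1].components["lipid_tail"]
        )
        assert split == pytest.approx(inv0, rel=1e-12)
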