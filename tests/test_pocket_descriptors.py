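"""Descriptor engine validation: oracle equivalence, monotonicity,
ND behaviour and rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import brute_force_descriptors, monte_carlo_enclosure
from ppidrugg.pocket_descriptors import (
    PocketConfig,
    SiteDescriptors,
    candidate_grid,
    detect_site,
    enclosure_at,
    icosphere_directions,
)
from ppidrugg.structure_io import AtomRecord, LigandMolecule, ProteinStructure
from ppidrugg.superpose import RigidTransform, transform_structure
from ppidrugg.synthetic_data import CavitySpec, make_cavity_structure


def _single_atom_ligand(xyz=(0.0, 0.0, 0.0)):
    return LigandMolecule(
        atoms=[AtomRecord(serial=1, name="C1", element="C", residue_name="LIG",
                          residue_seq=1, chain_id="A", coords=xyz, is_hetero=True)],
        residue_name="LIG",
    )


def _structure_of(coords, element="C"):
    atoms = [
        AtomRecord(serial=i + 1, name="CA", element=element, residue_name="GLY",
                   residue_seq=i + 1, chain_id="A", coords=tuple(map(float, c)))
        for i, c in enumerate(coords)
    ]
    return ProteinStructure(atoms=atoms, id="toy")


EMPTY = ProteinStructure(
    atoms=[AtomRecord(serial=1, name="CA", element="C", residue_name="GLY",
                      residue_seq=1, chain_id="A", coords=(500.0, 500.0, 500.0))],
    id="far",
)


class TestIcosphere:
    def test_vertex_counts_and_unit_norm(self):
        for k, expect in ((0, 12), (1, 42), (2, 162)):
            d = icosphere_directions(k)
            assert d.shape == (expect, 3)
            assert np.allclose(np.linalg.norm(d, axis=1), 1.0)

    def test_deterministic(self):
        assert np.array_equal(icosphere_directions(2), icosphere_directions(2))


class TestCandidateGrid:
    def test_counting_no_protein(self):
        cfg = PocketConfig(region_margin=2.0, grid_spacing=1.0)
        pts = candidate_grid(EMPTY, _single_atom_ligand(), cfg)
        assert len(pts) == 5**3  # margin 2 on each side of a point ligand

    def test_single_atom_carves_sphere(self):
        cfg = PocketConfig(region_margin=2.0, grid_spacing=1.0)
        blocker = _structure_of([(0.0, 0.0, 0.0)])
        pts = candidate_grid(blocker, _single_atom_ligand(), cfg)
        # brute force: points farther than vdW(C) + probe from the origin
        expected = [
            (i, j, k)
            for i in range(-2, 3) for j in range(-2, 3) for k in range(-2, 3)
            if i * i + j * j + k * k >= (1.7 + 1.4) ** 2
        ]
        assert len(pts) == len(expected)
        assert all(np.linalg.norm(p) >= 1.7 + 1.4 for p in pts)


class TestEnclosure:
    def test_open_space_is_zero(self):
        assert enclosure_at((0.0, 0.0, 0.0), EMPTY, PocketConfig()) == 0.0

    def test_closed_shell_is_one(self):
        # dense spherical shell of atoms at radius 5
        dirs = icosphere_directions(2)
        shell = _structure_of(5.0 * dirs)
        assert enclosure_at((0.0, 0.0, 0.0), shell, PocketConfig()) == 1.0

    def test_flat_slab_converges_to_monte_carlo_oracle(self, flat_slab):
        """3 A above a flat slab the blocked fraction approaches an
        independent Monte-Carlo estimate (10^6 random directions) as the
        deterministic ray set is refined."""
        point = (0.0, 0.0, 3.0)
        mc = monte_carlo_enclosure(
            point, flat_slab.structure, PocketConfig(), n_rays=1_000_000, seed=8
        )
        coarse = enclosure_at(point, flat_slab.structure, PocketConfig(ray_subdivisions=2))
        fine = enclosure_at(point, flat_slab.structure, PocketConfig(ray_subdivisions=3))
        assert coarse == pytest.approx(mc, abs=0.03)  # 162 rays
        assert fine == pytest.approx(mc, abs=0.01)    # 642 rays


class TestDetectSite:
    def test_flat_slab_returns_nd(self, flat_slab):
        desc = detect_site(flat_slab.structure, flat_slab.ligand)
        assert not desc.detected
        assert desc.n is None and desc.e is None and desc.p is None

    def test_apolar_cavity_detected_with_zero_p(self, default_cavity):
        desc = detect_site(default_cavity.structure, default_cavity.ligand)
        assert desc.detected
        assert desc.n >= PocketConfig().min_site_points
        assert 0.0 <= desc.e <= 1.0
        assert desc.p == 0.0

    def test_polar_cavity(self, default_cavity, polar_cavity):
        d0 = detect_site(default_cavity.structure, default_cavity.ligand)
        d1 = detect_site(polar_cavity.structure, polar_cavity.ligand)
        # polar lining barely perturbs geometry (slightly smaller vdW radii)
        assert abs(d1.n - d0.n) / d0.n <= 0.15
        assert 0.0 < d1.p < PocketConfig().hydrophilicity_scale

    def test_brute_force_oracle_equivalence(self, mini_cavity, mini_config):
        """(n, e, p) equal an independent pure-Python recomputation of the
        grid, the ray-cast enclosure, the clustering and the contacts."""
        desc = detect_site(mini_cavity.structure, mini_cavity.ligand, mini_config)
        oracle = brute_force_descriptors(mini_cavity.structure, mini_cavity.ligand, mini_config)
        assert desc.detected and oracle is not None
        n, e, p = oracle
        assert desc.n == n
        assert desc.e == pytest.approx(e, abs=1e-12)
        assert desc.p == pytest.approx(p, abs=1e-12)

    def test_brute_force_oracle_nd_on_flat(self, mini_config):
        flat = make_cavity_structure(CavitySpec(depth=0.0, slab_half_width=7.0, slab_thickness=6.0))
        desc = detect_site(flat.structure, flat.ligand, mini_config)
        oracle = brute_force_descriptors(flat.structure, flat.ligand, mini_config)
        assert not desc.detected and oracle is None


class TestMonotonicity:
    def test_deeper_cavity_never_smaller(self):
        ns = []
        for depth in (2.0, 4.0, 6.0, 8.0):
            fx = make_cavity_structure(CavitySpec(depth=depth))
            ns.append(detect_site(fx.structure, fx.ligand).n)
        assert ns == sorted(ns)

    def test_rim_never_less_enclosed(self):
        es = []
        for rim in (0.0, 2.0, 4.0):
            fx = make_cavity_structure(CavitySpec(rim_height=rim))
            es.append(detect_site(fx.structure, fx.ligand).e)
        assert es == sorted(es)

    def test_polar_fraction_strictly_raises_p(self):
        ps = []
        for pf in (0.0, 0.25, 0.5, 0.75, 1.0):
            fx = make_cavity_structure(CavitySpec(polar_fraction=pf, seed=7))
            ps.append(detect_site(fx.structure, fx.ligand).p)
        assert all(b > a for a, b in zip(ps, ps[1:]))

    def test_wider_cavity_never_smaller(self):
        ns = []
        for radius in (3.0, 4.0, 5.0):
            fx = make_cavity_structure(CavitySpec(radius=radius, slab_half_width=13.0))
            ns.append(detect_site(fx.structure, fx.ligand).n)
        assert ns == sorted(ns)


class TestRigidMotionInvariance:
    def test_translation_exact(self, default_cavity):
        base = detect_site(default_cavity.structure, default_cavity.ligand)
        rng = np.random.default_rng(9)
        for _ in range(5):
            t = rng.uniform(-20, 20, size=3)
            motion = RigidTransform(np.eye(3), t, 0.0)
            st = transform_structure(default_cavity.structure, motion)
            lig = default_cavity.ligand.transformed(np.eye(3), t)
            moved = detect_site(st, lig)
            # the grid is anchored at the ligand centroid, so translations
            # shift everything rigidly and descriptors are unchanged
            assert moved.n == base.n
            assert moved.e == pytest.approx(base.e, abs=1e-9)
            assert moved.p == pytest.approx(base.p, abs=1e-9)

    def test_rotations_within_discretization_tolerance(self):
        # a pocket well above the probe-clearance resolution limit: lattice
        # aliasing stays within the stated tolerances only when the cavity
        # is a few grid cells wide in every direction
        fx = make_cavity_structure(
            CavitySpec(radius=5.0, depth=8.0, lattice_spacing=1.5,
                       slab_half_width=12.0, slab_thickness=13.0)
        )
        base = detect_site(fx.structure, fx.ligand)
        rng = np.random.default_rng(10)
        rots = Rotation.random(20, rng=rng)
        for rot in rots:
            r = rot.as_matrix()
            t = rng.uniform(-10, 10, size=3)
            motion = RigidTransform(r, t, 0.0)
            st = transform_structure(fx.structure, motion)
            lig = fx.ligand.transformed(r, t)
            moved = detect_site(st, lig)
            assert moved.detected
            assert abs(moved.n - base.n) / base.n <= 0.15
            assert abs(moved.e - base.e) <= 0.05


class TestDescriptorState:
    def test_nd_state_carries_nothing(self):
        nd = SiteDescriptors.nd()
        assert not nd.detected
        with pytest.raises(ValueError):
            SiteDescriptors(n=3, e=0.5, p=0.1, detected=False)

    def test_detected_requires_valid_ranges(self):
        with pytest.raises(ValueError):
            SiteDescriptors(n=10, e=1.2, p=0.0, detected=True)
        with pytest.raises(ValueError):
            SiteDescriptors(n=10, e=0.5, p=-0.1, detected=True)

    def test_determinism(self, default_cavity):
        a = detect_site(default_cavity.structure, default_cavity.ligand)
        b = detect_site(default_cavity.structure, default_cavity.ligand)
        assert (a.n, a.e, a.p) == (b.n, b.e, b.p)
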