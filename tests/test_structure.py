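import math

import numpy as np
import pytest

from aggrevar import (
    APR,
    apr_structural_summary,
    burial,
    load_structure,
    min_distance_variant_apr,
    shrake_rupley_sasa,
    sphere_points,
)
from aggrevar.structure import StructureModel, residue_metrics
from conftest import make_pdb


def model_from_atoms(atoms, tmp_path, name="toy"):
    pdb = tmp_path / f"{name}.pdb"
    pdb.write_text(make_pdb(atoms))
    return load_structure(str(pdb), name, chain="A")


@pytest.fixture
def triangle(tmp_path):
    # two single-atom residues at distance 5 (3-4-5 triangle)
    atoms = [
        (1, "ALA", "CA", "C", 0.0, 0.0, 0.0),
        (10, "ALA", "CA", "C", 3.0, 4.0, 0.0),
    ]
    return model_from_atoms(atoms, tmp_path)


@pytest.fixture
def five_residue(tmp_path):
    rng = np.random.default_rng(7)
    atoms = []
    for res in range(1, 6):
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")):
            x, y, z = rng.uniform(-8, 8, 3)
            atoms.append((res, "ALA", name, el, x, y, z))
    return model_from_atoms(atoms, tmp_path)


class TestMinDistance:
    def test_three_four_five_triangle(self, triangle):
        apr = APR("toy", 8, 12, region_score=50.0)
        assert min_distance_variant_apr(triangle, 1, apr) == pytest.approx(5.0)

    def test_variant_inside_apr_is_zero(self, triangle):
        apr = APR("toy", 1, 5, region_score=50.0)
        assert min_distance_variant_apr(triangle, 1, apr) == 0.0

    def test_symmetry(self, triangle):
        d1 = min_distance_variant_apr(triangle, 1, APR("toy", 8, 12, region_score=1))
        d2 = min_distance_variant_apr(triangle, 10, APR("toy", 1, 5, region_score=1))
        assert d1 == pytest.approx(d2)

    def test_equals_brute_force_pairwise_minimum(self, five_residue):
        apr = APR("toy", 3, 7, region_score=40.0)  # residues 6-7 unresolved
        got = min_distance_variant_apr(five_residue, 1, apr)
        vmask = five_residue.residue_index == 1
        amask = np.isin(five_residue.residue_index, [3, 4, 5])
        brute = min(
            math.dist(a, b)
            for a in five_residue.coords[vmask]
            for b in five_residue.coords[amask]
        )
        assert got == pytest.approx(brute, rel=1e-12)

    def test_unresolved_residue_gives_nan_with_warning(self, triangle):
        with pytest.warns(UserWarning, match="unresolved"):
            d = min_distance_variant_apr(triangle, 99, APR("toy", 8, 12, region_score=1))
        assert math.isnan(d)


def shell_atoms(center_res, shell_start, radius=3.0, n=100):
    """A single central atom enclosed by a shell of one-atom residues
    (each shell atom gets its own residue number)."""
    atoms = [(center_res, "ALA", "CB", "C", 0.0, 0.0, 0.0)]
    for i, (x, y, z) in enumerate(sphere_points(n) * radius):
        atoms.append((shell_start + i, "ALA", "CB", "C", x, y, z))
    return atoms


class TestBurial:
    def test_isolated_residue_is_fully_exposed(self, tmp_path):
        atoms = [
            (1, "ALA", "N", "N", 0.0, 0.0, 0.0),
            (1, "ALA", "CA", "C", 1.5, 0.0, 0.0),
            (1, "ALA", "CB", "C", 2.2, 1.2, 0.0),
        ]
        model = model_from_atoms(atoms, tmp_path)
        side, main = burial(model, 1)
        assert side == pytest.approx(0.0, abs=0.05)
        assert main == pytest.approx(0.0, abs=0.05)

    def test_enclosed_residue_is_fully_buried(self, tmp_path):
        model = model_from_atoms(shell_atoms(1, 10), tmp_path)
        side, _ = burial(model, 1)
        assert side == pytest.approx(1.0, abs=0.05)

    def test_burial_increases_as_neighbor_approaches(self, tmp_path):
        burials = []
        for i, d in enumerate((6.0, 4.5)):
            atoms = [
                (1, "ALA", "CB", "C", 0.0, 0.0, 0.0),
                (2, "ALA", "CB", "C", d, 0.0, 0.0),
            ]
            model = model_from_atoms(atoms, tmp_path, name=f"two{i}")
            burials.append(burial(model, 1)[0])
        assert burials[1] > burials[0] >= 0.0

    def test_glycine_sidechain_is_na(self, tmp_path):
        atoms = [
            (1, "GLY", "N", "N", 0.0, 0.0, 0.0),
            (1, "GLY", "CA", "C", 1.5, 0.0, 0.0),
            (1, "GLY", "C", "C", 2.5, 1.0, 0.0),
            (1, "GLY", "O", "O", 3.5, 0.6, 0.9),
        ]
        model = model_from_atoms(atoms, tmp_path)
        side, main = burial(model, 1)
        assert math.isnan(side)
        assert not math.isnan(main)

    def test_invariant_under_translation(self, five_residue):
        before = burial(five_residue, 2)
        after = burial(five_residue.translated([11.0, -4.0, 7.5]), 2)
        assert after == pytest.approx(before, abs=1e-12)

    def test_invariant_under_rotation_with_corotated_sampling(self, five_residue):
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0.0],
                [math.sin(theta), math.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        pts = sphere_points()
        before = burial(five_residue, 2, points=pts)
        after = burial(five_residue.rotated(rot), 2, points=pts @ rot.T)
        assert after == pytest.approx(before, abs=1e-6)

    def test_rotation_with_default_sampling_agrees_within_sampling_noise(
        self, five_residue
    ):
        rot = np.linalg.qr(np.random.default_rng(3).normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        before = burial(five_residue, 2)
        after = burial(five_residue.rotated(rot), 2)
        assert after[0] == pytest.approx(before[0], abs=0.05)
        assert after[1] == pytest.approx(before[1], abs=0.05)


class TestSasa:
    def test_isolated_sphere_area_exact(self):
        sasa = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]))
        assert sasa[0] == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=1e-9)

    def test_symmetric_pair_equal_areas_within_sampling_noise(self):
        # the fixed point set is not mirror-symmetric, so the two occluded
        # caps are sampled slightly differently
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        sasa = shrake_rupley_sasa(coords, np.array([1.7, 1.7]))
        assert sasa[0] == pytest.approx(sasa[1], rel=0.02)
        assert sasa[0] < 4 * math.pi * 3.1**2


class TestAprSummary:
    @pytest.fixture
    def buried_and_exposed(self, tmp_path):
        # residue 1 enclosed by a shell (residues 10+), residue 2 far away
        atoms = shell_atoms(1, 10) + [(2, "ALA", "CB", "C", 50.0, 50.0, 50.0)]
        return model_from_atoms(atoms, tmp_path)

    def test_means_over_span(self, buried_and_exposed):
        model = buried_and_exposed
        metrics = residue_metrics(model, dg={1: -1.5})
        (row,) = apr_structural_summary(
            model, [APR("toy", 1, 5, region_score=90.0)], metrics=metrics
        )
        assert row["mean_sidechain_burial"] == pytest.approx(
            np.nanmean(
                [metrics[1].sidechain_burial, metrics[2].sidechain_burial]
            ),
        )
        assert 0.4 < row["mean_sidechain_burial"] < 0.6  # mean of ~1 and ~0
        assert row["mean_dg"] == pytest.approx(-1.5)
        assert row["n_dg"] == 1
        assert row["n_unresolved"] == 3  # residues 3-5 absent from the model

    def test_dg_absent_gives_na_but_burial_computed(self, buried_and_exposed):
        (row,) = apr_structural_summary(
            buried_and_exposed, [APR("toy", 1, 5, region_score=9.0)]
        )
        assert math.isnan(row["mean_dg"])
        assert not math.isnan(row["mean_sidechain_burial"])

    def test_all_glycine_apr_sidechain_na(self, tmp_path):
        atoms = []
        for res in range(1, 6):
            atoms.append((res, "GLY", "N", "N", 2.0 * res, 0.0, 0.0))
            atoms.append((res, "GLY", "CA", "C", 2.0 * res, 1.0, 0.0))
        model = model_from_atoms(atoms, tmp_path)
        (row,) = apr_structural_summary(model, [APR("toy", 1, 5, region_score=9.0)])
        assert math.isnan(row["mean_sidechain_burial"])
        assert not math.isnan(row["mean_mainchain_burial"])
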