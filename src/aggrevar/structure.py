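"""Structural metrics from atomic coordinates: minimal all-atom
variant-to-APR distances and side/mainchain burial, plus pass-through of
externally supplied per-residue stability contributions (dG, kcal/mol,
negative = stabilizing).

Burial is 1 - (observed accessible surface area / reference ASA), computed
separately over sidechain and mainchain atoms with a deterministic
Shrake-Rupley sphere sampler (960-point golden-spiral sphere, 1.4 A probe,
standard van der Waals radii). The reference ASA of a residue is the ASA of
the same atom set evaluated in isolation with the same sampler, so an
isolated residue has burial ~0 and a fully enclosed one ~1 by construction,
for any residue chemistry. This reproduces the quantity class of a
force-field-internal burial, not any particular program's numbers.

Residue numbering in the structure must match sequence numbering
identically; unresolved residues yield NA metrics, never re-alignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .aprs import APR
from .datamodel import ValidationError

#: Mainchain (backbone) atom names; everything else is sidechain.
MAINCHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Van der Waals radii (Angstrom) by element.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90,
}
DEFAULT_VDW = 1.70

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960


@dataclass
class StructureModel:
    """One selected chain as flat per-atom arrays.

    ``residue_index`` is aligned to the 1-based sequence numbering of the
    corresponding :class:`~aggrevar.datamodel.ProteinRecord`.
    """

    protein_id: str
    chain_id: str
    residue_index: np.ndarray  # (n_atoms,) int
    atom_names: list[str]
    mainchain: np.ndarray  # (n_atoms,) bool
    coords: np.ndarray  # (n_atoms, 3) float
    radii: np.ndarray  # (n_atoms,) float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite atom coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residues(self) -> np.ndarray:
        return np.unique(self.residue_index)

    def atom_mask(self, residue_index: int) -> np.ndarray:
        return self.residue_index == residue_index

    def translated(self, shift: Sequence[float]) -> "StructureModel":
        return StructureModel(
            self.protein_id, self.chain_id, self.residue_index.copy(),
            list(self.atom_names), self.mainchain.copy(),
            self.coords + np.asarray(shift, dtype=float), self.radii.copy(),
        )

    def rotated(self, rotation: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.protein_id, self.chain_id, self.residue_index.copy(),
            list(self.atom_names), self.mainchain.copy(),
            self.coords @ np.asarray(rotation, dtype=float).T, self.radii.copy(),
        )


def load_structure(
    path: str, protein_id: str, chain: str = "A"
) -> StructureModel:
    """Load one chain of a PDB file (first model; heteroatoms skipped)."""
    parser = PDBParser(QUIET=True)
    model = parser.get_structure(protein_id, path)[0]
    if chain not in [c.id for c in model]:
        raise ValidationError(f"chain {chain!r} not found in {path}")
    residue_index, names, mainchain, coords, radii = [], [], [], [], []
    for res in model[chain]:
        if res.id[0] != " ":  # hetero/water
            continue
        for atom in res:
            residue_index.append(res.id[1])
            names.append(atom.get_name())
            mainchain.append(atom.get_name() in MAINCHAIN_ATOMS)
            coords.append(atom.get_coord())
            el = (atom.element or "").upper()
            radii.append(VDW_RADII.get(el, DEFAULT_VDW))
    if not names:
        raise ValidationError(f"no standard residues on chain {chain} of {path}")
    return StructureModel(
        protein_id=protein_id,
        chain_id=chain,
        residue_index=np.array(residue_index, dtype=int),
        atom_names=names,
        mainchain=np.array(mainchain, dtype=bool),
        coords=np.array(coords, dtype=float),
        radii=np.array(radii, dtype=float),
    )


def min_distance_variant_apr(
    structure: StructureModel, variant_position: int, apr: APR
) -> float:
    """Minimal Euclidean distance (Angstrom) over all atom pairs between the
    variant residue and any residue of the APR; 0 when the variant lies
    inside the APR span. NaN (with a warning) when either side is
    unresolved in the structure."""
    if apr.contains(variant_position):
        return 0.0
    vmask = structure.atom_mask(variant_position)
    amask = (structure.residue_index >= apr.start) & (
        structure.residue_index <= apr.end
    )
    if not vmask.any() or not amask.any():
        warnings.warn(
            f"unresolved residue(s) for distance {variant_position} -> "
            f"APR {apr.start}-{apr.end}; returning NA"
        )
        return math.nan
    diff = structure.coords[vmask][:, None, :] - structure.coords[amask][None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def sphere_points(n: int = N_SPHERE_POINTS) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    points: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    ``points`` lets callers pin the sampling orientation (e.g. to rotate it
    together with the structure); by default the fixed golden-spiral set is
    used.
    """
    if points is None:
        points = sphere_points()
    n_atoms = len(radii)
    expanded = radii + probe
    tree = cKDTree(coords)
    out = np.zeros(n_atoms)
    max_reach = expanded.max()
    for i in range(n_atoms):
        r = expanded[i]
        surface = coords[i] + r * points
        neighbors = tree.query_ball_point(coords[i], r + max_reach)
        neighbors = [j for j in neighbors if j != i]
        if neighbors:
            d = np.linalg.norm(
                surface[:, None, :] - coords[neighbors][None, :, :], axis=2
            )
            accessible = np.all(d >= expanded[neighbors][None, :], axis=1)
        else:
            accessible = np.ones(len(points), dtype=bool)
        out[i] = accessible.mean() * 4.0 * math.pi * r * r
    return out


def _burial_from_sasa(
    structure: StructureModel,
    residue_index: int,
    sasa: np.ndarray,
    points: np.ndarray | None,
) -> tuple[float, float]:
    mask = structure.atom_mask(residue_index)
    if not mask.any():
        raise ValidationError(f"residue {residue_index} unresolved in structure")
    iso = shrake_rupley_sasa(
        structure.coords[mask], structure.radii[mask], points=points
    )
    ref = np.zeros(structure.n_atoms)
    ref[mask] = iso  # isolated-residue reference, aligned to atom indexing

    result = []
    for part_mask in (mask & ~structure.mainchain, mask & structure.mainchain):
        ref_area = ref[part_mask].sum()
        if not part_mask.any() or ref_area <= 0:
            result.append(math.nan)
            continue
        b = 1.0 - sasa[part_mask].sum() / ref_area
        result.append(float(np.clip(b, 0.0, 1.0)))
    return result[0], result[1]


def burial(
    structure: StructureModel,
    residue_index: int,
    points: np.ndarray | None = None,
) -> tuple[float, float]:
    """(sidechain_burial, mainchain_burial) of one residue, each in [0, 1].

    The reference ASA is the residue's own atom set evaluated without the
    rest of the structure, using the same sampler. Residues without
    sidechain atoms (glycine) get NaN for the sidechain component."""
    sasa = shrake_rupley_sasa(structure.coords, structure.radii, points=points)
    return _burial_from_sasa(structure, residue_index, sasa, points)


@dataclass(frozen=True)
class ResidueStructMetrics:
    residue_index: int
    sidechain_burial: float  # NaN when no sidechain atoms
    mainchain_burial: float
    dg_contribution: float  # NaN when not supplied


def residue_metrics(
    structure: StructureModel,
    dg: Mapping[int, float] | None = None,
    points: np.ndarray | None = None,
) -> dict[int, ResidueStructMetrics]:
    """Burial and dG pass-through for every resolved residue."""
    sasa = shrake_rupley_sasa(structure.coords, structure.radii, points=points)
    out = {}
    for idx in structure.residues:
        side, main = _burial_from_sasa(structure, int(idx), sasa, points)
        out[int(idx)] = ResidueStructMetrics(
            residue_index=int(idx),
            sidechain_burial=side,
            mainchain_burial=main,
            dg_contribution=(dg or {}).get(int(idx), math.nan),
        )
    return out


def _nanmean_with_count(values: list[float]) -> tuple[float, int]:
    arr = np.asarray(values, dtype=float)
    ok = ~np.isnan(arr)
    return (float(arr[ok].mean()) if ok.any() else math.nan), int(ok.sum())


def apr_structural_summary(
    structure: StructureModel,
    aprs: Sequence[APR],
    metrics: Mapping[int, ResidueStructMetrics] | None = None,
    dg: Mapping[int, float] | None = None,
) -> list[dict]:
    """Per-APR mean sidechain/mainchain burial and mean dG contribution.

    NA components are skipped with the contributing residue count reported.
    """
    if metrics is None:
        metrics = residue_metrics(structure, dg=dg)
    out = []
    for apr in aprs:
        span = [metrics[i] for i in range(apr.start, apr.end + 1) if i in metrics]
        side, n_side = _nanmean_with_count([m.sidechain_burial for m in span])
        main, n_main = _nanmean_with_count([m.mainchain_burial for m in span])
        dgm, n_dg = _nanmean_with_count([m.dg_contribution for m in span])
        out.append(
            {
                "protein_id": apr.protein_id,
                "start": apr.start,
                "end": apr.end,
                "mean_sidechain_burial": side,
                "n_sidechain": n_side,
                "mean_mainchain_burial": main,
                "n_mainchain": n_main,
                "mean_dg": dgm,
                "n_dg": n_dg,
                "n_unresolved": apr.length - len(span),
            }
        )
    return out
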