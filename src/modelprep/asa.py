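"""Solvent-accessible surface area by the spherical-mesh (Shrake-Rupley) method.

Each atom's solvent-expanded sphere (van der Waals radius + probe radius)
is sampled with an approximately uniform point mesh; a mesh point is
accessible when it lies strictly outside every other atom's expanded
sphere.  The per-atom area is the accessible fraction of the full sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ModelPrepError
from .structure import Structure

# Van der Waals radii (Å).  The probe default of 1.4 Å is a water molecule.
DEFAULT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "H": 1.20, "P": 1.80,
}
OTHER_RADIUS = 1.80
DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


def sphere_mesh(n: int) -> np.ndarray:
    """`n` near-uniform unit vectors from the golden-section spiral."""
    if n < 4:
        raise ModelPrepError("mesh needs at least 4 points")
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


@dataclass
class AsaResult:
    """Per-atom accessible areas plus the parameters that produced them."""

    per_atom: dict[int, float]  # id(Atom) -> Å²
    probe_radius: float
    mesh_points: int
    radii_table: dict[str, float] = field(default_factory=dict)

    def area_of(self, atom) -> float:
        # atoms built after the ASA pass (e.g. reconstructed CB) get 0 Å²
        return self.per_atom.get(id(atom), 0.0)


def atom_radius(element: str, radii: dict[str, float],
                atom_name: str = "?") -> float:
    r = radii.get(element.upper())
    if r is None:
        r = radii.get("*", OTHER_RADIUS)
    if r is None:
        raise ModelPrepError(f"no van der Waals radius for atom {atom_name} "
                             f"(element {element})")
    return r


def compute_asa(structure: Structure, probe: float = DEFAULT_PROBE,
                n: int = DEFAULT_POINTS,
                radii: dict[str, float] | None = None) -> AsaResult:
    """Accessible surface area of every atom in the structure.

    All atoms present (including retained hetero compounds) both receive an
    area and occlude their neighbours.  A point exactly on another expanded
    sphere counts as accessible, so degenerate contacts are deterministic.
    """
    radii = dict(DEFAULT_RADII if radii is None else radii)
    atoms = list(structure.atoms())
    if not atoms:
        raise ModelPrepError("structure has no atoms")
    coords = np.array([a.pos for a in atoms], dtype=float)
    expanded = np.array([atom_radius(a.element, radii, a.name) + probe
                         for a in atoms])
    mesh = sphere_mesh(n)
    tree = cKDTree(coords)
    max_r = expanded.max()
    per_atom: dict[int, float] = {}
    for i, atom in enumerate(atoms):
        r_i = expanded[i]
        neighbours = [j for j in tree.query_ball_point(coords[i], r_i + max_r)
                      if j != i]
        points = coords[i] + r_i * mesh
        accessible = np.ones(n, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", points - coords[j], points - coords[j])
            accessible &= d2 >= expanded[j] ** 2  # on-surface counts accessible
        area = 4.0 * np.pi * r_i ** 2 * accessible.sum() / n
        per_atom[id(atom)] = float(area)
    return AsaResult(per_atom=per_atom, probe_radius=probe, mesh_points=n,
                     radii_table=radii)
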