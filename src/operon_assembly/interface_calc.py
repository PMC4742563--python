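"""Solvent-accessible surface areas and pairwise interface-area matrices.

SASA is estimated with a Shrake–Rupley-style scheme: a deterministic
spherical Fibonacci point set is placed on each atom's solvent-expanded
sphere (radius + probe), and the accessible fraction is the fraction of test
points not inside any other atom's expanded sphere.  The point set is fixed,
so results are exactly reproducible.

The interface area between two chain groups is half the solvent-accessible
surface buried on association,

    area(A, B) = (SASA(A) + SASA(B) - SASA(A ∪ B)) / 2 ,

the standard buried-surface convention.  The chain-by-chain
:class:`InterfaceMatrix` evaluates every unordered chain pair in the context
of the two isolated chains, so entries do not depend on the rest of the
complex; it is the sole input to assembly-pathway prediction, which depends
only on the ranking of areas.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .structure_model import Atom, ComplexModel

__all__ = [
    "SasaResult",
    "InterfaceMatrix",
    "fibonacci_sphere",
    "compute_sasa",
    "interface_area",
    "build_interface_matrix",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_SPHERE_POINTS",
]

DEFAULT_PROBE_RADIUS: float = 1.4
DEFAULT_SPHERE_POINTS: int = 960


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and total solvent-accessible surface area in A^2."""

    atom_areas: np.ndarray
    probe_radius: float
    sphere_points: int

    @property
    def total(self) -> float:
        return float(self.atom_areas.sum())


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere (deterministic spiral)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _atom_arrays(atoms: list[Atom]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([a.position for a in atoms], dtype=float)
    rad = np.array([a.radius for a in atoms], dtype=float)
    return pos, rad


def compute_sasa(
    atoms: list[Atom],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> SasaResult:
    """Shrake–Rupley SASA over a list of atoms.

    Parameters
    ----------
    atoms
        Atoms with positions and radii in Angstrom.
    probe_radius
        Solvent probe radius in Angstrom (water: 1.4).
    sphere_points
        Test points per atom; >= 92.  Accuracy improves roughly as 1/n.
    """
    if len(atoms) == 0:
        raise ValueError("need at least one atom")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if sphere_points < 92:
        raise ValueError("sphere_points must be >= 92")

    pos, rad = _atom_arrays(atoms)
    n = len(atoms)
    if n > 1:
        d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if np.any(d2 < 1e-12):
            warnings.warn("coincident atoms at identical coordinates", stacklevel=2)

    expanded = rad + probe_radius
    unit = fibonacci_sphere(sphere_points)
    areas = np.empty(n, dtype=float)

    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    max_exp = expanded.max()
    for i in range(n):
        # neighbours whose expanded sphere could cover points of sphere i
        nbrs = tree.query_ball_point(pos[i], expanded[i] + max_exp)
        nbrs = [j for j in nbrs if j != i]
        full = 4.0 * np.pi * expanded[i] ** 2
        if not nbrs:
            areas[i] = full
            continue
        pts = pos[i] + expanded[i] * unit
        buried = np.zeros(sphere_points, dtype=bool)
        for j in nbrs:
            d2j = np.sum((pts - pos[j]) ** 2, axis=1)
            buried |= d2j < expanded[j] ** 2
        areas[i] = full * (1.0 - buried.mean())
    return SasaResult(atom_areas=areas, probe_radius=probe_radius, sphere_points=sphere_points)


def _group_atoms(model: ComplexModel, chain_ids: set[str] | frozenset[str]) -> list[Atom]:
    atoms: list[Atom] = []
    for cid in sorted(chain_ids):
        atoms.extend(model.chain(cid).atoms)
    return atoms


def interface_area(
    model: ComplexModel,
    group_a: set[str] | frozenset[str],
    group_b: set[str] | frozenset[str],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> float:
    """Buried-surface interface area (A^2) between two disjoint chain groups.

    Half the ΔSASA of the union versus the isolated groups; symmetric and
    non-negative up to numerical tolerance (clamped at 0).
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("both chain groups must be non-empty")
    if group_a & group_b:
        raise ValueError(f"chain groups overlap: {sorted(group_a & group_b)}")
    atoms_a = _group_atoms(model, group_a)
    atoms_b = _group_atoms(model, group_b)
    sasa_a = compute_sasa(atoms_a, probe_radius, sphere_points).total
    sasa_b = compute_sasa(atoms_b, probe_radius, sphere_points).total
    sasa_ab = compute_sasa(atoms_a + atoms_b, probe_radius, sphere_points).total
    return max(0.0, (sasa_a + sasa_b - sasa_ab) / 2.0)


@dataclass
class InterfaceMatrix:
    """Symmetric chain-by-chain interface-area table in A^2, zero diagonal."""

    chain_ids: list[str]
    area: np.ndarray

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        n = len(self.chain_ids)
        if self.area.shape != (n, n):
            raise ValueError("area matrix shape does not match chain ids")
        if not np.allclose(self.area, self.area.T):
            raise ValueError("interface matrix must be symmetric")
        if np.any(np.diag(self.area) != 0):
            raise ValueError("interface matrix diagonal must be zero")
        if np.any(self.area < 0):
            raise ValueError("interface areas must be non-negative")
        self._index = {c: i for i, c in enumerate(self.chain_ids)}

    def get(self, chain_a: str, chain_b: str) -> float:
        try:
            ia, ib = self._index[chain_a], self._index[chain_b]
        except KeyError as exc:
            raise KeyError(f"chain {exc.args[0]!r} not in interface matrix") from exc
        return float(self.area[ia, ib])

    @classmethod
    def from_pairs(
        cls, chain_ids: list[str], pairs: dict[tuple[str, str], float]
    ) -> "InterfaceMatrix":
        n = len(chain_ids)
        idx = {c: i for i, c in enumerate(chain_ids)}
        area = np.zeros((n, n))
        for (a, b), v in pairs.items():
            area[idx[a], idx[b]] = v
            area[idx[b], idx[a]] = v
        return cls(chain_ids=list(chain_ids), area=area)

    def to_tsv(self, path: str) -> None:
        """Write as three-column TSV: chain_a, chain_b, area_A2 (upper triangle)."""
        with open(path, "w") as fh:
            fh.write("chain_a\tchain_b\tarea_A2\n")
            for i, a in enumerate(self.chain_ids):
                for j in range(i + 1, len(self.chain_ids)):
                    fh.write(f"{a}\t{self.chain_ids[j]}\t{float(self.area[i, j])!r}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "InterfaceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"chain_a": str, "chain_b": str})
        chain_ids = sorted(set(df["chain_a"]) | set(df["chain_b"]))
        pairs = {
            (row.chain_a, row.chain_b): float(row.area_A2)
            for row in df.itertuples(index=False)
        }
        return cls.from_pairs(chain_ids, pairs)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"chain_ids": self.chain_ids, "area": self.area.tolist()},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "InterfaceMatrix":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(chain_ids=obj["chain_ids"], area=np.array(obj["area"]))


def build_interface_matrix(
    model: ComplexModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> InterfaceMatrix:
    """Interface areas for all unordered chain pairs of a complex.

    Each pair is computed in the context of the two isolated chains, so
    entries are independent of the remaining chains.
    """
    ids = model.chain_ids
    if len(ids) < 2:
        raise ValueError("need at least two chains")
    pairs: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pairs[(a, b)] = interface_area(model, {a}, {b}, probe_radius, sphere_points)
    return InterfaceMatrix.from_pairs(sorted(ids), pairs)
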