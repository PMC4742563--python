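"""Protein complex structure model: reading, entity assignment, inclusion filters.

A :class:`ComplexModel` is the quaternary structure consumed by the assembly
predictor: an ordered list of polymer chains, each carrying residues and atoms
with coordinates and element-based van der Waals radii, plus an assignment of
chains to *entities* (distinct polypeptide species — one entity may appear as
several identical chain copies).

Entities are assigned by single-linkage clustering over pairwise global
sequence identity, which substitutes for a database mapping of chains to
reference sequences and keeps the operation self-contained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Chain",
    "ComplexModel",
    "FilterConfig",
    "FilterDecision",
    "StructureFormatError",
    "EmptyStructureError",
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "read_structure",
    "assign_entities",
    "pairwise_identity",
    "passes_filters",
]


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a structure file contains no polymer chains."""


#: Van der Waals radii in Angstrom, by element symbol (upper case).
#: Values follow the commonly used Bondi set for the elements that occur in
#: protein structures.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}

#: Fallback radius for elements missing from :data:`VDW_RADII`.
DEFAULT_RADIUS: float = 1.70


@dataclass(frozen=True)
class Atom:
    """A single atom: position in Angstrom, radius in Angstrom, provenance."""

    position: tuple[float, float, float]
    radius: float
    chain_id: str
    residue_index: int
    element: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"atom radius must be positive, got {self.radius}")


@dataclass
class Chain:
    """One polymer chain: ordered residue names plus its atoms."""

    chain_id: str
    residues: list[str]
    atoms: list[Atom]
    sequence: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"chain {self.chain_id!r} has no residues")

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass
class ComplexModel:
    """A protein complex: ordered chains and a chain → entity assignment."""

    complex_id: str
    chains: list[Chain]
    entity_of_chain: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in complex {self.complex_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in complex {self.complex_id!r}")

    @property
    def n_entities(self) -> int:
        return len(set(self.entity_of_chain.values()))

    def chains_of_entity(self, entity_id: str) -> list[str]:
        return [c for c, e in self.entity_of_chain.items() if e == entity_id]


@dataclass(frozen=True)
class FilterConfig:
    """Dataset inclusion thresholds.

    min_residues
        Minimum chain length (inclusive) for a chain to count, in residues.
    max_subunits
        Complexes with more chains than this are excluded; assembly
        prediction has not been validated for very large assemblies.
    redundancy_identity
        Pair-level redundancy threshold (fraction sequence identity).
    entity_grouping_identity
        Chains at or above this pairwise identity are copies of one entity.
    physical_interface_min
        Interface area in A^2 above which a subunit pair is considered to
        interact physically.
    """

    min_residues: int = 30
    max_subunits: int = 24
    redundancy_identity: float = 0.50
    entity_grouping_identity: float = 0.95
    physical_interface_min: float = 200.0

    def __post_init__(self) -> None:
        if self.min_residues <= 0 or self.max_subunits <= 0:
            raise ValueError("counts must be positive")
        for name in ("redundancy_identity", "entity_grouping_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str | None = None


def _element_radius(element: str, element_radii: dict[str, float] | None) -> float:
    el = element.strip().upper()
    if element_radii and el in element_radii:
        return element_radii[el]
    return VDW_RADII.get(el, DEFAULT_RADIUS)


def read_structure(
    path: str,
    fmt: str | None = None,
    element_radii: dict[str, float] | None = None,
) -> ComplexModel:
    """Read a PDB or mmCIF file into a :class:`ComplexModel`.

    Only the first model of multi-model files is used.  Non-polymer content
    (waters, ligands, ions) is excluded; a chain is kept when it contains at
    least one amino-acid residue.  Atom radii come from :data:`VDW_RADII`,
    optionally overridden per element through ``element_radii`` (this is how
    bead fixtures, whose beads are not real atoms, supply their radius).

    Parameters
    ----------
    path
        Structure file path.
    fmt
        ``"pdb"`` or ``"mmcif"``; inferred from the file extension if omitted.
    element_radii
        Optional element → radius (A) overrides.
    """
    import gemmi

    if fmt is None:
        lower = str(path).lower()
        fmt = "mmcif" if lower.endswith((".cif", ".mmcif", ".cif.gz")) else "pdb"
    if fmt not in ("pdb", "mmcif"):
        raise ValueError(f"unknown structure format {fmt!r}")

    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[str] = []
        atoms: list[Atom] = []
        seq_letters: list[str] = []
        res_index = 0
        for res in gchain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and (info.is_water() or not info.is_amino_acid()):
                continue
            if info is None and len(res) == 1 and res.name in ("HOH", "WAT"):
                continue
            residues.append(res.name)
            one = info.one_letter_code.upper() if info is not None else "X"
            seq_letters.append(one if one.isalpha() else "X")
            for at in res:
                if at.element.name.upper() == "H":
                    continue
                atoms.append(
                    Atom(
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        radius=_element_radius(at.element.name, element_radii),
                        chain_id=gchain.name,
                        residue_index=res_index,
                        element=at.element.name.upper(),
                        name=at.name,
                    )
                )
            res_index += 1
        if residues:
            chains.append(
                Chain(
                    chain_id=gchain.name,
                    residues=residues,
                    atoms=atoms,
                    sequence="".join(seq_letters),
                )
            )

    if not chains:
        raise EmptyStructureError(f"{path}: no polymer (protein) chains found")
    complex_id = st.name or str(path)
    return ComplexModel(complex_id=complex_id, chains=chains)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity between two residue strings.

    The sequences are aligned globally with match +1, mismatch 0, gap -1;
    identity is the number of identical aligned positions divided by the
    number of alignment columns (including gap columns).  Symmetric, in
    [0, 1].
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0
    return counts.identities / columns


def assign_entities(
    model: ComplexModel, grouping_identity: float = 0.95
) -> ComplexModel:
    """Partition chains into entities by single-linkage sequence identity.

    Two chains belong to the same entity when they are connected through a
    chain of pairwise identities >= ``grouping_identity``.  Entity ids are
    ``E1``, ``E2``, ... numbered by the lexicographically smallest chain id
    in each group, so the result does not depend on chain order.
    """
    ids = sorted(c.chain_id for c in model.chains)
    seq = {c.chain_id: c.sequence or "".join(c.residues) for c in model.chains}
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if pairwise_identity(seq[a], seq[b]) >= grouping_identity:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for cid in ids:
        groups.setdefault(find(cid), []).append(cid)
    entity_of_chain: dict[str, str] = {}
    for k, root in enumerate(sorted(groups), start=1):
        for cid in groups[root]:
            entity_of_chain[cid] = f"E{k}"
    return replace(model, entity_of_chain=entity_of_chain)


def passes_filters(model: ComplexModel, cfg: FilterConfig | None = None) -> FilterDecision:
    """Apply dataset inclusion filters to a complex.

    Chains shorter than ``cfg.min_residues`` are removed first; the complex
    is dropped when more than ``cfg.max_subunits`` chains remain or when the
    remaining chains cover fewer than two entities (not heteromeric).
    Requires entities to have been assigned.
    """
    cfg = cfg or FilterConfig()
    if not model.entity_of_chain:
        raise ValueError("entities must be assigned before filtering")
    kept = [c for c in model.chains if c.n_residues >= cfg.min_residues]
    if len(kept) > cfg.max_subunits:
        return FilterDecision(keep=False, reason="too many subunits")
    entities = {model.entity_of_chain[c.chain_id] for c in kept}
    if len(entities) < 2:
        return FilterDecision(keep=False, reason="not heteromeric")
    return FilterDecision(keep=True)
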