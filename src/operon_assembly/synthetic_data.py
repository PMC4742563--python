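"""Synthetic fixtures: bead-model complexes and operon/pair/abundance cohorts.

Two generators make every pipeline stage testable without any downloads:

* **Bead complexes** — each chain is a single sphere (optionally a small
  rigid bead cluster for reader tests) placed so that planned chain pairs
  overlap their solvent-expanded spheres at planned centre distances while
  all unplanned pairs stay clear.  Pairwise buried areas then have a
  closed-form two-sphere spherical-cap value, giving an analytic oracle for
  the numerical SASA/interface code.

* **Cohorts** — operon, pair and abundance tables with the statistical
  structure the analysis assumes: tunable co-operonic fraction, adjacency
  and distance distributions, interaction probability by adjacency class,
  log-normal interface areas and abundances, and a tunable probability that
  gene order matches predicted assembly order.  Each pair is backed by a
  small interface matrix whose greedy pathway realizes the drawn order, so
  recovery runs the real predictor rather than reading labels.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interface_calc import InterfaceMatrix, fibonacci_sphere
from .operon_map import GeneLocus, Operon
from .structure_model import Atom, Chain, ComplexModel

__all__ = [
    "BeadComplexSpec",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "InfeasibleGeometryError",
    "two_sphere_buried_area",
    "distance_for_area",
    "make_bead_complex",
    "write_bead_structure",
    "make_synthetic_cohort",
    "write_cohort",
]

_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


class InfeasibleGeometryError(ValueError):
    """Planned contacts cannot be embedded without an unplanned contact."""


def two_sphere_buried_area(
    r_a: float, r_b: float, probe: float, distance: float
) -> float:
    """Closed-form buried-surface area for two spheres (half ΔSASA), A^2.

    Spheres of radii ``r_a`` and ``r_b`` with solvent probe ``probe`` bury
    one spherical cap each when their expanded spheres (radius + probe)
    intersect; the interface area is half the total buried cap area.
    Returns 0 when the expanded spheres do not overlap.
    """
    ra, rb = r_a + probe, r_b + probe
    d = distance
    if d >= ra + rb:
        return 0.0
    if d <= abs(ra - rb):
        # full containment: the smaller expanded sphere is entirely buried
        small = min(ra, rb)
        return 0.5 * 4.0 * math.pi * small**2
    h_a = ra - (d * d + ra * ra - rb * rb) / (2.0 * d)
    h_b = rb - (d * d + rb * rb - ra * ra) / (2.0 * d)
    return 0.5 * (2.0 * math.pi * ra * h_a + 2.0 * math.pi * rb * h_b)


def distance_for_area(area: float, radius: float, probe: float) -> float:
    """Centre distance at which two equal beads bury ``area`` A^2 (half ΔSASA).

    Inverts :func:`two_sphere_buried_area` for the equal-radius case, where
    area = 2·pi·R·h with R = radius + probe and h = R − d/2.
    """
    R = radius + probe
    h = area / (2.0 * math.pi * R)
    if h <= 0 or h > R:
        raise ValueError(f"area {area} not realizable for radius {radius}, probe {probe}")
    return 2.0 * (R - h)


@dataclass(frozen=True)
class BeadComplexSpec:
    """Plan for a bead complex: chains, entities, and planned contacts.

    chains
        (chain_id, entity_id) in order.
    bead_radius
        Radius of every bead, A.
    contacts
        (chain_a, chain_b, centre distance in A); distances below
        2 (radius + probe) create a contact of known area.
    probe_radius
        Probe used for clearance checks and ground-truth areas.
    beads_per_chain
        Extra beads (reader tests only) laid away from all contacts; the
        analytic per-pair areas remain exact only for single-bead chains.
    """

    chains: tuple[tuple[str, str], ...]
    bead_radius: float = 3.0
    contacts: tuple[tuple[str, str, float], ...] = ()
    probe_radius: float = 1.4
    beads_per_chain: int = 1
    clearance_margin: float = 1.0


def _component_layout(
    spec: BeadComplexSpec,
) -> dict[str, np.ndarray]:
    """Embed the planned-contact graph in 3D; raise if infeasible."""
    chain_ids = [c for c, _ in spec.chains]
    planned = {}
    for a, b, d in spec.contacts:
        if a not in chain_ids or b not in chain_ids:
            raise ValueError(f"contact references unknown chain ({a}, {b})")
        if d < 0:
            raise ValueError("contact distances must be >= 0")
        planned[frozenset((a, b))] = float(d)
    adj: dict[str, list[str]] = {c: [] for c in chain_ids}
    for key in planned:
        a, b = sorted(key)
        adj[a].append(b)
        adj[b].append(a)

    clearance = 2.0 * (spec.bead_radius + spec.probe_radius) + spec.clearance_margin
    directions = fibonacci_sphere(64)
    pos: dict[str, np.ndarray] = {}
    offset = 0.0
    span = max([d for d in planned.values()] + [clearance]) * (len(chain_ids) + 1)

    for root in chain_ids:
        if root in pos:
            continue
        pos[root] = np.array([offset, 0.0, 0.0])
        queue = [root]
        while queue:
            parent = queue.pop(0)
            for child in sorted(adj[parent]):
                if child in pos:
                    continue
                d = planned[frozenset((parent, child))]
                placed_here = None
                for u in directions:
                    cand = pos[parent] + d * u
                    ok = True
                    for other, q in pos.items():
                        if other == parent:
                            continue
                        dist = float(np.linalg.norm(cand - q))
                        key = frozenset((child, other))
                        if key in planned:
                            if abs(dist - planned[key]) > 1e-6:
                                ok = False
                                break
                        elif dist < clearance:
                            ok = False
                            break
                    if ok:
                        placed_here = cand
                        break
                if placed_here is None:
                    offender = next(
                        o for o in pos if o != parent
                    )
                    raise InfeasibleGeometryError(
                        f"cannot place chain {child!r} at {d} A from {parent!r} "
                        f"without violating constraints involving {offender!r}"
                    )
                pos[child] = placed_here
                queue.append(child)
        offset += span

    # verify all planned (incl. non-tree) contacts land at their distance
    for key, d in planned.items():
        a, b = sorted(key)
        got = float(np.linalg.norm(pos[a] - pos[b]))
        if abs(got - d) > 1e-6:
            raise InfeasibleGeometryError(
                f"planned contact ({a}, {b}) realized at {got:.3f} A, wanted {d:.3f} A"
            )
    return pos


def make_bead_complex(
    spec: BeadComplexSpec, complex_id: str = "bead_complex"
) -> tuple[ComplexModel, dict[frozenset[str], float]]:
    """Build a bead :class:`ComplexModel` plus its ground-truth area table.

    Returns the model and a map ``frozenset({chain_a, chain_b})`` → buried
    area in A^2 from the closed-form cap formula (0 for unplanned pairs).
    """
    if len(spec.chains) < 1:
        raise ValueError("need at least one chain")
    if spec.beads_per_chain < 1:
        raise ValueError("beads_per_chain must be >= 1")
    pos = _component_layout(spec)

    chains: list[Chain] = []
    entity_of_chain: dict[str, str] = {}
    for chain_id, entity_id in spec.chains:
        entity_of_chain[chain_id] = entity_id
        centers = [pos[chain_id]]
        if spec.beads_per_chain > 1:
            # extra beads march away from every other chain's centroid
            others = [p for c, p in pos.items() if c != chain_id]
            away = pos[chain_id] - (np.mean(others, axis=0) if others else np.zeros(3))
            norm = np.linalg.norm(away)
            away = away / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
            for k in range(1, spec.beads_per_chain):
                centers.append(pos[chain_id] + away * (2.0 * spec.bead_radius * k))
        atoms = [
            Atom(
                position=tuple(float(x) for x in c),
                radius=spec.bead_radius,
                chain_id=chain_id,
                residue_index=i,
                element="C",
                name="CA",
            )
            for i, c in enumerate(centers)
        ]
        chains.append(
            Chain(
                chain_id=chain_id,
                residues=["GLY"] * len(centers),
                atoms=atoms,
                sequence="G" * len(centers),
            )
        )

    truth: dict[frozenset[str], float] = {}
    ids = [c for c, _ in spec.chains]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = float(np.linalg.norm(pos[a] - pos[b]))
            truth[frozenset((a, b))] = two_sphere_buried_area(
                spec.bead_radius, spec.bead_radius, spec.probe_radius, d
            )
    model = ComplexModel(
        complex_id=complex_id, chains=chains, entity_of_chain=entity_of_chain
    )
    return model, truth


def write_bead_structure(model: ComplexModel, path: str) -> dict[str, str]:
    """Write a bead model as a standard-conformant PDB file.

    One ATOM record per bead (CA of a GLY residue).  PDB chain identifiers
    are single characters: chain ids are used verbatim when they already
    are, otherwise assigned from A–Z, a–z, 0–9 in model order.  Returns the
    model-chain → file-chain id map.  More than 62 chains exhaust the
    identifier alphabet and raise.
    """
    ids = model.chain_ids
    if len(ids) > len(_CHAIN_ALPHABET):
        raise ValueError(f"PDB chain ids exhausted: {len(ids)} chains > 62")
    if all(len(c) == 1 for c in ids) and len(set(ids)) == len(ids):
        mapping = {c: c for c in ids}
    else:
        mapping = {c: _CHAIN_ALPHABET[i] for i, c in enumerate(ids)}

    lines: list[str] = []
    serial = 1
    for chain in model.chains:
        file_chain = mapping[chain.chain_id]
        for res_idx, atom in enumerate(chain.atoms, start=1):
            x, y, z = atom.position
            lines.append(
                f"ATOM  {serial:>5} {'CA':^4}{'':1}{'GLY':>3} {file_chain}"
                f"{res_idx:>4}{'':1}   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {'C':>2}"
            )
            serial += 1
        lines.append(f"TER   {serial:>5}      {'GLY':>3} {file_chain}{len(chain.atoms):>4}")
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return mapping


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Tunable statistical structure of a synthetic operon/pair cohort.

    Defaults reproduce the marginal frequencies of the study conditions:
    368 of 1079 subunit pairs co-operonic, 220 of 368 adjacent, physical
    interaction in 208/220 adjacent and 77/148 non-adjacent pairs, order
    resolved (non-simultaneous) in 101/220, gene order evolutionarily
    conserved in 72 of 101 resolved adjacent pairs, and gene order matching
    assembly order with probability 57/72 when conserved and 10/29
    otherwise.  Abundances are log-normal (ppm), lower and more correlated
    within operons, and lower again for pairs whose gene order matches
    assembly order.
    """

    n_pairs: int = 1079
    p_same_operon: float = 368 / 1079
    n_operons: int = 192
    operon_length_mean_extra: float = 3.6  # length = 2 + Poisson(this)
    max_operon_length: int = 12
    p_adjacent_given_same_operon: float = 220 / 368
    nonadjacent_distance_geom_p: float = 0.5
    p_interact_given_adjacent: float = 208 / 220
    p_interact_given_nonadjacent: float = 77 / 148
    p_interact_given_diff_tu: float = 0.6
    log_area_interacting: tuple[float, float] = (6.9, 0.8)
    log_area_noninteracting: tuple[float, float] = (4.0, 0.8)
    interface_threshold: float = 200.0
    p_ordered: float = 101 / 220
    p_conserved_given_ordered: float = 72 / 101
    p_order_match_given_conserved: float = 57 / 72
    p_order_match_given_nonconserved: float = 10 / 29
    log_abundance_same_operon: float = 3.0
    log_abundance_diff_tu: float = 4.0
    log_abundance_sigma: float = 1.5
    log_abundance_match_shift: float = -0.7
    abundance_correlation_same_operon: float = 0.7
    abundance_correlation_diff_tu: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_same_operon",
            "p_adjacent_given_same_operon",
            "p_interact_given_adjacent",
            "p_interact_given_nonadjacent",
            "p_interact_given_diff_tu",
            "p_ordered",
            "p_conserved_given_ordered",
            "p_order_match_given_conserved",
            "p_order_match_given_nonconserved",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SyntheticCohort:
    """In-memory cohort: tables, per-complex matrices, and ground truth."""

    spec: SyntheticCohortSpec
    operons: list[Operon]
    operon_table: pd.DataFrame
    pair_table: pd.DataFrame
    abundance_table: pd.DataFrame
    chain_entity_table: pd.DataFrame
    matrices: dict[str, InterfaceMatrix]
    truth: pd.DataFrame


def _draw_operon_length(rng: np.random.Generator, spec: SyntheticCohortSpec) -> int:
    return int(min(2 + rng.poisson(spec.operon_length_mean_extra), spec.max_operon_length))


def _pair_matrix(
    rng: np.random.Generator,
    order_class: str,
    area: float,
) -> tuple[InterfaceMatrix, list[tuple[str, str]]]:
    """Interface matrix whose greedy pathway realizes the drawn order.

    ``order_class``: ``upstream_first`` duplicates the upstream entity so
    it homodimerizes before binding the other subunit; ``downstream_first``
    mirrors that; ``simultaneous`` is a plain heterodimer.  Returns the
    matrix and the (chain_id, entity_id) assignment, with entity EX for the
    upstream gene and EY for the downstream one.
    """
    if order_class == "simultaneous":
        chains = [("A", "EX"), ("B", "EY")]
        m = InterfaceMatrix.from_pairs(["A", "B"], {("A", "B"): area})
        return m, chains
    dimer_area = 2.0 * area + 500.0 + float(rng.uniform(0, 100))
    if order_class == "upstream_first":
        chains = [("A1", "EX"), ("A2", "EX"), ("B", "EY")]
        pairs = {("A1", "A2"): dimer_area, ("A1", "B"): area, ("A2", "B"): area}
        ids = ["A1", "A2", "B"]
    elif order_class == "downstream_first":
        chains = [("A", "EX"), ("B1", "EY"), ("B2", "EY")]
        pairs = {("B1", "B2"): dimer_area, ("A", "B1"): area, ("A", "B2"): area}
        ids = ["A", "B1", "B2"]
    else:
        raise ValueError(f"unknown order class {order_class!r}")
    return InterfaceMatrix.from_pairs(ids, pairs), chains


def make_synthetic_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort per ``spec`` (deterministic by seed)."""
    rng = np.random.default_rng(spec.seed)

    # operon pool with free position slots
    operon_lengths = [_draw_operon_length(rng, spec) for _ in range(spec.n_operons)]
    free: list[set[int]] = [set(range(1, L + 1)) for L in operon_lengths]

    gene_counter = 0

    def new_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter:05d}"

    pair_rows = []
    truth_rows = []
    matrices: dict[str, InterfaceMatrix] = {}
    chain_rows = []
    placements: list[tuple[int, int, str]] = []  # (operon index, position, gene)

    n_same = int(rng.binomial(spec.n_pairs, spec.p_same_operon))
    for k in range(spec.n_pairs):
        complex_id = f"cplx{k + 1:05d}"
        same_operon = k < n_same
        operon_idx = None
        dist = None
        if same_operon:
            placed = False
            for _attempt in range(200):
                if rng.random() < spec.p_adjacent_given_same_operon:
                    d = 1
                else:
                    d = 2 + int(rng.geometric(spec.nonadjacent_distance_geom_p)) - 1
                cands = [
                    (i, p)
                    for i, slots in enumerate(free)
                    for p in slots
                    if (p + d) in slots
                ]
                if not cands:
                    continue
                i, p = cands[int(rng.integers(len(cands)))]
                operon_idx, dist = i, d
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    "could not place a co-operonic pair; operon pool exhausted"
                )
        gene_x, gene_y = new_gene(), new_gene()  # x upstream when co-operonic
        if same_operon:
            assert operon_idx is not None and dist is not None
            free[operon_idx] -= {p, p + dist}
            placements.append((operon_idx, p, gene_x))
            placements.append((operon_idx, p + dist, gene_y))
        adjacent = same_operon and dist == 1

        if same_operon:
            p_int = (
                spec.p_interact_given_adjacent
                if adjacent
                else spec.p_interact_given_nonadjacent
            )
        else:
            p_int = spec.p_interact_given_diff_tu
        interacting = bool(rng.random() < p_int)
        mu, sg = (
            spec.log_area_interacting if interacting else spec.log_area_noninteracting
        )
        for _ in range(1000):
            area = float(rng.lognormal(mu, sg))
            if interacting and area > spec.interface_threshold:
                break
            if not interacting and area <= spec.interface_threshold:
                break
        else:  # pragma: no cover - distribution parameters always admit both
            area = spec.interface_threshold + (1.0 if interacting else -1.0)

        ordered = bool(rng.random() < spec.p_ordered)
        conserved = bool(ordered and rng.random() < spec.p_conserved_given_ordered)
        if ordered:
            p_match = (
                spec.p_order_match_given_conserved
                if conserved
                else spec.p_order_match_given_nonconserved
            )
            match = bool(rng.random() < p_match)
            order_class = "upstream_first" if match else "downstream_first"
        else:
            order_class = "simultaneous"
        matrix, chains = _pair_matrix(rng, order_class, area)
        matrices[complex_id] = matrix
        for cid, eid in chains:
            chain_rows.append(
                {"complex_id": complex_id, "chain_id": cid, "entity_id": eid}
            )

        # abundances: correlated bivariate log-normal by co-operonic class
        if same_operon:
            mu_ab = spec.log_abundance_same_operon
            corr = spec.abundance_correlation_same_operon
        else:
            mu_ab = spec.log_abundance_diff_tu
            corr = spec.abundance_correlation_diff_tu
        if order_class == "upstream_first":
            mu_ab += spec.log_abundance_match_shift
        cov = spec.log_abundance_sigma**2 * np.array([[1.0, corr], [corr, 1.0]])
        log_ab = rng.multivariate_normal([mu_ab, mu_ab], cov)
        ab_x, ab_y = float(np.exp(log_ab[0])), float(np.exp(log_ab[1]))

        # write the pair in random orientation; mapping must restore it
        flip = bool(rng.random() < 0.5) and same_operon
        row = {
            "gene_x": gene_y if flip else gene_x,
            "gene_y": gene_x if flip else gene_y,
            "complex_id": complex_id,
            "entity_x": "EY" if flip else "EX",
            "entity_y": "EX" if flip else "EY",
            "conserved_order": conserved,
            "fusion_flag": False,
        }
        pair_rows.append(row)
        truth_rows.append(
            {
                "complex_id": complex_id,
                "gene_upstream": gene_x,
                "gene_downstream": gene_y,
                "same_operon": same_operon,
                "distance": dist if same_operon else np.nan,
                "adjacent": adjacent,
                "interacting": interacting,
                "interface_area": area,
                "order_class": order_class,
                "conserved_order": conserved,
                "abundance_x": ab_x,
                "abundance_y": ab_y,
            }
        )

    # build operons: placed genes at their positions, filler genes elsewhere
    operons: list[Operon] = []
    operon_rows = []
    by_operon: dict[int, dict[int, str]] = {}
    for i, p, g in placements:
        by_operon.setdefault(i, {})[p] = g
    used = [i for i in range(spec.n_operons) if i in by_operon]
    for i in used:
        L = operon_lengths[i]
        strand = "+" if rng.random() < 0.5 else "-"
        operon_id = f"op{i + 1:04d}"
        genes = []
        base = (i + 1) * 100_000
        for pos in range(1, L + 1):
            gid = by_operon[i].get(pos) or new_gene()
            if strand == "+":
                start = base + (pos - 1) * 1000
            else:
                start = base + (L - pos) * 1000
            genes.append(
                GeneLocus(gene_id=gid, start=start, end=start + 900, strand=strand, position=pos)
            )
        operons.append(Operon(operon_id=operon_id, genes=genes, species="synthetic"))
        for g in genes:
            operon_rows.append(
                {
                    "operon_id": operon_id,
                    "gene_id": g.gene_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "species": "synthetic",
                }
            )

    abundance_rows = []
    for tr in truth_rows:
        abundance_rows.append(
            {"gene_id": tr["gene_upstream"], "abundance_ppm": tr["abundance_x"]}
        )
        abundance_rows.append(
            {"gene_id": tr["gene_downstream"], "abundance_ppm": tr["abundance_y"]}
        )

    operon_table = pd.DataFrame(operon_rows).sort_values(
        ["operon_id", "start"], kind="stable", ignore_index=True
    )
    return SyntheticCohort(
        spec=spec,
        operons=operons,
        operon_table=operon_table,
        pair_table=pd.DataFrame(pair_rows),
        abundance_table=pd.DataFrame(abundance_rows),
        chain_entity_table=pd.DataFrame(chain_rows),
        matrices=matrices,
        truth=pd.DataFrame(truth_rows),
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str) -> dict[str, str]:
    """Write cohort tables (and per-complex matrices) as TSVs under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "operons": os.path.join(out_dir, "operons.tsv"),
        "pairs": os.path.join(out_dir, "pairs.tsv"),
        "abundance": os.path.join(out_dir, "abundance.tsv"),
        "chain_entities": os.path.join(out_dir, "chain_entities.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "matrices_dir": os.path.join(out_dir, "matrices"),
    }
    cohort.operon_table.to_csv(paths["operons"], sep="\t", index=False)
    cohort.pair_table.to_csv(paths["pairs"], sep="\t", index=False)
    cohort.abundance_table.to_csv(paths["abundance"], sep="\t", index=False)
    cohort.chain_entity_table.to_csv(paths["chain_entities"], sep="\t", index=False)
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    os.makedirs(paths["matrices_dir"], exist_ok=True)
    for cid, m in cohort.matrices.items():
        m.to_tsv(os.path.join(paths["matrices_dir"], f"{cid}.tsv"))
    return paths
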