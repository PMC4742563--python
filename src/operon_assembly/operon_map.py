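"""Operon tables: 5'→3' gene ordering, gene distances, pair mapping.

An operon is an ordered list of genes transcribed onto one polycistronic
mRNA.  Genes are arranged in order of expression using locus and strand:
ascending genomic start on the + strand, descending on the − strand, with
1-based positions.  When an operon contains more than one copy of a gene,
the gene's position is that of the first copy encountered reading 5'→3'.

Gene *distance* is the difference of operon positions (1 = adjacent);
intervening genes count whether or not they encode complex subunits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

from .assembly import PairOrder

__all__ = [
    "GeneLocus",
    "Operon",
    "SubunitPair",
    "GenePairRecord",
    "read_operon_table",
    "gene_distance",
    "map_pairs_to_operons",
    "deduplicate_operons",
    "filter_redundant_pairs",
]


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    start: int
    end: int
    strand: str
    position: int  # 1-based position in the operon, 5'→3'

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id!r}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.position < 1:
            raise ValueError("operon positions are 1-based")


@dataclass
class Operon:
    """Genes of one transcriptional unit, ordered 5'→3'."""

    operon_id: str
    genes: list[GeneLocus]
    species: str = ""

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def position_of(self, gene_id: str) -> int:
        """First-copy 5'→3' position of ``gene_id`` (KeyError if absent)."""
        for g in self.genes:
            if g.gene_id == gene_id:
                return g.position
        raise KeyError(f"gene {gene_id!r} not in operon {self.operon_id!r}")

    def __contains__(self, gene_id: str) -> bool:
        return any(g.gene_id == gene_id for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SubunitPair:
    """A heteromeric subunit pair, before operon mapping."""

    gene_x: str
    gene_y: str
    complex_id: str = ""
    entity_x: str = ""
    entity_y: str = ""
    interface_area: float | None = None
    conserved_order: bool | None = None
    fusion_flag: bool = False
    abundance_x: float | None = None
    abundance_y: float | None = None


@dataclass
class GenePairRecord:
    """One subunit pair with all operon and assembly annotations.

    When co-operonic, ``gene_x`` is the upstream (5') gene and ``gene_y``
    the downstream one; entity/abundance fields and ``pair_order`` follow
    the same orientation.
    """

    gene_x: str
    gene_y: str
    same_operon: bool
    operon_id: str | None = None
    distance: int | None = None
    adjacent: bool = False
    complex_id: str = ""
    entity_x: str = ""
    entity_y: str = ""
    interface_area: float | None = None
    physically_interacting: bool | None = None
    pair_order: PairOrder | None = None
    uniting_step: int | None = None
    conserved_order: bool | None = None
    fusion_flag: bool = False
    abundance_x: float | None = None
    abundance_y: float | None = None

    def __post_init__(self) -> None:
        if self.adjacent and not self.same_operon:
            raise ValueError("adjacent pairs must be co-operonic")


_REQUIRED_COLUMNS = ("operon_id", "gene_id", "start", "end", "strand")


def read_operon_table(path: str) -> list[Operon]:
    """Read a DOOR-style tab-separated operon table.

    Columns (header required): operon_id, gene_id, start, end, strand, and
    optionally species.  Genes are grouped by operon_id and ordered 5'→3'
    by the operon's strand; positions are assigned 1..n.  Mixed strands
    within one operon draw a warning and the majority strand is used.
    Malformed rows raise with their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    rows = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            start, end = int(row["start"]), int(row["end"])
            strand = str(row["strand"]).strip()
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand {strand!r}")
            if start >= end:
                raise ValueError(f"start {start} >= end {end}")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {line_no}: {exc}") from exc
        rows.append(
            {
                "operon_id": str(row["operon_id"]),
                "gene_id": str(row["gene_id"]),
                "start": start,
                "end": end,
                "strand": strand,
                "species": str(row.get("species", "") or ""),
            }
        )

    operons: list[Operon] = []
    table = pd.DataFrame(rows)
    for operon_id, grp in table.groupby("operon_id", sort=True):
        strands = grp["strand"].value_counts()
        if len(strands) > 1:
            warnings.warn(
                f"operon {operon_id}: mixed strands, using majority", stacklevel=2
            )
        strand = strands.idxmax()
        ordered = grp.sort_values("start", ascending=(strand == "+"), kind="stable")
        genes = [
            GeneLocus(
                gene_id=r.gene_id,
                start=r.start,
                end=r.end,
                strand=r.strand,
                position=pos,
            )
            for pos, r in enumerate(ordered.itertuples(index=False), start=1)
        ]
        species = grp["species"].iloc[0]
        operons.append(Operon(operon_id=str(operon_id), genes=genes, species=species))
    return operons


def gene_distance(operon: Operon, gene_a: str, gene_b: str) -> int:
    """Positional distance between two genes (first-copy positions; 1 = adjacent)."""
    return abs(operon.position_of(gene_a) - operon.position_of(gene_b))


def deduplicate_operons(operons: Iterable[Operon]) -> list[Operon]:
    """Collapse operons with identical ordered gene-id lists.

    Identical operons from similar strains or species are redundant; the one
    with the lexicographically smallest operon_id is kept.  Idempotent.
    """
    best: dict[tuple[str, ...], Operon] = {}
    for op in operons:
        key = tuple(op.gene_ids)
        if key not in best or op.operon_id < best[key].operon_id:
            best[key] = op
    return sorted(best.values(), key=lambda op: op.operon_id)


def _flip(order: PairOrder | None) -> PairOrder | None:
    if order == PairOrder.FIRST_PRECEDES:
        return PairOrder.SECOND_PRECEDES
    if order == PairOrder.SECOND_PRECEDES:
        return PairOrder.FIRST_PRECEDES
    return order


def map_pairs_to_operons(
    pairs: Iterable[SubunitPair],
    operons: Iterable[Operon],
    interface_threshold: float = 200.0,
) -> list[GenePairRecord]:
    """Join subunit pairs to operons, producing :class:`GenePairRecord` s.

    A pair is co-operonic when one operon contains both genes; co-operonic
    pairs get distance, adjacency, and upstream/downstream orientation
    (gene_x = smaller position, with entity and abundance fields swapped to
    match).  A gene found in several operons is resolved to the first
    operon by id, with a warning.  ``physically_interacting`` is
    ``interface_area > interface_threshold`` when the area is known.
    """
    operons = sorted(operons, key=lambda op: op.operon_id)
    gene_to_operon: dict[str, Operon] = {}
    seen_multi: set[str] = set()
    for op in operons:
        for gid in op.gene_ids:
            if gid in gene_to_operon and gene_to_operon[gid] is not op:
                seen_multi.add(gid)
            else:
                gene_to_operon.setdefault(gid, op)
    if seen_multi:
        warnings.warn(
            f"{len(seen_multi)} gene(s) in multiple operons; first operon by id used",
            stacklevel=2,
        )

    records: list[GenePairRecord] = []
    for pair in pairs:
        op_x = gene_to_operon.get(pair.gene_x)
        op_y = gene_to_operon.get(pair.gene_y)
        same = op_x is not None and op_x is op_y
        interacting = (
            pair.interface_area > interface_threshold
            if pair.interface_area is not None
            else None
        )
        if not same:
            records.append(
                GenePairRecord(
                    gene_x=pair.gene_x,
                    gene_y=pair.gene_y,
                    same_operon=False,
                    complex_id=pair.complex_id,
                    entity_x=pair.entity_x,
                    entity_y=pair.entity_y,
                    interface_area=pair.interface_area,
                    physically_interacting=interacting,
                    conserved_order=pair.conserved_order,
                    fusion_flag=pair.fusion_flag,
                    abundance_x=pair.abundance_x,
                    abundance_y=pair.abundance_y,
                )
            )
            continue
        assert op_x is not None
        pos_x = op_x.position_of(pair.gene_x)
        pos_y = op_x.position_of(pair.gene_y)
        swap = pos_x > pos_y
        p = pair
        if swap:
            p = replace(
                pair,
                gene_x=pair.gene_y,
                gene_y=pair.gene_x,
                entity_x=pair.entity_y,
                entity_y=pair.entity_x,
                abundance_x=pair.abundance_y,
                abundance_y=pair.abundance_x,
            )
        dist = abs(pos_x - pos_y)
        records.append(
            GenePairRecord(
                gene_x=p.gene_x,
                gene_y=p.gene_y,
                same_operon=True,
                operon_id=op_x.operon_id,
                distance=dist,
                adjacent=dist == 1,
                complex_id=p.complex_id,
                entity_x=p.entity_x,
                entity_y=p.entity_y,
                interface_area=p.interface_area,
                physically_interacting=interacting,
                conserved_order=p.conserved_order,
                fusion_flag=p.fusion_flag,
                abundance_x=p.abundance_x,
                abundance_y=p.abundance_y,
            )
        )
    return records


def filter_redundant_pairs(
    records: list[GenePairRecord],
    sequences: dict[str, str],
    identity_threshold: float = 0.50,
) -> list[GenePairRecord]:
    """Greedy pair-level redundancy filter at a sequence-identity threshold.

    Walking records in input order, a pair is dropped when BOTH of its
    members share more than ``identity_threshold`` identity with the
    corresponding members of an already-retained pair (either member
    correspondence is tried).  A single redundant member does not trigger
    removal.  Pairs with a missing sequence cannot be assessed and are
    dropped with a warning.
    """
    from .structure_model import pairwise_identity

    cache: dict[tuple[str, str], float] = {}

    def ident(g1: str, g2: str) -> float:
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        if key not in cache:
            cache[key] = pairwise_identity(sequences[key[0]], sequences[key[1]])
        return cache[key]

    retained: list[GenePairRecord] = []
    for rec in records:
        if rec.gene_x not in sequences or rec.gene_y not in sequences:
            warnings.warn(
                f"pair ({rec.gene_x}, {rec.gene_y}): missing sequence, skipped",
                stacklevel=2,
            )
            continue
        redundant = False
        for kept in retained:
            direct = (
                ident(rec.gene_x, kept.gene_x) > identity_threshold
                and ident(rec.gene_y, kept.gene_y) > identity_threshold
            )
            crossed = (
                ident(rec.gene_x, kept.gene_y) > identity_threshold
                and ident(rec.gene_y, kept.gene_x) > identity_threshold
            )
            if direct or crossed:
                redundant = True
                break
        if not redundant:
            retained.append(rec)
    return retained
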