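"""Greedy assembly-pathway prediction from an interface-area matrix.

The model assumes a complex assembles via formation of the largest possible
interface at every step: starting from free chains, the pair of current
subcomplexes with the maximal summed cross-interface area is merged, and the
process repeats until the full complex is assembled.  The relative assembly
order of two entities is read off the pathway: at the first step that brings
chains of both entities into one subcomplex, the entity contributed by the
larger pre-merge subcomplex (by chain count) assembles first; equal sizes —
as in a plain heterodimerization — mean the two assemble simultaneously.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .interface_calc import InterfaceMatrix
from .structure_model import ComplexModel

__all__ = [
    "PairOrder",
    "PairOrderResult",
    "AssemblyStep",
    "AssemblyPathway",
    "merge_gain",
    "predict_pathway",
    "classify_pair_order",
    "pathway_to_text",
    "parse_pathway_text",
]


class PairOrder(Enum):
    FIRST_PRECEDES = "first_precedes"
    SECOND_PRECEDES = "second_precedes"
    SIMULTANEOUS = "simultaneous"


@dataclass(frozen=True)
class PairOrderResult:
    order: PairOrder
    uniting_step: int  # 1-based index of the step that unites the pair


@dataclass(frozen=True)
class AssemblyStep:
    """One binary association: ``left`` and ``right`` merge with interface ``gain``."""

    left: frozenset[str]
    right: frozenset[str]
    gain: float
    step_index: int

    def __post_init__(self) -> None:
        if self.left & self.right:
            raise ValueError("merge partners must be disjoint")

    @property
    def merged(self) -> frozenset[str]:
        return self.left | self.right


@dataclass
class AssemblyPathway:
    """Ordered binary merges from free chains to the complete complex."""

    steps: list[AssemblyStep]
    chain_ids: frozenset[str]
    disconnected: bool = False

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.chain_ids) - 1:
            raise ValueError("a pathway over n chains must have n - 1 steps")
        if self.steps and self.steps[-1].merged != self.chain_ids:
            raise ValueError("last step must assemble the full complex")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssemblyPathway):
            return NotImplemented
        if self.chain_ids != other.chain_ids or len(self.steps) != len(other.steps):
            return False
        for a, b in zip(self.steps, other.steps):
            if {a.left, a.right} != {b.left, b.right} or a.gain != b.gain:
                return False
        return True


def merge_gain(
    a: frozenset[str] | set[str], b: frozenset[str] | set[str], m: InterfaceMatrix
) -> float:
    """Total interface area formed when subcomplexes ``a`` and ``b`` associate.

    Sum of matrix entries over all cross pairs (one chain from each side);
    this is the pairwise-additive estimate of the new interface.
    """
    if set(a) & set(b):
        raise ValueError("subcomplexes must be disjoint")
    return float(sum(m.get(x, y) for x in a for y in b))


def _tie_key(a: frozenset[str], b: frozenset[str]) -> tuple[str, ...]:
    return tuple(sorted(a | b))


def predict_pathway(m: InterfaceMatrix) -> AssemblyPathway:
    """Predict the assembly pathway by greedy largest-interface merging.

    At each step the pair of current subcomplexes with maximal
    :func:`merge_gain` is merged.  Exact ties (certain in symmetric
    complexes) are broken deterministically in favour of the merge whose
    sorted chain-id tuple is lexicographically smallest.  If at some step
    the best available gain is 0 the pathway is still completed but flagged
    ``disconnected``.
    """
    ids = list(m.chain_ids)
    if len(ids) < 2:
        raise ValueError("need at least two chains")
    current: list[frozenset[str]] = [frozenset([c]) for c in ids]
    steps: list[AssemblyStep] = []
    disconnected = False
    for step_index in range(1, len(ids)):
        best: tuple[float, tuple[str, ...]] | None = None
        best_pair: tuple[int, int] | None = None
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                gain = merge_gain(current[i], current[j], m)
                key = (-gain, _tie_key(current[i], current[j]))
                if best is None or key < best:
                    best = key
                    best_pair = (i, j)
        assert best is not None and best_pair is not None
        gain = -best[0]
        if gain <= 0.0:
            disconnected = True
        i, j = best_pair
        left, right = current[i], current[j]
        steps.append(AssemblyStep(left=left, right=right, gain=gain, step_index=step_index))
        current = [c for k, c in enumerate(current) if k not in (i, j)]
        current.append(left | right)
    return AssemblyPathway(
        steps=steps, chain_ids=frozenset(ids), disconnected=disconnected
    )


def classify_pair_order(
    pathway: AssemblyPathway,
    model: ComplexModel,
    entity_x: str,
    entity_y: str,
) -> PairOrderResult:
    """Relative assembly order of two entities along a pathway.

    The uniting step is the first step whose merged subcomplex contains at
    least one chain copy of each entity.  The entity whose chains sat in the
    larger pre-merge subcomplex (by chain count) assembles first; equal
    sizes mean simultaneous assembly.
    """
    chains_x = frozenset(model.chains_of_entity(entity_x))
    chains_y = frozenset(model.chains_of_entity(entity_y))
    if not chains_x:
        raise ValueError(f"entity {entity_x!r} absent from complex {model.complex_id!r}")
    if not chains_y:
        raise ValueError(f"entity {entity_y!r} absent from complex {model.complex_id!r}")
    if entity_x == entity_y:
        raise ValueError("entities must differ")
    for step in pathway.steps:
        merged = step.merged
        if merged & chains_x and merged & chains_y:
            # At the first uniting step each entity's chains lie entirely on
            # one side (otherwise an earlier step united the pair already).
            side_x = step.left if step.left & chains_x else step.right
            side_y = step.left if step.left & chains_y else step.right
            if len(side_x) > len(side_y):
                order = PairOrder.FIRST_PRECEDES
            elif len(side_x) < len(side_y):
                order = PairOrder.SECOND_PRECEDES
            else:
                order = PairOrder.SIMULTANEOUS
            return PairOrderResult(order=order, uniting_step=step.step_index)
    raise ValueError(
        f"pathway never unites entities {entity_x!r} and {entity_y!r}"
    )  # unreachable for a complete pathway


def _format_gain(gain: float) -> str:
    if gain == int(gain):
        return str(int(gain))
    return repr(gain)


def pathway_to_text(pathway: AssemblyPathway) -> str:
    """Render a pathway as a deterministic nested-parenthesis string.

    Each merge becomes ``(left,right):gain`` with the lexicographically
    smaller side first; leaves are chain ids.  Round-trips through
    :func:`parse_pathway_text`.
    """
    text: dict[frozenset[str], str] = {
        frozenset([c]): c for c in pathway.chain_ids
    }
    rendered = ""
    for step in pathway.steps:
        lt, rt = text[step.left], text[step.right]
        if tuple(sorted(step.left)) > tuple(sorted(step.right)):
            lt, rt = rt, lt
        rendered = f"({lt},{rt}):{_format_gain(step.gain)}"
        text[step.merged] = rendered
    return rendered


_TOKEN = re.compile(r"[A-Za-z0-9_]+")


def parse_pathway_text(text: str) -> AssemblyPathway:
    """Parse the nested-parenthesis rendering back into a pathway.

    The merge tree fixes only a partial order (children before parents);
    step order is recovered by replaying the greedy rule on the tree:
    repeatedly execute the available merge with the largest gain, breaking
    exact ties toward the lexicographically smallest merged chain-id tuple.
    For pathways produced by :func:`predict_pathway` this reproduces the
    original step sequence exactly.
    """
    pos = 0
    merges: list[tuple[frozenset[str], frozenset[str], float]] = []

    def parse_node() -> frozenset[str]:
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            left = parse_node()
            assert text[pos] == ",", f"expected ',' at {pos}"
            pos += 1
            right = parse_node()
            assert text[pos] == ")", f"expected ')' at {pos}"
            pos += 1
            assert text[pos] == ":", f"expected ':' at {pos}"
            pos += 1
            m = re.match(r"-?\d+(\.\d+)?([eE][+-]?\d+)?", text[pos:])
            assert m, f"expected number at {pos}"
            gain = float(m.group(0))
            pos += m.end()
            merges.append((left, right, gain))
            return left | right
        m = _TOKEN.match(text, pos)
        assert m, f"expected chain id at {pos}"
        pos = m.end()
        return frozenset([m.group(0)])

    chains = parse_node()
    produced: set[frozenset[str]] = {frozenset([c]) for c in chains}
    remaining = list(merges)
    out: list[AssemblyStep] = []
    while remaining:
        ready = [
            mg for mg in remaining if mg[0] in produced and mg[1] in produced
        ]
        assert ready, "malformed pathway text: no executable merge"
        left, right, gain = min(ready, key=lambda mg: (-mg[2], _tie_key(mg[0], mg[1])))
        out.append(
            AssemblyStep(left=left, right=right, gain=gain, step_index=len(out) + 1)
        )
        produced.add(left | right)
        remaining.remove((left, right, gain))
    return AssemblyPathway(steps=out, chain_ids=frozenset(chains))
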