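"""Round-tripping per-pair records through the emitted TSV."""

from __future__ import annotations

import pandas as pd

from .assembly import PairOrder
from .operon_map import GenePairRecord

__all__ = ["records_from_frame"]


def _opt_bool(v) -> bool | None:
    if v is None or v == "" or pd.isna(v):
        return None
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("true", "1", "yes")


def _opt_float(v) -> float | None:
    if v is None or v == "" or pd.isna(v):
        return None
    return float(v)


def _opt_int(v) -> int | None:
    f = _opt_float(v)
    return None if f is None else int(f)


def records_from_frame(frame: pd.DataFrame) -> list[GenePairRecord]:
    """Rebuild :class:`GenePairRecord` s from a per-pair TSV DataFrame.

    Inverse of :func:`operon_assembly.pipeline.records_to_frame`: every
    summary count is recomputable from the emitted table alone.
    """
    records = []
    for row in frame.itertuples(index=False):
        order = getattr(row, "pair_order", "")
        pair_order = (
            PairOrder(order) if isinstance(order, str) and order else None
        )
        operon_id = getattr(row, "operon_id", "")
        records.append(
            GenePairRecord(
                gene_x=str(row.gene_x),
                gene_y=str(row.gene_y),
                same_operon=bool(_opt_bool(row.same_operon)),
                operon_id=str(operon_id) if operon_id and not pd.isna(operon_id) else None,
                distance=_opt_int(getattr(row, "distance", None)),
                adjacent=bool(_opt_bool(getattr(row, "adjacent", False))),
                complex_id=str(getattr(row, "complex_id", "") or ""),
                entity_x=str(getattr(row, "entity_x", "") or ""),
                entity_y=str(getattr(row, "entity_y", "") or ""),
                interface_area=_opt_float(getattr(row, "interface_area", None)),
                physically_interacting=_opt_bool(getattr(row, "physically_interacting", None)),
                pair_order=pair_order,
                uniting_step=_opt_int(getattr(row, "uniting_step", None)),
                conserved_order=_opt_bool(getattr(row, "conserved_order", None)),
                fusion_flag=bool(_opt_bool(getattr(row, "fusion_flag", False)) or False),
                abundance_x=_opt_float(getattr(row, "abundance_x", None)),
                abundance_y=_opt_float(getattr(row, "abundance_y", None)),
            )
        )
    return records
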