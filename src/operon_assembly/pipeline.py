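"""End-to-end analysis: structures/matrices → pathways → operon concordance.

The pipeline joins three inputs — interface matrices (or complex structures
from which they are computed), an operon table, and per-gene annotations
(conservation of gene order, abundance) — into per-pair records, then
computes the summary statistics of the analysis:

* subunit-pair counts by gene distance, split by physical interaction;
* the adjacency × physical-interaction contingency with Fisher's exact test;
* the conservation × gene-order/assembly-order concordance contingency
  (adjacent, order-resolved pairs) with Fisher's exact test;
* the exact binomial test of gene-order/assembly-order concordance among
  conserved, order-resolved, adjacent pairs;
* Wilcoxon rank-sum comparisons of abundance (co-operonic versus different
  transcriptional units; concordant versus discordant pairs);
* the Spearman-correlation group-shuffle comparison of subunit abundances;
* Wilson intervals wherever a proportion is reported.

Every count in the report is recomputable from the per-pair table emitted
alongside it, and a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import PairOrder, classify_pair_order, predict_pathway
from .interface_calc import InterfaceMatrix, build_interface_matrix
from .operon_map import (
    GenePairRecord,
    Operon,
    SubunitPair,
    deduplicate_operons,
    map_pairs_to_operons,
    read_operon_table,
)
from .stats_suite import (
    ContingencyTable2x2,
    TestResult,
    binomial_test_two_sided,
    correlation_difference_shuffle,
    fisher_exact_two_sided,
    wilcoxon_rank_sum,
    wilson_interval,
)
from .structure_model import ComplexModel, FilterConfig, assign_entities, passes_filters, read_structure

__all__ = [
    "RunConfig",
    "SummaryReport",
    "classify_concordance",
    "records_from_tables",
    "summarize_records",
    "run_pipeline",
    "records_to_frame",
]


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run."""

    operon_table: str
    pairs_table: str
    out_dir: str
    abundance_table: str | None = None
    matrices_dir: str | None = None
    structure_paths: tuple[str, ...] = ()
    chain_entity_table: str | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    probe_radius: float = 1.4
    sphere_points: int = 960
    interface_threshold: float = 200.0
    n_shuffles: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        paths = [self.operon_table, self.pairs_table]
        if self.abundance_table:
            paths.append(self.abundance_table)
        if self.chain_entity_table:
            paths.append(self.chain_entity_table)
        paths.extend(self.structure_paths)
        if self.matrices_dir:
            paths.append(self.matrices_dir)
        for p in paths:
            if not os.path.exists(p):
                raise FileNotFoundError(p)
        if not self.matrices_dir and not self.structure_paths:
            raise ValueError("need matrices_dir or structure_paths")


def classify_concordance(record: GenePairRecord) -> str:
    """Relationship between gene order and assembly order for one pair.

    ``same`` when the upstream gene's subunit assembles first, ``different``
    when it assembles second, ``simultaneous`` when neither precedes, and
    ``not_applicable`` for pairs that are not co-operonic or lack a
    predicted order.  Records are oriented upstream-first, so the upstream
    entity is entity_x.
    """
    if not record.same_operon or record.pair_order is None:
        return "not_applicable"
    if record.pair_order == PairOrder.FIRST_PRECEDES:
        return "same"
    if record.pair_order == PairOrder.SECOND_PRECEDES:
        return "different"
    return "simultaneous"


@dataclass
class SummaryReport:
    """All summary tables and test results of one pipeline run."""

    n_pairs: int
    n_same_operon: int
    n_adjacent: int
    pct_adjacent_of_same_operon: float | None
    distance_counts: dict[int, dict[str, int]]
    adjacency_interaction_table: dict | None
    adjacency_interaction_fisher: TestResult | None
    interaction_rate_adjacent: dict | None
    interaction_rate_nonadjacent: dict | None
    conservation_concordance_table: dict | None
    conservation_concordance_fisher: TestResult | None
    concordance_counts: dict[str, int]
    concordant_of_conserved: dict | None
    concordance_binomial: TestResult | None
    abundance_operon_vs_diff_tu: TestResult | None
    abundance_concordant_vs_discordant: TestResult | None
    correlation_shuffle: TestResult | None
    seed: int = 0
    n_shuffles: int = 0

    def to_json(self, path: str) -> None:
        def default(obj):
            if isinstance(obj, TestResult):
                d = dataclasses.asdict(obj)
                d["statistic"] = None if np.isnan(obj.statistic) else obj.statistic
                return d
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            raise TypeError(f"not serializable: {type(obj)}")

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=default, sort_keys=True)
            fh.write("\n")


def _order_value(record: GenePairRecord) -> str:
    return record.pair_order.value if record.pair_order is not None else ""


def records_to_frame(records: list[GenePairRecord]) -> pd.DataFrame:
    """Per-pair records as a DataFrame (the emitted per-pair TSV)."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene_x": r.gene_x,
                "gene_y": r.gene_y,
                "complex_id": r.complex_id,
                "entity_x": r.entity_x,
                "entity_y": r.entity_y,
                "same_operon": r.same_operon,
                "operon_id": r.operon_id or "",
                "distance": r.distance if r.distance is not None else "",
                "adjacent": r.adjacent,
                "interface_area": r.interface_area if r.interface_area is not None else "",
                "physically_interacting": (
                    "" if r.physically_interacting is None else r.physically_interacting
                ),
                "pair_order": _order_value(r),
                "uniting_step": r.uniting_step if r.uniting_step is not None else "",
                "concordance": classify_concordance(r),
                "conserved_order": "" if r.conserved_order is None else r.conserved_order,
                "fusion_flag": r.fusion_flag,
                "abundance_x": r.abundance_x if r.abundance_x is not None else "",
                "abundance_y": r.abundance_y if r.abundance_y is not None else "",
            }
        )
    return pd.DataFrame(rows)


def _entity_interface_area(m: InterfaceMatrix, chains_x: list[str], chains_y: list[str]) -> float:
    """Representative pair interface: the largest cross-entity chain-pair area."""
    return max(m.get(a, b) for a in chains_x for b in chains_y)


def records_from_tables(
    pairs: pd.DataFrame,
    operons: list[Operon],
    matrices: dict[str, InterfaceMatrix],
    chain_entities: pd.DataFrame,
    abundance: pd.DataFrame | None = None,
    interface_threshold: float = 200.0,
) -> list[GenePairRecord]:
    """Build per-pair records: predict pathways, map to operons, annotate.

    ``pairs`` needs columns gene_x, gene_y, complex_id, entity_x, entity_y,
    conserved_order, fusion_flag; ``chain_entities`` maps complex_id and
    chain_id to entity_id; ``matrices`` holds one interface matrix per
    complex.  Pair order is classified on each complex's greedy pathway and
    flipped by the operon mapping when the pair is reoriented upstream-first.
    """
    ab_map: dict[str, float] = {}
    if abundance is not None:
        ab_map = dict(
            zip(abundance["gene_id"].astype(str), abundance["abundance_ppm"].astype(float))
        )

    pathways = {}
    chain_models: dict[str, ComplexModel] = {}
    for cid, m in matrices.items():
        pathways[cid] = predict_pathway(m)
        sub = chain_entities[chain_entities["complex_id"] == cid]
        entity_of_chain = dict(zip(sub["chain_id"].astype(str), sub["entity_id"].astype(str)))
        # minimal chain stubs: pair-order classification needs only the
        # chain → entity map, not coordinates
        from .structure_model import Atom, Chain

        chains = [
            Chain(
                chain_id=c,
                residues=["UNK"],
                atoms=[Atom(position=(0.0, 0.0, 0.0), radius=1.7, chain_id=c, residue_index=0)],
            )
            for c in m.chain_ids
        ]
        chain_models[cid] = ComplexModel(
            complex_id=cid, chains=chains, entity_of_chain=entity_of_chain
        )

    subunit_pairs = []
    for row in pairs.itertuples(index=False):
        cid = str(row.complex_id)
        m = matrices[cid]
        model = chain_models[cid]
        chains_x = model.chains_of_entity(str(row.entity_x))
        chains_y = model.chains_of_entity(str(row.entity_y))
        area = _entity_interface_area(m, chains_x, chains_y)
        res = classify_pair_order(pathways[cid], model, str(row.entity_x), str(row.entity_y))
        conserved = row.conserved_order
        if isinstance(conserved, str):
            conserved = conserved.strip().lower() in ("true", "1", "yes")
        subunit_pairs.append(
            (
                SubunitPair(
                    gene_x=str(row.gene_x),
                    gene_y=str(row.gene_y),
                    complex_id=cid,
                    entity_x=str(row.entity_x),
                    entity_y=str(row.entity_y),
                    interface_area=area,
                    conserved_order=bool(conserved),
                    fusion_flag=bool(getattr(row, "fusion_flag", False)),
                    abundance_x=ab_map.get(str(row.gene_x)),
                    abundance_y=ab_map.get(str(row.gene_y)),
                ),
                res,
            )
        )

    records = map_pairs_to_operons(
        [p for p, _ in subunit_pairs], operons, interface_threshold=interface_threshold
    )
    # attach pair order, flipping when the mapping reoriented the pair
    for record, (pair, res) in zip(records, subunit_pairs):
        order = res.order
        if record.gene_x != pair.gene_x:  # reoriented upstream-first
            if order == PairOrder.FIRST_PRECEDES:
                order = PairOrder.SECOND_PRECEDES
            elif order == PairOrder.SECOND_PRECEDES:
                order = PairOrder.FIRST_PRECEDES
        record.pair_order = order
        record.uniting_step = res.uniting_step
    return records


def summarize_records(
    records: list[GenePairRecord],
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> SummaryReport:
    """Compute the full summary report from per-pair records."""
    same = [r for r in records if r.same_operon]
    adjacent = [r for r in same if r.adjacent]
    nonadjacent = [r for r in same if not r.adjacent]

    distance_counts: dict[int, dict[str, int]] = {}
    for r in same:
        assert r.distance is not None
        bucket = distance_counts.setdefault(r.distance, {"interacting": 0, "not_interacting": 0})
        key = "interacting" if r.physically_interacting else "not_interacting"
        bucket[key] += 1

    def n_int(rs):
        return sum(1 for r in rs if r.physically_interacting)

    adjacency_interaction_table = None
    adjacency_interaction_fisher = None
    interaction_rate_adjacent = None
    interaction_rate_nonadjacent = None
    if adjacent and nonadjacent:
        a, b = n_int(adjacent), len(adjacent) - n_int(adjacent)
        c, d = n_int(nonadjacent), len(nonadjacent) - n_int(nonadjacent)
        table = ContingencyTable2x2(a, b, c, d)
        adjacency_interaction_table = {"adjacent": [a, b], "non_adjacent": [c, d]}
        adjacency_interaction_fisher = fisher_exact_two_sided(table)
        lo, hi = wilson_interval(a, a + b, 0.68)
        interaction_rate_adjacent = {"k": a, "n": a + b, "fraction": a / (a + b), "wilson68": [lo, hi]}
        lo, hi = wilson_interval(c, c + d, 0.68)
        interaction_rate_nonadjacent = {
            "k": c, "n": c + d, "fraction": c / (c + d), "wilson68": [lo, hi],
        }

    concordance_counts = {"same": 0, "different": 0, "simultaneous": 0, "not_applicable": 0}
    for r in records:
        concordance_counts[classify_concordance(r)] += 1

    # conservation × concordance among adjacent, order-resolved pairs
    resolved_adjacent = [
        r for r in adjacent if classify_concordance(r) in ("same", "different")
    ]
    conservation_concordance_table = None
    conservation_concordance_fisher = None
    if resolved_adjacent:
        cons = [r for r in resolved_adjacent if r.conserved_order]
        noncons = [r for r in resolved_adjacent if not r.conserved_order]
        a = sum(1 for r in cons if classify_concordance(r) == "same")
        b = len(cons) - a
        c = sum(1 for r in noncons if classify_concordance(r) == "same")
        d = len(noncons) - c
        conservation_concordance_table = {"conserved": [a, b], "not_conserved": [c, d]}
        if (a + b) and (c + d):
            conservation_concordance_fisher = fisher_exact_two_sided(
                ContingencyTable2x2(a, b, c, d)
            )

    # binomial test: conserved, order-resolved, adjacent pairs
    concordant_of_conserved = None
    concordance_binomial = None
    conserved_resolved = [r for r in resolved_adjacent if r.conserved_order]
    if conserved_resolved:
        k = sum(1 for r in conserved_resolved if classify_concordance(r) == "same")
        n = len(conserved_resolved)
        lo, hi = wilson_interval(k, n, 0.68)
        concordant_of_conserved = {"k": k, "n": n, "fraction": k / n, "wilson68": [lo, hi]}
        concordance_binomial = binomial_test_two_sided(k, n, 0.5)

    # abundance comparisons
    def abundances(rs):
        out = []
        for r in rs:
            if r.abundance_x is not None:
                out.append(r.abundance_x)
            if r.abundance_y is not None:
                out.append(r.abundance_y)
        return out

    diff_tu = [r for r in records if not r.same_operon]
    abundance_operon_vs_diff_tu = None
    ab_same, ab_diff = abundances(same), abundances(diff_tu)
    if ab_same and ab_diff:
        abundance_operon_vs_diff_tu = wilcoxon_rank_sum(ab_same, ab_diff)

    concordant = [r for r in records if classify_concordance(r) == "same"]
    discordant = [r for r in records if classify_concordance(r) == "different"]
    abundance_concordant_vs_discordant = None
    ab_c, ab_d = abundances(concordant), abundances(discordant)
    if ab_c and ab_d:
        abundance_concordant_vs_discordant = wilcoxon_rank_sum(ab_c, ab_d)

    # Spearman-correlation group-shuffle comparison
    def ab_pairs(rs):
        return [
            (r.abundance_x, r.abundance_y)
            for r in rs
            if r.abundance_x is not None and r.abundance_y is not None
        ]

    correlation_shuffle = None
    p_same, p_diff = ab_pairs(same), ab_pairs(diff_tu)
    if len(p_same) >= 3 and len(p_diff) >= 3 and n_shuffles > 0:
        correlation_shuffle = correlation_difference_shuffle(
            p_same, p_diff, n_shuffles=n_shuffles, seed=seed
        )

    pct = 100.0 * len(adjacent) / len(same) if same else None
    return SummaryReport(
        n_pairs=len(records),
        n_same_operon=len(same),
        n_adjacent=len(adjacent),
        pct_adjacent_of_same_operon=pct,
        distance_counts=distance_counts,
        adjacency_interaction_table=adjacency_interaction_table,
        adjacency_interaction_fisher=adjacency_interaction_fisher,
        interaction_rate_adjacent=interaction_rate_adjacent,
        interaction_rate_nonadjacent=interaction_rate_nonadjacent,
        conservation_concordance_table=conservation_concordance_table,
        conservation_concordance_fisher=conservation_concordance_fisher,
        concordance_counts=concordance_counts,
        concordant_of_conserved=concordant_of_conserved,
        concordance_binomial=concordance_binomial,
        abundance_operon_vs_diff_tu=abundance_operon_vs_diff_tu,
        abundance_concordant_vs_discordant=abundance_concordant_vs_discordant,
        correlation_shuffle=correlation_shuffle,
        seed=seed,
        n_shuffles=n_shuffles,
    )


def run_pipeline(cfg: RunConfig) -> tuple[SummaryReport, pd.DataFrame]:
    """Run the full analysis from files; write report JSON and per-pair TSV.

    Matrices are loaded from ``cfg.matrices_dir`` (one ``<complex_id>.tsv``
    per complex) and/or computed from ``cfg.structure_paths``; structures
    are filtered first (entity assignment, size filters) and dropped
    complexes are logged to ``dropped_complexes.tsv``.
    """
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)

    operons = deduplicate_operons(read_operon_table(cfg.operon_table))
    pairs = pd.read_csv(cfg.pairs_table, sep="\t", dtype=str)
    abundance = (
        pd.read_csv(cfg.abundance_table, sep="\t") if cfg.abundance_table else None
    )

    matrices: dict[str, InterfaceMatrix] = {}
    chain_entity_rows = []
    dropped = []
    if cfg.matrices_dir:
        for name in sorted(os.listdir(cfg.matrices_dir)):
            if name.endswith(".tsv"):
                cid = name[: -len(".tsv")]
                matrices[cid] = InterfaceMatrix.from_tsv(
                    os.path.join(cfg.matrices_dir, name)
                )
        if cfg.chain_entity_table:
            ce = pd.read_csv(cfg.chain_entity_table, sep="\t", dtype=str)
            chain_entity_rows.extend(ce.to_dict("records"))
    for path in cfg.structure_paths:
        model = read_structure(path)
        model = assign_entities(model, cfg.filter_config.entity_grouping_identity)
        decision = passes_filters(model, cfg.filter_config)
        if not decision.keep:
            dropped.append({"complex_id": model.complex_id, "reason": decision.reason})
            continue
        matrices[model.complex_id] = build_interface_matrix(
            model, cfg.probe_radius, cfg.sphere_points
        )
        for cid_chain, eid in model.entity_of_chain.items():
            chain_entity_rows.append(
                {"complex_id": model.complex_id, "chain_id": cid_chain, "entity_id": eid}
            )
    chain_entities = pd.DataFrame(
        chain_entity_rows, columns=["complex_id", "chain_id", "entity_id"]
    )

    # drop pairs whose complex was filtered out or has no matrix
    kept_pairs = pairs[pairs["complex_id"].isin(matrices)].reset_index(drop=True)
    records = records_from_tables(
        kept_pairs,
        operons,
        matrices,
        chain_entities,
        abundance,
        interface_threshold=cfg.interface_threshold,
    )
    report = summarize_records(records, n_shuffles=cfg.n_shuffles, seed=cfg.seed)

    frame = records_to_frame(records)
    frame.to_csv(os.path.join(cfg.out_dir, "pairs_annotated.tsv"), sep="\t", index=False)
    report.to_json(os.path.join(cfg.out_dir, "report.json"))
    if dropped:
        pd.DataFrame(dropped).to_csv(
            os.path.join(cfg.out_dir, "dropped_complexes.tsv"), sep="\t", index=False
        )
    return report, frame
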