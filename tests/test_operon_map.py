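"""Operon parsing, 5'→3' ordering, distances, pair mapping, redundancy."""

import itertools

import pytest

from operon_assembly import (
    GeneLocus,
    Operon,
    SubunitPair,
    deduplicate_operons,
    filter_redundant_pairs,
    gene_distance,
    map_pairs_to_operons,
    read_operon_table,
)


def _write_tsv(path, rows, header="operon_id\tgene_id\tstart\tend\tstrand"):
    path.write_text(header + "\n" + "\n".join("\t".join(map(str, r)) for r in rows) + "\n")


def _operon(operon_id, gene_ids):
    genes = [
        GeneLocus(gene_id=g, start=100 + 1000 * i, end=1000 + 1000 * i, strand="+", position=i + 1)
        for i, g in enumerate(gene_ids)
    ]
    return Operon(operon_id=operon_id, genes=genes)


# ---------------------------------------------------------------------------
# reading and ordering
# ---------------------------------------------------------------------------


def test_plus_strand_positions_follow_start(tmp_path):
    p = tmp_path / "op.tsv"
    _write_tsv(p, [("op1", "gA", 100, 400, "+"), ("op1", "gB", 500, 800, "+"), ("op1", "gC", 900, 1200, "+")])
    (op,) = read_operon_table(str(p))
    assert [g.gene_id for g in op.genes] == ["gA", "gB", "gC"]
    assert [g.position for g in op.genes] == [1, 2, 3]


def test_minus_strand_reverses_order(tmp_path):
    p = tmp_path / "op.tsv"
    _write_tsv(p, [("op1", "gA", 100, 400, "-"), ("op1", "gB", 500, 800, "-"), ("op1", "gC", 900, 1200, "-")])
    (op,) = read_operon_table(str(p))
    # position 1 is the 3'-most start: gC is transcribed first on the minus strand
    assert [g.gene_id for g in op.genes] == ["gC", "gB", "gA"]
    assert op.position_of("gC") == 1


def test_first_copy_rule_for_duplicated_gene(tmp_path):
    p = tmp_path / "op.tsv"
    rows = [("op1", f"g{i}", 100 + 1000 * i, 900 + 1000 * i, "+") for i in range(5)]
    rows[4] = ("op1", "g1", rows[4][2], rows[4][3], "+")  # g1 again at position 5
    _write_tsv(p, rows)
    (op,) = read_operon_table(str(p))
    assert op.position_of("g1") == 2
    # the minimum-over-copies convention would give distance 1 to g3; the
    # first-copy rule gives |2 - 4| = 2
    assert gene_distance(op, "g1", "g3") == 2
    copies = [g.position for g in op.genes if g.gene_id == "g1"]
    assert copies == [2, 5]
    assert min(abs(c - 4) for c in copies) == 1


def test_mixed_strands_warns_uses_majority(tmp_path):
    p = tmp_path / "op.tsv"
    _write_tsv(p, [("op1", "gA", 100, 400, "+"), ("op1", "gB", 500, 800, "+"), ("op1", "gC", 900, 1200, "-")])
    with pytest.warns(UserWarning, match="mixed strands"):
        (op,) = read_operon_table(str(p))
    assert [g.gene_id for g in op.genes] == ["gA", "gB", "gC"]


def test_malformed_row_reports_line_number(tmp_path):
    p = tmp_path / "op.tsv"
    _write_tsv(p, [("op1", "gA", 100, 400, "+"), ("op1", "gB", "oops", 800, "+")])
    with pytest.raises(ValueError, match="line 3"):
        read_operon_table(str(p))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_gene_distance_examples():
    op = _operon("op1", ["g1", "g2", "g3", "g4", "g5"])
    assert gene_distance(op, "g4", "g5") == 1
    assert gene_distance(op, "g1", "g4") == 3
    assert gene_distance(op, "g4", "g1") == 3  # symmetric
    with pytest.raises(KeyError):
        gene_distance(op, "g1", "missing")


def test_gene_distance_triangle_inequality():
    op = _operon("op1", [f"g{i}" for i in range(6)])
    ids = op.gene_ids
    for a, b, c in itertools.permutations(ids, 3):
        assert gene_distance(op, a, c) <= gene_distance(op, a, b) + gene_distance(op, b, c)


# ---------------------------------------------------------------------------
# pair mapping
# ---------------------------------------------------------------------------


def test_map_pair_same_operon_adjacent():
    ops = [_operon("op1", ["g1", "g2", "g3", "g4", "g5"])]
    (rec,) = map_pairs_to_operons([SubunitPair(gene_x="g2", gene_y="g3")], ops)
    assert rec.same_operon and rec.distance == 1 and rec.adjacent


def test_map_pair_different_operons():
    ops = [_operon("op1", ["g1", "g2"]), _operon("op2", ["g3", "g4"])]
    (rec,) = map_pairs_to_operons([SubunitPair(gene_x="g1", gene_y="g3")], ops)
    assert not rec.same_operon
    assert rec.distance is None and not rec.adjacent


def test_map_pair_reorients_upstream_first():
    ops = [_operon("op1", ["g1", "g2", "g3"])]
    pair = SubunitPair(
        gene_x="g3", gene_y="g1", entity_x="EX", entity_y="EY", abundance_x=9.0, abundance_y=1.0
    )
    (rec,) = map_pairs_to_operons([pair], ops)
    assert (rec.gene_x, rec.gene_y) == ("g1", "g3")
    assert (rec.entity_x, rec.entity_y) == ("EY", "EX")
    assert (rec.abundance_x, rec.abundance_y) == (1.0, 9.0)


def test_map_never_adjacent_without_same_operon():
    ops = [_operon("op1", ["g1", "g2", "g3", "g4"]), _operon("op2", ["h1", "h2"])]
    pairs = [
        SubunitPair(gene_x=a, gene_y=b)
        for a, b in [("g1", "g2"), ("g1", "g4"), ("g2", "h1"), ("h1", "h2"), ("zz", "g1")]
    ]
    for rec in map_pairs_to_operons(pairs, ops):
        assert not (rec.adjacent and not rec.same_operon)


def test_gene_in_multiple_operons_resolves_to_first_by_id():
    ops = [_operon("opB", ["g1", "g2"]), _operon("opA", ["g1", "g3"])]
    with pytest.warns(UserWarning, match="multiple operons"):
        (rec,) = map_pairs_to_operons([SubunitPair(gene_x="g1", gene_y="g3")], ops)
    assert rec.same_operon and rec.operon_id == "opA"


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def test_deduplicate_identical_gene_lists():
    ops = [_operon("opB", ["g1", "g2"]), _operon("opA", ["g1", "g2"])]
    out = deduplicate_operons(ops)
    assert [o.operon_id for o in out] == ["opA"]


def test_deduplicate_keeps_different_orders():
    ops = [_operon("opA", ["g1", "g2"]), _operon("opB", ["g2", "g1"])]
    assert len(deduplicate_operons(ops)) == 2


def test_deduplicate_matches_brute_force_and_idempotent():
    lists = [["a", "b"], ["a", "b"], ["b", "a"], ["c"], ["c"], ["c"], ["a", "b", "c"], ["a", "b"], ["d", "e"], ["d", "e"]]
    ops = [_operon(f"op{i:02d}", genes) for i, genes in enumerate(lists)]
    out = deduplicate_operons(ops)
    # brute force: pairwise comparison grouping
    groups = []
    for op in ops:
        for g in groups:
            if g[0].gene_ids == op.gene_ids:
                g.append(op)
                break
        else:
            groups.append([op])
    assert len(out) == len(groups)
    assert deduplicate_operons(out) == out


# ---------------------------------------------------------------------------
# pair redundancy filter
# ---------------------------------------------------------------------------

_SEQS = {
    "g1": "MKVLITGAGSGIGL",
    "g2": "WWYYFFPPQQRRSS",
    "g1b": "MKVLITGAGSGIGL",  # identical to g1
    "g2b": "WWYYFFPPQQRRSS",  # identical to g2
    "h1": "ACDEACDEACDEAC",
    "h2": "GGGGGGGGGGGGGG",
}


def _rec(x, y):
    ops = [_operon("op1", [x, y])]
    return map_pairs_to_operons([SubunitPair(gene_x=x, gene_y=y)], ops)[0]


def test_identical_strain_copies_collapse():
    records = [_rec("g1", "g2"), _rec("g1b", "g2b")]
    out = filter_redundant_pairs(records, _SEQS, 0.50)
    assert len(out) == 1
    assert (out[0].gene_x, out[0].gene_y) == ("g1", "g2")


def test_single_member_match_not_redundant():
    # g1b matches g1 but h2 matches nothing: pair retained
    records = [_rec("g1", "g2"), _rec("g1b", "h2")]
    out = filter_redundant_pairs(records, _SEQS, 0.50)
    assert len(out) == 2


def test_below_threshold_pairs_both_retained():
    records = [_rec("g1", "g2"), _rec("h1", "h2")]
    assert len(filter_redundant_pairs(records, _SEQS, 0.50)) == 2


def test_redundancy_clique_matches_greedy_oracle():
    seqs = dict(_SEQS)
    seqs.update({"g1c": seqs["g1"], "g2c": seqs["g2"]})
    records = [
        _rec("g1", "g2"),
        _rec("g1b", "g2b"),
        _rec("g1c", "g2c"),
        _rec("h1", "h2"),
        _rec("g1", "h2"),
        _rec("g2", "h1"),
    ]
    out = filter_redundant_pairs(records, seqs, 0.50)
    # greedy in input order keeps the first of the 3-pair clique plus the
    # three non-redundant pairs
    kept = [(r.gene_x, r.gene_y) for r in out]
    assert kept == [("g1", "g2"), ("h1", "h2"), ("g1", "h2"), ("g2", "h1")]


def test_missing_sequence_skipped_with_warning():
    records = [_rec("g1", "g2"), _rec("zz", "g2b")]
    with pytest.warns(UserWarning, match="missing sequence"):
        out = filter_redundant_pairs(records, _SEQS, 0.50)
    assert len(out) == 1
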