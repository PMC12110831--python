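"""Spacers, overlaps, gene order, control region, tandem repeats."""

import random

import numpy as np
import pytest

from mitochar import reference
from mitochar.architecture import (
    compare_orders,
    conservation_check,
    control_region_record,
    find_tandem_repeats,
    gene_order,
    spacers_and_overlaps,
)
from mitochar.model import Feature, Mitogenome


def test_published_spacer_accounting(lactinea_annotation):
    spacers, overlaps = spacers_and_overlaps(lactinea_annotation)
    assert len(spacers) == 23
    assert sum(s.length for s in spacers) == 297
    largest = max(spacers, key=lambda s: s.length)
    assert (largest.upstream, largest.downstream, largest.length) == ("tRNA-Gln", "ND2", 52)
    second = sorted(spacers, key=lambda s: -s.length)[1]
    assert (second.upstream, second.downstream, second.length) == ("ND5", "tRNA-His", 51)


def test_published_overlap_accounting(lactinea_annotation):
    _, overlaps = spacers_and_overlaps(lactinea_annotation)
    assert len(overlaps) == 6
    assert sum(o.length for o in overlaps) == 25
    biggest = max(overlaps, key=lambda o: o.length)
    assert (biggest.first, biggest.second, biggest.length) == ("tRNA-Trp", "tRNA-Cys", 8)


def test_conservation_law_on_published_ledger(lactinea_annotation):
    check = conservation_check(lactinea_annotation)
    assert check["balanced"]
    assert check["genome_length"] == 15380


def test_conservation_law_on_synthetic_genome(synthetic_genome):
    g, _ = synthetic_genome
    assert conservation_check(g)["balanced"]


def test_abutting_features_yield_neither_spacer_nor_overlap():
    g = Mitogenome(
        seq="A" * 200,
        features=[Feature("a", "PCG", "H", 1, 100), Feature("b", "PCG", "H", 101, 200)],
    )
    spacers, overlaps = spacers_and_overlaps(g)
    assert spacers == [] and overlaps == []


def test_control_region_record_published(lactinea_annotation):
    length, upstream, downstream = control_region_record(lactinea_annotation)
    assert length == 303
    assert upstream == "rrnS" and downstream == "tRNA-Met"


def test_control_region_wrapping_length():
    g = Mitogenome(
        seq="A" * 15380,
        features=[
            Feature("gene", "PCG", "H", 200, 15000),
            Feature("D-loop", "control", "H", 15300, 50),
        ],
    )
    length, upstream, downstream = control_region_record(g)
    assert length == 131
    assert upstream == "gene" and downstream == "gene"


def test_control_region_absent_raises(synthetic_genome):
    g = Mitogenome(seq="A" * 100, features=[Feature("x", "PCG", "H", 1, 50)])
    with pytest.raises(LookupError):
        control_region_record(g)


def test_gene_order_starts_at_trnmet(lactinea_annotation):
    order = gene_order(lactinea_annotation)
    heads = [(n.split("(")[0], s) for n, s in order.order[:4]]
    assert heads == [("trnM", "H"), ("trnI", "H"), ("trnQ", "L"), ("ND2", "H")]


def test_gene_order_rotation_invariance(lactinea_annotation):
    """Re-labelling coordinates by a rotation leaves the gene order equal."""
    g = lactinea_annotation
    shift = 5000
    rotated = []
    for f in g.features:
        ns = (f.start - 1 + shift) % g.length + 1
        ne = (f.end - 1 + shift) % g.length + 1
        rotated.append(Feature(f.name, f.ftype, f.strand, ns, ne, f.anticodon))
    g2 = Mitogenome(seq=g.seq, features=rotated, taxon=g.taxon)
    assert gene_order(g) == gene_order(g2)
    assert compare_orders(gene_order(g), gene_order(g2)) == (True, 0)


def test_gene_order_detects_swap(lactinea_annotation):
    g = lactinea_annotation
    feats = list(g.features)
    a, b = feats[5], feats[6]
    swapped = [
        Feature(b.name, b.ftype, b.strand, a.start, a.start + (b.end - b.start), b.anticodon)
        if f is a
        else Feature(a.name, a.ftype, a.strand, b.end - (a.end - a.start), b.end, a.anticodon)
        if f is b
        else f
        for f in feats
    ]
    g2 = Mitogenome(seq=g.seq, features=swapped, taxon="swapped")
    identical, bp = compare_orders(gene_order(g), gene_order(g2))
    assert not identical and bp > 0


def test_compare_orders_self_identity_random_orders():
    rng = random.Random(3)
    for _ in range(20):
        n = rng.randint(4, 12)
        feats = []
        pos = 1
        for i in range(n):
            ln = rng.randint(50, 200)
            feats.append(
                Feature(f"g{i}", "PCG", rng.choice("HL"), pos, pos + ln - 1)
            )
            pos += ln + rng.randint(0, 10)
        g = Mitogenome(seq="A" * (pos + 10), features=feats)
        order = gene_order(g)
        assert compare_orders(order, order) == (True, 0)


def test_two_gene_inversion_gives_two_breakpoints():
    def circle(rows):
        feats = [Feature(n, "PCG", s, 100 * i + 1, 100 * i + 90) for i, (n, s) in enumerate(rows)]
        return gene_order(Mitogenome(seq="A" * 1100, features=feats))

    base = [(f"g{i}", "H") for i in range(10)]
    inverted = list(base)
    inverted[3], inverted[4] = ("g4", "L"), ("g3", "L")
    identical, bp = compare_orders(circle(base), circle(inverted))
    assert not identical
    assert bp == 2


def test_compare_orders_disjoint_name_sets():
    f1 = [Feature("a", "PCG", "H", 1, 10), Feature("b", "PCG", "H", 20, 30)]
    f2 = [Feature("a", "PCG", "H", 1, 10), Feature("c", "PCG", "H", 20, 30)]
    o1 = gene_order(Mitogenome(seq="A" * 40, features=f1))
    o2 = gene_order(Mitogenome(seq="A" * 40, features=f2))
    with pytest.raises(ValueError, match="gene sets differ"):
        compare_orders(o1, o2)


def test_tandem_repeat_perfect():
    reps = find_tandem_repeats("ACGTACGTACGT", min_period=2, max_period=6)
    assert len(reps) == 1
    r = reps[0]
    assert (r.start, r.period, r.copies, r.identity) == (1, 4, 3.0, 1.0)


def test_tandem_repeat_homopolymer_reported_once():
    reps = find_tandem_repeats("A" * 24, min_period=2, max_period=10)
    assert len(reps) == 1
    assert reps[0].period == 2


def test_tandem_repeat_random_at_rich_usually_empty():
    """Random 303-mers at mitochondrial control-region composition rarely
    contain well-conserved tandem repeats at stringent settings."""
    rng = np.random.default_rng(5)
    empty = 0
    trials = 20
    for _ in range(trials):
        seq = "".join(rng.choice(list("ACGT"), size=303, p=[0.37, 0.13, 0.13, 0.37]))
        reps = find_tandem_repeats(seq, min_period=5, max_period=50,
                                   min_copies=3, min_identity=0.9)
        empty += not reps
    assert empty > trials / 2


def test_tandem_repeat_parameter_validation():
    with pytest.raises(ValueError):
        find_tandem_repeats("ACGTACGT", min_period=6, max_period=3)
    with pytest.raises(ValueError):
        find_tandem_repeats("")


def test_synthetic_genome_matches_planned_geometry(synthetic_genome):
    g, man = synthetic_genome
    spacers, overlaps = spacers_and_overlaps(g)
    assert [(s.upstream, s.downstream, s.length) for s in spacers] == man.spacers
    assert [(o.first, o.second, o.length) for o in overlaps] == man.overlaps
    assert [(n, s) for n, s in gene_order(g).order][0][0].startswith("trnM")
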