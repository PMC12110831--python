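"""Synthetic-data generators with known ground truth.

The generators emit inputs carrying the statistical structure every
pipeline stage assumes — a lepidopteran-style circular mitogenome
(~15.4 kb, 13 PCGs / 22 tRNAs / 2 rRNAs / 1 control region, strong A+T
bias, genes on both strands, ATN starts, complete and incomplete stops,
planted spacers and overlaps), tRNA sequences whose maximal-pairing
cloverleaf is known by construction, and multiple-sequence alignments
evolved on a known tree under Jukes-Cantor — together with a manifest
of the ground truth each stage should recover.

Composition targets are enforced in expectation (bases are sampled), so
recovery tests use binomial-scale tolerances; architecture, codon
counts and planted folds are exact.  A single integer seed makes every
output byte-reproducible.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

import dendropy
import numpy as np

from mitochar import reference
from mitochar.codon import INVERTEBRATE_MITO
from mitochar.model import Feature, Mitogenome

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_BASES = ("A", "C", "G", "T")


def base_probs(at_content: float, at_skew: float = 0.0, gc_skew: float = 0.0) -> dict[str, float]:
    """Per-base probabilities hitting given A+T content and skews exactly."""
    if not 0 < at_content < 1:
        raise ValueError("at_content must be in (0,1)")
    gc = 1 - at_content
    return {
        "A": at_content / 2 * (1 + at_skew),
        "T": at_content / 2 * (1 - at_skew),
        "G": gc / 2 * (1 + gc_skew),
        "C": gc / 2 * (1 - gc_skew),
    }


def random_sequence(
    length: int,
    at_content: float,
    rng: np.random.Generator,
    at_skew: float = 0.0,
    gc_skew: float = 0.0,
) -> str:
    """I.i.d. nucleotide sequence at a target A+T content and skew."""
    probs = base_probs(at_content, at_skew, gc_skew)
    p = [probs[b] for b in _BASES]
    return "".join(rng.choice(_BASES, size=length, p=p))


# ---------------------------------------------------------------------------
# tRNA generator
# ---------------------------------------------------------------------------

_LOOP_ALPHABET = ("A", "C")  # A/C cannot pair with each other, so loops
# and spacers never compete with the planted stems for pairings


@dataclass
class PlantedTrna:
    seq: str
    anticodon: str
    acceptor_len: int
    dhu_len: int
    anticodon_len: int
    tpsic_len: int
    wobble_count: int
    arm_starts: dict = field(default_factory=dict)


def generate_trna(
    arms: tuple[int, int, int, int],
    wobble_count: int,
    rng: np.random.Generator,
    anticodon: str = "CAT",
    length: Optional[int] = None,
    fixed: Optional[Mapping[int, str]] = None,
) -> PlantedTrna:
    """Build a tRNA gene sequence with a planted cloverleaf fold.

    ``arms`` gives stem lengths (acceptor, DHU, anticodon, TpsiC); a DHU
    or TpsiC stem of 0 plants a missing arm.  Exactly ``wobble_count``
    stem pairs are converted from Watson-Crick to G-T wobble.  If
    ``length`` is given, the DHU and TpsiC loop sizes are adjusted to
    hit it; ``fixed`` pins individual positions (0-based, gene
    orientation) to given bases, with stem partners kept complementary
    where possible — used when embedding tRNAs into a genome where they
    overlap neighboring genes.
    """
    a, d, c, t = arms
    if not (6 <= a <= 8):
        raise ValueError("acceptor stem must be 6-8 bp")
    if not (0 <= d <= 4 and 3 <= c <= 6 and 0 <= t <= 5):
        raise ValueError("arm stem lengths outside template bounds")
    fixed = dict(fixed or {})
    s1, s2, v = 2, 1, 4
    dloop = 7 if d else 0
    tloop = 5 if t else 0
    base_len = 2 * a + s1 + (2 * d + dloop) + s2 + 2 * c + 7 + v + (2 * t + tloop) + 0
    if length is not None:
        delta = length - base_len
        # absorb the difference into the DHU and TpsiC loops (or the
        # unpaired region standing in for a missing arm)
        while delta != 0:
            step = 1 if delta > 0 else -1
            if d and ((3 <= dloop + step <= 10) if step < 0 else dloop < 10):
                dloop += step
            elif t and (3 <= tloop + step <= 9):
                tloop += step
            elif not d and 0 <= dloop + step <= 10:
                dloop += step
            elif not t and 0 <= tloop + step <= 9:
                tloop += step
            elif 0 <= v + step <= 9:
                v += step
            elif 1 <= s1 + step <= 3:
                s1 += step
            else:
                raise ValueError(f"cannot reach length {length} with arms {arms}")
            delta -= step
    L = 2 * a + s1 + (2 * d + dloop) + s2 + 2 * c + 7 + v + (2 * t + tloop)

    seq: list[Optional[str]] = [None] * L
    for pos, b in fixed.items():
        if 0 <= pos < L:
            seq[pos] = b.upper()

    # segment layout
    acc5 = range(0, a)
    dstart = a + s1
    ac5_start = dstart + 2 * d + dloop + s2
    loop_start = ac5_start + c
    anti_pos = loop_start + 2  # anticodon centered in the 7-nt loop
    ac3_start = loop_start + 7
    tstart = ac3_start + c + v
    acc3_start = tstart + 2 * t + tloop

    stems = (
        [(i, L - 1 - i) for i in range(a)]
        + [(dstart + i, dstart + 2 * d + dloop - 1 - i) for i in range(d)]
        + [(ac5_start + i, ac3_start + c - 1 - i) for i in range(c)]
        + [(tstart + i, tstart + 2 * t + tloop - 1 - i) for i in range(t)]
    )
    if wobble_count > len(stems):
        raise ValueError(f"wobble_count {wobble_count} exceeds {len(stems)} stem pairs")

    # anticodon anchor
    for k, b in enumerate(anticodon.upper().replace("U", "T")):
        if seq[anti_pos + k] is None:
            seq[anti_pos + k] = b

    # Outermost anticodon stem pair is pinned A-T (A on the 5' side): if a
    # rival template sheds this pair, the freed A cannot pair with the A/C
    # loop alphabet and fake a DHU stem, keeping the planted fold maximal.
    ac_outer = (ac5_start, ac3_start + c - 1)
    if seq[ac_outer[0]] is None and seq[ac_outer[1]] is None:
        seq[ac_outer[0]], seq[ac_outer[1]] = "A", "T"

    free_pairs = []
    for i, j in stems:
        if seq[i] is not None and seq[j] is not None:
            continue  # both pinned; pairing may be broken, recorded as-is
        if seq[i] is not None:
            seq[j] = _COMP.get(seq[i], "A")
        elif seq[j] is not None:
            seq[i] = _COMP.get(seq[j], "A")
        else:
            b = str(rng.choice(_BASES))
            seq[i], seq[j] = b, _COMP[b]
            free_pairs.append((i, j))

    # Convert WC pairs to G-T wobble.  Wobble pairs are planted in the
    # acceptor stem: its pair positions are anchored at the sequence ends,
    # so no rival template can re-pair them and the planted wobble count
    # is exactly what the folder recovers.
    planted_wobble = 0
    if wobble_count:
        candidates = [(i, j) for i, j in free_pairs if i < a]
        if wobble_count > len(candidates):
            raise ValueError("not enough unconstrained acceptor stem pairs for requested wobble count")
        chosen = rng.choice(len(candidates), size=wobble_count, replace=False)
        for idx in sorted(int(x) for x in chosen):
            i, j = candidates[idx]
            x = seq[i]
            if x == "G":
                seq[j] = "T"
            elif x == "C":
                seq[i] = "T"  # T-G
            elif x == "A":
                seq[i] = "G"  # G-T
            else:  # x == "T"
                seq[j] = "G"
            planted_wobble += 1

    for i in range(L):
        if seq[i] is None:
            seq[i] = str(rng.choice(_LOOP_ALPHABET))

    # Block stem extensions so the planted fold is the unique maximum:
    # a longer acceptor or TpsiC stem would need the boundary position to
    # pair, so rewrite that (loop-alphabet) base to a non-pairing choice.
    protected = {i for ij in stems for i in ij}
    protected |= set(range(anti_pos, anti_pos + 3))
    protected |= set(fixed)

    def block(pos: int, partner: int) -> None:
        if pos in protected or not (0 <= pos < L and 0 <= partner < L):
            return
        if (seq[pos], seq[partner]) in {("A", "T"), ("T", "A"), ("G", "C"),
                                        ("C", "G"), ("G", "T"), ("T", "G")}:
            seq[pos] = "C" if seq[partner] in ("T", "A") else "A"

    block(a, L - 1 - a)  # acceptor stem extension
    if t:
        block(tstart - 1, tstart + 2 * t + tloop)  # TpsiC stem extension
    if d:
        block(dstart - 1, dstart + 2 * d + dloop)  # DHU stem extension

    return PlantedTrna(
        seq="".join(seq),
        anticodon=anticodon.upper().replace("U", "T"),
        acceptor_len=a,
        dhu_len=d,
        anticodon_len=c,
        tpsic_len=t,
        wobble_count=planted_wobble,
        arm_starts={
            "dhu": dstart if d else None,
            "anticodon": ac5_start,
            "tpsic": tstart if t else None,
            "anticodon_pos": anti_pos,
        },
    )


# ---------------------------------------------------------------------------
# Whole-genome generator
# ---------------------------------------------------------------------------


@dataclass
class GenomeSpec:
    """Layout and statistical targets for a synthetic mitogenome."""

    length: int
    # rows: (name, ftype, strand, start, end, anticodon, start_codon, stop_codon)
    layout: list[tuple]
    codon_weights: Mapping[str, float]
    at_noncoding: float = 0.81
    at_rrna: float = 0.8528
    at_control: float = 0.7425
    taxon: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        for row in self.layout:
            name, ftype, strand, start, end = row[:5]
            if not (1 <= start <= self.length and 1 <= end <= self.length):
                raise ValueError(f"{name}: coordinates outside genome")
        total = sum(w for w in self.codon_weights.values())
        if total <= 0:
            raise ValueError("codon weights must have positive total")


def lactinea_like_spec(seed: int = 0) -> GenomeSpec:
    """The default study-scale spec: the published *A. lactinea* layout
    (coordinates, strands, anticodons, start/stop codons) with codon
    weights from the published usage counts and the published A+T
    targets for the noncoding classes."""
    return GenomeSpec(
        length=reference.GENOME_LENGTH,
        layout=list(reference.FEATURE_ROWS),
        codon_weights=dict(reference.CODON_COUNTS),
        at_noncoding=0.81,
        at_rrna=0.8528,
        at_control=0.7425,
        taxon="synthetic-lactinea",
        seed=seed,
    )


@dataclass
class Manifest:
    """Ground truth for one generated genome, recomputable from its files."""

    genome_length: int
    taxon: str
    seed: int
    spacers: list[tuple[str, str, int]]
    overlaps: list[tuple[str, str, int]]
    gene_order: list[tuple[str, str]]
    control_length: Optional[int]
    control_flanks: Optional[tuple[str, str]]
    codon_counts: dict[str, int]
    codon_counts_by_strand: dict[str, dict[str, int]]
    start_stop: dict[str, tuple[str, str]]
    trna_arms: dict[str, tuple[int, int, int, int]]
    trna_wobble: dict[str, int]
    at_targets: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=list)


_SENSE = sorted(INVERTEBRATE_MITO.forward)


def _cds_to_h(strand: str, start: int, end: int, k: int) -> int:
    """0-based H-strand index of coding-strand position k (0-based)."""
    return (start - 1 + k) if strand == "H" else (end - 1 - k)


def _read_cds_base(seq, strand, start, end, k):
    b = seq[_cds_to_h(strand, start, end, k)]
    if b is None:
        return None
    return b if strand == "H" else _COMP[b]


def _write_cds_base(seq, strand, start, end, k, base) -> None:
    seq[_cds_to_h(strand, start, end, k)] = base if strand == "H" else _COMP[base]


def generate_mitogenome(
    spec: GenomeSpec, seed: Optional[int] = None
) -> tuple[Mitogenome, Manifest]:
    """Generate a mitogenome realizing a :class:`GenomeSpec`.

    Order of construction: PCG start/stop codons are pinned first, tRNAs
    are built by the cloverleaf constructor (respecting any positions
    already pinned where genes overlap), PCG bodies are then filled
    codon-by-codon from the codon-weight profile (sense codons only,
    honoring pinned positions), and remaining positions (rRNA, control
    region, spacers) are sampled i.i.d. at their A+T targets.  The
    manifest records the realized codon counts, planted folds and the
    geometric ground truth.  Deterministic for a given seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = spec.length
    seq: list[Optional[str]] = [None] * L

    pcg_rows = [r for r in spec.layout if r[1] == "PCG"]
    trna_rows = [r for r in spec.layout if r[1] == "tRNA"]

    # 1) pin start and stop codons
    for name, _, strand, start, end, _, start_codon, stop_codon in pcg_rows:
        clen = end - start + 1
        for k, b in enumerate(start_codon):
            _write_cds_base(seq, strand, start, end, k, b)
        for k, b in enumerate(stop_codon):
            _write_cds_base(seq, strand, start, end, clen - len(stop_codon) + k, b)

    # 2) tRNAs with planted cloverleafs
    trna_arms: dict[str, tuple[int, int, int, int]] = {}
    trna_wobble: dict[str, int] = {}
    for name, _, strand, start, end, anticodon, _, _ in trna_rows:
        tlen = end - start + 1
        fixed = {}
        for k in range(tlen):
            b = _read_cds_base(seq, strand, start, end, k)
            if b is not None:
                fixed[k] = b
        arms = (7, 4, 5, 4)
        planted = generate_trna(
            arms, wobble_count=0, rng=rng, anticodon=anticodon, length=tlen, fixed=fixed
        )
        for k, b in enumerate(planted.seq):
            if _read_cds_base(seq, strand, start, end, k) is None:
                _write_cds_base(seq, strand, start, end, k, b)
        trna_arms[name] = arms
        trna_wobble[name] = planted.wobble_count

    # 3) PCG bodies from the codon profile
    weights = {c: float(spec.codon_weights.get(c, 0.0)) for c in _SENSE}
    wsum = sum(weights.values())
    probs = np.array([weights[c] / wsum for c in _SENSE])
    codon_counts: Counter = Counter()
    by_strand = {"H": Counter(), "L": Counter()}
    start_stop: dict[str, tuple[str, str]] = {}
    for name, _, strand, start, end, _, start_codon, stop_codon in pcg_rows:
        clen = end - start + 1
        n_triplets = clen // 3
        has_complete_stop = clen % 3 == 0
        body = range(1, n_triplets - 1 if has_complete_stop else n_triplets)
        for ci in body:
            pinned = [
                _read_cds_base(seq, strand, start, end, 3 * ci + k) for k in range(3)
            ]
            if all(b is not None for b in pinned):
                codon = "".join(pinned)
            else:
                ok = [
                    idx
                    for idx, c in enumerate(_SENSE)
                    if all(p is None or c[k] == p for k, p in enumerate(pinned))
                ]
                if not ok:
                    codon = "".join(p if p is not None else "A" for p in pinned)
                else:
                    p_ok = probs[ok]
                    if p_ok.sum() == 0:
                        p_ok = np.ones(len(ok))
                    codon = _SENSE[int(rng.choice(ok, p=p_ok / p_ok.sum()))]
                for k in range(3):
                    if pinned[k] is None:
                        _write_cds_base(seq, strand, start, end, 3 * ci + k, codon[k])
            if codon not in INVERTEBRATE_MITO.stops:
                codon_counts[codon] += 1
                by_strand[strand][codon] += 1
        # the start codon is retained in usage counts
        codon_counts[start_codon] += 1
        by_strand[strand][start_codon] += 1
        start_stop[name] = (start_codon, stop_codon)

    # 4) noncoding fill at per-class A+T targets
    targets = {"rRNA": spec.at_rrna, "control": spec.at_control}
    class_of = [None] * L
    for row in spec.layout:
        name, ftype, strand, start, end = row[:5]
        if ftype in targets:
            if start <= end:
                rngspan = range(start - 1, end)
            else:
                rngspan = list(range(start - 1, L)) + list(range(0, end))
            for i in rngspan:
                if class_of[i] is None:
                    class_of[i] = ftype
    prob_cache = {
        "rRNA": [base_probs(spec.at_rrna)[b] for b in _BASES],
        "control": [base_probs(spec.at_control)[b] for b in _BASES],
        None: [base_probs(spec.at_noncoding)[b] for b in _BASES],
    }
    for i in range(L):
        if seq[i] is None:
            seq[i] = str(rng.choice(_BASES, p=prob_cache[class_of[i]]))

    features = [
        Feature(name=r[0], ftype=r[1], strand=r[2], start=r[3], end=r[4], anticodon=r[5])
        for r in spec.layout
    ]
    genome = Mitogenome(seq="".join(seq), features=features, taxon=spec.taxon)

    manifest = Manifest(
        genome_length=L,
        taxon=spec.taxon,
        seed=int(spec.seed if seed is None else seed),
        spacers=_planned_gaps(spec, positive=True),
        overlaps=_planned_gaps(spec, positive=False),
        gene_order=[(r[0], r[2]) for r in sorted(spec.layout, key=lambda r: r[3])],
        control_length=next(
            (r[4] - r[3] + 1 for r in spec.layout if r[1] == "control"), None
        ),
        control_flanks=_control_flanks(spec),
        codon_counts=dict(codon_counts),
        codon_counts_by_strand={s: dict(c) for s, c in by_strand.items()},
        start_stop=start_stop,
        trna_arms=trna_arms,
        trna_wobble=trna_wobble,
        at_targets={
            "noncoding": spec.at_noncoding,
            "rRNA": spec.at_rrna,
            "control": spec.at_control,
        },
    )
    return genome, manifest


def _planned_gaps(spec: GenomeSpec, positive: bool) -> list[tuple[str, str, int]]:
    rows = sorted(spec.layout, key=lambda r: (r[3], r[4], r[0]))
    out = []
    for prev, nxt in zip(rows, rows[1:] + rows[:1]):
        if nxt is rows[0]:
            gap = nxt[3] + spec.length - prev[4] - 1
        else:
            gap = nxt[3] - prev[4] - 1
        if positive and gap > 0:
            out.append((prev[0], nxt[0], gap))
        elif not positive and gap < 0:
            out.append((prev[0], nxt[0], -gap))
    return out


def _control_flanks(spec: GenomeSpec) -> Optional[tuple[str, str]]:
    rows = sorted(spec.layout, key=lambda r: r[3])
    for i, r in enumerate(rows):
        if r[1] == "control":
            return (rows[i - 1][0], rows[(i + 1) % len(rows)][0])
    return None


# ---------------------------------------------------------------------------
# Alignment simulator (Jukes-Cantor along a tree)
# ---------------------------------------------------------------------------


def expected_jc_p_distance(t: float) -> float:
    """Expected proportion of differing sites after path length t under JC."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


def simulate_jc_alignment(
    newick: str, length: int, seed: int
) -> dict[str, str]:
    """Evolve one alignment of ``length`` sites on a newick tree under
    Jukes-Cantor (site-independent, no indels)."""
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    tree = dendropy.Tree.get(data=newick, schema="newick")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    out: dict[str, str] = {}

    def evolve(parent_seq, node):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            keep = rng.random(length) < np.exp(-4.0 * t / 3.0)
            child_seq = np.where(keep, parent_seq, rng.integers(0, 4, size=length))
            if child.is_leaf():
                out[child.taxon.label.replace(" ", "_")] = "".join(
                    _BASES[i] for i in child_seq
                )
            else:
                evolve(child_seq, child)

    evolve(root_seq, tree.seed_node)
    if tree.seed_node.is_leaf():
        out[tree.seed_node.taxon.label.replace(" ", "_")] = "".join(
            _BASES[i] for i in root_seq
        )
    return out


def generate_alignment_set(
    newick: str,
    gene_lengths: Mapping[str, int],
    seed: int,
) -> tuple[dict[str, dict[str, str]], dict]:
    """Per-gene alignments evolved on one tree; manifest carries the truth.

    Each gene gets an independent JC simulation (seed derived from the
    master seed and the gene's rank) on the same tree.
    """
    if not gene_lengths:
        raise ValueError("no genes requested")
    alignments = {}
    for i, gene in enumerate(sorted(gene_lengths)):
        alignments[gene] = simulate_jc_alignment(
            newick, gene_lengths[gene], seed=(seed * 10007 + i) % (2**31 - 1)
        )
    manifest = {"true_tree": newick, "seed": seed, "gene_lengths": dict(gene_lengths)}
    return alignments, manifest
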