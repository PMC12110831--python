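"""Circular-genome geometry: spacers, overlaps, gene order, control region.

All accounting walks the features sorted by linearized start and uses the
single circular successor relation, mixing strands in one ledger (the way
a mitogenome gene table is conventionally printed).  For consecutive
features *p*, *q* the signed gap is ``q.start - p.end - 1``: positive is
an intergenic spacer, negative an overlap of that many bp, zero means
abutting genes.  The junction across the origin is included, so on a
complete annotation the conservation law

    sum(feature lengths) - sum(overlaps) + sum(spacers) == genome length

holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from mitochar.model import Feature, Mitogenome, feature_length


@dataclass(frozen=True)
class SpacerRecord:
    upstream: str
    downstream: str
    length: int


@dataclass(frozen=True)
class OverlapRecord:
    first: str
    second: str
    length: int


@dataclass(frozen=True)
class TandemRepeat:
    start: int  # 1-based within the scanned region
    period: int
    copies: float
    identity: float


def _circular_gaps(g: Mitogenome) -> list[tuple[Feature, Feature, int]]:
    """(prev, next, signed gap) for every circular-successor pair."""
    feats = g.features
    if len(feats) < 2:
        raise ValueError("need at least two features for gap accounting")
    out = []
    n = g.length
    for prev, nxt in zip(feats, feats[1:]):
        if prev.end < prev.start:
            # wrapping feature linearized past the origin
            out.append((prev, nxt, nxt.start - (prev.end + n) - 1))
        else:
            out.append((prev, nxt, nxt.start - prev.end - 1))
    last, first = feats[-1], feats[0]
    if last.wraps:
        out.append((last, first, first.start - last.end - 1))
    else:
        out.append((last, first, first.start + n - last.end - 1))
    return out


def spacers_and_overlaps(
    g: Mitogenome,
) -> tuple[list[SpacerRecord], list[OverlapRecord]]:
    """Intergenic spacers and gene overlaps around the circle.

    The control region is a feature like any other, so the stretch it
    occupies is never reported as a spacer.  A feature nested entirely
    inside its predecessor is flagged with a warning; it still only
    contributes its relation to the circular successor.
    """
    spacers: list[SpacerRecord] = []
    overlaps: list[OverlapRecord] = []
    for prev, nxt, gap in _circular_gaps(g):
        if not prev.wraps and not nxt.wraps and nxt.end < prev.end and nxt.start >= prev.start:
            warnings.warn(f"feature {nxt.name} is nested inside {prev.name}")
        if gap > 0:
            spacers.append(SpacerRecord(prev.name, nxt.name, gap))
        elif gap < 0:
            overlaps.append(OverlapRecord(prev.name, nxt.name, -gap))
    return spacers, overlaps


def conservation_check(g: Mitogenome) -> dict:
    """Verify sum(lengths) - sum(overlaps) + sum(spacers) == genome length."""
    spacers, overlaps = spacers_and_overlaps(g)
    total_len = sum(feature_length(f, g.length) for f in g.features)
    total_sp = sum(s.length for s in spacers)
    total_ov = sum(o.length for o in overlaps)
    return {
        "feature_total": total_len,
        "spacer_total": total_sp,
        "overlap_total": total_ov,
        "genome_length": g.length,
        "balanced": total_len - total_ov + total_sp == g.length,
    }


def control_region_record(g: Mitogenome) -> tuple[int, str, str]:
    """(length, upstream neighbor, downstream neighbor) of the control region.

    Neighbors are the circularly adjacent features; on the lepidopteran
    map the control region sits between rrnS and tRNA-Met.
    """
    feats = g.features
    idx = next((i for i, f in enumerate(feats) if f.ftype == "control"), None)
    if idx is None:
        raise LookupError("no control region annotated")
    control = feats[idx]
    upstream = feats[idx - 1] if len(feats) > 1 else control
    downstream = feats[(idx + 1) % len(feats)] if len(feats) > 1 else control
    return feature_length(control, g.length), upstream.name, downstream.name


# ---------------------------------------------------------------------------
# Gene order
# ---------------------------------------------------------------------------

_AA1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}


def _normalize_name(f: Feature) -> str:
    """Canonical short label: tRNAs become trnX(anticodon), others keep name."""
    if f.ftype != "tRNA":
        return f.name
    label = f.name
    for long, short in _AA1.items():
        if long in label:
            ac = f" ({f.anticodon})" if f.anticodon else ""
            return f"trn{short}{ac}".replace(" ", "")
    return label


@dataclass(frozen=True)
class GeneOrder:
    """Circular list of (gene, strand), rotated to a canonical anchor."""

    taxon: str
    order: tuple[tuple[str, str], ...]
    anchored: bool = True

    def __eq__(self, other) -> bool:  # rotation-invariant
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return _canonical_rotation(self.order) == _canonical_rotation(other.order)

    def __hash__(self) -> int:
        return hash(_canonical_rotation(self.order))


def _canonical_rotation(order: Sequence[tuple[str, str]]) -> tuple:
    rots = [tuple(order[i:]) + tuple(order[:i]) for i in range(len(order))]
    return min(rots)


def gene_order(g: Mitogenome, anchor: str = "trnM") -> GeneOrder:
    """Gene order in circular start order, rotated so tRNA-Met leads.

    If the anchor tRNA is absent the rotation falls back to the
    lexicographically smallest label and the order is flagged
    unanchored.
    """
    if not g.features:
        raise ValueError("genome has no features")
    labels = [(_normalize_name(f), f.strand) for f in g.features]
    names = [l for l, _ in labels]
    anchored = True
    if any(n.startswith(anchor) for n in names):
        i = next(i for i, n in enumerate(names) if n.startswith(anchor))
    else:
        i = names.index(min(names))
        anchored = False
        warnings.warn(f"anchor {anchor} absent; rotated to {names[i]}")
    rotated = tuple(labels[i:] + labels[:i])
    return GeneOrder(taxon=g.taxon, order=rotated, anchored=anchored)


def _adjacency_set(order: Sequence[tuple[str, str]]) -> set:
    """Oriented adjacencies of a circular order, both readings."""
    flip = {"H": "L", "L": "H"}
    adj = set()
    n = len(order)
    for i in range(n):
        a, b = order[i], order[(i + 1) % n]
        adj.add((a, b))
        adj.add(((b[0], flip[b[1]]), (a[0], flip[a[1]])))
    return adj


def compare_orders(a: GeneOrder, b: GeneOrder) -> tuple[bool, int]:
    """(identical, breakpoint count) between two circular gene orders.

    Identity means the same circular sequence of (gene, strand) in either
    reading direction; a breakpoint is an adjacency of ``a`` absent from
    ``b``.  The circle is treated as unoriented.
    """
    names_a = {n for n, _ in a.order}
    names_b = {n for n, _ in b.order}
    if names_a != names_b:
        raise ValueError(
            f"gene sets differ: only in a: {sorted(names_a - names_b)}; "
            f"only in b: {sorted(names_b - names_a)}"
        )
    adj_b = _adjacency_set(b.order)
    n = len(a.order)
    breakpoints = sum(
        1
        for i in range(n)
        if (a.order[i], a.order[(i + 1) % n]) not in adj_b
    )
    flip = {"H": "L", "L": "H"}
    reversed_a = tuple((nm, flip[s]) for nm, s in reversed(a.order))
    identical = (
        _canonical_rotation(a.order) == _canonical_rotation(b.order)
        or _canonical_rotation(reversed_a) == _canonical_rotation(b.order)
    )
    return identical, breakpoints


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------


def find_tandem_repeats(
    region: str,
    min_period: int = 2,
    max_period: int = 50,
    min_copies: float = 2.0,
    min_identity: float = 0.8,
) -> list[TandemRepeat]:
    """Scan a region for tandem repeats by exhaustive period search.

    For every start and period the first period-length window is the
    template; successive (possibly partial) copies are appended while
    each copy's identity to the template stays at or above
    ``min_identity``.  Maximal repeats with at least ``min_copies``
    copies are reported after a redundancy filter that drops any repeat
    whose span lies within an already-reported repeat.  Defaults emulate
    a common Tandem Repeats Finder operating point.
    """
    region = region.upper()
    n = len(region)
    if not region:
        raise ValueError("empty region")
    if not (2 <= min_period <= max_period):
        raise ValueError("need 2 <= min_period <= max_period")
    if max_period > n // 2:
        max_period = n // 2
    if max_period < min_period:
        return []
    candidates: list[TandemRepeat] = []
    for period in range(min_period, max_period + 1):
        for start in range(0, n - 2 * period + 1):
            template = region[start : start + period]
            end = start + period
            matches = 0
            compared = 0
            while end < n:
                chunk = region[end : end + period]
                m = sum(1 for x, y in zip(chunk, template) if x == y)
                if m / len(chunk) < min_identity:
                    break
                matches += m
                compared += len(chunk)
                end += len(chunk)
            copies = (end - start) / period
            if copies >= min_copies and compared:
                rec = TandemRepeat(
                    start=start + 1,
                    period=period,
                    copies=round(copies, 2),
                    identity=matches / compared,
                )
                candidates.append((start + 1, end, rec))
    # redundancy filter: keep repeats whose span is not inside a kept one
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[2].period, c[0]))
    kept: list[tuple[int, int, TandemRepeat]] = []
    for cand in candidates:
        if not any(cand[0] >= k[0] and cand[1] <= k[1] for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: (c[0], c[2].period))
    return [c[2] for c in kept]
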