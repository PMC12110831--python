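"""Constrained cloverleaf folding of mitochondrial tRNA genes.

The fold is found by exhaustive search over an anchored four-arm
template rather than free-energy minimization: the anticodon triplet
(known from the annotation) must sit centered in the anticodon loop,
and the arms are bounded by canonical size ranges

    acceptor stem   6-8 bp   (+ 0-1 nt unpaired 3' tail)
    DHU arm         stem 0-4 bp, loop 3-10 nt   (stem 0 = arm missing)
    anticodon arm   stem 3-6 bp, loop 5/7/9 nt centered on the anticodon
    TpsiC arm       stem 0-5 bp, loop 3-9 nt    (stem 0 = arm missing)

with 1-3 nt between acceptor and DHU arm, 0-2 nt before the anticodon
stem and a 0-9 nt variable loop before the TpsiC arm.  Stems admit
Watson-Crick pairs plus the G-U (here G-T) wobble pair; a stem position
that cannot pair invalidates that template.  Among feasible templates
the fold maximizing total paired bases wins, with ties broken by more
Watson-Crick pairs, longer acceptor stem, then the 5'-most DHU arm.
Scoring is a pure pair count — adequate for the descriptive use the
structure is put to (arm inventory, missing arms, wobble-pair counts)
and exactly reproducible.

Mitochondrial tRNAs frequently deviate from the canonical cloverleaf
(e.g. serine tRNAs lacking the DHU arm); such arms are reported missing,
and a sequence admitting no feasible template at all is returned as an
unfoldable diagnostic result, not an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

ACCEPTOR_RANGE = (6, 8)
TAIL_RANGE = (0, 1)
DHU_STEM_RANGE = (0, 4)
DHU_LOOP_RANGE = (3, 10)
AC_STEM_RANGE = (3, 6)
AC_LOOP_SIZES = (5, 7, 9)
TPSIC_STEM_RANGE = (0, 5)
TPSIC_LOOP_RANGE = (3, 9)
SPACER1_RANGE = (1, 3)
SPACER2_RANGE = (0, 2)
VARLOOP_RANGE = (0, 9)


def _can_pair(x: str, y: str) -> bool:
    return (x, y) in _PAIRS


@dataclass(frozen=True)
class Arm:
    """One stem-loop: 0-based stem ranges and loop range, stem length in bp."""

    stem5_start: int
    stem_len: int
    loop_start: int
    loop_len: int
    stem3_start: int


@dataclass
class CloverleafFold:
    seq: str
    anticodon: str
    foldable: bool
    acceptor_len: int = 0
    tail: int = 0
    dhu_arm: Optional[Arm] = None
    anticodon_arm: Optional[Arm] = None
    tpsic_arm: Optional[Arm] = None
    pairs: list[tuple[int, int]] = field(default_factory=list)
    wobble_pairs: int = 0
    wc_pairs: int = 0
    missing_arms: list[str] = field(default_factory=list)
    diagnostics: str = ""

    @property
    def paired_bases(self) -> int:
        return 2 * len(self.pairs)

    @property
    def unpaired(self) -> list[int]:
        used = {i for p in self.pairs for i in p}
        return [i for i in range(len(self.seq)) if i not in used]

    def dot_bracket(self) -> str:
        s = ["."] * len(self.seq)
        for i, j in self.pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)


def _stem_pairs(seq: str, start5: int, start3_last: int, length: int):
    """Pair list for a stem, or None if some position cannot pair.

    Position ``start5 + i`` pairs with ``start3_last - i``.
    """
    pairs = []
    for i in range(length):
        a, b = start5 + i, start3_last - i
        if not _can_pair(seq[a], seq[b]):
            return None
        pairs.append((a, b))
    return pairs


def _wc_count(seq: str, pairs) -> int:
    return sum(1 for i, j in pairs if (seq[i], seq[j]) in _WC)


def fold_trna(seq: str, anticodon: str) -> CloverleafFold:
    """Fold a tRNA gene sequence (gene orientation, DNA alphabet).

    Requires 55 <= len(seq) <= 75 and the anticodon to occur in the
    sequence (every occurrence is tried as the anchor).  Returns an
    unfoldable diagnostic result when no template fits.
    """
    seq = seq.upper().replace("U", "T")
    anticodon = anticodon.upper().replace("U", "T")
    L = len(seq)
    if not (55 <= L <= 75):
        raise ValueError(f"tRNA length {L} outside the 55-75 nt template range")
    anchors = [
        i for i in range(L - 2) if seq[i : i + 3] == anticodon
    ]
    if not anchors:
        raise ValueError(f"anticodon {anticodon} does not occur in the sequence")

    best = None  # (key tuple, fold parts)
    for p in anchors:
        for cl in AC_LOOP_SIZES:
            loop_start = p - (cl - 3) // 2
            for c in range(AC_STEM_RANGE[0], AC_STEM_RANGE[1] + 1):
                s5 = loop_start - c
                s3 = loop_start + cl
                if s5 < 0 or s3 + c > L:
                    continue
                ac_pairs = _stem_pairs(seq, s5, s3 + c - 1, c)
                if ac_pairs is None:
                    continue
                for a in range(ACCEPTOR_RANGE[0], ACCEPTOR_RANGE[1] + 1):
                    for tail in range(TAIL_RANGE[0], TAIL_RANGE[1] + 1):
                        acc3 = L - tail - a
                        if acc3 <= s3 + c:
                            continue
                        acc_pairs = _stem_pairs(seq, 0, L - tail - 1, a)
                        if acc_pairs is None:
                            continue
                        left = _best_left(seq, a, s5)
                        if left is None:
                            continue
                        right = _best_right(seq, s3 + c, acc3)
                        if right is None:
                            continue
                        for d, (d_wc, d_start, d_loop, d_s1) in left.items():
                            for t, (t_wc, t_start, t_loop, t_v) in right.items():
                                total = a + c + d + t
                                wc = (
                                    _wc_count(seq, acc_pairs)
                                    + _wc_count(seq, ac_pairs)
                                    + d_wc
                                    + t_wc
                                )
                                key = (total, wc, a, -(d_start if d else L))
                                cand = (key, p, cl, c, a, tail, d, d_start, d_loop, t, t_start, t_loop)
                                if best is None or cand[0] > best[0] or (
                                    cand[0] == best[0] and cand[1:] < best[1:]
                                ):
                                    best = cand
    if best is None:
        return CloverleafFold(
            seq=seq,
            anticodon=anticodon,
            foldable=False,
            diagnostics="no feasible cloverleaf template "
            "(no arm assignment with fully paired stems fits the length)",
        )
    return _build_fold(seq, anticodon, best)


def _best_left(seq: str, a: int, ac_stem5: int):
    """Best DHU-arm assignment per stem length for the segment between
    acceptor 5' arm and anticodon stem.  Returns {d: (wc, dhu_start,
    dhu_loop, s1)} maximal per d, or None if the segment is infeasible."""
    seg_len = ac_stem5 - a
    if seg_len < 0:
        return None
    out: dict[int, tuple] = {}
    # missing DHU arm: whole segment unpaired (bounded to a plausible size)
    if 0 <= seg_len <= SPACER1_RANGE[1] + DHU_LOOP_RANGE[1] + SPACER2_RANGE[1]:
        out[0] = (0, 0, 0, 0)
    for d in range(1, DHU_STEM_RANGE[1] + 1):
        best = None
        for s1 in range(SPACER1_RANGE[0], SPACER1_RANGE[1] + 1):
            for s2 in range(SPACER2_RANGE[0], SPACER2_RANGE[1] + 1):
                dloop = seg_len - s1 - s2 - 2 * d
                if not (DHU_LOOP_RANGE[0] <= dloop <= DHU_LOOP_RANGE[1]):
                    continue
                dstart = a + s1
                pairs = _stem_pairs(seq, dstart, dstart + 2 * d + dloop - 1, d)
                if pairs is None:
                    continue
                wc = _wc_count(seq, pairs)
                cand = (wc, -dstart, dloop, s1)
                if best is None or cand > best:
                    best = cand
        if best is not None:
            out[d] = (best[0], -best[1], best[2], best[3])
    return out if out else None


def _best_right(seq: str, start: int, acc3: int):
    """Best TpsiC-arm assignment per stem length for the segment between
    anticodon stem 3' end and acceptor 3' arm."""
    seg_len = acc3 - start
    if seg_len < 0:
        return None
    out: dict[int, tuple] = {}
    if 0 <= seg_len <= VARLOOP_RANGE[1] + TPSIC_LOOP_RANGE[1]:
        out[0] = (0, 0, 0, 0)
    for t in range(1, TPSIC_STEM_RANGE[1] + 1):
        best = None
        for v in range(VARLOOP_RANGE[0], VARLOOP_RANGE[1] + 1):
            tloop = seg_len - v - 2 * t
            if not (TPSIC_LOOP_RANGE[0] <= tloop <= TPSIC_LOOP_RANGE[1]):
                continue
            tstart = start + v
            pairs = _stem_pairs(seq, tstart, tstart + 2 * t + tloop - 1, t)
            if pairs is None:
                continue
            wc = _wc_count(seq, pairs)
            cand = (wc, -tstart, tloop, v)
            if best is None or cand > best:
                best = cand
        if best is not None:
            out[t] = (best[0], -best[1], best[2], best[3])
    return out if out else None


def _build_fold(seq: str, anticodon: str, best) -> CloverleafFold:
    (_, p, cl, c, a, tail, d, d_start, d_loop, t, t_start, t_loop) = best
    L = len(seq)
    loop_start = p - (cl - 3) // 2
    pairs = []
    pairs += _stem_pairs(seq, 0, L - tail - 1, a)
    ac5 = loop_start - c
    pairs += _stem_pairs(seq, ac5, loop_start + cl + c - 1, c)
    missing = []
    dhu = tpsic = None
    if d:
        pairs += _stem_pairs(seq, d_start, d_start + 2 * d + d_loop - 1, d)
        dhu = Arm(d_start, d, d_start + d, d_loop, d_start + d + d_loop)
    else:
        missing.append("DHU")
    if t:
        pairs += _stem_pairs(seq, t_start, t_start + 2 * t + t_loop - 1, t)
        tpsic = Arm(t_start, t, t_start + t, t_loop, t_start + t + t_loop)
    else:
        missing.append("TpsiC")
    wobble = sum(1 for i, j in pairs if {seq[i], seq[j]} == {"G", "T"})
    return CloverleafFold(
        seq=seq,
        anticodon=anticodon,
        foldable=True,
        acceptor_len=a,
        tail=tail,
        dhu_arm=dhu,
        anticodon_arm=Arm(ac5, c, loop_start, cl, loop_start + cl),
        tpsic_arm=tpsic,
        pairs=sorted(pairs),
        wobble_pairs=wobble,
        wc_pairs=_wc_count(seq, pairs),
        missing_arms=missing,
    )


@dataclass
class FoldSummary:
    n_folds: int
    total_wobble: int
    non_canonical: int  # sequences admitting no cloverleaf template
    missing_dhu: list[str]
    missing_tpsic: list[str]
    acceptor_range: tuple[int, int]
    anticodon_loop_range: tuple[int, int]


def summarize_folds(folds: list[CloverleafFold], names: Optional[list[str]] = None) -> FoldSummary:
    """Aggregate a set of folds: wobble totals, non-canonical count, arm ranges."""
    if not folds:
        raise ValueError("no folds to summarize")
    names = names or [f"tRNA{i + 1}" for i in range(len(folds))]
    ok = [f for f in folds if f.foldable]
    acc = [f.acceptor_len for f in ok] or [0]
    loops = [f.anticodon_arm.loop_len for f in ok if f.anticodon_arm] or [0]
    return FoldSummary(
        n_folds=len(folds),
        total_wobble=sum(f.wobble_pairs for f in ok),
        non_canonical=sum(1 for f in folds if not f.foldable),
        missing_dhu=[n for n, f in zip(names, folds) if f.foldable and "DHU" in f.missing_arms],
        missing_tpsic=[n for n, f in zip(names, folds) if f.foldable and "TpsiC" in f.missing_arms],
        acceptor_range=(min(acc), max(acc)),
        anticodon_loop_range=(min(loops), max(loops)),
    )
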