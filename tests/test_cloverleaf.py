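"""Cloverleaf folding: planted-structure recovery and oracle equivalence."""

import numpy as np
import pytest

from mitochar.cloverleaf import fold_trna, summarize_folds
from mitochar.simulate import generate_trna

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def naive_max_paired(seq: str, anticodon: str) -> int:
    """Independent brute force: enumerate the full template grid without any
    decomposition and return the maximum number of paired stem positions."""

    def stem_ok(s5, last3, ln):
        return all((seq[s5 + i], seq[last3 - i]) in _PAIRS for i in range(ln))

    L = len(seq)
    best = -1
    anchors = [i for i in range(L - 2) if seq[i : i + 3] == anticodon]
    for p in anchors:
        for cl in (5, 7, 9):
            loop_start = p - (cl - 3) // 2
            for c in range(3, 7):
                s5, s3 = loop_start - c, loop_start + cl
                if s5 < 0 or s3 + c > L or not stem_ok(s5, s3 + c - 1, c):
                    continue
                for a in range(6, 9):
                    for tail in (0, 1):
                        acc3 = L - tail - a
                        if acc3 <= s3 + c or not stem_ok(0, L - tail - 1, a):
                            continue
                        left = s5 - a
                        right = acc3 - (s3 + c)
                        dmax = -1
                        if 0 <= left <= 3 + 10 + 2:
                            dmax = 0
                        for d in range(1, 5):
                            for s1 in range(1, 4):
                                for s2 in range(0, 3):
                                    dloop = left - s1 - s2 - 2 * d
                                    if not 3 <= dloop <= 10:
                                        continue
                                    ds = a + s1
                                    if stem_ok(ds, ds + 2 * d + dloop - 1, d):
                                        dmax = max(dmax, d)
                        tmax = -1
                        if 0 <= right <= 9 + 9:
                            tmax = 0
                        for t in range(1, 6):
                            for v in range(0, 10):
                                tloop = right - v - 2 * t
                                if not 3 <= tloop <= 9:
                                    continue
                                ts = s3 + c + v
                                if stem_ok(ts, ts + 2 * t + tloop - 1, t):
                                    tmax = max(tmax, t)
                        if dmax >= 0 and tmax >= 0:
                            best = max(best, 2 * (a + c + dmax + tmax))
    return best


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_fold_equals_bruteforce_maximum(seed):
    """The decomposed search attains the brute-force maximal pairing."""
    rng = np.random.default_rng(seed)
    planted = generate_trna((7, 4, 5, 4), wobble_count=0, rng=rng,
                            anticodon="CAT", length=66)
    fold = fold_trna(planted.seq, planted.anticodon)
    assert fold.foldable
    assert fold.paired_bases == naive_max_paired(planted.seq, planted.anticodon)


@pytest.mark.parametrize(
    "arms, wobble, anticodon, length",
    [
        ((7, 4, 5, 4), 0, "CAT", 66),
        ((7, 4, 5, 5), 0, "TAC", 68),
        ((6, 3, 4, 4), 0, "GTT", 64),
        ((8, 4, 6, 5), 0, "GTG", 70),
        ((7, 3, 5, 4), 2, "GAA", 67),
        ((7, 4, 5, 4), 3, "TTC", 66),
    ],
)
def test_planted_fold_recovered_exactly(arms, wobble, anticodon, length, rng):
    planted = generate_trna(arms, wobble_count=wobble, rng=rng,
                            anticodon=anticodon, length=length)
    fold = fold_trna(planted.seq, planted.anticodon)
    assert fold.foldable
    got = (
        fold.acceptor_len,
        fold.dhu_arm.stem_len if fold.dhu_arm else 0,
        fold.anticodon_arm.stem_len,
        fold.tpsic_arm.stem_len if fold.tpsic_arm else 0,
    )
    assert got == arms
    assert fold.wobble_pairs == wobble
    assert fold.missing_arms == []


def test_single_substitution_creates_one_wobble(rng):
    """Converting one acceptor A-T pair to G-T adds exactly one wobble pair."""
    planted = generate_trna((7, 4, 5, 4), wobble_count=0, rng=rng,
                            anticodon="CAT", length=66)
    seq = planted.seq
    # find an acceptor-stem A-T pair (position i pairs with L-1-i) and make it G-T
    L = len(seq)
    for i in range(7):
        if seq[i] == "A" and seq[L - 1 - i] == "T":
            mutated = seq[:i] + "G" + seq[i + 1 :]
            break
    else:
        pytest.skip("no A-T acceptor pair in this draw")
    fold = fold_trna(mutated, planted.anticodon)
    assert fold.foldable and fold.wobble_pairs == 1


def test_missing_dhu_arm_detected(rng):
    planted = generate_trna((7, 0, 5, 4), wobble_count=0, rng=rng,
                            anticodon="TCG", length=63)
    fold = fold_trna(planted.seq, planted.anticodon)
    assert fold.foldable
    assert fold.missing_arms == ["DHU"]
    assert fold.dhu_arm is None


def test_missing_tpsic_arm_detected(rng):
    planted = generate_trna((7, 3, 4, 0), wobble_count=0, rng=rng,
                            anticodon="GAA", length=62)
    fold = fold_trna(planted.seq, planted.anticodon)
    assert fold.foldable
    assert fold.missing_arms == ["TpsiC"]


def test_unfoldable_sequence_returns_diagnostic():
    # poly-A cannot pair at all, so no template is feasible
    seq = "A" * 60
    fold = fold_trna(seq, "AAA")
    assert not fold.foldable
    assert fold.diagnostics


def test_fold_requires_anchor_and_plausible_length():
    with pytest.raises(ValueError, match="anticodon"):
        fold_trna("ACGT" * 16, "AAA")
    with pytest.raises(ValueError, match="length"):
        fold_trna("ACGTACGT", "ACG")


def test_fold_invariants(rng):
    planted = generate_trna((7, 4, 5, 4), wobble_count=1, rng=rng,
                            anticodon="TGC", length=66)
    fold = fold_trna(planted.seq, planted.anticodon)
    # every base in at most one pair; pairs are nested (non-crossing)
    flat = [i for p in fold.pairs for i in p]
    assert len(flat) == len(set(flat))
    for i, j in fold.pairs:
        for k, l in fold.pairs:
            assert not (i < k < j < l)
    # anticodon centered in its loop
    arm = fold.anticodon_arm
    anti_start = arm.loop_start + (arm.loop_len - 3) // 2
    assert fold.seq[anti_start : anti_start + 3] == planted.anticodon
    # dot-bracket is balanced
    db = fold.dot_bracket()
    assert db.count("(") == db.count(")") == len(fold.pairs)


def test_summarize_folds(rng):
    folds = [
        generate_trna((7, 4, 5, 4), 0, rng, anticodon="CAT", length=66),
        generate_trna((7, 0, 5, 4), 0, rng, anticodon="TCG", length=63),
        generate_trna((7, 4, 5, 4), 2, rng, anticodon="GAA", length=66),
    ]
    results = [fold_trna(p.seq, p.anticodon) for p in folds]
    results.append(fold_trna("A" * 60, "AAA"))  # unfoldable member
    summary = summarize_folds(results, ["a", "b", "c", "bad"])
    assert summary.n_folds == 4
    assert summary.non_canonical == 1
    assert summary.total_wobble == 2
    assert summary.missing_dhu == ["b"]


def test_genome_embedded_trnas_all_fold(synthetic_genome):
    from mitochar.model import extract_feature_seq

    g, man = synthetic_genome
    folds = []
    for f in g.trnas:
        fold = fold_trna(extract_feature_seq(g, f), f.anticodon)
        assert fold.foldable, f.name
        folds.append(fold)
    summary = summarize_folds(folds, [f.name for f in g.trnas])
    assert summary.non_canonical == 0
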