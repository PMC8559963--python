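"""PWM scanning: scores, exact p-values, BH q-values, threshold filter."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nlrkit.model import AA_ALPHABET, MotifHit, ProteinRecord
from nlrkit.motifs import (
    PWM,
    bh_qvalues,
    filter_motif_hits,
    scan_records,
    score_pvalue_table,
    score_sequence,
)

GRAN = 1e-3


def random_pwm(rng, length, alphabet=AA_ALPHABET, motif_id="m"):
    return PWM(motif_id, rng.dirichlet(np.ones(len(alphabet)), size=length),
               alphabet=alphabet)


# ------------------------------------------------------------- scoring

def test_single_letter_motif_closed_form():
    pwm = PWM("m", np.array([[1.0] + [0.0] * 19]))
    wins = score_sequence(pwm, ProteinRecord("A", "AAA"))
    assert len(wins) == 3
    # log2(20 * (1 + pseudocount)) ~ 4.322 bits
    for w in wins:
        assert w.score == pytest.approx(np.log2(20 * (1 + 1e-4)), abs=GRAN)


def test_low_probability_letters_score_negative():
    pwm = PWM("m", np.array([[1.0] + [0.0] * 19] * 2))
    wins = score_sequence(pwm, ProteinRecord("A", "CCCCC"))
    assert wins and all(w.score < 0 for w in wins)


def test_sequence_shorter_than_motif_yields_empty():
    pwm = PWM("m", np.full((5, 20), 0.05))
    assert score_sequence(pwm, ProteinRecord("A", "MKV")) == []


def test_unknown_letter_scores_as_background():
    pwm = PWM("m", np.array([[1.0] + [0.0] * 19]))
    (win,) = score_sequence(pwm, ProteinRecord("A", "X"))
    assert win.score == pytest.approx(0.0, abs=GRAN)


def test_window_scores_match_per_position_hand_summation(rng):
    """Brute-force oracle: each window score equals the sum of that
    window's per-position log-odds (up to the 1/1000-bit score grid)."""
    seq = "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, 200)])
    rec = ProteinRecord("A", seq)
    for L in (1, 3, 8):
        pwm = random_pwm(rng, L)
        logodds = np.log2((pwm.matrix + pwm.pseudocount) / pwm.background)
        index = {a: i for i, a in enumerate(AA_ALPHABET)}
        wins = score_sequence(pwm, rec)
        assert len(wins) == 200 - L + 1
        for w in wins:
            hand = sum(logodds[j, index[seq[w.position - 1 + j]]] for j in range(L))
            assert w.score == pytest.approx(hand, abs=L * GRAN)


# ------------------------------------------------------------ p-values

def test_pvalue_single_letter_enumeration():
    # A scores highest; P(score >= max) over random letters = 1/20
    pwm = PWM("m", np.array([[1.0] + [0.0] * 19]))
    table = score_pvalue_table(pwm)
    (win,) = score_sequence(pwm, ProteinRecord("A", "A"))
    assert table.pvalue(win.score) == pytest.approx(0.05)
    assert table.pvalue(-1e9) == 1.0


@pytest.mark.parametrize("length,alphabet", [(2, "ACDE"), (3, "ACDE"), (3, "ACDEF")])
def test_dp_pvalues_equal_exhaustive_enumeration(rng, length, alphabet):
    """Full word enumeration reproduces the DP survival function."""
    pwm = random_pwm(rng, length, alphabet=alphabet)
    table = score_pvalue_table(pwm)
    # independent quantization of the same log-odds definition
    q = np.rint(np.log2((pwm.matrix + pwm.pseudocount) / pwm.background) / GRAN)
    bg = pwm.background
    n = len(alphabet)
    words = list(itertools.product(range(n), repeat=length))
    scores = {sum(q[j, w[j]] for j in range(length)) for w in words}
    for s in scores:
        enum_p = sum(
            float(np.prod([bg[c] for c in w]))
            for w in words if sum(q[j, w[j]] for j in range(length)) >= s
        )
        assert table.pvalue(s * GRAN) == pytest.approx(enum_p, abs=1e-6)


def test_pvalue_at_maximum_score_is_best_word_probability(rng):
    pwm = random_pwm(rng, 2, alphabet="ACDE")
    table = score_pvalue_table(pwm)
    q = pwm.quantized_scores()
    max_score = q.max(axis=1).sum() * GRAN
    best = np.prod([pwm.background[np.argmax(q[j])] for j in range(2)])
    assert table.pvalue(max_score) == pytest.approx(best, rel=1e-9)


def test_pvalues_monotone_non_increasing_in_score(rng):
    pwm = random_pwm(rng, 3)
    table = score_pvalue_table(pwm)
    grid = np.linspace(-30, 30, 500)
    ps = [table.pvalue(s) for s in grid]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    assert ps[0] == 1.0


# ------------------------------------------------------------ BH

def test_bh_hand_computation():
    assert bh_qvalues([0.001, 0.01, 0.02, 0.05]) == pytest.approx(
        [0.004, 0.02, 0.02 * 4 / 3, 0.05])


def test_bh_single_pvalue_identity():
    assert bh_qvalues([0.5]) == [0.5]


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_qvalues([0.0, 0.5])
    with pytest.raises(ValueError):
        bh_qvalues([1.5])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30),
       st.randoms(use_true_random=False))
def test_bh_properties_and_permutation_invariance(pvals, rnd):
    q = bh_qvalues(pvals)
    assert all(qi >= pi - 1e-12 for qi, pi in zip(q, pvals))
    order = sorted(range(len(pvals)), key=lambda i: pvals[i])
    assert all(q[order[i]] <= q[order[i + 1]] + 1e-12 for i in range(len(order) - 1))
    perm = list(range(len(pvals)))
    rnd.shuffle(perm)
    q_perm = bh_qvalues([pvals[i] for i in perm])
    assert all(q_perm[j] == pytest.approx(q[perm[j]]) for j in range(len(perm)))


# ------------------------------------------------------------ filter

@pytest.mark.parametrize("motif,score,qvalue,kept,eligible", [
    (2, 61.0, 0.005, True, True),     # RNBS-D over both thresholds
    (7, 70.0, 0.005, True, False),    # MHD kept for annotation, not extraction
    (7, 85.0, 0.005, True, True),     # MHD at the strict boundary
    (8, 84.9, 0.005, True, False),    # linker just under strict cutoff
    (2, 59.9, 1e-4, False, False),    # under the score floor
    (2, 90.0, 0.011, False, False),   # over the q-value ceiling
    (2, 60.0, 0.01, True, True),      # both boundaries inclusive
])
def test_filter_thresholds(motif, score, qvalue, kept, eligible):
    hit = MotifHit("P1", motif, 10, 24, score, 1e-9, qvalue)
    out = filter_motif_hits([hit])
    assert bool(out) is kept
    if kept:
        assert out[0].extraction_ok is eligible


def test_filter_is_subset_and_idempotent(rng):
    hits = [MotifHit("P1", int(rng.integers(1, 9)), 1, 15,
                     float(rng.uniform(0, 120)), 1e-9,
                     float(rng.uniform(0, 0.05))) for _ in range(200)]
    once = filter_motif_hits(hits)
    keys = {(h.seq_id, h.motif_id, h.start, h.score, h.qvalue) for h in hits}
    assert all((h.seq_id, h.motif_id, h.start, h.score, h.qvalue) in keys for h in once)
    twice = filter_motif_hits(once)
    assert twice == once


# ------------------------------------------------------------ scanning

def test_scan_finds_planted_motif(rng):
    """A strongly informative PWM ranks its planted site first."""
    target = "MKVLWAAL"
    matrix = np.full((8, 20), 0.05 / 19)
    for j, c in enumerate(target):
        matrix[j] = (1 - 0.95) / 19
        matrix[j, AA_ALPHABET.index(c)] = 0.95
    pwm = PWM("planted", matrix)
    background = "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, 120)])
    seq = background[:50] + target + background[50:]
    hits = scan_records([pwm], [ProteinRecord("P1", seq)], report_pvalue_max=1e-4)
    assert hits
    best = max(hits, key=lambda h: h.score)
    assert best.start == 51
    assert best.matched_seq == target
    assert best.qvalue <= best.pvalue * len(seq)  # BH never exceeds Bonferroni
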