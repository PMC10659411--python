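"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package's dynamic-programming
implementations: alignments are scored by exhaustive enumeration of all
gapped pairings, and profile-HMM scores by exhaustive enumeration of
all state paths.  They are only feasible at tiny problem sizes, which
is the point.
"""

from __future__ import annotations

import math

from gsdmkit.align import substitution_score


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment (gapped string pair, no gap-gap columns)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for rest_a, rest_b in enumerate_alignments(a[1:], b):
            yield a[0] + rest_a, "-" + rest_b
    if b:
        for rest_a, rest_b in enumerate_alignments(a, b[1:]):
            yield "-" + rest_a, b[0] + rest_b
    if a and b:
        for rest_a, rest_b in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + rest_a, b[0] + rest_b


def score_gapped_pair(ala: str, alb: str, gap_open: float, gap_extend: float) -> float:
    """Affine score of one alignment: a length-L gap run costs open + L*extend."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ala, alb):
        if x == "-":
            score -= gap_extend if in_gap_a else gap_open + gap_extend
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= gap_extend if in_gap_b else gap_open + gap_extend
            in_gap_b, in_gap_a = True, False
        else:
            score += substitution_score(x, y)
            in_gap_a = in_gap_b = False
    return score


def brute_force_global(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Exhaustive DFS over all alignments, scoring moves incrementally."""
    best = -math.inf

    def walk(i: int, j: int, score: float, gap_state: int) -> None:
        # gap_state: 0 = none open, 1 = gap in a, 2 = gap in b
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + substitution_score(a[i], b[j]), 0)
        if j < len(b):
            cost = gap_extend if gap_state == 1 else gap_open + gap_extend
            walk(i, j + 1, score - cost, 1)
        if i < len(a):
            cost = gap_extend if gap_state == 2 else gap_open + gap_extend
            walk(i + 1, j, score - cost, 2)

    walk(0, 0, 0.0, 0)
    return best


def brute_force_local(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Best over all substring pairs (including the empty alignment, score 0)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    score = brute_force_global(a[i1:i2], b[j1:j2], gap_open, gap_extend)
                    best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# profile-HMM path enumeration


def _emission_score(hmm, state_index: int, residue: str) -> float:
    from gsdmkit.records import AMINO_ACIDS

    if residue not in AMINO_ACIDS:
        return 0.0
    aa = AMINO_ACIDS.index(residue)
    return math.log2(hmm.match_emissions[state_index - 1, aa] / hmm.background[aa])


def enumerate_path_scores(seq: str, hmm) -> list[float]:
    """Scores of every complete local path through the model.

    A path enters at any match state / residue (entry cost
    log2(1/n_match)), moves through M/I/D states with the model's
    transition log-probabilities (insert emissions at background = 0),
    and exits, cost-free, from any match state; flanking residues are
    free.
    """
    k = hmm.n_match
    L = len(seq)
    entry = math.log2(1.0 / k)
    lt = {
        name: [math.log2(p) if p > 0 else -math.inf for p in getattr(hmm, name)]
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
    }
    scores: list[float] = []

    def extend(state: str, j: int, i: int, acc: float) -> None:
        # state at match-state j, having consumed residues up to i (1-based)
        if state == "M":
            scores.append(acc)  # exit here, remaining residues are free flank
            if i < L and j < k:
                extend("M", j + 1, i + 1, acc + lt["t_mm"][j] + _emission_score(hmm, j + 1, seq[i]))
            if i < L:
                extend("I", j, i + 1, acc + lt["t_mi"][j])
            if j < k:
                extend("D", j + 1, i, acc + lt["t_md"][j])
        elif state == "I":
            if i < L and j < k:
                extend("M", j + 1, i + 1, acc + lt["t_im"][j] + _emission_score(hmm, j + 1, seq[i]))
            if i < L:
                extend("I", j, i + 1, acc + lt["t_ii"][j])
        else:  # D
            if i < L and j < k:
                extend("M", j + 1, i + 1, acc + lt["t_dm"][j] + _emission_score(hmm, j + 1, seq[i]))
            if j < k:
                extend("D", j + 1, i, acc + lt["t_dd"][j])

    for start in range(1, L + 1):
        for j in range(1, k + 1):
            extend("M", j, start, entry + _emission_score(hmm, j, seq[start - 1]))
    return scores


def brute_force_viterbi(seq: str, hmm) -> float:
    return max(enumerate_path_scores(seq, hmm))


def brute_force_forward(seq: str, hmm) -> float:
    scores = enumerate_path_scores(seq, hmm)
    peak = max(scores)
    return peak + math.log2(sum(2.0 ** (s - peak) for s in scores))
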