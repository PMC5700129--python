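"""Brute-force global-alignment oracle: enumerate every alignment path and
score it directly from the gap-run definition.  Exponential; for tiny
sequences only.  Written independently of the dynamic program it checks."""

from __future__ import annotations

from ampedit.pairwise_align import ScoringScheme


def brute_force_best_score(query: str, reference: str, sc: ScoringScheme) -> float:
    """Maximum score over all global alignments of query to reference.

    Recursion enumerates every monotone path of diagonal / delete / insert
    steps, accumulating the score step by step; a gap step pays the open
    penalty whenever the previous step was a different operation.
    """
    n, m = len(query), len(reference)

    def step_cost(op: str, prev: str, qi: int, rj: int) -> float:
        if op == "diag":
            return sc.match if query[qi] == reference[rj] else sc.mismatch
        cost = sc.gap_extend
        if sc.mode == "affine" and prev != op:
            cost += sc.gap_open
        return cost

    best = float("-inf")

    def walk(qi: int, rj: int, prev: str, acc: float) -> None:
        nonlocal best
        if qi == n and rj == m:
            best = max(best, acc)
            return
        if qi < n and rj < m:
            walk(qi + 1, rj + 1, "diag", acc + step_cost("diag", prev, qi, rj))
        if rj < m:  # deletion: reference base against a gap
            walk(qi, rj + 1, "del", acc + step_cost("del", prev, qi, rj))
        if qi < n:  # insertion: query base against a gap
            walk(qi + 1, rj, "ins", acc + step_cost("ins", prev, qi, rj))

    walk(0, 0, "start", 0.0)
    return best
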