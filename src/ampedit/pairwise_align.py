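"""Global pairwise alignment and edit-event extraction.

Implements Needleman–Wunsch global alignment with either linear or affine
gap costs, a deterministic traceback, indel left-normalization, and a
column scan that turns the gapped alignment into a compact list of
match / mismatch / insertion / deletion events with reference positions
and lengths.  These events are the substrate for editing-outcome
classification.

Scoring conventions
-------------------
Affine mode charges ``gap_open + L * gap_extend`` for a gap of length
``L`` (the open penalty is a one-time surcharge); linear mode charges
``gap_extend`` per gapped base and ignores ``gap_open``.  Adjacent gap
runs in opposite rows are distinct runs and each pays the open penalty.

Determinism
-----------
Traceback prefers diagonal over deletion (gap in query) over insertion
(gap in reference); afterwards every indel is shifted to its leftmost
score-equivalent position (the variant-normalization convention), so
identical inputs always yield identical aligned strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from ._dna import is_dna

__all__ = [
    "AlignmentError",
    "ScoringScheme",
    "EditEvent",
    "Alignment",
    "global_align",
    "extract_events",
    "events_to_cigar",
    "score_from_events",
    "format_alignment",
]

NEG_INF = float("-inf")


class AlignmentError(ValueError):
    """Invalid alignment input or malformed alignment."""


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and gap penalties.

    Defaults favour consolidated indels (affine, open −6 / extend −1),
    so an NHEJ deletion is reported as one event rather than scattered
    single-base gaps.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    mode: str = "affine"

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise AlignmentError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise AlignmentError("gap penalties must be non-positive")
        if self.mode not in ("linear", "affine"):
            raise AlignmentError("mode must be 'linear' or 'affine'")

    def gap_cost(self, length: int) -> float:
        if length <= 0:
            return 0.0
        if self.mode == "affine":
            return self.gap_open + length * self.gap_extend
        return length * self.gap_extend


@dataclass(frozen=True)
class EditEvent:
    """A maximal run of one alignment column kind.

    ``ref_pos`` is a 0-based reference coordinate; for insertions it is the
    bond index before which the bases are inserted.  ``bases`` holds the
    query bases for mismatches and insertions and is empty otherwise.
    """

    kind: str  # match_run | mismatch | insertion | deletion
    ref_pos: int
    length: int
    bases: str = ""


@dataclass
class Alignment:
    ref_aligned: str
    query_aligned: str
    score: float
    events: List[EditEvent] = field(default_factory=list)


# --------------------------------------------------------------------------
# Dynamic programming
# --------------------------------------------------------------------------

def _dp_linear(query: str, reference: str, sc: ScoringScheme):
    m, n = len(reference), len(query)
    gap = sc.gap_extend
    H = np.empty((m + 1, n + 1))
    H[0, :] = np.arange(n + 1) * gap
    H[:, 0] = np.arange(m + 1) * gap
    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    rarr = np.frombuffer(reference.encode(), dtype=np.uint8)
    for i in range(1, m + 1):
        sub = np.where(qarr == rarr[i - 1], sc.match, sc.mismatch)
        prev, cur = H[i - 1], H[i]
        diag = prev[:-1] + sub
        up = prev[1:] + gap
        best = np.maximum(diag, up)
        # the left move depends on cur[j-1]: sequential scan
        acc = cur[0]
        for j in range(1, n + 1):
            acc = max(best[j - 1], acc + gap)
            cur[j] = acc
    return H


def _dp_affine(query: str, reference: str, sc: ScoringScheme):
    """Three-state recurrence: M (aligned pair), D (gap in query, consumes
    reference), I (gap in reference, consumes query)."""
    m, n = len(reference), len(query)
    go, ge = sc.gap_open, sc.gap_extend
    M = np.full((m + 1, n + 1), NEG_INF)
    D = np.full((m + 1, n + 1), NEG_INF)
    I = np.full((m + 1, n + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        D[i, 0] = go + i * ge
    for j in range(1, n + 1):
        I[0, j] = go + j * ge
    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    rarr = np.frombuffer(reference.encode(), dtype=np.uint8)
    for i in range(1, m + 1):
        sub = np.where(qarr == rarr[i - 1], sc.match, sc.mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1], D[i - 1]), I[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        D[i] = np.maximum(
            np.maximum(M[i - 1], I[i - 1]) + go + ge,
            D[i - 1] + ge,
        )
        D[i, 0] = go + i * ge
        Mi, Di, Ii = M[i], D[i], I[i]
        for j in range(1, n + 1):
            Ii[j] = max(max(Mi[j - 1], Di[j - 1]) + go + ge, Ii[j - 1] + ge)
    return M, D, I


_EPS = 1e-9


def _traceback_linear(query, reference, sc, H):
    i, j = len(reference), len(query)
    gap = sc.gap_extend
    ref_al: list[str] = []
    qry_al: list[str] = []
    while i > 0 or j > 0:
        here = H[i, j]
        if i > 0 and j > 0:
            s = sc.match if query[j - 1] == reference[i - 1] else sc.mismatch
            if abs(H[i - 1, j - 1] + s - here) < _EPS:
                ref_al.append(reference[i - 1])
                qry_al.append(query[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and abs(H[i - 1, j] + gap - here) < _EPS:
            ref_al.append(reference[i - 1])
            qry_al.append("-")
            i -= 1
            continue
        ref_al.append("-")
        qry_al.append(query[j - 1])
        j -= 1
    return "".join(reversed(ref_al)), "".join(reversed(qry_al))


def _traceback_affine(query, reference, sc, M, D, I):
    m, n = len(reference), len(query)
    go, ge = sc.gap_open, sc.gap_extend
    finals = (M[m, n], D[m, n], I[m, n])
    state = int(np.argmax(finals))  # priority M > D > I on exact ties
    ref_al: list[str] = []
    qry_al: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if state == 0:  # M: consumed (ref[i-1], query[j-1])
            ref_al.append(reference[i - 1])
            qry_al.append(query[j - 1])
            i -= 1
            j -= 1
            if i == 0 and j == 0:
                break
            here = M[i + 1, j + 1]
            s = sc.match if query[j] == reference[i] else sc.mismatch
            if abs(M[i, j] + s - here) < _EPS:
                state = 0
            elif abs(D[i, j] + s - here) < _EPS:
                state = 1
            else:
                state = 2
        elif state == 1:  # D: consumed ref[i-1] against a gap
            ref_al.append(reference[i - 1])
            qry_al.append("-")
            i -= 1
            here = D[i + 1, j]
            if abs(M[i, j] + go + ge - here) < _EPS:
                state = 0
            elif abs(D[i, j] + ge - here) < _EPS:
                state = 1
            else:
                state = 2
        else:  # I: consumed query[j-1] against a gap
            ref_al.append("-")
            qry_al.append(query[j - 1])
            j -= 1
            here = I[i, j + 1]
            if abs(M[i, j] + go + ge - here) < _EPS:
                state = 0
            elif abs(D[i, j] + go + ge - here) < _EPS:
                state = 1
            else:
                state = 2
    return "".join(reversed(ref_al)), "".join(reversed(qry_al))


def _left_shift_gaps(ref_al: str, qry_al: str) -> tuple[str, str]:
    """Shift every indel run to its leftmost score-equivalent position."""
    ref = list(ref_al)
    qry = list(qry_al)

    def shift_row(gapped: list[str], solid: list[str]) -> bool:
        # gapped carries the '-' run; solid carries bases throughout the run
        changed = False
        c = 0
        length = len(gapped)
        while c < length:
            if gapped[c] != "-":
                c += 1
                continue
            c2 = c
            while c2 < length and gapped[c2] == "-":
                c2 += 1
            # run covers [c, c2)
            c1 = c
            while c1 > 0 and gapped[c1 - 1] != "-" and solid[c1 - 1] != "-" and \
                    solid[c1 - 1] == solid[c2 - 1]:
                # move the aligned pair from the left edge to the right edge
                gapped[c2 - 1] = gapped[c1 - 1]
                gapped[c1 - 1] = "-"
                c1 -= 1
                c2 -= 1
                changed = True
            c = c2 if c2 > c else c + 1
            while c < length and gapped[c] == "-":
                c += 1
        return changed

    # iterate to fixpoint: a shift can expose another shiftable run
    for _ in range(len(ref)):
        moved = shift_row(qry, ref) | shift_row(ref, qry)
        if not moved:
            break
    return "".join(ref), "".join(qry)


def global_align(query: str, reference: str, scoring: ScoringScheme | None = None) -> Alignment:
    """Optimal Needleman–Wunsch global alignment of query to reference.

    Returns an :class:`Alignment` whose ``events`` list is already
    populated.  Raises :class:`AlignmentError` for empty or non-ACGT input.
    """
    scoring = scoring or ScoringScheme()
    if not query or not reference:
        raise AlignmentError("sequences must be non-empty")
    if not is_dna(query) or not is_dna(reference):
        raise AlignmentError("sequences must contain only A/C/G/T")
    if scoring.mode == "linear":
        H = _dp_linear(query, reference, scoring)
        score = float(H[len(reference), len(query)])
        ref_al, qry_al = _traceback_linear(query, reference, scoring, H)
    else:
        M, D, I = _dp_affine(query, reference, scoring)
        score = float(max(M[-1, -1], D[-1, -1], I[-1, -1]))
        ref_al, qry_al = _traceback_affine(query, reference, scoring, M, D, I)
    ref_al, qry_al = _left_shift_gaps(ref_al, qry_al)
    aln = Alignment(ref_aligned=ref_al, query_aligned=qry_al, score=score)
    aln.events = extract_events(aln)
    return aln


# --------------------------------------------------------------------------
# Event extraction
# --------------------------------------------------------------------------

def extract_events(alignment: Alignment) -> List[EditEvent]:
    """Column-scan the alignment into maximal match/mismatch/indel runs.

    The run lengths satisfy two conservation identities: match + mismatch +
    deletion lengths sum to the reference length, and match + mismatch +
    insertion lengths sum to the query length.
    """
    ref_al, qry_al = alignment.ref_aligned, alignment.query_aligned
    if len(ref_al) != len(qry_al):
        raise AlignmentError("aligned strings differ in length")
    events: List[EditEvent] = []
    ref_pos = 0
    kind = None
    run_start = 0
    run_len = 0
    bases: list[str] = []

    def flush():
        nonlocal kind, run_len, bases
        if kind is not None and run_len > 0:
            events.append(EditEvent(kind, run_start, run_len, "".join(bases)))
        kind = None
        run_len = 0
        bases = []

    for r, q in zip(ref_al, qry_al):
        if r == "-" and q == "-":
            raise AlignmentError("gap-gap column in alignment")
        if r == "-":
            col = "insertion"
        elif q == "-":
            col = "deletion"
        elif r == q:
            col = "match_run"
        else:
            col = "mismatch"
        if col != kind:
            flush()
            kind = col
            run_start = ref_pos
        run_len += 1
        if col in ("insertion", "mismatch"):
            bases.append(q)
        if r != "-":
            ref_pos += 1
    flush()
    return events


def score_from_events(events: List[EditEvent], scoring: ScoringScheme) -> float:
    """Recompute the alignment score from the event list (additivity check)."""
    total = 0.0
    for ev in events:
        if ev.kind == "match_run":
            total += ev.length * scoring.match
        elif ev.kind == "mismatch":
            total += ev.length * scoring.mismatch
        else:
            total += scoring.gap_cost(ev.length)
    return total


_CIGAR_CODE = {"match_run": "M", "mismatch": "X", "insertion": "I", "deletion": "D"}


def events_to_cigar(events: List[EditEvent]) -> str:
    """Run-length M/X/I/D encoding of the event list."""
    return "".join(f"{ev.length}{_CIGAR_CODE[ev.kind]}" for ev in events)


def format_alignment(alignment: Alignment) -> str:
    """Two-line gapped text rendering (reference over query)."""
    return f"{alignment.ref_aligned}\n{alignment.query_aligned}"
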