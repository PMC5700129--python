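"""Editing-outcome classification of target sequences.

Each unique target sequence is labelled WT, HDR, NHEJ, or AMBIGUOUS:

1. exact match to the expected HDR allele -> HDR;
2. exact match to the wild-type amplicon -> WT;
3. otherwise the sequence is globally aligned to the amplicon.  In
   ``edits_present`` mode a sequence is still HDR when every programmed
   donor edit is reproduced, no other indel is present, no stray
   substitution falls inside the cut-site window, and at most
   ``max_outside_mismatches`` stray substitutions fall elsewhere
   (tolerating sequencing error without abandoning the template match);
4. any non-programmed indel overlapping the cut-site window -> NHEJ
   (imprecise repair);
5. anything else -> AMBIGUOUS.

"Precise" means scarless: a read carrying the programmed edit plus an
extra cut-site indel is NHEJ, with ``hdr_marker_present`` set for
auditing.  Substitution-only changes near the cut do not count as NHEJ
by default — indels are the imprecision currency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Optional, Sequence

from .locus_model import DonorSpec, LocusSpec, expected_hdr_allele
from .pairwise_align import (
    Alignment,
    EditEvent,
    ScoringScheme,
    global_align,
)
from .preprocess import UniqueSequence

__all__ = ["ClassParams", "AlleleCall", "classify_sequence", "classify_sample"]

LABELS = ("WT", "HDR", "NHEJ", "AMBIGUOUS")


@dataclass(frozen=True)
class ClassParams:
    """Classification tuning knobs.

    ``window_nt`` is the half-width (in bonds) of the cut-site window an
    indel must overlap to count as NHEJ.  ``hdr_mode`` selects strict
    whole-allele matching (``exact_allele``) or tolerant programmed-edit
    matching (``edits_present``).
    """

    window_nt: int = 5
    hdr_mode: str = "edits_present"
    max_outside_mismatches: int = 2
    count_substitutions_in_window_as_nhej: bool = False

    def __post_init__(self) -> None:
        if self.window_nt < 0:
            raise ValueError("window_nt must be >= 0")
        if self.hdr_mode not in ("exact_allele", "edits_present"):
            raise ValueError("hdr_mode must be 'exact_allele' or 'edits_present'")


@dataclass
class AlleleCall:
    sequence: str
    count: int
    label: str
    events: List[EditEvent] = field(default_factory=list)
    hdr_marker_present: bool = False
    indel_in_window: bool = False


def _indel_signature(ev: EditEvent) -> tuple:
    return (ev.kind, ev.ref_pos, ev.length, ev.bases)


@lru_cache(maxsize=32)
def _programmed_signatures(
    locus: LocusSpec, donor: DonorSpec, scoring: ScoringScheme
) -> tuple[frozenset, tuple]:
    """Programmed-edit signatures in the aligner's own (left-normalized)
    event representation.

    The expected HDR allele is aligned back to the amplicon so that
    programmed indels are expressed exactly as the aligner would report
    them (an insertion starting with the same base as its left context
    left-shifts, for example); naive edit coordinates would not compare
    equal to observed events.
    """
    expected = expected_hdr_allele(locus, donor)
    aln = global_align(expected, locus.amplicon, scoring)
    indels = frozenset(
        _indel_signature(ev)
        for ev in aln.events
        if ev.kind in ("insertion", "deletion")
    )
    subs: dict[int, str] = {}
    for ev in aln.events:
        if ev.kind == "mismatch":
            for i, base in enumerate(ev.bases):
                subs[ev.ref_pos + i] = base
    return indels, tuple(sorted(subs.items()))


def _query_base_map(alignment: Alignment) -> dict[int, str]:
    """Reference position -> aligned query base (absent where deleted)."""
    out: dict[int, str] = {}
    pos = 0
    for r, q in zip(alignment.ref_aligned, alignment.query_aligned):
        if r != "-":
            if q != "-":
                out[pos] = q
            pos += 1
    return out


def _indel_overlaps_window(ev: EditEvent, cut: int, window: int) -> bool:
    lo, hi = cut - window, cut + window  # bond interval
    if ev.kind == "insertion":
        return lo <= ev.ref_pos <= hi
    if ev.kind == "deletion":
        return ev.ref_pos <= hi and ev.ref_pos + ev.length >= lo
    return False


def classify_sequence(
    unique: UniqueSequence,
    locus: LocusSpec,
    donor: Optional[DonorSpec],
    params: Optional[ClassParams] = None,
    scoring: Optional[ScoringScheme] = None,
) -> AlleleCall:
    """Label one target sequence; every sequence receives exactly one label."""
    params = params or ClassParams()
    scoring = scoring or ScoringScheme()
    seq = unique.sequence
    amplicon = locus.amplicon
    cut = locus.cut_index
    assert cut is not None

    expected = None
    programmed_indels: frozenset = frozenset()
    programmed_subs: dict[int, str] = {}
    if donor is not None:
        expected = expected_hdr_allele(locus, donor)
        if donor.edits is None:
            donor = dataclasses.replace(donor, edits=donor.resolved_edits(locus))
        indels, subs = _programmed_signatures(locus, donor, scoring)
        programmed_indels = indels
        programmed_subs = dict(subs)

    if expected is not None and seq == expected:
        aln = global_align(seq, amplicon, scoring)
        return AlleleCall(seq, unique.count, "HDR", aln.events, True, False)
    if seq == amplicon:
        aln = global_align(seq, amplicon, scoring)
        return AlleleCall(seq, unique.count, "WT", aln.events, False, False)

    aln = global_align(seq, amplicon, scoring)
    indel_events = [ev for ev in aln.events if ev.kind in ("insertion", "deletion")]
    observed = {_indel_signature(ev) for ev in indel_events}
    extra_indels = [
        ev for ev in indel_events if _indel_signature(ev) not in programmed_indels
    ]
    qmap = _query_base_map(aln)

    marker = bool(programmed_indels or programmed_subs)
    marker = marker and programmed_indels <= observed
    marker = marker and all(qmap.get(p) == b for p, b in programmed_subs.items())

    # stray substitutions: mismatched positions not explained by the donor
    stray = [
        p
        for p, q in qmap.items()
        if p < len(amplicon) and q != amplicon[p] and programmed_subs.get(p) != q
    ]
    in_window = [p for p in stray if cut - params.window_nt <= p < cut + params.window_nt]
    outside = [p for p in stray if p not in in_window]

    indel_in_window = any(
        _indel_overlaps_window(ev, cut, params.window_nt) for ev in extra_indels
    )

    if (
        params.hdr_mode == "edits_present"
        and donor is not None
        and marker
        and not extra_indels
        and not in_window
        and len(outside) <= params.max_outside_mismatches
    ):
        return AlleleCall(seq, unique.count, "HDR", aln.events, marker, indel_in_window)

    if indel_in_window or (
        params.count_substitutions_in_window_as_nhej and in_window
    ):
        return AlleleCall(seq, unique.count, "NHEJ", aln.events, marker, indel_in_window)

    return AlleleCall(seq, unique.count, "AMBIGUOUS", aln.events, marker, indel_in_window)


def classify_sample(
    targets: Sequence[UniqueSequence],
    locus: LocusSpec,
    donor: Optional[DonorSpec],
    params: Optional[ClassParams] = None,
    scoring: Optional[ScoringScheme] = None,
) -> List[AlleleCall]:
    """Classify every target sequence, preserving input order."""
    params = params or ClassParams()
    scoring = scoring or ScoringScheme()
    return [classify_sequence(u, locus, donor, params, scoring) for u in targets]
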