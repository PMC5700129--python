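"""FASTQ preprocessing: quality filter, read collapsing, frequency filter,
and primer-anchored target identification.

The stages mirror standard amplicon practice: reads below a mean-quality
threshold are dropped; surviving reads are collapsed to unique sequences
with counts; unique sequences seen fewer than ``min_count`` times (default
10, strict ``< 10`` removal) are discarded as likely PCR/sequencing
artifacts; and the remainder are kept only if both primers anchor near the
read ends, orientation-normalized to the plus strand, and trimmed to the
primer-to-primer amplicon span ("target sequences").
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional

from Bio import SeqIO

from ._dna import hamming, is_dna, revcomp
from .locus_model import LocusSpec

__all__ = [
    "FastqParseError",
    "ReadRecord",
    "UniqueSequence",
    "StageCounts",
    "parse_fastq",
    "filter_low_quality",
    "collapse_reads",
    "filter_low_frequency",
    "identify_targets",
    "preprocess_sample",
]

DEFAULT_MIN_MEAN_Q = 20.0
DEFAULT_MIN_COUNT = 10
PRIMER_ANCHOR_WINDOW = 5


class FastqParseError(ValueError):
    pass


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


@dataclass(frozen=True)
class UniqueSequence:
    """A collapsed read sequence with its observed count."""

    sequence: str
    count: int


@dataclass
class StageCounts:
    """Per-stage read accounting for one sample."""

    n_raw: int = 0
    n_quality_pass: int = 0
    n_lowq_discarded: int = 0
    n_unique: int = 0
    n_freq_pass: int = 0
    freq_discarded_reads: int = 0
    n_target: int = 0
    target_reads: int = 0
    target_discarded_reads: int = 0
    n_orientation_flipped: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def parse_fastq(path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTQ file (Phred+33; .gz accepted)."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as handle:
        index = 0
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                seq = str(rec.seq).upper()
                quals = tuple(rec.letter_annotations["phred_quality"])
                if not is_dna(seq, allow_n=True):
                    raise FastqParseError(
                        f"record {index} ({rec.id}): non-DNA characters in sequence"
                    )
                yield ReadRecord(rec.id, seq, quals)
                index += 1
        except ValueError as exc:
            if isinstance(exc, FastqParseError):
                raise
            raise FastqParseError(f"malformed FASTQ record at index {index}: {exc}") from exc


def filter_low_quality(
    reads: Iterable[ReadRecord], min_mean_q: float = DEFAULT_MIN_MEAN_Q
) -> tuple[List[ReadRecord], int]:
    """Keep reads whose mean Phred quality is >= ``min_mean_q``.

    Returns the retained reads (input order preserved) and the number
    discarded.
    """
    kept: List[ReadRecord] = []
    discarded = 0
    for read in reads:
        if read.mean_quality() >= min_mean_q:
            kept.append(read)
        else:
            discarded += 1
    return kept, discarded


def collapse_reads(reads: Iterable[ReadRecord]) -> List[UniqueSequence]:
    """Group reads by exact sequence; sort by descending count, then sequence."""
    counts = Counter(read.sequence for read in reads)
    return [
        UniqueSequence(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def filter_low_frequency(
    uniques: Iterable[UniqueSequence], min_count: int = DEFAULT_MIN_COUNT
) -> tuple[List[UniqueSequence], int]:
    """Drop unique sequences with count < ``min_count`` (strict).

    Returns retained uniques and the total read mass removed.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept: List[UniqueSequence] = []
    removed_reads = 0
    for u in uniques:
        if u.count >= min_count:
            kept.append(u)
        else:
            removed_reads += u.count
    return kept, removed_reads


def _find_primer_start(seq: str, primer: str, max_mismatch: int, window: int) -> int:
    """Offset in [0, window) where the primer matches with <= max_mismatch
    substitutions (no indels), or -1."""
    plen = len(primer)
    for off in range(window):
        if off + plen > len(seq):
            break
        if hamming(seq[off : off + plen], primer) <= max_mismatch:
            return off
    return -1


def _find_primer_end(seq: str, primer_rc: str, max_mismatch: int, window: int) -> int:
    """End coordinate (exclusive) of the reverse-primer revcomp when it ends
    within the last ``window`` nt, or -1."""
    plen = len(primer_rc)
    for off in range(window):
        end = len(seq) - off
        if end - plen < 0:
            break
        if hamming(seq[end - plen : end], primer_rc) <= max_mismatch:
            return end
    return -1


@dataclass
class TargetResult:
    targets: List[UniqueSequence] = field(default_factory=list)
    discarded_reads: int = 0
    n_flipped: int = 0


def identify_targets(
    uniques: Iterable[UniqueSequence],
    locus: LocusSpec,
    max_primer_mismatch: int = 0,
    anchor_window: int = PRIMER_ANCHOR_WINDOW,
) -> TargetResult:
    """Select primer-bounded target sequences and normalize orientation.

    A sequence is a target when the forward primer matches (substitutions
    only) starting within the first ``anchor_window`` nt of one end and the
    reverse complement of the reverse primer ends within the last
    ``anchor_window`` nt of the other end, in either read orientation.
    Matching sequences are flipped to plus orientation as needed and
    trimmed to the primer-to-primer span; after trimming, identical
    sequences are re-merged.  Sequences containing N or lacking a primer
    are discarded (counted, never an error).
    """
    fwd = locus.fwd_primer
    rev_rc = revcomp(locus.rev_primer)
    if not fwd or not locus.rev_primer:
        raise ValueError("locus must define both primers for target identification")

    merged: Counter = Counter()
    result = TargetResult()

    def try_orientation(seq: str) -> Optional[str]:
        f_off = _find_primer_start(seq, fwd, max_primer_mismatch, anchor_window)
        if f_off == -1:
            return None
        r_end = _find_primer_end(seq, rev_rc, max_primer_mismatch, anchor_window)
        if r_end == -1 or r_end <= f_off:
            return None
        return seq[f_off:r_end]

    for u in uniques:
        trimmed = try_orientation(u.sequence)
        flipped = False
        if trimmed is None:
            trimmed = try_orientation(revcomp(u.sequence))
            flipped = trimmed is not None
        if trimmed is None or not is_dna(trimmed):
            result.discarded_reads += u.count
            continue
        if flipped:
            result.n_flipped += u.count
        merged[trimmed] += u.count

    result.targets = [
        UniqueSequence(seq, n)
        for seq, n in sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return result


def preprocess_sample(
    reads: Iterable[ReadRecord],
    locus: LocusSpec,
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    min_count: int = DEFAULT_MIN_COUNT,
    max_primer_mismatch: int = 0,
) -> tuple[List[UniqueSequence], StageCounts]:
    """Full preprocessing chain: quality -> collapse -> frequency -> target."""
    reads = list(reads)
    counts = StageCounts(n_raw=len(reads))
    kept, counts.n_lowq_discarded = filter_low_quality(reads, min_mean_q)
    counts.n_quality_pass = len(kept)
    uniques = collapse_reads(kept)
    counts.n_unique = len(uniques)
    freq_pass, counts.freq_discarded_reads = filter_low_frequency(uniques, min_count)
    counts.n_freq_pass = len(freq_pass)
    target_result = identify_targets(freq_pass, locus, max_primer_mismatch)
    counts.n_target = len(target_result.targets)
    counts.target_reads = sum(t.count for t in target_result.targets)
    counts.target_discarded_reads = target_result.discarded_reads
    counts.n_orientation_flipped = target_result.n_flipped
    return target_result.targets, counts
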