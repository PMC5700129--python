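"""Amplicon locus, guide, and ssODN donor models.

A :class:`LocusSpec` describes the wild-type amplicon (the PCR product
between and including the primer pair), the SpCas9 protospacer with its
NGG PAM, and the derived blunt cut site.  A :class:`DonorSpec` describes a
single-stranded oligodeoxynucleotide (ssODN) repair template as homology
arms flanking one or more programmed edits; applying those edits to the
amplicon yields the expected homology-directed-repair (HDR) allele that the
classifier matches reads against.

Coordinate conventions
----------------------
All coordinates are 0-based on the plus strand of the amplicon.  The cut
site is a *bond* index: ``cut_index = i`` means the break falls between
``amplicon[i-1]`` and ``amplicon[i]``.  SpCas9 cuts bluntly 3 nt 5' of the
PAM on the protospacer strand.  Edits are half-open intervals on the
reference; an insertion's ``ref_pos`` is the bond before which bases are
inserted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml
from Bio import SeqIO

from ._dna import is_dna, revcomp

__all__ = [
    "LocusError",
    "Edit",
    "LocusSpec",
    "DonorSpec",
    "derive_cut_index",
    "apply_edits",
    "expected_hdr_allele",
    "infer_edits",
    "load_locus_config",
    "demo_locus",
    "demo_donor",
]


class LocusError(ValueError):
    """A locus or donor definition violates its invariants."""


@dataclass(frozen=True, order=True)
class Edit:
    """One programmed change in reference (amplicon) coordinates.

    ``substitution``: ``ref_bases`` replaced by ``alt_bases`` (equal length).
    ``insertion``: ``alt_bases`` inserted before bond ``ref_pos``
    (``ref_bases`` empty).  ``deletion``: ``ref_bases`` removed starting at
    ``ref_pos`` (``alt_bases`` empty).
    """

    ref_pos: int
    kind: str = "substitution"
    ref_bases: str = ""
    alt_bases: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise LocusError(f"unknown edit kind {self.kind!r}")
        if self.ref_pos < 0:
            raise LocusError("edit ref_pos must be >= 0")
        if self.kind == "substitution":
            if not self.ref_bases or len(self.ref_bases) != len(self.alt_bases):
                raise LocusError("substitution needs equal-length ref/alt bases")
        elif self.kind == "insertion":
            if self.ref_bases or not self.alt_bases:
                raise LocusError("insertion needs empty ref_bases, non-empty alt_bases")
        else:  # deletion
            if not self.ref_bases or self.alt_bases:
                raise LocusError("deletion needs non-empty ref_bases, empty alt_bases")
        for bases in (self.ref_bases, self.alt_bases):
            if bases and not is_dna(bases):
                raise LocusError(f"edit bases must be uppercase ACGT: {bases!r}")

    @property
    def span(self) -> tuple[int, int]:
        """Half-open reference interval consumed by this edit."""
        return self.ref_pos, self.ref_pos + len(self.ref_bases)

    @property
    def net_length_change(self) -> int:
        return len(self.alt_bases) - len(self.ref_bases)


def _find_protospacer_sites(amplicon: str, protospacer: str, pam_strand: str) -> list[int]:
    """Return cut bond indices for every protospacer+NGG occurrence."""
    sites: list[int] = []
    if pam_strand == "plus":
        needle = protospacer
        start = 0
        while (s := amplicon.find(needle, start)) != -1:
            start = s + 1
            pam_start = s + len(needle)
            if pam_start + 3 <= len(amplicon) and amplicon[pam_start + 1 : pam_start + 3] == "GG":
                sites.append(pam_start - 3)
    else:
        needle = revcomp(protospacer)
        start = 0
        while (s := amplicon.find(needle, start)) != -1:
            start = s + 1
            # PAM on the minus strand reads NGG 5'->3'; on the plus strand it
            # appears as CCN immediately 5' of the protospacer's revcomp.
            if s - 3 >= 0 and amplicon[s - 3 : s - 1] == "CC":
                sites.append(s + 3)
    return sites


def derive_cut_index(locus: "LocusSpec") -> int:
    """Locate the protospacer and return the blunt SpCas9 cut bond.

    The cut falls 3 nt 5' of the NGG PAM on the protospacer strand,
    converted to plus-strand amplicon coordinates.

    Raises
    ------
    LocusError
        If the protospacer is absent, occurs more than once with a valid
        PAM, or never abuts an NGG.
    """
    needle = locus.protospacer if locus.pam_strand == "plus" else revcomp(locus.protospacer)
    if needle not in locus.amplicon:
        raise LocusError(
            f"protospacer {locus.protospacer!r} not found in amplicon "
            f"(pam_strand={locus.pam_strand})"
        )
    sites = _find_protospacer_sites(locus.amplicon, locus.protospacer, locus.pam_strand)
    if not sites:
        raise LocusError("protospacer found but not followed by an NGG PAM")
    if len(sites) > 1:
        raise LocusError(f"protospacer+PAM occurs {len(sites)} times; must be unique")
    return sites[0]


@dataclass(frozen=True)
class LocusSpec:
    """Wild-type amplicon with guide and primer annotations.

    ``cut_index`` may be omitted; it is then derived from the protospacer
    and PAM position on construction.
    """

    name: str
    amplicon: str
    protospacer: str
    pam_strand: str = "plus"
    fwd_primer: str = ""
    rev_primer: str = ""
    cut_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not is_dna(self.amplicon):
            raise LocusError("amplicon must be a non-empty uppercase ACGT string")
        if not is_dna(self.protospacer) or not 17 <= len(self.protospacer) <= 20:
            raise LocusError("protospacer must be 17-20 uppercase ACGT bases")
        if self.pam_strand not in ("plus", "minus"):
            raise LocusError("pam_strand must be 'plus' or 'minus'")
        for primer in (self.fwd_primer, self.rev_primer):
            if primer and not is_dna(primer):
                raise LocusError("primers must be uppercase ACGT")
        if self.fwd_primer and not self.amplicon.startswith(self.fwd_primer):
            raise LocusError("fwd_primer must be a prefix of the amplicon")
        if self.rev_primer and not self.amplicon.endswith(revcomp(self.rev_primer)):
            raise LocusError("revcomp(rev_primer) must be a suffix of the amplicon")
        if self.cut_index is None:
            object.__setattr__(self, "cut_index", derive_cut_index(self))
        elif not 0 < self.cut_index < len(self.amplicon):
            raise LocusError("cut_index must lie strictly inside the amplicon")


def apply_edits(amplicon: str, edits: Sequence[Edit]) -> str:
    """Apply non-overlapping edits to the amplicon, left to right.

    Raises :class:`LocusError` on an empty edit list, an out-of-bounds
    edit, overlapping edits, or a substitution/deletion whose ``ref_bases``
    do not match the amplicon.
    """
    if not edits:
        raise LocusError("edit list is empty; a donor identical to reference is rejected")
    ordered = sorted(edits, key=lambda e: e.span)
    out: list[str] = []
    cursor = 0
    for i, edit in enumerate(ordered):
        start, end = edit.span
        if end > len(amplicon) or (edit.kind == "insertion" and start > len(amplicon)):
            raise LocusError(f"edit at {start} extends past the amplicon end")
        if start < cursor or (i > 0 and edit.span == ordered[i - 1].span):
            raise LocusError(f"edits overlap at reference position {start}")
        if edit.ref_bases and amplicon[start:end] != edit.ref_bases:
            raise LocusError(
                f"edit ref_bases {edit.ref_bases!r} do not match amplicon "
                f"{amplicon[start:end]!r} at {start}"
            )
        out.append(amplicon[cursor:start])
        out.append(edit.alt_bases)
        cursor = end
    out.append(amplicon[cursor:])
    return "".join(out)


def infer_edits(oriented_ssodn: str, locus: LocusSpec, anchor_len: int = 12) -> tuple[Edit, ...]:
    """Derive programmed edits by anchored alignment of the donor to the amplicon.

    The donor's terminal ``anchor_len`` bases (assumed to lie in the exact
    homology arms) are located uniquely in the amplicon; the spanned region
    is then globally aligned and non-match events converted to edits.
    """
    from .pairwise_align import ScoringScheme, extract_events, global_align

    amp = locus.amplicon
    if len(oriented_ssodn) < 2 * anchor_len:
        raise LocusError("ssODN too short to anchor both homology arms")
    head, tail = oriented_ssodn[:anchor_len], oriented_ssodn[-anchor_len:]
    p = amp.find(head)
    if p == -1 or amp.find(head, p + 1) != -1:
        raise LocusError("donor 5' arm does not anchor uniquely in the amplicon")
    q = amp.find(tail)
    if q == -1 or amp.find(tail, q + 1) != -1:
        raise LocusError("donor 3' arm does not anchor uniquely in the amplicon")
    q_end = q + anchor_len
    if q_end <= p:
        raise LocusError("donor arms anchor in inverted order on the amplicon")
    aln = global_align(oriented_ssodn, amp[p:q_end], ScoringScheme())
    edits: list[Edit] = []
    for ev in extract_events(aln):
        pos = ev.ref_pos + p
        if ev.kind == "mismatch":
            edits.append(
                Edit(pos, "substitution", ref_bases=amp[pos : pos + ev.length], alt_bases=ev.bases)
            )
        elif ev.kind == "insertion":
            edits.append(Edit(pos, "insertion", alt_bases=ev.bases))
        elif ev.kind == "deletion":
            edits.append(Edit(pos, "deletion", ref_bases=amp[pos : pos + ev.length]))
    if not edits:
        raise LocusError("donor is identical to the reference amplicon")
    return tuple(edits)


@dataclass(frozen=True)
class DonorSpec:
    """ssODN donor template.

    ``strand`` says whether the oligo sequence is written on the PAM strand
    or the non-PAM strand; together with the locus' ``pam_strand`` this
    fixes its orientation relative to the plus-strand amplicon.
    ``biotin_end`` is carried as metadata only.  ``edits`` may be declared
    explicitly; when omitted they are inferred from the ssODN by anchored
    alignment (explicit declaration wins).
    """

    ssodn: str
    strand: str = "pam"
    biotin_end: str = "none"
    arm_upstream_nt: Optional[int] = None
    arm_downstream_nt: Optional[int] = None
    edits: Optional[tuple[Edit, ...]] = None

    def __post_init__(self) -> None:
        if not is_dna(self.ssodn):
            raise LocusError("ssodn must be a non-empty uppercase ACGT string")
        if self.strand not in ("pam", "non_pam"):
            raise LocusError("donor strand must be 'pam' or 'non_pam'")
        if self.biotin_end not in ("five_prime", "three_prime", "none"):
            raise LocusError("biotin_end must be five_prime, three_prime or none")
        if self.edits is not None and len(self.edits) == 0:
            raise LocusError("explicit edit list must be non-empty")

    def is_plus_oriented(self, locus: LocusSpec) -> bool:
        return (self.strand == "pam") == (locus.pam_strand == "plus")

    def oriented_ssodn(self, locus: LocusSpec) -> str:
        """Donor sequence rewritten 5'->3' on the amplicon plus strand."""
        return self.ssodn if self.is_plus_oriented(locus) else revcomp(self.ssodn)

    def normalized(self, locus: LocusSpec) -> "DonorSpec":
        """Plus-strand-oriented copy of this donor (idempotent)."""
        if self.is_plus_oriented(locus):
            return self
        strand = "pam" if locus.pam_strand == "plus" else "non_pam"
        biotin = {
            "five_prime": "three_prime",
            "three_prime": "five_prime",
            "none": "none",
        }[self.biotin_end]
        return dataclasses.replace(
            self, ssodn=revcomp(self.ssodn), strand=strand, biotin_end=biotin
        )

    def resolved_edits(self, locus: LocusSpec) -> tuple[Edit, ...]:
        if self.edits is not None:
            return tuple(self.edits)
        return infer_edits(self.oriented_ssodn(locus), locus)

    def validate(self, locus: LocusSpec) -> None:
        """Check donor invariants against the locus; raises LocusError."""
        edits = self.resolved_edits(locus)
        expected = apply_edits(locus.amplicon, edits)
        oriented = self.oriented_ssodn(locus)
        if oriented not in expected:
            raise LocusError("ssODN (arms + edited core) does not match the edited amplicon")
        up = self.arm_upstream_nt
        down = self.arm_downstream_nt
        if up and locus.amplicon.find(oriented[:up]) == -1:
            raise LocusError("upstream homology arm does not match the amplicon")
        if down and locus.amplicon.find(oriented[-down:]) == -1:
            raise LocusError("downstream homology arm does not match the amplicon")

    @classmethod
    def from_edits(
        cls,
        locus: LocusSpec,
        edits: Iterable[Edit],
        arm_upstream_nt: int = 40,
        arm_downstream_nt: int = 40,
        strand: str = "pam",
        biotin_end: str = "none",
    ) -> "DonorSpec":
        """Synthesize the ssODN sequence from explicit edits and arm lengths."""
        edits = tuple(sorted(edits, key=lambda e: e.span))
        expected = apply_edits(locus.amplicon, edits)
        first = edits[0].span[0]
        last_ref_end = edits[-1].span[1]
        net = sum(e.net_length_change for e in edits)
        start = max(0, first - arm_upstream_nt)
        end = min(len(expected), last_ref_end + net + arm_downstream_nt)
        oriented = expected[start:end]
        ssodn = oriented
        plus_is_pam = locus.pam_strand == "plus"
        if (strand == "pam") != plus_is_pam:
            ssodn = revcomp(oriented)
        donor = cls(
            ssodn=ssodn,
            strand=strand,
            biotin_end=biotin_end,
            arm_upstream_nt=first - start,
            arm_downstream_nt=end - (last_ref_end + net),
            edits=edits,
        )
        donor.validate(locus)
        return donor


def expected_hdr_allele(locus: LocusSpec, donor: DonorSpec) -> str:
    """The full amplicon-length allele produced by precise HDR from the donor."""
    return apply_edits(locus.amplicon, donor.resolved_edits(locus))


# --------------------------------------------------------------------------
# Configuration I/O
# --------------------------------------------------------------------------

def _read_sequence_field(entry, base_dir: Path) -> str:
    """A sequence is either an inline string or {fasta: path[, record: id]}."""
    if isinstance(entry, str):
        return entry.upper()
    if isinstance(entry, dict) and "fasta" in entry:
        path = base_dir / entry["fasta"]
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise LocusError(f"no records in FASTA {path}")
        if "record" in entry:
            for rec in records:
                if rec.id == entry["record"]:
                    return str(rec.seq).upper()
            raise LocusError(f"record {entry['record']!r} not found in {path}")
        return str(records[0].seq).upper()
    raise LocusError(f"cannot interpret sequence entry {entry!r}")


def _edit_from_dict(d: dict) -> Edit:
    return Edit(
        ref_pos=int(d["ref_pos"]),
        kind=d.get("kind", "substitution"),
        ref_bases=str(d.get("ref_bases", "")).upper(),
        alt_bases=str(d.get("alt_bases", "")).upper(),
    )


def load_locus_config(path) -> tuple[LocusSpec, Optional[DonorSpec]]:
    """Load one locus (and optional donor) from a YAML config document."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "locus" not in doc:
        raise LocusError(f"config {path} must contain a 'locus' mapping")
    loc = doc["locus"]
    locus = LocusSpec(
        name=str(loc.get("name", path.stem)),
        amplicon=_read_sequence_field(loc["amplicon"], path.parent),
        protospacer=str(loc["protospacer"]).upper(),
        pam_strand=loc.get("pam_strand", "plus"),
        fwd_primer=str(loc.get("fwd_primer", "")).upper(),
        rev_primer=str(loc.get("rev_primer", "")).upper(),
        cut_index=loc.get("cut_index"),
    )
    donor = None
    if "donor" in doc and doc["donor"]:
        dn = doc["donor"]
        edits = None
        if dn.get("edits"):
            edits = tuple(_edit_from_dict(e) for e in dn["edits"])
        donor = DonorSpec(
            ssodn=_read_sequence_field(dn["ssodn"], path.parent),
            strand=dn.get("strand", "pam"),
            biotin_end=dn.get("biotin_end", "none"),
            arm_upstream_nt=dn.get("arm_upstream_nt"),
            arm_downstream_nt=dn.get("arm_downstream_nt"),
            edits=edits,
        )
        donor.validate(locus)
    return locus, donor


# --------------------------------------------------------------------------
# Demo locus (synthetic) for examples and tests
# --------------------------------------------------------------------------

# Synthetic 160 bp amplicon (not a genomic sequence): 20 bp primers at both
# ends, a unique 20 nt protospacer at positions 62-81 followed by a TGG PAM,
# hence a cut bond at index 79.
_DEMO_AMPLICON = (
    "CAAAGGGGTACGCGAGCAGCGCGTTATTCCGTCTGCAAAAGCAAGCAATAGGTAGAGTAGTC"
    "CGAACGGGGTTATTGGCGGTTGGTCGATCAGTAATATCGCGACCTTGCAGATTAAGACAACA"
    "GAGCTGACCCCGAACGGTGTCCGCAACGGGGTTGAT"
)


def demo_locus() -> LocusSpec:
    """A synthetic demonstration locus with a plus-strand guide."""
    return LocusSpec(
        name="demo",
        amplicon=_DEMO_AMPLICON,
        protospacer=_DEMO_AMPLICON[62:82],
        pam_strand="plus",
        fwd_primer=_DEMO_AMPLICON[:20],
        rev_primer=revcomp(_DEMO_AMPLICON[-20:]),
    )


def demo_donor(kind: str = "snv3", locus: Optional[LocusSpec] = None) -> DonorSpec:
    """Synthetic donors emulating the study's edit types.

    ``snv3``: a 3-nucleotide switch at the cut (fluorophore-switch style);
    ``ins12``: a 12-nucleotide insertion at the cut bond;
    ``ins18``: an 18-nucleotide insertion at the cut bond.
    """
    locus = locus or demo_locus()
    cut = locus.cut_index
    assert cut is not None
    if kind == "snv3":
        ref = locus.amplicon[cut : cut + 3]
        alt = "".join({"A": "C", "C": "A", "G": "T", "T": "G"}[b] for b in ref)
        edits = [Edit(cut, "substitution", ref_bases=ref, alt_bases=alt)]
    elif kind == "ins12":
        edits = [Edit(cut, "insertion", alt_bases="GAATTCGGATCC")]
    elif kind == "ins18":
        edits = [Edit(cut, "insertion", alt_bases="GAATTCGGATCCAAGCTT")]
    else:
        raise ValueError(f"unknown demo donor kind {kind!r}")
    return DonorSpec.from_edits(locus, edits, arm_upstream_nt=40, arm_downstream_nt=40)
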