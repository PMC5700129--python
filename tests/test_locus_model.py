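"""Locus/donor geometry: cut-site derivation, edit application, donor handling."""

import pytest

from ampedit import (
    DonorSpec,
    Edit,
    LocusError,
    LocusSpec,
    apply_edits,
    demo_donor,
    demo_locus,
    derive_cut_index,
    expected_hdr_allele,
    load_locus_config,
)
from ampedit._dna import revcomp
from ampedit.locus_model import infer_edits


class TestCutIndex:
    def test_plus_strand_cut_is_three_nt_from_pam(self, locus):
        # protospacer occupies [62, 82), PAM at 82; blunt cut 3 nt 5' of PAM
        assert locus.cut_index == 82 - 3

    def test_minus_strand_cut_mirrors_through_revcomp(self, locus):
        flipped = LocusSpec(
            name="demo_rc",
            amplicon=revcomp(locus.amplicon),
            protospacer=locus.protospacer,
            pam_strand="minus",
        )
        assert flipped.cut_index == len(locus.amplicon) - locus.cut_index

    def test_absent_protospacer_raises(self, locus):
        with pytest.raises(LocusError, match="not found"):
            LocusSpec(name="x", amplicon=locus.amplicon, protospacer="A" * 20)

    def test_protospacer_without_pam_raises(self):
        # protospacer present but followed by TAT, not NGG
        amp = "CCCCAAAATTTTGGGGACGTACGTACGTACGTAGCT" + "TAT" + "CCAACCAAGGTTGGTTACGT"
        proto = "ACGTACGTACGTACGTAGCT"
        with pytest.raises(LocusError, match="PAM"):
            LocusSpec(name="x", amplicon=amp, protospacer=proto)

    def test_duplicated_protospacer_raises(self):
        core = "ACGTTACGGATCCTAGCAAT"
        amp = "GGCCTTAA" + core + "TGG" + "CATCAT" + core + "TGG" + "AATTCCGG"
        with pytest.raises(LocusError, match="unique"):
            LocusSpec(name="x", amplicon=amp, protospacer=core)


class TestApplyEdits:
    def test_substitution(self):
        edit = Edit(4, "substitution", ref_bases="C", alt_bases="T")
        assert apply_edits("AAACCCGGG", [edit]) == "AAACTCGGG"

    def test_insertion_length_arithmetic(self, locus, donor_ins12):
        allele = expected_hdr_allele(locus, donor_ins12)
        assert len(allele) == len(locus.amplicon) + 12

    def test_deletion(self):
        edit = Edit(3, "deletion", ref_bases="CCC")
        assert apply_edits("AAACCCGGG", [edit]) == "AAAGGG"

    def test_empty_edit_list_rejected(self):
        with pytest.raises(LocusError, match="empty"):
            apply_edits("AAACCCGGG", [])

    def test_overlapping_edits_rejected(self):
        edits = [
            Edit(2, "deletion", ref_bases="AC"),
            Edit(3, "substitution", ref_bases="C", alt_bases="G"),
        ]
        with pytest.raises(LocusError, match="overlap"):
            apply_edits("AAACCCGGG", edits)

    def test_edit_outside_amplicon_rejected(self):
        with pytest.raises(LocusError):
            apply_edits("AAACCC", [Edit(5, "deletion", ref_bases="CC")])

    def test_mismatched_ref_bases_rejected(self):
        with pytest.raises(LocusError, match="do not match"):
            apply_edits("AAACCC", [Edit(0, "substitution", ref_bases="G", alt_bases="T")])

    @pytest.mark.parametrize("kind", ["snv3", "ins12", "ins18"])
    def test_expected_allele_differs_from_amplicon(self, locus, kind):
        allele = expected_hdr_allele(locus, demo_donor(kind, locus))
        assert allele != locus.amplicon


class TestDonor:
    def test_net_length_change_matches_edit_sum(self, locus):
        for kind in ("snv3", "ins12", "ins18"):
            donor = demo_donor(kind, locus)
            allele = expected_hdr_allele(locus, donor)
            net = sum(e.net_length_change for e in donor.resolved_edits(locus))
            assert len(allele) - len(locus.amplicon) == net

    def test_strand_normalization_is_involution(self, locus, donor_snv3):
        import dataclasses

        non_pam = dataclasses.replace(
            donor_snv3, ssodn=revcomp(donor_snv3.ssodn), strand="non_pam"
        )
        once = non_pam.normalized(locus)
        assert once.normalized(locus) == once
        assert once.ssodn == donor_snv3.ssodn

    def test_inferred_edits_match_declared(self, locus):
        for kind in ("snv3", "ins12", "ins18"):
            donor = demo_donor(kind, locus)
            inferred = infer_edits(donor.oriented_ssodn(locus), locus)
            assert apply_edits(locus.amplicon, inferred) == expected_hdr_allele(locus, donor)

    def test_donor_identical_to_reference_rejected(self, locus):
        with pytest.raises(LocusError):
            infer_edits(locus.amplicon[40:120], locus)

    def test_alignment_round_trip_recovers_net_length(self, locus, donor_ins12):
        from ampedit import extract_events, global_align

        allele = expected_hdr_allele(locus, donor_ins12)
        events = global_align(allele, locus.amplicon).events
        net = sum(e.length for e in events if e.kind == "insertion") - sum(
            e.length for e in events if e.kind == "deletion"
        )
        assert net == 12


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path, locus, donor_snv3):
        cfg = tmp_path / "locus.yaml"
        cfg.write_text(
            "locus:\n"
            f"  name: demo\n"
            f"  amplicon: {locus.amplicon}\n"
            f"  protospacer: {locus.protospacer}\n"
            f"  pam_strand: plus\n"
            f"  fwd_primer: {locus.fwd_primer}\n"
            f"  rev_primer: {locus.rev_primer}\n"
            "donor:\n"
            f"  ssodn: {donor_snv3.ssodn}\n"
            f"  strand: pam\n"
        )
        loaded_locus, loaded_donor = load_locus_config(cfg)
        assert loaded_locus.cut_index == locus.cut_index
        assert loaded_donor is not None
        assert expected_hdr_allele(loaded_locus, loaded_donor) == expected_hdr_allele(
            locus, donor_snv3
        )

    def test_amplicon_from_fasta(self, tmp_path, locus):
        (tmp_path / "amp.fasta").write_text(f">demo\n{locus.amplicon}\n")
        cfg = tmp_path / "locus.yaml"
        cfg.write_text(
            "locus:\n"
            "  name: demo\n"
            "  amplicon: {fasta: amp.fasta, record: demo}\n"
            f"  protospacer: {locus.protospacer}\n"
        )
        loaded, _ = load_locus_config(cfg)
        assert loaded.amplicon == locus.amplicon

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(LocusError):
            LocusSpec(name="x", amplicon="ACGTRYACGT", protospacer="A" * 17)
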