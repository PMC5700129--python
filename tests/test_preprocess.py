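"""Preprocessing: quality filtering, collapsing, the strict <10 frequency
filter, and primer-anchored target identification."""

import pytest

from ampedit import (
    ReadRecord,
    SimulationConfig,
    UniqueSequence,
    collapse_reads,
    filter_low_frequency,
    filter_low_quality,
    identify_targets,
    parse_fastq,
    preprocess_sample,
    simulate_sample,
    write_fastq,
)
from ampedit._dna import revcomp
from ampedit.preprocess import FastqParseError

from conftest import truth_class_by_sequence


def make_read(seq, q=40, read_id="r"):
    return ReadRecord(read_id, seq, (q,) * len(seq))


class TestQualityFilter:
    def test_high_quality_reads_retained(self):
        reads = [make_read("ACGT", 40, f"r{i}") for i in range(5)]
        kept, discarded = filter_low_quality(reads, 20)
        assert kept == reads and discarded == 0

    def test_low_mean_quality_discarded(self):
        kept, discarded = filter_low_quality([make_read("ACGT", 10)], 20)
        assert kept == [] and discarded == 1

    def test_threshold_separates_simulated_quality_classes(self, locus, donor_snv3):
        cfg = SimulationConfig(
            locus=locus, donor=donor_snv3, n_reads=1000, subst_error_rate=0.0,
            frac_low_quality=0.1, seed=5,
        )
        reads, truth = simulate_sample(cfg)
        n_lowq = int((truth["true_class"] == "LOWQ").sum())
        records = [
            ReadRecord(r.read_id, r.sequence, tuple(ord(c) - 33 for c in r.quality))
            for r in reads
        ]
        kept, discarded = filter_low_quality(records, 20)
        assert discarded == n_lowq
        kept_ids = {r.read_id for r in kept}
        lowq_ids = set(truth.loc[truth["true_class"] == "LOWQ", "read_id"])
        assert kept_ids.isdisjoint(lowq_ids)


class TestCollapse:
    def test_counts_and_tie_breaking(self):
        reads = [make_read(s) for s in ["AAA", "AAT", "AAA"]]
        assert collapse_reads(reads) == [
            UniqueSequence("AAA", 2),
            UniqueSequence("AAT", 1),
        ]

    def test_empty_stream(self):
        assert collapse_reads([]) == []

    def test_noise_free_uniques_equal_truth_alleles(self, locus, donor_snv3):
        cfg = SimulationConfig(
            locus=locus, donor=donor_snv3, n_reads=2000, subst_error_rate=0.0, seed=3,
        )
        reads, truth = simulate_sample(cfg)
        uniques = collapse_reads(
            [ReadRecord(r.read_id, r.sequence, (40,)) for r in reads]
        )
        n_alleles = len({r.sequence for r in reads})
        assert len(uniques) == n_alleles
        assert sum(u.count for u in uniques) == len(reads)


class TestFrequencyFilter:
    def test_strict_threshold_boundary(self):
        uniques = [UniqueSequence("A" * 30, 12), UniqueSequence("C" * 30, 9)]
        kept, removed = filter_low_frequency(uniques, 10)
        assert kept == [UniqueSequence("A" * 30, 12)]
        assert removed == 9

    def test_count_exactly_ten_retained(self):
        kept, _ = filter_low_frequency([UniqueSequence("A" * 30, 10)], 10)
        assert kept == [UniqueSequence("A" * 30, 10)]

    def test_min_count_one_is_identity(self):
        uniques = [UniqueSequence("ACGT", 1), UniqueSequence("TTTT", 500)]
        kept, removed = filter_low_frequency(uniques, 1)
        assert kept == uniques and removed == 0


class TestTargetIdentification:
    def test_exact_amplicon_is_target(self, locus):
        result = identify_targets([UniqueSequence(locus.amplicon, 5)], locus)
        assert result.targets == [UniqueSequence(locus.amplicon, 5)]

    def test_reverse_complement_is_flipped(self, locus):
        result = identify_targets([UniqueSequence(revcomp(locus.amplicon), 5)], locus)
        assert result.targets == [UniqueSequence(locus.amplicon, 5)]
        assert result.n_flipped == 5

    def test_extra_flanking_bases_trimmed(self, locus):
        padded = "GT" + locus.amplicon + "AC"
        result = identify_targets([UniqueSequence(padded, 3)], locus)
        assert result.targets == [UniqueSequence(locus.amplicon, 3)]

    def test_shuffled_amplicon_discarded(self, locus, donor_snv3):
        cfg = SimulationConfig(
            locus=locus, donor=donor_snv3, n_reads=500, subst_error_rate=0.0,
            frac_offtarget=0.2, seed=9,
        )
        reads, truth = simulate_sample(cfg)
        by_seq = truth_class_by_sequence(reads, truth)
        uniques = collapse_reads(
            [ReadRecord(r.read_id, r.sequence, (40,)) for r in reads]
        )
        result = identify_targets(uniques, locus)
        n_offtarget = int((truth["true_class"] == "OFFTARGET").sum())
        assert result.discarded_reads == n_offtarget
        assert all(by_seq.get(t.sequence) != "OFFTARGET" for t in result.targets)

    def test_idempotent(self, locus):
        first = identify_targets([UniqueSequence(revcomp(locus.amplicon), 4)], locus)
        second = identify_targets(first.targets, locus)
        assert second.targets == first.targets

    def test_primer_longer_than_sequence_discards(self, locus):
        result = identify_targets([UniqueSequence("ACG", 2)], locus)
        assert result.targets == [] and result.discarded_reads == 2


class TestPipelineConservation:
    def test_stage_counts_conserve_reads(self, tmp_path, locus, donor_snv3):
        cfg = SimulationConfig(
            locus=locus, donor=donor_snv3, n_reads=3000, subst_error_rate=0.002,
            frac_low_quality=0.05, frac_offtarget=0.05, frac_reverse_orientation=0.1,
            seed=21,
        )
        reads, _ = simulate_sample(cfg)
        path = tmp_path / "sample.fastq"
        write_fastq(reads, path)
        targets, counts = preprocess_sample(parse_fastq(path), locus)
        assert counts.n_raw == 3000
        assert counts.n_raw == counts.n_quality_pass + counts.n_lowq_discarded
        assert (
            counts.target_reads + counts.target_discarded_reads
            + counts.freq_discarded_reads
            == counts.n_quality_pass
        )
        assert sum(t.count for t in targets) == counts.target_reads

    def test_noise_free_sample_fully_retained(self, tmp_path, locus, donor_snv3):
        cfg = SimulationConfig(
            locus=locus, donor=donor_snv3, n_reads=2000, subst_error_rate=0.0, seed=2,
        )
        reads, _ = simulate_sample(cfg)
        uniques = collapse_reads(
            [ReadRecord(r.read_id, r.sequence, (40,)) for r in reads]
        )
        result = identify_targets(uniques, locus)
        assert result.discarded_reads == 0
        assert sum(t.count for t in result.targets) == 2000

    def test_malformed_fastq_raises_with_index(self, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n+\nII\n")
        with pytest.raises(FastqParseError, match="index 1"):
            list(parse_fastq(bad))
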