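"""Amplicon read simulator with a known truth table.

Generates single-orientation FASTQ reads spanning the full amplicon as a
stand-in for deposited HiSeq/MiSeq amplicon data: a configured mixture of
wild-type, ssODN-templated HDR, and cut-site-centered NHEJ indel alleles,
plus optional nuisance classes (off-target reads without primers,
low-quality reads, reverse-orientation reads) and uniform per-base
substitution error.  Every read is recorded in a truth table so pipeline
output can be scored against known labels.

NHEJ model: one indel per read.  A deletion's interval is chosen uniformly
among placements containing the (jittered) cut bond; an insertion of
uniform random bases is placed at the jittered bond.  Indel lengths follow
truncated geometric distributions.  Off-target and low-quality fractions
carve probability mass from the whole; the allele classes share the
remainder in proportion to ``p_hdr``/``p_nhej``/``p_wt``.
"""

from __future__ import annotations

import dataclasses
import gzip
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from ._dna import DNA_BASES, revcomp
from .locus_model import DonorSpec, LocusSpec, expected_hdr_allele

__all__ = [
    "SimulationConfigError",
    "IndelModel",
    "SimulationConfig",
    "FastqRead",
    "PairedSimulation",
    "simulate_sample",
    "simulate_paired_conditions",
    "write_fastq",
    "write_truth_table",
]


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class IndelModel:
    """NHEJ indel spectrum: small, cut-site-proximal events dominate."""

    p_deletion: float = 0.6
    del_len_geometric_p: float = 0.5
    max_del_len: int = 12
    ins_len_geometric_p: float = 0.8
    max_ins_len: int = 6
    position_jitter_nt: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_deletion <= 1.0:
            raise SimulationConfigError("p_deletion must be in [0,1]")
        for p in (self.del_len_geometric_p, self.ins_len_geometric_p):
            if not 0.0 < p <= 1.0:
                raise SimulationConfigError("geometric parameters must be in (0,1]")
        if self.max_del_len < 1 or self.max_ins_len < 1:
            raise SimulationConfigError("max indel lengths must be >= 1")
        if self.position_jitter_nt < 0:
            raise SimulationConfigError("position_jitter_nt must be >= 0")


@dataclass
class SimulationConfig:
    """One simulated sample's study conditions.

    Defaults mirror a bulk-editing amplicon experiment: 50,000 reads with
    4% HDR and 16% NHEJ alleles and a 0.1% per-base substitution error.
    """

    locus: LocusSpec
    donor: Optional[DonorSpec]
    n_reads: int = 50_000
    p_hdr: float = 0.04
    p_nhej: float = 0.16
    indel_model: IndelModel = field(default_factory=IndelModel)
    subst_error_rate: float = 0.001
    q_high: int = 35
    q_low: int = 8
    frac_low_quality: float = 0.0
    frac_offtarget: float = 0.0
    frac_reverse_orientation: float = 0.0
    compound_hdr_frac: float = 0.0
    sample_id: str = "sim"
    seed: int = 1

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise SimulationConfigError("n_reads must be > 0")
        for name in (
            "p_hdr",
            "p_nhej",
            "subst_error_rate",
            "frac_low_quality",
            "frac_offtarget",
            "frac_reverse_orientation",
            "compound_hdr_frac",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0,1]")
        if self.p_hdr + self.p_nhej > 1.0 + 1e-12:
            raise SimulationConfigError("p_hdr + p_nhej must be <= 1")
        if self.frac_low_quality + self.frac_offtarget > 1.0 + 1e-12:
            raise SimulationConfigError("nuisance fractions must sum to <= 1")
        if self.p_hdr > 0 and self.donor is None:
            raise SimulationConfigError("p_hdr > 0 requires a donor")
        self.indel_model.validate()


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    quality: str  # Phred+33 encoded


def _truncated_geometric_cdf(p: float, max_len: int) -> np.ndarray:
    lengths = np.arange(1, max_len + 1)
    pmf = p * (1.0 - p) ** (lengths - 1)
    pmf /= pmf.sum()
    return np.cumsum(pmf)


def _draw_length(rng: np.random.Generator, cdf: np.ndarray) -> int:
    return int(np.searchsorted(cdf, rng.random()) + 1)


def _apply_substitution_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0.0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in DNA_BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _draw_nhej_allele(
    background: str,
    cut: int,
    model: IndelModel,
    rng: np.random.Generator,
    del_cdf: np.ndarray,
    ins_cdf: np.ndarray,
) -> tuple[str, dict]:
    """One indel allele on ``background``; returns (sequence, event dict)."""
    jitter = model.position_jitter_nt
    bond = cut + int(rng.integers(-jitter, jitter + 1)) if jitter else cut
    bond = min(max(bond, 1), len(background) - 1)
    if rng.random() < model.p_deletion:
        length = _draw_length(rng, del_cdf)
        # choose a deletion interval containing the bond, inside the primers
        lo = max(1, bond - length)
        hi = min(bond, len(background) - length - 1)
        start = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
        seq = background[:start] + background[start + length :]
        event = {
            "event_kind": "deletion",
            "event_ref_pos": start,
            "event_length": length,
            "event_bases": "",
        }
    else:
        length = _draw_length(rng, ins_cdf)
        bases = "".join(DNA_BASES[i] for i in rng.integers(0, 4, size=length))
        seq = background[:bond] + bases + background[bond:]
        event = {
            "event_kind": "insertion",
            "event_ref_pos": bond,
            "event_length": length,
            "event_bases": bases,
        }
    return seq, event


_EMPTY_EVENT = {
    "event_kind": "",
    "event_ref_pos": -1,
    "event_length": 0,
    "event_bases": "",
}


def simulate_sample(config: SimulationConfig) -> tuple[List[FastqRead], pd.DataFrame]:
    """Emit ``n_reads`` FASTQ records plus a truth table (one row per read).

    Deterministic for a fixed config (including seed): running twice yields
    byte-identical FASTQ content.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    locus = config.locus
    amplicon = locus.amplicon
    cut = locus.cut_index
    assert cut is not None
    hdr_allele = (
        expected_hdr_allele(locus, config.donor) if config.donor is not None else None
    )
    model = config.indel_model
    del_cdf = _truncated_geometric_cdf(model.del_len_geometric_p, model.max_del_len)
    ins_cdf = _truncated_geometric_cdf(model.ins_len_geometric_p, model.max_ins_len)

    p_off = config.frac_offtarget
    p_lowq = config.frac_low_quality
    remaining = 1.0 - p_off - p_lowq
    p_wt = max(0.0, 1.0 - config.p_hdr - config.p_nhej)

    reads: List[FastqRead] = []
    truth_rows: List[dict] = []

    def allele_class() -> str:
        r = rng.random()
        if r < config.p_hdr:
            return "HDR"
        if r < config.p_hdr + config.p_nhej:
            return "NHEJ"
        return "WT"

    for i in range(config.n_reads):
        read_id = f"{config.sample_id}:{i:06d}"
        r = rng.random()
        event = dict(_EMPTY_EVENT)
        on_hdr_background = False
        if r < p_off:
            true_class = "OFFTARGET"
            seq = amplicon
            for _ in range(10):
                perm = rng.permutation(len(amplicon))
                seq = "".join(amplicon[k] for k in perm)
                if locus.fwd_primer not in seq and revcomp(locus.rev_primer) not in seq:
                    break
            quality = config.q_high
        elif r < p_off + p_lowq:
            true_class = "LOWQ"
            base_class = allele_class()
            if base_class == "HDR":
                seq = hdr_allele  # type: ignore[assignment]
            elif base_class == "NHEJ":
                seq, event = _draw_nhej_allele(amplicon, cut, model, rng, del_cdf, ins_cdf)
            else:
                seq = amplicon
            quality = config.q_low
        else:
            true_class = allele_class()
            if true_class == "HDR":
                seq = hdr_allele  # type: ignore[assignment]
            elif true_class == "NHEJ":
                background = amplicon
                if (
                    config.compound_hdr_frac > 0.0
                    and hdr_allele is not None
                    and rng.random() < config.compound_hdr_frac
                ):
                    background = hdr_allele
                    on_hdr_background = True
                bg_cut = cut if background is amplicon else _shifted_cut(config, cut)
                seq, event = _draw_nhej_allele(
                    background, bg_cut, model, rng, del_cdf, ins_cdf
                )
            else:
                seq = amplicon
            quality = config.q_high

        seq = _apply_substitution_errors(seq, config.subst_error_rate, rng)
        reverse = (
            config.frac_reverse_orientation > 0.0
            and rng.random() < config.frac_reverse_orientation
        )
        if reverse:
            seq = revcomp(seq)
        reads.append(FastqRead(read_id, seq, chr(quality + 33) * len(seq)))
        truth_rows.append(
            {
                "read_id": read_id,
                "true_class": true_class,
                **event,
                "on_hdr_background": on_hdr_background,
                "reverse_orientation": reverse,
            }
        )

    truth = pd.DataFrame(truth_rows)
    return reads, truth


def _shifted_cut(config: SimulationConfig, cut: int) -> int:
    """Cut bond in expected-HDR-allele coordinates (edits may shift it)."""
    assert config.donor is not None
    shift = 0
    for e in config.donor.resolved_edits(config.locus):
        if e.span[1] <= cut:
            shift += e.net_length_change
    return cut + shift


@dataclass
class PairedSimulation:
    sample_a: tuple[List[FastqRead], pd.DataFrame]
    sample_b: tuple[List[FastqRead], pd.DataFrame]
    configured_fold_change: Optional[float]
    realized_fold_change: Optional[float]


def _truth_ratio(truth: pd.DataFrame) -> Optional[float]:
    n_hdr = int((truth["true_class"] == "HDR").sum())
    n_nhej = int((truth["true_class"] == "NHEJ").sum())
    return n_hdr / n_nhej if n_nhej > 0 else None


def simulate_paired_conditions(
    cfg_a: SimulationConfig, cfg_b: SimulationConfig
) -> PairedSimulation:
    """Simulate two conditions and record the truth HDR:NHEJ fold-change
    (a vs b).  Fold-changes are None when a denominator is zero."""
    sample_a = simulate_sample(cfg_a)
    sample_b = simulate_sample(cfg_b)
    configured = None
    if cfg_a.p_nhej > 0 and cfg_b.p_nhej > 0 and cfg_b.p_hdr > 0:
        configured = (cfg_a.p_hdr / cfg_a.p_nhej) / (cfg_b.p_hdr / cfg_b.p_nhej)
    ratio_a = _truth_ratio(sample_a[1])
    ratio_b = _truth_ratio(sample_b[1])
    realized = None
    if ratio_a is not None and ratio_b:
        realized = ratio_a / ratio_b
    return PairedSimulation(sample_a, sample_b, configured, realized)


def write_fastq(reads: List[FastqRead], path) -> None:
    """Write Phred+33 FASTQ (gzip when path ends in .gz)."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
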