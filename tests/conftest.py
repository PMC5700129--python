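"""Shared fixtures: the synthetic demo locus, donors, and truth helpers."""

from __future__ import annotations

import pandas as pd
import pytest

from ampedit import demo_donor, demo_locus
from ampedit.synthetic_reads import FastqRead


@pytest.fixture(scope="session")
def locus():
    return demo_locus()


@pytest.fixture(scope="session")
def donor_snv3(locus):
    return demo_donor("snv3", locus)


@pytest.fixture(scope="session")
def donor_ins12(locus):
    return demo_donor("ins12", locus)


def truth_class_by_sequence(reads: list[FastqRead], truth: pd.DataFrame) -> dict[str, str]:
    """Map emitted read sequence -> truth class (noise-free simulations only:
    each distinct sequence then belongs to exactly one class)."""
    classes = dict(zip(truth["read_id"], truth["true_class"]))
    out: dict[str, str] = {}
    for read in reads:
        cls = classes[read.read_id]
        prev = out.setdefault(read.sequence, cls)
        assert prev == cls, "sequence maps to two truth classes; not noise-free?"
    return out
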