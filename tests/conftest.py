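"""Shared fixtures: the six-plex barcode set and small simulator models."""

import numpy as np
import pandas as pd
import pytest

from traelseq import forksim
from traelseq.readproc import BarcodeTable, ReadLayout

# the six adaptor-strand multiplexing indexes used throughout
ADAPTOR_BARCODES = [
    ("index1", "GACT"),
    ("index3", "CAAG"),
    ("index5", "CCTT"),
    ("index6", "GGAA"),
    ("index7", "GCAC"),
    ("index8", "TGGC"),
]


@pytest.fixture
def barcode_table() -> BarcodeTable:
    return BarcodeTable(entries=list(ADAPTOR_BARCODES))


@pytest.fixture
def layout() -> ReadLayout:
    return ReadLayout()


@pytest.fixture
def lone_origin_model() -> forksim.ForkModel:
    """2 Mb chromosome with one fully efficient central initiation zone."""
    return forksim.ForkModel(
        genome={"chr1": 2_000_000},
        izs=[
            forksim.InitiationZone(
                "chr1", 980_000, 1_020_000, efficiency=1.0, firing_time=1.0, firing_spread=0.1
            )
        ],
        n_cells=20,
        capture_rate=500.0,
    )


def make_read(
    umi: str = "ACGTACGT",
    barcode: str = "AGTC",
    polyt: int = 3,
    insert: str = "GATTACAGATTACAGATTACA",
) -> tuple[str, str]:
    """Construct a raw read from the documented layout; returns (seq, qual)."""
    seq = umi + barcode + "T" * polyt + insert
    return seq, "I" * len(seq)
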