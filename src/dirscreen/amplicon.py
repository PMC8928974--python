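"""Amplicon layout shared by the read simulator and the counting pipeline.

The barcode cassette of every reporter construct is a 450-bp region that is
sequenced as two overlapping amplicons (271 bp first half, 270 bp second
half) under 150-bp paired-end reads.  In the simulated design the first-half
amplicon carries, at fixed offsets from its 5' end:

    [ sub-library primer (20 nt) | sample index (8 nt) | barcode | filler ]

Twenty-four primer sequences and twelve index sequences address up to
24 x 12 = 288 sub-libraries in one pooled run.  The oligo tables below are
deterministic (generated once from a fixed internal seed, with minimum
pairwise Hamming distances so that single sequencing errors cannot convert
one primer/index into another) and are the contract between
:mod:`dirscreen.simdata` and :mod:`dirscreen.readproc`.  Real libraries with
a different architecture can override them via the explicit sequence
arguments of the demultiplexer.
"""

from __future__ import annotations

import numpy as np

from ._utils import BASES

PRIMER_LEN = 20
INDEX_LEN = 8
#: barcode starts right after primer + index
BARCODE_OFFSET = PRIMER_LEN + INDEX_LEN
DEFAULT_BARCODE_LEN = 15
BARCODE_REGION_LEN = 450
FIRST_AMPLICON_LEN = 271
SECOND_AMPLICON_LEN = 270
READ_LEN = 150
N_PRIMERS = 24
N_INDEXES = 12


def _make_oligos(rng: np.random.Generator, n: int, length: int, min_dist: int) -> list[str]:
    accepted: list[np.ndarray] = []
    while len(accepted) < n:
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != a).sum()) >= min_dist for a in accepted):
            accepted.append(cand)
    return ["".join(BASES[b] for b in a) for a in accepted]


_rng = np.random.default_rng(20160801)
PRIMERS: list[str] = _make_oligos(_rng, N_PRIMERS, PRIMER_LEN, 8)
INDEXES: list[str] = _make_oligos(_rng, N_INDEXES, INDEX_LEN, 3)
#: constant filler padding every simulated cassette to 450 bp
FILLER: str = "".join(BASES[b] for b in _rng.integers(0, 4, size=BARCODE_REGION_LEN))
del _rng


def primer_seq(primer_set: int) -> str:
    """Sequence of 1-based primer set 1..24."""
    if not 1 <= primer_set <= N_PRIMERS:
        raise ValueError(f"primer_set must be in 1..{N_PRIMERS}, got {primer_set}")
    return PRIMERS[primer_set - 1]


def index_seq(index: int) -> str:
    """Sequence of 1-based sequencing index 1..12."""
    if not 1 <= index <= N_INDEXES:
        raise ValueError(f"index must be in 1..{N_INDEXES}, got {index}")
    return INDEXES[index - 1]


def build_region(barcode: str, primer_set: int, index: int) -> str:
    """Full 450-bp barcode cassette for one construct in one sub-library."""
    head = primer_seq(primer_set) + index_seq(index) + barcode
    if len(head) > BARCODE_REGION_LEN:
        raise ValueError("barcode too long for the cassette layout")
    return head + FILLER[: BARCODE_REGION_LEN - len(head)]
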