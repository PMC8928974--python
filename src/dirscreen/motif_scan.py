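"""Allele-delta scoring of transcription-factor motifs at a SNP.

Both allele windows (the 55-mers used for the reporter inserts) are scanned
with a position weight matrix derived from a JASPAR position frequency
matrix; only scoring windows that cover the SNP base are considered, since
windows that miss it cannot distinguish the alleles.  Per allele the best
log2-odds hit over offsets and strands is kept; the reported delta is
best(risk) - best(normal), so a positive delta means the risk allele
strengthens the motif match (e.g. an allele that creates a binding site for
a repressor scores delta > 0 for that repressor's matrix).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from ._utils import BASE_INDEX, revcomp, seq_to_u8
from .snp_library import Construct

_ROWS = "ACGT"


@dataclass
class Pwm:
    """Probability/log-odds matrix (rows A, C, G, T) with its pseudocount."""

    name: str
    counts: np.ndarray  # (4, L)
    pseudocount: float = 0.5
    background: np.ndarray | None = None  # (4,), default uniform

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x L matrix with L >= 1")
        if (self.counts < 0).any():
            raise ValueError("negative counts in PFM")
        if self.background is None:
            self.background = np.full(4, 0.25)
        totals = self.counts.sum(axis=0) + 4 * self.pseudocount
        self.probs = (self.counts + self.pseudocount) / totals
        self.log_odds = np.log2(self.probs / self.background[:, None])

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def to_jaspar(self) -> str:
        lines = [f">{self.name}"]
        for i, base in enumerate(_ROWS):
            vals = "  ".join(f"{v:g}" for v in self.counts[i])
            lines.append(f"{base}  [ {vals} ]")
        return "\n".join(lines) + "\n"


def parse_jaspar(source: str | Path, pseudocount: float = 0.5) -> Pwm:
    """Parse a JASPAR-format PFM (text or file path) into a :class:`Pwm`."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        motif = bio_motifs.read(io.StringIO(text), "jaspar")
    except Exception as exc:
        raise ValueError(f"cannot parse JASPAR PFM: {exc}") from exc
    counts = np.array([motif.counts[b] for b in _ROWS], dtype=float)
    name = motif.name or motif.matrix_id or "motif"
    return Pwm(name=name, counts=counts, pseudocount=pseudocount)


def parse_jaspar_all(source: str | Path, pseudocount: float = 0.5) -> list[Pwm]:
    """Parse a multi-record JASPAR PFM file."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    out = []
    for motif in bio_motifs.parse(io.StringIO(text), "jaspar"):
        counts = np.array([motif.counts[b] for b in _ROWS], dtype=float)
        out.append(Pwm(motif.name or motif.matrix_id or "motif", counts, pseudocount))
    return out


@dataclass
class MotifAlleleScore:
    motif: str
    best_normal: float
    best_risk: float
    offset_normal: int
    offset_risk: int
    strand_normal: str
    strand_risk: str

    @property
    def delta(self) -> float:
        return self.best_risk - self.best_normal


def _best_over_center(seq: str, pwm: Pwm, center: int, strands: str) -> tuple[float, int, str]:
    """Max log-odds over windows covering ``center`` (0-based) and strands.

    The minus strand scores the reverse complement of each window; offsets
    always refer to the forward sequence.
    """
    L = pwm.length
    if L > len(seq):
        raise ValueError(f"motif length {L} exceeds sequence length {len(seq)}")
    codes = BASE_INDEX[seq_to_u8(seq.upper())]
    rc_codes = BASE_INDEX[seq_to_u8(revcomp(seq.upper()))]
    lo = max(0, center - L + 1)
    hi = min(len(seq) - L, center)
    best = (-np.inf, -1, "+")
    cols = np.arange(L)
    for o in range(lo, hi + 1):
        if strands in ("both", "+"):
            s = float(pwm.log_odds[codes[o : o + L], cols].sum())
            if s > best[0]:
                best = (s, o, "+")
        if strands in ("both", "-"):
            ro = len(seq) - L - o  # same window on the reverse complement
            s = float(pwm.log_odds[rc_codes[ro : ro + L], cols].sum())
            if s > best[0]:
                best = (s, o, "-")
    return best


def score_alleles(
    seq_normal: str, seq_risk: str, pwm: Pwm, strands: str = "both"
) -> MotifAlleleScore:
    """Best motif hit per allele, windows constrained to cover the SNP base.

    The sequences must be equal-length and differ only at the center base.
    """
    if len(seq_normal) != len(seq_risk):
        raise ValueError("allele sequences must have equal length")
    center = len(seq_normal) // 2
    diffs = [i for i, (a, b) in enumerate(zip(seq_normal, seq_risk)) if a != b]
    if diffs and diffs != [center]:
        raise ValueError(f"allele sequences differ away from the center: {diffs}")
    sn, on, stn = _best_over_center(seq_normal, pwm, center, strands)
    sr, orr, strr = _best_over_center(seq_risk, pwm, center, strands)
    return MotifAlleleScore(pwm.name, sn, sr, on, orr, stn, strr)


def scan_panel(
    constructs: Sequence[Construct], pwms: Sequence[Pwm], strands: str = "both"
) -> pd.DataFrame:
    """Score every SNP x motif pair; rows ranked by |delta| (descending),
    ties broken by (rs_id, motif) for determinism."""
    by_rs: dict[str, dict[str, str]] = {}
    for c in constructs:
        if c.allele_class in ("normal", "risk"):
            by_rs.setdefault(c.rs_id, {})[c.allele_class] = c.insert_seq
    rows = []
    for rs in sorted(by_rs):
        pair = by_rs[rs]
        if set(pair) != {"normal", "risk"}:
            continue
        for pwm in pwms:
            s = score_alleles(pair["normal"], pair["risk"], pwm, strands)
            rows.append(
                {
                    "rs_id": rs,
                    "motif": s.motif,
                    "best_normal": s.best_normal,
                    "best_risk": s.best_risk,
                    "delta": s.delta,
                    "offset_normal": s.offset_normal,
                    "offset_risk": s.offset_risk,
                    "strand_normal": s.strand_normal,
                    "strand_risk": s.strand_risk,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "rs_id",
            "motif",
            "best_normal",
            "best_risk",
            "delta",
            "offset_normal",
            "offset_risk",
            "strand_normal",
            "strand_risk",
        ],
    )
    if len(df):
        df["abs_delta"] = df["delta"].abs()
        df = df.sort_values(
            ["abs_delta", "rs_id", "motif"], ascending=[False, True, True]
        ).drop(columns="abs_delta")
    return df.reset_index(drop=True)
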