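"""Chromatin-assay peak support for nominated SNPs.

Open-chromatin assays (ATAC-seq, DNase-seq) and active histone marks
(H3K27ac, H3K4me3) are loaded as BED peak sets; each screen-nominated SNP is
annotated with a boolean support matrix, and the "active chromatin" rule —
by default (ATAC or DNase) and (H3K27ac or H3K4me3) — picks the final
nominations.  The rule is a first-class boolean expression over assay
names, e.g. ``"(ATAC | DNase) & (H3K27ac | H3K4me3)"``.
"""

from __future__ import annotations

import ast
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .snp_library import SnpRecord

DEFAULT_RULE = "(ATAC | DNase) & (H3K27ac | H3K4me3)"


def _norm_chrom(chrom: str) -> str:
    c = chrom.strip()
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class PeakSet:
    """Sorted genomic intervals (0-based half-open) from one assay."""

    assay: str
    intervals: dict[str, tuple[list[int], list[int]]] = field(default_factory=dict, repr=False)
    # per chromosome: (starts sorted, running max of ends) for O(log n) point queries

    @classmethod
    def from_intervals(cls, assay: str, rows: Sequence[tuple[str, int, int]]) -> "PeakSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in rows:
            if start >= end:
                raise ValueError(f"interval start >= end: {chrom}:{start}-{end}")
            by_chrom.setdefault(_norm_chrom(chrom), []).append((int(start), int(end)))
        intervals = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = [s for s, _ in ivs]
            maxend = list(np.maximum.accumulate([e for _, e in ivs]))
            intervals[chrom] = (starts, maxend)
        return cls(assay, intervals)

    def covers(self, chrom: str, pos0: int) -> bool:
        """True iff 0-based position lies inside some interval."""
        entry = self.intervals.get(_norm_chrom(chrom))
        if entry is None:
            return False
        starts, maxend = entry
        i = bisect_right(starts, pos0)
        return i > 0 and maxend[i - 1] > pos0

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self.intervals.values())


def read_bed(path: str | Path, assay: str | None = None) -> PeakSet:
    """Load a BED file (>= 3 columns; track/comment lines skipped)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 tab-separated columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rows.append((chrom, start, end))
    return PeakSet.from_intervals(assay or Path(path).stem, rows)


def snp_in_peaks(snp: SnpRecord, peaks: PeakSet) -> bool:
    """True iff the SNP's 0-based position (pos - 1) lies in some peak."""
    return peaks.covers(snp.chrom, snp.pos - 1)


def _compile_rule(rule: str, assays: Sequence[str]):
    """Validate a boolean expression over assay names and return an evaluator."""
    tree = ast.parse(rule, mode="eval")
    names: set[str] = set()

    def check(node) -> None:
        if isinstance(node, ast.Expression):
            check(node.body)
        elif isinstance(node, ast.BoolOp) and isinstance(node.op, (ast.And, ast.Or)):
            for v in node.values:
                check(v)
        elif isinstance(node, ast.BinOp) and isinstance(node.op, (ast.BitAnd, ast.BitOr)):
            check(node.left)
            check(node.right)
        elif isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.Not, ast.Invert)):
            check(node.operand)
        elif isinstance(node, ast.Name):
            names.add(node.id)
        else:
            raise ValueError(f"unsupported element in rule: {ast.dump(node)}")

    check(tree)
    missing = names - set(assays)
    if missing:
        raise ValueError(f"rule references assays not provided: {sorted(missing)}")
    code = compile(tree, "<rule>", "eval")

    def evaluate(support: Mapping[str, bool]) -> bool:
        return bool(eval(code, {"__builtins__": {}}, dict(support)))

    return evaluate


def nominate_active(
    dir_hits: Sequence[str],
    peaksets: Mapping[str, PeakSet],
    snps: Sequence[SnpRecord],
    rule: str = DEFAULT_RULE,
) -> pd.DataFrame:
    """Support matrix and nominations for the screen-positive SNPs.

    Returns one row per rs_id in ``dir_hits`` with a boolean column per
    assay and a ``nominated`` column under ``rule``.
    """
    if not dir_hits:
        raise ValueError("empty dir_hits")
    by_rs = {s.rs_id: s for s in snps}
    unknown = [r for r in dir_hits if r not in by_rs]
    if unknown:
        raise ValueError(f"dir_hits not in panel: {unknown}")
    evaluate = _compile_rule(rule, list(peaksets))
    rows = []
    for rs in dir_hits:
        support = {assay: snp_in_peaks(by_rs[rs], ps) for assay, ps in peaksets.items()}
        rows.append({"rs_id": rs, **support, "nominated": evaluate(support)})
    return pd.DataFrame(rows)
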