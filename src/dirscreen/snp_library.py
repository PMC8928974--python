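"""Reporter construct registry for a SNP panel.

A screen library carries, for every biallelic SNP in the panel, two reporter
constructs — one per allele — whose insert is the 55-bp genomic window
centered on the variant (27-nt flanks, allele at 1-based position 28), plus
a single promoter-only "blank" construct that defines activity = 1.  Every
construct is tagged with a unique barcode; sub-libraries (cell line x
DNA/RNA fraction x replicate) are addressed by a 24-primer x 12-index
sample sheet, i.e. at most 288 sub-libraries per pooled run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._utils import BASES, check_dna
from .amplicon import N_INDEXES, N_PRIMERS

#: reserved construct/rs identifier for the promoter-only control
BLANK_ID = "blank"
DEFAULT_FLANK = 27


class ReferenceMismatchWarning(UserWarning):
    """Reference base at the SNP position matches neither panel allele."""


@dataclass(frozen=True)
class SnpRecord:
    """One GWAS SNP with its normal and risk alleles (1-based coordinate)."""

    rs_id: str
    chrom: str
    pos: int
    normal_allele: str
    risk_allele: str
    source_pvalue: float | None = None

    def __post_init__(self):
        for name in ("normal_allele", "risk_allele"):
            allele = getattr(self, name)
            if len(allele) != 1 or allele.upper() not in BASES:
                raise ValueError(
                    f"{self.rs_id}: {name}={allele!r} is not a single A/C/G/T base "
                    "(only biallelic single-nucleotide substitutions are supported)"
                )
            object.__setattr__(self, name, allele.upper())
        if self.normal_allele == self.risk_allele:
            raise ValueError(f"{self.rs_id}: normal and risk alleles are identical")
        if self.pos < 1:
            raise ValueError(f"{self.rs_id}: pos must be >= 1 (1-based), got {self.pos}")


@dataclass(frozen=True)
class Construct:
    """One reporter insert (SNP x allele, or the blank control) with its barcode."""

    construct_id: str
    rs_id: str
    allele_class: str  # "normal" | "risk" | "blank"
    insert_seq: str  # 55-mer for SNP constructs, "" for blank
    barcode: str
    sub_panel: str | None = None

    def __post_init__(self):
        if self.allele_class not in ("normal", "risk", "blank"):
            raise ValueError(f"bad allele_class {self.allele_class!r}")
        if self.allele_class == "blank":
            if self.insert_seq:
                raise ValueError("blank construct must have an empty insert")
        check_dna(self.barcode, "barcode")


@dataclass
class SampleSheet:
    """Sub-library addressing: sample -> (primer_set 1..24, index 1..12)."""

    rows: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "cell_line", "fraction", "replicate", "primer_set", "index")

    def __post_init__(self):
        df = self.rows
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if len(df) > N_PRIMERS * N_INDEXES:
            raise ValueError(
                f"sample-sheet capacity is {N_PRIMERS * N_INDEXES} "
                f"({N_PRIMERS} primers x {N_INDEXES} indexes); got {len(df)} samples"
            )
        pairs = list(zip(df["primer_set"], df["index"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (primer_set, index) pairs in sample sheet")
        bad = df[~df["fraction"].isin(["DNA", "RNA"])]
        if len(bad):
            raise ValueError(f"fraction must be DNA or RNA: {bad['sample_id'].tolist()}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")

    def pair_to_sample(self) -> dict[tuple[int, int], str]:
        return {
            (int(p), int(i)): s
            for p, i, s in zip(self.rows["primer_set"], self.rows["index"], self.rows["sample_id"])
        }

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# panel IO


def read_panel(path: str | Path) -> list[SnpRecord]:
    """Read a SNP panel TSV (rs_id, chrom, pos, normal_allele, risk_allele[, pvalue])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["rs_id", "chrom", "pos", "normal_allele", "risk_allele"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"panel file missing columns: {missing}")
    snps = [
        SnpRecord(
            rs_id=row.rs_id,
            chrom=str(row.chrom),
            pos=int(row.pos),
            normal_allele=row.normal_allele,
            risk_allele=row.risk_allele,
            source_pvalue=float(row.pvalue) if "pvalue" in df.columns else None,
        )
        for row in df.itertuples()
    ]
    _check_unique([s.rs_id for s in snps])
    return snps


def _check_unique(rs_ids: Sequence[str]) -> None:
    seen, dup = set(), set()
    for r in rs_ids:
        (dup if r in seen else seen).add(r)
    if dup:
        raise ValueError(f"duplicate rs_id in panel: {sorted(dup)}")


# ---------------------------------------------------------------------------
# window extraction


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Fetch [start0, end0) from a mapping of contigs or a fetch()-style object
    (pysam.FastaFile, pyfaidx.Fasta)."""
    if start0 < 0:
        raise ValueError(f"window [{start0}, {end0}) extends past the start of {chrom}")
    fetch = getattr(reference, "fetch", None)
    if callable(fetch):
        seq = str(fetch(chrom, start0, end0))
    else:
        try:
            contig = reference[chrom]
        except KeyError as exc:
            raise ValueError(f"chromosome {chrom!r} not in reference") from exc
        seq = str(contig[start0:end0])
    if len(seq) != end0 - start0:
        raise ValueError(f"window [{start0}, {end0}) out of reference bounds on {chrom}")
    return seq.upper()


def extract_snp_window(
    reference, snp: SnpRecord, flank: int = DEFAULT_FLANK
) -> tuple[str, str]:
    """Extract the SNP-centered insert pair (normal, risk) on the plus strand.

    Both returned strings have length ``2*flank + 1`` and are identical except
    at the center base, which carries the respective allele.  If the reference
    base at the SNP position matches neither allele a
    :class:`ReferenceMismatchWarning` is issued and the alleles are
    substituted in anyway.
    """
    start0 = snp.pos - 1 - flank
    window = _fetch(reference, snp.chrom, start0, snp.pos + flank)
    ref_base = window[flank]
    if ref_base not in (snp.normal_allele, snp.risk_allele):
        warnings.warn(
            f"{snp.rs_id}: reference base {ref_base!r} at {snp.chrom}:{snp.pos} matches "
            f"neither allele ({snp.normal_allele}/{snp.risk_allele}); substituting",
            ReferenceMismatchWarning,
            stacklevel=2,
        )
    left, right = window[:flank], window[flank + 1 :]
    return left + snp.normal_allele + right, left + snp.risk_allele + right


# ---------------------------------------------------------------------------
# barcodes and library assembly


def _sample_barcodes(
    rng: np.random.Generator, n: int, length: int, min_dist: int
) -> list[str]:
    accepted = np.empty((n, length), dtype=np.int64)
    count = 0
    attempts = 0
    max_attempts = 2000 * n + 10000
    while count < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"barcode space exhausted: could not place {n} barcodes of length "
                f"{length} at pairwise Hamming distance >= {min_dist}"
            )
        cand = rng.integers(0, 4, size=length)
        if count == 0 or ((accepted[:count] != cand).sum(axis=1) >= min_dist).all():
            accepted[count] = cand
            count += 1
    return ["".join(BASES[b] for b in row) for row in accepted]


def build_library(
    snps: Sequence[SnpRecord],
    reference=None,
    *,
    barcode_length: int = 15,
    min_barcode_distance: int = 3,
    flank: int = DEFAULT_FLANK,
    seed: int = 0,
) -> list[Construct]:
    """Build the construct registry: 2 constructs per SNP plus one blank.

    ``reference`` may be any object accepted by :func:`extract_snp_window`.
    When it is None, synthetic flanking sequence is drawn from the seeded
    generator (useful for simulated studies; the insert is then a synthetic
    stand-in for the genomic window, not real genome sequence).

    Barcodes are rejection-sampled with pairwise Hamming distance >=
    ``min_barcode_distance`` and are deterministic under a fixed seed.
    """
    if not snps:
        raise ValueError("empty SNP panel")
    _check_unique([s.rs_id for s in snps])
    n_constructs = 2 * len(snps) + 1
    if 4**barcode_length < n_constructs:
        raise ValueError(
            f"4^{barcode_length} barcodes cannot label {n_constructs} constructs"
        )
    rng = np.random.default_rng(seed)
    barcodes = _sample_barcodes(rng, n_constructs, barcode_length, min_barcode_distance)

    constructs = [
        Construct(
            construct_id=BLANK_ID,
            rs_id=BLANK_ID,
            allele_class="blank",
            insert_seq="",
            barcode=barcodes[0],
        )
    ]
    k = 1
    for snp in snps:
        if reference is None:
            left = "".join(BASES[b] for b in rng.integers(0, 4, size=flank))
            right = "".join(BASES[b] for b in rng.integers(0, 4, size=flank))
            normal = left + snp.normal_allele + right
            risk = left + snp.risk_allele + right
        else:
            normal, risk = extract_snp_window(reference, snp, flank=flank)
        for allele_class, insert in (("normal", normal), ("risk", risk)):
            constructs.append(
                Construct(
                    construct_id=f"{snp.rs_id}_{allele_class}",
                    rs_id=snp.rs_id,
                    allele_class=allele_class,
                    insert_seq=insert,
                    barcode=barcodes[k],
                )
            )
            k += 1
    return constructs


def build_sample_sheet(
    samples: Iterable[tuple[str, str, int]] | pd.DataFrame,
) -> SampleSheet:
    """Assign (primer_set, index) pairs to samples, filled index-major.

    ``samples`` is an iterable of (cell_line, fraction, replicate) triples;
    sample k gets primer_set ``k // 12 + 1`` and index ``k % 12 + 1``, so the
    index cycles fastest and 288 samples use every pair exactly once.
    """
    if isinstance(samples, pd.DataFrame):
        triples = list(samples[["cell_line", "fraction", "replicate"]].itertuples(index=False))
    else:
        triples = list(samples)
    capacity = N_PRIMERS * N_INDEXES
    if len(triples) > capacity:
        raise ValueError(
            f"sample-sheet capacity is {capacity} ({N_PRIMERS} primers x "
            f"{N_INDEXES} indexes); got {len(triples)} samples"
        )
    rows = []
    for k, (cell, fraction, rep) in enumerate(triples):
        rows.append(
            {
                "sample_id": f"{cell}_{fraction}_r{rep}",
                "cell_line": cell,
                "fraction": fraction,
                "replicate": int(rep),
                "primer_set": k // N_INDEXES + 1,
                "index": k % N_INDEXES + 1,
            }
        )
    return SampleSheet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# construct IO


def constructs_to_frame(constructs: Sequence[Construct]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "construct_id": [c.construct_id for c in constructs],
            "rs_id": [c.rs_id for c in constructs],
            "allele_class": [c.allele_class for c in constructs],
            "insert_seq": [c.insert_seq for c in constructs],
            "barcode": [c.barcode for c in constructs],
        }
    )


def write_constructs_tsv(constructs: Sequence[Construct], path: str | Path) -> None:
    constructs_to_frame(constructs).to_csv(path, sep="\t", index=False)


def read_constructs_tsv(path: str | Path) -> list[Construct]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        Construct(
            construct_id=row.construct_id,
            rs_id=row.rs_id,
            allele_class=row.allele_class,
            insert_seq=row.insert_seq,
            barcode=row.barcode,
        )
        for row in df.itertuples()
    ]


def barcode_map(constructs: Sequence[Construct]) -> dict[str, str]:
    """barcode -> construct_id; errors on duplicate barcodes."""
    out: dict[str, str] = {}
    for c in constructs:
        if c.barcode in out:
            raise ValueError(f"duplicate barcode {c.barcode} in library")
        out[c.barcode] = c.construct_id
    return out


def write_oligo_fasta(
    constructs: Sequence[Construct],
    path: str | Path,
    adapter5: str = "",
    adapter3: str = "",
) -> None:
    """Emit insert oligos as FASTA, with optional cloning-adapter prefix/suffix."""
    records = [
        SeqRecord(
            Seq(adapter5 + c.insert_seq + adapter3),
            id=c.construct_id,
            description=f"{c.rs_id} {c.allele_class}",
        )
        for c in constructs
        if c.allele_class != "blank"
    ]
    SeqIO.write(records, str(path), "fasta")
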