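"""Synthetic study generator with planted ground truth.

Emulates the statistical structure the analysis assumes, end to end:

* a construct library with planted per-allele reporter activities (blank = 1);
* a plasmid-pool (DNA) abundance distribution drawn once from a symmetric
  Dirichlet, then multinomial sequencing counts per sub-library;
* RNA counts whose expected proportions are DNA proportion x true activity x
  per-construct lognormal replicate noise — under this model the RNA/DNA
  counts-per-million ratio is a consistent estimator of activity;
* 150-bp paired-end reads off the 271-bp first-half barcode amplicon, with
  primer/index/barcode at the fixed offsets of :mod:`dirscreen.amplicon` and
  i.i.d. per-base substitution errors;
* BED peak sets covering a chosen SNP subset, and qPCR Ct tables with
  Ct = baseline - log2(abundance) + Gaussian noise.

Every output is deterministic under a fixed seed.  The planted regulatory
pattern follows the two-stage nomination rule: a regulatory SNP's two
alleles sit at ``c*sqrt(f)`` and ``c/sqrt(f)`` with ``c = 1.5/sqrt(2)``, so a
fold-2 SNP has allele activities 1.5 and 0.75 — differing between alleles
and with at least one allele outside the [0.8, 1.2] band.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import amplicon
from ._utils import BASE_U8, seq_to_u8
from .snp_library import (
    BLANK_ID,
    Construct,
    SampleSheet,
    SnpRecord,
    build_library,
    build_sample_sheet,
)

#: geometric center of the planted allele pair; sqrt(2)*scale = 1.5
ACTIVITY_SCALE = 1.5 / math.sqrt(2.0)


@dataclass
class SimConfig:
    """Study conditions for the synthetic screen.

    Defaults mirror the screen design this package models: triplicate
    transfections, ~10^6 reads per sub-library, a moderately uneven plasmid
    pool, tight replicate agreement (CV 10%), and the 450-bp cassette split
    into 271/270-bp amplicons for 150-bp paired-end reads.
    """

    n_snps: int = 288
    fraction_regulatory: float = 0.1
    fold_range: tuple[float, ...] = (2.0,)
    n_replicates: int = 3
    read_depth: int = 1_000_000
    dna_dirichlet_concentration: float = 5.0
    replicate_noise_cv: float = 0.10
    per_base_error_rate: float = 0.0
    barcode_region_length: int = amplicon.BARCODE_REGION_LEN
    read_length: int = amplicon.READ_LEN
    amplicon_split: tuple[int, int] = (
        amplicon.FIRST_AMPLICON_LEN,
        amplicon.SECOND_AMPLICON_LEN,
    )
    barcode_length: int = amplicon.DEFAULT_BARCODE_LEN
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1 or self.n_replicates < 1 or self.read_depth < 1:
            raise ValueError("n_snps, n_replicates and read_depth must be positive")
        if not 0.0 <= self.fraction_regulatory <= 1.0:
            raise ValueError("fraction_regulatory must lie in [0, 1]")
        if self.per_base_error_rate < 0 or self.per_base_error_rate >= 1:
            raise ValueError("per_base_error_rate must lie in [0, 1)")
        first, second = self.amplicon_split
        if first > self.barcode_region_length or second > self.barcode_region_length:
            raise ValueError("amplicon halves cannot exceed the barcode region")
        if 2 * self.read_length - first < 1:
            raise ValueError("read pairs must overlap on the first amplicon")
        if amplicon.BARCODE_OFFSET + self.barcode_length > self.read_length:
            raise ValueError("barcode is unreachable within the first read")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("fold_range", "amplicon_split"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["fold_range"] = list(self.fold_range)
        d["amplicon_split"] = list(self.amplicon_split)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Planted activities per construct and the implied per-SNP truth flags."""

    constructs: pd.DataFrame = field(repr=False)  # construct_id, rs_id, allele_class, true_activity
    snps: pd.DataFrame = field(repr=False)  # rs_id, normal/risk activity, true_fold, direction, is_regulatory

    def activity_vector(self, construct_ids: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.constructs["construct_id"], self.constructs["true_activity"]))
        return np.array([lookup[c] for c in construct_ids])


def plant_truth(
    constructs: Sequence[Construct],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    *,
    n_increased: int | None = None,
    n_decreased: int | None = None,
) -> GroundTruth:
    """Assign true activities: a fraction of SNPs regulatory, the rest null.

    By default ``round(fraction_regulatory * n_snps)`` SNPs are regulatory
    with direction chosen at random; ``n_increased``/``n_decreased`` plant
    exact direction counts instead (both must then be given).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    for f in cfg.fold_range:
        if f <= 0:
            raise ValueError("folds must be positive")
        if math.isclose(f, 1.0):
            raise ValueError("fold_range must not contain 1 (regulatory SNPs need an effect)")
        hi, lo = ACTIVITY_SCALE * math.sqrt(f), ACTIVITY_SCALE / math.sqrt(f)
        if 0.8 <= lo and hi <= 1.2:
            raise ValueError(
                f"fold {f} keeps both planted alleles inside [0.8, 1.2]; "
                "such SNPs would not satisfy the regulatory truth definition"
            )

    rs_ids = sorted({c.rs_id for c in constructs if c.allele_class != "blank"})
    n = len(rs_ids)
    if (n_increased is None) != (n_decreased is None):
        raise ValueError("give both n_increased and n_decreased, or neither")
    if n_increased is not None:
        n_reg = n_increased + n_decreased
    else:
        n_reg = round(cfg.fraction_regulatory * n)
    if n_reg > n:
        raise ValueError("more regulatory SNPs requested than SNPs in the panel")

    order = rng.permutation(n)
    regulatory = [rs_ids[i] for i in order[:n_reg]]
    if n_increased is not None:
        increased = set(regulatory[:n_increased])
    else:
        increased = {r for r in regulatory if rng.random() < 0.5}

    snp_rows = []
    act: dict[str, tuple[float, float]] = {}
    for rs in rs_ids:
        if rs in set(regulatory):
            f = float(rng.choice(cfg.fold_range))
            hi, lo = ACTIVITY_SCALE * math.sqrt(f), ACTIVITY_SCALE / math.sqrt(f)
            if rs in increased:
                normal, risk, fold, direction = lo, hi, f, "increased"
            else:
                normal, risk, fold, direction = hi, lo, 1.0 / f, "decreased"
            is_reg = True
        else:
            normal = risk = fold = 1.0
            direction, is_reg = "none", False
        act[rs] = (normal, risk)
        snp_rows.append(
            {
                "rs_id": rs,
                "normal_activity": normal,
                "risk_activity": risk,
                "true_fold": fold,
                "direction": direction,
                "is_regulatory": is_reg,
            }
        )

    cons_rows = []
    for c in constructs:
        if c.allele_class == "blank":
            a = 1.0
        else:
            a = act[c.rs_id][0 if c.allele_class == "normal" else 1]
        cons_rows.append(
            {
                "construct_id": c.construct_id,
                "rs_id": c.rs_id,
                "allele_class": c.allele_class,
                "true_activity": a,
            }
        )
    return GroundTruth(pd.DataFrame(cons_rows), pd.DataFrame(snp_rows))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multiplicative noise with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_counts(
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    cell_line: str = "SIM",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the construct x sample count matrix for one cell line.

    Returns ``(counts, samples)``: counts indexed by construct_id with one
    column per sub-library, and a sample table (sample_id, cell_line,
    fraction, replicate).  Column totals equal ``cfg.read_depth`` exactly.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    ids = truth.constructs["construct_id"].tolist()
    activity = truth.constructs["true_activity"].to_numpy()
    k = len(ids)
    if cfg.read_depth < k:
        import warnings

        warnings.warn(
            f"read depth {cfg.read_depth} below library size {k}: counts will be sparse",
            stacklevel=2,
        )
    props = rng.dirichlet(np.full(k, cfg.dna_dirichlet_concentration))

    counts: dict[str, np.ndarray] = {}
    samples = []
    for rep in range(1, cfg.n_replicates + 1):
        counts[f"{cell_line}_DNA_r{rep}"] = rng.multinomial(cfg.read_depth, props)
        samples.append((cell_line, "DNA", rep))
    for rep in range(1, cfg.n_replicates + 1):
        expect = props * activity * _lognormal_noise(rng, cfg.replicate_noise_cv, k)
        counts[f"{cell_line}_RNA_r{rep}"] = rng.multinomial(
            cfg.read_depth, expect / expect.sum()
        )
        samples.append((cell_line, "RNA", rep))

    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="construct_id"))
    samples_df = pd.DataFrame(
        {
            "sample_id": list(counts),
            "cell_line": [s[0] for s in samples],
            "fraction": [s[1] for s in samples],
            "replicate": [s[2] for s in samples],
        }
    )
    return counts_df, samples_df


# ---------------------------------------------------------------------------
# FASTQ


def _open_maybe_gz(path: str | Path, mode: str = "wt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def simulate_fastq(
    count_column: pd.Series,
    constructs: Sequence[Construct],
    primer_set: int,
    index: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    r1_path: str | Path,
    r2_path: str | Path,
    *,
    include_second_half: bool = False,
) -> int:
    """Write paired FASTQ for one sub-library; returns the number of read pairs.

    Each counted molecule yields one read pair off the first-half amplicon
    (mate 2 reverse-complemented from its 3' end); per-base substitution
    errors at ``cfg.per_base_error_rate``; constant Q37 qualities.  With
    ``include_second_half`` an extra pair per molecule covers the barcode-free
    second-half amplicon (those reads are unassignable by design).
    """
    first_len, second_len = cfg.amplicon_split
    read_len = cfg.read_length
    by_id = {c.construct_id: c for c in constructs}

    templates = []
    reps = []
    for cid, n in count_column.items():
        n = int(n)
        if n == 0:
            continue
        region = amplicon.build_region(by_id[cid].barcode, primer_set, index)
        templates.append(seq_to_u8(region[:first_len]))
        reps.append(n)
        if include_second_half:
            templates.append(
                seq_to_u8(region[cfg.barcode_region_length - second_len :])[:second_len]
            )
            reps.append(n)

    with _open_maybe_gz(r1_path) as f1, _open_maybe_gz(r2_path) as f2:
        if not templates:
            return 0
        # uniform-length batches (first/second halves differ by one base)
        total = 0
        qual = "F" * read_len
        for length in sorted({t.size for t in templates}):
            group = [
                (t, r) for t, r in zip(templates, reps) if t.size == length
            ]
            mat = np.repeat(
                np.stack([t for t, _ in group]), [r for _, r in group], axis=0
            )
            # base-index representation for error injection
            from ._utils import BASE_INDEX

            codes = BASE_INDEX[mat]
            if cfg.per_base_error_rate > 0:
                err = rng.random(codes.shape) < cfg.per_base_error_rate
                shift = rng.integers(1, 4, size=codes.shape)
                codes = np.where(err, (codes + shift) % 4, codes)
            mat = BASE_U8[codes]
            mat = mat[rng.permutation(mat.shape[0])]
            r1 = mat[:, :read_len]
            r2 = (BASE_U8[(3 - BASE_INDEX[mat[:, length - read_len :]])])[:, ::-1]
            for i in range(mat.shape[0]):
                name = f"sim:{primer_set}:{index}:{total + i}"
                f1.write(f"@{name}/1\n{r1[i].tobytes().decode()}\n+\n{qual}\n")
                f2.write(f"@{name}/2\n{r2[i].tobytes().decode()}\n+\n{qual}\n")
            total += mat.shape[0]
    return total


# ---------------------------------------------------------------------------
# peaks and Ct tables


def simulate_peaks(
    snps: Sequence[SnpRecord],
    supported_rsids: Sequence[str],
    assays: Sequence[str] = ("ATAC", "DNase", "H3K27ac", "H3K4me3"),
    peak_halfwidth: int = 100,
) -> dict[str, pd.DataFrame]:
    """One BED-style interval table per assay covering exactly the supported SNPs.

    Intervals are 0-based half-open and contain the supported SNP's position;
    unsupported SNPs are covered by none.
    """
    panel = {s.rs_id for s in snps}
    unknown = set(supported_rsids) - panel
    if unknown:
        raise ValueError(f"supported_rsids not in panel: {sorted(unknown)}")
    supported = set(supported_rsids)
    out = {}
    for assay in assays:
        rows = [
            {
                "chrom": s.chrom,
                "start": max(0, s.pos - 1 - peak_halfwidth),
                "end": s.pos + peak_halfwidth,
            }
            for s in snps
            if s.rs_id in supported
        ]
        out[assay] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals.to_csv(path, sep="\t", index=False, header=False)


def _ct(baseline: float, abundance: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    return baseline - np.log2(abundance) + rng.normal(0.0, noise_sd, size=abundance.shape)


def simulate_chip_ct(
    fold: float,
    rng: np.random.Generator,
    baseline: float = 22.0,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Ct table for a ChIP/FAIRE enrichment scenario with planted target fold."""
    rows = []
    for region, frac, ab in (
        ("target", "input", 1.0),
        ("control", "input", 1.0),
        ("target", "IP", fold),
        ("control", "IP", 1.0),
    ):
        cts = _ct(baseline, np.full(n_replicates, ab), noise_sd, rng)
        rows += [
            {"region": region, "fraction": frac, "replicate": r + 1, "ct": ct}
            for r, ct in enumerate(cts)
        ]
    return pd.DataFrame(rows)


def simulate_asqpcr_ct(
    ratio: float,
    rng: np.random.Generator,
    baseline: float = 24.0,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Allele-specific qPCR scenario: sample imbalance ``ratio`` (allele A : B),
    heterozygous genomic DNA as the 1:1 calibrator."""
    rows = []
    for template, allele, ab in (
        ("sample", "A", ratio),
        ("sample", "B", 1.0),
        ("gdna", "A", 1.0),
        ("gdna", "B", 1.0),
    ):
        cts = _ct(baseline, np.full(n_replicates, ab), noise_sd, rng)
        rows += [
            {"template": template, "allele": allele, "replicate": r + 1, "ct": ct}
            for r, ct in enumerate(cts)
        ]
    return pd.DataFrame(rows)


def simulate_getpcr_ct(
    wt_fraction: float,
    rng: np.random.Generator,
    baseline: float = 26.0,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Editing-efficiency scenario: the watch amplicon amplifies only intact
    (wild-type) template; the nearby control amplicon amplifies everything."""
    rows = []
    for condition, target, ab in (
        ("edited", "watch", wt_fraction),
        ("edited", "control", 1.0),
        ("mock", "watch", 1.0),
        ("mock", "control", 1.0),
    ):
        cts = _ct(baseline, np.full(n_replicates, ab), noise_sd, rng)
        rows += [
            {"condition": condition, "amplicon": target, "replicate": r + 1, "ct": ct}
            for r, ct in enumerate(cts)
        ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-study convenience


@dataclass
class SimStudy:
    snps: list[SnpRecord]
    constructs: list[Construct]
    truth: GroundTruth
    counts: pd.DataFrame
    samples: pd.DataFrame
    sheet: SampleSheet


def synthetic_panel(n_snps: int, rng: np.random.Generator) -> list[SnpRecord]:
    """A synthetic SNP panel spread along one synthetic chromosome."""
    alleles = ["A", "C", "G", "T"]
    snps = []
    for i in range(n_snps):
        a, b = rng.choice(4, size=2, replace=False)
        snps.append(
            SnpRecord(
                rs_id=f"rs{1000000 + i}",
                chrom="chrS",
                pos=1000 + 500 * i,
                normal_allele=alleles[a],
                risk_allele=alleles[b],
            )
        )
    return snps


def simulate_study(
    cfg: SimConfig,
    cell_line: str = "SIM",
    *,
    n_increased: int | None = None,
    n_decreased: int | None = None,
) -> SimStudy:
    """Panel -> library -> planted truth -> counts, under one seed."""
    rng = np.random.default_rng(cfg.seed)
    snps = synthetic_panel(cfg.n_snps, rng)
    constructs = build_library(snps, barcode_length=cfg.barcode_length, seed=cfg.seed)
    truth = plant_truth(
        constructs, cfg, rng, n_increased=n_increased, n_decreased=n_decreased
    )
    counts, samples = simulate_counts(truth, cfg, rng, cell_line=cell_line)
    sheet = build_sample_sheet(
        [(cell_line, f, r) for f in ("DNA", "RNA") for r in range(1, cfg.n_replicates + 1)]
    )
    return SimStudy(snps, constructs, truth, counts, samples, sheet)
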