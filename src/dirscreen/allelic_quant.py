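"""Small allelic quantification formulas: ddCt qPCR and allele read counts.

Covers four readouts used around a reporter screen:

* ChIP/FAIRE qPCR fold enrichment of a target region over the input
  control, normalized to a control region (ddCt with amplification
  efficiency E, default exactly 2 for validated primer pairs);
* allele-specific qPCR (discriminating base at the primer 3' end), the
  allele ratio calibrated against heterozygous genomic DNA (1:1 by
  definition) so primer-efficiency differences cancel;
* getPCR editing quantification: percent wild-type DNA from a "watch"
  amplicon across the cut site normalized to a nearby control amplicon,
  relative to mock-edited cells;
* allele-specific read counting at a heterozygous SNP, from alignments
  (SAM) or raw reads via exact flanking-context anchoring, with a
  two-sided exact binomial test against the 0.5 heterozygous expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from scipy.stats import binomtest

from ._utils import revcomp
from .snp_library import SnpRecord, extract_snp_window


def _check_efficiency(efficiency: float) -> None:
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"amplification efficiency must be in (1, 2], got {efficiency}")


def chip_enrichment(
    ct_target_ip: float,
    ct_target_input: float,
    ct_ctrl_ip: float,
    ct_ctrl_input: float,
    efficiency: float = 2.0,
) -> float:
    """Fold enrichment of the target region over input, normalized to the
    control region: E^-[(dCt_target) - (dCt_control)]."""
    _check_efficiency(efficiency)
    ddct = (ct_target_ip - ct_target_input) - (ct_ctrl_ip - ct_ctrl_input)
    return efficiency**-ddct


def allele_ratio_asqpcr(
    ct_alleleA_sample: float,
    ct_alleleB_sample: float,
    ct_alleleA_gdna: float,
    ct_alleleB_gdna: float,
    efficiency: float = 2.0,
    calibrated: bool = True,
) -> float:
    """A:B allele ratio in a sample, calibrated to heterozygous genomic DNA.

    Ratio 1 means no allelic imbalance beyond what the primer pair itself
    shows on the 1:1 calibrator.  ``calibrated=False`` skips the genomic-DNA
    correction (assumes perfectly allele-specific primers).
    """
    _check_efficiency(efficiency)
    dct = ct_alleleA_sample - ct_alleleB_sample
    if calibrated:
        dct -= ct_alleleA_gdna - ct_alleleB_gdna
    return efficiency**-dct


def getpcr_wt_fraction(
    ct_watch_edited: float,
    ct_ctrl_edited: float,
    ct_watch_mock: float,
    ct_ctrl_mock: float,
    efficiency: float = 2.0,
) -> tuple[float, float]:
    """Percent wild-type DNA (and indel % = 100 - WT%) after genome editing.

    100 x E^-[(Ct_watch - Ct_ctrl)_edited - (Ct_watch - Ct_ctrl)_mock],
    clamped to [0, 100] with a warning on out-of-range values.
    """
    _check_efficiency(efficiency)
    ddct = (ct_watch_edited - ct_ctrl_edited) - (ct_watch_mock - ct_ctrl_mock)
    wt = 100.0 * efficiency**-ddct
    if wt > 100.0:
        warnings.warn(
            f"wild-type estimate {wt:.1f}% exceeds 100% (negative ddCt); clamped",
            stacklevel=2,
        )
        wt = 100.0
    return wt, 100.0 - wt


@dataclass
class AlleleCount:
    rs_id: str
    n_normal: int
    n_risk: int
    n_other: int
    p_value: float  # two-sided exact binomial vs 0.5 on the two-allele counts


def _binom_p(n_a: int, n_b: int) -> float:
    n = n_a + n_b
    if n == 0:
        return 1.0
    return float(binomtest(n_a, n, 0.5, alternative="two-sided").pvalue)


def count_alleles_sam(sam_path: str | Path, snp: SnpRecord) -> AlleleCount:
    """Count the base each aligned read carries at the SNP position.

    Works on SAM/BAM; orientation is honored by the aligner's query
    representation, so reverse-strand reads count identically.
    """
    pos0 = snp.pos - 1
    n_normal = n_risk = n_other = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name != snp.chrom:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos == pos0:
                    base = read.query_sequence[qpos].upper()
                    if base == snp.normal_allele:
                        n_normal += 1
                    elif base == snp.risk_allele:
                        n_risk += 1
                    else:
                        n_other += 1
                    break
    return AlleleCount(snp.rs_id, n_normal, n_risk, n_other, _binom_p(n_normal, n_risk))


def count_alleles_reads(
    reads: Iterable[str],
    snp: SnpRecord,
    reference,
    context_k: int = 5,
) -> AlleleCount:
    """Alignment-free allele counting via exact flanking-context anchoring.

    The ``2*context_k + 1``-mer around the SNP is taken from the reference;
    a read (either strand) matching the flanks exactly contributes the base
    it carries between them.  Reads matching neither allele at the SNP are
    tallied as ``n_other`` and excluded from the binomial test.
    """
    window_n, _ = extract_snp_window(reference, snp, flank=context_k)
    left, right = window_n[:context_k], window_n[context_k + 1 :]
    if not left or not right:
        raise ValueError(f"context_k={context_k} leaves an empty flank")

    def base_between(seq: str) -> str | None:
        start = 0
        while True:
            i = seq.find(left, start)
            if i < 0:
                return None
            j = i + context_k
            if j < len(seq) and seq[j + 1 : j + 1 + context_k] == right:
                return seq[j]
            start = i + 1

    n_normal = n_risk = n_other = 0
    for read in reads:
        read = read.upper()
        base = base_between(read)
        if base is None:
            base = base_between(revcomp(read))
        if base is None:
            continue
        if base == snp.normal_allele:
            n_normal += 1
        elif base == snp.risk_allele:
            n_risk += 1
        else:
            n_other += 1
    return AlleleCount(snp.rs_id, n_normal, n_risk, n_other, _binom_p(n_normal, n_risk))


def count_alleles_at_snp(
    source,
    snp: SnpRecord,
    reference=None,
    context_k: int = 5,
) -> AlleleCount:
    """Dispatch: a SAM/BAM path goes through the alignment counter, an
    iterable of read sequences through context anchoring (needs ``reference``)."""
    if isinstance(source, (str, Path)) and str(source).endswith((".sam", ".bam")):
        return count_alleles_sam(source, snp)
    if reference is None:
        raise ValueError("raw-read counting needs a reference for the context anchor")
    return count_alleles_reads(source, snp, reference, context_k=context_k)
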