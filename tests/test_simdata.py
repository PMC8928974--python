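"""Synthetic study generator: planted truth, count model, FASTQ, Ct tables."""

import numpy as np
import pandas as pd
import pytest

from dirscreen import simdata
from dirscreen.readproc import merge_pair
from dirscreen.simdata import GroundTruth, SimConfig, plant_truth, simulate_counts


def _cfg(**kw):
    base = dict(n_snps=20, read_depth=100_000, seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestPlantTruth:
    def test_no_regulatory_fraction_means_all_null(self, small_library):
        truth = plant_truth(small_library, _cfg(fraction_regulatory=0.0))
        assert (truth.snps["true_fold"] == 1.0).all()
        assert not truth.snps["is_regulatory"].any()
        assert (truth.constructs["true_activity"] == 1.0).all()

    def test_all_regulatory_fold_2(self, small_library):
        truth = plant_truth(small_library, _cfg(fraction_regulatory=1.0))
        assert truth.snps["is_regulatory"].all()
        assert set(np.round(truth.snps["true_fold"], 9)) == {2.0, 0.5}
        # planted pattern: alleles at 1.5 and 0.75
        acts = truth.constructs.query("allele_class != 'blank'")["true_activity"]
        assert set(np.round(acts, 6)) == {1.5, 0.75}

    def test_exact_regulatory_count(self):
        rng = np.random.default_rng(0)
        from dirscreen.snp_library import build_library

        lib = build_library(simdata.synthetic_panel(300, rng), seed=0)
        truth = plant_truth(lib, _cfg(n_snps=300, fraction_regulatory=0.1))
        assert int(truth.snps["is_regulatory"].sum()) == 30

    def test_blank_activity_is_one(self, small_library):
        truth = plant_truth(small_library, _cfg(fraction_regulatory=0.5))
        blank = truth.constructs.query("allele_class == 'blank'")
        assert blank["true_activity"].tolist() == [1.0]

    def test_fold_one_is_a_config_error(self, small_library):
        with pytest.raises(ValueError, match="fold_range"):
            plant_truth(small_library, _cfg(fold_range=(1.0,)))

    def test_truth_flag_consistent_with_band_rule(self, small_library):
        truth = plant_truth(small_library, _cfg(fraction_regulatory=0.4))
        for row in truth.snps.itertuples():
            outside = not (0.8 <= row.normal_activity <= 1.2) or not (
                0.8 <= row.risk_activity <= 1.2
            )
            assert row.is_regulatory == ((row.true_fold != 1.0) and outside)

    def test_planted_direction_counts(self, small_library):
        truth = plant_truth(
            small_library, _cfg(), n_increased=3, n_decreased=5
        )
        counts = truth.snps["direction"].value_counts()
        assert counts.get("increased", 0) == 3 and counts.get("decreased", 0) == 5


class TestSimulateCounts:
    def test_column_totals_equal_depth(self, small_study):
        assert (small_study.counts.sum() == 100_000).all()

    def test_bit_identical_under_seed(self):
        a = simdata.simulate_study(_cfg(seed=11)).counts
        b = simdata.simulate_study(_cfg(seed=11)).counts
        assert a.equals(b)
        c = simdata.simulate_study(_cfg(seed=12)).counts
        assert not a.equals(c)

    def test_null_model_ratio_near_one(self, small_library):
        cfg = _cfg(fraction_regulatory=0.0, replicate_noise_cv=0.0, read_depth=1_000_000)
        truth = plant_truth(small_library, cfg)
        counts, _ = simulate_counts(truth, cfg)
        cpm = counts / counts.sum() * 1e6
        ratio = cpm["SIM_RNA_r1"] / cpm["SIM_DNA_r1"]
        assert abs(np.median(ratio) - 1.0) < 0.05

    def test_activity_two_doubles_expected_ratio(self, small_library):
        cfg = _cfg(replicate_noise_cv=0.0, read_depth=2_000_000)
        truth = plant_truth(small_library, _cfg(fraction_regulatory=0.0))
        tc = truth.constructs.copy()
        target = tc.index[tc["allele_class"] == "risk"][0]
        tc.loc[target, "true_activity"] = 2.0
        truth2 = GroundTruth(tc, truth.snps)
        counts, _ = simulate_counts(truth2, cfg)
        cpm = counts / counts.sum() * 1e6
        ratio = cpm["SIM_RNA_r1"] / cpm["SIM_DNA_r1"]
        boosted = ratio.iloc[target]
        others = ratio.drop(ratio.index[target]).median()
        assert boosted / others == pytest.approx(2.0, rel=0.15)

    def test_planted_fold_recovered_within_mc_error(self):
        """Monte-Carlo oracle: the estimated fold of a planted fold-2 SNP is an
        unbiased estimate across repeated simulations."""
        cfg = _cfg(n_snps=50, read_depth=100_000, fraction_regulatory=0.1)
        folds = []
        for seed in range(60):
            cfg_i = _cfg(n_snps=50, read_depth=100_000, fraction_regulatory=0.1, seed=seed)
            st = simdata.simulate_study(cfg_i)
            cpm = st.counts / st.counts.sum() * 1e6
            reg = st.truth.snps.query("direction == 'increased'")["rs_id"]
            if reg.empty:
                continue
            rs = reg.iloc[0]
            ratios = {}
            for cls in ("normal", "risk"):
                cid = f"{rs}_{cls}"
                i = st.counts.index.get_loc(cid)
                vals = [
                    cpm.iloc[i][f"SIM_RNA_r{r}"] / cpm.iloc[i][f"SIM_DNA_r{r}"]
                    for r in (1, 2, 3)
                ]
                ratios[cls] = np.mean(vals)
            folds.append(ratios["risk"] / ratios["normal"])
        folds = np.array(folds)
        se = folds.std(ddof=1) / np.sqrt(len(folds))
        assert abs(folds.mean() - 2.0) < 3 * se + 0.02


class TestSimulateFastq:
    def test_zero_counts_give_empty_fastq(self, small_study, tmp_path):
        col = pd.Series(0, index=small_study.counts.index)
        rng = np.random.default_rng(0)
        n = simdata.simulate_fastq(
            col, small_study.constructs, 1, 1, _cfg(), rng,
            tmp_path / "r1.fq", tmp_path / "r2.fq",
        )
        assert n == 0
        assert (tmp_path / "r1.fq").read_text() == ""

    def test_first_amplicon_is_271_bp(self, small_study, tmp_path):
        """Merging an error-free pair reconstructs the full 271-bp amplicon."""
        col = pd.Series(0, index=small_study.counts.index)
        col.iloc[0] = 1
        rng = np.random.default_rng(0)
        simdata.simulate_fastq(
            col, small_study.constructs, 1, 1, _cfg(), rng,
            tmp_path / "r1.fq", tmp_path / "r2.fq",
        )
        r1 = (tmp_path / "r1.fq").read_text().splitlines()[1]
        r2 = (tmp_path / "r2.fq").read_text().splitlines()[1]
        assert len(r1) == len(r2) == 150
        merged = merge_pair(r1, r2)
        assert merged is not None and len(merged.sequence) == 271

    def test_reads_carry_layout_fields(self, small_study, tmp_path):
        from dirscreen.amplicon import BARCODE_OFFSET, index_seq, primer_seq

        col = pd.Series(0, index=small_study.counts.index)
        col.iloc[3] = 2
        rng = np.random.default_rng(1)
        simdata.simulate_fastq(
            col, small_study.constructs, 5, 7, _cfg(), rng,
            tmp_path / "r1.fq", tmp_path / "r2.fq",
        )
        r1 = (tmp_path / "r1.fq").read_text().splitlines()[1]
        assert r1.startswith(primer_seq(5) + index_seq(7))
        barcode = small_study.constructs[3].barcode
        assert r1[BARCODE_OFFSET : BARCODE_OFFSET + 15] == barcode


class TestSimulatePeaks:
    def test_empty_supported_set(self, small_panel):
        peaks = simdata.simulate_peaks(small_panel, [])
        assert all(len(df) == 0 for df in peaks.values())

    def test_supported_snp_covered_in_zero_based_coords(self):
        from dirscreen.snp_library import SnpRecord

        snp = SnpRecord("rs1", "chr1", 150, "A", "G")
        peaks = simdata.simulate_peaks([snp], ["rs1"])
        for df in peaks.values():
            start, end = int(df.iloc[0]["start"]), int(df.iloc[0]["end"])
            assert start <= 149 < end

    def test_unknown_rsid_rejected(self, small_panel):
        with pytest.raises(ValueError, match="not in panel"):
            simdata.simulate_peaks(small_panel, ["rs_nope"])


class TestCtTables:
    def test_unit_abundance_noiseless_gives_equal_cts(self):
        rng = np.random.default_rng(0)
        ct = simdata.simulate_chip_ct(1.0, rng, noise_sd=0.0)
        assert ct["ct"].nunique() == 1

    def test_fourfold_enrichment_shifts_ct_by_minus_two(self):
        rng = np.random.default_rng(0)
        ct = simdata.simulate_chip_ct(4.0, rng, noise_sd=0.0)
        ip_t = ct.query("region=='target' and fraction=='IP'")["ct"].iloc[0]
        ip_c = ct.query("region=='control' and fraction=='IP'")["ct"].iloc[0]
        assert ip_t - ip_c == pytest.approx(-2.0)


def test_yaml_config_roundtrip(tmp_path):
    cfg = SimConfig(n_snps=12, fraction_regulatory=0.25, seed=9)
    cfg.to_yaml(tmp_path / "cfg.yaml")
    back = SimConfig.from_yaml(tmp_path / "cfg.yaml")
    assert back == cfg
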