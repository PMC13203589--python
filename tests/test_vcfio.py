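"""Tests for the VCF bridge: extraction, filters, concordance, partitioning."""

import numpy as np
import pandas as pd
import pytest

from diaqc.model import DIAModel, estimate_dia, estimation_accuracy
from diaqc.simulate import DiaDistributionSpec, SimulationConfig, simulate_dataset
from diaqc.vcfio import (
    ConcordanceCounts,
    QualityFilters,
    apply_cnv_allele_p,
    bins_to_frame,
    concordance_metrics,
    dataset_to_vcf_records,
    extract_het_loci,
    filter_by_quality,
    load_records,
    partitioned_dia,
    read_cnv_segments,
    somatic_mutation_calls,
    write_synthetic_vcf,
)


def _toy_records(rows):
    """Build a wide records table from (chrom, pos, gt-per-sample) dicts."""
    out = []
    for r in rows:
        row = {"chrom": r.get("chrom", "chr1"), "pos": r["pos"], "ref": "A", "alt": "T"}
        for s, gt in r["gt"].items():
            ad_alt = r.get("ad", {}).get(s, (15, 15))[1]
            ad_ref = r.get("ad", {}).get(s, (15, 15))[0]
            row[f"{s}:gt"] = gt
            row[f"{s}:ad_ref"] = ad_ref
            row[f"{s}:ad_alt"] = ad_alt
            row[f"{s}:dp"] = r.get("dp", {}).get(s, ad_ref + ad_alt)
            row[f"{s}:gq"] = r.get("gq", {}).get(s, 99)
        out.append(row)
    df = pd.DataFrame(out)
    df.attrs["samples"] = sorted({k for r in rows for k in r["gt"]})
    return df


class TestRoundTrip:
    def test_synthetic_vcf_round_trips_losslessly(self, tmp_path):
        ds = simulate_dataset(
            SimulationConfig(n_loci=500, dia_spec=DiaDistributionSpec(dia_avg=10), seed=4)
        )
        rec = dataset_to_vcf_records(ds, seed=5)
        path = tmp_path / "trio.vcf"
        write_synthetic_vcf(rec, path)
        back = load_records(path, ["bulk", "cell"])
        assert len(back) == len(rec)
        for col in ("cell:ad_ref", "cell:ad_alt", "bulk:gt", "cell:gt", "pos"):
            assert back[col].astype(rec[col].dtype).equals(rec[col])

    def test_header_only_vcf(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_synthetic_vcf(pd.DataFrame(columns=["chrom", "pos"]), path, samples=["s1"])
        back = load_records(path, ["s1"])
        assert back.empty

    def test_estimate_equivalence_disk_vs_memory(self, tmp_path):
        """Exported + re-extracted loci give the same DIA as the in-memory path."""
        ds = simulate_dataset(
            SimulationConfig(n_loci=2000, dia_spec=DiaDistributionSpec(dia_avg=30), seed=6)
        )
        direct = estimate_dia(ds.observations)
        rec = dataset_to_vcf_records(ds, seed=7)
        path = tmp_path / "sim.vcf"
        write_synthetic_vcf(rec, path)
        loci = extract_het_loci(path, "bulk", "cell")
        via_vcf = estimate_dia(loci)
        assert via_vcf.dia_hat == pytest.approx(direct.dia_hat)
        assert via_vcf.n_loci == direct.n_loci

    def test_unknown_sample_names_available(self, tmp_path):
        ds = simulate_dataset(SimulationConfig(n_loci=10, seed=8))
        path = tmp_path / "s.vcf"
        write_synthetic_vcf(dataset_to_vcf_records(ds), path)
        with pytest.raises(KeyError, match="bulk"):
            load_records(path, ["nosuch"])


class TestExtraction:
    def test_field_extraction(self):
        rec = _toy_records(
            [{"pos": 100, "gt": {"b": "0/1", "c": "0/1"}, "ad": {"c": (10, 20)}}]
        )
        loci = extract_het_loci(rec, "b", "c")
        assert loci.iloc[0]["depth_total"] == 30
        assert loci.iloc[0]["depth_alt"] == 20

    def test_non_bulk_het_excluded(self):
        rec = _toy_records(
            [
                {"pos": 1, "gt": {"b": "0/0", "c": "0/1"}},
                {"pos": 2, "gt": {"b": "1/1", "c": "0/1"}},
                {"pos": 3, "gt": {"b": "./.", "c": "0/1"}},
                {"pos": 4, "gt": {"b": "0/1", "c": "0/0"}},
            ]
        )
        loci = extract_het_loci(rec, "b", "c")
        assert list(loci["pos"]) == [4]

    def test_zero_depth_loci_dropped_and_counted(self):
        rec = _toy_records(
            [
                {"pos": 1, "gt": {"b": "0/1", "c": "0/1"}, "ad": {"c": (0, 0)}, "dp": {"c": 30}},
                {"pos": 2, "gt": {"b": "0/1", "c": "0/1"}},
            ]
        )
        loci = extract_het_loci(rec, "b", "c")
        assert list(loci["pos"]) == [2]
        assert loci.attrs["n_zero_depth"] == 1


class TestQualityFilter:
    def test_inclusive_thresholds(self):
        rec = _toy_records(
            [
                {"pos": 1, "gt": {"s": "0/1"}, "gq": {"s": 19}, "dp": {"s": 50}},
                {"pos": 2, "gt": {"s": "0/1"}, "gq": {"s": 20}, "dp": {"s": 10}, "chrom": "chr7"},
                {"pos": 3, "gt": {"s": "0/1"}, "gq": {"s": 99}, "dp": {"s": 9}},
            ]
        )
        kept = filter_by_quality(rec, ["s"])
        assert list(kept["pos"]) == [2]

    def test_autosomes_only(self):
        rec = _toy_records(
            [
                {"pos": 1, "chrom": "chrX", "gt": {"s": "0/1"}},
                {"pos": 2, "chrom": "X", "gt": {"s": "0/1"}},
                {"pos": 3, "chrom": "22", "gt": {"s": "0/1"}},
                {"pos": 4, "chrom": "chr5", "gt": {"s": "0/1"}},
            ]
        )
        kept = filter_by_quality(rec, ["s"])
        assert list(kept["pos"]) == [3, 4]
        all_chroms = filter_by_quality(rec, ["s"], autosomes_only=False)
        assert len(all_chroms) == 4

    def test_missing_values_fail(self):
        rec = _toy_records([{"pos": 1, "gt": {"s": "0/1"}, "gq": {"s": -1}}])
        assert filter_by_quality(rec, ["s"]).empty


class TestConcordance:
    def test_four_rule_table(self):
        rec = _toy_records(
            [
                {"pos": 1, "gt": {"b": "0/1", "c": "1/1"}},
                {"pos": 2, "gt": {"b": "1/1", "c": "0/0"}},
                {"pos": 3, "gt": {"b": "0/0", "c": "0/1"}},
                {"pos": 4, "gt": {"b": "0/0", "c": "0/0"}},
            ]
        )
        cc = concordance_metrics(rec, "b", "c")
        assert (cc.tp, cc.fn, cc.fp, cc.tn) == (1, 1, 1, 1)
        assert cc.sensitivity == pytest.approx(0.5)
        assert cc.precision == pytest.approx(0.5)

    def test_partition_property(self):
        """Every locus with called genotypes lands in exactly one cell."""
        rng = np.random.default_rng(0)
        gts = ["0/0", "0/1", "1/1", "./."]
        rows = [
            {"pos": i, "gt": {"b": rng.choice(gts), "c": rng.choice(gts)}}
            for i in range(1, 300)
        ]
        rec = _toy_records(rows)
        cc = concordance_metrics(rec, "b", "c")
        n_called = sum(
            1
            for r in rows
            if r["gt"]["b"] != "./." and r["gt"]["c"] != "./."
        )
        assert cc.tp + cc.fn + cc.fp + cc.tn == n_called

    def test_all_concordant(self):
        rec = _toy_records([{"pos": i, "gt": {"b": "0/1", "c": "0/1"}} for i in (1, 2)])
        cc = concordance_metrics(rec, "b", "c")
        assert cc.fn == cc.fp == 0
        assert cc.sensitivity == 1.0 and cc.precision == 1.0

    def test_empty_input(self):
        cc = concordance_metrics(pd.DataFrame(), "b", "c")
        assert (cc.tp, cc.fn, cc.fp, cc.tn) == (0, 0, 0, 0)
        assert np.isnan(cc.sensitivity)


class TestSomaticMutations:
    def test_biological_filter(self):
        rec = _toy_records(
            [
                {"pos": 1, "gt": {"b": "0/0", "c": "0/1", "o": "0/1"}},  # SM
                {"pos": 2, "gt": {"b": "0/0", "c": "0/1", "o": "0/0"}},  # artifact
                {"pos": 3, "gt": {"b": "0/1", "c": "0/1", "o": "0/1"}},  # germline
                {"pos": 4, "gt": {"b": "0/0", "c": "1/1", "o": "0/1"}},  # SM
            ]
        )
        sm = somatic_mutation_calls(rec, "b", "c", "o")
        assert list(sm["pos"]) == [1, 4]

    def test_missing_organoid_is_error(self):
        rec = _toy_records([{"pos": 1, "gt": {"b": "0/0", "c": "0/1"}}])
        with pytest.raises(KeyError, match="organoid"):
            somatic_mutation_calls(rec, "b", "c", "o")

    def test_snr(self):
        cc = ConcordanceCounts(tp=10, fn=1, fp=4, tn=100, sm_count=2)
        assert cc.snr == pytest.approx(0.5)


class TestPartitionedDia:
    def test_single_bin_equals_whole_genome(self, baseline_dataset):
        obs = baseline_dataset.observations.head(3000).assign(chrom="chr1")
        bins = partitioned_dia(obs, bin_size=10_000_000)
        assert len(bins) == 1
        whole = estimate_dia(obs)
        assert bins[0].estimate.dia_hat == pytest.approx(whole.dia_hat)

    def test_low_confidence_threshold(self, baseline_dataset):
        obs = baseline_dataset.observations.head(999).assign(chrom="chr1")
        bins = partitioned_dia(obs, bin_size=10_000_000)
        assert bins[0].low_confidence
        obs = baseline_dataset.observations.head(1000).assign(chrom="chr1")
        assert not partitioned_dia(obs, bin_size=10_000_000)[0].low_confidence

    def test_two_regime_recovery(self):
        """Bins simulated at DIA 5 and 50 are recovered regionally."""
        low = simulate_dataset(
            SimulationConfig(n_loci=20_000, dia_spec=DiaDistributionSpec(dia_avg=5), seed=21)
        ).observations.assign(chrom="chr1", pos=lambda d: d["pos"] * 100)
        high = simulate_dataset(
            SimulationConfig(n_loci=20_000, dia_spec=DiaDistributionSpec(dia_avg=50), seed=22)
        ).observations.assign(chrom="chr1", pos=lambda d: 10_000_000 + d["pos"] * 100)
        obs = pd.concat([low, high], ignore_index=True)
        bins = partitioned_dia(obs, bin_size=10_000_000)
        assert len(bins) == 2
        assert estimation_accuracy(bins[0].estimate.dia_hat, 5) > 0.9
        assert estimation_accuracy(bins[1].estimate.dia_hat, 50) > 0.9
        whole = estimate_dia(obs).dia_hat
        assert bins[0].estimate.dia_hat < whole < bins[1].estimate.dia_hat

    def test_empty_intermediate_bin_emitted(self):
        obs = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [100, 2_000_100],
                "depth_total": [30, 30],
                "depth_alt": [10, 20],
            }
        )
        bins = partitioned_dia(obs, bin_size=1_000_000)
        assert len(bins) == 3
        assert bins[1].estimate is None and bins[1].n_loci == 0
        frame = bins_to_frame(bins)
        assert frame["dia_hat"].isna().sum() == 1

    def test_cnv_segment_override(self, tmp_path):
        seg_path = tmp_path / "cnv.tsv"
        seg_path.write_text("chr1\t0\t500\t0.333333\n")
        segments = read_cnv_segments(seg_path)
        obs = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [100, 900],
                "depth_total": [30, 30],
                "depth_alt": [10, 10],
            }
        )
        out = apply_cnv_allele_p(obs, segments)
        assert out["p"].tolist() == pytest.approx([0.333333, 0.5])
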