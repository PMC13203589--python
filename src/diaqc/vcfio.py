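"""Bridge between multi-sample VCFs and the DIA estimator.

Real-data workflow: germline heterozygous SNVs are identified by requiring
a 0/1 genotype in the matched bulk sample; the amplified sample's allelic
depths (AD) at those bulk-confirmed loci provide the VAF observations the
estimator consumes. Genotype-concordance counts (TP/FN/FP/TN), somatic-
mutation calls with the organoid biological filter, and genome partitioning
into fixed-size bins for regional DIA estimates all live here, as does a
minimal synthetic-VCF writer used to exercise the full path in tests.

Records are held in a flat pandas DataFrame with one row per biallelic SNV
and per-sample columns ``{sample}:gt`` (genotype string), ``{sample}:ad_ref``,
``{sample}:ad_alt``, ``{sample}:dp`` and ``{sample}:gq``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import DIAEstimate, DIAModel

__all__ = [
    "AUTOSOMES",
    "ConcordanceCounts",
    "GenomicBin",
    "QualityFilters",
    "apply_cnv_allele_p",
    "bins_to_frame",
    "concordance_metrics",
    "dataset_to_vcf_records",
    "extract_het_loci",
    "filter_by_quality",
    "load_records",
    "partitioned_dia",
    "read_cnv_segments",
    "read_depth_windows",
    "somatic_mutation_calls",
    "write_synthetic_vcf",
]

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

_NON_REF = frozenset({"0/1", "1/1"})


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def is_autosome(chrom: str) -> bool:
    return _norm_chrom(chrom) in AUTOSOMES


@dataclass(frozen=True)
class QualityFilters:
    """Hard genotype-quality filters applied before counting.

    A record is kept only if GQ >= ``min_gq`` and DP >= ``min_dp`` in every
    evaluated sample (missing values fail), and, when ``autosomes_only`` is
    set, the locus lies on an autosome (chromosomes 1-22, with or without
    a ``chr`` prefix).
    """

    min_gq: int = 20
    min_dp: int = 10
    autosomes_only: bool = True


def load_records(path, samples: list[str] | None = None) -> pd.DataFrame:
    """Read biallelic SNV records from a VCF/gVCF into a flat DataFrame.

    Multiallelic records, indels and malformed rows are skipped; counters
    for skipped records are stored in ``df.attrs``. Missing AD/DP/GQ values
    become -1 (which any quality filter fails).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    available = list(vcf.samples)
    if samples is None:
        samples = available
    missing = [s for s in samples if s not in available]
    if missing:
        raise KeyError(
            f"sample(s) {missing} not in VCF; available samples: {available}"
        )
    idx = [available.index(s) for s in samples]
    rows = []
    n_multiallelic = n_not_snv = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multiallelic += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_not_snv += 1
            continue
        row = {"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0]}
        ad = v.format("AD")
        dp = v.gt_depths
        gq = v.gt_quals
        genotypes = v.genotypes
        for s, i in zip(samples, idx):
            a, b = genotypes[i][0], genotypes[i][1]
            row[f"{s}:gt"] = "./." if a < 0 or b < 0 else f"{min(a, b)}/{max(a, b)}"
            if ad is not None and ad.shape[1] >= 2:
                row[f"{s}:ad_ref"] = int(ad[i, 0]) if ad[i, 0] >= 0 else -1
                row[f"{s}:ad_alt"] = int(ad[i, 1]) if ad[i, 1] >= 0 else -1
            else:
                row[f"{s}:ad_ref"] = row[f"{s}:ad_alt"] = -1
            row[f"{s}:dp"] = int(dp[i]) if dp is not None else -1
            row[f"{s}:gq"] = float(gq[i]) if gq is not None else -1.0
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["samples"] = samples
    df.attrs["n_multiallelic_skipped"] = n_multiallelic
    df.attrs["n_non_snv_skipped"] = n_not_snv
    return df


def filter_by_quality(
    records: pd.DataFrame,
    samples: list[str] | None = None,
    min_gq: int = 20,
    min_dp: int = 10,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Keep records passing GQ/DP thresholds in the evaluated samples.

    Thresholds are inclusive (GQ >= min_gq, DP >= min_dp); missing values
    (encoded -1) fail. With ``autosomes_only``, sex chromosomes and other
    contigs are removed.
    """
    if records.empty:
        return records
    if samples is None:
        samples = records.attrs.get("samples") or sorted(
            {c.split(":")[0] for c in records.columns if ":" in c}
        )
    keep = pd.Series(True, index=records.index)
    for s in samples:
        keep &= records[f"{s}:gq"] >= min_gq
        keep &= records[f"{s}:dp"] >= min_dp
    if autosomes_only:
        keep &= records["chrom"].map(is_autosome)
    out = records.loc[keep].reset_index(drop=True)
    out.attrs.update(records.attrs)
    out.attrs["n_quality_filtered"] = int(len(records) - keep.sum())
    return out


def extract_het_loci(
    source,
    bulk_sample: str,
    amplified_sample: str,
    filters: QualityFilters = QualityFilters(),
) -> pd.DataFrame:
    """Select bulk-confirmed heterozygous loci for DIA estimation.

    ``source`` is a VCF path or a DataFrame from :func:`load_records`.
    Keeps biallelic SNVs where the bulk genotype is exactly 0/1 and both
    samples pass the quality filters; the observation depths come from the
    amplified sample's allelic depths (ref + alt), so reads assigned to
    other alleles do not bias the VAF. Loci whose amplified-sample allelic
    depth is zero are dropped (counted in ``df.attrs['n_zero_depth']``).

    Returns a DataFrame with columns chrom, pos, depth_total, depth_alt.
    """
    if isinstance(source, (str, Path)):
        records = load_records(source, [bulk_sample, amplified_sample])
    else:
        records = source
    if records.empty:
        out = pd.DataFrame(columns=["chrom", "pos", "depth_total", "depth_alt"])
        out.attrs["n_zero_depth"] = 0
        return out
    records = filter_by_quality(
        records,
        samples=[bulk_sample, amplified_sample],
        min_gq=filters.min_gq,
        min_dp=filters.min_dp,
        autosomes_only=filters.autosomes_only,
    )
    het = records.loc[records[f"{bulk_sample}:gt"] == "0/1"]
    ad_ref = het[f"{amplified_sample}:ad_ref"].clip(lower=0)
    ad_alt = het[f"{amplified_sample}:ad_alt"].clip(lower=0)
    total = ad_ref + ad_alt
    nonzero = total > 0
    out = pd.DataFrame(
        {
            "chrom": het.loc[nonzero, "chrom"].to_numpy(),
            "pos": het.loc[nonzero, "pos"].to_numpy(dtype=np.int64),
            "depth_total": total[nonzero].to_numpy(dtype=np.int64),
            "depth_alt": ad_alt[nonzero].to_numpy(dtype=np.int64),
        }
    )
    out.attrs["n_zero_depth"] = int((~nonzero).sum())
    out.attrs["n_bulk_het"] = int(len(het))
    return out


@dataclass
class ConcordanceCounts:
    """Bulk-vs-amplified germline genotype concordance counts.

    TP: non-reference (0/1 or 1/1) in bulk and in the amplified sample;
    FN: non-reference in bulk, 0/0 in the amplified sample;
    FP: 0/0 in bulk, non-reference in the amplified sample;
    TN: 0/0 in both. Loci with a missing genotype in either sample are
    excluded.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    sm_count: int | None = None

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else np.nan

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else np.nan

    @property
    def snr(self) -> float:
        """High-confidence somatic mutations per false-positive call."""
        if self.sm_count is None or self.fp == 0:
            return np.nan
        return self.sm_count / self.fp


def concordance_metrics(
    records: pd.DataFrame, bulk_sample: str, amplified_sample: str
) -> ConcordanceCounts:
    """TP/FN/FP/TN counts between a bulk and an amplified sample."""
    if records.empty:
        return ConcordanceCounts(0, 0, 0, 0)
    bulk = records[f"{bulk_sample}:gt"]
    amp = records[f"{amplified_sample}:gt"]
    bulk_var = bulk.isin(_NON_REF)
    bulk_ref = bulk == "0/0"
    amp_var = amp.isin(_NON_REF)
    amp_ref = amp == "0/0"
    return ConcordanceCounts(
        tp=int((bulk_var & amp_var).sum()),
        fn=int((bulk_var & amp_ref).sum()),
        fp=int((bulk_ref & amp_var).sum()),
        tn=int((bulk_ref & amp_ref).sum()),
    )


def somatic_mutation_calls(
    records: pd.DataFrame,
    bulk_sample: str,
    single_cell_sample: str,
    organoid_sample: str,
) -> pd.DataFrame:
    """Somatic-mutation loci under the organoid biological filter.

    A locus is a somatic-mutation call when the bulk genotype is 0/0 and
    both the single cell and its parent organoid carry a non-reference
    genotype (0/1 or 1/1). Requiring the organoid distinguishes mutations
    present in the founding cell from stochastic amplification artifacts.
    """
    for s in (bulk_sample, single_cell_sample, organoid_sample):
        if f"{s}:gt" not in records.columns:
            raise KeyError(
                f"sample {s!r} not present in records; the organoid biological "
                "filter requires bulk, single-cell and organoid genotypes"
            )
    mask = (
        (records[f"{bulk_sample}:gt"] == "0/0")
        & records[f"{single_cell_sample}:gt"].isin(_NON_REF)
        & records[f"{organoid_sample}:gt"].isin(_NON_REF)
    )
    return records.loc[mask].reset_index(drop=True)


# --------------------------------------------------------------------- #
# Genome partitioning


@dataclass
class GenomicBin:
    """One fixed-size genomic bin with its regional DIA estimate."""

    chrom: str
    start: int  # 0-based, half-open
    end: int
    n_loci: int
    estimate: DIAEstimate | None
    low_confidence: bool


def partitioned_dia(
    observations: pd.DataFrame,
    bin_size: int = 10_000_000,
    p=0.5,
    min_informative: int = 1000,
    bootstrap: bool = False,
    n_boot: int = 1000,
    level: float = 0.95,
    seed=None,
    cnv_segments: pd.DataFrame | None = None,
) -> list[GenomicBin]:
    """Independent DIA estimates over fixed-size genomic bins.

    Bins are 0-based half-open multiples of ``bin_size`` per chromosome
    (VCF positions are 1-based, so position ``pos`` falls in the bin
    containing ``pos - 1``). Bins with fewer than ``min_informative`` loci
    are flagged ``low_confidence``; empty bins inside the observed range
    are emitted with a missing estimate. A CNV segment table (chrom,
    start, end, allele_p) overrides the expected allele fraction per
    locus.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    obs = observations
    if cnv_segments is not None:
        obs = apply_cnv_allele_p(obs, cnv_segments, default_p=np.mean(p))
    rng = np.random.default_rng(seed)
    bins: list[GenomicBin] = []
    for chrom, group in obs.groupby("chrom", sort=False):
        zero_based = group["pos"].to_numpy(dtype=np.int64) - 1
        first = int(zero_based.min() // bin_size)
        last = int(zero_based.max() // bin_size)
        bin_idx = zero_based // bin_size
        for b in range(first, last + 1):
            sel = group.loc[bin_idx == b]
            start, end = b * bin_size, (b + 1) * bin_size
            if sel.empty:
                bins.append(GenomicBin(chrom, start, end, 0, None, True))
                continue
            p_bin = sel["p"].to_numpy(dtype=float) if "p" in sel.columns else p
            region = f"{chrom}:{start}-{end}"
            model = DIAModel(
                sel["depth_total"].to_numpy(),
                sel["depth_alt"].to_numpy(),
                p=p_bin,
            )
            res = model.fit(
                bootstrap=bootstrap,
                n_boot=n_boot,
                level=level,
                seed=rng.integers(2**31) if bootstrap else None,
                region=region,
            )
            bins.append(
                GenomicBin(
                    chrom,
                    start,
                    end,
                    int(len(sel)),
                    res.estimate,
                    len(sel) < min_informative,
                )
            )
    return bins


def bins_to_frame(bins: list[GenomicBin]) -> pd.DataFrame:
    """Flatten per-bin estimates into a DataFrame (TSV-ready)."""
    rows = []
    for b in bins:
        e = b.estimate
        rows.append(
            {
                "chrom": b.chrom,
                "start": b.start,
                "end": b.end,
                "n_loci": b.n_loci,
                "dia_hat": np.nan if e is None else e.dia_hat,
                "saturated": None if e is None else e.saturated,
                "ci_low": None if e is None else e.ci_low,
                "ci_high": None if e is None else e.ci_high,
                "low_confidence": b.low_confidence,
            }
        )
    return pd.DataFrame(rows)


def apply_cnv_allele_p(
    observations: pd.DataFrame, segments: pd.DataFrame, default_p: float = 0.5
) -> pd.DataFrame:
    """Attach per-locus expected allele fractions from CNV segments.

    ``segments`` is BED-like (chrom, start, end, allele_p; 0-based
    half-open). Loci outside every segment keep ``default_p``.
    """
    p = np.full(len(observations), float(default_p))
    zero_based = observations["pos"].to_numpy(dtype=np.int64) - 1
    chroms = observations["chrom"].map(_norm_chrom).to_numpy()
    for seg in segments.itertuples(index=False):
        mask = (
            (chroms == _norm_chrom(str(seg.chrom)))
            & (zero_based >= int(seg.start))
            & (zero_based < int(seg.end))
        )
        p[mask] = float(seg.allele_p)
    return observations.assign(p=p)


def read_cnv_segments(path) -> pd.DataFrame:
    """Read a BED-like TSV of CNV segments (chrom, start, end, allele_p)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 4:
        raise ValueError("CNV segment table needs chrom, start, end, allele_p")
    first = df.iloc[0]
    try:
        float(first[1])
    except (TypeError, ValueError):  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "allele_p"]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["allele_p"] = df["allele_p"].astype(float)
    if np.any((df["allele_p"] <= 0) | (df["allele_p"] >= 1)):
        raise ValueError("allele_p must lie in (0, 1)")
    return df


def read_depth_windows(path) -> pd.DataFrame:
    """Read a per-window coverage TSV (chrom, start, end, mean_depth)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"chrom", "start", "end", "mean_depth"}
    if not needed.issubset(df.columns):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "mean_depth"],
        )
    return df


# --------------------------------------------------------------------- #
# Synthetic VCF fixture generation

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_synthetic_vcf(records: pd.DataFrame, path, samples: list[str] | None = None) -> None:
    """Write a minimal VCF 4.2 with GT:AD:DP:GQ from a flat record table.

    ``records`` uses the same wide layout as :func:`load_records` (columns
    ``chrom, pos, ref, alt`` plus ``{sample}:gt/ad_ref/ad_alt/dp/gq``).
    The output round-trips losslessly through :func:`load_records`. This
    writer exists to generate synthetic test fixtures, not to re-emit real
    call sets.
    """
    if samples is None:
        samples = records.attrs.get("samples") or sorted(
            {c.split(":")[0] for c in records.columns if ":" in c}
        )
    contigs = list(dict.fromkeys(records["chrom"])) if len(records) else []
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for d in records.to_dict(orient="records"):
            fields = [
                str(d["chrom"]), str(d["pos"]), ".", str(d.get("ref", "A")),
                str(d.get("alt", "T")), ".", "PASS", ".", "GT:AD:DP:GQ",
            ]
            for s in samples:
                gt = d.get(f"{s}:gt", "./.")
                ar = int(d.get(f"{s}:ad_ref", 0))
                aa = int(d.get(f"{s}:ad_alt", 0))
                dp = d.get(f"{s}:dp")
                dp = ar + aa if dp is None or (isinstance(dp, float) and np.isnan(dp)) else int(dp)
                gq = int(d.get(f"{s}:gq", 99))
                fields.append(f"{gt}:{ar},{aa}:{dp}:{gq}")
            fh.write("\t".join(fields) + "\n")


def dataset_to_vcf_records(
    dataset,
    bulk_sample: str = "bulk",
    amplified_sample: str = "cell",
    bulk_depth: int = 30,
    chrom: str = "chr1",
    spacing: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Wrap a simulated dataset as two-sample VCF records.

    The bulk sample is genotyped 0/1 at every locus with balanced allelic
    depths drawn as ``Binomial(bulk_depth, 0.5)``; the amplified sample
    carries the simulated allele counts. Positions are laid out every
    ``spacing`` bp on ``chrom`` (override the observation coordinates to
    exercise genome partitioning).
    """
    rng = np.random.default_rng(seed)
    obs = dataset.observations
    n = len(obs)
    bulk_alt = rng.binomial(bulk_depth, 0.5, size=n)
    amp_gt = np.select(
        [obs["depth_alt"] == 0, obs["depth_alt"] == obs["depth_total"]],
        ["0/0", "1/1"],
        default="0/1",
    )
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n + 1, dtype=np.int64) * spacing,
            "ref": "A",
            "alt": "T",
            f"{bulk_sample}:gt": "0/1",
            f"{bulk_sample}:ad_ref": bulk_depth - bulk_alt,
            f"{bulk_sample}:ad_alt": bulk_alt,
            f"{bulk_sample}:dp": bulk_depth,
            f"{bulk_sample}:gq": 99,
            f"{amplified_sample}:gt": amp_gt,
            f"{amplified_sample}:ad_ref": obs["depth_total"] - obs["depth_alt"],
            f"{amplified_sample}:ad_alt": obs["depth_alt"],
            f"{amplified_sample}:dp": obs["depth_total"],
            f"{amplified_sample}:gq": 99,
        }
    )
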