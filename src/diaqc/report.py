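"""Self-contained HTML quality report for one amplified sample.

The report combines the whole-genome DIA estimate with its bootstrap
interval, per-bin regional estimates, and the VAF distribution at the
informative heterozygous loci. Figures are rendered with matplotlib and
embedded as inline SVG, so the file opens without network access and is
suitable for archival QC. A machine-readable JSON summary is written
alongside so downstream tooling never parses HTML.
"""

from __future__ import annotations

import html
import io
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

from .model import DIAResults
from .vcfio import GenomicBin, bins_to_frame

__all__ = ["ReportPayload", "render_report"]


@dataclass
class ReportPayload:
    """Everything the HTML report renders, plus reproducibility metadata."""

    sample: str
    results: DIAResults
    bins: list[GenomicBin] = field(default_factory=list)
    vaf: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def vaf_values(self) -> np.ndarray:
        if self.vaf is not None:
            return np.asarray(self.vaf, dtype=float)
        m = self.results.model
        return m.depth_alt / m.depth_total

    def summary_dict(self) -> dict:
        return {
            "sample": self.sample,
            "whole_genome": self.results.to_dict(),
            "bins": bins_to_frame(self.bins).to_dict(orient="records") if self.bins else [],
            "metadata": self.metadata,
        }


def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg", bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    svg = buf.getvalue()
    return svg[svg.index("<svg") :]


def _vaf_panel(payload: ReportPayload) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vaf = payload.vaf_values()
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.hist(vaf, bins=np.linspace(0, 1, 51), density=True, color="#4878a8", alpha=0.85)
    ax.set_xlabel("variant allele frequency")
    ax.set_ylabel("density")
    ax.set_title(f"VAF at {vaf.size} informative heterozygous loci")
    ax.axvline(0.5, color="grey", ls="--", lw=0.8)
    return _fig_to_svg(fig)


def _bins_panel(payload: ReportPayload) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = bins_to_frame(payload.bins)
    plotted = df.dropna(subset=["dia_hat"])
    plotted = plotted[np.isfinite(plotted["dia_hat"])]
    fig, ax = plt.subplots(figsize=(7, 3.2))
    x = np.arange(len(plotted))
    dia_hat = plotted["dia_hat"].to_numpy(dtype=float)
    ax.scatter(x, dia_hat, s=18, color="#a85048", zorder=3)
    if plotted["ci_low"].notna().any():
        lo = dia_hat - plotted["ci_low"].to_numpy(dtype=float)
        hi = plotted["ci_high"].to_numpy(dtype=float) - dia_hat
        ax.errorbar(
            x, dia_hat, yerr=[np.nan_to_num(lo), np.nan_to_num(hi)],
            fmt="none", ecolor="#a85048", alpha=0.5, lw=1,
        )
    labels = [f"{r.chrom}:{r.start // 1_000_000}M" for r in plotted.itertuples()]
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("DIA estimate")
    ax.set_title("Regional DIA (fixed genomic bins)")
    wg = payload.results.dia_hat
    if np.isfinite(wg):
        ax.axhline(wg, color="grey", ls="--", lw=0.8, label="whole genome")
        ax.legend(fontsize=7)
    return _fig_to_svg(fig)


def render_report(payload: ReportPayload, path) -> None:
    """Write the self-contained HTML report and its JSON sidecar.

    The sidecar (``<path>.json``) holds every number shown in the report.
    """
    res = payload.results
    e = res.estimate
    dia_txt = "saturated (&#8734;)" if e.saturated else f"{e.dia_hat:.2f}"
    ci_txt = (
        f"[{e.ci_low:.2f}, {e.ci_high:.2f}]"
        if e.ci_low is not None
        else "&mdash;"
    )
    rows = [
        ("Sample", html.escape(payload.sample)),
        ("DIA (whole genome)", dia_txt),
        (f"Bootstrap CI ({res.level:.0%})", ci_txt),
        ("Informative heterozygous loci", f"{e.n_loci:,}"),
        ("Mean allelic depth", f"{res.mean_depth:.1f}"),
        ("Generated", datetime.now(timezone.utc).isoformat(timespec="seconds")),
    ]
    for key, value in payload.metadata.items():
        rows.append((html.escape(str(key)), html.escape(str(value))))
    table = "\n".join(
        f"<tr><th>{k}</th><td>{v}</td></tr>" for k, v in rows
    )
    warning = ""
    if e.saturated:
        warning = (
            "<p class='warn'>Observed VAF dispersion does not exceed the "
            "sequencing-binomial floor; no finite DIA is identifiable.</p>"
        )
    if not payload.bins:
        warning += (
            "<p class='warn'>No regional bins available; whole-genome "
            "estimate only.</p>"
        )
    low_conf = sum(b.low_confidence for b in payload.bins)
    if low_conf:
        warning += (
            f"<p class='warn'>{low_conf} bin(s) have fewer than the "
            "recommended 1000 informative loci; their estimates are "
            "flagged low-confidence.</p>"
        )
    panels = [_vaf_panel(payload)]
    if payload.bins:
        panels.append(_bins_panel(payload))
    body = "\n".join(f"<div class='panel'>{svg}</div>" for svg in panels)
    doc = f"""<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8">
<title>scWGA quality report — {html.escape(payload.sample)}</title>
<style>
 body {{ font-family: sans-serif; margin: 2em auto; max-width: 60em; color: #222; }}
 table {{ border-collapse: collapse; margin-bottom: 1.5em; }}
 th, td {{ border: 1px solid #ccc; padding: 0.3em 0.8em; text-align: left; }}
 th {{ background: #f4f4f4; }}
 .warn {{ color: #a33; }}
 .panel {{ margin: 1em 0; }}
</style></head><body>
<h1>Single-cell WGA library quality report</h1>
<p>Depth of independent amplicons (DIA) estimated from the VAF
distribution at bulk-confirmed heterozygous loci.</p>
<table>{table}</table>
{warning}
{body}
</body></html>
"""
    with open(path, "w") as fh:
        fh.write(doc)
    with open(f"{path}.json", "w") as fh:
        json.dump(payload.summary_dict(), fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return str(obj)
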