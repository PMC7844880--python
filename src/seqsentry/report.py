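"""Pipeline orchestration and consolidated run reports.

The JSON report is canonical; HTML is a rendered view embedding the
diagnostic plots.  Every stage writes its artifacts to disk so stages can
also be run standalone from the CLI.
"""

from __future__ import annotations

import base64
import io
import json
import logging
import math
import time
from pathlib import Path

import numpy as np

from . import __version__
from . import insert_size_km as ikm
from . import read_qc, variant_qc
from .contam_ancestry import SvdPanel, estimate as contam_estimate
from .mini_aligner import Aligner, align_pairs, write_sam
from .panel_builder import ReducedReference
from .read_qc import mark_duplicates
from .simulator import ReadPair
from .spaced_hash import SpacedHashIndex, screen_reads_batch

log = logging.getLogger(__name__)


def _finite(x):
    if x is None:
        return None
    if isinstance(x, float) and not math.isfinite(x):
        return None
    return x


def screening_summary(hit_counts: np.ndarray, k_min: int) -> dict:
    total = int(len(hit_counts))
    passed = int((hit_counts >= k_min).sum())
    hist_vals, hist_counts = np.unique(hit_counts, return_counts=True)
    return {
        "total_reads": total,
        "min_hits": k_min,
        "passed_reads": passed,
        "filtered_fraction": _finite((total - passed) / total) if total else None,
        "hit_count_histogram": {int(v): int(n) for v, n in zip(hist_vals, hist_counts)},
    }


def run_pipeline(pairs: list[ReadPair], index: SpacedHashIndex,
                 ref: ReducedReference, svd_panel: SvdPanel | None = None,
                 k_min: int = 3, out_dir: str | None = None,
                 params: dict | None = None) -> dict:
    """screen -> align -> QC -> insert size -> genotypes -> contamination.

    Returns the run report as a JSON-serializable dict; artifacts (SAM,
    VCF, curve TSV) are written under ``out_dir`` when given.
    """
    t0 = time.time()
    outp = Path(out_dir) if out_dir else None
    if outp:
        outp.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "seqsentry",
        "version": __version__,
        "params": params or {"min_hits": k_min},
        "warnings": [],
    }

    # screening: a pair is retained when either mate passes
    reads = [p.seq1 for p in pairs] + [p.seq2 for p in pairs]
    n = len(pairs)
    if n == 0:
        report["screening"] = screening_summary(np.empty(0, np.int16), k_min)
        report["mapping"] = read_qc.mapping_summary(0, 0, []).__dict__
        for key in ("base_qc", "variant_qc", "insert_size", "contamination"):
            report[key] = None
        report["warnings"].append("empty input")
        return report
    hits = screen_reads_batch(reads, index, k_min)
    report["screening"] = screening_summary(hits, k_min)
    keep = (hits[:n] >= k_min) | (hits[n:] >= k_min)
    kept_pairs = [p for p, k in zip(pairs, keep) if k]
    log.info("screening: kept %d/%d pairs", len(kept_pairs), n)

    aligner = Aligner(index, ref)
    aligned = align_pairs(kept_pairs, aligner)
    mark_duplicates(aligned)
    if outp:
        write_sam(aligned, ref, str(outp / "aligned.sam"))

    all_reads = [(p.seq1, p.qual1) for p in pairs] + [(p.seq2, p.qual2) for p in pairs]
    tables = read_qc.accumulate_base_stats(aligned, ref, all_reads=all_reads)
    summary = read_qc.mapping_summary(2 * n, int((hits >= k_min).sum()),
                                      aligned, tables)
    report["mapping"] = {k: _finite(v) for k, v in summary.__dict__.items()}
    report["base_qc"] = {
        "mean_quality_by_cycle": [_finite(float(x)) for x in tables.mean_quality_by_cycle()],
        "empirical_quality_by_bin": {
            int(q): float(e)
            for q, e in enumerate(tables.empirical_quality())
            if tables.qual_total[q] > 0
        },
        "depth": read_qc.depth_distribution(tables),
        "gc_bias": read_qc.gc_bias(tables),
    }

    # insert sizes (paired-end only)
    try:
        tuples = ikm.build_tuples(aligned, ref)
        curve = ikm.km_estimate(tuples)
        naive = ikm.naive_estimate(tuples)
        d, w = ikm.distribution_distance(curve.cdf, naive)
        report["insert_size"] = {
            **curve.summary(),
            "km_vs_naive_ks": d,
            "km_vs_naive_wasserstein": w,
        }
        if outp:
            ikm.write_curve_tsv(curve, str(outp / "insert_size.tsv"))
            report["insert_size"]["curve_tsv"] = "insert_size.tsv"
            report["_insert_curves"] = {
                "km_t": curve.times.tolist(),
                "km_f": (1.0 - curve.survival).tolist(),
                "naive_t": naive.times.tolist(),
                "naive_f": naive.values.tolist(),
            }
    except ValueError as exc:
        report["insert_size"] = None
        report["warnings"].append(f"insert size not estimated: {exc}")

    # genotypes
    sites = variant_qc.pileup(aligned, ref)
    calls = variant_qc.call_all(sites, variant_qc.panel_afs(ref))
    n_called = sum(c.called for c in calls)
    report["variant_qc"] = {
        "n_markers": len(sites),
        "n_called": n_called,
        "mean_site_depth": _finite(float(np.mean([s.depth for s in sites]))
                                   if sites else None),
    }
    if outp:
        variant_qc.write_vcf(calls, sites, ref, str(outp / "genotypes.vcf"))
        report["variant_qc"]["vcf"] = "genotypes.vcf"

    # contamination / ancestry
    if svd_panel is not None:
        try:
            est = contam_estimate(sites, svd_panel)
            report["contamination"] = {
                "alpha": est.alpha,
                "pc": est.pc.tolist(),
                "population": est.population,
                "loglik": _finite(est.loglik),
                "n_sites": est.n_sites,
                "converged": est.converged,
                "warnings": est.warnings,
            }
        except ValueError as exc:
            report["contamination"] = None
            report["warnings"].append(f"contamination not estimated: {exc}")
    else:
        report["contamination"] = None

    report["elapsed_seconds"] = round(time.time() - t0, 3)
    if outp:
        payload = {k: v for k, v in report.items() if not k.startswith("_")}
        (outp / "report.json").write_text(json.dumps(payload, indent=2))
    return report


# ---------------------------------------------------------------------------
# HTML rendering


def _fig_to_b64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, metadata={"Software": None})
    import matplotlib.pyplot as plt

    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


def _plots(report: dict, svd_panel: SvdPanel | None = None) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = {}
    bq = report.get("base_qc") or {}
    if bq.get("mean_quality_by_cycle"):
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(bq["mean_quality_by_cycle"])
        ax.set_xlabel("cycle")
        ax.set_ylabel("mean reported quality")
        out["quality_by_cycle"] = _fig_to_b64(fig)
    gc = bq.get("gc_bias")
    if gc:
        xs = [(g["gc_low"] + g["gc_high"]) / 2 for g in gc if g["normalized_depth"] is not None]
        ys = [g["normalized_depth"] for g in gc if g["normalized_depth"] is not None]
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(xs, ys, marker="o")
        ax.axhline(1.0, ls="--", c="grey")
        ax.set_xlabel("contig GC fraction")
        ax.set_ylabel("normalized mean depth")
        out["gc_bias"] = _fig_to_b64(fig)
    depth = (bq.get("depth") or {}).get("histogram")
    if depth:
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar([int(k) for k in depth], list(depth.values()))
        ax.set_xlabel("depth")
        ax.set_ylabel("callable positions")
        out["depth_histogram"] = _fig_to_b64(fig)
    curves = report.get("_insert_curves")
    if curves:
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.step(curves["km_t"], curves["km_f"], where="post", label="KM-adjusted")
        ax.step(curves["naive_t"], curves["naive_f"], where="post", label="observed")
        ax.set_xlabel("insert size (bp)")
        ax.set_ylabel("CDF")
        ax.legend()
        out["insert_size_cdf"] = _fig_to_b64(fig)
    contam = report.get("contamination")
    if contam and svd_panel is not None and len(svd_panel.ref_coords):
        fig, ax = plt.subplots(figsize=(4, 4))
        pops = sorted(set(svd_panel.ref_pops))
        for pop in pops:
            sel = [i for i, p in enumerate(svd_panel.ref_pops) if p == pop]
            ax.scatter(svd_panel.ref_coords[sel, 0], svd_panel.ref_coords[sel, 1],
                       s=12, label=pop)
        pc = contam["pc"]
        ax.scatter([pc[0]], [pc[1]], marker="*", s=180, c="black", label="sample")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=7)
        out["ancestry"] = _fig_to_b64(fig)
    return out


_SECTION_TITLES = {
    "quality_by_cycle": "Reported base quality by cycle",
    "gc_bias": "GC bias (normalized mean depth)",
    "depth_histogram": "Depth distribution (callable positions)",
    "insert_size_cdf": "Insert size CDF (KM-adjusted vs observed)",
    "ancestry": "Genetic ancestry",
}


def render_report(report: dict, path: str, svd_panel: SvdPanel | None = None) -> str:
    """Static self-contained HTML view of a run report."""
    plots = _plots(report, svd_panel)
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>seqsentry run report</title>",
        "<style>body{font-family:sans-serif;margin:2em}h2{margin-top:1.5em}"
        "table{border-collapse:collapse}td,th{border:1px solid #ccc;"
        "padding:4px 8px}</style></head><body>",
        f"<h1>seqsentry {report.get('version', '')} run report</h1>",
    ]
    scr = report.get("screening") or {}
    mp = report.get("mapping") or {}
    contam = report.get("contamination")
    rows = [
        ("Total reads", scr.get("total_reads")),
        ("Filtered fraction", scr.get("filtered_fraction")),
        ("Screen pass fraction", mp.get("screen_pass_fraction")),
        ("Mapped fraction (of screened)", mp.get("mapped_fraction_of_screened")),
        ("Duplicate rate", mp.get("duplicate_rate")),
        ("Mean callable depth", mp.get("mean_callable_depth")),
        ("Contamination alpha", contam.get("alpha") if contam else "not computed"),
        ("Ancestry", contam.get("population") if contam else "not computed"),
    ]
    parts.append("<table>")
    for name, val in rows:
        if isinstance(val, float):
            val = f"{val:.4g}"
        parts.append(f"<tr><th>{name}</th><td>{val}</td></tr>")
    parts.append("</table>")
    for key, title in _SECTION_TITLES.items():
        parts.append(f"<h2>{title}</h2>")
        if key in plots:
            parts.append(f"<img src='data:image/png;base64,{plots[key]}'/>")
        else:
            parts.append("<p><em>not computed</em></p>")
    if report.get("warnings"):
        parts.append("<h2>Warnings</h2><ul>")
        parts.extend(f"<li>{w}</li>" for w in report["warnings"])
        parts.append("</ul>")
    parts.append("</body></html>")
    html = "\n".join(parts)
    Path(path).write_text(html)
    return html
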