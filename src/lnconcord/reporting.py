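"""Report rendering and run manifests.

Every emitted report carries a :class:`RunManifest` (command, config hash,
seed, input digests, tool version, timestamp) so a result can always be
traced back to the exact invocation that produced it.  Undefined statistics
serialise as the literal token ``NA``; infinities are never written.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .concordance import CohortSummary, ChiSquareResult, OddsRatioResult
from .io import NA_TOKEN
from .suspicion import PATTERN_ORDER


def file_digest(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    seed: Optional[int] = None
    config_hash: Optional[str] = None
    input_digests: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    def header_lines(self) -> list[str]:
        d = asdict(self)
        return [f"# {k}: {d[k]}" for k in ("command", "version", "seed",
                                           "config_hash", "timestamp")
                if d[k] is not None]


def _fmt(x, nd: int = 4) -> str:
    if x is None:
        return NA_TOKEN
    if isinstance(x, float):
        return f"{x:.{nd}f}"
    return str(x)


def summary_to_frame(summary: CohortSummary) -> pd.DataFrame:
    """Flatten a CohortSummary into a (group, metric, value) CSV frame."""
    rows: list[tuple[str, str, object]] = [
        ("cohort", "n_patients", summary.n_patients),
        ("cohort", "n_ct_nodes", summary.n_ct_nodes),
        ("cohort", "n_suspicious", summary.n_suspicious),
        ("cohort", "n_harvested", summary.n_harvested),
        ("cohort", "n_positive", summary.n_positive),
        ("cohort", "suspicious_fraction", summary.suspicious_fraction),
        ("cohort", "node_metastasis_rate", summary.node_metastasis_rate),
        ("cohort", "patient_positive_fraction", summary.patient_positive_fraction),
        ("cohort", "overall_lnr", summary.overall_lnr),
        ("cohort", "overall_spr", summary.overall_spr),
    ]
    rows += [("band_spr", band, v) for band, v in summary.band_spr.items()]
    rows += [("site_spr", site, v) for site, v in summary.site_spr.items()]
    rows += [("category_counts", cat, v) for cat, v in summary.category_counts.items()]
    for level, metrics in (("node", summary.node_metrics),
                           ("patient", summary.patient_metrics)):
        if metrics is None:
            continue
        rows += [
            (f"{level}_metrics", "sensitivity", metrics.sensitivity),
            (f"{level}_metrics", "specificity", metrics.specificity),
            (f"{level}_metrics", "ppv", metrics.ppv),
            (f"{level}_metrics", "npv", metrics.npv),
        ]
    df = pd.DataFrame(rows, columns=["group", "metric", "value"])
    df["value"] = [NA_TOKEN if v is None else v for v in df["value"]]
    return df


def render_chi_square(result: ChiSquareResult, counts) -> list[str]:
    """Text block mirroring the printed suspicious-vs-metastatic 2x2:
    observed (expected) [contribution] per cell plus the statistic."""
    (a, b), (c, d) = (counts[0], counts[1]), (counts[2], counts[3])
    e, g = result.expected, result.contributions
    lines = [
        "2x2 association, suspicion vs metastasis "
        + ("(Yates-corrected)" if result.yates else "(plain Pearson)"),
        f"{'':>16s} {'LNM+':>22s} {'LNM-':>22s} {'total':>8s}",
    ]
    for label, row, erow, grow in (
        ("suspicious", (a, b), e[0], g[0]),
        ("non-suspicious", (c, d), e[1], g[1]),
    ):
        cells = [
            f"{int(o)} ({ex:.2f}) [{co:.2f}]"
            for o, ex, co in zip(row, erow, grow)
        ]
        lines.append(f"{label:>16s} {cells[0]:>22s} {cells[1]:>22s} {sum(row):>8d}")
    lines.append(
        f"{'total':>16s} {int(a + c):>22d} {int(b + d):>22d} {int(a+b+c+d):>8d}"
    )
    p_txt = "< 0.00001" if result.p_value < 1e-5 else f"{result.p_value:.5f}"
    lines.append(
        f"chi-square statistic {result.statistic:.4f}, df {result.df}, p {p_txt}"
    )
    return lines


def render_pattern_ors(results: dict) -> list[str]:
    lines = [
        "enhancement pattern vs metastasis (one-vs-rest odds of metastasis)",
        f"{'pattern':>12s} {'OR':>8s} {'CI low':>8s} {'CI high':>9s} {'p':>9s} {'0.5-corr':>9s}",
    ]
    for pat in PATTERN_ORDER:
        if pat not in results:
            continue
        r: OddsRatioResult = results[pat]
        lines.append(
            f"{pat.value:>12s} {r.odds_ratio:>8.2f} {r.ci_low:>8.2f} "
            f"{r.ci_high:>9.2f} {r.p_value:>9.4f} {str(r.correction_applied):>9s}"
        )
    return lines


def render_summary_text(
    summary: CohortSummary,
    pattern_ors: Optional[dict] = None,
    manifest: Optional[RunManifest] = None,
) -> str:
    """Human-readable concordance report."""
    lines: list[str] = []
    if manifest is not None:
        lines += manifest.header_lines() + [""]
    lines += [
        "=== cohort concordance summary ===",
        f"patients: {summary.n_patients}  "
        f"(node-positive {_fmt(summary.patient_positive_fraction, 4)})",
        f"CT nodes: {summary.n_ct_nodes}  suspicious: {summary.n_suspicious} "
        f"({_fmt(summary.suspicious_fraction, 4)})",
        f"harvested nodes: {summary.n_harvested}  metastatic: {summary.n_positive} "
        f"({_fmt(summary.node_metastasis_rate, 4)})",
        f"overall LNR: {_fmt(summary.overall_lnr)}   "
        f"overall SPR: {_fmt(summary.overall_spr, 2)}",
        "",
        "SPR by station band (suspicious/positive, pooled counts):",
    ]
    lines += [f"  {band:>13s}: {_fmt(v, 2)}" for band, v in summary.band_spr.items()]
    lines.append("SPR by tumor site:")
    lines += [f"  {site:>16s}: {_fmt(v, 2)}" for site, v in summary.site_spr.items()]
    lines.append("concordance categories (patient-station level):")
    lines += [f"  {cat:>15s}: {n}" for cat, n in summary.category_counts.items()]
    lines.append("")
    t = summary.node_table
    chi = None
    try:
        from .concordance import pearson_chi_square
        chi = pearson_chi_square(t)
    except Exception:
        lines.append("node-level 2x2 degenerate; chi-square not computed")
    if chi is not None:
        lines += render_chi_square(chi, (t.a, t.b, t.c, t.d))
    nm = summary.node_metrics
    lines.append(
        f"node-level   sens {_fmt(nm.sensitivity, 3)}  spec {_fmt(nm.specificity, 3)}  "
        f"PPV {_fmt(nm.ppv, 3)}  NPV {_fmt(nm.npv, 3)}"
    )
    if summary.patient_metrics is not None:
        pm = summary.patient_metrics
        lines.append(
            f"patient-level sens {_fmt(pm.sensitivity, 3)}  spec {_fmt(pm.specificity, 3)}  "
            f"PPV {_fmt(pm.ppv, 3)}  NPV {_fmt(pm.npv, 3)}"
        )
    if pattern_ors:
        lines.append("")
        lines += render_pattern_ors(pattern_ors)
    return "\n".join(lines) + "\n"
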