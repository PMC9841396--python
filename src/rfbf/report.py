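"""Red-flag/blue-flag HTML comparison table and delta scatter diagnostics.

The table contrasts each filter's behaviour on two datasets (typically
train vs validate, or train vs holdout): one row per filter, two cells
per row. A cell heading carries the ngram-independent facts — filter
index, rank under the active sort, AUC, central patient logit (red),
central control logit (blue), their delta, and the filter importance
coloured by class sign — and the cell body lists the top distinct
max-pool ngrams with class-coloured occurrence counts, logit, cosine
and embedding magnitude. Patient-associated quantities render in the
patient colour (red by default), control in blue — hence the name.

Rendering is deterministic: identical inputs produce byte-identical
HTML. Every displayed number comes straight from the ZF dictionaries /
filter metrics; nothing is computed only in the renderer.
"""

from __future__ import annotations

import csv
import html
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import TextCNNModel
from .zf import FilterMetrics, ZFDict, RANK_KEYS, compute_filter_metrics, rank_filters

__all__ = ["ReportOptions", "make_zfs_table", "delta_scatter", "write_scatter_table", "mad_sign_outlier_policy"]


@dataclass(frozen=True)
class ReportOptions:
    """Sort, statistic and colour options of the comparison table."""

    sort_key: str = "delta_mean"
    sort_on: str = "first"
    central_statistic: str = "median"
    max_ngrams_per_cell: int = 4
    patient_color: str = "#c0392b"  # red
    control_color: str = "#2963c0"  # blue

    def __post_init__(self) -> None:
        if self.sort_key not in RANK_KEYS:
            raise ValueError(f"sort_key must be one of {RANK_KEYS}")
        if self.sort_on not in ("first", "second"):
            raise ValueError("sort_on must be 'first' or 'second'")
        if self.central_statistic not in ("mean", "median"):
            raise ValueError("central_statistic must be 'mean' or 'median'")
        if self.max_ngrams_per_cell < 1:
            raise ValueError("max_ngrams_per_cell must be >= 1")


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _cell_html(rec, metrics: FilterMetrics, rank: int, options: ReportOptions) -> str:
    pc, cc = options.patient_color, options.control_color
    imp_color = pc if metrics.class_sign > 0 else cc
    lines = [
        "<div class='heading'>",
        f"<b>filter {metrics.filter_index}</b> &middot; rank {rank} &middot; AUC {_fmt(metrics.auc)}<br>",
        f"<span style='color:{pc}'>patient {_fmt(metrics.patient_central)}</span> "
        f"<span style='color:{cc}'>control {_fmt(metrics.control_central)}</span> "
        f"&Delta; {_fmt(metrics.patient_central - metrics.control_central)}<br>",
        f"<span style='color:{imp_color}'>Imp {_fmt(metrics.importance)}</span>",
        "</div>",
        "<ul class='ngrams'>",
    ]
    for act in rec.top_activations[: options.max_ngrams_per_cell]:
        ngram = html.escape(" ".join(act.ngram_tokens))
        lines.append(
            "<li>"
            f"<span class='ngram'>{ngram}</span> "
            f"<span style='color:{pc}'>{act.patient_count}</span>/"
            f"<span style='color:{cc}'>{act.control_count}</span> "
            f"logit {_fmt(act.logit)} cos {_fmt(act.cosine)} mag {_fmt(act.embedding_magnitude)}"
            "</li>"
        )
    lines.append("</ul>")
    return "\n".join(lines)


def make_zfs_table(
    zf_first: ZFDict,
    zf_second: ZFDict,
    model: TextCNNModel,
    options: ReportOptions = ReportOptions(),
) -> str:
    """Render the two-dataset filter comparison table as a self-contained
    HTML document (inline styles, no external assets)."""
    if zf_first.n_filters != zf_second.n_filters:
        raise ValueError(
            f"ZF dictionaries disagree on filter count: {zf_first.n_filters} vs {zf_second.n_filters}"
        )
    if zf_first.n_filters != model.n_filters:
        raise ValueError("ZF dictionaries were not computed with this model")
    metrics_first = compute_filter_metrics(zf_first, model, options.central_statistic)
    metrics_second = compute_filter_metrics(zf_second, model, options.central_statistic)
    order = rank_filters(metrics_first, metrics_second, options.sort_key, options.sort_on)

    head = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>\n"
        "<title>filter comparison</title>\n"
        "<style>\n"
        "table{border-collapse:collapse;font-family:monospace;font-size:12px;}\n"
        "td,th{border:1px solid #999;vertical-align:top;padding:4px;}\n"
        "ul.ngrams{margin:2px 0 0 14px;padding:0;}\n"
        "div.heading{margin-bottom:2px;}\n"
        "</style></head><body>\n"
        f"<p>sort: {options.sort_key} on {options.sort_on} dataset; "
        f"central statistic: {options.central_statistic}</p>\n"
        "<table>\n"
        f"<tr><th>{html.escape(zf_first.dataset_name)}</th>"
        f"<th>{html.escape(zf_second.dataset_name)}</th></tr>\n"
    )
    rows = []
    for rank, k in enumerate(order, start=1):
        rows.append(
            "<tr class='filter-row'>"
            f"<td>{_cell_html(zf_first[k], metrics_first[k], rank, options)}</td>"
            f"<td>{_cell_html(zf_second[k], metrics_second[k], rank, options)}</td>"
            "</tr>"
        )
    return head + "\n".join(rows) + "\n</table></body></html>\n"


def mad_sign_outlier_policy(delta_first: np.ndarray, delta_second: np.ndarray) -> list[int]:
    """Default cross-dataset outlier rule.

    A filter is flagged when its delta difference (second minus first)
    lies outside median +/- 3 * 1.4826 * MAD of all differences, or when
    its two deltas have opposite signs and both magnitudes exceed the
    median absolute delta over both datasets.
    """
    diffs = delta_second - delta_first
    med = float(np.median(diffs))
    mad = float(np.median(np.abs(diffs - med)))
    robust_sd = 1.4826 * mad
    med_abs = float(np.median(np.abs(np.concatenate([delta_first, delta_second]))))
    out = []
    for k in range(diffs.size):
        spread = abs(diffs[k] - med) > 3.0 * robust_sd
        flipped = (
            delta_first[k] * delta_second[k] < 0
            and abs(delta_first[k]) > med_abs
            and abs(delta_second[k]) > med_abs
        )
        if spread or flipped:
            out.append(k)
    return out


def delta_scatter(
    metrics_first: Sequence[FilterMetrics],
    metrics_second: Sequence[FilterMetrics],
    statistic: str = "median",
    outlier_policy: Callable[[np.ndarray, np.ndarray], list[int]] = mad_sign_outlier_policy,
) -> tuple[np.ndarray, list[int]]:
    """Per-filter (delta_first, delta_second) points with outlier flags.

    Used to spot filters that discriminate on one dataset but not the
    other (distribution drift) — candidates for ablation. The outlier
    rule is a swappable policy; see :func:`mad_sign_outlier_policy`.
    """
    if len(metrics_first) != len(metrics_second):
        raise ValueError("metric lists must have equal length")
    attr = "delta_median" if statistic == "median" else "delta_mean"
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    d1 = np.array([getattr(m, attr) for m in metrics_first])
    d2 = np.array([getattr(m, attr) for m in metrics_second])
    points = np.column_stack([d1, d2])
    return points, outlier_policy(d1, d2)


def write_scatter_table(points: np.ndarray, outliers: Sequence[int], path) -> None:
    """Write the scatter as a tab-separated table
    (filter_index, delta_first, delta_second, outlier_flag)."""
    flagged = set(outliers)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["filter_index", "delta_first", "delta_second", "outlier_flag"])
        for k, (a, b) in enumerate(points):
            w.writerow([k, f"{a:.6g}", f"{b:.6g}", int(k in flagged)])


def plot_delta_scatter(points: np.ndarray, outliers: Sequence[int], path) -> None:
    """Optional rendered scatter image (matplotlib, Agg backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flagged = sorted(set(outliers))
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(points[:, 0], points[:, 1], s=14, color="#555", label="filters")
    if flagged:
        ax.scatter(points[flagged, 0], points[flagged, 1], s=30, color="#c0392b", label="outliers")
        for k in flagged:
            ax.annotate(str(k), points[k], textcoords="offset points", xytext=(4, 4), fontsize=8)
    lim = np.abs(points).max() * 1.1 + 1e-9
    ax.plot([-lim, lim], [-lim, lim], lw=0.5, color="#aaa")
    ax.set_xlabel("delta (first dataset)")
    ax.set_ylabel("delta (second dataset)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
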