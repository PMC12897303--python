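"""Result tables and the class-overlay EEG figure.

``summarize_results`` lays out one table per task with one row per model and
the five headline metrics formatted as percentages with two decimals.
``render_overlay_plot`` draws the stacked multi-channel traces with colored
spans over the seconds carrying each abnormal class: slowing (B) red,
epileptiform discharges (C) orange, seizure (D) purple; normal (A) stays on
the plain black background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import matplotlib
import numpy as np
import pandas as pd

from .epoching import Epoch
from .evaluation import MetricsReport
from .synthetic import SubjectRecording

__all__ = ["CLASS_COLORS", "RunSummary", "summarize_results", "render_overlay_plot"]

CLASS_COLORS = {"B": "red", "C": "orange", "D": "purple"}
_METRIC_COLUMNS = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass
class RunSummary:
    """Per-task metric tables plus run provenance."""

    tables: dict[int, pd.DataFrame]
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "tasks": {
                str(tid): df.to_dict(orient="index") for tid, df in self.tables.items()
            },
        }
        return json.dumps(payload, indent=2)

    def to_csv(self, path) -> None:
        frames = []
        for tid, df in self.tables.items():
            block = df.copy()
            block.insert(0, "task", tid)
            block.insert(1, "model", block.index)
            frames.append(block)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def format_percent(fraction_or_percent: float, already_percent: bool = True) -> str:
    """Render a metric as 'NN.NN%'; pass fractions with already_percent=False."""
    v = fraction_or_percent if already_percent else 100 * fraction_or_percent
    return f"{v:.2f}%"


def summarize_results(reports: list[MetricsReport], seed: int | None = None,
                      config: dict | None = None) -> RunSummary:
    """Group reports into per-task tables (rows = models, columns = metrics)."""
    if not reports:
        raise ValueError("no reports to summarize")
    seen: set[tuple[int, str]] = set()
    by_task: dict[int, dict[str, dict[str, str]]] = {}
    for rep in reports:
        key = (rep.task_id, rep.model)
        if key in seen:
            raise ValueError(f"duplicate report for task {key[0]}, model {key[1]}")
        seen.add(key)
        row = {col: format_percent(getattr(rep, col)) for col in _METRIC_COLUMNS}
        by_task.setdefault(rep.task_id, {})[rep.model] = row
    tables = {
        tid: pd.DataFrame.from_dict(rows, orient="index", columns=_METRIC_COLUMNS)
        for tid, rows in sorted(by_task.items())
    }
    return RunSummary(tables=tables, seed=seed, config=config or {})


def label_spans(epochs: list[Epoch], epoch_len: float = 1.0) -> dict[str, list[tuple[float, float]]]:
    """Merge consecutive same-label epochs into (start, end) spans per class."""
    spans: dict[str, list[tuple[float, float]]] = {}
    for ep in sorted(epochs, key=lambda e: e.start):
        if ep.label is None:
            continue
        lst = spans.setdefault(ep.label, [])
        if lst and abs(lst[-1][1] - ep.start) < 1e-9:
            lst[-1] = (lst[-1][0], ep.start + epoch_len)
        else:
            lst.append((ep.start, ep.start + epoch_len))
    return spans


def render_overlay_plot(rec: SubjectRecording, epochs: list[Epoch], out_path,
                        epoch_len: float = 1.0, max_seconds: float | None = None):
    """Write the stacked-trace figure with class-colored spans; returns spans.

    ``epochs`` may carry predicted or expert labels — the caller chooses which
    story the figure tells.
    """
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    for ep in epochs:
        if ep.subject_id != rec.subject_id:
            raise ValueError(
                f"epoch from subject {ep.subject_id!r} does not belong to "
                f"recording {rec.subject_id!r}"
            )
    n_ch, n_samp = rec.signal.shape
    t_max = rec.duration if max_seconds is None else min(max_seconds, rec.duration)
    n_show = int(t_max * rec.fs)
    t = np.arange(n_show) / rec.fs
    # vertical offsets scaled to the signal spread
    spread = np.percentile(np.abs(rec.signal), 99) * 2.5
    fig, ax = plt.subplots(figsize=(14, 0.45 * n_ch + 2))
    for i in range(n_ch):
        ax.plot(t, rec.signal[i, :n_show] + (n_ch - 1 - i) * spread,
                color="black", linewidth=0.4)
    spans = label_spans([ep for ep in epochs if ep.start < t_max], epoch_len)
    for label, intervals in spans.items():
        color = CLASS_COLORS.get(label)
        if color is None:  # class A: plain background
            continue
        for start, end in intervals:
            ax.axvspan(start, min(end, t_max), color=color, alpha=0.25,
                       label=label)
    handles, labels = ax.get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    if uniq:
        ax.legend(uniq.values(), uniq.keys(), loc="upper right")
    ax.set_yticks([(n_ch - 1 - i) * spread for i in range(n_ch)])
    ax.set_yticklabels(rec.channel_names, fontsize=6)
    ax.set_xlabel("time (s)")
    ax.set_xlim(0, t_max)
    ax.set_title(f"subject {rec.subject_id}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return spans
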