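"""Hierarchical wall-clock instrumentation and stacked-area aggregation.

One :class:`ProfileRecord` is produced per processing-loop iteration,
whether or not the full processing arc completed.  Each record is a tree:
instrumented segments opened while a parent segment is active become its
children, and the root node spans the whole iteration.  Wall-clock time is
used deliberately, so waiting (for data, for the OS) is included.

For reporting, records are averaged in consecutive batches; a segment name
is one category wherever it appears in the tree, each node contributes its
*own* time (duration minus children), the ten largest categories are kept
and the remainder grouped into ``other`` — so the per-batch category sums
reproduce the mean total time exactly.
"""

from __future__ import annotations

import time
from contextlib import contextmanager
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["ProfileNode", "ProfileRecord", "Profiler", "aggregate", "write_aggregate_tsv"]


@dataclass
class ProfileNode:
    name: str
    duration: float = 0.0
    children: list["ProfileNode"] = field(default_factory=list)


@dataclass
class ProfileRecord:
    root: ProfileNode
    completion_index: int

    def flatten(self) -> dict[str, float]:
        """Own-time (duration minus children) per segment name.

        The same name at different tree positions accumulates into one
        category; the residual of every parent stays under the parent's own
        name, so the values sum exactly to the root duration.
        """
        out: dict[str, float] = {}

        def walk(node: ProfileNode) -> None:
            own = node.duration - sum(c.duration for c in node.children)
            out[node.name] = out.get(node.name, 0.0) + own
            for c in node.children:
                walk(c)

        walk(self.root)
        return out


class Profiler:
    """Collects one timing tree per frame.

    ``clock`` is injectable for testing; it defaults to
    :func:`time.perf_counter`.
    """

    def __init__(self, clock=time.perf_counter):
        self._clock = clock
        self._stack: list[ProfileNode] = []
        self.records: list[ProfileRecord] = []

    @contextmanager
    def record(self):
        """Open one processing-loop record; the root segment is ``root``."""
        if self._stack:
            raise RuntimeError("a record is already open")
        root = ProfileNode("root")
        self._stack = [root]
        t0 = self._clock()
        try:
            yield root
        finally:
            root.duration = self._clock() - t0
            if len(self._stack) != 1:
                self._stack = []
                raise RuntimeError("unbalanced time_block nesting at record close")
            self._stack = []
            self.records.append(ProfileRecord(root=root, completion_index=len(self.records)))

    @contextmanager
    def time_block(self, name: str):
        """Time a code segment; nesting builds the tree."""
        if not self._stack:
            raise RuntimeError("time_block used outside an open record")
        node = ProfileNode(name)
        self._stack[-1].children.append(node)
        self._stack.append(node)
        t0 = self._clock()
        try:
            yield node
        finally:
            node.duration = self._clock() - t0
            if self._stack[-1] is not node:
                raise RuntimeError("unbalanced time_block enter/leave")
            self._stack.pop()


def aggregate(records: list[ProfileRecord], batch_size: int, top_n: int = 10) -> pd.DataFrame:
    """Batch-averaged per-category mean times.

    Records are taken in completion order and averaged in consecutive
    batches of ``batch_size`` (the final partial batch is kept).  Categories
    are ranked by their total time over the whole input; the ``top_n``
    largest are reported individually and the rest summed into ``other``.
    Returns a tidy frame with columns ``batch``, ``category``,
    ``mean_seconds``.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be at least 1")
    if not records:
        return pd.DataFrame(columns=["batch", "category", "mean_seconds"])
    ordered = sorted(records, key=lambda r: r.completion_index)
    flats = [r.flatten() for r in ordered]
    totals: dict[str, float] = {}
    for f in flats:
        for k, v in f.items():
            totals[k] = totals.get(k, 0.0) + v
    ranked = sorted(totals, key=lambda k: -totals[k])
    keep = set(ranked[:top_n])
    categories = [c for c in ranked if c in keep] + (["other"] if len(ranked) > top_n else [])

    rows = []
    for b_start in range(0, len(flats), batch_size):
        batch = flats[b_start : b_start + batch_size]
        b_idx = b_start // batch_size
        acc = {c: 0.0 for c in categories}
        for f in batch:
            for k, v in f.items():
                acc[k if k in keep else "other"] = acc.get(k if k in keep else "other", 0.0) + v
        for c in categories:
            rows.append(
                {"batch": b_idx, "category": c, "mean_seconds": acc.get(c, 0.0) / len(batch)}
            )
    return pd.DataFrame(rows)


def write_aggregate_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def plot_aggregate(table: pd.DataFrame, path) -> None:  # pragma: no cover - optional
    """Stacked-area plot of the aggregated table (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot(index="batch", columns="category", values="mean_seconds").fillna(0.0)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.stackplot(pivot.index, pivot.T.values, labels=list(pivot.columns))
    ax.set_xlabel("batch")
    ax.set_ylabel("mean seconds per frame")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
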