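"""Windowed fragment-density profiles along a chromosome.

Fragment counts and the average cut coordinate are binned into fixed-width
windows (default 100 kb, step = width, i.e. tumbling bins; a smaller step
gives true sliding windows).  A fragment belongs to the window containing
its start coordinate, so tumbling-window counts are disjoint and sum to the
number of fragments on the record.  These profiles show where a digest
samples a chromosome densely and where assembly gaps or site-poor regions
leave it uncovered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .digest import CutSite, Fragment


@dataclass(frozen=True)
class WindowBin:
    """One window: fragment count and mean cut coordinate within it."""

    record_id: str
    start: int
    end: int
    n_fragments: int
    mean_cut_position: float  # NaN when the window holds no cuts

    @property
    def width(self) -> int:
        return self.end - self.start


def window_profile(
    fragments: Iterable[Fragment],
    cuts: Iterable[CutSite],
    record_length: int,
    width: int = 100_000,
    step: int | None = None,
    record_id: str | None = None,
) -> list[WindowBin]:
    """Per-window fragment counts and mean cut position for one record.

    Windows start at 0, width ``width`` and stride ``step`` (default
    ``step = width``); the final window is truncated at the record end and
    kept.  Fragment assignment is by start coordinate; with overlapping
    windows (step < width) a fragment counts in every window containing its
    start.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    step = width if step is None else step
    if step <= 0:
        raise ValueError(f"window step must be positive, got {step}")
    frag_list = list(fragments)
    if record_id is None:
        record_id = frag_list[0].record_id if frag_list else ""
    cut_pos = sorted(c.position for c in cuts)
    starts = [f.start for f in frag_list]

    bins: list[WindowBin] = []
    w_start = 0
    while w_start < record_length or (w_start == 0 and record_length == 0):
        w_end = min(w_start + width, record_length)
        n = sum(1 for s in starts if w_start <= s < w_end)
        in_win = [p for p in cut_pos if w_start <= p < w_end]
        mean_cut = sum(in_win) / len(in_win) if in_win else math.nan
        bins.append(WindowBin(record_id, w_start, w_end, n, mean_cut))
        if record_length == 0:
            break
        w_start += step
    return bins


def chromosome_mean_count(bins: Sequence[WindowBin]) -> float:
    """Average fragment count per window over a chromosome's profile."""
    if not bins:
        raise ValueError("cannot average an empty window list")
    return sum(b.n_fragments for b in bins) / len(bins)


def profile_to_frame(bins: Iterable[WindowBin]) -> pd.DataFrame:
    """Tabular (bedgraph-like) view: record_id, start, end, count, mean cut."""
    return pd.DataFrame(
        [
            {
                "record_id": b.record_id,
                "start": b.start,
                "end": b.end,
                "n_fragments": b.n_fragments,
                "mean_cut_position": b.mean_cut_position,
            }
            for b in bins
        ]
    )


def plot_profile(bins: Sequence[WindowBin], ax=None, label: str | None = None):
    """Optional presentation hook: fragment count per window plus its mean line."""
    import matplotlib.pyplot as plt  # deferred; plotting is optional

    if ax is None:
        _, ax = plt.subplots()
    mids = [(b.start + b.end) / 2 for b in bins]
    counts = [b.n_fragments for b in bins]
    (line,) = ax.plot(mids, counts, label=label)
    ax.axhline(chromosome_mean_count(bins), color=line.get_color(), linestyle="--", alpha=0.6)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("fragments per window")
    if label:
        ax.legend()
    return ax
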