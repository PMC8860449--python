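"""Peristimulus time histograms of spike-wave events.

Event onsets are aligned to a stimulus origin (gas-exchange or laser onset,
t = 0), counted in half-open 5-min bins covering ±15 min by default
("three bins per side"), and summarized per animal as pre/post totals and
mean counts per bin with a group mean ± SE.  An event is assigned by its
onset only; t = 0 belongs to the post side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .swd import SwdEvent

__all__ = ["PsthResult", "align", "bin_edges", "bin_counts", "summarize",
           "stacked_histogram"]


@dataclass
class PsthResult:
    """Binned per-animal event counts aligned to the stimulus onset."""

    bin_edges: np.ndarray          # s relative to t_zero, len n_bins + 1
    counts: np.ndarray             # (animal × bin) non-negative integers
    pre_total: np.ndarray          # per-animal Σ counts in [−window, 0)
    post_total: np.ndarray         # per-animal Σ counts in [0, +window)
    mean_pre: np.ndarray           # pre_total / n_pre_bins
    mean_post: np.ndarray
    group_mean_pre: float
    group_se_pre: float
    group_mean_post: float
    group_se_post: float


def align(events: Sequence[SwdEvent | float], t_zero: float) -> np.ndarray:
    """Onset times relative to ``t_zero`` (plain floats pass through)."""
    onsets = np.array(
        [e.t_onset if isinstance(e, SwdEvent) else float(e) for e in events]
    )
    return onsets - t_zero


def bin_edges(window_min: float = 15.0, n_bins_per_side: int = 3) -> np.ndarray:
    """Edges (in seconds) of the 2·n half-open bins covering ±window."""
    if window_min <= 0 or n_bins_per_side <= 0:
        raise ValueError("window and bin count must be positive")
    return np.linspace(
        -window_min * 60.0, window_min * 60.0, 2 * n_bins_per_side + 1
    )


def bin_counts(
    rel_times: np.ndarray,
    window_min: float = 15.0,
    n_bins_per_side: int = 3,
) -> np.ndarray:
    """Integer counts per half-open bin [lo, hi); outside events are ignored.

    A relative time of exactly −window is included in the first bin; exactly
    +window is excluded.
    """
    edges = bin_edges(window_min, n_bins_per_side)
    rel = np.asarray(rel_times, dtype=float)
    counts = np.zeros(edges.size - 1, dtype=int)
    for t in rel:
        if t < edges[0] or t >= edges[-1]:
            continue
        counts[int(np.searchsorted(edges, t, side="right")) - 1] += 1
    return counts


def summarize(
    counts: np.ndarray,
    window_min: float = 15.0,
    n_bins_per_side: int | None = None,
) -> PsthResult:
    """Per-animal pre/post totals and mean counts per bin, plus the group
    mean ± SE across animals (SE = SD/√n, animals are the unit)."""
    counts = np.atleast_2d(np.asarray(counts, dtype=int))
    n_bins = counts.shape[1]
    if n_bins % 2 != 0:
        raise ValueError("counts must have an even number of bins (pre | post)")
    n_side = n_bins // 2 if n_bins_per_side is None else n_bins_per_side
    edges = bin_edges(window_min, n_side)
    pre = counts[:, :n_side].sum(axis=1)
    post = counts[:, n_side:].sum(axis=1)
    mean_pre = pre / n_side
    mean_post = post / n_side
    n_animals = counts.shape[0]

    def se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(n_animals)) if n_animals > 1 else 0.0

    return PsthResult(
        bin_edges=edges,
        counts=counts,
        pre_total=pre,
        post_total=post,
        mean_pre=mean_pre,
        mean_post=mean_post,
        group_mean_pre=float(mean_pre.mean()),
        group_se_pre=se(mean_pre),
        group_mean_post=float(mean_post.mean()),
        group_se_post=se(mean_post),
    )


def stacked_histogram(
    counts: np.ndarray, animal_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Plot-ready long-format table (animal, bin, count) whose per-bin sums
    equal the column sums of the counts matrix."""
    counts = np.atleast_2d(np.asarray(counts, dtype=int))
    if counts.size == 0:
        return pd.DataFrame(columns=["animal", "bin", "count"])
    if animal_ids is None:
        animal_ids = [f"animal_{i}" for i in range(counts.shape[0])]
    records = [
        (animal_ids[a], b, int(counts[a, b]))
        for a in range(counts.shape[0])
        for b in range(counts.shape[1])
    ]
    return pd.DataFrame(records, columns=["animal", "bin", "count"])
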