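"""Permutation test for ChIP-seq peak enrichment over repeat classes.

The observed statistic is, per repeat class, the number of peaks overlapping
at least one element of that class by >= 1 bp (a peak spanning several
copies of one class still counts once; a peak overlapping two classes counts
for both). The null is built by relocating every peak, length preserved,
to a uniformly random position wholly inside the mappable regions, N times;
the empirical p-value uses the add-one estimator
``p = (1 + #{null >= observed}) / (N + 1)`` so it can never be zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .repeats import RepeatElement

__all__ = [
    "Interval",
    "read_bed_intervals",
    "overlap_counts",
    "shuffle_peaks",
    "enrichment_test",
    "EnrichmentResult",
]

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]


def read_bed_intervals(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def _normalize(intervals: Sequence[Interval]) -> list[Interval]:
    """Sort and merge overlapping/touching intervals into a disjoint set."""
    out: list[Interval] = []
    for chrom, start, end in sorted(intervals):
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out.pop()
            out.append((chrom, prev[1], max(prev[2], end)))
        else:
            out.append((chrom, start, end))
    return out


def overlap_counts(
    peaks: Sequence[Interval],
    elements: Sequence[RepeatElement],
) -> dict[str, int]:
    """Number of peaks overlapping each repeat class by >= 1 bp.

    Unsorted inputs are handled (sorted internally, with a log warning).
    """
    if list(peaks) != sorted(peaks):
        logger.warning("peaks were not sorted; sorting internally")
        peaks = sorted(peaks)
    trees: dict[str, IntervalTree] = {}
    for e in elements:
        trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, e.repeat_name)
    counts = {e.repeat_name: 0 for e in elements}
    for chrom, start, end in peaks:
        tree = trees.get(chrom)
        if tree is None:
            continue
        hit_classes = {iv.data for iv in tree.overlap(start, end)}
        for name in hit_classes:
            counts[name] += 1
    return counts


def shuffle_peaks(
    peaks: Sequence[Interval],
    mappable: Sequence[Interval],
    rng: np.random.Generator | int,
) -> list[Interval]:
    """Relocate each peak, length preserved, uniformly over mappable space.

    The start offset is uniform over all positions, across all mappable
    regions, at which the whole peak fits. Peak count and lengths are
    preserved exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    regions = _normalize(mappable)
    region_lens = np.array([e - s for _, s, e in regions], dtype=np.int64)
    out: list[Interval] = []
    for chrom, start, end in peaks:
        L = end - start
        valid = np.maximum(region_lens - L + 1, 0)
        total = int(valid.sum())
        if total == 0:
            raise ValueError(
                f"peak {chrom}:{start}-{end} (length {L}) fits in no mappable region"
            )
        pick = int(rng.integers(0, total))
        cum = np.cumsum(valid)
        ridx = int(np.searchsorted(cum, pick, side="right"))
        offset = pick - (int(cum[ridx - 1]) if ridx else 0)
        rchrom, rstart, _ = regions[ridx]
        out.append((rchrom, rstart + offset, rstart + offset + L))
    return out


@dataclass
class EnrichmentResult:
    """Observed vs shuffled-null overlaps per repeat class."""

    table: pd.DataFrame  # observed, null_mean, null_sd, ratio, pvalue
    n_shuffles: int

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="repeat_class")


def enrichment_test(
    peaks: Sequence[Interval],
    elements: Sequence[RepeatElement],
    mappable: Sequence[Interval],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Compare observed per-class peak overlaps against N shuffled controls.

    ``ratio`` is observed over null mean (1.0 when both are zero, inf when
    the null never overlaps but the observed does); ``pvalue`` is the
    add-one empirical estimate, in (0, 1].
    """
    if n_shuffles < 1:
        raise ValueError(f"n_shuffles must be >= 1, got {n_shuffles}")
    rng = np.random.default_rng(seed)
    observed = overlap_counts(peaks, elements)
    classes = sorted(observed)
    null = np.zeros((n_shuffles, len(classes)), dtype=np.int64)
    for i in range(n_shuffles):
        shuffled = shuffle_peaks(peaks, mappable, rng)
        cnt = overlap_counts(sorted(shuffled), elements)
        null[i] = [cnt[c] for c in classes]
    obs = np.array([observed[c] for c in classes], dtype=float)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1) if n_shuffles > 1 else np.zeros(len(classes))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            null_mean > 0,
            obs / null_mean,
            np.where(obs == 0, 1.0, np.inf),
        )
    ge = (null >= obs[None, :]).sum(axis=0)
    pval = np.where(
        (null_mean == 0) & (obs == 0),
        1.0,
        (1.0 + ge) / (n_shuffles + 1.0),
    )
    table = pd.DataFrame(
        {
            "observed": obs.astype(int),
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ratio": ratio,
            "pvalue": pval,
        },
        index=pd.Index(classes, name="repeat_class"),
    )
    return EnrichmentResult(table, n_shuffles)
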