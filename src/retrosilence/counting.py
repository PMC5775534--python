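"""Read counting over repeats under two mapping regimes, plus copy-level calls.

Two regimes mirror the two questions asked of repeat expression data:

* *inclusive*: multi-mapping reads were assigned upstream to one of their
  equally-best placements at random, and every read is counted once at its
  primary placement — this recovers class-level expression even for young,
  non-uniquely-mappable repeat families;
* *unique*: only reads with a single placement are counted, attributed to
  individual merged elements — this resolves copy-level expression at the
  price of ignoring unmappable copies.

A read is attributed to the element covering at least half of its aligned
span; ties across distinct elements are broken by longest element, then
lexicographic name. Reads overlapping no annotated repeat are tallied as
unassigned so that assigned + unassigned equals the library size exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .repeats import RepeatElement

__all__ = [
    "ReadAlignment",
    "ClassCountTable",
    "CopyCountTable",
    "read_sam_alignments",
    "count_by_class_inclusive",
    "count_by_copy_unique",
    "build_class_table",
    "build_copy_table",
    "rpm",
    "filter_detectable",
    "classify_fold_change",
    "classification_percent",
    "summarize_classification",
]

DETECTION_RPM = 0.25  # element kept if any sample exceeds this (strictly)
TENFOLD = 10.0
DEFAULT_PSEUDOCOUNT_RPM = 0.1


@dataclass
class ReadAlignment:
    """All placements of one read; exactly one is primary."""

    name: str
    placements: list[tuple[str, int, int]]  # (chrom, start, end), 0-based half-open
    primary_index: int

    @property
    def primary(self) -> tuple[str, int, int]:
        if not 0 <= self.primary_index < len(self.placements):
            raise ValueError(f"read {self.name}: no valid primary placement")
        return self.placements[self.primary_index]

    @property
    def is_unique(self) -> bool:
        return len(self.placements) == 1


def read_sam_alignments(path: str | Path) -> list[ReadAlignment]:
    """Group SAM records by read name into :class:`ReadAlignment` objects.

    Secondary alignments (flag 0x100) are collected as extra placements of
    the same read; exactly one non-secondary record per read is expected.
    """
    grouped: dict[str, ReadAlignment] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            placement = (rec.reference_name, rec.reference_start, rec.reference_end)
            if rec.query_name not in grouped:
                grouped[rec.query_name] = ReadAlignment(rec.query_name, [], -1)
                order.append(rec.query_name)
            aln = grouped[rec.query_name]
            if not rec.is_secondary:
                aln.primary_index = len(aln.placements)
            aln.placements.append(placement)
    out = []
    for name in order:
        aln = grouped[name]
        if aln.primary_index < 0:
            raise ValueError(f"read {name} has no primary alignment")
        out.append(aln)
    return out


@dataclass
class ClassCountTable:
    """Raw counts per repeat class (rows) per sample (columns)."""

    counts: pd.DataFrame
    unassigned: pd.Series
    library_sizes: pd.Series

    def rpm(self) -> pd.DataFrame:
        return rpm(self.counts, self.library_sizes)


@dataclass
class CopyCountTable:
    """Unique-regime counts per element copy (rows) per sample (columns)."""

    counts: pd.DataFrame
    library_sizes: pd.Series
    elements: dict[str, RepeatElement] = field(default_factory=dict)

    def rpm(self) -> pd.DataFrame:
        return rpm(self.counts, self.library_sizes)


def _build_tree(elements: Sequence[RepeatElement]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, e in enumerate(elements):
        trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, (i, e))
    return trees


def _attribute(
    trees: dict[str, IntervalTree],
    chrom: str,
    start: int,
    end: int,
    known_chroms: set[str] | None = None,
) -> RepeatElement | None:
    """Element covering >= 50% of the read span, ties to longest then name."""
    if known_chroms is not None and chrom not in known_chroms:
        raise ValueError(f"alignment on unknown chromosome {chrom!r}")
    tree = trees.get(chrom)
    if tree is None:
        return None
    span = end - start
    best: RepeatElement | None = None
    for iv in tree.overlap(start, end):
        ovl = min(end, iv.end) - max(start, iv.begin)
        if 2 * ovl < span:
            continue
        e = iv.data[1]
        if best is None or (e.length, _neg_name(e)) > (best.length, _neg_name(best)):
            best = e
    return best


class _neg_name:
    """Orders names ascending inside a max() comparison."""

    __slots__ = ("name",)

    def __init__(self, e: RepeatElement):
        self.name = e.repeat_name

    def __lt__(self, other: "_neg_name") -> bool:
        return self.name > other.name

    def __gt__(self, other: "_neg_name") -> bool:
        return self.name < other.name

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_name) and self.name == other.name


def count_by_class_inclusive(
    alignments: Iterable[ReadAlignment],
    elements: Sequence[RepeatElement],
    chrom_names: set[str] | None = None,
) -> tuple[dict[str, int], int]:
    """Inclusive-regime counting: every read once, at its primary placement.

    Returns (per-class counts, unassigned count). Multi-mapped reads count
    through the primary placement that was chosen uniformly at random among
    their equally-best hits upstream.
    """
    trees = _build_tree(elements)
    counts: dict[str, int] = {e.repeat_name: 0 for e in elements}
    unassigned = 0
    for aln in alignments:
        chrom, start, end = aln.primary
        e = _attribute(trees, chrom, start, end, chrom_names)
        if e is None:
            unassigned += 1
        else:
            counts[e.repeat_name] += 1
    return counts, unassigned


def count_by_copy_unique(
    alignments: Iterable[ReadAlignment],
    elements: Sequence[RepeatElement],
    chrom_names: set[str] | None = None,
) -> dict[str, int]:
    """Unique-regime counting over merged element copies.

    Only reads with exactly one placement contribute; attribution uses the
    same >= 50%-overlap rule. Keys are ``name@chrom:start-end(strand)``
    copy identifiers.
    """
    trees = _build_tree(elements)
    counts = {copy_key(e): 0 for e in elements}
    for aln in alignments:
        if not aln.is_unique:
            continue
        chrom, start, end = aln.primary
        e = _attribute(trees, chrom, start, end, chrom_names)
        if e is not None:
            counts[copy_key(e)] += 1
    return counts


def copy_key(e: RepeatElement) -> str:
    return f"{e.repeat_name}@{e.chrom}:{e.start}-{e.end}({e.strand})"


def build_class_table(
    per_sample: dict[str, tuple[dict[str, int], int]],
    library_sizes: dict[str, int],
) -> ClassCountTable:
    """Assemble per-sample (counts, unassigned) pairs into one table."""
    samples = list(per_sample)
    classes = sorted({k for cnts, _ in per_sample.values() for k in cnts})
    mat = pd.DataFrame(
        {s: [per_sample[s][0].get(c, 0) for c in classes] for s in samples},
        index=classes,
        dtype=int,
    )
    unassigned = pd.Series({s: per_sample[s][1] for s in samples}, dtype=int)
    libs = pd.Series(library_sizes, dtype=int).reindex(samples)
    return ClassCountTable(mat, unassigned, libs)


def build_copy_table(
    per_sample: dict[str, dict[str, int]],
    library_sizes: dict[str, int],
    elements: Sequence[RepeatElement] = (),
) -> CopyCountTable:
    samples = list(per_sample)
    copies = sorted({k for cnts in per_sample.values() for k in cnts})
    mat = pd.DataFrame(
        {s: [per_sample[s].get(c, 0) for c in copies] for s in samples},
        index=copies,
        dtype=int,
    )
    libs = pd.Series(library_sizes, dtype=int).reindex(samples)
    emap = {copy_key(e): e for e in elements}
    return CopyCountTable(mat, libs, emap)


def rpm(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Reads per million of total library size (all reads, not just assigned)."""
    return counts * 1e6 / library_sizes.reindex(counts.columns)


def filter_detectable(
    copy_rpm: pd.DataFrame, threshold: float = DETECTION_RPM
) -> pd.DataFrame:
    """Keep copies whose RPM exceeds the threshold in any sample (strictly).

    A copy at exactly the threshold in every sample is dropped.
    """
    keep = (copy_rpm > threshold).any(axis=1)
    return copy_rpm.loc[keep]


def classify_fold_change(
    copy_rpm_control: pd.Series | pd.DataFrame,
    copy_rpm_depleted: pd.Series | pd.DataFrame,
    fold: float = TENFOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_RPM,
) -> pd.Series:
    """Per-copy tenfold-activation call from mean RPM in each condition.

    A copy is upregulated iff
    ``(mean depleted RPM + pseudocount) / (mean control RPM + pseudocount)``
    strictly exceeds ``fold``. The pseudocount guards the ratio against
    zero-expression copies in the control.
    """
    ctrl = (
        copy_rpm_control.mean(axis=1)
        if isinstance(copy_rpm_control, pd.DataFrame)
        else copy_rpm_control
    )
    depl = (
        copy_rpm_depleted.mean(axis=1)
        if isinstance(copy_rpm_depleted, pd.DataFrame)
        else copy_rpm_depleted
    )
    if (ctrl < 0).any() or (depl < 0).any():
        raise ValueError("RPM values must be non-negative")
    ratio = (depl + pseudocount) / (ctrl + pseudocount)
    return ratio > fold


def classification_percent(n_detectable: int, n_upregulated: int) -> int | None:
    """Integer percentage of detectable copies called upregulated.

    ``None`` (undefined, not zero) when nothing is detectable.
    """
    if n_detectable == 0:
        return None
    return int(round(100.0 * n_upregulated / n_detectable))


def summarize_classification(copy_calls: pd.Series | Sequence[bool]) -> dict:
    """Summarize copy-level calls as counts and an integer percentage.

    Returns ``{"n_detectable", "n_upregulated", "percent_upregulated"}``;
    the percentage is rounded to the nearest integer and is ``None``
    (undefined, not zero) when no copy is detectable.
    """
    calls = pd.Series(copy_calls, dtype=bool)
    n = int(len(calls))
    n_up = int(calls.sum())
    return {
        "n_detectable": n,
        "n_upregulated": n_up,
        "percent_upregulated": classification_percent(n, n_up),
    }
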