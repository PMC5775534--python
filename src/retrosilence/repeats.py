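"""RepeatMasker annotation handling: parsing, fragment merging, full-length calls.

Intracisternal A particle (IAP) proviruses are annotated by RepeatMasker as
separate fragments (internal IAPEz-int segments flanked by IAPLTR1/IAPLTR2
long terminal repeats, frequently interrupted by small unannotated gaps).
Copy-level expression analysis therefore works on a custom annotation in
which same-strand fragments of the same repeat lying within 100 bp of each
other are merged into a single element; merged elements spanning more than
5 kb are classified as full-length proviruses, the rest as truncated.

Coordinate conventions: RepeatMasker ``.out`` files are 1-based inclusive and
use ``C`` for the minus strand; everything downstream of the parser is 0-based
half-open BED-style.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RepeatFragment",
    "RepeatElement",
    "parse_repeatmasker",
    "merge_fragments",
    "classify_full_length",
    "write_bed",
    "read_bed",
]

#: merged span (bp) above which an element counts as a full-length provirus
FULL_LENGTH_BP = 5000

#: maximum gap (bp, bases strictly between fragments) bridged when merging
DEFAULT_MERGE_GAP = 100


@dataclass(frozen=True)
class RepeatFragment:
    """One RepeatMasker hit, already converted to 0-based half-open coords."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_family: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty fragment {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/- , got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatElement:
    """A merged, stranded repeat element (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    n_fragments: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def full_length(self) -> bool:
        return classify_full_length(self)


class RepeatMaskerParseError(ValueError):
    pass


def parse_repeatmasker(path: str | Path) -> list[RepeatFragment]:
    """Parse a RepeatMasker ``.out`` file into fragments, in file order.

    The dialect has 2-3 header lines, whitespace-delimited columns, and uses
    ``C`` in the strand column for minus-strand hits. Input coordinates
    (1-based inclusive) are converted to 0-based half-open here, at the
    parser boundary.
    """
    fragments: list[RepeatFragment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            # header lines start with column titles, not a numeric SW score
            if not fields[0].lstrip("-").isdigit():
                continue
            if len(fields) < 11:
                raise RepeatMaskerParseError(
                    f"{path}:{lineno}: expected >= 11 columns, got {len(fields)}"
                )
            chrom = fields[4]
            start_1based = int(fields[5])
            end_1based = int(fields[6])
            strand = "-" if fields[8] == "C" else "+"
            repeat_name = fields[9]
            repeat_family = fields[10]
            fragments.append(
                RepeatFragment(
                    chrom=chrom,
                    start=start_1based - 1,
                    end=end_1based,
                    strand=strand,
                    repeat_name=repeat_name,
                    repeat_family=repeat_family,
                )
            )
    return fragments


def merge_fragments(
    fragments: Iterable[RepeatFragment],
    gap: int = DEFAULT_MERGE_GAP,
    name_scope: set[str] | None = None,
) -> list[RepeatElement]:
    """Merge same-chrom/strand/name fragments separated by at most ``gap`` bp.

    ``gap`` counts the bases strictly between two fragments; touching or
    overlapping fragments have gap 0. Merging is transitive and exhaustive,
    so output elements of the same name and strand are pairwise separated by
    more than ``gap`` bases. Fragments whose name is outside ``name_scope``
    (when given) pass through as single-fragment elements.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    frags = sorted(fragments, key=lambda f: (f.chrom, f.start, f.end))
    out: list[RepeatElement] = []
    # open element per (chrom, strand, name) group; sorted sweep suffices
    open_by_key: dict[tuple[str, str, str], RepeatElement] = {}
    for f in frags:
        key = (f.chrom, f.strand, f.repeat_name)
        if name_scope is not None and f.repeat_name not in name_scope:
            out.append(
                RepeatElement(f.chrom, f.start, f.end, f.strand, f.repeat_name, 1)
            )
            continue
        cur = open_by_key.get(key)
        if cur is not None and f.start - cur.end <= gap:
            open_by_key[key] = RepeatElement(
                cur.chrom,
                cur.start,
                max(cur.end, f.end),
                cur.strand,
                cur.repeat_name,
                cur.n_fragments + 1,
            )
        else:
            if cur is not None:
                out.append(cur)
            open_by_key[key] = RepeatElement(
                f.chrom, f.start, f.end, f.strand, f.repeat_name, 1
            )
    out.extend(open_by_key.values())
    out.sort(key=lambda e: (e.chrom, e.start, e.end, e.strand, e.repeat_name))
    return out


def classify_full_length(element: RepeatElement) -> bool:
    """True iff the merged span exceeds 5 kb (strictly).

    A span of exactly 5000 bp is truncated: the classification rule is
    "longer than 5 kb".
    """
    return element.length > FULL_LENGTH_BP


def write_bed(elements: Sequence[RepeatElement], path: str | Path) -> None:
    """Write elements as BED6 (name = repeat name, score = fragment count)."""
    with open(path, "w") as fh:
        for e in elements:
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{e.repeat_name}\t{e.n_fragments}\t{e.strand}\n"
            )


def read_bed(path: str | Path) -> list[RepeatElement]:
    """Read a BED6 file written by :func:`write_bed` back into elements."""
    elements: list[RepeatElement] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = int(fields[4]) if len(fields) > 4 and fields[4] != "." else 1
            strand = fields[5] if len(fields) > 5 else "+"
            elements.append(RepeatElement(chrom, start, end, strand, name, score))
    return elements
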