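"""Per-CpG 5mC/5hmC calling from paired BS / oxBS amplicon sequencing.

Bisulfite (BS) conversion leaves both 5-methylcytosine and
5-hydroxymethylcytosine unconverted, so the BS C-fraction at a CpG estimates
5mC + 5hmC. Oxidative bisulfite (oxBS) first oxidizes 5hmC so that it
converts like an unmodified C, and the oxBS C-fraction estimates 5mC alone.
Their difference, clamped at zero, estimates 5hmC:

    5mC  = level_oxBS
    5hmC = max(0, level_BS - level_oxBS)

Amplicon reads span the whole reference, so alignment reduces to ungapped
conversion-aware matching: a read is compared against each amplicon in both
orientations with reference-C positions exempt from mismatch counting (they
legitimately read C or T), and assigned to the best match if its mismatch
rate is at most 10%. Only CpGs covered by at least 100 reads in both
treatments pass QC; no incomplete-conversion correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "Amplicon",
    "CpGStateCounts",
    "MethylationCall",
    "load_amplicons",
    "match_amplicon_reads",
    "tally_cpg_states",
    "call_methylation",
    "aggregate_amplicon",
    "run_oxbs",
]

MIN_COVERAGE = 100  # "at least 100 reads", inclusive, per treatment
MAX_MISMATCH_FRACTION = 0.10


@dataclass
class Amplicon:
    """An amplicon reference with its CpG cytosine offsets (0-based)."""

    name: str
    seq: str
    cpg_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.cpg_positions:
            self.cpg_positions = [
                i for i in range(len(self.seq) - 1) if self.seq[i : i + 2] == "CG"
            ]
        for p in self.cpg_positions:
            if self.seq[p : p + 2] != "CG":
                raise ValueError(f"{self.name}: offset {p} does not hold a CpG")


def load_amplicons(path: str | Path) -> list[Amplicon]:
    """Read amplicon references from FASTA; CpGs are located automatically."""
    return [Amplicon(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq_sequences(path: str | Path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


@dataclass
class _PreparedAmplicon:
    amplicon: Amplicon
    ref: np.ndarray  # uint8 reference bases
    exempt: np.ndarray  # bool, reference-C positions


def _prepare(amplicons: Sequence[Amplicon]) -> list[_PreparedAmplicon]:
    out = []
    for a in amplicons:
        ref = np.frombuffer(a.seq.encode(), dtype=np.uint8)
        out.append(_PreparedAmplicon(a, ref, ref == ord("C")))
    return out


def _mismatches(read: np.ndarray, prep: _PreparedAmplicon, forward: bool) -> int | None:
    """Ungapped mismatch count with reference-C exemption, or None if too long.

    Forward reads are anchored at the amplicon start; reverse-orientation
    reads are reverse-complemented and anchored at the amplicon end.
    """
    L = read.size
    if L > prep.ref.size:
        return None
    if forward:
        ref = prep.ref[:L]
        exempt = prep.exempt[:L]
        r = read
    else:
        ref = prep.ref[-L:]
        exempt = prep.exempt[-L:]
        rc = reverse_complement(read.tobytes().decode())
        r = np.frombuffer(rc.encode(), dtype=np.uint8)
    diff = (r != ref) & ~exempt
    return int(diff.sum())


def match_amplicon_reads(
    reads: Iterable[str],
    amplicons: Sequence[Amplicon],
    max_mismatch_fraction: float = MAX_MISMATCH_FRACTION,
) -> list[tuple[int | None, str | None]]:
    """Assign each read to (amplicon index, orientation) or (None, None).

    A read is assigned to the amplicon/orientation pair minimizing the
    conversion-aware mismatch count if that minimum is at most
    ``max_mismatch_fraction`` of the read length; otherwise it stays
    unassigned. Orientation is ``"+"`` (read as the top strand) or ``"-"``
    (reverse-complemented read matches the reference).
    """
    prepared = _prepare(amplicons)
    out: list[tuple[int | None, str | None]] = []
    for seq in reads:
        read = np.frombuffer(seq.encode(), dtype=np.uint8)
        best: tuple[int, int, str] | None = None  # (mismatches, index, orientation)
        for i, prep in enumerate(prepared):
            for forward in (True, False):
                mm = _mismatches(read, prep, forward)
                if mm is None:
                    continue
                cand = (mm, i, "+" if forward else "-")
                if best is None or cand < best:
                    best = cand
        if best is not None and best[0] <= max_mismatch_fraction * read.size:
            out.append((best[1], best[2]))
        else:
            out.append((None, None))
    return out


@dataclass
class CpGStateCounts:
    """Per-CpG converted/unconverted tallies for one treatment of one amplicon."""

    amplicon: str
    n_C: dict[int, int]
    n_T: dict[int, int]

    def coverage(self, pos: int) -> int:
        return self.n_C.get(pos, 0) + self.n_T.get(pos, 0)

    def level(self, pos: int) -> float:
        cov = self.coverage(pos)
        return self.n_C.get(pos, 0) / cov if cov else float("nan")


def tally_cpg_states(
    reads: Sequence[str],
    assignments: Sequence[tuple[int | None, str | None]],
    amplicons: Sequence[Amplicon],
) -> list[CpGStateCounts]:
    """Count C (unconverted) and T (converted) observations at each CpG.

    Reverse-orientation reads are complemented into top-strand coordinates
    first. Bases other than C/T at a CpG cytosine are ignored.
    """
    tallies = [
        CpGStateCounts(a.name, {p: 0 for p in a.cpg_positions}, {p: 0 for p in a.cpg_positions})
        for a in amplicons
    ]
    for seq, (idx, orient) in zip(reads, assignments):
        if idx is None:
            continue
        amp = amplicons[idx]
        if orient == "-":
            seq = reverse_complement(seq)
            offset = len(amp.seq) - len(seq)  # reverse reads anchor at the 3' end
        else:
            offset = 0
        for p in amp.cpg_positions:
            j = p - offset
            if j < 0 or j >= len(seq):
                continue
            base = seq[j]
            if base == "C":
                tallies[idx].n_C[p] += 1
            elif base == "T":
                tallies[idx].n_T[p] += 1
    return tallies


@dataclass
class MethylationCall:
    """Per-CpG 5mC/5hmC estimate with its BS/oxBS coverages and QC flag."""

    amplicon: str
    position: int
    coverage_BS: int
    coverage_oxBS: int
    level_BS: float  # estimates 5mC + 5hmC
    level_oxBS: float  # estimates 5mC
    five_mC: float
    five_hmC: float
    qc_pass: bool
    missing_treatment: bool = False


def call_methylation(
    counts_BS: CpGStateCounts,
    counts_oxBS: CpGStateCounts,
    min_coverage: int = MIN_COVERAGE,
) -> list[MethylationCall]:
    """Combine paired BS/oxBS tallies into per-CpG 5mC and 5hmC calls.

    ``five_hmC`` is clamped at zero (sampling noise can make the oxBS level
    exceed the BS level). QC passes iff both treatments reach
    ``min_coverage`` reads (inclusive) at the CpG; failing calls are still
    reported, flagged.
    """
    if counts_BS.amplicon != counts_oxBS.amplicon:
        raise ValueError("BS and oxBS tallies are from different amplicons")
    calls = []
    positions = sorted(set(counts_BS.n_C) | set(counts_oxBS.n_C))
    for p in positions:
        cov_bs = counts_BS.coverage(p)
        cov_ox = counts_oxBS.coverage(p)
        lvl_bs = counts_BS.level(p)
        lvl_ox = counts_oxBS.level(p)
        missing = cov_bs == 0 or cov_ox == 0
        five_mc = lvl_ox
        five_hmc = max(0.0, lvl_bs - lvl_ox) if not missing else float("nan")
        calls.append(
            MethylationCall(
                amplicon=counts_BS.amplicon,
                position=p,
                coverage_BS=cov_bs,
                coverage_oxBS=cov_ox,
                level_BS=lvl_bs,
                level_oxBS=lvl_ox,
                five_mC=five_mc,
                five_hmC=five_hmc,
                qc_pass=(cov_bs >= min_coverage and cov_ox >= min_coverage),
                missing_treatment=missing,
            )
        )
    return calls


def aggregate_amplicon(
    replicate_calls: Sequence[Sequence[MethylationCall]],
) -> pd.DataFrame:
    """Average 5mC/5hmC across QC-passing replicates, per CpG.

    Each data point is the unweighted mean over replicates that pass QC at
    that CpG; CpGs with no passing replicate are omitted. Returns a
    DataFrame indexed by (amplicon, position).
    """
    rows: dict[tuple[str, int], list[MethylationCall]] = {}
    for calls in replicate_calls:
        for c in calls:
            if c.qc_pass:
                rows.setdefault((c.amplicon, c.position), []).append(c)
    records = []
    for (amp, pos), cs in sorted(rows.items()):
        records.append(
            {
                "amplicon": amp,
                "position": pos,
                "n_replicates": len(cs),
                "five_mC": float(np.mean([c.five_mC for c in cs])),
                "five_hmC": float(np.mean([c.five_hmC for c in cs])),
                "level_BS": float(np.mean([c.level_BS for c in cs])),
                "level_oxBS": float(np.mean([c.level_oxBS for c in cs])),
            }
        )
    return pd.DataFrame(records).set_index(["amplicon", "position"]) if records else pd.DataFrame(
        columns=["amplicon", "position", "n_replicates", "five_mC", "five_hmC",
                 "level_BS", "level_oxBS"]
    ).set_index(["amplicon", "position"])


def run_oxbs(
    amplicons: Sequence[Amplicon],
    bs_reads: Sequence[str],
    oxbs_reads: Sequence[str],
    min_coverage: int = MIN_COVERAGE,
) -> list[MethylationCall]:
    """Match, tally and call one replicate's paired BS/oxBS libraries."""
    bs_assign = match_amplicon_reads(bs_reads, amplicons)
    ox_assign = match_amplicon_reads(oxbs_reads, amplicons)
    bs_tallies = tally_cpg_states(bs_reads, bs_assign, amplicons)
    ox_tallies = tally_cpg_states(oxbs_reads, ox_assign, amplicons)
    calls: list[MethylationCall] = []
    for bs_t, ox_t in zip(bs_tallies, ox_tallies):
        calls.extend(call_methylation(bs_t, ox_t, min_coverage=min_coverage))
    return calls


def calls_to_frame(calls: Sequence[MethylationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "amplicon": c.amplicon,
                "position": c.position,
                "coverage_BS": c.coverage_BS,
                "coverage_oxBS": c.coverage_oxBS,
                "level_BS": c.level_BS,
                "level_oxBS": c.level_oxBS,
                "five_mC": c.five_mC,
                "five_hmC": c.five_hmC,
                "qc_pass": c.qc_pass,
            }
            for c in calls
        ]
    )
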