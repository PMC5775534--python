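"""Synthetic data with known ground truth for the retroelement pipeline.

The generator emulates the study design used to quantify endogenous
retrovirus (ERV) derepression after SETDB1 knockdown in mouse embryonic stem
cells:

* a toy genome carrying several repeat classes, each with multiple copies of
  high mutual sequence identity (so short reads multi-map), including both
  full-length (>5 kb) and truncated copies, annotated in RepeatMasker
  ``.out`` format with copies split into merge-able fragments;
* RNA-seq alignments for control ("A", shScr-like) and depleted ("B",
  shSETDB1-like) conditions, where an IAP-like class is activated more than
  tenfold; every read carries all equally-best candidate placements as SAM
  secondary alignments, with the primary drawn uniformly at random;
* paired bisulfite (BS) / oxidative-bisulfite (oxBS) amplicon reads generated
  from known per-CpG 5mC/5hmC levels under an explicit chemistry model;
* ChIP-seq-like peak sets that are, or are not, enriched over chosen repeat
  classes, together with the mappable-region BED the permutation null uses.

All randomness flows from ``numpy.random.default_rng`` seeded with
``[config.seed, operation offset, ...]`` so each operation is independently
reproducible and a fixed config yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .repeats import RepeatElement

__all__ = [
    "SimulationConfig",
    "CopyTruth",
    "AmpliconTruth",
    "GroundTruth",
    "ToyGenome",
    "SimulatedRead",
    "build_toy_genome",
    "simulate_rnaseq_alignments",
    "simulate_bisulfite_reads",
    "simulate_peaks",
    "write_genome_fasta",
    "write_repeatmasker_out",
    "write_sam",
    "write_fastq",
    "write_bed_intervals",
    "simulate_all",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")

# per-operation RNG stream offsets (seeded as [seed, offset, ...])
_OFF_GENOME = 0
_OFF_RNASEQ = 1
_OFF_BISULFITE = 2
_OFF_PEAKS = 3
_OFF_AMPLICONS = 4

_DEFAULT_CLASS_NAMES = ("IAPEz", "RLTR4_MM", "L1Md_A", "MERVL")


class SizingError(ValueError):
    """A repeat copy does not fit in the requested chromosome."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the emulated experiment: several ERV-like repeat
    classes with six near-identical copies each, three biological replicates
    per condition, and an IAP-like class activated twelvefold in the
    depleted condition.
    """

    seed: int = 0
    n_classes: int = 4
    copies_per_class: int = 6
    copy_length_range: tuple[int, int] = (800, 7000)
    inter_copy_divergence: float = 0.02
    read_length: int = 50
    library_sizes: dict[str, int] = field(default_factory=dict)
    sample_conditions: dict[str, str] = field(default_factory=dict)
    class_fold_changes: dict[str, float] = field(default_factory=dict)
    bs_conversion_efficiency: float = 0.995
    oxidation_efficiency: float = 0.95
    # genome layout
    chromosome_name: str = "chr1"
    chromosome_length: int | None = None  # None: auto-sized to fit layout
    spacer_length_range: tuple[int, int] = (500, 2000)
    # expression model; background dominates, as gene-derived reads do in
    # real total RNA-seq, so repeat activation is measurable on the RPM scale
    background_fraction: float = 0.9  # expected non-repeat read share, condition A
    replicate_cv: float = 0.1  # lognormal CV of per-replicate class expression
    error_rate: float = 0.0  # uniform substitution rate in RNA-seq reads
    # amplicons
    n_amplicons: int = 2
    amplicon_length: int = 300
    n_cpgs_per_amplicon: int = 8
    bs_reads_per_treatment: int = 2000
    bs_replicates: int = 2
    # peaks
    n_peaks: int = 300
    peak_length: int = 300
    peak_enrichment_fraction: float = 0.8
    enriched_classes: tuple[str, ...] = ("IAPEz",)

    def __post_init__(self) -> None:
        lo, hi = self.copy_length_range
        if not (lo < 5000 < hi):
            raise ValueError(
                "copy_length_range must span 5000 bp so both truncated and "
                f"full-length copies exist, got {self.copy_length_range}"
            )
        for name, p in (
            ("inter_copy_divergence", self.inter_copy_divergence),
            ("bs_conversion_efficiency", self.bs_conversion_efficiency),
            ("oxidation_efficiency", self.oxidation_efficiency),
            ("background_fraction", self.background_fraction),
            ("peak_enrichment_fraction", self.peak_enrichment_fraction),
            ("error_rate", self.error_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.inter_copy_divergence >= 1.0:
            raise ValueError("inter_copy_divergence must be < 1")
        if not self.library_sizes:
            self.library_sizes = {
                f"{cond}_{i}": 30_000
                for cond in ("control", "depleted")
                for i in (1, 2, 3)
            }
        if not self.sample_conditions:
            self.sample_conditions = {
                s: ("A" if s.startswith("control") else "B")
                for s in self.library_sizes
            }
        if not self.class_fold_changes:
            self.class_fold_changes = {"IAPEz": 15.0}

    @property
    def class_names(self) -> list[str]:
        names = list(_DEFAULT_CLASS_NAMES[: self.n_classes])
        names += [f"REP{i}" for i in range(len(names) + 1, self.n_classes + 1)]
        return names

    @property
    def samples(self) -> list[str]:
        return list(self.library_sizes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CopyTruth:
    """One planted repeat copy: coordinates plus its consensus-frame sequence."""

    chrom: str
    start: int  # 0-based half-open genomic span
    end: int
    strand: str
    class_name: str
    copy_id: str
    cons_seq: str  # copy sequence in consensus orientation (5' aligned)
    fragments: list[tuple[int, int]]  # genomic sub-spans written to the .out file

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_element(self) -> RepeatElement:
        return RepeatElement(
            self.chrom, self.start, self.end, self.strand, self.class_name,
            n_fragments=len(self.fragments),
        )


@dataclass
class AmpliconTruth:
    name: str
    seq: str
    cpg_positions: list[int]  # 0-based offsets of the CpG cytosine
    five_mC: dict[int, float]
    five_hmC: dict[int, float]

    def __post_init__(self) -> None:
        for pos in self.cpg_positions:
            if self.seq[pos : pos + 2] != "CG":
                raise ValueError(f"{self.name}: position {pos} is not a CpG")
            if self.five_mC[pos] + self.five_hmC[pos] > 1.0 + 1e-12:
                raise ValueError(f"{self.name}: 5mC + 5hmC > 1 at CpG {pos}")


@dataclass
class GroundTruth:
    copies: list[CopyTruth]
    class_expression: dict[str, dict[str, float]]  # condition -> class -> weight
    background_weight: float
    amplicons: list[AmpliconTruth]
    enriched_classes: tuple[str, ...]

    def copies_of(self, class_name: str) -> list[CopyTruth]:
        return [c for c in self.copies if c.class_name == class_name]


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    truth: GroundTruth

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


# ---------------------------------------------------------------------------
# genome construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=int(hit.sum()))
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        codes = np.array([idx[b] for b in arr[hit]])
        arr[hit] = _BASES[(codes + shift) % 4]
    return arr.tobytes().decode()


def _fragment_copy(
    rng: np.random.Generator, start: int, end: int
) -> list[tuple[int, int]]:
    """Split a copy span into 1-3 fragments separated by gaps of <= 100 bp."""
    length = end - start
    n_frag = int(rng.integers(1, 4))
    if length < n_frag * 150:
        n_frag = 1
    if n_frag == 1:
        return [(start, end)]
    gaps = rng.integers(10, 101, size=n_frag - 1)
    inner = length - int(gaps.sum())
    cuts = np.sort(rng.choice(np.arange(1, inner), size=n_frag - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [inner]]))
    frags = []
    pos = start
    for i, sz in enumerate(sizes):
        frags.append((pos, pos + int(sz)))
        pos += int(sz)
        if i < len(gaps):
            pos += int(gaps[i])
    return frags


def build_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Build the toy genome, its repeat annotation and full ground truth.

    Copy lengths within a class are spread evenly over
    ``copy_length_range`` so each class contains both truncated and
    full-length (>5 kb) copies. Each copy is the class consensus (or a 5'
    prefix of it, for truncated copies) mutated at ``inter_copy_divergence``
    substitutions per site, inserted on a random strand.
    """
    rng = np.random.default_rng([config.seed, _OFF_GENOME])
    lo, hi = config.copy_length_range

    consensi = {
        name: _random_seq(rng, hi) for name in config.class_names
    }
    lengths = np.linspace(lo, hi, config.copies_per_class).astype(int)

    # interleave copies of all classes in shuffled order
    plan: list[tuple[str, int]] = []
    for name in config.class_names:
        for L in lengths:
            plan.append((name, int(L)))
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    if config.chromosome_length is not None:
        too_big = [L for _, L in plan if L > config.chromosome_length]
        if too_big:
            raise SizingError(
                f"copy of length {max(too_big)} bp exceeds chromosome length "
                f"{config.chromosome_length} bp"
            )

    chrom = config.chromosome_name
    parts: list[str] = []
    pos = 0
    copies: list[CopyTruth] = []
    counters: dict[str, int] = {}
    slo, shi = config.spacer_length_range
    for name, L in plan:
        spacer = _random_seq(rng, int(rng.integers(slo, shi + 1)))
        parts.append(spacer)
        pos += len(spacer)
        cons = _mutate(rng, consensi[name][:L], config.inter_copy_divergence)
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = cons if strand == "+" else _revcomp(cons)
        start, end = pos, pos + L
        counters[name] = counters.get(name, 0) + 1
        copies.append(
            CopyTruth(
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                class_name=name,
                copy_id=f"{name}.{counters[name]}",
                cons_seq=cons,
                fragments=_fragment_copy(rng, start, end),
            )
        )
        parts.append(genomic)
        pos += L
    tail = _random_seq(rng, int(rng.integers(slo, shi + 1)))
    parts.append(tail)
    pos += len(tail)

    if config.chromosome_length is not None and pos > config.chromosome_length:
        raise SizingError(
            f"layout needs {pos} bp but chromosome_length is "
            f"{config.chromosome_length} bp"
        )

    genome_seq = "".join(parts)

    # per-condition relative class expression; condition B scales by fold change
    expr_a = {name: 1.0 for name in config.class_names}
    expr_b = {
        name: expr_a[name] * config.class_fold_changes.get(name, 1.0)
        for name in config.class_names
    }
    # background weight set so condition A has the configured background share
    repeat_weight_a = sum(
        expr_a[c.class_name] * c.length
        for c in copies
        if c.length >= config.read_length
    )
    f = config.background_fraction
    background_weight = f / (1.0 - f) * repeat_weight_a if f > 0 else 0.0

    amplicons = _generate_amplicons(config)

    truth = GroundTruth(
        copies=copies,
        class_expression={"A": expr_a, "B": expr_b},
        background_weight=background_weight,
        amplicons=amplicons,
        enriched_classes=config.enriched_classes,
    )
    return ToyGenome(sequences={chrom: genome_seq}, truth=truth)


def _generate_amplicons(config: SimulationConfig) -> list[AmpliconTruth]:
    """Amplicon references with planted CpGs and known 5mC/5hmC levels.

    The first amplicon mimics a highly methylated IAP LTR (5mC 0.4-0.9);
    the others mimic hypomethylated ERVs (5mC 0.05-0.3). 5hmC is low
    (0-0.1), as observed at ERVs.
    """
    rng = np.random.default_rng([config.seed, _OFF_AMPLICONS])
    amplicons = []
    L = config.amplicon_length
    n_cpg = config.n_cpgs_per_amplicon
    for i in range(config.n_amplicons):
        arr = np.frombuffer(_random_seq(rng, L).encode(), dtype=np.uint8).copy()
        # strip accidental CpGs, then plant them at evenly spaced offsets
        for j in range(L - 1):
            if arr[j] == ord("C") and arr[j + 1] == ord("G"):
                arr[j + 1] = ord("A")
        positions = np.linspace(10, L - 12, n_cpg).astype(int)
        for p in positions:
            arr[p] = ord("C")
            arr[p + 1] = ord("G")
            if p + 2 < L and arr[p + 2] == ord("G"):  # avoid creating CGG->CG twice
                pass
        # planting may create a new CpG immediately before a planted C; clean up
        for p in positions:
            if p >= 1 and arr[p - 1] == ord("C"):
                arr[p - 1] = ord("T")
        seq = arr.tobytes().decode()
        cpg_positions = sorted(int(p) for p in positions)
        if i == 0:
            m = rng.uniform(0.4, 0.9, size=n_cpg)
        else:
            m = rng.uniform(0.05, 0.3, size=n_cpg)
        h = rng.uniform(0.0, 0.1, size=n_cpg)
        h = np.minimum(h, 1.0 - m)
        name = f"amp_{config.class_names[i % config.n_classes]}_{i + 1}"
        amplicons.append(
            AmpliconTruth(
                name=name,
                seq=seq,
                cpg_positions=cpg_positions,
                five_mC={p: float(mi) for p, mi in zip(cpg_positions, m)},
                five_hmC={p: float(hi) for p, hi in zip(cpg_positions, h)},
            )
        )
    return amplicons


# ---------------------------------------------------------------------------
# RNA-seq alignment simulation


@dataclass
class SimulatedRead:
    """One simulated read with all equally-best placements.

    ``placements`` are (chrom, start, end, strand) tuples; ``primary_index``
    selects the placement reported as the SAM primary alignment.
    """

    name: str
    seq: str  # in consensus orientation (as sequenced)
    placements: list[tuple[str, int, int, str]]
    primary_index: int
    source_class: str | None  # None for background reads
    source_copy: str | None = None

    @property
    def primary(self) -> tuple[str, int, int, str]:
        return self.placements[self.primary_index]

    @property
    def is_unique(self) -> bool:
        return len(self.placements) == 1


def _nonrepeat_start_positions(
    genome: ToyGenome, read_length: int
) -> tuple[str, np.ndarray]:
    """Valid read start offsets whose window overlaps no repeat copy."""
    chrom = next(iter(genome.sequences))
    glen = len(genome.sequences[chrom])
    mask = np.ones(glen - read_length + 1, dtype=bool)
    for c in genome.truth.copies:
        lo = max(0, c.start - read_length + 1)
        hi = min(mask.size, c.end)
        mask[lo:hi] = False
    return chrom, np.flatnonzero(mask)


def simulate_rnaseq_alignments(
    genome: ToyGenome,
    condition: str,
    config: SimulationConfig,
    sample_index: int = 0,
    library_size: int | None = None,
) -> list[SimulatedRead]:
    """Simulate one sample's RNA-seq alignments.

    Reads are drawn from repeat copies proportional to true class expression
    times copy length (plus a uniform non-repeat background), with a
    per-replicate lognormal wobble on class expression. For each repeat read
    the set of equally-best placements is computed by comparing the read
    against the homologous window of every same-class copy; the primary is
    chosen uniformly at random among the ties.
    """
    if condition not in ("A", "B"):
        raise ValueError(f"condition must be 'A' or 'B', got {condition!r}")
    rng = np.random.default_rng([config.seed, _OFF_RNASEQ, sample_index])
    if library_size is None:
        library_size = next(iter(config.library_sizes.values()))
    truth = genome.truth
    rl = config.read_length

    expr = dict(truth.class_expression[condition])
    if config.replicate_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.replicate_cv**2)))
        for name in expr:
            expr[name] *= float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))

    eligible = [c for c in truth.copies if c.length >= rl]
    weights = np.array([expr[c.class_name] * c.length for c in eligible], float)
    weights = np.append(weights, truth.background_weight)
    if library_size == 0:
        return []
    counts = rng.multinomial(library_size, weights / weights.sum())

    # consensus-frame byte arrays per copy, grouped by class
    by_class: dict[str, list[CopyTruth]] = {}
    for c in eligible:
        by_class.setdefault(c.class_name, []).append(c)
    cons_arr = {
        c.copy_id: np.frombuffer(c.cons_seq.encode(), dtype=np.uint8)
        for c in eligible
    }

    bg_chrom, bg_starts = _nonrepeat_start_positions(genome, rl)
    reads: list[SimulatedRead] = []
    read_no = 0

    def _placement(c: CopyTruth, off: int) -> tuple[str, int, int, str]:
        if c.strand == "+":
            s = c.start + off
        else:
            s = c.end - off - rl
        return (c.chrom, s, s + rl, c.strand)

    for src, n in zip(eligible, counts[:-1]):
        if n == 0:
            continue
        sibs = by_class[src.class_name]
        offsets = rng.integers(0, src.length - rl + 1, size=n)
        for off in offsets:
            off = int(off)
            read_arr = cons_arr[src.copy_id][off : off + rl]
            if config.error_rate > 0:
                read_arr = np.frombuffer(
                    _mutate(rng, read_arr.tobytes().decode(), config.error_rate).encode(),
                    dtype=np.uint8,
                )
            # candidate = same consensus window in every long-enough sibling
            cands = [c for c in sibs if c.length >= off + rl]
            mism = np.array(
                [int((cons_arr[c.copy_id][off : off + rl] != read_arr).sum()) for c in cands]
            )
            best = mism == mism.min()
            best_copies = [c for c, b in zip(cands, best) if b]
            placements = [_placement(c, off) for c in best_copies]
            primary = int(rng.integers(0, len(placements)))
            read_no += 1
            reads.append(
                SimulatedRead(
                    name=f"read_{condition}{sample_index}_{read_no:07d}",
                    seq=read_arr.tobytes().decode(),
                    placements=placements,
                    primary_index=primary,
                    source_class=src.class_name,
                    source_copy=src.copy_id,
                )
            )
    n_bg = int(counts[-1])
    if n_bg > 0:
        starts = rng.choice(bg_starts, size=n_bg)
        for s in starts:
            s = int(s)
            read_no += 1
            reads.append(
                SimulatedRead(
                    name=f"read_{condition}{sample_index}_{read_no:07d}",
                    seq=genome.fetch(bg_chrom, s, s + rl),
                    placements=[(bg_chrom, s, s + rl, "+")],
                    primary_index=0,
                    source_class=None,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# bisulfite read simulation


def simulate_bisulfite_reads(
    amplicon: AmpliconTruth,
    treatment: str,
    n_reads: int,
    config: SimulationConfig,
    replicate: int = 0,
) -> list[tuple[str, str]]:
    """Simulate full-length amplicon reads under BS or oxBS chemistry.

    Per cytosine per read: an unmethylated C converts to T with probability
    ``bs_conversion_efficiency``; 5mC always reads C; 5hmC reads C under BS
    and converts to T under oxBS with probability
    ``oxidation_efficiency * bs_conversion_efficiency``. Cytosines outside
    CpG context are simulated as unmethylated. Returns (read name, sequence)
    pairs.
    """
    if treatment not in ("BS", "oxBS"):
        raise ValueError(f"treatment must be 'BS' or 'oxBS', got {treatment!r}")
    for p in amplicon.cpg_positions:
        if amplicon.five_mC[p] + amplicon.five_hmC[p] > 1.0 + 1e-12:
            raise ValueError(f"5mC + 5hmC > 1 at CpG {p} of {amplicon.name}")
    rng = np.random.default_rng(
        [config.seed, _OFF_BISULFITE, 0 if treatment == "BS" else 1, replicate]
    )
    ref = np.frombuffer(amplicon.seq.encode(), dtype=np.uint8)
    c_pos = np.flatnonzero(ref == ord("C"))
    is_cpg = np.isin(c_pos, amplicon.cpg_positions)
    m = np.array([amplicon.five_mC.get(int(p), 0.0) for p in c_pos])
    h = np.array([amplicon.five_hmC.get(int(p), 0.0) for p in c_pos])
    m[~is_cpg] = 0.0
    h[~is_cpg] = 0.0

    bs_eff = config.bs_conversion_efficiency
    ox_eff = config.oxidation_efficiency
    # state codes: 0 = unmethylated, 1 = 5mC, 2 = 5hmC
    u = rng.random((n_reads, c_pos.size))
    state = np.zeros((n_reads, c_pos.size), dtype=np.int8)
    state[u < m + h] = 2
    state[u < m] = 1
    p_convert = np.array(
        [bs_eff, 0.0, 0.0 if treatment == "BS" else ox_eff * bs_eff]
    )
    to_t = rng.random((n_reads, c_pos.size)) < p_convert[state]

    reads = []
    for i in range(n_reads):
        arr = ref.copy()
        arr[c_pos[to_t[i]]] = ord("T")
        reads.append((f"{amplicon.name}_{treatment}_r{replicate}_{i:06d}", arr.tobytes().decode()))
    return reads


# ---------------------------------------------------------------------------
# peak simulation


def simulate_peaks(
    genome: ToyGenome,
    enriched_classes: Sequence[str],
    n_peaks: int,
    config: SimulationConfig,
) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """Simulate a ChIP-seq-like peak set and the mappable-region BED.

    A fraction ``peak_enrichment_fraction`` of peaks is placed wholly inside
    copies of the enriched classes (chosen with probability proportional to
    the number of valid start offsets); the remainder is uniform over the
    mappable regions, here the whole toy chromosome. Returns
    (peaks, mappable), both as (chrom, start, end) lists.
    """
    if n_peaks < 0:
        raise ValueError(f"n_peaks must be >= 0, got {n_peaks}")
    known = {c.class_name for c in genome.truth.copies}
    unknown = set(enriched_classes) - known
    if unknown:
        raise ValueError(f"enriched classes not in annotation: {sorted(unknown)}")
    rng = np.random.default_rng([config.seed, _OFF_PEAKS])
    L = config.peak_length
    mappable = [
        (chrom, 0, len(seq)) for chrom, seq in genome.sequences.items()
    ]
    hosts = [
        c
        for c in genome.truth.copies
        if c.class_name in enriched_classes and c.length >= L
    ]
    host_w = np.array([c.length - L + 1 for c in hosts], dtype=float)
    peaks: list[tuple[str, int, int]] = []
    frac = config.peak_enrichment_fraction if hosts else 0.0
    for _ in range(n_peaks):
        if hosts and rng.random() < frac:
            c = hosts[int(rng.choice(len(hosts), p=host_w / host_w.sum()))]
            s = int(rng.integers(c.start, c.end - L + 1))
            peaks.append((c.chrom, s, s + L))
        else:
            chrom, _, glen = mappable[int(rng.integers(0, len(mappable)))]
            s = int(rng.integers(0, glen - L + 1))
            peaks.append((chrom, s, s + L))
    return peaks, mappable


# ---------------------------------------------------------------------------
# writers


def write_genome_fasta(genome: ToyGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def write_repeatmasker_out(genome: ToyGenome, path: str | Path) -> None:
    """Write the planted fragments in RepeatMasker ``.out`` format.

    Coordinates are converted to the format's 1-based inclusive convention;
    minus-strand fragments get ``C`` in the strand column.
    """
    chrom_len = {c: len(s) for c, s in genome.sequences.items()}
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        rid = 0
        for copy in genome.truth.copies:
            family = "LTR/ERVK" if copy.class_name.startswith("IAP") else "LTR/ERV"
            rid += 1
            for fs, fe in copy.fragments:
                left = chrom_len[copy.chrom] - fe
                strand = "+" if copy.strand == "+" else "C"
                fh.write(
                    f" 1000  2.0  0.0  0.0  {copy.chrom} {fs + 1:>9} {fe:>9} "
                    f"({left}) {strand} {copy.class_name:<18} {family:<18} "
                    f"1 {fe - fs} (0) {rid}\n"
                )


def write_sam(
    reads: Sequence[SimulatedRead],
    genome: ToyGenome,
    path: str | Path,
) -> None:
    """Write simulated reads as SAM with secondary-alignment flags.

    The randomly chosen placement is the primary record (full SEQ); the
    remaining equally-best placements are flagged secondary with SEQ ``*``.
    Reads placed on the minus strand are stored reverse-complemented, per
    SAM convention.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": chrom, "LN": len(seq)}
            for chrom, seq in genome.sequences.items()
        ],
    }
    with pysam.AlignmentFile(str(path), "wh", header=pysam.AlignmentHeader.from_dict(header)) as out:
        for read in reads:
            order = [read.primary_index] + [
                i for i in range(len(read.placements)) if i != read.primary_index
            ]
            for rank, i in enumerate(order):
                chrom, start, end, strand = read.placements[i]
                a = pysam.AlignedSegment(out.header)
                a.query_name = read.name
                a.flag = (0x10 if strand == "-" else 0) | (0x100 if rank > 0 else 0)
                a.reference_name = chrom
                a.reference_start = start
                a.mapping_quality = 60 if read.is_unique else 0
                a.cigarstring = f"{len(read.seq)}M"
                if rank == 0:
                    seq = read.seq if strand == "+" else _revcomp(read.seq)
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                out.write(a)


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_bed_intervals(
    intervals: Sequence[tuple[str, int, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_amplicon_fasta(amplicons: Sequence[AmpliconTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(f">{a.name}\n{a.seq}\n")


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every simulator stage and write all files; returns output paths.

    Produces: genome FASTA, RepeatMasker ``.out``, one SAM per sample,
    amplicon FASTA plus BS/oxBS FASTQs per replicate, peak and mappable
    BEDs, and TSV ground-truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = build_toy_genome(config)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_genome_fasta(genome, paths["genome"])
    paths["repeatmasker"] = outdir / "repeats.out"
    write_repeatmasker_out(genome, paths["repeatmasker"])

    for i, (sample, libsize) in enumerate(config.library_sizes.items()):
        cond = config.sample_conditions[sample]
        reads = simulate_rnaseq_alignments(
            genome, cond, config, sample_index=i, library_size=libsize
        )
        p = outdir / f"{sample}.sam"
        write_sam(reads, genome, p)
        paths[f"sam:{sample}"] = p

    paths["amplicons"] = outdir / "amplicons.fa"
    write_amplicon_fasta(genome.truth.amplicons, paths["amplicons"])
    for amp in genome.truth.amplicons:
        for treatment in ("BS", "oxBS"):
            for rep in range(config.bs_replicates):
                reads = simulate_bisulfite_reads(
                    amp, treatment, config.bs_reads_per_treatment, config, replicate=rep
                )
                p = outdir / f"{amp.name}_{treatment}_rep{rep + 1}.fastq"
                write_fastq(reads, p)
                paths[f"fastq:{amp.name}:{treatment}:{rep + 1}"] = p

    peaks, mappable = simulate_peaks(
        genome, config.enriched_classes, config.n_peaks, config
    )
    paths["peaks"] = outdir / "peaks.bed"
    write_bed_intervals(peaks, paths["peaks"])
    paths["mappable"] = outdir / "mappable.bed"
    write_bed_intervals(mappable, paths["mappable"])

    _write_truth_tables(genome.truth, config, outdir, paths)
    return paths


def _write_truth_tables(
    truth: GroundTruth, config: SimulationConfig, outdir: Path, paths: dict[str, Path]
) -> None:
    p = outdir / "truth_copies.tsv"
    with open(p, "w") as fh:
        fh.write("copy_id\tchrom\tstart\tend\tstrand\tclass\tlength\tfull_length\n")
        for c in truth.copies:
            fh.write(
                f"{c.copy_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t"
                f"{c.class_name}\t{c.length}\t{c.length > 5000}\n"
            )
    paths["truth_copies"] = p
    p = outdir / "truth_expression.tsv"
    with open(p, "w") as fh:
        fh.write("class\texpr_A\texpr_B\tfold_change\n")
        for name in config.class_names:
            a = truth.class_expression["A"][name]
            b = truth.class_expression["B"][name]
            fh.write(f"{name}\t{a}\t{b}\t{b / a}\n")
    paths["truth_expression"] = p
    p = outdir / "truth_methylation.tsv"
    with open(p, "w") as fh:
        fh.write("amplicon\tposition\tfive_mC\tfive_hmC\n")
        for a in truth.amplicons:
            for pos in a.cpg_positions:
                fh.write(f"{a.name}\t{pos}\t{a.five_mC[pos]}\t{a.five_hmC[pos]}\n")
    paths["truth_methylation"] = p
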