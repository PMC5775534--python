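"""Counting regimes, detection filter, tenfold classification, summaries."""

import numpy as np
import pandas as pd
import pytest

from retrosilence import counting
from retrosilence.counting import (
    ReadAlignment,
    build_class_table,
    classification_percent,
    classify_fold_change,
    copy_key,
    count_by_class_inclusive,
    count_by_copy_unique,
    filter_detectable,
    read_sam_alignments,
    summarize_classification,
)
from retrosilence.repeats import RepeatElement
from retrosilence.simulate import simulate_rnaseq_alignments, write_sam

from conftest import small_config

IAP = RepeatElement("chr1", 1000, 8000, "+", "IAPEz")
L1 = RepeatElement("chr1", 20000, 26000, "-", "L1Md_A")
ELEMENTS = [IAP, L1]


def aln(name, placements, primary=0):
    return ReadAlignment(name, placements, primary)


class TestInclusive:
    def test_no_reads_zero_table(self):
        counts, unassigned = count_by_class_inclusive([], ELEMENTS)
        assert set(counts.values()) == {0} and unassigned == 0

    def test_direct_attribution(self):
        reads = [aln(f"r{i}", [("chr1", 2000 + i, 2050 + i)]) for i in range(3)]
        counts, unassigned = count_by_class_inclusive(reads, ELEMENTS)
        assert counts["IAPEz"] == 3 and unassigned == 0

    def test_half_overlap_rule(self):
        # read 50 bp, 25 bp inside the element: exactly 50% -> attributed
        at_half = aln("r1", [("chr1", 975, 1025)])
        below_half = aln("r2", [("chr1", 974, 1024)])
        counts, unassigned = count_by_class_inclusive([at_half, below_half], ELEMENTS)
        assert counts["IAPEz"] == 1 and unassigned == 1

    def test_unknown_chromosome_rejected(self):
        reads = [aln("r1", [("chrX", 0, 50)])]
        with pytest.raises(ValueError, match="chrX"):
            count_by_class_inclusive(reads, ELEMENTS, chrom_names={"chr1"})

    def test_multimapper_counts_once_via_primary(self):
        r = aln("r1", [("chr1", 2000, 2050), ("chr1", 21000, 21050)], primary=1)
        counts, _ = count_by_class_inclusive([r], ELEMENTS)
        assert counts == {"IAPEz": 0, "L1Md_A": 1}

    def test_ground_truth_bookkeeping_oracle(self, sim_config, toy_genome, tmp_path):
        """Inclusive class counts equal the simulator's per-read source tally,
        and assigned + unassigned equals the library size exactly."""
        reads = simulate_rnaseq_alignments(toy_genome, "B", sim_config, 2, 6000)
        sam = tmp_path / "s.sam"
        write_sam(reads, toy_genome, sam)
        alignments = read_sam_alignments(sam)
        elements = [c.as_element() for c in toy_genome.truth.copies]
        counts, unassigned = count_by_class_inclusive(alignments, elements)
        expected = {}
        for r in reads:
            if r.source_class is not None:
                expected[r.source_class] = expected.get(r.source_class, 0) + 1
        for name in {c.class_name for c in toy_genome.truth.copies}:
            assert counts.get(name, 0) == expected.get(name, 0)
        assert sum(counts.values()) + unassigned == 6000


class TestUnique:
    def test_multimapped_contribute_nothing(self):
        r = aln("r1", [("chr1", 2000, 2050), ("chr1", 21000, 21050)])
        counts = count_by_copy_unique([r], ELEMENTS)
        assert set(counts.values()) == {0}

    def test_single_unique_read(self):
        r = aln("r1", [("chr1", 2000, 2050)])
        counts = count_by_copy_unique([r], ELEMENTS)
        assert counts[copy_key(IAP)] == 1 and counts[copy_key(L1)] == 0

    def test_matches_brute_force_oracle(self, sim_config, toy_genome, tmp_path):
        reads = simulate_rnaseq_alignments(toy_genome, "A", sim_config, 3, 4000)
        sam = tmp_path / "s.sam"
        write_sam(reads, toy_genome, sam)
        alignments = read_sam_alignments(sam)
        elements = [c.as_element() for c in toy_genome.truth.copies]
        got = count_by_copy_unique(alignments, elements)
        # brute force: single-placement reads, best >= 50% overlap
        expected = {copy_key(e): 0 for e in elements}
        for a in alignments:
            if len(a.placements) != 1:
                continue
            chrom, s, e = a.placements[0]
            best, best_score = None, None
            for el in elements:
                if el.chrom != chrom:
                    continue
                ovl = min(e, el.end) - max(s, el.start)
                if ovl * 2 < (e - s):
                    continue
                score = (el.length, el.repeat_name)
                if best is None or score[0] > best_score[0] or (
                    score[0] == best_score[0] and score[1] < best_score[1]
                ):
                    best, best_score = el, score
            if best is not None:
                expected[copy_key(best)] += 1
        assert got == expected

    def test_unique_le_inclusive_per_feature(self, sim_config, toy_genome, tmp_path):
        reads = simulate_rnaseq_alignments(toy_genome, "B", sim_config, 4, 4000)
        sam = tmp_path / "s.sam"
        write_sam(reads, toy_genome, sam)
        alignments = read_sam_alignments(sam)
        elements = [c.as_element() for c in toy_genome.truth.copies]
        inclusive, _ = count_by_class_inclusive(alignments, elements)
        unique = count_by_copy_unique(alignments, elements)
        per_class_unique = {}
        for e in elements:
            per_class_unique[e.repeat_name] = (
                per_class_unique.get(e.repeat_name, 0) + unique[copy_key(e)]
            )
        for name, n_unique in per_class_unique.items():
            assert n_unique <= inclusive[name]


class TestRpmAndFilters:
    def test_rpm_scale_sums_to_million(self):
        per_sample = {
            "s1": ({"IAPEz": 40, "L1Md_A": 30}, 30),
            "s2": ({"IAPEz": 10, "L1Md_A": 0}, 90),
        }
        table = build_class_table(per_sample, {"s1": 100, "s2": 100})
        total = table.rpm().sum(axis=0) + table.unassigned * 1e6 / table.library_sizes
        assert np.allclose(total, 1e6)

    @pytest.mark.parametrize(
        "row,kept",
        [((0.3, 0.0), True), ((0.25, 0.25), False), ((0.0, 0.0), False)],
    )
    def test_detection_threshold_strict(self, row, kept):
        rpm = pd.DataFrame([row], index=["c1"], columns=["s1", "s2"])
        assert ("c1" in filter_detectable(rpm).index) is kept

    def test_fold_classification_arithmetic(self):
        ctrl = pd.Series({"c1": 0.5, "c2": 1.0})
        depl = pd.Series({"c1": 6.0, "c2": 1.0})
        calls = classify_fold_change(ctrl, depl, fold=10, pseudocount=0.1)
        assert bool(calls["c1"]) is True  # 6.1 / 0.6 = 10.17 > 10
        assert bool(calls["c2"]) is False  # ratio 1

    def test_negative_rpm_rejected(self):
        with pytest.raises(ValueError):
            classify_fold_change(pd.Series([-1.0]), pd.Series([1.0]))


class TestSummary:
    @pytest.mark.parametrize(
        "n,up,pct", [(1009, 681, 67), (1009, 257, 25), (5, 0, 0)]
    )
    def test_percentages(self, n, up, pct):
        assert classification_percent(n, up) == pct

    def test_empty_is_undefined_not_zero(self):
        summary = summarize_classification(pd.Series([], dtype=bool))
        assert summary["percent_upregulated"] is None

    def test_counts_from_calls(self):
        calls = pd.Series([True, True, False, True])
        s = summarize_classification(calls)
        assert (s["n_detectable"], s["n_upregulated"]) == (4, 3)
        assert s["percent_upregulated"] == 75


class TestFoldRecovery:
    def test_planted_tenfold_class_copies_called(self):
        """With deep noise-free libraries, every detectable copy of the
        activated class is classified upregulated and no other copy is."""
        cfg = small_config(
            n_classes=4,
            replicate_cv=0.0,
            background_fraction=0.95,
            inter_copy_divergence=0.05,
            class_fold_changes={"IAPEz": 15.0},
            library_sizes={
                s: 100_000
                for s in ("control_1", "control_2", "depleted_1", "depleted_2")
            },
            sample_conditions={
                "control_1": "A", "control_2": "A",
                "depleted_1": "B", "depleted_2": "B",
            },
        )
        from retrosilence.simulate import build_toy_genome

        genome = build_toy_genome(cfg)
        elements = [c.as_element() for c in genome.truth.copies]
        per_sample = {}
        libs = {}
        for i, (sample, n) in enumerate(cfg.library_sizes.items()):
            cond = cfg.sample_conditions[sample]
            reads = simulate_rnaseq_alignments(genome, cond, cfg, i, n)
            alns = [
                ReadAlignment(r.name, [p[:3] for p in r.placements], r.primary_index)
                for r in reads
            ]
            per_sample[sample] = count_by_copy_unique(alns, elements)
            libs[sample] = n
        table = counting.build_copy_table(per_sample, libs, elements)
        rpm = filter_detectable(table.rpm())
        ctrl = [s for s in libs if cfg.sample_conditions[s] == "A"]
        depl = [s for s in libs if cfg.sample_conditions[s] == "B"]
        calls = classify_fold_change(rpm[ctrl], rpm[depl])
        iap_calls = calls[calls.index.str.startswith("IAPEz@")]
        other_calls = calls[~calls.index.str.startswith("IAPEz@")]
        assert iap_calls.mean() >= 0.9
        assert other_calls.sum() == 0
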