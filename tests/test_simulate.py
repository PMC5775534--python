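"""Simulator contracts: determinism, conservation, multi-mapping, chemistry."""

import numpy as np
import pytest

from retrosilence.simulate import (
    AmpliconTruth,
    SimulationConfig,
    SizingError,
    build_toy_genome,
    simulate_bisulfite_reads,
    simulate_peaks,
    simulate_rnaseq_alignments,
    write_fastq,
    write_genome_fasta,
    write_sam,
)

from conftest import small_config


class TestToyGenome:
    def test_planted_fragment_bookkeeping(self):
        cfg = small_config(n_classes=2, copies_per_class=3)
        genome = build_toy_genome(cfg)
        copies = genome.truth.copies
        assert len(copies) == 6
        assert len({c.class_name for c in copies}) == 2
        chrom_len = len(genome.sequences[cfg.chromosome_name])
        for c in copies:
            assert 0 <= c.start < c.end <= chrom_len

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        paths = []
        for i in (1, 2):
            cfg = small_config()
            p = tmp_path / f"g{i}.fa"
            write_genome_fasta(build_toy_genome(cfg), p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_zero_divergence_identical_copies(self):
        cfg = small_config(inter_copy_divergence=0.0)
        genome = build_toy_genome(cfg)
        for name in cfg.class_names:
            seqs = [c.cons_seq for c in genome.truth.copies_of(name)]
            shortest = min(len(s) for s in seqs)
            # truncated copies are 5' prefixes of the longest
            assert len({s[:shortest] for s in seqs}) == 1

    def test_both_truncated_and_full_length_planted(self, toy_genome):
        lengths = [c.length for c in toy_genome.truth.copies]
        assert any(L > 5000 for L in lengths) and any(L <= 5000 for L in lengths)

    def test_copy_larger_than_chromosome_rejected(self):
        cfg = small_config(chromosome_length=3000)
        with pytest.raises(SizingError):
            build_toy_genome(cfg)

    def test_length_range_must_span_5kb(self):
        with pytest.raises(ValueError, match="5000"):
            small_config(copy_length_range=(100, 2000))


class TestRnaseqSimulation:
    def test_read_count_equals_library_size(self, sim_config, toy_genome):
        reads = simulate_rnaseq_alignments(toy_genome, "A", sim_config, 0, 5000)
        assert len(reads) == 5000

    def test_unknown_condition_rejected(self, sim_config, toy_genome):
        with pytest.raises(ValueError, match="condition"):
            simulate_rnaseq_alignments(toy_genome, "Z", sim_config, 0, 10)

    def test_zero_library_empty_sam_with_header(self, sim_config, toy_genome, tmp_path):
        reads = simulate_rnaseq_alignments(toy_genome, "A", sim_config, 0, 0)
        assert reads == []
        p = tmp_path / "empty.sam"
        write_sam(reads, toy_genome, p)
        text = p.read_text()
        assert "@SQ" in text and "\tchr1\t" not in text.replace("SN:chr1", "")

    def test_identical_copies_multimap_everywhere(self):
        cfg = small_config(
            n_classes=1, copies_per_class=2, inter_copy_divergence=0.0,
            replicate_cv=0.0, background_fraction=0.0,
        )
        genome = build_toy_genome(cfg)
        short_len = min(c.length for c in genome.truth.copies)
        reads = simulate_rnaseq_alignments(genome, "A", cfg, 0, 2000)
        checked = 0
        for r in reads:
            # reads from the shortest copy fit inside both copies, which are
            # identical at zero divergence, so both placements tie
            src = next(c for c in genome.truth.copies if c.copy_id == r.source_copy)
            if src.length == short_len:
                assert len(r.placements) == 2
                checked += 1
        assert checked > 0

    def test_primary_placement_flagged_once(self, sim_config, toy_genome, tmp_path):
        import pysam

        reads = simulate_rnaseq_alignments(toy_genome, "B", sim_config, 1, 2000)
        p = tmp_path / "s.sam"
        write_sam(reads, toy_genome, p)
        primaries = {}
        with pysam.AlignmentFile(str(p), "r") as sam:
            for rec in sam:
                if not rec.is_secondary:
                    primaries[rec.query_name] = primaries.get(rec.query_name, 0) + 1
        assert set(primaries.values()) == {1}
        assert len(primaries) == 2000

    def test_fold_change_recovered_within_3se(self):
        """Realized depleted/control read-count ratio matches the planted
        activation after accounting for the compositional squeeze."""
        fold = 15.0
        cfg = small_config(
            n_classes=2,
            copies_per_class=3,
            replicate_cv=0.0,
            class_fold_changes={"IAPEz": fold},
            background_fraction=0.9,
        )
        genome = build_toy_genome(cfg)
        n = 60_000
        reads_a = simulate_rnaseq_alignments(genome, "A", cfg, 0, n)
        reads_b = simulate_rnaseq_alignments(genome, "B", cfg, 1, n)
        count_a = sum(r.source_class == "IAPEz" for r in reads_a)
        count_b = sum(r.source_class == "IAPEz" for r in reads_b)
        # expected read shares from the known sampling weights
        truth = genome.truth
        w = {
            cond: sum(
                truth.class_expression[cond][c.class_name] * c.length
                for c in truth.copies
                if c.length >= cfg.read_length
            )
            + truth.background_weight
            for cond in ("A", "B")
        }
        share = {
            cond: sum(
                truth.class_expression[cond]["IAPEz"] * c.length
                for c in truth.copies_of("IAPEz")
                if c.length >= cfg.read_length
            )
            / w[cond]
            for cond in ("A", "B")
        }
        for count, cond in ((count_a, "A"), (count_b, "B")):
            se = np.sqrt(n * share[cond] * (1 - share[cond]))
            assert abs(count - n * share[cond]) < 3 * se


class TestBisulfiteChemistry:
    @staticmethod
    def amplicon(m, h):
        seq = "ATTGACGATTCAGGACGTTAGGA"  # CpGs at 5 and 15, non-CpG C at 10
        positions = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
        return AmpliconTruth(
            name="amp",
            seq=seq,
            cpg_positions=positions,
            five_mC={p: m for p in positions},
            five_hmC={p: h for p in positions},
        )

    def test_fully_methylated_always_c(self):
        cfg = small_config(bs_conversion_efficiency=1.0, oxidation_efficiency=1.0)
        amp = self.amplicon(1.0, 0.0)
        for treatment in ("BS", "oxBS"):
            reads = simulate_bisulfite_reads(amp, treatment, 200, cfg)
            for _, seq in reads:
                for p in amp.cpg_positions:
                    assert seq[p] == "C"

    def test_pure_hydroxymethyl_c_in_bs_t_in_oxbs(self):
        cfg = small_config(bs_conversion_efficiency=1.0, oxidation_efficiency=1.0)
        amp = self.amplicon(0.0, 1.0)
        for _, seq in simulate_bisulfite_reads(amp, "BS", 100, cfg):
            assert all(seq[p] == "C" for p in amp.cpg_positions)
        for _, seq in simulate_bisulfite_reads(amp, "oxBS", 100, cfg):
            assert all(seq[p] == "T" for p in amp.cpg_positions)

    def test_binomial_recovery_and_hmc_difference(self):
        """BS C-fraction ~ 5mC+5hmC, oxBS C-fraction ~ 5mC, difference ~ 5hmC."""
        cfg = small_config(bs_conversion_efficiency=1.0, oxidation_efficiency=1.0)
        m, h, n = 0.7, 0.1, 10_000
        amp = self.amplicon(m, h)
        fractions = {}
        for treatment, expected in (("BS", m + h), ("oxBS", m)):
            reads = simulate_bisulfite_reads(amp, treatment, n, cfg)
            p0 = amp.cpg_positions[0]
            frac = sum(seq[p0] == "C" for _, seq in reads) / n
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(frac - expected) < 3 * se
            fractions[treatment] = frac
        se_diff = np.sqrt((m + h) * (1 - m - h) / n + m * (1 - m) / n)
        assert abs((fractions["BS"] - fractions["oxBS"]) - h) < 3 * se_diff

    def test_non_cpg_cytosines_convert(self):
        cfg = small_config(bs_conversion_efficiency=1.0)
        amp = self.amplicon(1.0, 0.0)
        non_cpg_c = [
            i
            for i, b in enumerate(amp.seq)
            if b == "C" and i not in amp.cpg_positions
        ]
        assert non_cpg_c
        for _, seq in simulate_bisulfite_reads(amp, "BS", 50, cfg):
            assert all(seq[i] == "T" for i in non_cpg_c)

    def test_invalid_truth_rejected(self):
        cfg = small_config()
        amp = self.amplicon(0.6, 0.3)
        amp.five_hmC[amp.cpg_positions[0]] = 0.7  # now 5mC + 5hmC > 1
        with pytest.raises(ValueError, match="> 1"):
            simulate_bisulfite_reads(amp, "BS", 10, cfg)

    def test_determinism(self, tmp_path):
        cfg = small_config()
        amp = self.amplicon(0.5, 0.1)
        blobs = []
        for i in (1, 2):
            p = tmp_path / f"r{i}.fastq"
            write_fastq(simulate_bisulfite_reads(amp, "BS", 100, cfg), p)
            blobs.append(p.read_bytes())
        assert blobs[0] == blobs[1]


class TestPeakSimulation:
    def test_no_enrichment_uniform(self, sim_config, toy_genome):
        peaks, mappable = simulate_peaks(toy_genome, [], 200, sim_config)
        assert len(peaks) == 200
        (chrom, start, end) = mappable[0]
        assert all(s >= start and e <= end for _, s, e in peaks)

    def test_full_enrichment_all_inside_class(self, toy_genome):
        cfg = small_config(peak_enrichment_fraction=1.0, peak_length=200)
        peaks, _ = simulate_peaks(toy_genome, ["IAPEz"], 100, cfg)
        copies = toy_genome.truth.copies_of("IAPEz")
        for chrom, s, e in peaks:
            assert any(c.start <= s and e <= c.end for c in copies)

    def test_negative_count_rejected(self, sim_config, toy_genome):
        with pytest.raises(ValueError):
            simulate_peaks(toy_genome, [], -1, sim_config)

    def test_unknown_class_rejected(self, sim_config, toy_genome):
        with pytest.raises(ValueError, match="not in annotation"):
            simulate_peaks(toy_genome, ["NOPE"], 10, sim_config)

    def test_determinism(self, sim_config, toy_genome):
        p1, _ = simulate_peaks(toy_genome, ["IAPEz"], 50, sim_config)
        p2, _ = simulate_peaks(toy_genome, ["IAPEz"], 50, sim_config)
        assert p1 == p2
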