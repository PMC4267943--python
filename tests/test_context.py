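import numpy as np
import pytest

from nqospec import (
    GenomeSequence,
    SubstitutionClass,
    VariantRecord,
    build_context_matrix,
    classify_calls,
    extract_context,
)
from nqospec.context import (
    ContextWindow,
    context_bias_report,
    information_content,
    reverse_complement,
)


def _genome(seq, name="chrI"):
    return GenomeSequence(chrom_names=[name], sequences={name: seq})


def _call(genome, pos, ref, alt, strain="s"):
    return classify_calls([VariantRecord("chrI", pos, ref, alt, strain)])[0]


class TestExtractContext:
    SEQ = "AAAAAAAAAAGTTTTTTTTTT"  # G at 1-based position 11

    def test_purine_reference_window(self):
        g = _genome(self.SEQ)
        w = extract_context(g, _call(g, 11, "G", "A"))
        assert w.sequence == self.SEQ
        assert w.center == "G" and not w.padded

    def test_pyrimidine_reference_reverse_complemented(self):
        seq = "AAAAAAAAAACTTTTTTTTTT"  # C at position 11
        g = _genome(seq)
        w = extract_context(g, _call(g, 11, "C", "T"))
        assert w.sequence == reverse_complement(seq)
        assert w.center == "G"

    def test_contig_edge_padded_with_n(self):
        g = _genome("GGGAGGGGGGGGGGGGGGGG")
        w = extract_context(g, _call(g, 3, "G", "A"))
        assert w.padded
        assert w.sequence.startswith("NNNNNNNN")
        assert w.center == "G"
        assert len(w.sequence) == 21

    def test_missing_chromosome_rejected(self):
        g = _genome(self.SEQ)
        call = classify_calls([VariantRecord("chrX", 11, "G", "A", "s")])[0]
        with pytest.raises(KeyError):
            extract_context(g, call)


class TestBuildContextMatrix:
    def test_identical_windows_full_information(self):
        w = ContextWindow("ACGTA", SubstitutionClass.G_TO_A, False)
        m = build_context_matrix([w] * 40)
        assert m.info_content == pytest.approx(np.full(5, 2.0))
        assert m.counts.sum() == 5 * 40

    def test_center_always_the_purine(self, small_cohort):
        _, genome, _, per_strain, _, _ = small_cohort
        calls = classify_calls([r for rs in per_strain.values() for r in rs])
        snv = [c for c in calls if c.klass.is_snv][:400]
        mats = build_context_matrix(
            [extract_context(genome, c) for c in snv], by_class=True
        )
        for klass, m in mats.items():
            center = m.counts[m.flank]
            idx = "ACGT".index(klass.source_purine)
            assert center[idx] == m.n_windows
            assert m.info_content[m.flank] == pytest.approx(2.0)

    def test_n_bases_skipped(self):
        w = ContextWindow("NCGTN", SubstitutionClass.G_TO_A, True)
        m = build_context_matrix([w, ContextWindow("ACGTA", w.klass, False)])
        assert m.counts[0].sum() == 1  # one window contributed an N here
        assert m.counts[2].sum() == 2

    def test_iid_background_flanks_carry_no_information(self):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        windows = [
            ContextWindow(
                "".join(rng.choice(bases, 10)) + "G" + "".join(rng.choice(bases, 10)),
                SubstitutionClass.G_TO_A,
                False,
            )
            for _ in range(5000)
        ]
        m = build_context_matrix(windows)
        assert (m.flanking_info() < 0.01).all()

    def test_mixed_flanks_rejected(self):
        a = ContextWindow("ACGTA", SubstitutionClass.G_TO_A, False)
        b = ContextWindow("ACG", SubstitutionClass.G_TO_A, False)
        with pytest.raises(ValueError):
            build_context_matrix([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_context_matrix([])


class TestInformationContent:
    def test_ordering_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(21, 4))
        perm = rng.permutation(21)
        assert information_content(counts)[perm] == pytest.approx(
            information_content(counts[perm])
        )

    def test_pooling_cannot_increase_information(self):
        # entropy is concave: the pooled (marginal-expected) profile is at
        # most as informative as the average per-position profile
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 50, size=(10, 4)).astype(float)
        per_pos = information_content(counts)
        pooled = information_content(counts.sum(axis=0, keepdims=True))
        assert pooled[0] <= per_pos.mean() + 1e-12


class TestReverseComplementSymmetry:
    def test_matrices_identical_on_reverse_complement_genome(self, small_cohort):
        _, genome, _, per_strain, _, _ = small_cohort
        records = [r for rs in per_strain.values() for r in rs if len(r.ref) == 1 and len(r.alt) == 1][:300]
        calls = classify_calls(records)
        m_fwd = build_context_matrix([extract_context(genome, c) for c in calls])

        rc_genome = GenomeSequence(
            chrom_names=genome.chrom_names,
            sequences={
                c: reverse_complement(s) for c, s in genome.sequences.items()
            },
        )
        comp = str.maketrans("ACGT", "TGCA")
        rc_records = [
            VariantRecord(
                r.chrom,
                len(genome.sequences[r.chrom]) - r.pos + 1,
                r.ref.translate(comp),
                r.alt.translate(comp),
                r.strain,
            )
            for r in records
        ]
        m_rev = build_context_matrix(
            [extract_context(rc_genome, c) for c in classify_calls(rc_records)]
        )
        np.testing.assert_array_equal(m_fwd.counts, m_rev.counts)


class TestContextBiasReport:
    def test_single_window_insufficient(self):
        w = ContextWindow("A" * 10 + "G" + "A" * 10, SubstitutionClass.G_TO_A, False)
        report = context_bias_report({SubstitutionClass.G_TO_A: build_context_matrix([w])})
        assert report[SubstitutionClass.G_TO_A].verdict == "insufficient data"

    def test_null_windows_report_no_bias(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        mats = {}
        for klass in (SubstitutionClass.G_TO_A, SubstitutionClass.A_TO_G):
            center = klass.source_purine
            windows = [
                ContextWindow(
                    "".join(rng.choice(bases, 10))
                    + center
                    + "".join(rng.choice(bases, 10)),
                    klass,
                    False,
                )
                for _ in range(800)
            ]
            mats[klass] = build_context_matrix(windows)
        report = context_bias_report(mats, seed=0)
        assert all(v.verdict == "no bias" for v in report.values())

    def test_planted_motif_detected_at_adjacent_offsets(self, small_cohort):
        from nqospec import SimConfig, simulate_mutagenesis

        _, genome, _, _, _, _ = small_cohort
        config = SimConfig(
            seed=13,
            total_length=2_000_000,
            n_strains=8,
            context_motif=(SubstitutionClass.G_TO_A, "TGT"),
        )
        per_strain, _, _ = simulate_mutagenesis(genome, config)
        calls = classify_calls([r for rs in per_strain.values() for r in rs])
        snv = [c for c in calls if c.klass.is_snv]
        mats = build_context_matrix(
            [extract_context(genome, c) for c in snv], by_class=True
        )
        report = context_bias_report(mats, seed=0)
        verdict = report[SubstitutionClass.G_TO_A]
        assert verdict.verdict == "bias"
        assert set(verdict.biased_offsets) == {-1, 1}
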