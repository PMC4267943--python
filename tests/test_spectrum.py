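import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nqospec import (
    SNV_CLASSES,
    StrainTable,
    SubstitutionClass,
    VariantRecord,
    classify_calls,
    classify_substitution,
    compare_spectra,
    flag_hypermutators,
    purine_ratio,
    region_classify,
    summarize_spectrum,
    transition_bias_test,
)
from nqospec.io_formats import AnnotationSet

COMP = str.maketrans("ACGT", "TGCA")


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "ref,alt,klass,flipped",
        [
            ("G", "A", SubstitutionClass.G_TO_A, False),
            ("C", "T", SubstitutionClass.G_TO_A, True),
            ("T", "G", SubstitutionClass.A_TO_C, True),
            ("A", "T", SubstitutionClass.A_TO_T, False),
            ("T", "A", SubstitutionClass.A_TO_T, True),
            ("C", "G", SubstitutionClass.G_TO_C, True),
        ],
    )
    def test_purine_normalization(self, ref, alt, klass, flipped):
        assert classify_substitution(ref, alt) == (klass, flipped)

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("G", "G")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("N", "A")

    @settings(deadline=None, derandomize=True)
    @given(
        ref=st.sampled_from("ACGT"),
        alt=st.sampled_from("ACGT"),
    )
    def test_strand_symmetry(self, ref, alt):
        """Complementing both alleles preserves the class, flips the flag."""
        if ref == alt:
            return
        k1, f1 = classify_substitution(ref, alt)
        k2, f2 = classify_substitution(ref.translate(COMP), alt.translate(COMP))
        assert k1 == k2
        assert f1 != f2
        assert k1.source_purine in "GA"
        assert k1.is_transition == (k1 in (SubstitutionClass.G_TO_A, SubstitutionClass.A_TO_G))


def _snv(pos, ref, alt, strain="s"):
    return VariantRecord("chrI", pos, ref, alt, strain)


class TestSummarizeSpectrum:
    def test_one_of_each_class(self):
        records = [
            _snv(1, "G", "A"),
            _snv(2, "G", "T"),
            _snv(3, "G", "C"),
            _snv(4, "A", "G"),
            _snv(5, "A", "C"),
            _snv(6, "A", "T"),
        ]
        s = summarize_spectrum(classify_calls(records))
        assert s.total_snv == 6
        assert all(s.frequencies[k] == pytest.approx(1 / 6) for k in SNV_CLASSES)
        assert s.transitions_G == s.transversions_A / 2 == 1
        assert s.guanine_total == s.adenine_total == 3

    def test_indels_counted_separately(self):
        records = [_snv(i, "G", "A") for i in range(1, 10)]
        records.append(VariantRecord("chrI", 50, "GA", "G", "s"))
        s = summarize_spectrum(classify_calls(records))
        assert s.total_snv == 9
        assert s.counts[SubstitutionClass.DELETION] == 1
        assert s.indel_total == 1

    def test_counts_and_frequencies_consistent(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        records = []
        for i in range(500):
            ref, alt = rng.choice(list(bases), size=2, replace=False)
            records.append(_snv(i + 1, ref, alt))
        s = summarize_spectrum(classify_calls(records))
        assert sum(s.counts[k] for k in SNV_CLASSES) == s.total_snv == 500
        assert s.guanine_total + s.adenine_total == s.total_snv
        assert sum(s.frequencies.values()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_spectrum([])


class TestTransitionBiasTest:
    def test_even_split_is_null(self):
        r = transition_bias_test(50, 50)
        assert r.statistic == 0 and r.p_value == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        assert (
            transition_bias_test(30, 70).statistic
            == transition_bias_test(70, 30).statistic
        )

    def test_df_is_one_no_continuity_correction(self):
        # hand computation: (60-50)^2/50 * 2 = 4
        r = transition_bias_test(60, 40)
        assert r.statistic == pytest.approx(4.0)
        assert r.df == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            transition_bias_test(0, 0)


class TestPurineRatio:
    def _summary(self, g, a):
        records = [_snv(i + 1, "G", "A") for i in range(g)]
        records += [_snv(g + i + 1, "A", "G") for i in range(a)]
        return summarize_spectrum(classify_calls(records))

    def test_equal_totals(self):
        ratio, label = purine_ratio(self._summary(100, 100))
        assert ratio == 1.0 and label == "1:1"

    def test_no_guanine(self):
        ratio, _ = purine_ratio(self._summary(0, 10))
        assert ratio == 0.0

    def test_no_adenine_is_infinite(self):
        ratio, _ = purine_ratio(self._summary(10, 0))
        assert ratio == float("inf")


def _table(loads, kills=None):
    n = len(loads)
    return StrainTable(
        pd.DataFrame(
            {
                "strain": [f"s{i}" for i in range(n)],
                "dose": ["d"] * n,
                "kill": kills or [0.5] * n,
                "n_mutations": loads,
            }
        )
    )


class TestFlagHypermutators:
    def test_iqr_rule_flags_outlier(self):
        # Q1=103, Q3=110, fence = 110 + 1.5*7 = 120.5 -> only 980 flagged
        table = flag_hypermutators(_table([100, 105, 110, 103, 980]))
        assert list(table.frame["excluded"]) == [False, False, False, False, True]

    def test_equal_loads_unflagged(self):
        table = flag_hypermutators(_table([105] * 6))
        assert not table.frame["excluded"].any()

    def test_too_few_strains_warns(self):
        with pytest.warns(UserWarning):
            table = flag_hypermutators(_table([1, 2, 1000]))
        assert not table.frame["excluded"].any()

    def test_repair_gene_corroboration_required(self):
        loads = [100, 105, 110, 103, 102, 107, 99, 104, 980, 990]
        hits = {"s8": ["mutS-like"]}  # the 990-load strain has no repair hit
        plain = flag_hypermutators(_table(loads))
        assert list(plain.frame["excluded"]) == [False] * 8 + [True, True]
        table = flag_hypermutators(_table(loads), repair_gene_hits=hits)
        assert list(table.frame["excluded"]) == [False] * 8 + [True, False]


class TestCompareSpectra:
    def test_proportional_counts_give_zero(self):
        freqs = [0.5, 0.2, 0.1, 0.1, 0.05, 0.05]
        obs = [int(1000 * f) for f in freqs]
        r = compare_spectra(obs, freqs)
        assert r.statistic == pytest.approx(0.0)
        assert r.df == 5

    def test_concentrated_counts_vs_uniform(self):
        # exp = 10/6 each; chi2 = (10 - 10/6)^2/(10/6) + 5*(10/6) = 50
        r = compare_spectra([10, 0, 0, 0, 0, 0], [1 / 6] * 6)
        assert r.statistic == pytest.approx(50.0)

    def test_reference_renormalized(self):
        a = compare_spectra([5, 10, 15, 20, 25, 30], [1, 2, 3, 4, 5, 6])
        b = compare_spectra([5, 10, 15, 20, 25, 30], [x / 21 for x in range(1, 7)])
        assert a.statistic == pytest.approx(b.statistic)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            compare_spectra([1, 1, 1, 1, 1, 1], [0.5, 0.5, 0, 0, 0, 0])


class TestRegionClassify:
    def _annot(self):
        return AnnotationSet(
            transcribed={"chrI": [(99, 200)]}, chrom_lengths={"chrI": 1000}
        )

    def test_point_in_interval(self):
        calls = classify_calls([_snv(150, "G", "A")])
        counts, labels = region_classify(calls, self._annot())
        assert counts == {"transcribed": 1, "intergenic": 0}
        assert labels == ["transcribed"]

    def test_interval_start_is_transcribed(self):
        calls = classify_calls([_snv(100, "G", "A")])
        counts, _ = region_classify(calls, self._annot())
        assert counts["transcribed"] == 1

    def test_unannotated_chromosome_warns_intergenic(self):
        calls = classify_calls([VariantRecord("chrX", 5, "G", "A", "s")])
        with pytest.warns(UserWarning, match="chrX"):
            counts, _ = region_classify(calls, self._annot())
        assert counts["intergenic"] == 1

    def test_uniform_mutations_match_coverage(self):
        # 60% transcribed coverage; 1000 uniform positions
        annot = AnnotationSet(
            transcribed={"chrI": [(0, 600)]}, chrom_lengths={"chrI": 1000}
        )
        rng = np.random.default_rng(42)
        positions = rng.integers(1, 1001, size=1000)
        calls = classify_calls(
            [VariantRecord("chrI", int(p), "G", "A", "s") for p in positions]
        )
        counts, _ = region_classify(calls, annot)
        # binomial 99% CI around 600 at n=1000
        half = 2.576 * np.sqrt(1000 * 0.6 * 0.4)
        assert abs(counts["transcribed"] - 600) < half
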