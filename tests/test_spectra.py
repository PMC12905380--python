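"""Channel conventions, spectra, strand bias and per-category group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutpanel.channels import (
    BASES,
    CHANNEL_LABELS,
    SUBSTITUTION_TYPES,
    channel_of,
    parse_channel_label,
    revcomp,
    sixfold_index,
)
from mutpanel.spectra import (
    AMBIGUOUS,
    INTERGENIC,
    TRANSCRIBED,
    UNTRANSCRIBED,
    GeneInterval,
    annotate_strand,
    build_spectrum,
    channelize,
    group_count_tests,
    sixfold_from_spectrum,
    strand_bias,
    triplet_channel,
)

base = st.sampled_from("ACGT")


class TestChannels:
    def test_96_unique_labels(self):
        assert len(CHANNEL_LABELS) == 96
        assert len(set(CHANNEL_LABELS)) == 96

    def test_purine_reference_is_reverse_complemented(self):
        # TGT with G>A maps to A[C>T]A after pyrimidine normalization
        assert CHANNEL_LABELS[channel_of("TGT", "A")] == "A[C>T]A"

    def test_label_parsing_both_styles(self):
        for i, label in enumerate(CHANNEL_LABELS):
            assert parse_channel_label(label) == i
        assert parse_channel_label("ACA>AAA") == parse_channel_label("A[C>A]A")

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            parse_channel_label("A[C>C]A")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(f5=base, ref=base, alt=base, f3=base)
    def test_strand_involution_property(self, f5, ref, alt, f3):
        if ref == alt:
            return
        triplet = f5 + ref + f3
        assert channel_of(triplet, alt) == channel_of(revcomp(triplet), revcomp(alt))

    def test_sixfold_partition(self):
        for i in range(96):
            change = SUBSTITUTION_TYPES[sixfold_index(i)]
            assert CHANNEL_LABELS[i][2:5] == change


class TestTripletChannel:
    REF = {"chr1": "ATGTA"}

    def test_purine_site_normalized(self):
        context, channel = triplet_channel(self.REF, "chr1", 3, "G", "A")
        assert context == "ACA"
        assert CHANNEL_LABELS[channel] == "A[C>T]A"

    def test_contig_edge_returns_none(self):
        assert triplet_channel(self.REF, "chr1", 1, "A", "C") is None
        assert triplet_channel(self.REF, "chr1", 5, "A", "C") is None

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            triplet_channel(self.REF, "chr1", 3, "C", "A")


class TestSpectrum:
    def test_channelize_skips_edges_and_indels(self):
        calls = [
            ("chr1", 3, "G", "A"),
            ("chr1", 1, "A", "C"),  # off-edge: skipped and counted
            ("chr1", 3, "G", "INS"),  # indel: silently excluded
        ]
        records, skipped = channelize(calls, self.reference())
        assert len(records) == 1 and skipped == 1

    def test_spectrum_conserves_counts(self):
        rng = np.random.default_rng(0)
        ref = {"chr1": "".join(rng.choice(list(BASES), 500))}
        calls = []
        for pos in range(2, 400):
            r = ref["chr1"][pos - 1]
            alt = next(b for b in BASES if b != r)
            calls.append(("chr1", pos, r, alt))
        records, skipped = channelize(calls, ref)
        spectrum = build_spectrum(records)
        assert spectrum.sum() == len(records) == len(calls)
        assert skipped == 0
        assert sixfold_from_spectrum(spectrum).sum() == spectrum.sum()

    @staticmethod
    def reference():
        return {"chr1": "ATGTA"}


class TestStrandBias:
    # reference with known pyrimidine/purine sites inside stranded genes
    REF = {"chr1": "AACTGACTGACTGACTGACTGACTGACTGACTGACTGACT"}

    def _records(self, positions_alts):
        calls = []
        for pos, alt in positions_alts:
            calls.append(("chr1", pos, self.REF["chr1"][pos - 1], alt))
        records, _ = channelize(calls, self.REF)
        return records

    def test_no_genes_everything_intergenic(self):
        records = annotate_strand(self._records([(3, "T"), (4, "C")]), [])
        assert all(r.strand == INTERGENIC for r in records)

    def test_pyrimidine_in_plus_gene_is_untranscribed(self):
        gene = GeneInterval("chr1", 1, 40, "+")
        # position 3 is C (a reference-strand pyrimidine)
        (rec,) = annotate_strand(self._records([(3, "T")]), [gene])
        assert rec.strand == UNTRANSCRIBED

    def test_pyrimidine_in_minus_gene_is_transcribed(self):
        gene = GeneInterval("chr1", 1, 40, "-")
        (rec,) = annotate_strand(self._records([(3, "T")]), [gene])
        assert rec.strand == TRANSCRIBED

    def test_purine_site_flips_category(self):
        # position 5 is G: the pyrimidine lies on the minus strand
        plus = GeneInterval("chr1", 1, 40, "+")
        (rec,) = annotate_strand(self._records([(5, "A")]), [plus])
        assert rec.strand == TRANSCRIBED

    def test_opposite_overlapping_genes_are_ambiguous(self):
        genes = [GeneInterval("chr1", 1, 40, "+"), GeneInterval("chr1", 1, 40, "-")]
        (rec,) = annotate_strand(self._records([(3, "T")]), genes)
        assert rec.strand == AMBIGUOUS

    def test_symmetric_construction_gives_p_one(self):
        # one C>T on each strand orientation: 1 transcribed vs 1 untranscribed
        genes = [GeneInterval("chr1", 1, 40, "+")]
        # position 3 (reference C) and position 5 (reference G, normalized)
        # both land in the C>T category, one on each strand orientation
        records = self._records([(3, "T"), (5, "A")])
        table = strand_bias(records, genes)
        row = table[table["base_change"] == "C>T"].iloc[0]
        assert row[TRANSCRIBED] == row[UNTRANSCRIBED] == 1
        assert row["p_value"] == pytest.approx(1.0)

    def test_empty_categories_get_p_one(self):
        table = strand_bias([], [GeneInterval("chr1", 1, 40, "+")])
        assert (table["p_value"] == 1.0).all()

    def test_gene_strand_validation(self):
        with pytest.raises(ValueError, match="strand"):
            GeneInterval("chr1", 1, 10, "x")


class TestGroupCountTests:
    def _frame(self, a_rows, b_rows):
        data = a_rows + b_rows
        idx = [f"s{i}" for i in range(len(data))]
        labels = {f"s{i}": ("x" if i < len(a_rows) else "y") for i in range(len(data))}
        return pd.DataFrame(data, index=idx, columns=["C>T"]), labels

    def test_pooled_t_oracle(self):
        # frozen against the classic pooled two-sample t-test:
        # {1,2,3} vs {4,5,6} -> t = -3.674235, p = 0.021312
        counts, labels = self._frame([[1], [2], [3]], [[4], [5], [6]])
        out = group_count_tests(counts, labels, n_comparisons=1)
        assert out.loc[0, "t_statistic"] == pytest.approx(-3.674235, abs=1e-6)
        assert out.loc[0, "p_value"] == pytest.approx(0.021312, abs=1e-6)

    def test_identical_constant_groups_give_p_one(self):
        counts, labels = self._frame([[5], [5]], [[5], [5]])
        out = group_count_tests(counts, labels)
        assert out.loc[0, "t_statistic"] == 0.0 and out.loc[0, "p_value"] == 1.0

    def test_bonferroni_capped_at_one(self):
        counts, labels = self._frame([[1], [2], [3]], [[1], [3], [2]])
        out = group_count_tests(counts, labels, n_comparisons=6)
        assert out.loc[0, "p_bonferroni"] == min(1.0, 6 * out.loc[0, "p_value"])
        assert out.loc[0, "p_bonferroni"] <= 1.0

    def test_bonferroni_is_six_p_for_small_p(self):
        counts, labels = self._frame([[0], [0], [1]], [[50], [52], [51]])
        out = group_count_tests(counts, labels, n_comparisons=6)
        assert out.loc[0, "p_bonferroni"] == pytest.approx(6 * out.loc[0, "p_value"])

    def test_requires_exactly_two_groups(self):
        counts = pd.DataFrame([[1], [2], [3]], index=["a", "b", "c"], columns=["C>T"])
        with pytest.raises(ValueError, match="2 groups"):
            group_count_tests(counts, {"a": "x", "b": "y", "c": "z"})

    def test_requires_two_per_group(self):
        counts = pd.DataFrame([[1], [2], [3]], index=["a", "b", "c"], columns=["C>T"])
        with pytest.raises(ValueError, match="at least 2"):
            group_count_tests(counts, {"a": "x", "b": "y", "c": "y"})
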