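"""Dataset-construction operations: filtering, augmentation, balancing,
splitting, pooling and negative controls."""

import numpy as np
import pytest
from scipy import stats

from sebird.datasets import (
    LabeledSequence,
    LengthBinning,
    augment_te_lengths,
    balance_bins,
    build_integrative,
    exclude_overlaps,
    filter_se,
    make_negative_controls,
    split_train_test,
)
from sebird.intervals import Genome, GenomicInterval


def iv(start, end, chrom="chr1", label=None):
    return GenomicInterval(chrom, start, end, label=label)


def seqs(lengths, label):
    return [
        LabeledSequence(seq="A", label=label, source=iv(1000 * i, 1000 * i + 10),
                        n_tokens=n)
        for i, n in enumerate(lengths)
    ]


class TestFilterSe:
    def test_short_removed_long_trimmed(self):
        out = filter_se([iv(0, 2000), iv(0, 2500), iv(0, 30000)])
        assert [o.length() for o in out] == [2500, 25000]

    def test_within_bounds_identity(self):
        ivs = [iv(0, 2500), iv(10, 25010), iv(5, 10000)]
        assert filter_se(ivs) == ivs

    def test_trim_is_centered_on_midpoint(self):
        (out,) = filter_se([iv(0, 30000)])
        assert (out.start, out.end) == (2500, 27500)

    def test_boundary_lengths_kept_untrimmed(self):
        out = filter_se([iv(0, 2499), iv(0, 25000)])
        assert [(o.start, o.end) for o in out] == [(0, 25000)]


class TestExcludeOverlaps:
    def test_annotation_overlap_removed(self):
        assert exclude_overlaps([iv(100, 200)], [iv(150, 160)]) == []

    def test_touching_annotation_kept(self):
        kept = exclude_overlaps([iv(100, 200)], [iv(200, 300)])
        assert kept == [iv(100, 200)]

    def test_mutual_overlap_first_kept_wins(self):
        ivs = [iv(0, 100), iv(50, 150), iv(200, 300)]
        assert exclude_overlaps(ivs, []) == [iv(0, 100), iv(200, 300)]

    def test_agrees_with_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            data = [
                iv(s, s + l, chrom=f"chr{rng.integers(2)}")
                for s, l in zip(rng.integers(0, 500, 30), rng.integers(1, 80, 30))
            ]
            ann = [
                iv(s, s + l, chrom=f"chr{rng.integers(2)}")
                for s, l in zip(rng.integers(0, 500, 5), rng.integers(1, 60, 5))
            ]
            expected = []
            for candidate in data:
                if any(candidate.overlaps(a) for a in ann):
                    continue
                if any(candidate.overlaps(k) for k in expected):
                    continue
                expected.append(candidate)
            assert exclude_overlaps(data, ann) == expected


class TestAugmentTeLengths:
    chrom_lengths = {"chr1": 10_000_000}

    def _se_lengths(self, rng, n=300):
        return np.clip(
            rng.lognormal(np.log(8000), 0.5, n).astype(int), 2500, 25000
        )

    def _tes(self, rng, n=120):
        out = []
        pos = 10_000
        for length in rng.integers(200, 2400, n):
            out.append(iv(pos, pos + int(length), label=0))
            pos += 40_000
        return out

    def test_every_output_contains_its_source(self):
        rng = np.random.default_rng(1)
        ses = self._se_lengths(rng)
        tes = self._tes(rng)
        out = augment_te_lengths(tes, ses, self.chrom_lengths, rng)
        for src, aug in zip(tes, out):
            assert aug.contains(src)
            assert int(aug.length()) in set(ses.tolist()) or aug.length() == src.length()

    def test_equal_length_draw_leaves_interval_unchanged(self):
        te = iv(1000, 1200)
        out = augment_te_lengths([te], [200], {"chr1": 5000},
                                 np.random.default_rng(0))
        assert out == [te]

    def test_deterministic_under_seed(self):
        ses = self._se_lengths(np.random.default_rng(2))
        tes = self._tes(np.random.default_rng(3))
        a = augment_te_lengths(tes, ses, self.chrom_lengths,
                               np.random.default_rng(42))
        b = augment_te_lengths(tes, ses, self.chrom_lengths,
                               np.random.default_rng(42))
        assert a == b

    def test_ks_statistic_decreases_after_augmentation(self):
        rng = np.random.default_rng(4)
        ses = self._se_lengths(rng, n=500)
        tes = self._tes(rng, n=120)
        out = augment_te_lengths(tes, ses, self.chrom_lengths, rng)
        before = stats.ks_2samp([t.length() for t in tes], ses).statistic
        after = stats.ks_2samp([t.length() for t in out], ses).statistic
        assert after < before

    def test_boundary_clipping_preserves_length_and_containment(self):
        te = iv(50, 250)  # near chromosome start: window must shift right
        rng = np.random.default_rng(0)
        out = augment_te_lengths([te], [4000], {"chr1": 6000}, rng)
        (aug,) = out
        assert aug.start >= 0 and aug.end <= 6000
        assert aug.length() == 4000
        assert aug.contains(te)

    def test_empty_se_lengths_rejected(self):
        with pytest.raises(ValueError):
            augment_te_lengths([iv(0, 100)], [], {"chr1": 1000},
                               np.random.default_rng(0))


class TestBalanceBins:
    def test_min_rule_within_bin(self):
        se = seqs([100] * 10, 1)
        te = seqs([110] * 7, 0)
        se_out, te_out = balance_bins(se, te, np.random.default_rng(0))
        assert len(se_out) == len(te_out) == 7

    def test_already_equal_bins_untouched(self):
        se = seqs([100, 160, 210], 1)
        te = seqs([101, 161, 211], 0)
        se_out, te_out = balance_bins(se, te, np.random.default_rng(0))
        assert se_out == se and te_out == te

    def test_enumerated_per_bin_minima(self):
        # bin A (~100 tokens): 5 SE / 3 TE; bin B (~200): 0 SE / 4 TE
        se = seqs([100] * 5, 1)
        te = seqs([100] * 3 + [200] * 4, 0)
        se_out, te_out = balance_bins(se, te, np.random.default_rng(0))
        assert len(se_out) == len(te_out) == 3

    def test_per_bin_counts_equal_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            se = seqs(rng.integers(50, 600, rng.integers(5, 60)), 1)
            te = seqs(rng.integers(50, 600, rng.integers(5, 60)), 0)
            se_out, te_out = balance_bins(se, te, rng)
            binning = LengthBinning.from_step(
                [s.n_tokens for s in se + te], 50, unit="tokens"
            )
            for b in range(binning.n_bins):
                n_se = sum(binning.assign(s.n_tokens) == b for s in se_out)
                n_te = sum(binning.assign(s.n_tokens) == b for s in te_out)
                assert n_se == n_te

    def test_missing_token_length_rejected(self):
        bad = [LabeledSequence(seq="A", label=1, source=iv(0, 10))]
        with pytest.raises(ValueError):
            balance_bins(bad, seqs([100], 0), np.random.default_rng(0))


class TestSplitTrainTest:
    def test_exact_three_to_one(self):
        split = split_train_test(seqs(range(100, 200), 1),
                                 np.random.default_rng(0))
        assert (len(split.train), len(split.test)) == (75, 25)

    def test_odd_size_extra_goes_to_train(self):
        split = split_train_test(seqs(range(100, 201), 1),
                                 np.random.default_rng(0))
        assert (len(split.train), len(split.test)) == (76, 25)

    def test_partition_disjoint_and_complete(self):
        data = seqs(range(100, 140), 1)
        split = split_train_test(data, np.random.default_rng(3))
        ids = {s.source_id for s in data}
        train_ids = {s.source_id for s in split.train}
        test_ids = {s.source_id for s in split.test}
        assert train_ids | test_ids == ids
        assert not (train_ids & test_ids)

    def test_same_seed_same_partition(self):
        data = seqs(range(100, 150), 1)
        a = split_train_test(data, np.random.default_rng(5))
        b = split_train_test(data, np.random.default_rng(5))
        assert [s.source_id for s in a.train] == [s.source_id for s in b.train]

    def test_too_few_examples_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(seqs([100, 101, 102], 1), np.random.default_rng(0))


class TestBuildIntegrative:
    def _lines(self, n_lines=7, per_line=900):
        return {
            f"line{i}": [
                LabeledSequence(seq="A", label=j % 2,
                                source=iv(j * 10, j * 10 + 5, chrom=f"c{i}"),
                                cell_line=f"line{i}")
                for j in range(per_line)
            ]
            for i in range(n_lines)
        }

    def test_pool_and_sample_sizes(self):
        out = build_integrative(self._lines(), np.random.default_rng(0))
        assert len(out) == 2500
        # drawn without replacement
        assert len({s.source_id for s in out}) == 2500

    def test_small_line_fully_included_when_per_line_n_matches(self):
        lines = self._lines(n_lines=2, per_line=10)
        out = build_integrative(lines, np.random.default_rng(0),
                                per_line_n=10, total_n=20)
        assert {s.source_id for s in out} == {
            s.source_id for line in lines.values() for s in line
        }

    def test_deterministic_under_seed(self):
        a = build_integrative(self._lines(), np.random.default_rng(7))
        b = build_integrative(self._lines(), np.random.default_rng(7))
        assert [s.source_id for s in a] == [s.source_id for s in b]

    def test_undersized_line_rejected(self):
        with pytest.raises(ValueError):
            build_integrative(self._lines(per_line=100), np.random.default_rng(0))

    def test_pool_smaller_than_total_rejected(self):
        with pytest.raises(ValueError):
            build_integrative(self._lines(n_lines=2), np.random.default_rng(0),
                              per_line_n=800, total_n=2500)


class TestNegativeControls:
    genome = Genome({"chr1": "ACGT" * 2500, "chr2": "ACGT" * 1000})

    def test_default_contract(self):
        out = make_negative_controls(self.genome, np.random.default_rng(0),
                                     n=50, min_len=100, max_len=500)
        assert len(out) == 50
        assert all(100 <= o.length() <= 500 for o in out)
        assert all(o.label is None for o in out)

    def test_degenerate_range_gives_exact_lengths(self):
        out = make_negative_controls(self.genome, np.random.default_rng(0),
                                     n=10, min_len=5000, max_len=5000)
        assert all(o.length() == 5000 for o in out)
        assert all(o.chrom == "chr1" for o in out)  # chr2 too short

    def test_same_seed_same_controls(self):
        a = make_negative_controls(self.genome, np.random.default_rng(4), n=20,
                                   min_len=50, max_len=200)
        b = make_negative_controls(self.genome, np.random.default_rng(4), n=20,
                                   min_len=50, max_len=200)
        assert a == b

    def test_no_chromosome_long_enough_rejected(self):
        with pytest.raises(ValueError):
            make_negative_controls(self.genome, np.random.default_rng(0),
                                   n=1, min_len=100_000, max_len=100_000)
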