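import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4forge.dataset_builder import (
    DatasetSpec,
    build_dataset,
    ratio_counts,
    read_labeled_fasta,
    sample_negative_interval,
    split_train_eval,
    standardize_length,
    write_labeled_fasta,
    LabeledSequence,
)
from g4forge.genome_io import Genome, GenomicInterval


class TestStandardizeLength:
    def test_exact_length_unchanged(self, rng):
        seq = "ACGT" * 50
        assert standardize_length(seq, 200, rng) == seq

    def test_center_crop_floor_tiebreak(self, rng):
        seq = "".join("ACGT"[i % 4] for i in range(300))
        assert standardize_length(seq, 200, rng) == seq[50:250]

    def test_padding_conserves_sequence(self, rng):
        seq = "ACGT" * 37 + "GG"  # 150 nt
        out = standardize_length(seq, 200, rng)
        assert len(out) == 200
        assert seq in out
        assert out.count("N") == 50
        assert out.strip("N") == seq  # Ns only on the flanks

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            standardize_length("", 200, rng)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_n_count_conservation(self, seq, seed):
        out = standardize_length(seq, 200, np.random.default_rng(seed))
        assert len(out) == 200
        assert out.count("N") == max(0, 200 - len(seq))

    def test_crop_is_seed_independent(self):
        seq = "A" * 123 + "G" * 200
        a = standardize_length(seq, 200, np.random.default_rng(1))
        b = standardize_length(seq, 200, np.random.default_rng(999))
        assert a == b


class TestRatioCounts:
    @pytest.mark.parametrize("k,total,expected", [(1, 20, (10, 10)), (9, 100, (10, 90)),
                                                  (99, 10000, (100, 9900)),
                                                  (999, 10000, (10, 9990))])
    def test_exact_arithmetic(self, k, total, expected):
        assert ratio_counts(k, total) == expected

    def test_indivisible_total_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            DatasetSpec(ratio_k=9, total_count=101)


class TestNegativeSampling:
    def test_fully_blocked_genome_errors(self, rng):
        genome = Genome({"c": "A" * 1000})
        blocked = [GenomicInterval("c", 0, 1000)]
        with pytest.raises(RuntimeError, match="attempts"):
            sample_negative_interval(genome, blocked, 200, rng, max_attempts=50)

    def test_feasible_region_respected(self, rng):
        genome = Genome({"c": "A" * 1000})
        positives = [GenomicInterval("c", 0, 500)]
        for _ in range(50):
            iv = sample_negative_interval(genome, positives, 100, rng)
            assert 500 <= iv.start <= 900
            assert iv.strand == "+"
            assert len(iv) == 100

    def test_chromosome_choice_proportional_to_valid_starts(self, rng):
        genome = Genome({"c1": "A" * 1000, "c2": "A" * 3000})
        n, length = 10000, 100
        p = (3000 - length + 1) / ((1000 - length + 1) + (3000 - length + 1))
        draws = sum(
            sample_negative_interval(genome, [], length, rng).chrom == "c2"
            for _ in range(n)
        )
        se = np.sqrt(p * (1 - p) / n)
        assert abs(draws / n - p) < 3 * se


def _toy_genome_and_positives():
    rng = np.random.default_rng(42)
    chrom = "".join("ACGT"[i] for i in rng.integers(0, 4, 20000))
    genome = Genome({"c": chrom})
    positives = [
        GenomicInterval("c", s, s + int(l), "+" if i % 2 else "-")
        for i, (s, l) in enumerate(
            zip(range(100, 18000, 600), rng.integers(120, 280, 30))
        )
    ]
    return genome, positives


class TestBuildDataset:
    def test_balanced_counts_and_lengths(self):
        genome, positives = _toy_genome_and_positives()
        data = build_dataset(positives, genome, DatasetSpec(1, 20, seed=0))
        labels = [s.label for s in data]
        assert labels.count(1) == 10 and labels.count(0) == 10
        assert all(len(s.sequence) == 200 for s in data)

    def test_one_to_nine_ratio(self):
        genome, positives = _toy_genome_and_positives()
        data = build_dataset(positives, genome, DatasetSpec(9, 100, seed=1))
        labels = [s.label for s in data]
        assert labels.count(1) == 10 and labels.count(0) == 90

    def test_deterministic_given_seed(self):
        genome, positives = _toy_genome_and_positives()
        spec = DatasetSpec(1, 20, seed=7)
        a = build_dataset(positives, genome, spec)
        b = build_dataset(positives, genome, spec)
        assert [(s.sequence, s.label, s.source) for s in a] == [
            (s.sequence, s.label, s.source) for s in b
        ]

    def test_negatives_avoid_all_positives(self):
        genome, positives = _toy_genome_and_positives()
        data = build_dataset(positives, genome, DatasetSpec(9, 100, seed=3))
        for rec in data:
            if rec.label == 0:
                assert not any(rec.source.overlaps(p) for p in positives)

    def test_insufficient_positives(self):
        genome, positives = _toy_genome_and_positives()
        with pytest.raises(ValueError, match="positives"):
            build_dataset(positives[:3], genome, DatasetSpec(1, 20, seed=0))


class TestSplitTrainEval:
    def test_balanced_stratification(self, rng):
        data = [LabeledSequence("A" * 200, i % 2) for i in range(100)]
        train, eval_ = split_train_eval(data, 0.1, rng)
        assert sum(s.label for s in eval_) == 5 and len(eval_) == 10
        assert len(train) == 90

    def test_imbalanced_stratification(self, rng):
        data = [LabeledSequence("A" * 200, 1) for _ in range(10)] + [
            LabeledSequence("C" * 200, 0) for _ in range(990)
        ]
        train, eval_ = split_train_eval(data, 0.1, rng)
        assert sum(s.label for s in eval_) == 1
        assert len(eval_) == 100

    def test_disjoint_exhaustive_partition(self, rng):
        data = [LabeledSequence("ACGT" * 50, i % 2) for i in range(60)]
        train, eval_ = split_train_eval(data, 0.25, rng)
        assert len(train) + len(eval_) == 60
        ids = {id(s) for s in train} | {id(s) for s in eval_}
        assert len(ids) == 60  # no record in both halves

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_bounds(self, rng, fraction):
        data = [LabeledSequence("A" * 200, 1)]
        with pytest.raises(ValueError):
            split_train_eval(data, fraction, rng)


def test_labeled_fasta_roundtrip(tmp_path):
    data = [
        LabeledSequence("ACGT" * 50, 1, GenomicInterval("c", 5, 205, "-")),
        LabeledSequence("N" * 10 + "G" * 190, 0),
    ]
    path = tmp_path / "ds.fasta.gz"
    write_labeled_fasta(data, path)
    back = read_labeled_fasta(path)
    assert [(r.sequence, r.label) for r in back] == [
        (r.sequence, r.label) for r in data
    ]
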