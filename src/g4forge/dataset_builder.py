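"""Assemble fixed-length labeled G4 datasets at controlled class ratios.

Positives come from experimentally mapped G4 intervals (e.g. G4-seq peaks in
BED) extracted strand-aware from a genome; each negative is a random genomic
locus of the same pre-padding length as a sampled positive, required not to
overlap any positive interval. All sequences are standardized to a fixed
length (default 200 nt): longer sequences are center-cropped, shorter ones
are padded with Ns split randomly between the two flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_io import Genome, GenomicInterval, extract_sequence, open_text

__all__ = [
    "LabeledSequence",
    "DatasetSpec",
    "ratio_counts",
    "standardize_length",
    "NegativeSampler",
    "sample_negative_interval",
    "build_dataset",
    "split_train_eval",
    "write_labeled_fasta",
    "read_labeled_fasta",
]


@dataclass
class LabeledSequence:
    """A fixed-length sequence with a binary G4 label and provenance."""

    sequence: str
    label: int
    source: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class DatasetSpec:
    """Recipe for one dataset: 1:k class ratio, total size, seed, length.

    ``ratio_k`` is the k of a 1:k pos:neg ratio (1, 9, 99, 999 in the
    canonical ladder, but any k >= 1 is accepted). ``total_count`` must
    divide exactly into total/(k+1) positives and k*total/(k+1) negatives.
    """

    ratio_k: int = 1
    total_count: int = 1000
    seed: int = 0
    target_length: int = 200

    def __post_init__(self) -> None:
        if self.ratio_k < 1:
            raise ValueError("ratio_k must be >= 1")
        if self.target_length < 1:
            raise ValueError("target_length must be >= 1")
        ratio_counts(self.ratio_k, self.total_count)  # validates divisibility

    @property
    def n_positive(self) -> int:
        return ratio_counts(self.ratio_k, self.total_count)[0]

    @property
    def n_negative(self) -> int:
        return ratio_counts(self.ratio_k, self.total_count)[1]


def ratio_counts(k: int, total: int) -> tuple[int, int]:
    """Exact (positives, negatives) for a 1:k ratio; error if not divisible."""
    if total % (k + 1) != 0:
        raise ValueError(
            f"total {total} does not split exactly at ratio 1:{k} "
            f"(must be divisible by {k + 1})"
        )
    n_pos = total // (k + 1)
    return n_pos, total - n_pos


def standardize_length(
    seq: str, target_length: int, rng: np.random.Generator
) -> str:
    """Center-crop or random-N-pad a sequence to ``target_length``.

    Longer inputs keep the central window starting at floor((len-target)/2).
    Shorter inputs get ``deficit`` Ns total, split uniformly at random
    between the left and right flank. Exact-length inputs pass through.
    """
    if len(seq) == 0:
        raise ValueError("cannot standardize an empty sequence")
    n = len(seq)
    if n == target_length:
        return seq
    if n > target_length:
        off = (n - target_length) // 2
        return seq[off : off + target_length]
    deficit = target_length - n
    left = int(rng.integers(0, deficit + 1))
    return "N" * left + seq + "N" * (deficit - left)


class NegativeSampler:
    """Uniform sampler of plus-strand intervals avoiding a blocked set.

    Chromosomes are chosen with probability proportional to their number of
    valid start positions for the requested length; candidate intervals are
    rejection-sampled against an interval tree of the positive set.
    """

    def __init__(self, genome: Genome, positives: Iterable[GenomicInterval]):
        self._genome = genome
        self._lengths = genome.lengths()
        self._trees: dict[str, IntervalTree] = {}
        for iv in positives:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def overlaps_positive(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    def sample(
        self, length: int, rng: np.random.Generator, max_attempts: int = 1000
    ) -> GenomicInterval:
        if length < 1:
            raise ValueError("length must be >= 1")
        chroms = [c for c, n in self._lengths.items() if n >= length]
        if not chroms:
            raise ValueError(f"no chromosome can host an interval of length {length}")
        starts = np.array([self._lengths[c] - length + 1 for c in chroms], float)
        probs = starts / starts.sum()
        for _ in range(max_attempts):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            start = int(rng.integers(0, self._lengths[chrom] - length + 1))
            candidate = GenomicInterval(chrom, start, start + length, "+")
            if not self.overlaps_positive(candidate):
                return candidate
        raise RuntimeError(
            f"failed to place a non-overlapping {length} nt interval "
            f"after {max_attempts} attempts"
        )


def sample_negative_interval(
    genome: Genome,
    positives: Sequence[GenomicInterval],
    length: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> GenomicInterval:
    """One-shot convenience wrapper around :class:`NegativeSampler`."""
    return NegativeSampler(genome, positives).sample(length, rng, max_attempts)


def build_dataset(
    positives: Sequence[GenomicInterval],
    genome: Genome,
    spec: DatasetSpec,
) -> list[LabeledSequence]:
    """Build a shuffled labeled dataset at the spec's exact 1:k ratio.

    Positives are sampled without replacement, extracted strand-aware and
    standardized. Each sampled positive is paired with k negatives of its
    own pre-padding length (its extracted length capped at target_length),
    sampled on the plus strand so that they overlap no interval of the full
    positive set, then standardized identically.
    """
    n_pos, n_neg = ratio_counts(spec.ratio_k, spec.total_count)
    if n_pos > len(positives):
        raise ValueError(
            f"need {n_pos} positives but only {len(positives)} are available"
        )
    rng = np.random.default_rng(spec.seed)
    sampler = NegativeSampler(genome, positives)

    chosen_idx = rng.choice(len(positives), size=n_pos, replace=False)
    dataset: list[LabeledSequence] = []
    for idx in chosen_idx:
        iv = positives[int(idx)]
        raw = extract_sequence(genome, iv)
        dataset.append(
            LabeledSequence(standardize_length(raw, spec.target_length, rng), 1, iv)
        )
        pre_pad_len = min(len(raw), spec.target_length)
        for _ in range(spec.ratio_k if n_neg else 0):
            neg_iv = sampler.sample(pre_pad_len, rng)
            neg_raw = extract_sequence(genome, neg_iv)
            dataset.append(
                LabeledSequence(
                    standardize_length(neg_raw, spec.target_length, rng), 0, neg_iv
                )
            )
    order = rng.permutation(len(dataset))
    return [dataset[i] for i in order]


def split_train_eval(
    dataset: Sequence[LabeledSequence],
    eval_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[LabeledSequence], list[LabeledSequence]]:
    """Stratified disjoint split into (train, eval) preserving class ratio."""
    if not dataset:
        raise ValueError("dataset is empty")
    if not 0.0 < eval_fraction < 1.0:
        raise ValueError(f"eval_fraction must be in (0,1), got {eval_fraction}")
    train: list[LabeledSequence] = []
    eval_: list[LabeledSequence] = []
    for label in (0, 1):
        idx = [i for i, s in enumerate(dataset) if s.label == label]
        if not idx:
            continue
        perm = rng.permutation(len(idx))
        n_eval = int(round(eval_fraction * len(idx)))
        for j, p in enumerate(perm):
            (eval_ if j < n_eval else train).append(dataset[idx[p]])
    rng.shuffle(train)  # type: ignore[arg-type]
    rng.shuffle(eval_)  # type: ignore[arg-type]
    return train, eval_


def write_labeled_fasta(
    dataset: Iterable[LabeledSequence], path: str | Path
) -> None:
    """Write a labeled dataset as FASTA with label/provenance in headers."""
    with open_text(path, "wt") as handle:
        for i, rec in enumerate(dataset):
            src = f" source={rec.source}" if rec.source is not None else ""
            handle.write(f">seq{i:06d} label={rec.label}{src}\n{rec.sequence}\n")


def read_labeled_fasta(path: str | Path) -> list[LabeledSequence]:
    """Read a dataset written by :func:`write_labeled_fasta`."""
    records: list[LabeledSequence] = []
    name, label, chunks = None, None, []

    def flush() -> None:
        if name is not None:
            if label is None:
                raise ValueError(f"record {name!r} lacks a label= tag")
            records.append(LabeledSequence("".join(chunks), label))

    with open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                chunks = []
                parts = line[1:].split()
                name = parts[0] if parts else ""
                label = None
                for tag in parts[1:]:
                    if tag.startswith("label="):
                        label = int(tag[6:])
            else:
                chunks.append(line.upper())
    flush()
    return records
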