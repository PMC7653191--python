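"""Synthetic G4 data with known ground truth.

Positives are random-background sequences with a planted canonical motif —
``n_tracts`` G-runs (lengths 3-5 by default) joined by short loops — so the
planted interval is exact ground truth for interpretation experiments and
every positive matches the canonical regex. Negatives are i.i.d.
background at a configurable GC content (0.4 by default, roughly genomic),
optionally rejection-sampled to be regex-free so labels are clean.

Loop bases are drawn from {A, C, T}: a G inside a loop could merge or
extend adjacent planted tracts, which would blur both the tract count and
the planted-interval ground truth.

The module also plants motifs into a whole synthetic genome (FASTA +
intervals) so the BED-driven dataset builder can be exercised end-to-end
without downloading a real assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .baselines import regex_match
from .dataset_builder import LabeledSequence, ratio_counts
from .genome_io import Genome, GenomicInterval, reverse_complement

__all__ = [
    "SyntheticSpec",
    "build_motif",
    "random_background",
    "generate_positive",
    "generate_negative",
    "generate_dataset",
    "plant_in_genome",
]

_LOOP_BASES = "ACT"
_ALL_BASES = "ACGT"


@dataclass
class SyntheticSpec:
    """Parameters of the planted-motif generator.

    Defaults mirror the canonical G4 grammar: four G-tracts of length 3-5
    joined by 1-7-nt loops, embedded in 200-nt background of 40% GC.
    """

    n_tracts: int = 4
    tract_length_range: tuple[int, int] = (3, 5)
    loop_length_range: tuple[int, int] = (1, 7)
    background_gc: float = 0.4
    target_length: int = 200
    exclude_regex_in_negatives: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracts < 4:
            raise ValueError("n_tracts must be >= 4 for a quadruplex")
        lo, hi = self.tract_length_range
        if not 3 <= lo <= hi:
            raise ValueError("tract lengths must satisfy 3 <= lo <= hi")
        llo, lhi = self.loop_length_range
        if not 1 <= llo <= lhi <= 7:
            raise ValueError("loop lengths must stay within the canonical 1..7")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must be in (0,1)")
        max_motif = self.n_tracts * hi + (self.n_tracts - 1) * lhi
        if max_motif > self.target_length:
            raise ValueError(
                f"maximal motif length {max_motif} exceeds target_length "
                f"{self.target_length}"
            )


def build_motif(spec: SyntheticSpec, rng: np.random.Generator) -> str:
    """One planted motif: G-tracts joined by A/C/T loops."""
    tlo, thi = spec.tract_length_range
    llo, lhi = spec.loop_length_range
    parts = []
    for i in range(spec.n_tracts):
        parts.append("G" * int(rng.integers(tlo, thi + 1)))
        if i < spec.n_tracts - 1:
            loop_len = int(rng.integers(llo, lhi + 1))
            parts.append(
                "".join(_LOOP_BASES[b] for b in rng.integers(0, 3, size=loop_len))
            )
    return "".join(parts)


def random_background(n: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. sequence with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(_ALL_BASES[b] for b in rng.choice(4, size=n, p=probs))


def generate_positive(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[LabeledSequence, tuple[int, int]]:
    """A labeled positive plus the planted motif's (start, end) interval."""
    motif = build_motif(spec, rng)
    background = random_background(spec.target_length, spec.background_gc, rng)
    offset = int(rng.integers(0, spec.target_length - len(motif) + 1))
    seq = background[:offset] + motif + background[offset + len(motif) :]
    interval = (offset, offset + len(motif))
    record = LabeledSequence(
        seq, 1, GenomicInterval("synthetic", interval[0], interval[1], "+")
    )
    return record, interval


def generate_negative(
    spec: SyntheticSpec, rng: np.random.Generator, max_attempts: int = 1000
) -> LabeledSequence:
    """An i.i.d. background negative, regex-free when the spec says so."""
    for _ in range(max_attempts):
        seq = random_background(spec.target_length, spec.background_gc, rng)
        if not spec.exclude_regex_in_negatives or not regex_match(seq):
            return LabeledSequence(seq, 0, None)
    raise RuntimeError(
        f"could not draw a regex-free negative in {max_attempts} attempts; "
        "consider lowering background_gc"
    )


def generate_dataset(
    spec: SyntheticSpec,
    ratio_k: int,
    total: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[LabeledSequence], list[dict]]:
    """A shuffled 1:k dataset plus the planted-interval table.

    The table has one row per positive: its index in the shuffled dataset
    and the planted motif's start/end, for interpretation ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n_pos, n_neg = ratio_counts(ratio_k, total)
    records: list[tuple[LabeledSequence, tuple[int, int] | None]] = []
    for _ in range(n_pos):
        rec, interval = generate_positive(spec, rng)
        records.append((rec, interval))
    for _ in range(n_neg):
        records.append((generate_negative(spec, rng), None))
    order = rng.permutation(len(records))
    dataset = [records[i][0] for i in order]
    planted = [
        {"index": pos, "start": records[i][1][0], "end": records[i][1][1]}
        for pos, i in enumerate(order)
        if records[i][1] is not None
    ]
    return dataset, planted


def plant_in_genome(
    n_sites: int,
    chrom_lengths: dict[str, int],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    interval_length_range: tuple[int, int] = (120, 280),
    slot: int = 400,
) -> tuple[Genome, list[GenomicInterval]]:
    """Random genome with ``n_sites`` planted motifs and their peak intervals.

    Motifs are written into disjoint ``slot``-sized tiles so the returned
    intervals never overlap; half the intervals are annotated on the minus
    strand (the motif is planted reverse-complemented there), exercising
    strand-aware extraction. Interval lengths vary within
    ``interval_length_range`` to exercise both cropping and N-padding.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    ilo, ihi = interval_length_range
    if ihi > slot:
        raise ValueError("interval_length_range must fit inside a slot")
    slots: list[tuple[str, int]] = []
    for chrom, length in chrom_lengths.items():
        slots.extend((chrom, s) for s in range(0, length - slot + 1, slot))
    if len(slots) < n_sites:
        raise ValueError(
            f"genome has {len(slots)} slots of {slot} nt but {n_sites} sites requested"
        )
    chosen = rng.choice(len(slots), size=n_sites, replace=False)

    chrom_arrays = {
        chrom: list(random_background(length, spec.background_gc, rng))
        for chrom, length in chrom_lengths.items()
    }
    intervals: list[GenomicInterval] = []
    for slot_idx in chosen:
        chrom, slot_start = slots[int(slot_idx)]
        iv_len = int(rng.integers(ilo, ihi + 1))
        iv_start = slot_start + int(rng.integers(0, slot - iv_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        motif = build_motif(spec, rng)
        m_start = iv_start + (iv_len - len(motif)) // 2
        planted = motif if strand == "+" else reverse_complement(motif)
        chrom_arrays[chrom][m_start : m_start + len(motif)] = planted
        intervals.append(GenomicInterval(chrom, iv_start, iv_start + iv_len, strand))
    genome = Genome({c: "".join(a) for c, a in chrom_arrays.items()})
    return genome, intervals
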