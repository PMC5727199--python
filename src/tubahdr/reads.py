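"""Raw reads -> deduplicated pileups and a flank-based error-rate estimate.

The 42-nt clustering sequence consists of *Kras* codons 12-13, the 22-nt
barcoded region, and the seven invariant nucleotides on each side. The two
flanks are invariant by design, so every flank mismatch across the pileup
is a residual sequencing/PCR error; their rate calibrates the denoiser.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from typing import Iterable, Iterator

import numpy as np

from .design import BarcodeDesign, InvalidInputError

#: Minimum base quality inside the clustering window.
MIN_QUALITY = 20

#: Minimum fractional identity of a read pair's overlap for merging.
MIN_OVERLAP_IDENTITY = 0.9

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclasses.dataclass
class SamplePileup:
    """Unique clustering sequences of one sample with their read counts."""

    sample: str
    counts: dict[str, int]
    accepted: int = 0
    rejected: Counter = dataclasses.field(default_factory=Counter)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence\tcount\n")
            for seq, n in sorted(self.counts.items(),
                                 key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{seq}\t{n}\n")

    def rejects_json(self) -> str:
        return json.dumps({"accepted": self.accepted,
                           "rejected": dict(self.rejected)}, sort_keys=True)


def phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8) - 33


def merge_pairs(r1: tuple[str, str], r2: tuple[str, str],
                expected_core: int) -> tuple[str, str] | None:
    """Merge a read pair at the offset implied by the fragment length.

    ``r1`` is the sense-strand read, ``r2`` the reverse-complement read.
    At overlap mismatches the higher-quality base wins; pairs whose
    overlap identity falls below 90% (or which leave part of the fragment
    uncovered) are rejected by returning None.
    """
    seq1, qual1 = r1
    seq2, qual2 = r2
    seq2 = seq2.translate(_COMP)[::-1]
    qual2 = qual2[::-1]
    offset = expected_core - len(seq2)
    lo, hi = max(0, offset), min(len(seq1), expected_core)
    if lo >= hi:  # reads too short to overlap
        return None
    if len(seq1) < expected_core and offset > len(seq1):
        return None  # gap in coverage
    merged = [""] * expected_core
    quals = np.zeros(expected_core, dtype=np.uint8)
    q1, q2 = phred(qual1), phred(qual2)
    mismatches = overlap = 0
    for pos in range(expected_core):
        a = seq1[pos] if pos < len(seq1) else None
        j = pos - offset
        b = seq2[j] if 0 <= j < len(seq2) else None
        if a is None and b is None:
            return None
        if a is not None and b is not None:
            overlap += 1
            if a != b:
                mismatches += 1
            if q1[pos] >= q2[j]:
                merged[pos], quals[pos] = a, q1[pos]
            else:
                merged[pos], quals[pos] = b, q2[j]
        elif a is not None:
            merged[pos], quals[pos] = a, q1[pos]
        else:
            merged[pos], quals[pos] = b, q2[j]
    if overlap == 0 or mismatches / overlap > 1 - MIN_OVERLAP_IDENTITY:
        return None
    return "".join(merged), "".join(chr(q + 33) for q in quals)


def filter_and_trim(seq: str, design: BarcodeDesign,
                    qual: str | None = None,
                    min_quality: int = MIN_QUALITY) -> tuple[str | None, str | None]:
    """Excise the 42-nt clustering sequence from a merged read.

    Locates the configured PAM* primer context (the first seven bases of the
    lead), then slices the clustering window at its fixed offset. Returns
    ``(sequence, None)`` on success or ``(None, reason)`` on rejection with
    reason in {no_primer, bad_length, low_quality}.
    """
    primer = design.lead[:7]
    i = seq.find(primer)
    if i < 0:
        return None, "no_primer"
    start = i + design.clustering_offset
    window = seq[start:start + design.clustering_length]
    if len(window) != design.clustering_length or len(seq) - i != design.core_length:
        return None, "bad_length"
    if qual is not None:
        q = phred(qual[start:start + design.clustering_length])
        if (q < min_quality).any():
            return None, "low_quality"
    return window, None


def tally_pileups(sequences: Iterable[str], sample: str = "sample",
                  rejected: Counter | None = None) -> SamplePileup:
    """Exact multiset count of equal-length clustering sequences."""
    counts: Counter = Counter()
    length = None
    for seq in sequences:
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise InvalidInputError("clustering sequences must be equal length")
        counts[seq] += 1
    pileup = SamplePileup(sample, dict(counts),
                          accepted=sum(counts.values()),
                          rejected=rejected or Counter())
    return pileup


def process_reads(reads: Iterable[str | tuple[str, str]], design: BarcodeDesign,
                  sample: str = "sample") -> SamplePileup:
    """Trim + quality-filter + tally merged reads into a pileup."""
    rejected: Counter = Counter()

    def gen() -> Iterator[str]:
        for r in reads:
            seq, qual = (r, None) if isinstance(r, str) else r
            window, reason = filter_and_trim(seq, design, qual)
            if window is None:
                rejected[reason] += 1
            else:
                yield window

    pileup = tally_pileups(gen(), sample=sample, rejected=rejected)
    return pileup


def estimate_error_rate(pileup: SamplePileup, design: BarcodeDesign) -> float:
    """Residual per-base error rate from the two invariant 7-nt flanks.

    Every mismatch at the 14 flank positions is an error; the estimate is
    the read-count-weighted mismatch fraction over all flank bases.
    """
    up, dn = design.upstream_flank, design.downstream_flank
    n_flank = len(up) + len(dn)
    L = design.clustering_length
    mismatches = 0
    total = 0
    for seq, n in pileup.counts.items():
        if len(seq) != L:
            raise InvalidInputError("pileup sequence length mismatch")
        d = sum(a != b for a, b in zip(seq[:7], up))
        d += sum(a != b for a, b in zip(seq[L - 7:], dn))
        mismatches += d * n
        total += n_flank * n
    if total == 0:
        raise InvalidInputError("empty pileup: no flank bases")
    return mismatches / total
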