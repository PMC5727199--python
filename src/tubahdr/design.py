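"""Kras HDR allele space: amplicon layout, variant enumeration, read parsing.

The experimental system installs, by homology-directed repair at the
endogenous *Kras* locus, one of twelve non-synonymous single-nucleotide
substitutions at codon 12 or 13 (or the wild-type codons, as a control)
together with a random 8-nucleotide barcode written into degenerate
("wobble") positions of a 22-nt region adjacent to the mutated codons.
Three fixed *anchor* bases inside that region differ from wild type in
every HDR allele and distinguish HDR alleles from the native locus.

This module defines the amplicon geometry (:class:`BarcodeDesign`), the
allele classes (:func:`enumerate_variants`, :class:`KrasAllele`), exact
parsing of a merged 60-nt amplicon core into a ``(variant, barcode)`` pair
(:func:`parse_read`), and two sequence-level scores used in the analysis:
a codon-usage score over the barcoded region and pairwise protein identity.

The default design is synthetic-but-consistent: the restricted wobble
alphabets were chosen so that the barcode space has exactly 24,576 members
described by 21 free per-position frequency parameters (six 4-letter
positions, one 3-letter, one 2-letter: 6*3 + 2 + 1 = 21). Every element of
the geometry can be overridden through a YAML/JSON config.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from typing import Iterator

import yaml
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"

#: 1-qualified amino-acid positions of the two mutated codons.
CODON12_RESIDUE = 12
CODON13_RESIDUE = 13


class InvalidInputError(ValueError):
    """Raised for malformed sequences or inconsistent arguments."""


class ConfigError(ValueError):
    """Raised for invalid design / table configuration."""


def translate_codon(codon: str) -> str:
    if len(codon) != 3 or any(c not in NUCLEOTIDES for c in codon):
        raise InvalidInputError(f"not a DNA codon: {codon!r}")
    return str(Seq(codon).translate())


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Barcode / amplicon design
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BarcodeDesign:
    """Layout of the 60-nt amplicon core.

    Core layout (1-based)::

        1..16   lead (PAM* context; last 7 nt = invariant upstream flank)
        17..19  codon 12          22..43  44..50            51..59
        20..22  codon 13          barcoded downstream flank  trailing
                                  region   (7 nt invariant)  context

    Within the 22-nt barcoded region, ``wobble_positions`` (1-based, region
    coordinates) carry the random barcode, ``anchor_positions`` carry fixed
    bases that differ from the wild-type sequence, and every remaining base
    equals wild type.
    """

    lead: str = "AGTAGTCGTTGGAGCT"
    codon12_wt: str = "GGT"
    codon13_wt: str = "GGC"
    region_wt: str = "GTAGGCAAGAGCGCCTTGACGA"
    anchor_positions: tuple[int, ...] = (2, 11, 20)
    anchor_bases: tuple[str, ...] = ("A", "C", "T")
    wobble_positions: tuple[int, ...] = (1, 4, 7, 10, 13, 16, 19, 22)
    wobble_alphabets: tuple[str, ...] = (
        "ACGT", "ACGT", "ACGT", "ACGT", "ACGT", "ACGT", "ACG", "AT",
    )
    downstream_flank: str = "TACAGCT"
    tail: str = "AATTCAGAA"

    def __post_init__(self) -> None:
        if len(self.region_wt) != self.region_length:
            raise ConfigError("region_wt must be 22 nt")
        if len(self.downstream_flank) != 7 or len(self.lead) < 7:
            raise ConfigError("flanks must be 7 nt")
        if len(self.wobble_positions) != len(self.wobble_alphabets):
            raise ConfigError("one alphabet per wobble position")
        for alph in self.wobble_alphabets:
            if not alph or any(c not in NUCLEOTIDES for c in alph):
                raise ConfigError(f"invalid wobble alphabet {alph!r}")
            if list(alph) != sorted(set(alph)):
                raise ConfigError(f"alphabet must be sorted, unique: {alph!r}")
        if set(self.anchor_positions) & set(self.wobble_positions):
            raise ConfigError("anchor cannot sit on a wobble position")
        for pos, base in zip(self.anchor_positions, self.anchor_bases):
            if base == self.region_wt[pos - 1]:
                raise ConfigError(f"anchor at region position {pos} equals wild type")
        for seq in (self.lead, self.codon12_wt, self.codon13_wt,
                    self.region_wt, self.downstream_flank, self.tail):
            if any(c not in NUCLEOTIDES for c in seq):
                raise ConfigError(f"non-ACGT base in design sequence {seq!r}")

    # -- geometry -----------------------------------------------------------

    region_length: int = dataclasses.field(default=22, init=False, repr=False)

    @property
    def upstream_flank(self) -> str:
        """The 7 invariant nt immediately 5' of codon 12."""
        return self.lead[-7:]

    @property
    def core_length(self) -> int:
        return len(self.lead) + 6 + self.region_length + len(self.downstream_flank) + len(self.tail)

    @property
    def codon12_offset(self) -> int:
        """0-based offset of codon 12 within the core."""
        return len(self.lead)

    @property
    def region_offset(self) -> int:
        return len(self.lead) + 6

    @property
    def clustering_offset(self) -> int:
        """0-based core offset of the 42-nt clustering window."""
        return len(self.lead) - 7

    @property
    def clustering_length(self) -> int:
        return 7 + 6 + self.region_length + 7

    @property
    def barcode_length(self) -> int:
        return len(self.wobble_positions)

    @property
    def barcode_space_size(self) -> int:
        return math.prod(len(a) for a in self.wobble_alphabets)

    @property
    def free_parameters(self) -> int:
        """Free parameters of an independent per-position frequency model."""
        return sum(len(a) - 1 for a in self.wobble_alphabets)

    @property
    def wt_wobble_bases(self) -> str:
        """Wild-type bases at the eight wobble positions ("minimal" barcode)."""
        return "".join(self.region_wt[p - 1] for p in self.wobble_positions)

    # -- sequence assembly --------------------------------------------------

    @property
    def region_invariant(self) -> dict[int, str]:
        """Region position (1-based) -> fixed base, for non-wobble positions."""
        fixed = {}
        anchors = dict(zip(self.anchor_positions, self.anchor_bases))
        for pos in range(1, self.region_length + 1):
            if pos in self.wobble_positions:
                continue
            fixed[pos] = anchors.get(pos, self.region_wt[pos - 1])
        return fixed

    def region_for_barcode(self, barcode: str) -> str:
        if len(barcode) != self.barcode_length:
            raise InvalidInputError("barcode length mismatch")
        bases = list(self.region_wt)
        for pos, base in self.region_invariant.items():
            bases[pos - 1] = base
        for pos, base, alph in zip(self.wobble_positions, barcode, self.wobble_alphabets):
            if base not in alph:
                raise InvalidInputError(
                    f"barcode base {base!r} not in alphabet {alph!r}")
            bases[pos - 1] = base
        return "".join(bases)

    @property
    def minimal_region(self) -> str:
        """Anchors installed, wild-type bases at all wobble positions."""
        return self.region_for_barcode(self.wt_wobble_bases)

    def synthesize_core(self, variant_label: str, barcode: str) -> str:
        """Error-free 60-nt amplicon core for an allele. Inverse of parse_read."""
        codon12, codon13 = variant_codons(self)[variant_label]
        return (self.lead + codon12 + codon13 + self.region_for_barcode(barcode)
                + self.downstream_flank + self.tail)

    def iter_barcodes(self) -> Iterator[str]:
        """All barcodes, lexicographic order (alphabets are kept sorted)."""
        for combo in itertools.product(*self.wobble_alphabets):
            yield "".join(combo)

    def barcode_from_index(self, index: int) -> str:
        if not 0 <= index < self.barcode_space_size:
            raise InvalidInputError("barcode index out of range")
        out = []
        for alph in reversed(self.wobble_alphabets):
            index, r = divmod(index, len(alph))
            out.append(alph[r])
        return "".join(reversed(out))

    def barcode_index(self, barcode: str) -> int:
        idx = 0
        for base, alph in zip(barcode, self.wobble_alphabets):
            idx = idx * len(alph) + alph.index(base)
        return idx

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("region_length", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BarcodeDesign":
        kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "BarcodeDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: The normalization-control (spike-in) allele: a G12V clone with a known
#: barcode, added to every bulk lung sample at a known cell number.
SPIKEIN_VARIANT = "G12V"
SPIKEIN_BARCODE = "CGGGAAGT"
SPIKEIN_CELLS = 5e5


# ---------------------------------------------------------------------------
# Variant enumeration
# ---------------------------------------------------------------------------

def enumerate_variants(codon12_wt: str = "GGT", codon13_wt: str = "GGC") -> list[str]:
    """All non-synonymous single-nucleotide substitutions of the two codons.

    Returns sorted labels like ``G12D``; wild type is excluded. For the
    default Gly codons this yields exactly 12 variants (third-position
    substitutions are synonymous and drop out).
    """
    return sorted(_variant_map(codon12_wt, codon13_wt))


def _variant_map(codon12_wt: str, codon13_wt: str) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    for residue, codon_wt, other_wt, first in (
        (CODON12_RESIDUE, codon12_wt, codon13_wt, True),
        (CODON13_RESIDUE, codon13_wt, codon12_wt, False),
    ):
        wt_aa = translate_codon(codon_wt)
        for pos in range(3):
            for nuc in NUCLEOTIDES:
                if nuc == codon_wt[pos]:
                    continue
                mut = codon_wt[:pos] + nuc + codon_wt[pos + 1:]
                aa = translate_codon(mut)
                if aa == wt_aa:
                    continue
                label = f"{wt_aa}{residue}{aa}"
                if label in out:
                    raise ConfigError(f"ambiguous variant label {label}")
                out[label] = (mut, other_wt) if first else (other_wt, mut)
    return out


def variant_codons(design: BarcodeDesign) -> dict[str, tuple[str, str]]:
    """Label -> (codon12, codon13) for all 13 allele classes (incl. WT)."""
    m = _variant_map(design.codon12_wt, design.codon13_wt)
    m["WT"] = (design.codon12_wt, design.codon13_wt)
    return m


def enumerate_barcodes(design: BarcodeDesign) -> tuple[int, Iterator[str]]:
    """Barcode-space size and a lexicographic iterator over all barcodes."""
    return design.barcode_space_size, design.iter_barcodes()


# ---------------------------------------------------------------------------
# Alleles and parsing
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class KrasAllele:
    variant_label: str
    codon12: str
    codon13: str
    barcode: str

    def validate(self, design: BarcodeDesign) -> None:
        codons = variant_codons(design)
        if self.variant_label not in codons:
            raise InvalidInputError(f"unknown variant {self.variant_label}")
        if codons[self.variant_label] != (self.codon12, self.codon13):
            raise InvalidInputError("codons inconsistent with variant label")
        for base, alph in zip(self.barcode, design.wobble_alphabets):
            if base not in alph:
                raise InvalidInputError("barcode base outside its alphabet")


def spikein_allele(design: BarcodeDesign) -> KrasAllele:
    c12, c13 = variant_codons(design)[SPIKEIN_VARIANT]
    return KrasAllele(SPIKEIN_VARIANT, c12, c13, SPIKEIN_BARCODE)


@dataclasses.dataclass(frozen=True)
class ParsedRead:
    variant: str | None
    barcode: str | None
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.reason is None


def parse_clustering_sequence(seq: str, design: BarcodeDesign) -> ParsedRead:
    """Parse the 42-nt clustering window (flank+codons+region+flank)."""
    if len(seq) != design.clustering_length:
        return ParsedRead(None, None, "bad_length")
    flank_up = seq[:7]
    codon12 = seq[7:10]
    codon13 = seq[10:13]
    region = seq[13:13 + design.region_length]
    flank_dn = seq[13 + design.region_length:]
    if flank_up != design.upstream_flank or flank_dn != design.downstream_flank:
        return ParsedRead(None, None, "anchor_mismatch")
    for pos, base in design.region_invariant.items():
        if region[pos - 1] != base:
            return ParsedRead(None, None, "anchor_mismatch")
    by_codons = {v: k for k, v in variant_codons(design).items()}
    variant = by_codons.get((codon12, codon13))
    if variant is None:
        return ParsedRead(None, None, "unknown_codon")
    barcode = "".join(region[p - 1] for p in design.wobble_positions)
    for base, alph in zip(barcode, design.wobble_alphabets):
        if base not in alph:
            return ParsedRead(None, None, "bad_barcode_base")
    return ParsedRead(variant, barcode)


def parse_read(seq: str, design: BarcodeDesign) -> ParsedRead:
    """Parse a merged, trimmed amplicon core into (variant, barcode).

    All invariant bases (lead, non-wobble region bases including the three
    anchors, downstream flank, trailing context) must match exactly; codons
    12/13 must decode to one of the 13 allele classes; every barcode base
    must belong to its position's alphabet. Failures return a rejection with
    a reason code rather than raising.
    """
    if any(c not in NUCLEOTIDES for c in seq):
        raise InvalidInputError("non-ACGT character in read")
    if len(seq) != design.core_length:
        return ParsedRead(None, None, "bad_length")
    o = design.codon12_offset
    if seq[:o] != design.lead:
        return ParsedRead(None, None, "anchor_mismatch")
    end = design.region_offset + design.region_length + 7
    if seq[end:] != design.tail:
        return ParsedRead(None, None, "anchor_mismatch")
    w = design.clustering_offset
    return parse_clustering_sequence(seq[w:w + design.clustering_length], design)


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CodonUsageTable:
    """64-entry codon -> usage frequency (fraction) table."""

    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        codons = {"".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)}
        if set(self.frequencies) != codons:
            raise ConfigError("codon usage table must have exactly the 64 codons")
        if any(f < 0 for f in self.frequencies.values()):
            raise ConfigError("codon frequencies must be non-negative")

    def __getitem__(self, codon: str) -> float:
        try:
            return self.frequencies[codon]
        except KeyError:
            raise ConfigError(f"codon {codon!r} absent from table") from None

    @classmethod
    def uniform(cls) -> "CodonUsageTable":
        return cls({"".join(c): 1 / 64
                    for c in itertools.product(NUCLEOTIDES, repeat=3)})

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageTable":
        freqs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, freq = line.split("\t")[:2]
                freqs[codon.upper().replace("U", "T")] = float(freq)
        return cls(freqs)

    def to_json(self) -> str:
        return json.dumps(self.frequencies, sort_keys=True)


def _codons_overlapping_region(design: BarcodeDesign, core: str) -> list[str]:
    # The reading frame of the core starts one base in (the lead opens with
    # the final base of the preceding codon); region bounds in 0-based core
    # coordinates are [region_offset, region_offset + 22).
    start, stop = design.region_offset, design.region_offset + design.region_length
    out = []
    for s in range(1, len(core) - 2, 3):
        if s + 3 > start and s < stop:
            out.append(core[s:s + 3])
    return out


def codon_usage_score(allele: KrasAllele, design: BarcodeDesign,
                      table: CodonUsageTable) -> float:
    """Sum of codon-usage frequencies over codons overlapping the 22-nt region.

    The region is not codon-aligned, so codons partially overlapping it are
    included whole (8 codons under the default design).
    """
    allele.validate(design)
    core = design.synthesize_core(allele.variant_label, allele.barcode)
    return sum(table[c] for c in _codons_overlapping_region(design, core))


def codon_usage_score_wt(design: BarcodeDesign, table: CodonUsageTable) -> float:
    """Score of the unmodified wild-type locus (no anchors, WT wobbles)."""
    core = (design.lead + design.codon12_wt + design.codon13_wt
            + design.region_wt + design.downstream_flank + design.tail)
    return sum(table[c] for c in _codons_overlapping_region(design, core))


def codon_usage_score_minimal(design: BarcodeDesign, table: CodonUsageTable) -> float:
    """Score of the "minimal" HDR allele: anchors only, WT wobble bases."""
    return codon_usage_score(
        KrasAllele("WT", design.codon12_wt, design.codon13_wt,
                   design.wt_wobble_bases),
        design, table)


def codon_usage_log2fc(table: CodonUsageTable) -> dict[str, float]:
    """Per-codon log2(frequency / (1/64)); zero frequency maps to -inf."""
    out = {}
    for codon, freq in table.frequencies.items():
        out[codon] = math.log2(freq * 64) if freq > 0 else float("-inf")
    return out


# ---------------------------------------------------------------------------
# Ortholog comparison
# ---------------------------------------------------------------------------

def pairwise_identity(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """Position-wise identity of two equal-length, ungapped protein sequences.

    Returns ``(matches, length, percent)`` with percent rounded to an
    integer for reporting (183/188 -> 97).
    """
    if len(seq_a) != len(seq_b):
        raise InvalidInputError("sequences must have equal length")
    if not seq_a:
        raise InvalidInputError("empty sequences")
    matches = sum(a == b for a, b in zip(seq_a, seq_b))
    return matches, len(seq_a), round(100 * matches / len(seq_a))
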