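"""Trinucleotide mutational-signature arithmetic for KRAS codon 12/13.

Mutational signatures assign a probability to each of the 96
pyrimidine-centric substitution classes (the substituted base plus its 5'
and 3' neighbors, with purine-reference substitutions reverse-complemented
onto the pyrimidine strand). Summing the probabilities of tumor-extrinsic
signatures (e.g. the smoking-related and clock-like processes) over the 12
possible non-synonymous codon 12/13 substitutions, and normalizing within
those 12, approximates each mutation's relative induction frequency in the
cells of origin; observed human mutation spectra can then be divided by
these induction frequencies to compare oncogenic selection rather than
mutational supply.
"""

from __future__ import annotations

import dataclasses
import itertools
import re

import pandas as pd

from .design import ConfigError, InvalidInputError, translate_codon

_PYRIMIDINES = "CT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CLASS_RE = re.compile(r"^([ACGT])\[([CT])>([ACGT])\]([ACGT])$")


def all_context_classes() -> list[str]:
    """The 96 pyrimidine-centric substitution classes, sorted."""
    out = []
    for ref in "CT":
        for alt in "ACGT":
            if alt == ref:
                continue
            for five in "ACGT":
                for three in "ACGT":
                    out.append(f"{five}[{ref}>{alt}]{three}")
    return sorted(out)


@dataclasses.dataclass
class SignatureTable:
    """Per-signature probabilities over the 96 trinucleotide classes."""

    probabilities: pd.DataFrame     # index: class label, columns: signatures

    def __post_init__(self) -> None:
        expected = set(all_context_classes())
        if set(self.probabilities.index) != expected:
            raise ConfigError("signature table must cover exactly the 96 classes")
        if (self.probabilities < 0).any().any():
            raise ConfigError("signature probabilities must be non-negative")

    @property
    def signatures(self) -> list[str]:
        return list(self.probabilities.columns)

    @classmethod
    def from_tsv(cls, path, context_col: str = "context") -> "SignatureTable":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index(context_col)
        return cls(df.astype(float))

    def lookup(self, label: str, signatures: list[str]) -> float:
        if label not in self.probabilities.index:
            raise InvalidInputError(f"class {label} missing from table")
        return float(self.probabilities.loc[label, signatures].sum())


def mutation_context(cds: str, position: int, alt: str) -> str:
    """96-class label of a substitution at a 1-based CDS position.

    If the reference base is a purine, substitution and context are
    reverse-complemented onto the pyrimidine strand before labeling.
    """
    if position < 2 or position > len(cds) - 1:
        raise InvalidInputError("position must have both neighbors")
    ref = cds[position - 1]
    if alt == ref:
        raise InvalidInputError("alt equals reference base")
    five, three = cds[position - 2], cds[position]
    if ref not in _PYRIMIDINES:
        five, ref, alt, three = (_COMPLEMENT[three], _COMPLEMENT[ref],
                                 _COMPLEMENT[alt], _COMPLEMENT[five])
    return f"{five}[{ref}>{alt}]{three}"


def codon_mutations(cds: str, residues: tuple[int, ...] = (12, 13)) -> dict[str, tuple[int, str]]:
    """Non-synonymous single-nt substitutions in the given codons.

    Returns label (e.g. ``G12D``) -> (1-based CDS position, alt base).
    """
    out: dict[str, tuple[int, str]] = {}
    for residue in residues:
        start = (residue - 1) * 3
        codon = cds[start:start + 3]
        wt_aa = translate_codon(codon)
        for i in range(3):
            for alt in "ACGT":
                if alt == codon[i]:
                    continue
                mut = codon[:i] + alt + codon[i + 1:]
                aa = translate_codon(mut)
                if aa == wt_aa:
                    continue
                out[f"{wt_aa}{residue}{aa}"] = (start + i + 1, alt)
    return out


def relative_induction(cds: str, table: SignatureTable,
                       signatures: list[str],
                       residues: tuple[int, ...] = (12, 13)) -> pd.Series:
    """Relative induction frequency of the codon 12/13 mutations.

    For each of the 12 mutations, the included signatures' probabilities of
    its trinucleotide class are summed; the 12 sums are normalized to one.
    """
    muts = codon_mutations(cds, residues)
    raw = {}
    for label, (pos, alt) in muts.items():
        raw[label] = table.lookup(mutation_context(cds, pos, alt), signatures)
    total = sum(raw.values())
    if total <= 0:
        raise InvalidInputError("all induction probabilities are zero")
    return pd.Series(raw).sort_index() / total


def normalize_prevalence(observed: pd.Series, induction: pd.Series) -> pd.Series:
    """Mutation-rate-adjusted relative prevalence.

    adjusted_v = count_v / induction_v, renormalized to sum to one; an
    observed mutation with zero induction probability is an error.
    """
    observed = observed.astype(float)
    if (observed < 0).any():
        raise InvalidInputError("negative observed counts")
    bad = observed[(observed > 0) & (induction.reindex(observed.index) <= 0)]
    if len(bad):
        raise InvalidInputError(
            f"zero induction frequency for observed mutations: {list(bad.index)}")
    adjusted = observed / induction.reindex(observed.index)
    adjusted = adjusted.fillna(0.0)
    total = adjusted.sum()
    if total <= 0:
        raise InvalidInputError("nothing observed")
    return adjusted / total
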