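"""Synthetic plasmid pools, mouse cohorts and amplicon reads, with ground truth.

The generator emulates the statistical structure the analysis assumes:

* a plasmid library in which the wild-type allele is represented ~4x higher
  than each of the 12 mutant alleles, and barcodes are drawn with mild,
  independent per-position nucleotide skew (as would arise from uneven
  nucleotide concentrations during synthesis);
* per-mouse tumor cohorts in which each tumor's variant is drawn
  proportionally to (library representation x per-variant oncogenicity
  multiplier), its barcode from the library's conditional barcode
  distribution (with replacement, so barcode collisions arise naturally),
  and its size from a heavy-tailed lognormal;
* pre-merged 60-nt amplicon reads with a known spike-in control and iid
  per-base substitution errors (~1 per 10^4 bases by default).

Everything is deterministic under a fixed seed and serializes its ground
truth to TSV for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import (
    BarcodeDesign, ConfigError, InvalidInputError, KrasAllele,
    SPIKEIN_CELLS, enumerate_variants, spikein_allele, variant_codons,
)

_ENC = {b: i for i, b in enumerate("ACGT")}
_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Defaults: the study conditions the generator emulates
# ---------------------------------------------------------------------------

#: Wild type is deliberately over-represented ~4x in the pool.
DEFAULT_WT_FACTOR = 4.0

#: Mild per-position nucleotide skew (synthesis-concentration imbalance).
#: Keyed by alphabet size; rotated across positions so no two positions
#: share exactly the same marginal.
_SKEW_BY_SIZE = {
    4: (0.30, 0.27, 0.23, 0.20),
    3: (0.40, 0.33, 0.27),
    2: (0.55, 0.45),
}

#: Per-base substitution error rate after read merging (~1 per 10^4 bases).
DEFAULT_ERROR_RATE = 1e-4

#: Lognormal tumor sizes: median 2e5 cells, sigma of 0.5 in log10 units,
#: truncated below at 1e3 cells.
DEFAULT_SIZE_MEDIAN = 2e5
DEFAULT_SIZE_SIGMA_LOG10 = 0.5
DEFAULT_SIZE_FLOOR = 1e3

#: Sequencing depth relative to cell number (reads per cell): puts the
#: 5e5-cell spike-in at ~200 reads and a median tumor at ~80 reads.
DEFAULT_READS_PER_CELL = 4e-4


def default_skew(design: BarcodeDesign) -> list[dict[str, float]]:
    """Default per-position nucleotide weights for the pool simulation."""
    out = []
    for i, alph in enumerate(design.wobble_alphabets):
        w = _SKEW_BY_SIZE[len(alph)]
        w = w[i % len(w):] + w[:i % len(w)]   # rotate per position
        out.append(dict(zip(alph, w)))
    return out


@dataclasses.dataclass(frozen=True)
class ErrorModel:
    """Uniform iid per-base substitution model."""

    rate: float = DEFAULT_ERROR_RATE

    def __post_init__(self) -> None:
        if not 0 <= self.rate < 0.25:
            raise ConfigError("error rate must lie in [0, 0.25)")


# ---------------------------------------------------------------------------
# Plasmid pool
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlasmidPool:
    """Read counts of the vector library: one row per (variant, barcode)."""

    counts: pd.DataFrame  # columns: variant, barcode, reads

    def __post_init__(self) -> None:
        expected = ["variant", "barcode", "reads"]
        if list(self.counts.columns) != expected:
            raise ConfigError(f"pool table must have columns {expected}")
        if (self.counts["reads"] < 0).any():
            raise ConfigError("pool read counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(self.counts["reads"].sum())

    def variant_totals(self) -> pd.Series:
        return self.counts.groupby("variant")["reads"].sum()

    def barcode_totals(self) -> pd.Series:
        """Reads per barcode, summed over variants."""
        return self.counts.groupby("barcode")["reads"].sum()

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PlasmidPool":
        return cls(pd.read_csv(path, sep="\t",
                               dtype={"variant": str, "barcode": str,
                                      "reads": np.int64}))


def _sample_barcode_indices(design: BarcodeDesign,
                            skew: Sequence[dict[str, float]],
                            n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n barcodes as lexicographic indices under per-position weights."""
    idx = np.zeros(n, dtype=np.int64)
    for alph, weights in zip(design.wobble_alphabets, skew):
        w = np.array([weights.get(b, 0.0) for b in alph], dtype=float)
        if w.sum() <= 0:
            raise ConfigError("all-zero weight vector for a wobble position")
        if (w < 0).any():
            raise ConfigError("negative nucleotide weight")
        w = w / w.sum()
        draws = rng.choice(len(alph), size=n, p=w)
        idx = idx * len(alph) + draws
    return idx


def simulate_plasmid_pool(design: BarcodeDesign,
                          skew: Sequence[dict[str, float]] | None = None,
                          wt_factor: float = DEFAULT_WT_FACTOR,
                          depth: int = 1_000_000,
                          seed: int | np.random.Generator = 0) -> PlasmidPool:
    """Simulate library sequencing of the plasmid pool.

    Variant marginals are proportional to ``wt_factor`` for WT and 1 for
    each mutant; barcodes follow independent per-position weights.
    """
    if depth <= 0:
        raise ConfigError("depth must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if skew is None:
        skew = default_skew(design)
    variants = enumerate_variants(design.codon12_wt, design.codon13_wt)
    labels = ["WT"] + variants
    probs = np.array([wt_factor] + [1.0] * len(variants))
    probs = probs / probs.sum()
    per_variant = rng.multinomial(depth, probs)
    frames = []
    for label, n in zip(labels, per_variant):
        if n == 0:
            continue
        idx = _sample_barcode_indices(design, skew, int(n), rng)
        counts = np.bincount(idx, minlength=design.barcode_space_size)
        nz = np.nonzero(counts)[0]
        frames.append(pd.DataFrame({
            "variant": label,
            "barcode": [design.barcode_from_index(i) for i in nz],
            "reads": counts[nz],
        }))
    df = pd.concat(frames, ignore_index=True)
    return PlasmidPool(df.sort_values(["variant", "barcode"],
                                      ignore_index=True))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TrueTumor:
    variant: str
    barcode: str
    cells: float


@dataclasses.dataclass
class MouseTruth:
    mouse_id: str
    genotype: str
    tumors: list[TrueTumor]


@dataclasses.dataclass
class TruthSet:
    """Ground truth of a simulated cohort."""

    mice: list[MouseTruth]
    spikein_cells: float = SPIKEIN_CELLS
    dilution: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m.mouse_id, m.genotype, t.variant, t.barcode, t.cells)
            for m in self.mice for t in m.tumors
        ]
        return pd.DataFrame(rows, columns=["mouse", "genotype", "variant",
                                           "barcode", "cells"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


#: Per-variant oncogenicity multipliers used for recovery experiments;
#: they span ~0-10 with a near-null wild type (the study found few WT
#: tumors above threshold).
DEFAULT_MULTIPLIERS = {
    "WT": 0.25,
    "G12D": 10.0, "G12V": 8.0, "G13V": 6.0, "G12C": 5.0, "G13D": 4.0,
    "G12A": 3.0, "G12R": 2.0, "G12S": 1.5, "G13R": 1.0, "G13A": 0.5,
    "G13C": 0.3, "G13S": 0.2,
}


def _truncated_lognormal(n: int, median: float, sigma_log10: float,
                         floor: float, rng: np.random.Generator) -> np.ndarray:
    mu = math.log(median)
    sigma = sigma_log10 * math.log(10)
    out = rng.lognormal(mu, sigma, size=n)
    while True:
        bad = out < floor
        if not bad.any():
            return out
        out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))


def simulate_cohort(pool: PlasmidPool,
                    multipliers: dict[str, float] | None = None,
                    mean_tumors_per_mouse: float = 150.0,
                    size_median: float = DEFAULT_SIZE_MEDIAN,
                    size_sigma_log10: float = DEFAULT_SIZE_SIGMA_LOG10,
                    size_floor: float = DEFAULT_SIZE_FLOOR,
                    n_mice: int = 15,
                    genotype: str = "PT;H11-Cas9",
                    seed: int | np.random.Generator = 0) -> TruthSet:
    """Simulate per-mouse tumors under a selection model.

    Each tumor's variant is drawn proportional to pool representation times
    its oncogenicity multiplier; its barcode is drawn with replacement from
    the pool's conditional barcode distribution (so two tumors can collide
    on a barcode); sizes are iid truncated lognormal.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if multipliers is None:
        multipliers = DEFAULT_MULTIPLIERS
    if any(v < 0 for v in multipliers.values()):
        raise ConfigError("multipliers must be non-negative")
    totals = pool.variant_totals()
    labels = [v for v in totals.index if multipliers.get(v, 0.0) > 0]
    weights = np.array([totals[v] * multipliers[v] for v in labels], dtype=float)
    if not labels or weights.sum() <= 0:
        raise ConfigError("all variant weights are zero")
    weights = weights / weights.sum()

    # conditional barcode distribution per variant
    per_variant = {
        v: (g["barcode"].to_numpy(),
            g["reads"].to_numpy(dtype=float) / g["reads"].sum())
        for v, g in pool.counts.groupby("variant")
    }

    mice = []
    for m in range(n_mice):
        k = int(rng.poisson(mean_tumors_per_mouse))
        variants = rng.choice(len(labels), size=k, p=weights)
        sizes = _truncated_lognormal(k, size_median, size_sigma_log10,
                                     size_floor, rng)
        tumors = []
        for vi, cells in zip(variants, sizes):
            label = labels[vi]
            bcs, probs = per_variant[label]
            bc = bcs[rng.choice(len(bcs), p=probs)]
            tumors.append(TrueTumor(label, bc, float(cells)))
        mice.append(MouseTruth(f"mouse{m:02d}", genotype, tumors))
    return TruthSet(mice)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _apply_errors(reads: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0 or reads.size == 0:
        return reads
    lut = np.zeros(256, dtype=np.uint8)
    for b, i in _ENC.items():
        lut[ord(b)] = i
    reads = reads.copy()
    chunk = max(1, 50_000_000 // max(reads.shape[1], 1))
    for lo in range(0, reads.shape[0], chunk):
        block = reads[lo:lo + chunk]
        mask = rng.random(block.shape) < rate
        n = int(mask.sum())
        if n == 0:
            continue
        codes = lut[block[mask]]
        codes = (codes + rng.integers(1, 4, size=n)) % 4   # any of the 3 others
        block[mask] = _DEC[codes]
    return reads


def simulate_sample_reads(mouse: MouseTruth, design: BarcodeDesign,
                          error_model: ErrorModel | None = None,
                          reads_per_cell: float = DEFAULT_READS_PER_CELL,
                          include_spikein: bool = True,
                          spikein_cells: float = SPIKEIN_CELLS,
                          seed: int | np.random.Generator = 0,
                          ) -> tuple[list[str], dict]:
    """Emit pre-merged 60-nt reads for one bulk sample.

    The total read count is ``round(total cells x reads_per_cell)`` and is
    split across lesions (and the spike-in) multinomially in proportion to
    cell number. Returns the reads and a manifest.
    """
    if reads_per_cell <= 0:
        raise ConfigError("reads_per_cell must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if error_model is None:
        error_model = ErrorModel()
    lesions: list[tuple[str, str, float]] = [
        (t.variant, t.barcode, t.cells) for t in mouse.tumors
    ]
    if include_spikein:
        spike = spikein_allele(design)
        lesions.append((spike.variant_label, spike.barcode, spikein_cells))
    cells = np.array([c for _, _, c in lesions], dtype=float)
    total_reads = int(round(cells.sum() * reads_per_cell))
    counts = rng.multinomial(total_reads, cells / cells.sum())

    rows = []
    for (variant, barcode, _), n in zip(lesions, counts):
        if n == 0:
            continue
        core = _encode(design.synthesize_core(variant, barcode))
        rows.append(np.tile(core, (int(n), 1)))
    if rows:
        arr = np.concatenate(rows, axis=0)
        arr = _apply_errors(arr, error_model.rate, rng)
        reads = [bytes(row).decode() for row in arr]
    else:
        reads = []
    manifest = {
        "sample": mouse.mouse_id,
        "n_reads": len(reads),
        "reads_per_cell": reads_per_cell,
        "error_rate": error_model.rate,
        "spikein": include_spikein,
        "spikein_cells": spikein_cells if include_spikein else None,
    }
    return reads, manifest


def write_fastq(reads: Iterable[str], path, quality_char: str = "F") -> None:
    """Write reads as Sanger Phred+33 FASTQ with constant quality (Q37)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_paired_fastq(reads: Iterable[str], path_r1, path_r2,
                       read_length: int = 150,
                       quality_char: str = "F") -> None:
    """Optional paired mode: overlapping pairs for exercising the merger.

    R1 reads the fragment from the 5' end, R2 is the reverse complement
    from the 3' end; for a 60-nt fragment and 150-nt reads the pair fully
    overlaps, as in the sequencing design this emulates.
    """
    comp = str.maketrans("ACGT", "TGCA")
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for i, seq in enumerate(reads):
            r1 = seq[:read_length]
            r2 = seq[-read_length:].translate(comp)[::-1]
            f1.write(f"@read{i}/1\n{r1}\n+\n{quality_char * len(r1)}\n")
            f2.write(f"@read{i}/2\n{r2}\n+\n{quality_char * len(r2)}\n")


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Multi-region / metastasis truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MultiRegionTruth:
    """Region and metastasis samples with ground-truth lineage links."""

    samples: dict[str, list[TrueTumor]]
    roles: dict[str, str]                       # sample -> primary|metastasis
    lineage: list[tuple[str, str, str, str]]    # (src sample, dst sample, variant, barcode)


def simulate_multiregion(mouse: MouseTruth, n_regions: int = 3,
                         shared_fraction: float = 0.2,
                         n_mets: int = 2,
                         seed: int | np.random.Generator = 0) -> MultiRegionTruth:
    """Distribute one mouse's tumors over adjacent regions plus metastases.

    A ``shared_fraction`` of clones is placed into a second adjacent region
    (same variant-barcode pair, region-continuity ground truth); each
    metastasis copies the pair of a randomly chosen large primary clone.
    """
    if n_regions < 1:
        raise InvalidInputError("need at least one region")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    regions = {f"{mouse.mouse_id}.region{r}": [] for r in range(n_regions)}
    names = list(regions)
    lineage: list[tuple[str, str, str, str]] = []
    placement: list[tuple[str, TrueTumor]] = []
    for t in mouse.tumors:
        r = int(rng.integers(n_regions))
        regions[names[r]].append(t)
        placement.append((names[r], t))
        if n_regions > 1 and rng.random() < shared_fraction:
            r2 = (r + 1) % n_regions
            part = TrueTumor(t.variant, t.barcode, t.cells * float(rng.uniform(0.2, 0.8)))
            regions[names[r2]].append(part)
            lineage.append((names[r], names[r2], t.variant, t.barcode))
    roles = {name: "primary" for name in names}
    if mouse.tumors and n_mets > 0:
        sizes = np.array([t.cells for _, t in placement])
        for m in range(n_mets):
            src_name, src = placement[
                int(rng.choice(len(placement), p=sizes / sizes.sum()))]
            met_name = f"{mouse.mouse_id}.met{m}"
            met = TrueTumor(src.variant, src.barcode,
                            src.cells * float(rng.uniform(0.01, 0.2)))
            regions[met_name] = [met]
            roles[met_name] = "metastasis"
            lineage.append((src_name, met_name, src.variant, src.barcode))
    return MultiRegionTruth(regions, roles, lineage)
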