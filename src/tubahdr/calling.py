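"""Cluster read pileups into tumors and convert reads to cell numbers.

The denoiser is a deliberately simplified amplicon denoiser in the style of
divisive abundance-p-value clustering: the per-base error rate is fixed in
advance from the invariant flanks (so there is no error-model
self-consistency loop and no quality-score dependence), the expected count
of an error sequence at Hamming distance d from a cluster of A reads is

    lambda = A * (rate / 3) ** d

and a member sequence founds its own cluster when the probability of
seeing at least its read count under Poisson(lambda), conditioned on being
seen at all, falls below the abundance threshold omega_a (default 0.01).

Two post-processing steps mirror the study's bookkeeping: "shadow" clusters
within Hamming distance 1 of a cluster >= 10,000x larger are discarded, and
read counts are converted to absolute neoplastic-cell numbers against a
spike-in control of known cell number.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .design import (
    BarcodeDesign, ConfigError, InvalidInputError,
    SPIKEIN_CELLS, parse_clustering_sequence, spikein_allele,
)
from .reads import SamplePileup


@dataclasses.dataclass(frozen=True)
class DenoiseConfig:
    omega_a: float = 0.01
    error_rate: float = 1e-4
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.omega_a < 1:
            raise ConfigError("omega_a must lie in (0, 1)")
        if not 0 <= self.error_rate < 0.75:
            raise ConfigError("error rate out of range")


@dataclasses.dataclass
class TumorCall:
    sample: str
    variant: str
    barcode: str
    reads: int
    cells: float | None = None
    collision_factor: float = 1.0
    shadow_removed: bool = False
    below_cutoff: bool = False
    is_spikein: bool = False
    excluded_dissected: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.variant, self.barcode)


# ---------------------------------------------------------------------------
# Denoising
# ---------------------------------------------------------------------------

def abundance_pvalue(count: int, lam: float) -> float:
    """P(Poisson(lam) >= count | >= 1): the abundance p-value of a member."""
    if count < 1:
        return 1.0
    if lam <= 0:
        return 0.0
    tail = stats.poisson.sf(count - 1, lam)
    denom = -math.expm1(-lam)
    return float(min(1.0, tail / denom))


def _encode_seqs(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), len(seqs[0]))


def denoise(pileup: SamplePileup, cfg: DenoiseConfig) -> dict[str, int]:
    """Greedy divisive clustering of a pileup into inferred true sequences.

    Returns cluster center sequence -> aggregated read count. Reads are
    conserved: cluster counts sum to the pileup total.
    """
    if not pileup.counts:
        raise InvalidInputError("empty pileup")
    items = sorted(pileup.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    seqs = [s for s, _ in items]
    counts = np.array([n for _, n in items], dtype=np.int64)
    n_seq = len(seqs)
    enc = _encode_seqs(seqs)

    # log per-mismatch penalty; -inf when errors are impossible
    log_e3 = math.log(cfg.error_rate / 3) if cfg.error_rate > 0 else -math.inf

    centers = [0]                       # indices into seqs, most abundant first
    dist = np.empty((n_seq, 0), dtype=np.int32)
    dist = np.hstack([dist, _hamming_col(enc, 0)])

    for _ in range(cfg.max_iterations):
        assign, totals = _assign(dist, counts, centers, log_e3)
        # expected error count of each member under its assigned cluster
        d_assigned = dist[np.arange(n_seq), assign]
        if cfg.error_rate > 0:
            lam = totals[assign] * (cfg.error_rate / 3) ** d_assigned
        else:
            lam = np.where(d_assigned > 0, 0.0, totals[assign])
        pvals = np.ones(n_seq)
        center_set = set(centers)
        for i in range(n_seq):
            if i in center_set:
                continue
            pvals[i] = abundance_pvalue(int(counts[i]), float(lam[i]))
        worst = int(np.lexsort((np.arange(n_seq), -counts, pvals))[0])
        if pvals[worst] >= cfg.omega_a or worst in center_set:
            break
        centers.append(worst)
        dist = np.hstack([dist, _hamming_col(enc, worst)])
    assign, totals = _assign(dist, counts, centers, log_e3)
    return {seqs[c]: int(totals[j]) for j, c in enumerate(centers)}


def _hamming_col(enc: np.ndarray, idx: int) -> np.ndarray:
    return (enc != enc[idx]).sum(axis=1, dtype=np.int32).reshape(-1, 1)


def _assign(dist: np.ndarray, counts: np.ndarray, centers: list[int],
            log_e3: float) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively assign each sequence to its most likely cluster.

    Likelihood of membership is cluster_reads * (rate/3)^d, maximized in
    log space; cluster totals and assignments are alternated to a fixed
    point (they converge in a couple of rounds at realistic error rates).
    """
    n_seq = len(counts)
    totals = None
    assign = np.zeros(n_seq, dtype=np.int64)
    log_counts = np.log(counts[centers].astype(float))
    score = (log_counts[None, :]
             + (dist * log_e3 if not math.isinf(log_e3)
                else np.where(dist > 0, -np.inf, 0.0)))
    # a sequence always may stay with its own cluster if it is a center
    for j, c in enumerate(centers):
        score[c, :] = -np.inf
        score[c, j] = 0.0
    for _ in range(8):
        new_assign = np.argmax(score, axis=1)
        new_totals = np.zeros(len(centers))
        np.add.at(new_totals, new_assign, counts)
        if totals is not None and (new_assign == assign).all():
            break
        assign, totals = new_assign, new_totals
        with np.errstate(divide="ignore"):
            log_totals = np.where(totals > 0, np.log(np.maximum(totals, 1e-300)), -np.inf)
        score = (log_totals[None, :]
                 + (dist * log_e3 if not math.isinf(log_e3)
                    else np.where(dist > 0, -np.inf, 0.0)))
        for j, c in enumerate(centers):
            score[c, :] = -np.inf
            score[c, j] = 0.0
    return assign, totals


# ---------------------------------------------------------------------------
# Shadow removal
# ---------------------------------------------------------------------------

def remove_shadows(clusters: dict[str, int], ratio_threshold: float = 1e4,
                   distance: int = 1) -> tuple[dict[str, int], float]:
    """Drop clusters within Hamming ``distance`` of a vastly larger cluster.

    A cluster is a "shadow" when some other cluster is at least
    ``ratio_threshold`` times larger and its center differs by at most
    ``distance`` nucleotides; shadows are discarded (reads not reassigned).
    Returns the filtered clusters and the fraction of calls removed.
    """
    if not clusters:
        return {}, 0.0
    seqs = list(clusters)
    counts = np.array([clusters[s] for s in seqs], dtype=np.int64)
    enc = _encode_seqs(seqs)
    keep = np.ones(len(seqs), dtype=bool)
    order = np.argsort(-counts)
    for big in order:
        d = (enc != enc[big]).sum(axis=1)
        shadows = (d > 0) & (d <= distance) & (counts[big] >= ratio_threshold * counts)
        keep &= ~shadows
    kept = {s: int(c) for s, c, k in zip(seqs, counts, keep) if k}
    removed_fraction = 1 - keep.sum() / len(seqs)
    return kept, float(removed_fraction)


# ---------------------------------------------------------------------------
# Calls, spike-in normalization, cutoffs
# ---------------------------------------------------------------------------

def clusters_to_calls(clusters: dict[str, int], design: BarcodeDesign,
                      sample: str) -> tuple[list[TumorCall], dict[str, int]]:
    """Parse cluster centers into tumor calls; unparseable centers are dropped.

    Returns the calls and a counter of rejection reasons (reads in clusters
    whose center fails allele parsing, e.g. residual error sequences).
    """
    calls, dropped = [], {}
    for seq, n in sorted(clusters.items(), key=lambda kv: (-kv[1], kv[0])):
        parsed = parse_clustering_sequence(seq, design)
        if not parsed.ok:
            dropped[parsed.reason] = dropped.get(parsed.reason, 0) + n
            continue
        calls.append(TumorCall(sample, parsed.variant, parsed.barcode, int(n)))
    return calls, dropped


def normalize_to_spikein(calls: list[TumorCall], design: BarcodeDesign,
                         spikein_cells: float = SPIKEIN_CELLS) -> list[TumorCall]:
    """Convert read counts to absolute cell numbers against the spike-in.

    cells_t = reads_t / reads_spikein * spikein_cells. The spike-in call is
    flagged and must be excluded from downstream tumor sets by the caller.
    """
    spike = spikein_allele(design)
    spike_key = (spike.variant_label, spike.barcode)
    spikes = [c for c in calls if c.key == spike_key]
    if not spikes:
        raise InvalidInputError("no spike-in call in sample")
    spike_reads = max(c.reads for c in spikes)
    for call in calls:
        call.is_spikein = call.key == spike_key
        call.cells = call.reads / spike_reads * spikein_cells
    return calls


def apply_cutoff(calls: list[TumorCall], mode: str = "lung",
                 min_cells: float = 1e5) -> tuple[list[TumorCall], list[TumorCall]]:
    """Size cutoff: lung keeps cells > min_cells (strict); pancreas keeps
    reads > 2x the largest wild-type call in the sample."""
    tumors = [c for c in calls if not c.is_spikein]
    if mode == "lung":
        def keep(c: TumorCall) -> bool:
            if c.cells is None:
                raise InvalidInputError("lung cutoff requires absolute cells")
            return c.cells > min_cells
    elif mode == "pancreas":
        wt_reads = [c.reads for c in tumors if c.variant == "WT"]
        threshold = 2 * max(wt_reads) if wt_reads else 0

        def keep(c: TumorCall) -> bool:
            return c.reads > threshold
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    kept, dropped = [], []
    for c in tumors:
        (kept if keep(c) else dropped).append(c)
        c.below_cutoff = not keep(c)
    return kept, dropped


def mark_dissected(calls: list[TumorCall],
                   exclusions: set[tuple[str, str]]) -> list[TumorCall]:
    """Flag calls matching dissected tumors: excluded from size analyses
    but still counted in tumor-number analyses."""
    for c in calls:
        if c.key in exclusions:
            c.excluded_dissected = True
    return calls


def replicate_concordance(calls_a: list[TumorCall],
                          calls_b: list[TumorCall]) -> float:
    """R^2 of log10 cell numbers over shared (variant, barcode) pairs."""
    a = {c.key: c.cells for c in calls_a if not c.is_spikein}
    b = {c.key: c.cells for c in calls_b if not c.is_spikein}
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise InvalidInputError("need at least 3 shared pairs")
    xs = np.log10([a[k] for k in shared])
    ys = np.log10([b[k] for k in shared])
    r = stats.linregress(xs, ys).rvalue
    return float(r ** 2)


def calls_to_frame(calls: list[TumorCall]):
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(c) for c in calls])
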