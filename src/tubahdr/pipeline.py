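"""End-to-end orchestration: reads -> pileups -> calls -> statistics.

The full chain mirrors the analysis this package implements: process reads
into pileups, estimate the residual error rate from invariant flanks,
denoise into clusters, drop shadow artifacts, normalize to the spike-in,
exclude over-represented barcodes, collision-correct sizes per mouse,
apply the size cutoff, and summarize per-variant oncogenicity across mice.
`run_simulated_experiment` wires the synthetic generator into that chain
for parameter-recovery studies and is what the acceptance analysis runs.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from . import calling, collisions, reads as rp, simulate, stats
from .design import BarcodeDesign, InvalidInputError, SPIKEIN_CELLS


@dataclasses.dataclass
class SampleResult:
    sample: str
    calls: list[calling.TumorCall]          # collision-corrected, spike-in excluded
    kept: list[calling.TumorCall]           # above cutoff
    error_rate: float
    shadow_fraction: float
    collision: collisions.CollisionEstimate | None
    dropped_reads: dict[str, int]


@dataclasses.dataclass
class ExperimentResult:
    pool: simulate.PlasmidPool
    model: collisions.BarcodeFrequencyModel
    truth: simulate.TruthSet
    samples: list[SampleResult]
    summary: pd.DataFrame

    @property
    def counts_above_cutoff(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.samples:
            for c in s.kept:
                out[c.variant] = out.get(c.variant, 0) + 1
        return out

    def mean_collision_fraction(self) -> float:
        fr = [s.collision.total_expected_collisions / s.collision.n_total
              for s in self.samples
              if s.collision is not None and s.collision.n_total > 0]
        return float(np.mean(fr)) if fr else 0.0

    def mean_shadow_fraction(self) -> float:
        return float(np.mean([s.shadow_fraction for s in self.samples]))

    def mean_error_rate(self) -> float:
        return float(np.mean([s.error_rate for s in self.samples]))


def call_sample(read_seqs, design: BarcodeDesign, sample: str,
                mode: str = "lung",
                model: collisions.BarcodeFrequencyModel | None = None,
                min_cells: float = 1e5,
                spikein_cells: float = SPIKEIN_CELLS,
                omega_a: float = 0.01,
                error_rate: float | None = None) -> SampleResult:
    """Run one bulk sample through processing, denoising and calling.

    ``error_rate`` defaults to the flank-based estimate from the sample
    itself. In lung mode the spike-in is required, barcodes excluded by the
    frequency model are dropped, sizes are collision-corrected and the
    absolute cell cutoff applied; pancreas mode uses the internal
    WT-read-based cutoff on uncorrected read counts.
    """
    pileup = rp.process_reads(read_seqs, design, sample=sample)
    if not pileup.counts:
        raise InvalidInputError(f"sample {sample}: no reads accepted")
    est_rate = rp.estimate_error_rate(pileup, design)
    cfg = calling.DenoiseConfig(
        omega_a=omega_a,
        error_rate=est_rate if error_rate is None else error_rate)
    clusters = calling.denoise(pileup, cfg)
    clusters, shadow_fraction = calling.remove_shadows(clusters)
    calls, dropped = calling.clusters_to_calls(clusters, design, sample)

    collision_est = None
    if mode == "lung":
        calls = calling.normalize_to_spikein(calls, design, spikein_cells)
        tumors = [c for c in calls if not c.is_spikein]
        if model is not None:
            tumors = [c for c in tumors if c.barcode not in model.excluded]
            n_obs = len(tumors)
            if n_obs:
                collision_est = collisions.solve_total_tumors(n_obs, model)
                tumors, _ = collisions.correct_sizes(tumors, collision_est)
        kept, _ = calling.apply_cutoff(tumors, mode="lung", min_cells=min_cells)
        calls = tumors
    else:
        kept, _ = calling.apply_cutoff(calls, mode="pancreas")
    return SampleResult(sample, calls, kept, est_rate, shadow_fraction,
                        collision_est, dropped)


def run_simulated_experiment(
        n_mice: int = 15,
        multipliers: dict[str, float] | None = None,
        mean_tumors_per_mouse: float = 150.0,
        pool_depth: int = 1_000_000,
        reads_per_cell: float = simulate.DEFAULT_READS_PER_CELL,
        error_rate: float = simulate.DEFAULT_ERROR_RATE,
        min_cells: float = 1e5,
        exclusion_fraction: float = 0.10,
        trim_percentile: float = 98.0,
        n_boot: int = 1000,
        design: BarcodeDesign | None = None,
        seed: int = 0) -> ExperimentResult:
    """Simulate a lung cohort and analyze it end to end.

    Defaults mirror the study conditions the generator emulates: WT 4x
    over-represented in the pool, lognormal tumor sizes (median 2e5 cells),
    a 5e5-cell spike-in per sample, ~1e-4 per-base errors, and the
    100,000-cell tumor cutoff.
    """
    if design is None:
        design = BarcodeDesign()
    rng = np.random.default_rng(seed)
    pool = simulate.simulate_plasmid_pool(design, depth=pool_depth, seed=rng)
    model = collisions.fit_frequencies(pool, design)
    model = collisions.exclude_frequent(model, pool.barcode_totals(),
                                        exclusion_fraction)
    truth = simulate.simulate_cohort(
        pool, multipliers=multipliers, mean_tumors_per_mouse=mean_tumors_per_mouse,
        n_mice=n_mice, seed=rng)
    err = simulate.ErrorModel(error_rate)
    samples = []
    for mouse in truth.mice:
        read_seqs, _ = simulate.simulate_sample_reads(
            mouse, design, error_model=err, reads_per_cell=reads_per_cell,
            seed=rng)
        samples.append(call_sample(read_seqs, design, mouse.mouse_id,
                                   mode="lung", model=model,
                                   min_cells=min_cells))
    counts: dict[str, int] = {}
    for s in samples:
        for c in s.kept:
            counts[c.variant] = counts.get(c.variant, 0) + 1
    summary = stats.summarize_variants(counts, pool,
                                       trim_percentile=trim_percentile,
                                       n_boot=n_boot, seed=rng)
    return ExperimentResult(pool, model, truth, samples, summary)


def hdr_efficiency(tumors_hdr_undiluted: float, tumors_cre_diluted: float,
                   dilution: float, oncogenic_fraction: float = 1.0) -> float:
    """HDR frequency (%) from the dilution comparison.

    Mice in which tumors arise by Cre alone, transduced with virus diluted
    ``dilution``-fold, are compared with undiluted HDR-initiated mice:

        frequency = (tumors_hdr / tumors_cre) / dilution / oncogenic_fraction

    expressed in percent. With a 2:1 tumor ratio at 1:10,000 dilution this
    gives 0.02% if every library allele is oncogenic and 0.1% if only 20%
    are.
    """
    if tumors_hdr_undiluted <= 0 or tumors_cre_diluted <= 0:
        raise InvalidInputError("tumor counts must be positive")
    if dilution < 1:
        raise InvalidInputError("dilution factor must be >= 1")
    if not 0 < oncogenic_fraction <= 1:
        raise InvalidInputError("oncogenic fraction must lie in (0, 1]")
    ratio = tumors_hdr_undiluted / tumors_cre_diluted
    return ratio / dilution / oncogenic_fraction * 100.0


def write_run_manifest(path, config: dict) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
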