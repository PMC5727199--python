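"""Barcode-collision statistics.

Two independently initiated tumors can receive the same barcode ("collide")
and then be observed as one larger tumor. The model here treats barcode
assignment within a mouse as multinomial sampling of ``N`` tumors over the
barcode space, with per-barcode probabilities ``p_i`` predicted from
independent per-position nucleotide frequencies:

    p_i = prod_b f_{b, n_i(b)}                  (21 free parameters)

The expected number of collisions hiding behind an *observed* barcode i is

    C_i(p_i, N) = N p_i + (1 - p_i)^N - 1

and the unknown total tumor number N is recovered from the observed number
of distinct tumors N_obs by solving

    N_obs = N - sum_i C_i(p_i, N)

with Brent's method (the sum runs over all retained barcodes, which makes
the fixed point algebraically well defined: N - sum C_i equals the expected
number of distinct barcodes). Observed tumor sizes are then deflated by
1 + C_i to remove the average size bias collisions impart.

Because over-represented barcodes collide most, the 10% most frequently
observed barcodes in the plasmid library (after correcting for nucleotide
frequencies) are excluded and the retained p_i renormalized to one.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from scipy import optimize

from .design import BarcodeDesign, ConfigError, InvalidInputError
from .calling import TumorCall
from .simulate import PlasmidPool


@dataclasses.dataclass
class BarcodeFrequencyModel:
    """Independent per-position nucleotide frequencies and barcode probabilities."""

    design: BarcodeDesign
    frequencies: list[dict[str, float]]      # one dict per wobble position
    p: pd.Series                             # retained barcode -> probability
    excluded: set = dataclasses.field(default_factory=set)

    @property
    def free_parameters(self) -> int:
        return sum(len(f) - 1 for f in self.frequencies)

    @property
    def retained_barcodes(self) -> pd.Index:
        return self.p.index

    def to_json(self) -> str:
        return json.dumps({
            "frequencies": self.frequencies,
            "excluded": sorted(self.excluded),
            "n_retained": int(len(self.p)),
        }, sort_keys=True)


@dataclasses.dataclass
class CollisionEstimate:
    """Solved total tumor number and per-barcode expected collisions."""

    n_total: float
    n_observed: float
    p: pd.Series
    c: pd.Series            # expected collisions per retained barcode at n_total

    @property
    def total_expected_collisions(self) -> float:
        return float(self.c.sum())


# ---------------------------------------------------------------------------
# Frequency model
# ---------------------------------------------------------------------------

def fit_frequencies(pool: PlasmidPool, design: BarcodeDesign) -> BarcodeFrequencyModel:
    """Read-weighted per-position nucleotide frequencies and barcode p_i.

    Probabilities are computed over the full barcode space and renormalized
    to sum to one. Barcodes containing a never-observed nucleotide get
    p_i = 0 and are dropped from the retained set (flagged via exclusion).
    """
    if pool.counts.empty:
        raise InvalidInputError("empty plasmid pool")
    per_bc = pool.barcode_totals()
    barcodes = per_bc.index.to_numpy()
    weights = per_bc.to_numpy(dtype=float)
    frequencies: list[dict[str, float]] = []
    per_pos_probs: list[np.ndarray] = []
    for b, alph in enumerate(design.wobble_alphabets):
        f = {}
        for n in alph:
            mask = np.array([bc[b] == n for bc in barcodes])
            f[n] = float(weights[mask].sum() / weights.sum())
        frequencies.append(f)
        per_pos_probs.append(np.array([f[n] for n in alph]))

    # p over the whole space via a mixed-radix outer product
    p = np.ones(1)
    for probs in per_pos_probs:
        p = np.multiply.outer(p, probs).ravel()
    all_barcodes = [design.barcode_from_index(i) for i in range(design.barcode_space_size)]
    series = pd.Series(p, index=all_barcodes)
    zero = series.index[series <= 0]
    series = series[series > 0]
    series = series / series.sum()
    return BarcodeFrequencyModel(design, frequencies, series, set(zero))


def exclude_frequent(model: BarcodeFrequencyModel,
                     observed: pd.Series,
                     fraction: float = 0.10) -> BarcodeFrequencyModel:
    """Exclude the most over-represented observed barcodes and renormalize.

    Observed barcodes (from plasmid-library sequencing, not the mice) are
    ranked by observed count / p_i; the top ``fraction`` are excluded, ties
    broken lexicographically, and the retained p_i renormalized to one.
    """
    if not 0 <= fraction < 1:
        raise ConfigError("fraction must lie in [0, 1)")
    if fraction == 0:
        return model
    observed = observed[observed.index.isin(model.p.index)]
    score = observed / model.p.reindex(observed.index)
    ranked = sorted(score.items(), key=lambda kv: (-kv[1], kv[0]))
    n_excl = int(len(ranked) * fraction)
    newly = {bc for bc, _ in ranked[:n_excl]}
    p = model.p[~model.p.index.isin(newly)]
    p = p / p.sum()
    return BarcodeFrequencyModel(model.design, model.frequencies, p,
                                 model.excluded | newly)


# ---------------------------------------------------------------------------
# Collision expectation and total-number solve
# ---------------------------------------------------------------------------

def expected_collisions(p: float | np.ndarray, n: float) -> float | np.ndarray:
    """C(p, N) = N p + (1 - p)^N - 1, clipped at 0 from below."""
    c = n * np.asarray(p, dtype=float) + (1 - np.asarray(p, dtype=float)) ** n - 1
    c = np.clip(c, 0.0, None)
    return float(c) if np.isscalar(p) else c


def solve_total_tumors(n_obs: float, model: BarcodeFrequencyModel) -> CollisionEstimate:
    """Recover the total tumor number N from the observed distinct count.

    Solves N - sum_i C_i(p_i, N) = N_obs over the retained barcodes, i.e.
    B - sum_i (1 - p_i)^N = N_obs, bracketing upward from 100 x N_obs and
    solving with Brent's method to an absolute residual below 1e-6.
    """
    p = model.p.to_numpy()
    n_barcodes = len(p)
    if n_obs < 0:
        raise InvalidInputError("observed tumor count must be non-negative")
    if n_obs >= n_barcodes:
        raise InvalidInputError(
            f"observed {n_obs} distinct tumors exceeds the {n_barcodes}-barcode space")
    if n_obs == 0:
        c = pd.Series(np.zeros(n_barcodes), index=model.p.index)
        return CollisionEstimate(0.0, 0.0, model.p, c)

    def objective(n: float) -> float:
        return n_barcodes - np.power(1 - p, n).sum() - n_obs

    upper = 100.0 * max(n_obs, 1.0)
    while objective(upper) < 0:
        upper *= 2
        if upper > 1e15:
            raise InvalidInputError("no bracket for the tumor-number solve")
    n_total = optimize.brentq(objective, 0.0, upper, xtol=1e-9, rtol=8.9e-16)
    assert abs(objective(n_total)) < 1e-6
    c = pd.Series(expected_collisions(p, n_total), index=model.p.index)
    return CollisionEstimate(float(n_total), float(n_obs), model.p, c)


def correct_sizes(calls: list[TumorCall],
                  estimate: CollisionEstimate) -> tuple[list[TumorCall], list[TumorCall]]:
    """Deflate each call's size by 1 + C_i of its barcode.

    Calls with excluded (non-retained) barcodes are dropped and returned
    separately. Both read-based and absolute sizes are corrected.
    """
    kept, dropped = [], []
    for call in calls:
        if call.barcode not in estimate.c.index:
            dropped.append(call)
            continue
        factor = 1.0 + float(estimate.c[call.barcode])
        call.collision_factor = factor
        if call.cells is not None:
            call.cells = call.cells / factor
        kept.append(call)
    return kept, dropped


def collision_hazard(p_i: float, n_a: float, n_b: float) -> float:
    """Probability a (variant, barcode) pair shared by two samples arises by
    independent initiation rather than clonality: the chance barcode i is
    drawn at least once in each sample's multinomial."""
    return float((1 - (1 - p_i) ** n_a) * (1 - (1 - p_i) ** n_b))
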