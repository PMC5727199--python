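"""Per-variant oncogenicity summaries and the associated exact tests.

Tumor counts per variant are normalized by each variant's initial
representation in the plasmid library (read fractions after trimming
extremely abundant barcodes) and scaled so wild type sits at 1; enrichment
against a reference variant (WT or G12D) is tested with two-sided Fisher
exact tests, Bonferroni-corrected over the 12 mutant variants, with a
binomial-tail generalization for cohorts in which zero wild-type tumors
were observed (a structural zero). Confidence intervals on relative tumor
number come from a percentile bootstrap over the pooled tumor list.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import TumorCall
from .design import ConfigError, InvalidInputError
from .simulate import PlasmidPool

N_MUTANT_VARIANTS = 12


@dataclasses.dataclass
class VariantSummary:
    variant: str
    tumor_count: int
    representation: float
    normalized_count: float
    relative_to_wt: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    p_vs_wt: float | None = None
    p_vs_g12d: float | None = None


def variant_representation(pool: PlasmidPool,
                           trim_percentile: float = 98.0) -> pd.Series:
    """Per-variant read fractions after trimming hyper-abundant barcodes.

    Rows of the pool above the ``trim_percentile`` of per-row read counts
    (computed pool-wide) are dropped before summing, so that extremely
    abundant variant-barcode pairs cannot dominate a variant's
    representation. Fractions sum to one.
    """
    counts = pool.counts
    cutoff = np.percentile(counts["reads"], trim_percentile)
    trimmed = counts[counts["reads"] <= cutoff]
    totals = trimmed.groupby("variant")["reads"].sum().astype(float)
    return totals / totals.sum()


def normalized_tumor_number(counts: dict[str, int],
                            representation: pd.Series) -> pd.DataFrame:
    """Tumor counts scaled by representation, relative to wild type.

    value_v = (count_v / rep_v) / (count_WT / rep_WT). When no wild-type
    tumors were observed (a structural zero) the relative column is left
    unscaled (NaN flag via ``wt_scaled = False``).
    """
    rows = []
    variants = sorted(set(counts) | set(representation.index))
    wt_count = counts.get("WT", 0)
    wt_rep = float(representation.get("WT", np.nan))
    wt_norm = wt_count / wt_rep if wt_count > 0 and wt_rep > 0 else None
    for v in variants:
        rep = float(representation.get(v, np.nan))
        if not rep > 0:
            raise InvalidInputError(f"variant {v} has no representation")
        norm = counts.get(v, 0) / rep
        rows.append({
            "variant": v,
            "tumor_count": counts.get(v, 0),
            "representation": rep,
            "normalized_count": norm,
            "relative_to_wt": norm / wt_norm if wt_norm else np.nan,
        })
    df = pd.DataFrame(rows).set_index("variant")
    df.attrs["wt_scaled"] = wt_norm is not None
    return df


def fisher_vs_reference(count_v: int, count_ref: int,
                        rep_reads_v: int, rep_reads_ref: int,
                        n_variants: int = N_MUTANT_VARIANTS) -> tuple[float, float]:
    """Two-sided Fisher exact test of tumor counts against representation.

    The 2x2 table is [[count_v, count_ref], [rep_reads_v, rep_reads_ref]]
    (tumor counts over raw plasmid-library read counts); returns the exact
    two-sided p and its Bonferroni correction min(1, p * n_variants).
    """
    table = np.array([[count_v, count_ref], [rep_reads_v, rep_reads_ref]])
    if (table < 0).any():
        raise InvalidInputError("counts must be non-negative")
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return 1.0, 1.0
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return p, min(1.0, p * n_variants)


def structural_zero_test(count_v: int, rep_fraction_v: float,
                         rep_fraction_ref: float) -> float:
    """Exact test against a reference whose tumor count is structurally zero.

    Under the null that each of the count_v tumors is independently the
    reference allele with probability rep_ref / (rep_ref + rep_v), the
    chance of seeing zero reference tumors is (1 - p_ref)^count_v; reported
    two-sided as min(1, 2p).
    """
    if count_v < 0 or rep_fraction_v < 0 or rep_fraction_ref < 0:
        raise InvalidInputError("negative input")
    if count_v == 0:
        return 1.0
    p_ref = rep_fraction_ref / (rep_fraction_ref + rep_fraction_v)
    p_one = (1 - p_ref) ** count_v
    return min(1.0, 2 * p_one)


def genotype_spectrum_chisq(table: pd.DataFrame) -> tuple[float, int, float]:
    """"Many cells" Pearson chi-square over a variant x genotype count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise InvalidInputError("need a 2-D table with at least 2 columns")
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    stat, p, dof, expected = sps.chi2_contingency(arr, correction=False)
    if (expected < 1).any():
        import warnings

        warnings.warn("expected cell below 1; chi-square approximation is weak")
    return float(stat), int(dof), float(p)


def bootstrap_ci(calls: list[TumorCall] | list[str],
                 representation: pd.Series,
                 n_boot: int = 2000, level: float = 0.95,
                 seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Percentile bootstrap CI on each variant's relative tumor number.

    The pooled tumor list is resampled with replacement ``n_boot`` times
    and the normalized, WT-scaled values recomputed each round.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = [c if isinstance(c, str) else c.variant for c in calls]
    variants = sorted(representation.index)
    vidx = {v: i for i, v in enumerate(variants)}
    obs = np.zeros(len(variants), dtype=np.int64)
    for lb in labels:
        obs[vidx[lb]] += 1
    rep = representation.reindex(variants).to_numpy(dtype=float)
    wt = vidx.get("WT")
    if wt is None or obs[wt] == 0:
        raise InvalidInputError("bootstrap CI needs at least one WT tumor")

    def relative(counts: np.ndarray) -> np.ndarray:
        norm = counts / rep
        with np.errstate(divide="ignore", invalid="ignore"):
            return norm / norm[..., [wt]]

    codes = np.array([vidx[lb] for lb in labels])
    n = len(codes)
    draws = rng.integers(0, n, size=(n_boot, n))
    boot_counts = np.zeros((n_boot, len(variants)), dtype=np.int64)
    for b in range(n_boot):
        boot_counts[b] = np.bincount(codes[draws[b]], minlength=len(variants))
    boot_rel = relative(boot_counts.astype(float))
    alpha = (1 - level) / 2
    lo = np.nanquantile(np.where(np.isfinite(boot_rel), boot_rel, np.nan),
                        alpha, axis=0)
    hi = np.nanquantile(np.where(np.isfinite(boot_rel), boot_rel, np.nan),
                        1 - alpha, axis=0)
    point = relative(obs.astype(float))
    return pd.DataFrame({"relative_to_wt": point, "ci_low": lo, "ci_high": hi},
                        index=pd.Index(variants, name="variant"))


def hdr_bias_correlation(plasmid_freqs: np.ndarray,
                         observed_freqs: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between library and observed allele frequencies.

    High correlation indicates the HDR machinery does not favor particular
    variant alleles (no HDR bias). Returns (r, R^2).
    """
    x = np.asarray(plasmid_freqs, dtype=float)
    y = np.asarray(observed_freqs, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("frequency vectors must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidInputError("zero-variance frequency vector")
    r = float(sps.pearsonr(x, y)[0])
    return r, r ** 2


def summarize_variants(counts: dict[str, int], pool: PlasmidPool,
                       trim_percentile: float = 98.0,
                       n_boot: int = 2000,
                       seed: int | np.random.Generator = 0,
                       reference: str = "G12D") -> pd.DataFrame:
    """Full per-variant summary: normalized numbers, CIs, exact tests."""
    rep = variant_representation(pool, trim_percentile)
    df = normalized_tumor_number(counts, rep)
    rep_reads = pool.variant_totals()
    labels = [v for c, v in
              ((counts.get(v, 0), v) for v in df.index)
              for _ in range(c)]
    if counts.get("WT", 0) > 0:
        ci = bootstrap_ci(labels, rep, n_boot=n_boot, seed=seed)
        df = df.join(ci[["ci_low", "ci_high"]])
    else:
        df["ci_low"] = np.nan
        df["ci_high"] = np.nan
    p_wt, p_ref = [], []
    for v in df.index:
        if counts.get("WT", 0) > 0:
            p = fisher_vs_reference(counts.get(v, 0), counts.get("WT", 0),
                                    int(rep_reads[v]), int(rep_reads["WT"]))[1]
        else:
            p = min(1.0, structural_zero_test(
                counts.get(v, 0), float(rep[v]), float(rep["WT"]))
                * N_MUTANT_VARIANTS)
        p_wt.append(p if v != "WT" else np.nan)
        p_ref.append(
            fisher_vs_reference(counts.get(v, 0), counts.get(reference, 0),
                                int(rep_reads[v]), int(rep_reads[reference]))[1]
            if v != reference else np.nan)
    df["p_vs_wt"] = p_wt
    df[f"p_vs_{reference.lower()}"] = p_ref
    return df
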