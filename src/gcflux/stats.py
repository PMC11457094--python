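"""Resampling and classical statistics for conversion-tract coverage.

Three permutation engines ask whether selection-candidate ("outlier") genes
receive less conversion coverage than expected: permuting the outlier labels
across genes, re-placing the observed tracts uniformly within their syntenic
regions, and generating tracts afresh from the fitted geometric model.  All
empirical p-values use the add-one rule (b + 1) / (m + 1) so a finite number
of replicates can never produce p = 0, and ties count on both sides.

The module also provides the chi-square goodness-of-fit and homogeneity tests
with standardized-residual flagging, the donor->recipient polarity
permutation, the per-region median tract-length permutation, one-way ANOVA
with a planned contrast of a focal arrangement against the pooled rest, the
three-category coverage classification, Tajima's D, and the heterokaryotype
frequency correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ConversionTract, GeneModel, PermutationResult, PhiFit, RegionMap

RESIDUAL_FLAG_THRESHOLD = 2.0


def _empirical_p(null: np.ndarray, observed: float) -> tuple[float, float]:
    m = len(null)
    p_lower = (np.count_nonzero(null <= observed) + 1) / (m + 1)
    p_upper = (np.count_nonzero(null >= observed) + 1) / (m + 1)
    return float(p_lower), float(p_upper)


def _result(name: str, observed: float, null: np.ndarray,
            seed: int) -> PermutationResult:
    p_lo, p_hi = _empirical_p(null, observed)
    return PermutationResult(
        statistic_name=name, observed=float(observed),
        n_replicates=len(null), p_lower=p_lo, p_upper=p_hi,
        null_min=float(null.min()), null_max=float(null.max()),
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# Outlier-label permutation
# ---------------------------------------------------------------------------

def permute_outlier_labels(
    per_gene_coverage: Sequence[float],
    outlier_mask: Sequence[bool],
    n_rep: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permute outlier/non-outlier labels across genes.

    The statistic is the mean coverage of outlier-labelled genes; ``p_lower``
    is the frequency of random label assignments with mean coverage at or
    below the observed value (add-one corrected).
    """
    cov = np.asarray(per_gene_coverage, dtype=float)
    mask = np.asarray(outlier_mask, dtype=bool)
    n = len(cov)
    if n == 0:
        raise ValueError("empty gene list")
    k = int(mask.sum())
    if k == 0:
        raise ValueError("no outlier genes")
    observed = float(cov[mask].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_rep)
    for i in range(n_rep):
        null[i] = cov[rng.choice(n, size=k, replace=False)].mean()
    return _result("mean_outlier_coverage[label permutation]", observed,
                   null, seed)


# ---------------------------------------------------------------------------
# Interval bookkeeping for the tract-placement nulls
# ---------------------------------------------------------------------------

def _outlier_cds_prefix(genes: Sequence[GeneModel], arrangement: str,
                        chromosome_length: int) -> tuple[np.ndarray, int]:
    """Cumulative count of outlier-CDS bases at positions <= i, and total."""
    ind = np.zeros(chromosome_length + 1, dtype=np.int64)
    for g in genes:
        if arrangement in g.outlier_in:
            for s, e in g.exons:
                ind[s:e + 1] = 1
    prefix = np.cumsum(ind)
    return prefix, int(prefix[-1])


def _overlap_sum(prefix: np.ndarray, starts: np.ndarray,
                 ends: np.ndarray) -> np.ndarray:
    """Summed outlier-CDS overlap of [start, end] intervals (vectorized)."""
    return prefix[ends] - prefix[starts - 1]


def outlier_mean_coverage(
    tracts: Iterable[ConversionTract],
    genes: Sequence[GeneModel],
    arrangement: str,
    chromosome_length: int,
) -> float:
    """Pooled mean coverage over outlier-CDS nucleotides for one arrangement."""
    prefix, total = _outlier_cds_prefix(genes, arrangement, chromosome_length)
    if total == 0:
        raise ValueError(f"no outlier genes for arrangement {arrangement}")
    starts = np.asarray([t.start for t in tracts], dtype=np.int64)
    ends = np.asarray([t.end for t in tracts], dtype=np.int64)
    if len(starts) == 0:
        return 0.0
    return float(_overlap_sum(prefix, starts, ends).sum() / total)


def shuffle_tracts(
    tracts: Sequence[ConversionTract],
    region_map: RegionMap,
    genes: Sequence[GeneModel],
    chromosome_length: int,
    arrangement: str | None = None,
    n_rep: int = 10_000,
    seed: int = 0,
    chromosome_wide: bool = False,
) -> PermutationResult:
    """Re-place the observed tracts uniformly and recompute outlier coverage.

    Each replicate keeps every tract's span length and draws a new uniform
    start within the tract's original syntenic region such that the tract
    fits (``chromosome_wide=True`` relaxes the placement to the whole
    chromosome).  The statistic is the pooled mean coverage of outlier-CDS
    nucleotides for the recipient arrangement.
    """
    if not tracts:
        raise ValueError("no tracts to shuffle")
    arrangement = arrangement or tracts[0].recipient_arrangement
    prefix, total = _outlier_cds_prefix(genes, arrangement, chromosome_length)
    if total == 0:
        raise ValueError(f"no outlier genes for arrangement {arrangement}")
    starts = np.asarray([t.start for t in tracts], dtype=np.int64)
    ends = np.asarray([t.end for t in tracts], dtype=np.int64)
    spans = ends - starts + 1
    observed = float(_overlap_sum(prefix, starts, ends).sum() / total)

    if chromosome_wide:
        lo = np.ones(len(tracts), dtype=np.int64)
        hi = chromosome_length - spans + 1
    else:
        ridx = region_map.region_index_of(starts)
        if (ridx < 0).any():
            raise ValueError("tract outside every region")
        lo = region_map.starts[ridx]
        hi = region_map.ends[ridx] - spans + 1
    if (hi < lo).any():
        raise ValueError("tract longer than its region")

    rng = np.random.default_rng(seed)
    null = np.empty(n_rep)
    space = (hi - lo + 1).astype(np.float64)
    for i in range(n_rep):
        new_starts = lo + (rng.random(len(tracts)) * space).astype(np.int64)
        null[i] = _overlap_sum(prefix, new_starts,
                               new_starts + spans - 1).sum() / total
    return _result("mean_outlier_coverage[tract shuffle]", observed, null, seed)


def generate_ml_tracts(
    phi_fits: Sequence[PhiFit],
    region_map: RegionMap,
    genes: Sequence[GeneModel],
    observed_tracts: Sequence[ConversionTract],
    chromosome_length: int,
    arrangement: str | None = None,
    n_rep: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Parametric null: generate tracts from the fitted geometric model.

    Per replicate and per (region, donor) fit, ``ceil(expected_k)`` tracts
    are drawn with geometric(phi_hat) lengths (redrawn while longer than the
    region) and uniform starts (redrawn while the tract would cross the
    region edge), then outlier-CDS mean coverage is recomputed.
    """
    if not observed_tracts:
        raise ValueError("no observed tracts")
    arrangement = arrangement or observed_tracts[0].recipient_arrangement
    fits = [f for f in phi_fits if f.recipient == arrangement]
    if not fits:
        raise ValueError(f"no phi fits for recipient {arrangement}")
    prefix, total = _outlier_cds_prefix(genes, arrangement, chromosome_length)
    if total == 0:
        raise ValueError(f"no outlier genes for arrangement {arrangement}")
    observed = outlier_mean_coverage(observed_tracts, genes, arrangement,
                                     chromosome_length)

    region_bounds = {rid: (s, e) for rid, s, e in region_map.regions}
    rng = np.random.default_rng(seed)
    null = np.zeros(n_rep)
    for fit in fits:
        if fit.region_id not in region_bounds:
            import warnings
            warnings.warn(f"no region {fit.region_id} in map; fit skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        rs, re = region_bounds[fit.region_id]
        size = re - rs + 1
        m = math.ceil(fit.expected_k)
        p_ext = 1.0 - fit.phi_hat
        lengths = rng.geometric(p_ext, size=(n_rep, m))
        for _ in range(100):
            bad = lengths > size
            if not bad.any():
                break
            lengths[bad] = rng.geometric(p_ext, size=int(bad.sum()))
        np.clip(lengths, 1, size, out=lengths)
        space = (size - lengths + 1).astype(np.float64)
        starts = rs + (rng.random((n_rep, m)) * space).astype(np.int64)
        overlaps = prefix[starts + lengths - 1] - prefix[starts - 1]
        null += overlaps.sum(axis=1) / total
    return _result("mean_outlier_coverage[ML tract null]", observed, null, seed)


# ---------------------------------------------------------------------------
# Three-category classification
# ---------------------------------------------------------------------------

@dataclass
class ThreeCategoryResult:
    table: pd.DataFrame          # rows outlier/non-outlier, cols below/within/above
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float
    low_expected_warning: bool


def three_category_classification(
    per_gene_coverage: Sequence[float],
    null_min: float,
    null_max: float,
    outlier_mask: Sequence[bool],
) -> ThreeCategoryResult:
    """Classify genes by the permutation null envelope and test homogeneity.

    Categories: coverage below the permuted minimum, within [min, max], or
    above the permuted maximum.  A 2 x 3 chi-square test of homogeneity
    (df = 2) compares outlier vs non-outlier genes; cells with expected
    count < 1 raise the validity flag.
    """
    if null_min > null_max:
        raise ValueError("null_min must be <= null_max")
    cov = np.asarray(per_gene_coverage, dtype=float)
    mask = np.asarray(outlier_mask, dtype=bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both outlier and non-outlier classes must be non-empty")
    cats = np.where(cov < null_min, 0, np.where(cov > null_max, 2, 1))
    table = np.zeros((2, 3), dtype=np.int64)
    for row, sel in enumerate((mask, ~mask)):
        table[row] = np.bincount(cats[sel], minlength=3)
    row_sums = table.sum(axis=1, keepdims=True)
    col_sums = table.sum(axis=0, keepdims=True)
    expected = row_sums * col_sums / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    df = 2
    p = float(sps.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return ThreeCategoryResult(
        table=pd.DataFrame(table, index=["outlier", "non_outlier"],
                           columns=["below_min", "within", "above_max"]),
        expected=expected, chi2=chi2, df=df, p_value=p,
        low_expected_warning=bool((expected < 1.0).any()),
    )


# ---------------------------------------------------------------------------
# Polarity permutation
# ---------------------------------------------------------------------------

def polarity_permutation(
    tracts: Sequence[ConversionTract],
    region_map: RegionMap,
    n_rep: int = 10_000,
    seed: int = 0,
) -> dict[tuple[str, str, str], PermutationResult]:
    """Permute donor/recipient labels of single-donor events across regions.

    Each event independently receives a new ordered (donor, recipient) pair
    drawn uniformly from all non-self ordered pairs, preserving its region.
    Results are keyed ``(region_id_or_"ALL", donor, recipient)``; a small
    ``p_upper`` flags an excess of events for that direction, a small
    ``p_lower`` a deficiency.
    """
    if any(len(t.donor_arrangements) != 1 for t in tracts):
        raise ValueError("polarity permutation requires single-donor tracts")
    arrs = sorted(
        {t.recipient_arrangement for t in tracts}
        | {next(iter(t.donor_arrangements)) for t in tracts})
    if len(arrs) < 2:
        raise ValueError("need at least two arrangements")
    pairs = [(d, r) for d in arrs for r in arrs if d != r]
    pair_index = {p: i for i, p in enumerate(pairs)}
    n_pairs = len(pairs)

    ev_pair = np.asarray([
        pair_index[(next(iter(t.donor_arrangements)), t.recipient_arrangement)]
        for t in tracts])
    starts = np.asarray([t.start for t in tracts], dtype=np.int64)
    ev_region = region_map.region_index_of(starts)

    rng = np.random.default_rng(seed)
    n_events = len(tracts)
    draws = rng.integers(0, n_pairs, size=(n_rep, n_events))

    def _null_counts(cols: np.ndarray) -> np.ndarray:
        sub = draws[:, cols]
        counts = np.zeros((n_rep, n_pairs), dtype=np.int64)
        rep_ids = np.repeat(np.arange(n_rep), sub.shape[1])
        np.add.at(counts, (rep_ids, sub.ravel()), 1)
        return counts

    results: dict[tuple[str, str, str], PermutationResult] = {}
    all_cols = np.arange(n_events)
    scopes: list[tuple[str, np.ndarray]] = [("ALL", all_cols)]
    for i, (rid, _, _) in enumerate(region_map.regions):
        cols = np.flatnonzero(ev_region == i)
        if len(cols):
            scopes.append((rid, cols))
    for scope, cols in scopes:
        counts = _null_counts(cols)
        obs = np.bincount(ev_pair[cols], minlength=n_pairs)
        for pi, (d, r) in enumerate(pairs):
            results[(scope, d, r)] = _result(
                f"event_count[{d}->{r}]", float(obs[pi]), counts[:, pi], seed)
    return results


# ---------------------------------------------------------------------------
# Median tract-length permutation
# ---------------------------------------------------------------------------

def median_length_permutation(
    tracts: Sequence[ConversionTract],
    region_map: RegionMap,
    n_rep: int = 10_000,
    seed: int = 0,
) -> dict[str, PermutationResult]:
    """Shuffle tracts across regions and recompute per-region median lengths.

    The shuffle keeps the number of tracts per region fixed at the observed
    value.  A region with ``p_lower <= alpha`` has shorter-than-expected
    tracts, ``p_upper <= alpha`` longer-than-expected.
    """
    lengths = np.asarray([t.length_excl_gaps for t in tracts], dtype=float)
    starts = np.asarray([t.start for t in tracts], dtype=np.int64)
    ridx = region_map.region_index_of(starts)
    if (ridx < 0).any():
        raise ValueError("tract outside every region")
    order = np.argsort(ridx, kind="stable")
    sorted_lengths = lengths[order]
    sorted_ridx = ridx[order]
    boundaries = np.flatnonzero(np.diff(sorted_ridx)) + 1
    slices = np.split(np.arange(len(tracts)), boundaries)
    present = [int(sorted_ridx[s[0]]) for s in slices]

    rng = np.random.default_rng(seed)
    null_medians = {i: np.empty(n_rep) for i in present}
    for rep in range(n_rep):
        perm = rng.permutation(sorted_lengths)
        for i, s in zip(present, slices):
            null_medians[i][rep] = np.median(perm[s])

    results = {}
    for i, s in zip(present, slices):
        rid = region_map.regions[i][0]
        observed = float(np.median(sorted_lengths[s]))
        results[rid] = _result(f"median_tract_length[{rid}]", observed,
                               null_medians[i], seed)
    return results


# ---------------------------------------------------------------------------
# Chi-square tests
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    expected: np.ndarray
    residuals: np.ndarray        # standardized (obs - exp) / sqrt(exp)
    flags: np.ndarray            # "deficient" / "excess" / ""


def _flag_residuals(residuals: np.ndarray) -> np.ndarray:
    flags = np.full(residuals.shape, "", dtype="<U9")
    flags[residuals > RESIDUAL_FLAG_THRESHOLD] = "excess"
    flags[residuals < -RESIDUAL_FLAG_THRESHOLD] = "deficient"
    return flags


def chi_square_gof(
    counts_per_arrangement: Sequence[int],
    strains_per_arrangement: Sequence[int],
) -> ChiSquareResult:
    """Are tract counts proportional to the number of strains sampled?

    Expected counts are total * (n_strains_i / sum n_strains); df = k - 1.
    """
    obs = np.asarray(counts_per_arrangement, dtype=float)
    strains = np.asarray(strains_per_arrangement, dtype=float)
    if len(obs) < 2 or len(obs) != len(strains):
        raise ValueError("need >= 2 matched categories")
    expected = obs.sum() * strains / strains.sum()
    if (expected == 0).any():
        raise ValueError("zero expected count")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    residuals = (obs - expected) / np.sqrt(expected)
    return ChiSquareResult(chi2=chi2, df=df,
                           p_value=float(sps.chi2.sf(chi2, df)),
                           expected=expected, residuals=residuals,
                           flags=_flag_residuals(residuals))


def chi_square_homogeneity(table: Sequence[Sequence[int]]) -> ChiSquareResult:
    """Contingency chi-square with per-cell standardized residual flags.

    For an r x c table df = (r - 1)(c - 1); a 14-region x 5-arrangement
    table has df = 52.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("need a 2-D contingency table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    residuals = (obs - expected) / np.sqrt(expected)
    return ChiSquareResult(chi2=chi2, df=df,
                           p_value=float(sps.chi2.sf(chi2, df)),
                           expected=expected, residuals=residuals,
                           flags=_flag_residuals(residuals))


# ---------------------------------------------------------------------------
# ANOVA with planned contrast
# ---------------------------------------------------------------------------

@dataclass
class AnovaContrastResult:
    f_stat: float
    f_p: float
    df_between: int
    df_within: int
    contrast_estimate: float
    t_stat: float
    t_p: float


def anova_normalized_coverage(
    values: Sequence[float],
    groups: Sequence[str],
    focal_group: str,
) -> AnovaContrastResult:
    """One-way ANOVA across arrangement backgrounds with a planned contrast.

    The contrast compares the focal (outlier) arrangement's mean against the
    unweighted mean of the remaining groups, tested on the pooled ANOVA error
    term with df = N - g.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if focal_group not in labels:
        raise ValueError(f"focal group {focal_group} not present")
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    data = [values[groups == g] for g in labels]
    if any(len(d) < 2 for d in data):
        raise ValueError("need >= 2 observations per group")
    n_tot = len(values)
    g = len(labels)
    grand = values.mean()
    means = np.array([d.mean() for d in data])
    ns = np.array([len(d) for d in data])
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((d - d.mean()) ** 2).sum() for d in data))
    df_b, df_w = g - 1, n_tot - g

    if ss_within == 0.0 and ss_between == 0.0:
        return AnovaContrastResult(0.0, 1.0, df_b, df_w, 0.0, 0.0, 1.0)
    mse = ss_within / df_w
    f_stat = (ss_between / df_b) / mse if mse > 0 else np.inf
    f_p = float(sps.f.sf(f_stat, df_b, df_w)) if np.isfinite(f_stat) else 0.0

    weights = np.array([1.0 if lab == focal_group else -1.0 / (g - 1)
                        for lab in labels])
    estimate = float((weights * means).sum())
    se = np.sqrt(mse * float((weights**2 / ns).sum())) if mse > 0 else 0.0
    if se == 0.0:
        t_stat = 0.0 if estimate == 0.0 else np.inf * np.sign(estimate)
        t_p = 1.0 if estimate == 0.0 else 0.0
    else:
        t_stat = estimate / se
        t_p = float(2.0 * sps.t.sf(abs(t_stat), df_w))
    return AnovaContrastResult(float(f_stat), f_p, df_b, df_w, estimate,
                               float(t_stat), t_p)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass
class TajimaResult:
    n_sequences: int
    s: int                      # segregating sites
    pi: float                   # mean pairwise differences
    theta_w: float              # Watterson's estimator
    d: float | None             # None when S = 0
    p_value: float | None       # beta-approximation two-sided p


def tajima_d(alleles: Sequence[Sequence[str]] | np.ndarray) -> TajimaResult:
    """Tajima's D for one gene within one arrangement.

    ``alleles`` is an (n_sequences x n_sites) character matrix; sites are
    used pairwise-complete: gap/N chromosomes are dropped per site and the
    per-site heterozygosity is computed from the remaining pairs.  The
    significance approximation treats D as a scaled beta variate over its
    theoretical range.
    """
    arr = np.asarray(alleles)
    if arr.dtype.kind in "SU":
        arr = arr.astype("U1")
    else:
        raise ValueError("allele matrix must contain characters")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need >= 2 sequences")

    s = 0
    pi = 0.0
    for j in range(arr.shape[1]):
        col = arr[:, j]
        keep = ~np.isin(col, ("N", "-", "n"))
        m = int(keep.sum())
        if m < 2:
            continue
        _, counts = np.unique(col[keep], return_counts=True)
        if len(counts) >= 2:
            s += 1
            pi += 1.0 - float((counts * (counts - 1)).sum()) / (m * (m - 1))

    a1 = float(np.sum(1.0 / np.arange(1, n)))
    theta_w = s / a1
    if s == 0:
        return TajimaResult(n, 0, 0.0, 0.0, None, None)

    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    d = float((pi - theta_w) / np.sqrt(var)) if var > 0 else 0.0

    # beta-distribution approximation over [d_min, d_max]
    p = None
    if e2 <= 0:  # degenerate for very small samples (n = 3)
        return TajimaResult(n, s, float(pi), float(theta_w), d, p)
    pi_max = n / (2 * (n - 1)) if n % 2 == 0 else (n + 1) / (2 * n)
    d_min = (2 / n - 1 / a1) / np.sqrt(e2)
    d_max = (pi_max - 1 / a1) / np.sqrt(e2)
    rng_ = d_max - d_min
    if rng_ > 0 and 1 + d_min * d_max < 0:
        alpha = d_min * (1 + d_min * d_max) / rng_
        beta = -d_max * (1 + d_min * d_max) / rng_
        x = np.clip((d - d_min) / rng_, 0.0, 1.0)
        cdf = float(sps.beta.cdf(x, alpha, beta))
        p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return TajimaResult(n, s, float(pi), float(theta_w), d, p)


# ---------------------------------------------------------------------------
# Heterokaryotype frequency correlation
# ---------------------------------------------------------------------------

def heterokaryotype_correlation(
    event_counts: Sequence[float],
    heterokaryotype_frequencies: Sequence[float],
) -> tuple[float | None, float | None]:
    """Spearman correlation of per-pair event counts vs heterokaryotype frequency.

    Returns ``(None, None)`` when either input is constant (the rank
    correlation is undefined).
    """
    x = np.asarray(event_counts, dtype=float)
    y = np.asarray(heterokaryotype_frequencies, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 matched pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


__all__ = [
    "permute_outlier_labels", "shuffle_tracts", "generate_ml_tracts",
    "outlier_mean_coverage", "three_category_classification",
    "ThreeCategoryResult", "polarity_permutation",
    "median_length_permutation", "chi_square_gof", "chi_square_homogeneity",
    "ChiSquareResult", "anova_normalized_coverage", "AnovaContrastResult",
    "tajima_d", "TajimaResult", "heterokaryotype_correlation",
    "RESIDUAL_FLAG_THRESHOLD",
]
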