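"""Per-nucleotide conversion-tract coverage maps and per-feature summaries.

Coverage counts the full tract span ``[start, end]`` -- including
non-informative interior sites -- because the converted segment is the span;
the informative sites merely mark its ends.  (The alternative of counting
only non-gap columns sits behind ``coverage_basis="nongap"``.)
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import ConversionTract, CoverageTrack, GeneModel, HaplotypePanel, RegionMap

logger = logging.getLogger("gcflux")

CATEGORY_CDS, CATEGORY_INTRON, CATEGORY_INTERGENIC = 0, 1, 2


def build_coverage(
    tracts: Iterable[ConversionTract],
    arrangement: str,
    chromosome_length: int,
    coverage_basis: str = "span",
) -> CoverageTrack:
    """Histogram of tract counts per nucleotide for one recipient arrangement.

    ``sum(values)`` equals the summed span lengths of the input tracts
    (exact conservation), or the summed ``length_excl_gaps`` under
    ``coverage_basis="nongap"`` where each tract contributes its non-gap
    length spread over the leading part of its span.
    """
    diff = np.zeros(chromosome_length + 1, dtype=np.int64)
    for t in tracts:
        if t.recipient_arrangement != arrangement:
            raise ValueError(
                f"tract in {t.recipient_arrangement} passed to track "
                f"for {arrangement}")
        if t.end > chromosome_length:
            raise ValueError("tract extends beyond chromosome end")
        end = t.end if coverage_basis == "span" else t.start + t.length_excl_gaps - 1
        diff[t.start - 1] += 1
        diff[end] -= 1
    return CoverageTrack(arrangement=arrangement,
                         values=np.cumsum(diff[:-1]))


def category_labels(genes: Sequence[GeneModel],
                    chromosome_length: int) -> np.ndarray:
    """Per-position category with precedence CDS > intron > intergenic."""
    if not genes:
        raise ValueError("empty annotation")
    labels = np.full(chromosome_length, CATEGORY_INTERGENIC, dtype=np.int8)
    for g in genes:
        for s, e in g.introns:
            labels[s - 1:e] = np.where(labels[s - 1:e] == CATEGORY_CDS,
                                       CATEGORY_CDS, CATEGORY_INTRON)
    overlap_logged = False
    for g in genes:
        for s, e in g.exons:
            if not overlap_logged and (labels[s - 1:e] != CATEGORY_INTERGENIC).any():
                logger.info("overlapping annotation near %s; CDS takes "
                            "precedence", g.gene_id)
                overlap_logged = True
            labels[s - 1:e] = CATEGORY_CDS
    return labels


def feature_coverage(track: CoverageTrack,
                     genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Mean coverage per sequence category (CDS, intron, intergenic).

    The three categories partition the chromosome, so their lengths sum to
    the chromosome length and every position is counted exactly once.
    """
    labels = category_labels(genes, track.chromosome_length)
    rows = []
    for cat, name in [(CATEGORY_CDS, "CDS"), (CATEGORY_INTRON, "intron"),
                      (CATEGORY_INTERGENIC, "intergenic")]:
        mask = labels == cat
        n = int(mask.sum())
        total = int(track.values[mask].sum())
        rows.append({"category": name, "n_sites": n, "total_coverage": total,
                     "mean_coverage": total / n if n else np.nan})
    return pd.DataFrame(rows).set_index("category")


def transcript_coverage(track: CoverageTrack, gene: GeneModel) -> float:
    """Unweighted mean over exons of the per-exon mean coverage.

    Deliberately not length-weighted: a 10 bp and a 1000 bp exon contribute
    equally to the transcript value.
    """
    if not gene.exons:
        raise ValueError(f"{gene.gene_id}: gene has no exons")
    means = [float(track.values[s - 1:e].mean()) for s, e in gene.exons]
    return float(np.mean(means))


def gene_coverage_table(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    arrangement_mean: float | None = None,
) -> pd.DataFrame:
    """Per-gene transcript coverage, outlier flag, and optional normalization."""
    rows = []
    for g in genes:
        cov = transcript_coverage(track, g)
        rows.append({
            "gene_id": g.gene_id,
            "arrangement": track.arrangement,
            "mean_coverage": cov,
            "outlier": track.arrangement in g.outlier_in,
        })
    df = pd.DataFrame(rows).set_index("gene_id")
    if arrangement_mean is not None:
        df["normalized_coverage"] = normalize_coverage(
            df["mean_coverage"].to_numpy(), arrangement_mean)
    return df


def flag_extremes(values: Sequence[float], k_sd: float = 2.0) -> np.ndarray:
    """Flag values beyond ``k_sd`` standard deviations of their own mean.

    Returns an array of ``{"low", "normal", "high"}``.  When the lower
    threshold is negative no value can be flagged low (coverage is
    non-negative); with fewer than two values nothing is flagged.
    """
    values = np.asarray(values, dtype=float)
    flags = np.full(len(values), "normal", dtype="<U6")
    if len(values) < 2:
        return flags
    mean = values.mean()
    sd = values.std(ddof=1)
    flags[values > mean + k_sd * sd] = "high"
    flags[values < mean - k_sd * sd] = "low"
    return flags


def gap_qc(panel: HaplotypePanel, region_map: RegionMap) -> pd.DataFrame:
    """Fraction of gap ('-') or missing ('N') cells per arrangement per region."""
    codes = panel.codes()
    bad = codes >= 4
    ridx = region_map.region_index_of(panel.positions)
    rows = []
    for arr in panel.arrangements:
        rws = panel.strain_indices(arr)
        for i, (rid, _, _) in enumerate(region_map.regions):
            cols = ridx == i
            n = int(cols.sum()) * len(rws)
            frac = float(bad[np.ix_(rws, np.flatnonzero(cols))].sum() / n) if n else np.nan
            rows.append({"arrangement": arr, "region_id": rid,
                         "gap_fraction": frac})
    return pd.DataFrame(rows)


def normalize_coverage(values, arrangement_mean: float):
    """Divide per-gene coverage by the arrangement's mean coverage."""
    if arrangement_mean <= 0:
        raise ValueError("arrangement mean coverage must be positive")
    return np.asarray(values, dtype=float) / arrangement_mean


def aa_polymorphism_count(cds_alignment: Sequence[str],
                          genetic_code: int | str = 1) -> int:
    """Number of codon positions with >= 2 distinct translated residues.

    ``cds_alignment`` is a list of equal-length in-frame CDS strings; codons
    containing gaps or N are skipped for that sequence.
    """
    lengths = {len(s) for s in cds_alignment}
    if len(lengths) != 1:
        raise ValueError("unaligned CDS input")
    length = lengths.pop()
    if length % 3 != 0:
        raise ValueError("frame violation: CDS length not divisible by 3")
    count = 0
    for i in range(0, length, 3):
        residues = set()
        for s in cds_alignment:
            codon = s[i:i + 3].upper()
            if "-" in codon or "N" in codon:
                continue
            residues.add(str(Seq(codon).translate(table=genetic_code)))
        if len(residues) >= 2:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Whole-study summary arithmetic
# ---------------------------------------------------------------------------

def mean_tracts_per_strain(total_tracts: int,
                           strains_per_arrangement: Mapping[str, int]) -> float:
    """Mean number of non-redundant tracts per sequenced strain."""
    n = sum(strains_per_arrangement.values())
    if n == 0:
        raise ValueError("no strains")
    return total_tracts / n


def fold_coverage(total_coverage_bp: float, chromosome_length: float) -> float:
    """Mean per-nucleotide coverage implied by summed tract coverage."""
    if chromosome_length <= 0:
        raise ValueError("chromosome length must be positive")
    return total_coverage_bp / chromosome_length


__all__ = [
    "build_coverage", "feature_coverage", "transcript_coverage",
    "gene_coverage_table", "flag_extremes", "gap_qc", "normalize_coverage",
    "aa_polymorphism_count", "category_labels",
    "mean_tracts_per_strain", "fold_coverage",
]
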