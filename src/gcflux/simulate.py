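"""Synthetic arrangement-structured haplotype panels with known conversion tracts.

The generator emulates the statistical structure that psi-based tract
detection consumes, not a full coalescent: inversion arrangements behave as
nearly isolated subpopulations, so inter-arrangement divergence is modelled
directly as arrangement-diagnostic biallelic sites (density ``divergence_rate``
per site), on top of shared ancestral sequence, within-arrangement
polymorphism, and alignment gaps.  Conversion events copy a geometric-length
window from a donor strain onto a recipient strain; a purifying-selection veto
removes (with probability ``veto_probability``) events that overlap an outlier
CDS of the recipient's own arrangement.  Every implanted event is recorded in
a truth table so downstream recall and calibration are checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import (
    CODE_TO_ALLELE,
    GAP_CODE,
    GeneModel,
    HaplotypePanel,
    RegionMap,
)

ARRANGEMENT_CODES = ("AR", "ST", "PP", "CH", "TL", "CU")


@dataclass
class SimConfig:
    """Parameters of the synthetic panel generator.

    Defaults mirror the study conditions at desk scale: five arrangement
    subpopulations with the study's sample sizes (15, 8, 10, 9, 9), a 500 kb
    chromosome split into 14 ordered syntenic regions, ~2% of cells gapped,
    and a tract-extension probability ``phi_true = 0.995`` (geometric mean
    length 200 bp, the 200-300 bp scale of fly conversion tracts).
    ``events_per_pair`` is the Poisson mean number of conversion events per
    ordered donor->recipient arrangement pair; 625 gives each recipient
    arrangement ~1x expected tract coverage of the chromosome.
    """

    n_arrangements: int = 5
    samples_per_arrangement: tuple[int, ...] = (15, 8, 10, 9, 9)
    chromosome_length: int = 500_000
    n_regions: int = 14
    divergence_rate: float = 0.03     # per-site P(arrangement-diagnostic allele)
    theta_site: float = 0.005         # per-site P(within-arrangement polymorphism)
    gap_rate: float = 0.02
    events_per_pair: float = 625.0    # lambda, per ordered arrangement pair
    phi_true: float = 0.995           # tract extension probability
    n_genes: int = 100
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 100
    intergenic_length: int = 500
    outlier_fraction: float = 0.05
    max_outlier_run: int = 2
    #: restrict outlier backgrounds to these arrangements (None = all); the
    #: per-arrangement coverage tests are sharpest when a focal background
    #: carries all outlier genes
    outlier_arrangements: tuple[str, ...] | None = None
    veto_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.samples_per_arrangement, int):
            self.samples_per_arrangement = tuple(
                [self.samples_per_arrangement] * self.n_arrangements)
        else:
            self.samples_per_arrangement = tuple(self.samples_per_arrangement)
        if len(self.samples_per_arrangement) != self.n_arrangements:
            raise ValueError("need one sample size per arrangement")
        for name in ("divergence_rate", "theta_site", "gap_rate",
                     "outlier_fraction", "veto_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.phi_true < 1.0:
            raise ValueError("phi_true must lie in (0, 1)")
        if self.events_per_pair < 0:
            raise ValueError("events_per_pair must be >= 0")
        if self.chromosome_length < self.n_regions:
            raise ValueError("chromosome shorter than the number of regions")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "samples_per_arrangement" in data:
            data["samples_per_arrangement"] = tuple(data["samples_per_arrangement"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["samples_per_arrangement"] = list(self.samples_per_arrangement)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class TruthEvent:
    """One implanted conversion event (surviving or vetoed)."""

    donor_arrangement: str
    donor_strain: str
    recipient_strain: str
    recipient_arrangement: str
    start: int
    length: int
    surviving: bool

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class TruthTable:
    events: list[TruthEvent] = field(default_factory=list)

    @property
    def surviving(self) -> list[TruthEvent]:
        return [e for e in self.events if e.surviving]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("donor_arr\tdonor_strain\trecipient_strain\t"
                     "recipient_arr\tstart\tlength\tsurviving\n")
            for e in self.events:
                fh.write(f"{e.donor_arrangement}\t{e.donor_strain}\t"
                         f"{e.recipient_strain}\t{e.recipient_arrangement}\t"
                         f"{e.start}\t{e.length}\t{int(e.surviving)}\n")


def _make_region_map(length: int, n_regions: int) -> RegionMap:
    bounds = np.linspace(0, length, n_regions + 1).astype(np.int64)
    regions = [
        (f"R{i + 1:02d}", int(bounds[i]) + 1, int(bounds[i + 1]))
        for i in range(n_regions)
    ]
    return RegionMap(regions)


def _make_genes(config: SimConfig) -> list[GeneModel]:
    gene_span = (config.exons_per_gene * config.exon_length
                 + (config.exons_per_gene - 1) * config.intron_length)
    unit = gene_span + config.intergenic_length
    if config.n_genes * unit > config.chromosome_length:
        raise ValueError("impossible geometry: genes exceed chromosome length")
    genes = []
    for i in range(config.n_genes):
        start = i * unit + config.intergenic_length // 2 + 1
        exons = []
        s = start
        for _ in range(config.exons_per_gene):
            exons.append((s, s + config.exon_length - 1))
            s += config.exon_length + config.intron_length
        genes.append(GeneModel(gene_id=f"g{i + 1:04d}",
                               strand="+" if i % 2 == 0 else "-",
                               exons=tuple(exons)))
    return genes


def plant_outliers(
    genes: Sequence[GeneModel],
    outlier_fraction: float,
    arrangements: Sequence[str],
    rng: np.random.Generator,
    max_run: int = 2,
) -> list[GeneModel]:
    """Label a fraction of genes as selection-candidate outliers.

    Each outlier gene is assigned to a single arrangement background drawn
    uniformly.  Outliers are interspersed along the chromosome: selections
    whose longest run of adjacent outlier genes exceeds ``max_run`` are
    rejected and redrawn (when geometrically possible).
    """
    if not 0.0 <= outlier_fraction <= 1.0:
        raise ValueError("outlier_fraction must lie in [0, 1]")
    n = len(genes)
    k = int(round(outlier_fraction * n))
    if k == 0:
        return [GeneModel(g.gene_id, g.strand, g.exons, frozenset(),
                          g.aa_polymorphism_count) for g in genes]
    chosen = None
    for _ in range(1000):
        cand = np.sort(rng.choice(n, size=k, replace=False))
        runs = np.split(cand, np.flatnonzero(np.diff(cand) != 1) + 1)
        if k >= n or max(len(r) for r in runs) <= max_run:
            chosen = cand
            break
    if chosen is None:  # geometrically impossible bound; accept last draw
        chosen = cand
    chosen_set = set(int(i) for i in chosen)
    out = []
    for i, g in enumerate(genes):
        if i in chosen_set:
            arr = arrangements[int(rng.integers(len(arrangements)))]
            label = frozenset({arr})
        else:
            label = frozenset()
        out.append(GeneModel(g.gene_id, g.strand, g.exons, label,
                             g.aa_polymorphism_count))
    return out


def _outlier_cds_prefix(genes: Sequence[GeneModel], arrangements: Sequence[str],
                        length: int) -> dict[str, np.ndarray]:
    """Per arrangement: prefix[i] = number of outlier-CDS bases at positions <= i."""
    out = {}
    for arr in arrangements:
        ind = np.zeros(length + 1, dtype=np.int64)
        for g in genes:
            if arr in g.outlier_in:
                for s, e in g.exons:
                    ind[s:e + 1] = 1
        out[arr] = np.cumsum(ind)
    return out


def simulate_panel(
    config: SimConfig,
) -> tuple[HaplotypePanel, RegionMap, list[GeneModel], TruthTable]:
    """Generate a panel, region map, annotated genes, and the truth table.

    Deterministic given ``config.seed``.  Arrangement-diagnostic alleles are
    fixed within their owner arrangement and absent elsewhere before any
    conversion; each surviving event copies the donor strain's current alleles
    onto the recipient over a geometric-length window that never straddles a
    region boundary.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chromosome_length
    arrs = list(ARRANGEMENT_CODES[: config.n_arrangements])
    strain_ids: list[str] = []
    strain_arr: dict[str, str] = {}
    for arr, n in zip(arrs, config.samples_per_arrangement):
        for i in range(n):
            sid = f"{arr}_{i + 1:02d}"
            strain_ids.append(sid)
            strain_arr[sid] = arr
    n_strains = len(strain_ids)
    arr_rows = {a: np.asarray([i for i, s in enumerate(strain_ids)
                               if strain_arr[s] == a]) for a in arrs}

    region_map = _make_region_map(L, config.n_regions)
    outlier_arrs = (list(config.outlier_arrangements)
                    if config.outlier_arrangements else arrs)
    genes = plant_outliers(_make_genes(config), config.outlier_fraction,
                           outlier_arrs, rng, config.max_outlier_run)

    # ancestral sequence and arrangement-diagnostic divergence
    base = rng.integers(0, 4, size=L, dtype=np.uint8)
    codes = np.tile(base, (n_strains, 1))
    diag_sites = np.flatnonzero(rng.random(L) < config.divergence_rate)
    if len(diag_sites):
        owners = rng.integers(0, len(arrs), size=len(diag_sites))
        alt = (base[diag_sites] + rng.integers(1, 4, size=len(diag_sites))) % 4
        for ai, arr in enumerate(arrs):
            sel = diag_sites[owners == ai]
            codes[np.ix_(arr_rows[arr], sel)] = alt[owners == ai]

    # within-arrangement shared polymorphism
    poly_sites = np.flatnonzero(rng.random(L) < config.theta_site)
    for j in poly_sites:
        arr = arrs[int(rng.integers(len(arrs)))]
        rows = arr_rows[arr]
        freq = rng.uniform(0.1, 0.6)
        carriers = rows[rng.random(len(rows)) < freq]
        if len(carriers):
            codes[carriers, j] = (base[j] + rng.integers(1, 4)) % 4

    # conversion events with purifying-selection veto
    prefixes = _outlier_cds_prefix(genes, arrs, L)
    reg_starts, reg_ends = region_map.starts, region_map.ends
    truth = TruthTable()
    for donor in arrs:
        for recip in arrs:
            if donor == recip:
                continue
            n_ev = int(rng.poisson(config.events_per_pair))
            for _ in range(n_ev):
                d_row = int(rng.choice(arr_rows[donor]))
                r_row = int(rng.choice(arr_rows[recip]))
                length = int(rng.geometric(1.0 - config.phi_true))
                length = min(length, L)
                # uniform start; redraw while the tract straddles a region edge
                for _ in range(1000):
                    start = int(rng.integers(1, L - length + 2))
                    end = start + length - 1
                    ri = np.searchsorted(reg_starts, start, side="right") - 1
                    if end <= reg_ends[ri]:
                        break
                else:  # pathological geometry; clip into the region
                    start = int(reg_starts[ri])
                    end = start + length - 1
                overlap = prefixes[recip][end] - prefixes[recip][start - 1]
                vetoed = overlap > 0 and rng.random() < config.veto_probability
                if not vetoed:
                    codes[r_row, start - 1:end] = codes[d_row, start - 1:end]
                truth.events.append(TruthEvent(
                    donor_arrangement=donor,
                    donor_strain=strain_ids[d_row],
                    recipient_strain=strain_ids[r_row],
                    recipient_arrangement=recip,
                    start=start, length=length, surviving=not vetoed,
                ))

    # alignment gaps, sprinkled uniformly per strain row
    if config.gap_rate > 0:
        for i in range(n_strains):
            gaps = rng.random(L) < config.gap_rate
            codes[i, gaps] = GAP_CODE

    panel = HaplotypePanel(
        strain_ids=strain_ids,
        arrangement_of=strain_arr,
        positions=np.arange(1, L + 1),
        alleles=CODE_TO_ALLELE[codes],
        chromosome_length=L,
    )
    return panel, region_map, genes, truth


__all__ = ["SimConfig", "TruthEvent", "TruthTable", "simulate_panel",
           "plant_outliers", "ARRANGEMENT_CODES"]
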