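"""psi-based gene conversion tract detection between inversion arrangements.

For an ordered (donor, recipient) arrangement pair, a site is *informative*
for a focal recipient strain when the strain's allele is at high frequency in
the donor arrangement and at lower frequency among the remaining strains of
its own arrangement; the informativeness probability is

    psi = f_donor * (1 - f_recipient_rest),

gated by ``f_donor > f_recipient_rest`` and ``f_donor >= min_donor_freq``.
psi is 1 for a perfectly diagnostic site (fixed in the donor, absent from the
recipient background) and decays as the frequency contrast weakens.

A conversion tract is a maximal run of two or more informative sites, within
one syntenic region, that is not interrupted by a *contradiction* site -- a
polymorphic site where the strain's allele has frequency zero in the donor
but non-zero frequency in the recipient rest (evidence the strain still sits
on its own background there).  Non-informative, non-contradicting sites are
neutral interior sites: converted segments legitimately contain positions
that were identical between arrangements.

Gap (``-``) and missing (``N``) chromosomes are excluded from every frequency
denominator site by site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import ConversionTract, HaplotypePanel, RegionMap

DEFAULT_MIN_DONOR_FREQ = 0.5


@dataclass(frozen=True)
class InformativeSite:
    """One site supporting a candidate tract in a focal recipient strain."""

    position: int
    recipient_strain: str
    donor_arrangement: str
    allele: str
    f_donor: float
    f_recipient_rest: float
    psi: float


def site_psi(
    allele_counts_donor: Mapping[str, int],
    allele_counts_recipient_rest: Mapping[str, int],
    focal_allele: str,
    min_donor_freq: float = DEFAULT_MIN_DONOR_FREQ,
) -> float | None:
    """psi for one site from per-group allele counts (gaps/N already excluded).

    Returns ``None`` when the site is not informative: no usable chromosomes
    in either group, donor frequency below ``min_donor_freq``, or no frequency
    excess of the donor over the recipient rest.  Multi-allelic sites reduce
    to focal allele vs rest.
    """
    n_donor = sum(allele_counts_donor.values())
    n_rest = sum(allele_counts_recipient_rest.values())
    if n_donor == 0 or n_rest == 0:
        return None
    f_donor = allele_counts_donor.get(focal_allele, 0) / n_donor
    f_rest = allele_counts_recipient_rest.get(focal_allele, 0) / n_rest
    if f_donor < min_donor_freq or f_donor <= f_rest:
        return None
    return f_donor * (1.0 - f_rest)


class _PanelContext:
    """Shared per-panel precomputation for the pairwise scans.

    Only panel-wide polymorphic columns can be informative or contradicting
    (at a monomorphic site every usable frequency is 1), so the scans are
    restricted to them; ``active`` maps back to panel column indices.
    """

    def __init__(self, panel: HaplotypePanel):
        codes = panel.codes()
        present = np.zeros((4, codes.shape[1]), dtype=bool)
        for b in range(4):
            present[b] = (codes == b).any(axis=0)
        self.active = np.flatnonzero(present.sum(axis=0) >= 2)
        self.counts: dict[str, np.ndarray] = {}
        sub_codes = codes[:, self.active]
        for arr in panel.arrangements:
            rows = panel.strain_indices(arr)
            counts = np.empty((len(self.active), 4), dtype=np.int32)
            for b in range(4):
                counts[:, b] = (sub_codes[rows] == b).sum(axis=0)
            self.counts[arr] = counts
        self.sub_codes = sub_codes
        self._codes = codes
        self._positions = panel.positions
        self._gap_pos_cache: dict[int, np.ndarray] = {}

    def gap_count(self, row: int, start: int, end: int) -> int:
        """Number of gap ('-') columns for one strain within [start, end]."""
        if row not in self._gap_pos_cache:
            self._gap_pos_cache[row] = self._positions[self._codes[row] == 5]
        gaps = self._gap_pos_cache[row]
        return int(np.searchsorted(gaps, end, side="right")
                   - np.searchsorted(gaps, start, side="left"))


def detect_tracts(
    panel: HaplotypePanel,
    region_map: RegionMap,
    donor: str,
    recipient: str,
    min_donor_freq: float = DEFAULT_MIN_DONOR_FREQ,
    min_informative: int = 2,
    chunk_size: int | None = None,
    _ctx: "_PanelContext | None" = None,
) -> list[ConversionTract]:
    """Infer donor->recipient conversion tracts for every recipient strain.

    Tracts never straddle region boundaries.  ``chunk_size`` batches the
    column-wise frequency computation (memory parity with subregion
    processing); tract calls are invariant to it because runs are only closed
    by contradiction sites and region edges, both evaluated globally.
    """
    if donor == recipient:
        raise ValueError("donor and recipient arrangements must differ")
    ctx = _ctx if _ctx is not None else _PanelContext(panel)
    if donor not in ctx.counts or recipient not in ctx.counts:
        raise ValueError("unknown arrangement code")
    donor_counts = ctx.counts[donor]
    recip_counts = ctx.counts[recipient]
    n_donor = donor_counts.sum(axis=1)
    n_recip = recip_counts.sum(axis=1)
    positions = panel.positions[ctx.active]
    region_idx = region_map.region_index_of(positions)

    n_sites = len(ctx.active)
    if chunk_size is None or chunk_size >= n_sites:
        chunks = [slice(0, n_sites)]
    else:
        chunks = [slice(i, min(i + chunk_size, n_sites))
                  for i in range(0, n_sites, chunk_size)]

    tracts: list[ConversionTract] = []
    for row in panel.strain_indices(recipient):
        strain = panel.strain_ids[row]
        informative = np.zeros(n_sites, dtype=bool)
        contradiction = np.zeros(n_sites, dtype=bool)
        psi = np.zeros(n_sites)
        for sl in chunks:
            c = ctx.sub_codes[row, sl]
            valid = c < 4
            cc = np.where(valid, c, 0)
            ar = np.arange(sl.start, sl.stop)
            fd_num = donor_counts[ar, cc]
            rest_num = recip_counts[ar, cc] - valid.astype(np.int32)
            n_rest = n_recip[sl] - valid.astype(np.int32)
            usable = valid & (n_donor[sl] > 0) & (n_rest > 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                fd = np.where(n_donor[sl] > 0, fd_num / n_donor[sl], 0.0)
                fr = np.where(n_rest > 0, rest_num / n_rest, 0.0)
            inf = usable & (fd >= min_donor_freq) & (fd > fr)
            con = usable & (fd_num == 0) & (rest_num > 0)
            informative[sl] = inf
            contradiction[sl] = con
            psi[sl] = np.where(inf, fd * (1.0 - fr), 0.0)

        inf_idx = np.flatnonzero(informative)
        if len(inf_idx) < min_informative:
            continue
        con_idx = np.flatnonzero(contradiction)
        # break a run between consecutive informative sites if a contradiction
        # site or a region boundary lies between them
        con_before = np.searchsorted(con_idx, inf_idx)
        breaks = np.flatnonzero(
            (np.diff(con_before) > 0)
            | (np.diff(region_idx[inf_idx]) != 0)
            | (region_idx[inf_idx][:-1] < 0)
        ) + 1
        donor_set = frozenset({donor})
        for run in np.split(inf_idx, breaks):
            if len(run) < min_informative or region_idx[run[0]] < 0:
                continue
            run_pos = positions[run]
            start = int(run_pos[0])
            end = int(run_pos[-1])
            n_gap = ctx.gap_count(row, start, end)
            run_psi = psi[run]
            sites = tuple(zip(run_pos.tolist(), run_psi.tolist()))
            tracts.append(ConversionTract(
                recipient_strain=strain,
                recipient_arrangement=recipient,
                donor_arrangements=donor_set,
                start=start,
                end=end,
                length_excl_gaps=end - start + 1 - n_gap,
                informative_sites=sites,
                mean_psi=float(run_psi.mean()),
            ))
    return tracts


def run_all_pairs(
    panel: HaplotypePanel,
    region_map: RegionMap,
    min_donor_freq: float = DEFAULT_MIN_DONOR_FREQ,
    min_informative: int = 2,
    chunk_size: int | None = None,
) -> list[ConversionTract]:
    """Detect tracts for every ordered (donor, recipient) arrangement pair.

    For k arrangements this runs k*(k-1) ordered comparisons; each tract is
    tagged with the donor it was detected under.
    """
    arrs = panel.arrangements
    if len(arrs) < 2:
        raise ValueError("need at least two arrangements")
    ctx = _PanelContext(panel)
    tracts: list[ConversionTract] = []
    for donor, recipient in itertools.permutations(arrs, 2):
        tracts.extend(detect_tracts(
            panel, region_map, donor, recipient,
            min_donor_freq=min_donor_freq,
            min_informative=min_informative,
            chunk_size=chunk_size,
            _ctx=ctx,
        ))
    return tracts


def deduplicate(tracts: Iterable[ConversionTract]) -> list[ConversionTract]:
    """Collapse redundant detections; idempotent.

    Rule 1 (multi-donor redundancy): tracts in the same recipient strain with
    overlapping spans collapse to one record; its coordinates come from the
    variant with the most informative sites (ties: longest span, then
    lexicographically smallest donor set) and its ``donor_arrangements`` is
    the union over the cluster.

    Rule 2 (multi-strain redundancy): tracts with identical (start, end) in
    different strains of the same arrangement -- one ancestral event risen in
    frequency -- collapse to the alphabetically first strain's record.
    """
    by_strain: dict[str, list[ConversionTract]] = {}
    for t in tracts:
        by_strain.setdefault(t.recipient_strain, []).append(t)

    stage1: list[ConversionTract] = []
    for strain, group in by_strain.items():
        group.sort(key=lambda t: (t.start, t.end))
        cluster: list[ConversionTract] = []
        cluster_end = -1
        for t in group:
            if cluster and t.start > cluster_end:
                stage1.append(_collapse_cluster(cluster))
                cluster = []
                cluster_end = -1
            cluster.append(t)
            cluster_end = max(cluster_end, t.end)
        if cluster:
            stage1.append(_collapse_cluster(cluster))

    by_key: dict[tuple[str, int, int], ConversionTract] = {}
    for t in stage1:
        key = (t.recipient_arrangement, t.start, t.end)
        prev = by_key.get(key)
        if prev is None or t.recipient_strain < prev.recipient_strain:
            by_key[key] = t
    out = list(by_key.values())
    out.sort(key=lambda t: (t.recipient_arrangement, t.start, t.end,
                            t.recipient_strain))
    return out


def _collapse_cluster(cluster: list[ConversionTract]) -> ConversionTract:
    rep = min(cluster, key=lambda t: (
        -t.n_informative, -(t.end - t.start), sorted(t.donor_arrangements)))
    donors = frozenset().union(*(t.donor_arrangements for t in cluster))
    if donors == rep.donor_arrangements:
        return rep
    return replace(rep, donor_arrangements=donors)


def polarity_subset(tracts: Iterable[ConversionTract]) -> list[ConversionTract]:
    """Tracts detected under a single donor, so polarity is unambiguous."""
    return [t for t in tracts if len(t.donor_arrangements) == 1]


__all__ = [
    "InformativeSite", "site_psi", "detect_tracts", "run_all_pairs",
    "deduplicate", "polarity_subset", "DEFAULT_MIN_DONOR_FREQ",
]
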