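"""Shared fixtures and small panel builders."""

from __future__ import annotations

import numpy as np
import pytest

from gcflux import ConversionTract, HaplotypePanel, RegionMap


def panel_from_strings(rows: dict[str, str], labels: dict[str, str],
                       positions=None, chromosome_length=None) -> HaplotypePanel:
    """Build a panel from {strain: allele-string} plus arrangement labels."""
    strains = list(rows)
    length = len(next(iter(rows.values())))
    if positions is None:
        positions = np.arange(1, length + 1)
    positions = np.asarray(positions, dtype=np.int64)
    alleles = np.array([list(rows[s]) for s in strains]).astype("S1")
    return HaplotypePanel(
        strain_ids=strains,
        arrangement_of=labels,
        positions=positions,
        alleles=alleles,
        chromosome_length=chromosome_length or int(positions[-1]),
    )


def make_tract(strain="AR_01", arr="AR", donors=("CH",), start=10, end=20,
               psi=1.0, n_sites=2, length_excl_gaps=None) -> ConversionTract:
    positions = np.linspace(start, end, n_sites).astype(int).tolist()
    positions[0], positions[-1] = start, end
    return ConversionTract(
        recipient_strain=strain,
        recipient_arrangement=arr,
        donor_arrangements=frozenset(donors),
        start=start,
        end=end,
        length_excl_gaps=length_excl_gaps
        if length_excl_gaps is not None else end - start + 1,
        informative_sites=tuple((p, psi) for p in positions),
        mean_psi=psi,
    )


def random_small_panel(rng: np.random.Generator) -> tuple[HaplotypePanel, RegionMap]:
    """Random panel with <= 8 strains, 2-3 arrangements, <= 50 polymorphic sites.

    Allele draws are biased toward an arrangement-typical allele so that
    informative runs actually occur; a few cells become gaps or N.
    """
    n_arr = int(rng.integers(2, 4))
    arrs = ["AR", "ST", "PP"][:n_arr]
    sizes = rng.integers(2, 4, size=n_arr)
    while sizes.sum() > 8:
        sizes[np.argmax(sizes)] -= 1
    strains, labels = [], {}
    for arr, k in zip(arrs, sizes):
        for i in range(k):
            s = f"{arr}_{i + 1}"
            strains.append(s)
            labels[s] = arr
    n_sites = int(rng.integers(5, 51))
    chrom_len = 10_000
    positions = np.sort(rng.choice(chrom_len, size=n_sites, replace=False)) + 1
    bases = np.array(list("ACGT"))
    rows = {}
    arr_allele = {arr: rng.integers(0, 4, size=n_sites) for arr in arrs}
    for s in strains:
        arr = labels[s]
        draw = arr_allele[arr].copy()
        # copy another arrangement's allele at ~20% of sites (conversion-like)
        other = arrs[int(rng.integers(n_arr))]
        swap = rng.random(n_sites) < 0.2
        draw[swap] = arr_allele[other][swap]
        noise = rng.random(n_sites) < 0.1
        draw[noise] = rng.integers(0, 4, size=int(noise.sum()))
        chars = bases[draw]
        special = rng.random(n_sites) < 0.05
        chars[special] = rng.choice(["-", "N"], size=int(special.sum()))
        rows[s] = "".join(chars)
    mid = chrom_len // 2
    region_map = RegionMap([("R1", 1, mid), ("R2", mid + 1, chrom_len)])
    panel = panel_from_strings(rows, labels, positions, chrom_len)
    return panel, region_map


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240729)
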