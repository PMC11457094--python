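"""Domain types and file formats for the gene-conversion pipeline.

Coordinate convention
---------------------
All in-memory coordinates are 1-based inclusive: a tract spanning positions
``start..end`` covers ``end - start + 1`` nucleotides.  BED and BedGraph files
are 0-based half-open on disk; the conversion happens exactly once, inside the
readers and writers in this module.

Alleles are single characters from ``{A, C, G, T, N, -}``.  ``N`` (missing
data) and ``-`` (alignment gap) are distinct, but both are excluded from every
allele-frequency denominator downstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("gcflux")

VALID_ALLELES = frozenset("ACGTN-")

#: integer codes used internally: A=0 C=1 G=2 T=3 N=4 -=5
ALLELE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
CODE_TO_ALLELE = np.array([b"A", b"C", b"G", b"T", b"N", b"-"], dtype="S1")
GAP_CODE = 5
MISSING_CODE = 4


def _encode_alleles(chars: np.ndarray) -> np.ndarray:
    """Map an ``S1`` allele matrix to uint8 codes (A=0..T=3, N=4, -=5)."""
    lut = np.full(256, 255, dtype=np.uint8)
    for ch, code in ALLELE_CODES.items():
        lut[ord(ch)] = code
    codes = lut[chars.view(np.uint8)]
    if (codes == 255).any():
        bad = chars.view(np.uint8)[codes == 255][0]
        raise ValueError(f"non-IUPAC character {chr(bad)!r} in alignment")
    return codes


# ---------------------------------------------------------------------------
# Haplotype panel
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Aligned allele matrix (strains x positions) with arrangement labels.

    ``positions`` are strictly increasing 1-based chromosome coordinates; the
    matrix may carry every site of a full alignment or only the polymorphic
    columns of a SNP table.  ``chromosome_length`` anchors the panel on the
    physical chromosome either way.
    """

    strain_ids: list[str]
    arrangement_of: dict[str, str]
    positions: np.ndarray
    alleles: np.ndarray  # dtype 'S1', shape (n_strains, n_positions)
    chromosome_length: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype="S1")
        if self.alleles.shape != (len(self.strain_ids), len(self.positions)):
            raise ValueError("allele matrix shape does not match strains x positions")
        missing = [s for s in self.strain_ids if s not in self.arrangement_of]
        if missing:
            raise ValueError(f"strain without arrangement label: {missing[0]}")
        if len(set(self.arrangement_of[s] for s in self.strain_ids)) < 2:
            raise ValueError("panel must contain at least two arrangements")
        if len(self.positions) and (
            self.positions[0] < 1 or self.positions[-1] > self.chromosome_length
        ):
            raise ValueError("positions outside [1, chromosome_length]")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        self._codes: np.ndarray | None = None
        self.codes()  # eager character-set validation

    # -- derived views ------------------------------------------------------

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def arrangements(self) -> list[str]:
        return sorted(set(self.arrangement_of[s] for s in self.strain_ids))

    def strain_indices(self, arrangement: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.strain_ids)
               if self.arrangement_of[s] == arrangement]
        if not idx:
            raise ValueError(f"unknown arrangement code: {arrangement}")
        return np.asarray(idx, dtype=np.intp)

    def codes(self) -> np.ndarray:
        """uint8-coded allele matrix (cached)."""
        if self._codes is None:
            self._codes = _encode_alleles(self.alleles)
        return self._codes


# ---------------------------------------------------------------------------
# Region map
# ---------------------------------------------------------------------------

@dataclass
class RegionMap:
    """Ordered syntenic blocks delimiting detection and resampling units.

    ``regions`` is a list of ``(region_id, start, end)`` with 1-based
    inclusive bounds, sorted and non-overlapping.  ``subregions`` optionally
    refines each region into processing chunks; every subregion nests in
    exactly one region.
    """

    regions: list[tuple[str, int, int]]
    subregions: dict[str, list[tuple[str, int, int]]] | None = None

    def __post_init__(self) -> None:
        prev_end = 0
        for rid, start, end in self.regions:
            if start > end or start < 1:
                raise ValueError(f"region {rid} has non-positive size")
            if start <= prev_end:
                raise ValueError(f"region {rid} overlaps or is unsorted")
            prev_end = end
        if self.subregions is not None:
            bounds = {rid: (s, e) for rid, s, e in self.regions}
            for rid, subs in self.subregions.items():
                lo, hi = bounds[rid]
                for sid, s, e in subs:
                    if not (lo <= s <= e <= hi):
                        raise ValueError(f"subregion {sid} not nested in {rid}")

    @property
    def starts(self) -> np.ndarray:
        return np.asarray([s for _, s, _ in self.regions], dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return np.asarray([e for _, _, e in self.regions], dtype=np.int64)

    def region_index_of(self, positions: np.ndarray) -> np.ndarray:
        """Index of the containing region per position (-1 if in no region)."""
        positions = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(self.starts, positions, side="right") - 1
        idx = np.clip(idx, 0, len(self.regions) - 1)
        inside = (positions >= self.starts[idx]) & (positions <= self.ends[idx])
        return np.where(inside, idx, -1)

    def subdivide(self, chunk: int = 250_000) -> "RegionMap":
        """Attach fixed-size processing subregions (default 250 kb)."""
        subs: dict[str, list[tuple[str, int, int]]] = {}
        for rid, start, end in self.regions:
            pieces = []
            s = start
            k = 1
            while s <= end:
                e = min(s + chunk - 1, end)
                pieces.append((f"{rid}.{k}", s, e))
                s = e + 1
                k += 1
            subs[rid] = pieces
        return RegionMap(list(self.regions), subs)


# ---------------------------------------------------------------------------
# Conversion tract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConversionTract:
    """One inferred donor-to-recipient exchange in a single recipient strain.

    ``informative_sites`` holds ``(position, psi)`` for every site supporting
    the tract; ``start``/``end`` equal the outermost informative positions and
    ``length_excl_gaps`` is the span length minus the recipient strain's gap
    columns inside the span.
    """

    recipient_strain: str
    recipient_arrangement: str
    donor_arrangements: frozenset[str]
    start: int
    end: int
    length_excl_gaps: int
    informative_sites: tuple[tuple[int, float], ...]
    mean_psi: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("tract start > end")
        if len(self.informative_sites) < 2:
            raise ValueError("tract needs >= 2 informative sites")
        pos = [p for p, _ in self.informative_sites]
        if min(pos) != self.start or max(pos) != self.end:
            raise ValueError("start/end must equal outermost informative sites")
        if self.length_excl_gaps > self.end - self.start + 1:
            raise ValueError("length_excl_gaps exceeds span")
        if not 0.0 < self.mean_psi <= 1.0:
            raise ValueError("mean_psi must be in (0, 1]")
        if self.recipient_arrangement in self.donor_arrangements:
            raise ValueError("recipient arrangement cannot be its own donor")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def n_informative(self) -> int:
        return len(self.informative_sites)


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Gene with exon/intron structure and per-arrangement outlier labels.

    Strand is bookkeeping only: conversion tracts are strandless exchanges,
    so coverage never consults it.
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    outlier_in: frozenset[str] = frozenset()
    aa_polymorphism_count: int | None = None

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(tuple(e) for e in self.exons))
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intervals strictly between consecutive exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


# ---------------------------------------------------------------------------
# Coverage track
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Per-nucleotide count of conversion tracts for one recipient arrangement."""

    arrangement: str
    values: np.ndarray  # int array, length = chromosome_length

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    @property
    def chromosome_length(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Model-fit and permutation results
# ---------------------------------------------------------------------------

@dataclass
class PhiFit:
    """ML fit of the geometric tract-length model for one (region, donor, recipient)."""

    region_id: str
    donor: str
    recipient: str
    phi_hat: float
    asymptotic_variance: float
    tract_length_mean: float
    tract_length_low: float
    tract_length_high: float
    p_unobserved: float
    expected_k: float
    n_observed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_hat < 1.0:
            raise ValueError("phi_hat must lie in (0, 1)")
        if not (self.tract_length_low <= self.tract_length_mean
                <= self.tract_length_high):
            raise ValueError("tract-length CI must bracket the point estimate")
        if not 0.0 <= self.p_unobserved < 1.0:
            raise ValueError("p_unobserved must lie in [0, 1)")
        if self.expected_k < self.n_observed:
            raise ValueError("expected_k must be >= observed tract count")


@dataclass
class PermutationResult:
    """Outcome of one permutation test, with both one-sided empirical p-values.

    p-values use the add-one rule (b+1)/(m+1); ties count on both sides, so
    ``p_lower + p_upper >= 1``.
    """

    statistic_name: str
    observed: float
    n_replicates: int
    p_lower: float
    p_upper: float
    null_min: float
    null_max: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if self.null_min > self.null_max:
            raise ValueError("null_min must be <= null_max")
        if self.p_lower + self.p_upper < 1.0 - 1e-12:
            raise ValueError("p_lower + p_upper must be >= 1 (ties both sides)")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, str]:
    """Read a strain -> arrangement table (TSV with header strain/arrangement)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["strain"]] = row["arrangement"]
    return out


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("strain\tarrangement\n")
        for strain, arr in labels.items():
            fh.write(f"{strain}\t{arr}\n")


def read_panel(
    path: str | Path,
    labels_path: str | Path,
    chromosome_length: int | None = None,
) -> HaplotypePanel:
    """Read an aligned FASTA or a SNP-table TSV into a :class:`HaplotypePanel`.

    FASTA input must be a gapped alignment of equal-length sequences; the
    chromosome length is the alignment length.  The SNP-table dialect has a
    header ``position  ref  <strain>...`` and one row per polymorphic site;
    ``chromosome_length`` defaults to the last position.
    """
    path = Path(path)
    labels = read_labels(labels_path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError("empty FASTA input")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValueError("unaligned input: sequences differ in length")
        length = lengths.pop()
        strain_ids = [r.id for r in records]
        alleles = np.frombuffer(
            "".join(str(r.seq).upper() for r in records).encode(), dtype="S1"
        ).reshape(len(records), length)
        panel = HaplotypePanel(
            strain_ids=strain_ids,
            arrangement_of={s: labels[s] for s in strain_ids if s in labels},
            positions=np.arange(1, length + 1),
            alleles=alleles.copy(),
            chromosome_length=chromosome_length or length,
        )
    else:
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header[:2] != ["position", "ref"]:
                raise ValueError("SNP table must start with columns position, ref")
            strain_ids = header[2:]
            positions = []
            rows = []
            for rec in reader:
                if not rec:
                    continue
                positions.append(int(rec[0]))
                rows.append(rec[2:])
        alleles = np.array(rows, dtype="S1").T if rows else np.empty(
            (len(strain_ids), 0), dtype="S1")
        panel = HaplotypePanel(
            strain_ids=strain_ids,
            arrangement_of={s: labels[s] for s in strain_ids if s in labels},
            positions=np.asarray(positions, dtype=np.int64),
            alleles=alleles,
            chromosome_length=chromosome_length
            or (int(positions[-1]) if positions else 0),
        )
    panel.codes()  # validates the character set eagerly
    return panel


def write_panel_fasta(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as an aligned FASTA (only valid for full alignments)."""
    if len(panel.positions) != panel.chromosome_length:
        raise ValueError("FASTA output requires a full per-nucleotide alignment")
    records = [
        SeqRecord(Seq(panel.alleles[i].tobytes().decode()), id=s, description="")
        for i, s in enumerate(panel.strain_ids)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_snp_table(panel: HaplotypePanel, path: str | Path,
                    polymorphic_only: bool = True) -> None:
    """Write the panel in the SNP-table TSV dialect.

    The ``ref`` column holds the major (most frequent non-gap, non-missing)
    allele per site; it is informational only on read-back.
    """
    codes = panel.codes()
    keep = np.arange(len(panel.positions))
    if polymorphic_only and len(panel.positions):
        usable = codes < 4
        poly = np.zeros(len(panel.positions), dtype=bool)
        for b in range(4):
            present = ((codes == b) & usable).any(axis=0)
            poly |= present & (
                ((codes != b) & usable).any(axis=0)
            )
        keep = np.flatnonzero(poly)
    with open(path, "w") as fh:
        fh.write("position\tref\t" + "\t".join(panel.strain_ids) + "\n")
        for j in keep:
            col = codes[:, j]
            counts = np.bincount(col[col < 4], minlength=4)
            ref = CODE_TO_ALLELE[int(np.argmax(counts))].decode() if counts.sum() else "N"
            row = panel.alleles[:, j].tobytes().decode()
            fh.write(f"{panel.positions[j]}\t{ref}\t" + "\t".join(row) + "\n")


def read_region_map(bed_path: str | Path, chromosome_length: int) -> RegionMap:
    """Read syntenic regions from BED4 (0-based half-open on disk)."""
    regions = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            start0, end0 = int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"R{len(regions) + 1}"
            if end0 > chromosome_length:
                raise ValueError(f"region {name} extends beyond chromosome end")
            regions.append((name, start0 + 1, end0))
    regions.sort(key=lambda r: r[1])
    return RegionMap(regions)


def write_region_map(region_map: RegionMap, path: str | Path,
                     chrom: str = "chr3") -> None:
    with open(path, "w") as fh:
        for rid, start, end in region_map.regions:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{rid}\n")


# -- tract TSV --------------------------------------------------------------

_TRACT_COLUMNS = [
    "recipient_strain", "recipient_arr", "donor_arrs", "start", "end",
    "length_excl_gaps", "n_informative", "mean_psi", "sites",
]


def write_tracts(tracts: Iterable[ConversionTract], path: str | Path) -> None:
    """Write tracts as TSV; per-site psi lists serialize as ``pos:psi;...``."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TRACT_COLUMNS) + "\n")
        for t in tracts:
            sites = ";".join(f"{p}:{psi:.17g}" for p, psi in t.informative_sites)
            fh.write("\t".join([
                t.recipient_strain,
                t.recipient_arrangement,
                ",".join(sorted(t.donor_arrangements)),
                str(t.start), str(t.end), str(t.length_excl_gaps),
                str(t.n_informative), f"{t.mean_psi:.17g}", sites,
            ]) + "\n")


def read_tracts(path: str | Path) -> list[ConversionTract]:
    tracts = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _TRACT_COLUMNS:
            raise ValueError("malformed tract file header")
        for row in reader:
            try:
                sites = tuple(
                    (int(p), float(v))
                    for p, v in (tok.split(":") for tok in row["sites"].split(";"))
                )
                tract = ConversionTract(
                    recipient_strain=row["recipient_strain"],
                    recipient_arrangement=row["recipient_arr"],
                    donor_arrangements=frozenset(row["donor_arrs"].split(",")),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    length_excl_gaps=int(row["length_excl_gaps"]),
                    informative_sites=sites,
                    mean_psi=float(row["mean_psi"]),
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"malformed tract row: {row}") from exc
            if tract.n_informative != int(row["n_informative"]):
                raise ValueError("n_informative disagrees with site list")
            tracts.append(tract)
    return tracts


# -- BedGraph coverage ------------------------------------------------------

def write_coverage(track: CoverageTrack, path: str | Path,
                   chrom: str = "chr3") -> None:
    """Write a run-length-encoded BedGraph; zero runs are omitted."""
    values = track.values
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name=coverage_{track.arrangement}\n")
        if len(values) == 0:
            return
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(values)]))
        for s, e in zip(starts, ends):
            v = int(values[s])
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_coverage(path: str | Path, chromosome_length: int,
                  arrangement: str = "") -> CoverageTrack:
    values = np.zeros(chromosome_length, dtype=np.int64)
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            _, s, e, v = line.split("\t")
            values[int(s):int(e)] = int(v)
    return CoverageTrack(arrangement=arrangement, values=values)


# -- gene annotation --------------------------------------------------------

def read_genes_bed(
    exons_bed: str | Path,
    outliers_tsv: str | Path | None = None,
) -> list[GeneModel]:
    """Read gene models from an exon BED file (name column = gene id).

    ``outliers_tsv`` optionally labels genes as selection-candidate outliers,
    one ``gene_id<TAB>arrangement`` row per label.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, str] = {}
    with open(exons_bed) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            gid = fields[3]
            exons.setdefault(gid, []).append((int(fields[1]) + 1, int(fields[2])))
            if len(fields) > 5:
                strands[gid] = fields[5]
    outliers: dict[str, set[str]] = {}
    if outliers_tsv is not None:
        with open(outliers_tsv) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                outliers.setdefault(row["gene_id"], set()).add(row["arrangement"])
    return [
        GeneModel(
            gene_id=gid,
            strand=strands.get(gid, "+"),
            exons=tuple(sorted(iv)),
            outlier_in=frozenset(outliers.get(gid, ())),
        )
        for gid, iv in sorted(exons.items())
    ]


def write_genes_bed(genes: Sequence[GeneModel], exons_bed: str | Path,
                    outliers_tsv: str | Path | None = None,
                    chrom: str = "chr3") -> None:
    with open(exons_bed, "w") as fh:
        for g in genes:
            for s, e in g.exons:
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{g.gene_id}\t0\t{g.strand}\n")
    if outliers_tsv is not None:
        with open(outliers_tsv, "w") as fh:
            fh.write("gene_id\tarrangement\n")
            for g in genes:
                for arr in sorted(g.outlier_in):
                    fh.write(f"{g.gene_id}\t{arr}\n")


def read_genes_gff3(path: str | Path,
                    outliers_tsv: str | Path | None = None) -> list[GeneModel]:
    """GFF3 gene reader: exon features grouped by their Parent (via gffutils)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="merge", keep_order=True)
    exons: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent") or [feat.id]
        for gid in parents:
            exons.setdefault(gid, []).append((feat.start, feat.end))
            strands[gid] = feat.strand
    outliers: dict[str, set[str]] = {}
    if outliers_tsv is not None:
        with open(outliers_tsv) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                outliers.setdefault(row["gene_id"], set()).add(row["arrangement"])
    return [
        GeneModel(gene_id=gid, strand=strands.get(gid, "+"),
                  exons=tuple(sorted(iv)),
                  outlier_in=frozenset(outliers.get(gid, ())))
        for gid, iv in sorted(exons.items())
    ]


__all__ = [
    "HaplotypePanel", "RegionMap", "ConversionTract", "GeneModel",
    "CoverageTrack", "PhiFit", "PermutationResult",
    "read_panel", "write_panel_fasta", "write_snp_table",
    "read_labels", "write_labels",
    "read_region_map", "write_region_map",
    "read_tracts", "write_tracts",
    "read_coverage", "write_coverage",
    "read_genes_bed", "write_genes_bed", "read_genes_gff3",
    "ALLELE_CODES", "CODE_TO_ALLELE", "GAP_CODE", "MISSING_CODE",
]
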