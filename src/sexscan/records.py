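"""Core in-memory containers shared across the pipeline.

Coordinate conventions
----------------------
On-disk formats (VCF, sync, bedGraph headers) use the 1-based inclusive
positions those formats define.  All internal interval arithmetic is 0-based
half-open; :mod:`sexscan.coords` holds the single audited conversion.
Structural-variant records keep the DELLY-style printed convention in which
``length = end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SEXES = ("male", "female")
ROLES = ("sire", "dam", "offspring")


@dataclass
class GenotypeMatrix:
    """Diploid genotypes at biallelic sites for a family or cohort.

    Parameters
    ----------
    sites : DataFrame with columns ``chrom, pos, ref, alt`` (pos 1-based,
        strictly increasing within a chromosome).
    genotypes : int8 array of shape ``(n_sites, n_individuals, 2)`` holding
        allele indices (0 = ref, 1 = alt) with :data:`MISSING` for no-calls.
    individuals : DataFrame with columns ``id, sex, role``.
    depth : optional per-call read depth, shape ``(n_sites, n_individuals)``.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    individuals: pd.DataFrame
    depth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 3 or g.shape[2] != 2:
            raise ValueError("genotypes must have shape (n_sites, n_individuals, 2)")
        if g.shape[0] != len(self.sites) or g.shape[1] != len(self.individuals):
            raise ValueError("genotype array does not match sites/individuals tables")
        bad_sex = set(self.individuals["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        bad_role = set(self.individuals["role"]) - set(ROLES)
        if bad_role:
            raise ValueError(f"unknown role labels: {sorted(bad_role)}")
        for _, sub in self.sites.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("positions must be strictly increasing within a chromosome")
        self.genotypes = g

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def offspring_mask(self) -> np.ndarray:
        return (self.individuals["role"] == "offspring").to_numpy()

    def sex_mask(self, sex: str) -> np.ndarray:
        return (self.individuals["sex"] == sex).to_numpy()

    def parent_index(self, role: str) -> int:
        idx = np.flatnonzero((self.individuals["role"] == role).to_numpy())
        if len(idx) != 1:
            raise ValueError(f"expected exactly one {role}, found {len(idx)}")
        return int(idx[0])

    def take_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            sites=self.sites.iloc[idx],
            genotypes=self.genotypes[idx],
            individuals=self.individuals,
            depth=None if self.depth is None else self.depth[idx],
        )

    def called(self) -> np.ndarray:
        """Boolean (n_sites, n_individuals): both alleles called."""
        return (self.genotypes != MISSING).all(axis=2)


@dataclass
class PoolCounts:
    """Per-site ref/alt read counts for a female pool and a male pool."""

    sites: pd.DataFrame  # chrom, pos, ref, alt
    female_ref: np.ndarray
    female_alt: np.ndarray
    male_ref: np.ndarray
    male_alt: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n = len(self.sites)
        for name in ("female_ref", "female_alt", "male_ref", "male_alt"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per site")
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative counts")
            setattr(self, name, arr)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def female_depth(self) -> np.ndarray:
        return self.female_ref + self.female_alt

    @property
    def male_depth(self) -> np.ndarray:
        return self.male_ref + self.male_alt

    def take_sites(self, mask: np.ndarray) -> "PoolCounts":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return PoolCounts(
            sites=self.sites.iloc[idx],
            female_ref=self.female_ref[idx],
            female_alt=self.female_alt[idx],
            male_ref=self.male_ref[idx],
            male_alt=self.male_alt[idx],
        )


@dataclass
class DepthProfile:
    """Binned read depth along one genomic segment for one pool.

    ``start`` is the 0-based coordinate of the left edge of the first bin;
    bin ``i`` covers ``[start + i*bin_size, start + (i+1)*bin_size)``.
    """

    chrom: str
    start: int
    bin_size: int
    depth: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError("depth must be a non-empty 1-D array")

    @property
    def n_bins(self) -> int:
        return self.depth.size

    @property
    def end(self) -> int:
        return self.start + self.n_bins * self.bin_size

    def bin_edges(self) -> np.ndarray:
        return self.start + np.arange(self.n_bins + 1) * self.bin_size

    def same_binning(self, other: "DepthProfile") -> bool:
        return (
            self.chrom == other.chrom
            and self.start == other.start
            and self.bin_size == other.bin_size
            and self.n_bins == other.n_bins
        )


@dataclass
class SVRecord:
    """A duplication or deletion with breakpoints on the reference.

    ``start``/``end`` follow the printed DELLY convention where the variant
    length is ``end - start``; ``ci`` is the symmetric +/- uncertainty (bp)
    around each breakpoint.
    """

    population: str
    start: int
    end: int
    ci: int
    type: str
    shared: Optional[bool] = None
    chrom: str = ""

    def __post_init__(self) -> None:
        if self.type not in ("duplication", "deletion"):
            raise ValueError(f"unknown SV type {self.type!r}")
        if self.ci < 0:
            raise ValueError("ci must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_valid(self) -> bool:
        return self.end > self.start


@dataclass
class VariantRecord:
    """A SNP or small indel with optional gene context and protein effect."""

    pos: int
    ref: str
    alt: str
    length: int
    type: str
    gene: str = ""
    context: str = ""
    exon_number: Optional[int] = None
    aa_change: Optional[str] = None
    literature: Optional[str] = None

    VALID_TYPES = ("snp", "complex", "insertion", "deletion")

    def __post_init__(self) -> None:
        if self.type not in self.VALID_TYPES:
            raise ValueError(f"unknown variant type {self.type!r}")

    @property
    def key(self) -> tuple:
        return (self.pos, self.ref, self.alt)


def classify_variant_type(ref: str, alt: str) -> str:
    """Type from allele lengths: 1:1 -> snp, longer alt -> insertion,
    longer ref -> deletion, equal multi-base -> complex."""
    if len(ref) == 1 and len(alt) == 1:
        return "snp"
    if len(alt) > len(ref):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "complex"


@dataclass
class MarkerPattern:
    """Presence/absence of the three amh PCR markers for one individual or
    one group of individuals sharing a pattern (``n`` > 1)."""

    individual: str
    phenotype: str
    amhX: str
    amhdY: str
    amhY: str
    n: int = 1
    population: str = ""
    group: str = ""
    known_genotype: str = ""
    predicted: str = ""  # printed predicted genotype, for cross-checks

    def __post_init__(self) -> None:
        if self.amhX not in ("+", "-"):
            raise ValueError("amhX must be '+' or '-'")
        if self.amhdY not in ("+", "-"):
            raise ValueError("amhdY must be '+' or '-'")
        if self.amhY not in ("+", "-", "ND"):
            raise ValueError("amhY must be '+', '-' or 'ND'")
        if self.n <= 0:
            raise ValueError("group size must be positive")


@dataclass
class HaplotypeSegment:
    """One tile of the reconstructed Y haplotype."""

    label: str
    source_start: int
    source_end: int
    copy: int  # 0 = single-copy flank, 1/2 = duplication copy index
    deletions: list = field(default_factory=list)  # (start, end) on reference

    @property
    def length(self) -> int:
        return (self.source_end - self.source_start) - sum(e - s for s, e in self.deletions)


@dataclass
class YHaplotypeModel:
    """Ordered segment model of the Y-specific region (tandem duplication
    with internal deletions) relative to the X reference."""

    region: tuple
    segments: Sequence[HaplotypeSegment]
    placement: str
    total_length: int

    def to_dict(self) -> dict:
        return {
            "region": list(self.region),
            "placement": self.placement,
            "total_length": self.total_length,
            "segments": [
                {
                    "label": s.label,
                    "source": [s.source_start, s.source_end],
                    "copy": s.copy,
                    "deletions": [list(d) for d in s.deletions],
                    "length": s.length,
                }
                for s in self.segments
            ],
        }


@dataclass
class ReferenceSegment:
    """A slice of reference sequence with its genomic offset.

    ``start`` is the 1-based position of the first base of ``seq``.
    """

    chrom: str
    start: int
    seq: str

    def base_at(self, pos: int) -> str:
        """Reference base at 1-based genomic position ``pos``."""
        i = pos - self.start
        if i < 0 or i >= len(self.seq):
            raise IndexError(f"position {pos} outside segment {self.chrom}:{self.start}-"
                             f"{self.start + len(self.seq) - 1}")
        return self.seq[i]

    def slice(self, start: int, end: int) -> str:
        """Sequence for the 1-based inclusive span [start, end]."""
        if start < self.start or end - self.start + 1 > len(self.seq):
            raise IndexError("requested span outside segment")
        return self.seq[start - self.start : end - self.start + 1]
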