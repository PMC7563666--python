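"""Synthetic family, pool and depth data with the structure the scans assume.

Three generators mirror the three data channels of the experimental design:

* :func:`simulate_family` — a ddRAD-like F1 family (two parents plus sexed
  offspring) segregating an XY or ZW locus, with Haldane recombination,
  symmetric allele-flip genotyping error and independent missingness.
* :func:`simulate_pools` — sex-pooled read counts with neutral sites,
  XY/ZW sex-patterned sites (near-fixed in the homogametic pool, ~0.5 in the
  heterogametic one) and contiguous high-coverage "B blocks" confined to one
  pool.
* :func:`simulate_depth_profiles` — male/female binned coverage across a
  region carrying a tandem duplication with internal deletions on the Y.

Every generator is a pure function of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .records import MISSING, DepthProfile, GenotypeMatrix, PoolCounts

_BASES = np.array(list("ACGT"))


@dataclass
class FamilyDesign:
    """Design of a simulated F1 family.

    Defaults follow the sequenced F1 families: 15 sons + 14 daughters genotyped at
    RAD-like biallelic sites on a ~40 Mb chromosome, XY locus at ~34.5 Mb.
    ``recomb_rate`` is crossovers per Mb per meiosis (default ~1.2 crossovers
    per chromosome arm-pair, a typical teleost map density).
    """

    n_sons: int = 15
    n_daughters: int = 14
    n_sites: int = 2000
    chrom_length: int = 40_000_000
    sd_position: int = 34_500_000
    recomb_rate: float = 0.03
    genotyping_error: float = 0.005
    missing_rate: float = 0.1
    system: str = "XY"
    sd_divergence_bp: int = 1_000_000
    chrom: str = "LG23"
    mean_depth: float = 20.0

    def validate(self) -> None:
        if self.n_sons <= 0 or self.n_daughters <= 0 or self.n_sites <= 0:
            raise ValueError("counts must be positive")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if not (0 <= self.sd_position <= self.chrom_length):
            raise ValueError("sd_position must lie within the chromosome")
        for name in ("genotyping_error", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        if self.system not in ("XY", "ZW", "none"):
            raise ValueError(f"system must be XY, ZW or none, got {self.system!r}")
        if self.sd_divergence_bp < 0:
            raise ValueError("sd_divergence_bp must be non-negative")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class PoolDesign:
    """Design of one population's sex-pooled sequencing experiment.

    Depth defaults span the 16-39x coverages of the sequenced pools.  Sex-
    patterned sites use the physical model of an X/Y divergent site: the
    homogametic pool is fixed up to a sequencing-error rate (``seq_error``),
    the heterogametic pool sits at 0.5; both are exposed for sensitivity
    studies (``sex_freq_female`` / ``sex_freq_male`` for the XY pattern).
    """

    n_females: int = 14
    n_males: int = 20
    mean_depth_f: float = 20.0
    mean_depth_m: float = 20.0
    n_sites: int = 4000
    frac_sex_patterned: float = 0.05
    frac_bblock: float = 0.01
    bblock_fold: float = 15.0
    seed: int = 0
    pattern: str = "XY"  # which pool is heterogametic at sex-patterned sites
    sex_freq_female: Optional[float] = None  # default: 1 - seq_error
    sex_freq_male: float = 0.5
    seq_error: float = 0.005
    bblock_pool: str = "male"
    site_spacing: int = 100
    bblock_sites_per_block: int = 30
    chrom: str = "LG23"

    def validate(self) -> None:
        if self.n_females <= 0 or self.n_males <= 0 or self.n_sites <= 0:
            raise ValueError("counts must be positive")
        if self.mean_depth_f <= 0 or self.mean_depth_m <= 0:
            raise ValueError("depths must be positive")
        for name in ("frac_sex_patterned", "frac_bblock", "seq_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_sex_patterned + self.frac_bblock > 1.0:
            raise ValueError("frac_sex_patterned + frac_bblock must not exceed 1")
        if self.bblock_fold <= 1:
            raise ValueError("bblock_fold must exceed 1")
        if self.bblock_pool not in ("male", "female"):
            raise ValueError("bblock_pool must be 'male' or 'female'")
        if self.pattern not in ("XY", "ZW"):
            raise ValueError("pattern must be 'XY' or 'ZW'")
        if self.sex_freq_female is not None and not (0.0 <= self.sex_freq_female <= 1.0):
            raise ValueError("sex_freq_female must be a frequency")
        if not (0.0 <= self.sex_freq_male <= 1.0):
            raise ValueError("sex_freq_male must be a frequency")


@dataclass
class SVScenario:
    """Geometry of a male-specific tandem duplication with internal deletions.

    Intervals are 0-based half-open base-pair spans on the reference;
    ``male_copy_ratio_dup`` is the male/female depth ratio inside the
    duplication (1.5 for a CN3/CN2 diploid male).
    """

    region: tuple = (34_485_000, 34_520_000)
    dup: tuple = (34_491_225, 34_512_737)
    deletions: list = field(default_factory=lambda: [(34_493_315, 34_498_588),
                                                     (34_503_117, 34_509_103)])
    male_copy_ratio_dup: float = 1.5
    bin_size: int = 50
    mean_depth: float = 40.0
    noise: str = "poisson"
    chrom: str = "LG23"

    def validate(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.male_copy_ratio_dup <= 1:
            raise ValueError("male_copy_ratio_dup must exceed 1")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        r0, r1 = self.region
        d0, d1 = self.dup
        if not (r0 <= d0 < d1 <= r1):
            raise ValueError("dup must lie within region")
        for s, e in self.deletions:
            if not (d0 <= s < e <= d1):
                raise ValueError(f"deletion ({s}, {e}) must lie within the dup span")


# ---------------------------------------------------------------------------
# family simulation


def _recombinant_indicator(rng: np.random.Generator, positions: np.ndarray,
                           chrom_length: int, recomb_rate: float) -> np.ndarray:
    """Which of the parent's two haplotypes each site comes from (0/1) for a
    single gamete, under a Haldane (no-interference) crossover process."""
    n_x = rng.poisson(recomb_rate * chrom_length / 1e6)
    start = rng.integers(0, 2)
    if n_x == 0:
        return np.full(positions.size, start, dtype=np.int8)
    xpos = rng.uniform(0, chrom_length, size=n_x)
    crossings = (positions[:, None] > xpos[None, :]).sum(axis=1)
    return ((start + crossings) % 2).astype(np.int8)


def simulate_family(design: FamilyDesign, seed: int) -> GenotypeMatrix:
    """Simulate parents plus sexed offspring under the design's sex system.

    With ``system='XY'`` the sire is heterozygous at ``sd_position`` and the
    Y-specific allele is transmitted to every son; 'ZW' mirrors this through
    the dam; 'none' segregates no sex-linked locus.  Genotyping error is a
    symmetric per-allele flip; missingness drops whole calls, independently.
    """
    design.validate()
    rng = np.random.default_rng(seed)

    # site positions: RAD-like random loci, with a site planted at the SD locus
    pos = np.unique(rng.integers(1, design.chrom_length + 1,
                                 size=design.n_sites + design.n_sites // 4 + 10))
    while pos.size < design.n_sites:
        extra = rng.integers(1, design.chrom_length + 1, size=design.n_sites)
        pos = np.unique(np.concatenate([pos, extra]))
    pos = np.sort(rng.choice(pos, size=design.n_sites, replace=False))
    if design.system in ("XY", "ZW"):
        if design.sd_position not in pos:
            nearest = int(np.argmin(np.abs(pos - design.sd_position)))
            pos[nearest] = design.sd_position
            pos = np.sort(pos)
        sd_idx = int(np.flatnonzero(pos == design.sd_position)[0])
    else:
        sd_idx = -1

    n_sites = design.n_sites
    # founder haplotypes: dam (0, 1), sire (2, 3); haplotype 3 (or 1) carries
    # the sex-specific allele when a system is present
    freq = rng.uniform(0.1, 0.9, size=n_sites)
    founders = (rng.uniform(size=(4, n_sites)) < freq[None, :]).astype(np.int8)
    if design.system in ("XY", "ZW"):
        # the sex haplotype carries a diverged block around the SD locus:
        # within it the three homogametic-lineage haplotypes share the ref
        # allele and only the Y (or W) carries the alternate — the
        # configuration that makes a site sex-patterned in the first place
        window = np.abs(pos - design.sd_position) <= design.sd_divergence_bp
        window[sd_idx] = True
        founders[:, window] = 0
        sex_hap = 3 if design.system == "XY" else 1  # Y on the sire, W on the dam
        founders[sex_hap, window] = 1

    n_off = design.n_sons + design.n_daughters
    sexes = ["male"] * design.n_sons + ["female"] * design.n_daughters
    geno = np.empty((n_sites, 2 + n_off, 2), dtype=np.int8)
    geno[:, 0, 0] = founders[0]  # dam
    geno[:, 0, 1] = founders[1]
    geno[:, 1, 0] = founders[2]  # sire
    geno[:, 1, 1] = founders[3]

    for j, sex in enumerate(sexes):
        mat_ind = _recombinant_indicator(rng, pos, design.chrom_length, design.recomb_rate)
        pat_ind = _recombinant_indicator(rng, pos, design.chrom_length, design.recomb_rate)
        if design.system == "XY":
            # condition the paternal gamete on the offspring's sex: sons carry
            # haplotype 3 (Y) at the SD site, daughters haplotype 2 (X)
            want = 1 if sex == "male" else 0
            if pat_ind[sd_idx] != want:
                pat_ind = 1 - pat_ind
        elif design.system == "ZW":
            want = 1 if sex == "female" else 0
            if mat_ind[sd_idx] != want:
                mat_ind = 1 - mat_ind
        geno[:, 2 + j, 0] = founders[mat_ind, np.arange(n_sites)]
        geno[:, 2 + j, 1] = founders[2 + pat_ind, np.arange(n_sites)]

    if design.genotyping_error > 0:
        flips = rng.uniform(size=geno.shape) < design.genotyping_error
        geno = np.where(flips, 1 - geno, geno)
    if design.missing_rate > 0:
        miss = rng.uniform(size=geno.shape[:2]) < design.missing_rate
        geno[miss] = MISSING

    depth = rng.poisson(design.mean_depth, size=geno.shape[:2]).astype(np.int32)
    depth[geno[:, :, 0] == MISSING] = 0

    ref_i = rng.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
    sites = pd.DataFrame({
        "chrom": design.chrom,
        "pos": pos.astype(np.int64),
        "ref": _BASES[ref_i],
        "alt": _BASES[alt_i],
    })
    ids = (["dam", "sire"]
           + [f"son{i + 1}" for i in range(design.n_sons)]
           + [f"dau{i + 1}" for i in range(design.n_daughters)])
    individuals = pd.DataFrame({
        "id": ids,
        "sex": ["female", "male"] + sexes,
        "role": ["dam", "sire"] + ["offspring"] * n_off,
    })
    return GenotypeMatrix(sites=sites, genotypes=geno, individuals=individuals, depth=depth)


# ---------------------------------------------------------------------------
# pool simulation


def simulate_pools(design: PoolDesign) -> tuple[PoolCounts, pd.DataFrame]:
    """Simulate sex-pooled allele counts plus a per-site truth table.

    Returns ``(PoolCounts, truth)`` where ``truth`` has one row per site with
    columns ``pos, category, freq_female, freq_male`` and category one of
    ``neutral | sex_patterned | bblock``.  Read counts are binomial draws from
    the pool allele frequency at a Poisson per-site depth, so ref + alt always
    equals the simulated depth.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_sites
    female_fixed = (1.0 - design.seq_error if design.sex_freq_female is None
                    else design.sex_freq_female)

    category = np.full(n, "neutral", dtype=object)
    n_bb = int(round(design.frac_bblock * n))
    n_sp = int(round(design.frac_sex_patterned * n))

    # B blocks: contiguous runs of sites
    bb_idx: list[int] = []
    if n_bb > 0:
        per = max(1, design.bblock_sites_per_block)
        n_blocks = max(1, round(n_bb / per))
        starts = rng.choice(max(1, n - per), size=n_blocks, replace=False)
        for s in np.sort(starts):
            bb_idx.extend(range(s, min(s + per, n)))
        bb_idx = sorted(set(bb_idx))[:n_bb]
        category[bb_idx] = "bblock"
    free = np.flatnonzero(category == "neutral")
    sp_idx = np.sort(rng.choice(free, size=min(n_sp, free.size), replace=False))
    category[sp_idx] = "sex_patterned"

    # neutral sites share one pool frequency; read counts are binomial draws
    # from it at the pool's depth (composition sampling within the finite
    # pool of fish is not modelled — see the package methods note)
    pf = rng.uniform(0.05, 0.95, size=n)
    pm = pf.copy()

    is_sp = category == "sex_patterned"
    if design.pattern == "XY":
        pf[is_sp] = female_fixed
        pm[is_sp] = design.sex_freq_male
    else:  # ZW: the male pool is the near-fixed homogametic one
        pm[is_sp] = female_fixed
        pf[is_sp] = design.sex_freq_male
    is_bb = category == "bblock"
    if design.bblock_pool == "male":
        pm[is_bb] = rng.uniform(0.35, 0.65, size=is_bb.sum())
        pf[is_bb] = 1.0 - design.seq_error
    else:
        pf[is_bb] = rng.uniform(0.35, 0.65, size=is_bb.sum())
        pm[is_bb] = 1.0 - design.seq_error

    depth_f = rng.poisson(design.mean_depth_f, size=n)
    depth_m = rng.poisson(design.mean_depth_m, size=n)
    if design.bblock_pool == "male":
        depth_m[is_bb] = rng.poisson(design.mean_depth_m * design.bblock_fold,
                                     size=is_bb.sum())
    else:
        depth_f[is_bb] = rng.poisson(design.mean_depth_f * design.bblock_fold,
                                     size=is_bb.sum())

    fr = rng.binomial(depth_f, pf)
    mr = rng.binomial(depth_m, pm)

    pos = (np.arange(n, dtype=np.int64) + 1) * design.site_spacing
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    sites = pd.DataFrame({"chrom": design.chrom, "pos": pos,
                          "ref": _BASES[ref_i], "alt": _BASES[alt_i]})
    pc = PoolCounts(sites=sites,
                    female_ref=fr, female_alt=depth_f - fr,
                    male_ref=mr, male_alt=depth_m - mr)
    truth = pd.DataFrame({"pos": pos, "category": category,
                          "freq_female": pf, "freq_male": pm})
    return pc, truth


# ---------------------------------------------------------------------------
# depth-profile simulation


def simulate_depth_profiles(scenario: SVScenario, seed: int
                            ) -> tuple[DepthProfile, DepthProfile]:
    """Simulate (male, female) binned depth across the scenario region.

    The female profile is flat at ``mean_depth``.  The male profile carries
    ``mean_depth * male_copy_ratio_dup`` inside the duplication, reverting to
    ``mean_depth`` across deletion spans (a deletion removes one of the two
    Y copies).  Bins partially overlapping a boundary get the length-weighted
    expectation.  ``noise='poisson'`` draws each bin from a Poisson at its
    expectation.
    """
    scenario.validate()
    rng = np.random.default_rng(seed)
    r0, r1 = scenario.region
    n_bins = (r1 - r0) // scenario.bin_size
    if n_bins < 1:
        raise ValueError("region shorter than one bin")
    edges = r0 + np.arange(n_bins + 1) * scenario.bin_size

    def overlap(lo: np.ndarray, hi: np.ndarray, s: int, e: int) -> np.ndarray:
        return np.clip(np.minimum(hi, e) - np.maximum(lo, s), 0, None)

    lo, hi = edges[:-1], edges[1:]
    dup_bp = overlap(lo, hi, *scenario.dup).astype(float)
    for s, e in scenario.deletions:
        dup_bp -= overlap(lo, hi, s, e)
    frac = dup_bp / scenario.bin_size
    male_exp = scenario.mean_depth * (1.0 + (scenario.male_copy_ratio_dup - 1.0) * frac)
    female_exp = np.full(n_bins, scenario.mean_depth)

    if scenario.noise == "poisson":
        male = rng.poisson(male_exp).astype(float)
        female = rng.poisson(female_exp).astype(float)
    else:
        male, female = male_exp, female_exp

    mk = DepthProfile(chrom=scenario.chrom, start=r0, bin_size=scenario.bin_size,
                      depth=male, label="male")
    fk = DepthProfile(chrom=scenario.chrom, start=r0, bin_size=scenario.bin_size,
                      depth=female, label="female")
    return mk, fk
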