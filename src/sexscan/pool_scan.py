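"""Pooled-sequencing scan: pool FST, per-site Fisher tests and the
Sex-SNP-Finder XY/ZW frequency criteria with windowed summaries.

Pool FST uses nucleotide diversity with the small-sample read-count
correction: for counts (a, b) with n = a + b,

    pi = n/(n-1) * (1 - (a/n)^2 - (b/n)^2)

pi_S is the mean of the two pool pi values, pi_T is computed from the summed
counts, and FST = (pi_T - pi_S) / pi_T (0 when pi_T = 0).  The Sex-SNP-Finder
criterion is major-allele based (reference-free): a site is XY-patterned when
the female pool's major allele is near fixation and that allele's complement
sits at intermediate frequency in the male pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import PoolCounts
from .stats import fisher_exact_2x2


@dataclass
class SexSnpParams:
    """Thresholds of the Sex-SNP-Finder criterion (defaults as used in the
    pooled scans: near-fixation 0.9, intermediate band 0.3-0.7, depth range
    10-100x, minimum minor-allele evidence 2 reads, 10 kb windows)."""

    fixed_threshold: float = 0.9
    min_polymorphic: float = 0.3
    max_polymorphic: float = 0.7
    min_depth: int = 10
    max_depth: int = 100
    min_read_count: int = 2
    window_size: int = 10_000

    def __post_init__(self) -> None:
        if not (0 <= self.min_polymorphic < self.max_polymorphic <= 1):
            raise ValueError("need 0 <= min_polymorphic < max_polymorphic <= 1")
        if not self.fixed_threshold > self.max_polymorphic:
            raise ValueError("fixed_threshold must exceed max_polymorphic")
        if not (0 < self.min_depth <= self.max_depth):
            raise ValueError("need 0 < min_depth <= max_depth")
        if self.min_read_count < 0 or self.window_size <= 0:
            raise ValueError("min_read_count >= 0 and window_size > 0 required")


def _pi(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    n = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n > 1,
                      (n / np.maximum(n - 1.0, 1e-300))
                      * (1.0 - (ref / np.maximum(n, 1)) ** 2
                         - (alt / np.maximum(n, 1)) ** 2),
                      0.0)
    return pi


def pooled_fst(pc: PoolCounts) -> np.ndarray:
    """Per-site pool FST; NaN flags sites with zero depth in either pool."""
    fr, fa = pc.female_ref.astype(float), pc.female_alt.astype(float)
    mr, ma = pc.male_ref.astype(float), pc.male_alt.astype(float)
    zero = ((fr + fa) == 0) | ((mr + ma) == 0)
    pi_f = _pi(fr, fa)
    pi_m = _pi(mr, ma)
    pi_s = 0.5 * (pi_f + pi_m)
    pi_t = _pi(fr + mr, fa + ma)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(pi_t > 0, (pi_t - pi_s) / np.maximum(pi_t, 1e-300), 0.0)
    fst = np.clip(fst, 0.0, 1.0)
    fst[zero] = np.nan
    return fst


def pooled_fet(pc: PoolCounts) -> np.ndarray:
    """Two-sided Fisher's exact p per site on the female/male read counts."""
    out = np.ones(pc.n_sites)
    for i in range(pc.n_sites):
        out[i] = fisher_exact_2x2(int(pc.female_ref[i]), int(pc.female_alt[i]),
                                  int(pc.male_ref[i]), int(pc.male_alt[i]))
    return out


def sex_snp_finder(pc: PoolCounts, params: SexSnpParams | None = None,
                   pattern: str = "XY") -> tuple[np.ndarray, pd.DataFrame]:
    """Flag sites matching the XY (or ZW) pooled frequency signature.

    For XY, a site is flagged when both pool depths lie in
    ``[min_depth, max_depth]``, the minor-allele read count in the male
    (heterogametic) pool is at least ``min_read_count``, the female pool's
    major-allele frequency is >= ``fixed_threshold`` and the frequency in the
    male pool of the female pool's minor allele falls inside
    ``[min_polymorphic, max_polymorphic]``.  ZW swaps the two pools.

    Returns ``(flags, windows)`` where ``windows`` counts flagged sites in
    non-overlapping ``window_size`` bins anchored at position 0.
    """
    if params is None:
        params = SexSnpParams()
    if pattern not in ("XY", "ZW"):
        raise ValueError(f"pattern must be 'XY' or 'ZW', got {pattern!r}")

    if pattern == "XY":
        hom_ref, hom_alt = pc.female_ref, pc.female_alt
        het_ref, het_alt = pc.male_ref, pc.male_alt
    else:
        hom_ref, hom_alt = pc.male_ref, pc.male_alt
        het_ref, het_alt = pc.female_ref, pc.female_alt

    hom_n = (hom_ref + hom_alt).astype(float)
    het_n = (het_ref + het_alt).astype(float)
    depth_ok = ((hom_n >= params.min_depth) & (hom_n <= params.max_depth)
                & (het_n >= params.min_depth) & (het_n <= params.max_depth))

    with np.errstate(divide="ignore", invalid="ignore"):
        hom_major = np.maximum(hom_ref, hom_alt) / np.maximum(hom_n, 1)
        # frequency in the heterogametic pool of the allele that is MINOR in
        # the homogametic pool (ref/alt resolved per site)
        hom_minor_is_alt = hom_alt <= hom_ref
        het_minor_count = np.where(hom_minor_is_alt, het_alt, het_ref)
        het_q = het_minor_count / np.maximum(het_n, 1)
    het_minor = np.minimum(het_ref, het_alt)

    flags = (depth_ok
             & (hom_major >= params.fixed_threshold)
             & (het_q >= params.min_polymorphic)
             & (het_q <= params.max_polymorphic)
             & (het_minor >= params.min_read_count))

    pos = pc.sites["pos"].to_numpy()
    win = (pos - 1) // params.window_size
    df = pd.DataFrame({"chrom": pc.sites["chrom"], "window": win,
                       "flagged": flags})
    windows = (df.groupby(["chrom", "window"], sort=True)["flagged"]
               .sum().reset_index())
    windows["window_start"] = windows.pop("window") * params.window_size + 1
    windows["window_end"] = windows["window_start"] + params.window_size - 1
    windows = windows.rename(columns={"flagged": "n_flagged"})
    return flags, windows[["chrom", "window_start", "window_end", "n_flagged"]]


def pool_scan_table(pc: PoolCounts, params: SexSnpParams | None = None,
                    pattern: str = "XY", alpha: float = 0.01) -> pd.DataFrame:
    """Per-site summary table: fst, fet_p, sex-pattern flag."""
    flags, _ = sex_snp_finder(pc, params, pattern)
    out = pc.sites.copy()
    out["fst"] = pooled_fst(pc)
    out["fet_p"] = pooled_fet(pc)
    out["significant"] = out["fet_p"] < alpha
    out["sex_pattern_flag"] = flags
    out["pattern"] = pattern
    return out
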