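"""Detection and masking of high-coverage "B blocks".

Supernumerary B chromosomes carry amplified fragments of ordinary
chromosomes; their reads pile up on the reference as localized blocks of
very high, highly polymorphic coverage that mimic sex-patterned signal in
one pool.  Blocks are called as runs of bins whose depth exceeds a fold
threshold times the pool's genome mean; the mean is computed after dropping
the top 1% of bins so the artefact does not inflate its own baseline.
A block footprint seen in the same-sex pool of every population is a
sex-linked candidate; anything else is a sex-independent artefact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .records import DepthProfile, PoolCounts

log = logging.getLogger(__name__)


@dataclass
class BBlockSet:
    """Blocks called for one pool: DataFrame (chrom, start, end, mean_fold,
    pool) with 0-based half-open intervals, plus the genome mean used."""

    blocks: pd.DataFrame
    genome_mean: float
    pool: str = ""

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def tree(self) -> IntervalTree:
        t = IntervalTree()
        for _, b in self.blocks.iterrows():
            t.addi(int(b.start), int(b.end), b.pool)
        return t


def robust_genome_mean(depth: np.ndarray, trim_top: float = 0.01) -> float:
    """Mean depth excluding the top ``trim_top`` fraction of bins."""
    d = np.asarray(depth, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no usable bins")
    cut = np.quantile(d, 1.0 - trim_top)
    kept = d[d <= cut]
    return float(kept.mean()) if kept.size else float(d.mean())


def flag_bblocks(profile: DepthProfile, fold_threshold: float = 10.0,
                 min_block: int = 1000) -> BBlockSet:
    """Call B-block candidates on one pool's depth profile.

    Bins with depth > ``fold_threshold`` x the robust genome mean are
    flagged; adjacent flagged bins merge; merged runs shorter than
    ``min_block`` bp are dropped.
    """
    mean = robust_genome_mean(profile.depth)
    if mean == 0:
        raise ValueError("genome mean depth is zero")
    hot = np.nan_to_num(profile.depth, nan=0.0) > fold_threshold * mean
    edges = profile.bin_edges()
    rows = []
    i = 0
    while i < hot.size:
        if hot[i]:
            j = i
            while j + 1 < hot.size and hot[j + 1]:
                j += 1
            start, end = int(edges[i]), int(edges[j + 1])
            if end - start >= min_block:
                fold = float(profile.depth[i:j + 1].mean() / mean)
                rows.append((profile.chrom, start, end, fold, profile.label))
            i = j + 1
        else:
            i += 1
    blocks = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                         "mean_fold", "pool"])
    return BBlockSet(blocks=blocks, genome_mean=mean, pool=profile.label)


def bblock_consistency(sets: dict) -> pd.DataFrame:
    """Cross-pool presence matrix and sex-consistency verdict per footprint.

    ``sets`` maps ``(population, sex)`` -> BBlockSet for at least two pools.
    Footprints are the union of all block intervals; a footprint is a
    "sex-linked candidate" only when some sex's pool contains it in every
    population, otherwise a "sex-independent artefact".
    """
    if len(sets) < 2:
        raise ValueError("need at least two pools")
    populations = sorted({k[0] for k in sets})
    union = IntervalTree()
    for bs in sets.values():
        for _, b in bs.blocks.iterrows():
            union.addi(int(b.start), int(b.end))
    union.merge_overlaps()
    trees = {k: bs.tree() for k, bs in sets.items()}
    rows = []
    for iv in sorted(union):
        presence = {k: bool(trees[k].overlap(iv.begin, iv.end)) for k in sets}
        sex_linked = any(
            all(presence.get((p, sex), False) for p in populations)
            for sex in ("male", "female"))
        row = {"start": iv.begin, "end": iv.end,
               "verdict": ("sex-linked candidate" if sex_linked
                           else "sex-independent artefact")}
        row.update({f"{p}_{s}": present for (p, s), present in presence.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def mask_sites(pc: PoolCounts, blocks: BBlockSet | list) -> PoolCounts:
    """Remove sites falling inside any flagged block; the count is logged."""
    if isinstance(blocks, BBlockSet):
        block_sets = [blocks]
    else:
        block_sets = list(blocks)
    tree = IntervalTree()
    for bs in block_sets:
        for _, b in bs.blocks.iterrows():
            tree.addi(int(b.start), int(b.end))
    if not tree:
        return pc
    pos0 = pc.sites["pos"].to_numpy() - 1  # 1-based position -> 0-based point
    keep = np.array([not tree.overlaps(p) for p in pos0])
    log.info("mask_sites: removed %d of %d sites inside B blocks",
             int((~keep).sum()), pc.n_sites)
    return pc.take_sites(keep)


def depth_profile_from_counts(pc: PoolCounts, pool: str, bin_size: int,
                              start: int = 0) -> DepthProfile:
    """Binned mean site depth for one pool, for B-block calling on pooled
    SNP data.  Bins with no sites get the profile's overall mean so they
    are depth-neutral."""
    if pool not in ("male", "female"):
        raise ValueError("pool must be 'male' or 'female'")
    depth = pc.male_depth if pool == "male" else pc.female_depth
    pos0 = pc.sites["pos"].to_numpy() - 1
    end = int(pos0.max()) + 1 if len(pos0) else start + bin_size
    n_bins = max(1, -(-(end - start) // bin_size))
    idx = np.clip((pos0 - start) // bin_size, 0, n_bins - 1)
    sums = np.bincount(idx, weights=depth, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    overall = float(np.nanmean(means)) if np.isfinite(means).any() else 0.0
    means = np.where(np.isnan(means), overall, means)
    chrom = pc.sites["chrom"].iloc[0] if len(pc.sites) else "."
    return DepthProfile(chrom=chrom, start=start, bin_size=bin_size,
                        depth=means, label=pool)
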