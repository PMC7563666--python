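"""Readers and writers for the on-disk formats the pipeline touches.

VCFv4.2 (GT and DP only), Popoolation2 sync, bedGraph, GFF3, FASTA segments,
plus the packaged TSV fixtures of the printed marker/SV/variant tables.
Files are 1-based inclusive; everything internal is 0-based half-open
(:mod:`sexscan.coords`).  Readers reject malformed records rather than
silently coercing them.
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources
from typing import Optional, Union

import numpy as np
import pandas as pd

from .records import (MISSING, DepthProfile, GenotypeMatrix, MarkerPattern,
                      PoolCounts, ReferenceSegment, SVRecord, VariantRecord)

log = logging.getLogger(__name__)

_SYNC_BASES = "ATCGN"  # column order of a sync count field, then 'del'


class FormatError(ValueError):
    """A malformed record in an input file."""


# ---------------------------------------------------------------------------
# VCF


def read_sex_map(path: str) -> pd.DataFrame:
    """TSV with columns id, sex, role (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c.lower() for c in df.columns]
    if set(cols) >= {"id", "sex", "role"}:
        df.columns = cols
    else:  # headerless
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None,
                         names=["id", "sex", "role"])
    return df[["id", "sex", "role"]]


def _prescan_vcf(path: str) -> None:
    """Structural check so malformed lines are reported with their number."""
    n_fixed = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < 10:
                    raise FormatError(f"{path}:{lineno}: VCF header has no samples")
                n_fixed = len(fields)
                continue
            if n_fixed is None:
                raise FormatError(f"{path}:{lineno}: data line before #CHROM header")
            if len(fields) != n_fixed:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_fixed} columns, found {len(fields)}")
            if not fields[1].isdigit():
                raise FormatError(f"{path}:{lineno}: POS is not an integer")


def read_genotype_vcf(path: str,
                      sex_map: Union[str, pd.DataFrame],
                      max_alleles: int = 2,
                      min_mean_depth: float = 5.0) -> GenotypeMatrix:
    """Read GT (and DP when present) from a VCF into a GenotypeMatrix.

    Sites with more than ``max_alleles`` alleles, or whose mean depth across
    called individuals is below ``min_mean_depth``, are removed; removal
    counts are logged.  Sites without DP are not depth-filtered.
    """
    from cyvcf2 import VCF

    _prescan_vcf(path)
    if isinstance(sex_map, str):
        sex_map = read_sex_map(sex_map)
    sex_map = sex_map.set_index("id")

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing_meta = [s for s in samples if s not in sex_map.index]
    if missing_meta:
        raise ValueError(f"samples absent from sex map: {missing_meta}")

    chroms, poss, refs, alts = [], [], [], []
    genos, depths = [], []
    n_multi = n_lowdp = 0
    for var in vcf:
        n_alleles = 1 + len(var.ALT)
        if n_alleles > max_alleles:
            n_multi += 1
            continue
        gt = np.asarray(var.genotype.array())[:, :2].astype(np.int8)
        gt[gt < 0] = MISSING
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            dp = np.asarray(dp).reshape(-1).astype(np.int32)
            dp[dp < 0] = 0
            called = (gt != MISSING).all(axis=1)
            mean_dp = dp[called].mean() if called.any() else 0.0
            if mean_dp < min_mean_depth:
                n_lowdp += 1
                continue
        else:
            dp = np.zeros(len(samples), dtype=np.int32)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        genos.append(gt)
        depths.append(dp)
    log.info("read_genotype_vcf: removed %d multi-allelic and %d low-depth sites",
             n_multi, n_lowdp)

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    geno = (np.stack(genos) if genos
            else np.empty((0, len(samples), 2), dtype=np.int8))
    depth = (np.stack(depths) if depths
             else np.empty((0, len(samples)), dtype=np.int32))
    individuals = pd.DataFrame({
        "id": samples,
        "sex": [sex_map.loc[s, "sex"] for s in samples],
        "role": [sex_map.loc[s, "role"] for s in samples],
    })
    return GenotypeMatrix(sites=sites, genotypes=geno, individuals=individuals,
                          depth=depth)


def write_genotype_vcf(gm: GenotypeMatrix, path: str,
                       seed: Optional[int] = None) -> None:
    """Minimal VCFv4.2 writer: GT:DP, one ALT per site."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sexscan\n")
        if seed is not None:
            fh.write(f"##sexscan_seed={seed}\n")
        chroms = gm.sites["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        ids = "\t".join(gm.individuals["id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ids}\n")
        for i, site in gm.sites.iterrows():
            cells = []
            for j in range(gm.n_individuals):
                a, b = gm.genotypes[i, j]
                gt = "./." if a == MISSING or b == MISSING else f"{a}/{b}"
                dp = 0 if gm.depth is None else int(gm.depth[i, j])
                cells.append(f"{gt}:{dp}")
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}"
                     f"\t.\tPASS\t.\tGT:DP\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Popoolation2 sync


def _parse_sync_field(field: str, path: str, lineno: int) -> np.ndarray:
    parts = field.split(":")
    if len(parts) != 6:
        raise FormatError(f"{path}:{lineno}: sync count field must have 6 values "
                          f"(A:T:C:G:N:del), got {field!r}")
    try:
        return np.array([int(x) for x in parts], dtype=np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer count in {field!r}") from exc


def read_sync(path: str, female_col: int = 0, male_col: int = 1) -> PoolCounts:
    """Parse a 2-pool sync file into PoolCounts.

    ``female_col``/``male_col`` index the pool columns (0-based, after the
    three site columns).  The alt allele is the highest-count non-reference
    base summed over both pools.  Sites whose reference base is not a counted
    base (A/T/C/G) are dropped with a warning.
    """
    rows = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected >= 5 columns, "
                                  f"found {len(fields)}")
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            if not pos_s.isdigit():
                raise FormatError(f"{path}:{lineno}: position {pos_s!r} not an integer")
            pools = fields[3:]
            if max(female_col, male_col) >= len(pools):
                raise FormatError(f"{path}:{lineno}: pool column out of range")
            f_counts = _parse_sync_field(pools[female_col], path, lineno)
            m_counts = _parse_sync_field(pools[male_col], path, lineno)
            if ref not in _SYNC_BASES[:4]:
                n_dropped += 1
                continue
            ref_i = _SYNC_BASES.index(ref)
            total = f_counts[:4] + m_counts[:4]
            total[ref_i] = -1
            alt_i = int(np.argmax(total))
            alt = _SYNC_BASES[alt_i] if total[alt_i] > 0 else "."
            rows.append((chrom, int(pos_s), ref, alt,
                         int(f_counts[ref_i]), int(f_counts[alt_i]) if alt != "." else 0,
                         int(m_counts[ref_i]), int(m_counts[alt_i]) if alt != "." else 0))
    if n_dropped:
        warnings.warn(f"read_sync: dropped {n_dropped} sites with uncounted "
                      "reference base")
    if not rows:
        warnings.warn(f"read_sync: no usable sites in {path}")
        sites = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        z = np.zeros(0, dtype=np.int64)
        return PoolCounts(sites=sites, female_ref=z, female_alt=z,
                          male_ref=z, male_alt=z)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "fr", "fa", "mr", "ma"])
    return PoolCounts(sites=df[["chrom", "pos", "ref", "alt"]],
                      female_ref=df["fr"].to_numpy(),
                      female_alt=df["fa"].to_numpy(),
                      male_ref=df["mr"].to_numpy(),
                      male_alt=df["ma"].to_numpy())


def write_sync(pc: PoolCounts, path: str, seed: Optional[int] = None) -> None:
    """Write PoolCounts as a 2-pool sync file (female pool first)."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"#sexscan_seed={seed}\n")
        for i in range(pc.n_sites):
            site = pc.sites.iloc[i]
            ref, alt = site.ref, site.alt

            def field(ref_n: int, alt_n: int) -> str:
                counts = [0] * 6
                counts[_SYNC_BASES.index(ref)] = ref_n
                if alt in _SYNC_BASES[:4]:
                    counts[_SYNC_BASES.index(alt)] = alt_n
                return ":".join(str(c) for c in counts)

            fh.write(f"{site.chrom}\t{site.pos}\t{ref}\t"
                     f"{field(pc.female_ref[i], pc.female_alt[i])}\t"
                     f"{field(pc.male_ref[i], pc.male_alt[i])}\n")


def pool_counts_to_tsv(pc: PoolCounts, path: str) -> None:
    df = pc.sites.copy()
    df["female_ref"] = pc.female_ref
    df["female_alt"] = pc.female_alt
    df["male_ref"] = pc.male_ref
    df["male_alt"] = pc.male_alt
    df.to_csv(path, sep="\t", index=False)


def pool_counts_from_tsv(path: str) -> PoolCounts:
    df = pd.read_csv(path, sep="\t")
    return PoolCounts(sites=df[["chrom", "pos", "ref", "alt"]],
                      female_ref=df["female_ref"].to_numpy(),
                      female_alt=df["female_alt"].to_numpy(),
                      male_ref=df["male_ref"].to_numpy(),
                      male_alt=df["male_alt"].to_numpy())


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(profile: DepthProfile, path: str,
                   seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"#sexscan_seed={seed}\n")
        fh.write(f'track type=bedGraph name="{profile.label}"\n')
        edges = profile.bin_edges()
        for i, v in enumerate(profile.depth):
            fh.write(f"{profile.chrom}\t{edges[i]}\t{edges[i + 1]}\t{v:g}\n")


def read_bedgraph(path: str, label: str = "") -> DepthProfile:
    """Read a uniform-bin bedGraph (0-based half-open intervals)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    if not rows:
        raise FormatError(f"{path}: empty bedGraph")
    chroms = {r[0] for r in rows}
    if len(chroms) != 1:
        raise FormatError(f"{path}: expected a single chromosome, got {sorted(chroms)}")
    rows.sort(key=lambda r: r[1])
    widths = {r[2] - r[1] for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: bins are not uniform ({sorted(widths)})")
    bin_size = widths.pop()
    for a, b in zip(rows, rows[1:]):
        if b[1] != a[2]:
            raise FormatError(f"{path}: bins not contiguous at {a[2]}")
    return DepthProfile(chrom=rows[0][0], start=rows[0][1], bin_size=bin_size,
                        depth=np.array([r[3] for r in rows]), label=label)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_segment(path: str) -> ReferenceSegment:
    """Read the first record of a FASTA file as a reference segment.

    A ``start=<pos>`` token in the description gives the 1-based genomic
    position of the first base (default 1).
    """
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    start = 1
    for token in rec.description.split():
        if token.startswith("start="):
            start = int(token[len("start="):])
    return ReferenceSegment(chrom=rec.id, start=start, seq=str(rec.seq).upper())


def write_fasta_segment(seg: ReferenceSegment, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seg.chrom} start={seg.start}\n")
        for i in range(0, len(seg.seq), 70):
            fh.write(seg.seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# packaged fixtures of the printed tables


def _fixture_frame(name: str) -> pd.DataFrame:
    with resources.files("sexscan.data").joinpath(f"{name}.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str).fillna("")


def read_table_fixture(name: str):
    """Load one of the packaged printed-table fixtures.

    ``table2`` -> list[MarkerPattern] (grouped patterns with group sizes),
    ``table3`` -> list[SVRecord], ``table4`` -> list[VariantRecord].
    """
    if name == "table2":
        df = _fixture_frame("table2")
        return [MarkerPattern(
            individual=f"{row.population}_{row.phenotype}_{i}",
            population=row.population, group=row.group,
            phenotype=row.phenotype, n=int(row.n),
            known_genotype=row.known_genotype, predicted=row.predicted,
            amhX=row.amhX, amhdY=row.amhdY, amhY=row.amhY)
            for i, row in df.iterrows()]
    if name == "table3":
        df = _fixture_frame("table3")
        return [SVRecord(population=row.population, start=int(row.start),
                         end=int(row.end), ci=int(row.ci), type=row.type,
                         shared=row.shared == "yes", chrom="LG23")
                for _, row in df.iterrows()]
    if name == "table4":
        df = _fixture_frame("table4")
        out = []
        for _, row in df.iterrows():
            ctx = row.context
            exon_no = None
            if ctx.startswith("exon ") and ctx.split()[-1].isdigit():
                exon_no = int(ctx.split()[-1])
                ctx = "exon"
            out.append(VariantRecord(
                pos=int(row.position), ref=row.ref, alt=row.alt,
                length=int(row.length), type=row.type, gene=row.gene,
                context=ctx, exon_number=exon_no,
                aa_change=row.aa_change or None,
                literature=row.literature or None))
        return out
    raise ValueError(f"unknown fixture {name!r}; expected table2, table3 or table4")
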