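"""Structural model of the Y-specific region: depth-based breakpoint
estimation, breakpoint gene context, Y-haplotype reconstruction, variant
annotation and the amh marker genotype rule.

The duplication/deletion caller works purely in read-depth space: the
male/female per-bin depth ratio is segmented into piecewise-constant pieces
by least-squares binary segmentation, segments near ratio 1.5 are called
duplication (CN3/CN2 in a diploid male carrying one extra Y copy) and
segments near ratio 1.0 nested inside a duplication are deletions of one Y
copy.  This captures the interpretable depth evidence of a tandem
duplication without re-implementing a paired-end/split-read engine.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np

from .genes import Gene, GeneModelSet, reverse_complement
from .records import (DepthProfile, HaplotypeSegment, MarkerPattern,
                      ReferenceSegment, SVRecord, VariantRecord,
                      YHaplotypeModel, classify_variant_type)

__all__ = ["sv_length", "estimate_breakpoints", "classify_breakpoint_context",
           "build_y_haplotype", "annotate_variant", "variant_set_ops",
           "predict_genotype_from_markers", "binary_segmentation"]


def sv_length(rec: SVRecord) -> int:
    """Variant length, printed convention: ``end - start``."""
    if not rec.is_valid:
        warnings.warn(f"degenerate SV record ({rec.start}, {rec.end}): length 0")
        return 0
    return rec.length


# ---------------------------------------------------------------------------
# change-point segmentation


def _seg_cost(cum: np.ndarray, cum2: np.ndarray, i: int, j: int) -> float:
    """Least-squares cost of fitting a constant on [i, j)."""
    n = j - i
    s = cum[j] - cum[i]
    s2 = cum2[j] - cum2[i]
    return s2 - s * s / n


def _best_split(cum: np.ndarray, cum2: np.ndarray, i: int, j: int
                ) -> tuple[Optional[int], float]:
    """Best single change-point within [i, j) and its cost reduction."""
    if j - i < 2:
        return None, 0.0
    ks = np.arange(i + 1, j)
    nl = ks - i
    nr = j - ks
    sl = cum[ks] - cum[i]
    sr = cum[j] - cum[ks]
    left = (cum2[ks] - cum2[i]) - sl * sl / nl
    right = (cum2[j] - cum2[ks]) - sr * sr / nr
    total = _seg_cost(cum, cum2, i, j)
    gains = total - (left + right)
    b = int(np.argmax(gains))
    return int(ks[b]), float(gains[b])


def binary_segmentation(x: np.ndarray, max_segments: int,
                        penalty: Optional[float] = None) -> list[int]:
    """Greedy least-squares binary segmentation.

    Returns interior change-point indices (sorted).  Splitting stops when the
    best remaining cost reduction drops to ``penalty`` or below, or when
    ``max_segments`` is reached.  With ``penalty=None`` a BIC-style default
    ``2 * sigma^2 * log(n)`` is used, with sigma estimated robustly from
    successive differences (exactly 0 for a noiseless profile, so noiseless
    signals are recovered exactly).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")
    if penalty is None:
        diffs = np.abs(np.diff(x))
        sigma = np.median(diffs) / (np.sqrt(2.0) * 0.6745) if diffs.size else 0.0
        penalty = 2.0 * sigma * sigma * np.log(max(n, 2))
    cum = np.concatenate([[0.0], np.cumsum(x)])
    cum2 = np.concatenate([[0.0], np.cumsum(x * x)])

    bounds = [0, n]
    while len(bounds) - 1 < max_segments:
        best = (None, penalty)  # (split index, gain) — must beat penalty
        for i, j in zip(bounds[:-1], bounds[1:]):
            k, gain = _best_split(cum, cum2, i, j)
            if k is not None and gain > best[1]:
                best = (k, gain)
        if best[0] is None:
            break
        bounds = sorted(bounds + [best[0]])
    return bounds[1:-1]


def _polish_bounds(x: np.ndarray, bounds: list[int], passes: int = 3) -> list[int]:
    """Re-optimize each change-point between its fixed neighbours.

    Greedy binary segmentation places each split optimally only within the
    segment it divided at the time; re-estimating every boundary as the
    single least-squares change-point between its two neighbours recovers
    near-optimal localization."""
    cum = np.concatenate([[0.0], np.cumsum(x)])
    cum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    full = [0] + list(bounds) + [x.size]
    for _ in range(passes):
        moved = False
        for k in range(1, len(full) - 1):
            new, _ = _best_split(cum, cum2, full[k - 1], full[k + 1])
            if new is not None and new != full[k]:
                full[k] = new
                moved = True
        full = sorted(set(full))
        if not moved:
            break
    return full[1:-1]


def _merge_segments(x: np.ndarray, bounds: list[int], tol: float) -> list[int]:
    """Drop interior boundaries between segments whose means differ < tol."""
    full = [0] + list(bounds) + [x.size]
    changed = True
    while changed:
        changed = False
        for k in range(1, len(full) - 1):
            left = x[full[k - 1]:full[k]].mean()
            right = x[full[k]:full[k + 1]].mean()
            if abs(left - right) < tol:
                full.pop(k)
                changed = True
                break
    return full[1:-1]


def estimate_breakpoints(male: DepthProfile, female: DepthProfile,
                         max_segments: int = 12,
                         dup_ratio: float = 1.5,
                         ratio_tol: float = 0.15,
                         ref_smooth_bins: int = 51,
                         population: str = "") -> list[SVRecord]:
    """Call duplication/deletion records from a male/female depth-ratio
    profile.

    The ratio series is segmented (binary segmentation, at most
    ``max_segments`` pieces); segments with mean within ``ratio_tol`` of
    ``dup_ratio`` are duplication-level and segments back near 1.0 nested
    between them are deletions of one Y copy.  The duplication record spans
    the first to the last duplication-level segment.  Each breakpoint's
    confidence interval is one bin.
    """
    if not male.same_binning(female):
        raise ValueError("male and female profiles must share binning")
    f = female.depth.copy()
    f[f <= 0] = max(float(f[f > 0].mean()), 1e-9) if (f > 0).any() else 1.0
    if ref_smooth_bins > 1:
        # the female profile is the diploid reference baseline: it carries no
        # breakpoint signal, so smoothing it removes its sampling noise from
        # the ratio without blurring the change-points (which live in the
        # male numerator)
        from scipy.ndimage import uniform_filter1d

        f = uniform_filter1d(f, size=int(ref_smooth_bins), mode="nearest")
    m = np.maximum(male.depth, 0.5)  # half-read floor so empty bins stay finite
    # segment the log-ratio: it is the variance-stabilized copy-number
    # statistic for Poisson depths, which sharpens change-point localization
    lr = np.log(m / f)

    log_gap = np.log(dup_ratio)  # level separation on the log scale
    bounds = binary_segmentation(lr, max_segments=max_segments)
    # merge spurious splits within one copy-number level, then re-localize
    # every boundary between its neighbours
    bounds = _merge_segments(lr, bounds, tol=log_gap / 2.0)
    bounds = _polish_bounds(lr, bounds)
    bounds = _merge_segments(lr, bounds, tol=log_gap / 2.0)
    full = [0] + bounds + [lr.size]
    means = [float(np.exp(lr[i:j].mean())) for i, j in zip(full[:-1], full[1:])]

    is_dup = [abs(m - dup_ratio) <= ratio_tol for m in means]
    is_norm = [abs(m - 1.0) <= ratio_tol for m in means]
    if not any(is_dup):
        return []
    first = is_dup.index(True)
    last = len(is_dup) - 1 - is_dup[::-1].index(True)

    def bp(idx: int) -> int:
        return male.start + idx * male.bin_size

    records = [SVRecord(population=population, chrom=male.chrom,
                        start=bp(full[first]), end=bp(full[last + 1]),
                        ci=male.bin_size, type="duplication")]
    for k in range(first + 1, last):
        if is_norm[k]:
            records.append(SVRecord(population=population, chrom=male.chrom,
                                    start=bp(full[k]), end=bp(full[k + 1]),
                                    ci=male.bin_size, type="deletion"))
    return records


# ---------------------------------------------------------------------------
# breakpoint gene context


def classify_breakpoint_context(rec: SVRecord, genes: GeneModelSet) -> dict:
    """Gene and feature label for each breakpoint of an SV record.

    Returns ``{'start': (gene_id, label), 'end': (gene_id, label)}`` with
    ``('intergenic', 'intergenic')`` outside all genes.  Feature numbering
    follows transcription order, so antisense genes are numbered from the
    genomic right."""
    out = {}
    for name, pos in (("start", rec.start), ("end", rec.end)):
        gene = genes.gene_at(pos, chrom=rec.chrom or None)
        if gene is None:
            out[name] = ("intergenic", "intergenic")
        else:
            out[name] = (gene.id, gene.feature_label(pos))
    return out


# ---------------------------------------------------------------------------
# Y-haplotype reconstruction


def build_y_haplotype(region: tuple, dup: SVRecord,
                      deletions: Iterable[SVRecord],
                      placement: str = "truncated-copy") -> YHaplotypeModel:
    """Assemble the ordered Y-haplotype segment model.

    The Y region is the reference region with the duplicated span present
    twice in tandem; each internal deletion removes one of the two copies of
    its span.  Under the default ``truncated-copy`` placement a deletion is
    assigned to the copy in which its flanking gene fragment is truncated
    (the biologically parsimonious choice: the deleted gene piece was
    already non-functional); ``intact-copy`` is the alternative scenario.
    Total length is placement-invariant:

        total = (region length) + (dup length) - sum(deletion lengths)
    """
    if placement not in ("truncated-copy", "intact-copy"):
        raise ValueError("placement must be 'truncated-copy' or 'intact-copy'")
    r0, r1 = region
    if not (r0 <= dup.start < dup.end <= r1):
        raise ValueError("duplication must lie within the region")
    dels = list(deletions)
    for d in dels:
        if not (dup.start <= d.start < d.end <= dup.end):
            raise ValueError(f"deletion ({d.start}, {d.end}) outside the "
                             "duplicated span")

    # Copy 1 is followed by copy 2; copy 1's right end and copy 2's left end
    # are the truncated gene fragments forming the internal chimera.  A
    # deletion nearer the dup start overlaps the left-side gene, whose
    # truncated fragment opens copy 2; one nearer the dup end overlaps the
    # right-side gene, truncated at the close of copy 1.
    assigned: dict[int, list] = {1: [], 2: []}
    for d in dels:
        start_side = (d.start - dup.start) <= (dup.end - d.end)
        truncated_copy = 2 if start_side else 1
        copy = truncated_copy if placement == "truncated-copy" else 3 - truncated_copy
        assigned[copy].append((d.start, d.end))

    segments = [
        HaplotypeSegment(label="flank-5'", source_start=r0, source_end=dup.start,
                         copy=0),
        HaplotypeSegment(label="dup-copy-1", source_start=dup.start,
                         source_end=dup.end, copy=1, deletions=sorted(assigned[1])),
        HaplotypeSegment(label="dup-copy-2", source_start=dup.start,
                         source_end=dup.end, copy=2, deletions=sorted(assigned[2])),
        HaplotypeSegment(label="flank-3'", source_start=dup.end, source_end=r1,
                         copy=0),
    ]
    total = (r1 - r0) + dup.length - sum(d.length for d in dels)
    assert total == sum(s.length for s in segments)
    return YHaplotypeModel(region=(r0, r1), segments=segments,
                           placement=placement, total_length=total)


# ---------------------------------------------------------------------------
# small-variant annotation


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}

_CODON_TABLE = None


def _translate(codon: str) -> str:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE[codon.upper()]


def annotate_variant(pos: int, ref: str, alt: str, genes: GeneModelSet,
                     seq: Optional[ReferenceSegment] = None) -> VariantRecord:
    """Assign gene context (and amino-acid change for coding SNPs).

    For a SNP inside an annotated CDS the codon is rebuilt from the
    reference segment honoring strand (alleles are reverse-complemented for
    antisense genes) and reading frame; a changed residue is reported as
    e.g. ``"Thr->Ala"``, synonymous changes as None.
    """
    vtype = classify_variant_type(ref, alt)
    length = abs(len(ref) - len(alt)) if vtype != "snp" else 1
    if vtype == "complex":
        length = len(ref)
    rec = VariantRecord(pos=pos, ref=ref, alt=alt, length=length, type=vtype)

    gene: Optional[Gene] = genes.gene_at(pos)
    if gene is None:
        rec.context = "non-coding"
        return rec
    rec.gene = gene.id
    label = gene.feature_label(pos)
    if label in ("5'UTR", "3'UTR"):
        rec.context = label
        return rec
    if label.startswith("intron"):
        rec.context = "intron"
        return rec
    rec.context = "exon"
    num = gene.exon_number(pos)
    rec.exon_number = num

    if vtype != "snp" or seq is None or gene.cds_segment(pos) is None:
        return rec
    if seq.base_at(pos) != ref.upper():
        raise ValueError(f"reference mismatch at {pos}: sequence has "
                         f"{seq.base_at(pos)}, variant says {ref}")
    cds = gene.spliced_cds(seq)
    off = gene.cds_offset(pos)
    if off is None:
        return rec
    frame = gene.first_phase()
    if off < frame:
        return rec
    codon_idx = (off - frame) // 3
    start = frame + 3 * codon_idx
    codon = cds[start:start + 3]
    if len(codon) < 3:
        return rec
    within = off - start
    alt_base = alt.upper() if gene.strand == "+" else reverse_complement(alt.upper())
    new_codon = codon[:within] + alt_base + codon[within + 1:]
    aa_ref = _translate(codon)
    aa_alt = _translate(new_codon)
    if aa_ref != aa_alt:
        rec.aa_change = f"{_AA3[aa_ref]}->{_AA3[aa_alt]}"
    return rec


# ---------------------------------------------------------------------------
# variant set operations


def variant_set_ops(set_a: Iterable[VariantRecord],
                    set_b: Iterable[VariantRecord]
                    ) -> tuple[list, list, list]:
    """Exact-key (pos, ref, alt) intersection and differences.

    Returns ``(shared, a_specific, b_specific)`` preserving input order and
    taking records from set A for the shared list.
    """
    a = list(set_a)
    b = list(set_b)
    keys_a = {v.key for v in a}
    keys_b = {v.key for v in b}
    shared = [v for v in a if v.key in keys_b]
    a_only = [v for v in a if v.key not in keys_b]
    b_only = [v for v in b if v.key not in keys_a]
    return shared, a_only, b_only


def variant_summary(records: Iterable[VariantRecord]) -> dict:
    """Counts by type and non-synonymous changes by gene."""
    records = list(records)
    by_type: dict[str, int] = {}
    aa_by_gene: dict[str, int] = {}
    for v in records:
        by_type[v.type] = by_type.get(v.type, 0) + 1
        if v.aa_change:
            aa_by_gene[v.gene] = aa_by_gene.get(v.gene, 0) + 1
    return {"n": len(records), "by_type": by_type,
            "aa_changes_by_gene": aa_by_gene}


# ---------------------------------------------------------------------------
# amh marker genotype rule


def predict_genotype_from_markers(m: MarkerPattern) -> str:
    """Predict the sex-chromosome genotype from the three amh markers.

    Rule precedence (YY before XY so the X-negative supermale pattern is
    never read as XY): amhX- with both Y markers present -> YY; amhX+ with
    either Y-copy marker present -> XY; amhX+ with both Y markers absent ->
    XX; amhX+ with the truncated-copy marker absent and amhY undetermined ->
    ND.  A pattern with no marker present is uninterpretable.
    """
    if m.amhX == "-":
        if m.amhdY == "+" and m.amhY == "+":
            return "YY"
        raise ValueError(f"uninterpretable marker pattern for {m.individual}: "
                         "no X marker and incomplete Y evidence")
    if m.amhdY == "+" or m.amhY == "+":
        return "XY"
    if m.amhY == "ND":
        return "ND"
    return "XX"
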