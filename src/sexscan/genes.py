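"""Gene models: exon/intron/UTR structure, strand-aware feature lookup.

Genes here are stored with 1-based inclusive genomic intervals (matching
GFF3) and every lookup takes a 1-based genomic position.  Feature numbering
("exon 3", "intron 2") follows transcription order, so for a minus-strand
gene exon 1 is the genomically rightmost exon — the convention used when a
breakpoint is described as falling "after the third exon" of a gene that is
antisense on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .records import ReferenceSegment

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Gene:
    """One gene model: intervals are 1-based inclusive (start, end) tuples."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list = field(default_factory=list)
    cds: list = field(default_factory=list)    # (start, end, phase)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for s, e, *_ in self.exons + self.cds + self.utr5 + self.utr3:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"feature ({s}, {e}) outside gene {self.id} span")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def _rank(self, i: int, total: int) -> int:
        """Genomic index -> transcription-order 1-based rank."""
        return i + 1 if self.strand == "+" else total - i

    def exon_number(self, pos: int) -> Optional[int]:
        for i, (s, e) in enumerate(self.exons):
            if s <= pos <= e:
                return self._rank(i, len(self.exons))
        return None

    def intron_number(self, pos: int) -> Optional[int]:
        """Introns are numbered after the preceding exon in transcription
        order: intron k separates exon k from exon k+1."""
        for i in range(len(self.exons) - 1):
            left_end = self.exons[i][1]
            right_start = self.exons[i + 1][0]
            if left_end < pos < right_start:
                # genomic gap i sits after genomic exon i; in transcription
                # order it follows exon rank(i) on + and rank(i+1) on -
                if self.strand == "+":
                    return i + 1
                return len(self.exons) - (i + 1)
        return None

    def utr_label(self, pos: int) -> Optional[str]:
        for s, e in self.utr5:
            if s <= pos <= e:
                return "5'UTR"
        for s, e in self.utr3:
            if s <= pos <= e:
                return "3'UTR"
        return None

    def cds_segment(self, pos: int) -> Optional[tuple]:
        for seg in self.cds:
            if seg[0] <= pos <= seg[1]:
                return seg
        return None

    def feature_label(self, pos: int) -> str:
        """Human-readable feature at ``pos``: "5'UTR", "exon 3", "intron 2"
        or "intron" / "exon" when structure is partial."""
        utr = self.utr_label(pos)
        if utr is not None:
            return utr
        ex = self.exon_number(pos)
        if ex is not None:
            return f"exon {ex}"
        intr = self.intron_number(pos)
        if intr is not None:
            return f"intron {intr}"
        return "intron"  # inside gene span, between annotated features

    # -- coding-sequence machinery -------------------------------------

    def spliced_cds(self, seg: ReferenceSegment) -> str:
        """The mRNA-sense CDS sequence assembled from the reference."""
        parts = [seg.slice(s, e) for s, e, *_ in self.cds]
        if self.strand == "+":
            return "".join(parts)
        return "".join(reverse_complement(p) for p in reversed(parts))

    def cds_offset(self, pos: int) -> Optional[int]:
        """0-based offset of a genomic position within the spliced CDS."""
        segs = self.cds if self.strand == "+" else list(reversed(self.cds))
        off = 0
        for s, e, *_ in segs:
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        return None

    def first_phase(self) -> int:
        if not self.cds:
            return 0
        segs = self.cds if self.strand == "+" else list(reversed(self.cds))
        ph = segs[0][2] if len(segs[0]) > 2 else 0
        return int(ph or 0)


@dataclass
class GeneModelSet:
    """A collection of gene models with position-based lookup."""

    genes: dict

    @classmethod
    def from_genes(cls, genes: list) -> "GeneModelSet":
        return cls(genes={g.id: g for g in genes})

    @classmethod
    def from_gff3(cls, path: str) -> "GeneModelSet":
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                                keep_order=True)
        # resolve each feature's gene through at most one mRNA hop
        to_gene: dict[str, str] = {}
        by_gene: dict[str, Gene] = {}
        names: dict[str, str] = {}
        for g in db.features_of_type("gene"):
            gid = g.attributes.get("ID", [g.id])[0]
            name = g.attributes.get("Name", [gid])[0]
            to_gene[gid] = gid
            names[gid] = name
            by_gene[gid] = Gene(id=name, chrom=g.seqid, strand=g.strand,
                                start=g.start, end=g.end)
        for t in db.features_of_type(("mRNA", "transcript")):
            tid = t.attributes.get("ID", [t.id])[0]
            parent = t.attributes.get("Parent", [None])[0]
            if parent in to_gene:
                to_gene[tid] = to_gene[parent]
        kinds = {"exon": "exons", "CDS": "cds",
                 "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}
        for ftype, attr in kinds.items():
            for f in db.features_of_type(ftype):
                for parent in f.attributes.get("Parent", []):
                    gid = to_gene.get(parent)
                    if gid is None:
                        continue
                    if ftype == "CDS":
                        ph = 0 if f.frame in (None, ".") else int(f.frame)
                        by_gene[gid].cds.append((f.start, f.end, ph))
                    else:
                        getattr(by_gene[gid], attr).append((f.start, f.end))
        for gene in by_gene.values():
            gene.exons = sorted(set(gene.exons))
            gene.cds = sorted(set(gene.cds))
            gene.utr5 = sorted(set(gene.utr5))
            gene.utr3 = sorted(set(gene.utr3))
        return cls(genes={g.id: g for g in by_gene.values()})

    def to_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes.values():
                fh.write(f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t."
                         f"\tID={g.id};Name={g.id}\n")
                mrna = f"{g.id}.t1"
                fh.write(f"{g.chrom}\t.\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t."
                         f"\tID={mrna};Parent={g.id}\n")
                for s, e in g.exons:
                    fh.write(f"{g.chrom}\t.\texon\t{s}\t{e}\t.\t{g.strand}\t."
                             f"\tParent={mrna}\n")
                for s, e, *ph in g.cds:
                    phase = ph[0] if ph else 0
                    fh.write(f"{g.chrom}\t.\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}"
                             f"\tParent={mrna}\n")
                for s, e in g.utr5:
                    fh.write(f"{g.chrom}\t.\tfive_prime_UTR\t{s}\t{e}\t.\t{g.strand}\t."
                             f"\tParent={mrna}\n")
                for s, e in g.utr3:
                    fh.write(f"{g.chrom}\t.\tthree_prime_UTR\t{s}\t{e}\t.\t{g.strand}\t."
                             f"\tParent={mrna}\n")

    def gene_at(self, pos: int, chrom: Optional[str] = None) -> Optional[Gene]:
        for g in self.genes.values():
            if chrom is not None and g.chrom != chrom:
                continue
            if g.contains(pos):
                return g
        return None
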