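"""Positional classification of retained lncRNAs and structural summaries.

A retained lncRNA is assigned exactly one class relative to the reference
annotation, with precedence:

1. ``sense_overlap`` — >=1 bp shared between a lncRNA exon and a reference
   exon on the same strand;
2. ``antisense``     — exonic overlap on the opposite strand;
3. ``intronic``      — contained entirely within an intron of a gene (either
   strand by default), with no exonic overlap;
4. ``lincRNA``       — overlaps no annotated gene.

Host-gene ties break by largest overlap, then lexicographic gene_id.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from intervaltree import IntervalTree

from .annotation import Annotation, TranscriptModel
from .errors import ValidationError

__all__ = [
    "LncRecord",
    "StructuralSummary",
    "AnnotationIndex",
    "classify_lncrna",
    "class_percentages",
    "summarize_structure",
    "CLASSES",
]

CLASSES = ("lincRNA", "antisense", "intronic", "sense_overlap")

DEFAULT_LENGTH_BINS = (200, 500, 1000, 2000, 5000)
DEFAULT_ORF_BINS = (100, 200, 300, 400, 500, 600)


@dataclass
class LncRecord:
    """A retained lncRNA with its positional class and structural stats."""

    transcript_id: str
    positional_class: str
    host_gene: str | None
    spliced_length_nt: int
    exon_count: int
    longest_orf_nt: int | None = None
    mean_fpkm: dict | None = None

    def __post_init__(self) -> None:
        if self.positional_class not in CLASSES:
            raise ValidationError(f"unknown class {self.positional_class!r}")
        if self.positional_class == "lincRNA" and self.host_gene is not None:
            raise ValidationError("lincRNA cannot have a host gene")
        if self.positional_class != "lincRNA" and self.host_gene is None:
            raise ValidationError(
                f"{self.positional_class} record requires a host gene"
            )


class AnnotationIndex:
    """Interval indexes over reference exons, introns and gene spans.

    Query results are required to match a linear scan exactly; the index is
    a speed device only.
    """

    def __init__(self, ann: Annotation):
        self.ann = ann
        self.exon_trees: dict[str, IntervalTree] = {}
        self.intron_trees: dict[str, IntervalTree] = {}
        self.span_trees: dict[str, IntervalTree] = {}
        for g in ann.genes.values():
            st = self.span_trees.setdefault(g.chrom, IntervalTree())
            st.addi(g.span[0], g.span[1], g.gene_id)
            et = self.exon_trees.setdefault(g.chrom, IntervalTree())
            it = self.intron_trees.setdefault(g.chrom, IntervalTree())
            for tx in g.transcripts:
                for s, e in tx.exons:
                    et.addi(s, e, (g.gene_id, g.strand))
                for s, e in tx.introns:
                    it.addi(s, e, (g.gene_id, g.strand))

    def exon_overlaps(self, chrom: str, start: int, end: int):
        tree = self.exon_trees.get(chrom)
        return [] if tree is None else list(tree.overlap(start, end))

    def intron_containers(self, chrom: str, start: int, end: int):
        """Introns that fully contain [start, end)."""
        tree = self.intron_trees.get(chrom)
        if tree is None:
            return []
        return [iv for iv in tree.overlap(start, end)
                if iv.begin <= start and end <= iv.end]

    def genes_near(self, chrom: str, start: int, end: int, window: int):
        tree = self.span_trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start - window, end + window)})


def classify_lncrna(
    t: TranscriptModel,
    index: AnnotationIndex | Annotation,
    sense_intronic_only: bool = False,
) -> tuple[str, str | None]:
    """Assign a positional class and host gene to one lncRNA."""
    if isinstance(index, Annotation):
        index = AnnotationIndex(index)

    # exonic overlap, bp aggregated per (gene, relative orientation)
    overlap_bp: dict[tuple[str, bool], int] = {}
    for s, e in t.exons:
        for iv in index.exon_overlaps(t.chrom, s, e):
            gid, gstrand = iv.data
            bp = min(e, iv.end) - max(s, iv.begin)
            if bp > 0:
                key = (gid, gstrand == t.strand)
                overlap_bp[key] = overlap_bp.get(key, 0) + bp

    def _pick(candidates: dict[str, int]) -> str:
        # largest overlap wins, ties by gene id
        return sorted(candidates, key=lambda g: (-candidates[g], g))[0]

    same = {g: bp for (g, is_same), bp in overlap_bp.items() if is_same}
    if same:
        return "sense_overlap", _pick(same)
    opp = {g: bp for (g, is_same), bp in overlap_bp.items() if not is_same}
    if opp:
        return "antisense", _pick(opp)

    span = t.span
    containers = index.intron_containers(t.chrom, *span)
    if sense_intronic_only:
        containers = [iv for iv in containers if iv.data[1] == t.strand]
    if containers:
        # smallest containing intron first, then gene id
        best = sorted(containers, key=lambda iv: (iv.end - iv.begin, iv.data[0]))[0]
        return "intronic", best.data[0]
    return "lincRNA", None


@dataclass
class StructuralSummary:
    """Class composition and length/exon/ORF distributions."""

    class_counts: dict[str, int]
    class_percentages: dict[str, float]
    total: int
    length_hist: dict[str, dict[str, int]]
    exon_hist: dict[str, dict[int, int]]
    orf_hist: dict[str, dict[str, int]]
    mean_length: dict[str, float]


def class_percentages(counts: dict[str, int], total: int | None = None) -> dict[str, float]:
    """Percentages of each class, rounded half-up to one decimal.

    ``100 * count / total`` per class. ``total`` defaults to the sum of the
    supplied counts; pass it explicitly when the denominator is a larger
    retained set than the classes listed.
    """
    if total is None:
        total = sum(counts.values())
    if total <= 0:
        raise ValidationError("cannot take percentages of zero records")
    out = {}
    for cls, n in counts.items():
        pct = Decimal(100 * n) / Decimal(total)
        out[cls] = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return out


def _bin_label(value: int, edges: tuple[int, ...]) -> str:
    prev = 0
    for edge in edges:
        if value <= edge:
            return f"({prev},{edge}]"
        prev = edge
    return f">{edges[-1]}"


def summarize_structure(
    records,
    mrnas=(),
    length_bins: tuple[int, ...] = DEFAULT_LENGTH_BINS,
    orf_bins: tuple[int, ...] = DEFAULT_ORF_BINS,
) -> StructuralSummary:
    """Compute class composition and structural distributions.

    ``records`` are LncRecords; ``mrnas`` is an optional collection of
    reference TranscriptModels summarized alongside as the "mRNA" group.
    """
    records = list(records)
    if not records:
        raise ValidationError("summarize_structure requires at least one record")
    counts = Counter(r.positional_class for r in records)
    groups = {"lncRNA": [(r.spliced_length_nt, r.exon_count, r.longest_orf_nt)
                         for r in records]}
    if mrnas:
        groups["mRNA"] = [(t.spliced_length, t.exon_count, None) for t in mrnas]

    length_hist, exon_hist, orf_hist, mean_length = {}, {}, {}, {}
    for name, rows in groups.items():
        length_hist[name] = dict(
            Counter(_bin_label(length, length_bins) for length, _, _ in rows)
        )
        exon_hist[name] = dict(Counter(n for _, n, _ in rows))
        orfs = [o for _, _, o in rows if o is not None]
        orf_hist[name] = dict(Counter(_bin_label(o, orf_bins) for o in orfs))
        mean_length[name] = sum(length for length, _, _ in rows) / len(rows)

    return StructuralSummary(
        class_counts=dict(counts),
        class_percentages=class_percentages(dict(counts)),
        total=len(records),
        length_hist=length_hist,
        exon_hist=exon_hist,
        orf_hist=orf_hist,
        mean_length=mean_length,
    )
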