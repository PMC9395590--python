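"""Coordinate model and GTF/GFF3 I/O.

All internal coordinates are 0-based half-open; the GTF convention (1-based,
closed) is converted exactly once at the I/O boundary. Downstream overlap and
distance arithmetic therefore never needs ±1 corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from gffutils.feature import feature_from_line

from .errors import GtfParseError, ValidationError

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "Annotation",
    "read_gtf",
    "write_gtf",
    "build_annotation",
    "read_chrom_lengths",
    "write_chrom_lengths",
]

_VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript on one chromosome.

    Exons are ``(start, end)`` intervals in 0-based half-open genome
    coordinates, sorted ascending and non-overlapping. ``class_code`` is the
    single-character assembly class code (Cuffmerge/StringTie convention:
    "u" intergenic, "i" intronic, "x" exonic-antisense, "o" sense-overlap,
    "=" known match); it is ``None`` for reference transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    class_code: str | None = None
    source: str = "assembly"

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has zero exons")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if s >= e:
                raise ValidationError(
                    f"{self.transcript_id}: exon ({s},{e}) has start >= end"
                )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"{self.transcript_id}: exons ({s1},{e1}) and ({s2},{e2}) "
                    "overlap or are unsorted"
                )
        if self.source not in ("reference", "assembly"):
            raise ValidationError(f"{self.transcript_id}: bad source {self.source!r}")

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, 0-based half-open."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        )


@dataclass
class GeneModel:
    """A gene: the union of its transcript models on one chromosome/strand."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcripts: list[TranscriptModel] = field(default_factory=list)
    biotype: str | None = None


@dataclass
class Annotation:
    """A reference annotation: genes plus chromosome lengths."""

    genes: dict[str, GeneModel]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for g in self.genes.values():
            length = self.chrom_lengths.get(g.chrom)
            if length is None:
                raise ValidationError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.span[0] < 0 or g.span[1] > length:
                raise ValidationError(
                    f"gene {g.gene_id}: span {g.span} outside {g.chrom} (len {length})"
                )

    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.genes.values() for t in g.transcripts]


def _parse_feature(line: str, lineno: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
    try:
        f = feature_from_line(line)
        int(fields[3]), int(fields[4])
    except Exception as exc:  # gffutils raises assorted types
        raise GtfParseError(f"line {lineno}: {exc}") from exc
    return f


def read_gtf(path, source: str = "assembly") -> list[TranscriptModel]:
    """Read transcripts from a GTF (StringTie/Cuffmerge dialect) or GFF3 file.

    GTF exon records carry ``transcript_id``/``gene_id`` (and optionally
    ``class_code``); GFF3 exons point at their transcript via ``Parent`` and
    transcripts at their gene likewise. Coordinates are converted from the
    file's 1-based closed convention to 0-based half-open.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}  # GFF3: transcript -> gene

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _parse_feature(line, lineno)
            ftype = f.featuretype.lower()
            attrs = f.attributes
            if ftype == "exon":
                if "transcript_id" in attrs:  # GTF dialect
                    tid = attrs["transcript_id"][0]
                    gid = attrs["gene_id"][0] if "gene_id" in attrs else tid
                    code = attrs["class_code"][0] if "class_code" in attrs else None
                elif "Parent" in attrs:  # GFF3 dialect
                    tid = attrs["Parent"][0]
                    gid = None
                    code = None
                else:
                    raise GtfParseError(
                        f"line {lineno}: exon lacks transcript_id/Parent attribute"
                    )
                exons.setdefault(tid, []).append((f.start - 1, f.end))
                m = meta.setdefault(tid, {"gene_id": gid, "chrom": f.chrom,
                                          "strand": f.strand, "class_code": code})
                if gid is not None:
                    m["gene_id"] = gid
                if code is not None:
                    m["class_code"] = code
            elif ftype == "transcript" or ftype.endswith("rna"):
                if "transcript_id" in attrs:
                    tid = attrs["transcript_id"][0]
                    code = attrs["class_code"][0] if "class_code" in attrs else None
                    m = meta.setdefault(tid, {"gene_id": None, "chrom": f.chrom,
                                              "strand": f.strand, "class_code": None})
                    if "gene_id" in attrs:
                        m["gene_id"] = attrs["gene_id"][0]
                    if code is not None:
                        m["class_code"] = code
                elif "ID" in attrs:
                    tid = attrs["ID"][0]
                    if "Parent" in attrs:
                        tx_parent[tid] = attrs["Parent"][0]

    out = []
    for tid, ex in exons.items():
        m = meta[tid]
        gid = m["gene_id"] or tx_parent.get(tid, tid)
        ex = sorted(ex)
        if not ex:
            raise ValidationError(f"{tid}: transcript has zero exons")
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(ex),
                class_code=m["class_code"],
                source=source,
            )
        )
    out.sort(key=lambda t: (t.chrom, t.span, t.transcript_id))
    return out


def write_gtf(transcripts, path) -> None:
    """Write transcripts as standard GTF (1-based closed coordinates).

    One ``transcript`` line plus one ``exon`` line per exon; attributes carry
    gene_id, transcript_id and class_code when set.
    """
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.class_code is not None:
                attrs += f' class_code "{t.class_code}";'
            s, e = t.span
            src = "lncpipe"
            fh.write(f"{t.chrom}\t{src}\ttranscript\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")
            for es, ee in t.exons:
                fh.write(f"{t.chrom}\t{src}\texon\t{es + 1}\t{ee}\t.\t{t.strand}\t.\t{attrs}\n")


def build_annotation(transcripts, chrom_lengths: dict[str, int]) -> Annotation:
    """Group reference transcripts into genes and validate spans.

    Gene spans are the min/max over member exon coordinates. Transcripts of
    one gene_id on different chromosomes or strands are rejected.
    """
    genes: dict[str, GeneModel] = {}
    for t in transcripts:
        g = genes.get(t.gene_id)
        if g is None:
            genes[t.gene_id] = GeneModel(
                gene_id=t.gene_id, chrom=t.chrom, strand=t.strand,
                span=t.span, transcripts=[t],
            )
        else:
            if g.chrom != t.chrom or g.strand != t.strand:
                raise ValidationError(
                    f"gene {t.gene_id}: transcripts on different chrom/strand "
                    f"({g.chrom}{g.strand} vs {t.chrom}{t.strand})"
                )
            g.transcripts.append(t)
            g.span = (min(g.span[0], t.span[0]), max(g.span[1], t.span[1]))
    return Annotation(genes=genes, chrom_lengths=dict(chrom_lengths))


def read_chrom_lengths(path) -> dict[str, int]:
    """Two-column TSV: chrom, length (bp)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            out[chrom] = int(length)
    return out


def write_chrom_lengths(lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")
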