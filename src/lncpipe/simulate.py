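"""Self-contained synthetic test universe with planted ground truth.

The generator emulates a staged fruit-development RNA-seq study at desk
scale: a small multi-chromosome genome annotation, an assembled transcript
set containing lncRNAs of every positional class plus one decoy per
screening filter, spliced transcript sequences, and a stages x replicates
FPKM matrix with planted differential expression and planted high-|r|
lncRNA-mRNA correlation structure.

Geometry is slot-based: genes are tiled with >= 25 kb spacing so every
10-kb proximity window is unambiguous. Planted lincRNAs sit either > 10 kb
from every gene or within (0, 10 kb] of exactly one gene (both sides and
the exact 10-kb boundary are exercised); antisense/sense-overlap lncRNAs
share >= 1 exonic bp with their host gene's first exon on the opposite/same
strand; intronic lncRNAs fall strictly inside the host's first intron.

Expression is simulated directly on the FPKM scale (log-normal): a
per-transcript baseline, planted stage effects, and Gaussian log2 noise.
Planted trans pairs share a fixed-spread latent stage profile (a
standardized ramp in random stage order) whose amplitude is chosen from
``noise_sd`` and ``planted_trans_r`` so the expected log-scale Pearson
correlation equals the target; the sign of the gene's copy of the latent
sets the pair's sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, TranscriptModel, build_annotation
from .errors import ConfigError
from .expression import ExpressionMatrix
from .screen import STEP_NAMES, scan_orfs

__all__ = ["SimConfig", "GroundTruth", "simulate_genome", "simulate_expression",
           "simulate_universe", "Universe", "write_universe"]

_SLOT = 30_000  # one gene or intergenic feature per slot; >= 25 kb gene spacing
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_NONSTOP = [c for c in _CODONS if c not in _STOPS]

CLASS_CODE_BY_CLASS = {
    "lincRNA": "u",
    "antisense": "x",
    "intronic": "i",
    "sense_overlap": "o",
}


def _default_lnc_counts() -> dict[str, int]:
    # intronic-heavy composition, mirroring field expectations for plants
    return {"lincRNA": 6, "antisense": 4, "intronic": 8, "sense_overlap": 2}


def _default_decoys() -> dict[str, int]:
    return {name: 1 for name in STEP_NAMES}


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic universe."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 600_000
    n_genes: int = 24
    n_lnc_per_class: dict[str, int] = field(default_factory=_default_lnc_counts)
    n_decoys_per_filter: dict[str, int] = field(default_factory=_default_decoys)
    stages: tuple[str, ...] = ("S1", "S2", "S3", "S4")
    replicates: int = 3
    de_fraction: float = 0.2
    lfc_range: tuple[float, float] = (2.0, 4.0)
    noise_sd: float = 0.05
    planted_trans_r: float = 0.99
    n_trans_pairs: int = 8

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.n_genes < 1 or self.chrom_length < _SLOT:
            raise ConfigError("chrom/gene counts and lengths must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must be in [0, 1]")
        if not 0.95 < self.planted_trans_r <= 1.0:
            raise ConfigError("planted_trans_r must be in (0.95, 1]")
        if any(n < 0 for n in self.n_lnc_per_class.values()):
            raise ConfigError("lncRNA class counts must be non-negative")
        unknown = set(self.n_decoys_per_filter) - set(STEP_NAMES)
        if unknown:
            raise ConfigError(f"unknown decoy filters: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted labels the pipeline is expected to recover."""

    lnc_class: dict[str, str] = field(default_factory=dict)
    filter_fate: dict[str, str] = field(default_factory=dict)
    de_truth: dict[tuple[str, str], str] = field(default_factory=dict)
    cis_truth: set[tuple[str, str, str]] = field(default_factory=set)
    trans_truth: set[tuple[str, str, str]] = field(default_factory=set)


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _orf_spans(seq: str) -> list[tuple[int, int]]:
    spans = []
    n = len(seq)
    for frame in range(3):
        open_starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                open_starts.append(i)
            elif codon in _STOPS:
                spans.extend((s, i + 3) for s in open_starts)
                open_starts = []
    return spans


def _cap_orfs(seq: str, limit: int = 300) -> str:
    """Break every ORF >= limit by planting an in-frame stop at its middle."""
    while True:
        long = [sp for sp in _orf_spans(seq) if sp[1] - sp[0] >= limit]
        if not long:
            return seq
        s, e = long[0]
        p = s + 3 * (((e - s) // 3) // 2)
        seq = seq[:p] + "TAA" + seq[p + 3 :]


def _noncoding_seq(rng: np.random.Generator, length: int, limit: int = 300) -> str:
    return _cap_orfs(_random_seq(rng, length), limit)


def _coding_seq(rng: np.random.Generator) -> str:
    """660-nt sequence whose longest ORF is a planted 600-nt ATG..TAA frame."""
    prefix = _random_seq(rng, 30).replace("ATG", "ATC")
    body = "ATG" + "".join(rng.choice(_NONSTOP, size=198)) + "TAA"
    suffix = _random_seq(rng, 30)
    return prefix + body + suffix


# ---------------------------------------------------------------------------
# genome


def _gene_model(gene_id: str, chrom: str, strand: str, gs: int) -> TranscriptModel:
    # 3-exon gene, 4.2 kb span; first intron (600, 2600) hosts intronic lncRNAs
    exons = ((gs, gs + 600), (gs + 2600, gs + 3300), (gs + 3700, gs + 4200))
    return TranscriptModel(
        transcript_id=f"{gene_id}.t1", gene_id=gene_id, chrom=chrom,
        strand=strand, exons=exons, source="reference",
    )


_GENE_LEN = 4200
_NEAR_PLANS = [  # (side relative to the gene, span gap in bp); 10 kb boundary included
    ("right", 10_000), ("left", 2_500), ("right", 1), ("left", 5_000),
    ("right", 7_000), ("left", 400),
]


def simulate_genome(
    config: SimConfig,
) -> tuple[Annotation, list[TranscriptModel], dict[str, str], GroundTruth]:
    """Generate annotation, assembly transcripts, sequences and truth labels.

    Returns (annotation, assembly_transcripts, sequences, truth) with
    ``truth.de_truth``/``truth.trans_truth`` left empty until
    :func:`simulate_expression` fills them.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])

    counts = {c: cfg.n_lnc_per_class.get(c, 0) for c in CLASS_CODE_BY_CLASS}
    n_linc = counts["lincRNA"]
    n_near = (n_linc + 1) // 2
    hosts_needed = counts["antisense"] + counts["sense_overlap"] + counts["intronic"] + n_near
    if hosts_needed > cfg.n_genes:
        raise ConfigError(
            f"{hosts_needed} host genes needed but only {cfg.n_genes} genes configured"
        )

    slots_per_chrom = cfg.chrom_length // _SLOT
    slots = [
        (f"chr{c + 1}", s * _SLOT)
        for c in range(cfg.n_chroms)
        for s in range(slots_per_chrom)
    ]
    n_far = n_linc - n_near
    n_decoys = sum(cfg.n_decoys_per_filter.values())
    if cfg.n_genes + n_far + n_decoys > len(slots):
        raise ConfigError(
            "geometry impossible: too many genes/features for the configured "
            f"genome ({cfg.n_genes + n_far + n_decoys} slots needed, {len(slots)} available)"
        )

    # reference genes
    ref_transcripts: list[TranscriptModel] = []
    gene_at_slot: list[tuple[str, int, str, str]] = []  # (chrom, gs, strand, gene_id)
    for i in range(cfg.n_genes):
        chrom, slot = slots[i]
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{i + 1:04d}"
        gs = slot + 10_000
        ref_transcripts.append(_gene_model(gid, chrom, strand, gs))
        gene_at_slot.append((chrom, gs, strand, gid))
    chrom_lengths = {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chroms)}
    annotation = build_annotation(ref_transcripts, chrom_lengths)

    truth = GroundTruth()
    assembly: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    lnc_idx = 0
    host_idx = 0

    def _new_lnc(cls: str, chrom: str, strand: str, exons) -> TranscriptModel:
        nonlocal lnc_idx
        lnc_idx += 1
        tid = f"LNC_{lnc_idx:04d}"
        t = TranscriptModel(
            transcript_id=tid, gene_id=tid, chrom=chrom, strand=strand,
            exons=tuple(exons), class_code=CLASS_CODE_BY_CLASS[cls],
            source="assembly",
        )
        assembly.append(t)
        truth.lnc_class[tid] = cls
        truth.filter_fate[tid] = "retained"
        sequences[tid] = _noncoding_seq(rng, t.spliced_length)
        return t

    # antisense / sense-overlap: share 200 exonic bp with the host's first exon
    for cls in ("antisense", "sense_overlap"):
        for _ in range(counts[cls]):
            chrom, gs, gstrand, gid = gene_at_slot[host_idx]
            host_idx += 1
            strand = ({"+": "-", "-": "+"}[gstrand] if cls == "antisense" else gstrand)
            t = _new_lnc(cls, chrom, strand,
                         [(gs - 300, gs + 200), (gs + 1000, gs + 1500)])
            cat = "antisense" if cls == "antisense" else "sense_overlap"
            truth.cis_truth.add((t.transcript_id, gid, cat))

    # intronic: strictly inside the host's first intron (gs+600, gs+2600)
    for _ in range(counts["intronic"]):
        chrom, gs, gstrand, gid = gene_at_slot[host_idx]
        host_idx += 1
        strand = "+" if rng.random() < 0.5 else "-"
        t = _new_lnc("intronic", chrom, strand,
                     [(gs + 800, gs + 1300), (gs + 1600, gs + 2300)])
        cat = "sense_overlap" if strand == gstrand else "antisense"
        truth.cis_truth.add((t.transcript_id, gid, cat))

    # near lincRNAs: within (0, 10 kb] of exactly one gene
    for k in range(n_near):
        chrom, gs, gstrand, gid = gene_at_slot[host_idx]
        host_idx += 1
        side, gap = _NEAR_PLANS[k % len(_NEAR_PLANS)]
        if side == "right":
            x = gs + _GENE_LEN + gap
            exons = [(x, x + 600), (x + 900, x + 1500)]
        else:
            x_end = gs - gap
            exons = [(x_end - 1500, x_end - 900), (x_end - 600, x_end)]
        strand = "+" if rng.random() < 0.5 else "-"
        t = _new_lnc("lincRNA", chrom, strand, exons)
        lnc_is_5prime = (side == "left") == (gstrand == "+")
        truth.cis_truth.add(
            (t.transcript_id, gid, "upstream" if lnc_is_5prime else "downstream")
        )

    # far lincRNAs and decoys get their own empty slots (> 10 kb from genes)
    free = iter(slots[cfg.n_genes:])
    for _ in range(n_far):
        chrom, slot = next(free)
        x = slot + 12_000
        strand = "+" if rng.random() < 0.5 else "-"
        _new_lnc("lincRNA", chrom, strand, [(x, x + 600), (x + 900, x + 1500)])

    decoy_idx = 0
    for step in STEP_NAMES:
        for _ in range(cfg.n_decoys_per_filter.get(step, 0)):
            decoy_idx += 1
            chrom, slot = next(free)
            x = slot + 12_000
            strand = "+" if rng.random() < 0.5 else "-"
            tid = f"DECOY_{decoy_idx:03d}_{step}"
            code = "=" if step == "novelty" else "u"
            if step == "exon_count":
                exons = [(x, x + 500)]
            elif step == "length":
                exons = [(x, x + 100), (x + 200, x + 300)]  # spliced 200, not > 200
            else:
                exons = [(x, x + 330), (x + 400, x + 730)]
            t = TranscriptModel(
                transcript_id=tid, gene_id=tid, chrom=chrom, strand=strand,
                exons=tuple(exons), class_code=code, source="assembly",
            )
            assembly.append(t)
            truth.filter_fate[tid] = step
            if step == "coding_potential":
                sequences[tid] = _coding_seq(rng)
                assert scan_orfs(sequences[tid])[0] >= 300
            else:
                sequences[tid] = _noncoding_seq(rng, t.spliced_length)

    return annotation, assembly, sequences, truth


# ---------------------------------------------------------------------------
# expression


def _latent_profile(rng: np.random.Generator, n_stages: int, sigma: float) -> np.ndarray:
    """Fixed-spread stage profile: a standardized ramp in random stage order.

    Using a fixed spread (rather than i.i.d. draws) pins the latent stage
    variance, so the planted correlation is controlled by ``noise_sd`` and
    not by latent sampling luck.
    """
    ramp = np.linspace(-1.0, 1.0, n_stages)
    ramp = (ramp - ramp.mean()) / ramp.std()
    return sigma * rng.permutation(ramp)


def simulate_expression(
    config: SimConfig,
    truth: GroundTruth,
    transcript_ids: list[str],
) -> ExpressionMatrix:
    """Simulate the staged FPKM matrix and fill de_truth / trans_truth.

    FPKM = 2**(baseline + stage effect + noise). DE effects are single-stage
    shifts of |log2FC| drawn from ``lfc_range``; trans pairs add a shared
    latent stage ramp (gene copy negated for negative pairs). ``de_truth``
    is derived from the realized noise-free stage-mean profiles with the DE
    caller's default gate (|diff| >= 1).
    """
    cfg = config
    if cfg.replicates < 2:
        raise ConfigError("need >= 2 replicates per stage (correlation undefined)")
    rng = np.random.default_rng([cfg.seed, 1])
    stages = list(cfg.stages)
    n_stages = len(stages)
    n_samples = n_stages * cfg.replicates

    low_decoys = [t for t, fate in truth.filter_fate.items() if fate == "expression"]
    lnc_ids = [t for t, fate in truth.filter_fate.items() if fate == "retained"]
    gene_tids = [t for t in transcript_ids
                 if t not in truth.filter_fate]  # reference mRNAs

    # planted trans pairs: latent amplitude from the target log-scale r
    r = cfg.planted_trans_r
    sigma_latent = (
        cfg.noise_sd * math.sqrt(r / (1.0 - r)) if r < 1.0 else 1.0
    )
    if sigma_latent == 0.0:  # noise-free limit: any positive amplitude gives |r| = 1
        sigma_latent = 0.5
    n_pairs = min(cfg.n_trans_pairs, len(lnc_ids), len(gene_tids))
    trans_lncs = list(rng.choice(lnc_ids, size=n_pairs, replace=False)) if n_pairs else []
    trans_genes = list(rng.choice(gene_tids, size=n_pairs, replace=False)) if n_pairs else []

    profiles: dict[str, np.ndarray] = {}
    baselines: dict[str, float] = {}
    for tid in transcript_ids:
        baselines[tid] = float(rng.uniform(3.0, 7.0))
        profiles[tid] = np.zeros(n_stages)

    for i, (lnc, gene) in enumerate(zip(trans_lncs, trans_genes)):
        z = _latent_profile(rng, n_stages, sigma_latent)
        sign = "positive" if i % 2 == 0 else "negative"
        profiles[lnc] = profiles[lnc] + z
        profiles[gene] = profiles[gene] + (z if sign == "positive" else -z)
        gene_id = gene[:-3] if gene.endswith(".t1") else gene
        truth.trans_truth.add((lnc, gene_id, sign))

    # planted single-stage DE shifts on transcripts not used for trans pairs
    de_eligible = [t for t in transcript_ids
                   if t not in set(trans_lncs) | set(trans_genes)
                   and t not in low_decoys]
    n_de = int(round(cfg.de_fraction * len(de_eligible)))
    de_chosen = list(rng.choice(de_eligible, size=n_de, replace=False)) if n_de else []
    for tid in de_chosen:
        stage_j = int(rng.integers(n_stages))
        lfc = float(rng.uniform(*cfg.lfc_range))
        direction = 1.0 if rng.random() < 0.5 else -1.0
        profiles[tid][stage_j] += direction * lfc

    # realized noise-free truth for every comparison (B vs A, stages in order)
    for tid in transcript_ids:
        mu = profiles[tid]
        for ia in range(n_stages):
            for ib in range(ia + 1, n_stages):
                comparison = f"{stages[ib]}_vs_{stages[ia]}"
                diff = mu[ib] - mu[ia]
                call = "up" if diff >= 1.0 else ("down" if diff <= -1.0 else "null")
                truth.de_truth[(tid, comparison)] = call

    sample_ids = [f"{s}_{j + 1}" for s in stages for j in range(cfg.replicates)]
    stage_of_sample = np.repeat(np.arange(n_stages), cfg.replicates)
    values = np.empty((n_samples, len(transcript_ids)))
    for j, tid in enumerate(transcript_ids):
        mu = baselines[tid] + profiles[tid][stage_of_sample]
        noise = rng.normal(0.0, cfg.noise_sd, size=n_samples) if cfg.noise_sd > 0 else 0.0
        values[:, j] = 2.0 ** (mu + noise)
    for tid in low_decoys:
        j = transcript_ids.index(tid)
        values[:, j] = rng.uniform(0.05, 0.45, size=n_samples)  # always < 0.5 FPKM
        for (t_, comp), _ in list(truth.de_truth.items()):
            if t_ == tid:
                truth.de_truth[(t_, comp)] = "null"

    df = pd.DataFrame(values, index=sample_ids, columns=transcript_ids)
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# bundle + writers


@dataclass
class Universe:
    """One fully simulated study: genome, transcripts, sequences, expression."""

    config: SimConfig
    annotation: Annotation
    assembly: list[TranscriptModel]
    sequences: dict[str, str]
    matrix: ExpressionMatrix
    truth: GroundTruth

    @property
    def reference_transcripts(self) -> list[TranscriptModel]:
        return self.annotation.transcripts()


def simulate_universe(config: SimConfig | None = None) -> Universe:
    cfg = config or SimConfig()
    annotation, assembly, sequences, truth = simulate_genome(cfg)
    tids = [t.transcript_id for t in annotation.transcripts()]
    tids += [t.transcript_id for t in assembly]
    matrix = simulate_expression(cfg, truth, tids)
    return Universe(cfg, annotation, assembly, sequences, matrix, truth)


def write_universe(u: Universe, outdir) -> None:
    """Write GFF3 reference, assembly GTF, FASTA, FPKM TSV and truth TSVs."""
    import os

    from .annotation import write_chrom_lengths, write_gtf

    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(str(outdir), name)

    with open(p("reference.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(u.annotation.genes.values(), key=lambda g: (g.chrom, g.span)):
            fh.write(f"{g.chrom}\tlncpipe\tgene\t{g.span[0] + 1}\t{g.span[1]}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for t in g.transcripts:
                s, e = t.span
                fh.write(f"{g.chrom}\tlncpipe\tmRNA\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                         f"ID={t.transcript_id};Parent={g.gene_id}\n")
                for es, ee in t.exons:
                    fh.write(f"{g.chrom}\tlncpipe\texon\t{es + 1}\t{ee}\t.\t{t.strand}\t.\t"
                             f"Parent={t.transcript_id}\n")

    write_gtf(u.assembly, p("assembly.gtf"))
    write_chrom_lengths(u.annotation.chrom_lengths, p("chrom_lengths.tsv"))

    with open(p("transcripts.fa"), "w") as fh:
        for tid in sorted(u.sequences):
            fh.write(f">{tid}\n{u.sequences[tid]}\n")

    u.matrix.to_tsv(p("fpkm.tsv"))

    t = u.truth
    with open(p("truth_lnc_class.tsv"), "w") as fh:
        fh.write("transcript_id\tclass\tfilter_fate\n")
        for tid in sorted(t.filter_fate):
            fh.write(f"{tid}\t{t.lnc_class.get(tid, '')}\t{t.filter_fate[tid]}\n")
    with open(p("truth_cis.tsv"), "w") as fh:
        fh.write("lnc_id\tgene_id\tcategory\n")
        for row in sorted(t.cis_truth):
            fh.write("\t".join(row) + "\n")
    with open(p("truth_trans.tsv"), "w") as fh:
        fh.write("lnc_id\tgene_id\tsign\n")
        for row in sorted(t.trans_truth):
            fh.write("\t".join(row) + "\n")
    with open(p("truth_de.tsv"), "w") as fh:
        fh.write("transcript_id\tcomparison\tcall\n")
        for (tid, comp), call in sorted(t.de_truth.items()):
            fh.write(f"{tid}\t{comp}\t{call}\n")
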