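"""cis and trans target prediction for lncRNAs.

cis: protein-coding genes whose span lies within a 10-kb window (inclusive)
of the lncRNA span. Overlapping pairs are categorized ``antisense`` or
``sense_overlap`` by relative strand with distance 0; non-overlapping pairs
are ``upstream``/``downstream`` relative to the *gene's* strand (a lncRNA on
the gene's 5' side is upstream), distance being the gap between the nearest
span boundaries.

trans: all lncRNA x gene expression pairs with |Pearson r| strictly > 0.95,
computed over every sample (stage x replicate) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotation import Annotation
from .classify import AnnotationIndex
from .errors import UndefinedCorrelationError, ValidationError

__all__ = [
    "TargetPair",
    "predict_cis",
    "predict_trans",
    "pearson",
    "cis_totals",
    "trans_totals",
    "CIS_CATEGORIES",
]

logger = logging.getLogger(__name__)

CIS_CATEGORIES = ("upstream", "downstream", "antisense", "sense_overlap")


@dataclass(frozen=True)
class TargetPair:
    """A predicted lncRNA -> gene edge, cis (category + distance) or trans (r)."""

    lnc_id: str
    gene_id: str
    mode: str
    cis_category: str | None = None
    distance_bp: int | None = None
    r: float | None = None
    sign: str | None = None
    p_r: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "cis":
            if self.cis_category not in CIS_CATEGORIES or self.distance_bp is None:
                raise ValidationError("cis pair requires category and distance")
            if self.r is not None:
                raise ValidationError("cis pair carries no correlation")
            overlap_cat = self.cis_category in ("antisense", "sense_overlap")
            if overlap_cat != (self.distance_bp == 0):
                raise ValidationError(
                    "distance 0 iff overlap category (antisense/sense_overlap)"
                )
        elif self.mode == "trans":
            if self.r is None or self.sign is None:
                raise ValidationError("trans pair requires r and sign")
            expected = "positive" if self.r > 0 else "negative"
            if self.sign != expected:
                raise ValidationError("sign must match sign(r)")
        else:
            raise ValidationError(f"unknown mode {self.mode!r}")


def _span_gap_and_side(lnc_span, gene_span) -> tuple[int, str]:
    """(gap_bp, side) with side in {left, right, overlap}; left = lnc before gene."""
    ls, le = lnc_span
    gs, ge = gene_span
    if le <= gs:
        return gs - le, "left"
    if ge <= ls:
        return ls - ge, "right"
    return 0, "overlap"


def predict_cis(
    lncs,
    ann: Annotation,
    window_bp: int = 10000,
    index: AnnotationIndex | None = None,
) -> list[TargetPair]:
    """Predict cis targets for each lncRNA transcript model.

    Every gene whose span gap to the lncRNA span is <= ``window_bp``
    (boundary inclusive) yields one pair; all qualifying genes are emitted,
    not only the nearest.
    """
    if index is None:
        index = AnnotationIndex(ann)
    pairs: list[TargetPair] = []
    seen: set[tuple[str, str, str]] = set()
    for t in lncs:
        span = t.span
        # candidate query widened 1 bp: half-open interval overlap would drop
        # a gene whose gap equals the window exactly; the gap test below is exact
        for gid in index.genes_near(t.chrom, span[0], span[1], window_bp + 1):
            gene = ann.genes[gid]
            gap, side = _span_gap_and_side(span, gene.span)
            if gap > window_bp:
                continue
            if side == "overlap":
                category = "sense_overlap" if gene.strand == t.strand else "antisense"
            else:
                lnc_is_5prime = (side == "left") == (gene.strand == "+")
                category = "upstream" if lnc_is_5prime else "downstream"
            key = (t.transcript_id, gid, category)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(
                TargetPair(
                    lnc_id=t.transcript_id, gene_id=gid, mode="cis",
                    cis_category=category, distance_bp=gap,
                )
            )
    return pairs


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson requires two equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("pearson requires at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt((xd * xd).sum()))
    sy = float(np.sqrt((yd * yd).sum()))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    r = float((xd * yd).sum() / (sx * sy))
    return max(-1.0, min(1.0, r))


def predict_trans(
    lnc_expr,
    gene_expr,
    r_threshold: float = 0.95,
) -> list[TargetPair]:
    """Emit all lncRNA x gene pairs with |r| strictly above the threshold.

    ``lnc_expr`` / ``gene_expr`` are DataFrames (samples x transcripts) or
    ExpressionMatrix objects sharing identical sample rows. Pairs involving a
    constant profile are skipped with a logged reason.
    """
    from .expression import ExpressionMatrix

    lv = lnc_expr.values if isinstance(lnc_expr, ExpressionMatrix) else lnc_expr
    gv = gene_expr.values if isinstance(gene_expr, ExpressionMatrix) else gene_expr
    if list(lv.index) != list(gv.index):
        raise ValidationError("lnc and gene matrices must share identical samples")
    n = lv.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 samples for correlation")

    la = lv.to_numpy(dtype=float)
    ga = gv.to_numpy(dtype=float)
    lc = la - la.mean(axis=0)
    gc = ga - ga.mean(axis=0)
    ls = np.sqrt((lc * lc).sum(axis=0))
    gs = np.sqrt((gc * gc).sum(axis=0))
    const_l = ls == 0
    const_g = gs == 0
    for name in np.array(lv.columns)[const_l]:
        logger.info("skipping lncRNA %s: constant expression profile", name)
    for name in np.array(gv.columns)[const_g]:
        logger.info("skipping gene %s: constant expression profile", name)

    ls_safe = np.where(const_l, 1.0, ls)
    gs_safe = np.where(const_g, 1.0, gs)
    rmat = (lc / ls_safe).T @ (gc / gs_safe)
    np.clip(rmat, -1.0, 1.0, out=rmat)
    rmat[const_l, :] = 0.0
    rmat[:, const_g] = 0.0

    pairs: list[TargetPair] = []
    hit_i, hit_j = np.nonzero(np.abs(rmat) > r_threshold)
    lnc_names = list(lv.columns)
    gene_names = list(gv.columns)
    for i, j in zip(hit_i, hit_j):
        r = float(rmat[i, j])
        pairs.append(
            TargetPair(
                lnc_id=lnc_names[i], gene_id=gene_names[j], mode="trans",
                r=r, sign="positive" if r > 0 else "negative",
            )
        )
    return pairs


def cis_totals(pairs_or_counts) -> dict[str, int]:
    """Per-category cis counts plus their exact total.

    Accepts an iterable of cis TargetPairs or a mapping category -> count.
    """
    if isinstance(pairs_or_counts, dict):
        counts = {c: int(pairs_or_counts.get(c, 0)) for c in CIS_CATEGORIES}
    else:
        counts = {c: 0 for c in CIS_CATEGORIES}
        for p in pairs_or_counts:
            if p.mode != "cis":
                raise ValidationError("cis_totals expects cis pairs")
            counts[p.cis_category] += 1
    counts["total"] = sum(counts[c] for c in CIS_CATEGORIES)
    return counts


def trans_totals(pairs_or_counts) -> dict[str, int]:
    """(positive, negative, total) trans counts with total = pos + neg.

    Accepts an iterable of trans TargetPairs or a mapping sign -> count.
    """
    if isinstance(pairs_or_counts, dict):
        pos = int(pairs_or_counts.get("positive", 0))
        neg = int(pairs_or_counts.get("negative", 0))
    else:
        pos = neg = 0
        for p in pairs_or_counts:
            if p.mode != "trans":
                raise ValidationError("trans_totals expects trans pairs")
            if p.sign == "positive":
                pos += 1
            else:
                neg += 1
    return {"positive": pos, "negative": neg, "total": pos + neg}
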