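"""cis/trans target prediction: boundaries, oracles, planted recovery."""

import numpy as np
import pandas as pd
import pytest

from lncpipe import (
    SimConfig,
    TranscriptModel,
    build_annotation,
    cis_totals,
    pearson,
    predict_cis,
    predict_trans,
    run_cascade,
    simulate_universe,
    trans_totals,
)
from lncpipe.errors import UndefinedCorrelationError, ValidationError


def _ref(gid, strand, exons, chrom="chr1"):
    return TranscriptModel(f"{gid}.t1", gid, chrom, strand, tuple(exons),
                           source="reference")


def _lnc(exons, strand="+", tid="L1"):
    return TranscriptModel(tid, tid, "chr1", strand, tuple(exons), "u", "assembly")


@pytest.fixture(scope="module")
def one_gene_annotation():
    # + strand gene spanning (50_000, 54_000)
    g = _ref("G1", "+", [(50_000, 50_600), (53_000, 54_000)])
    return build_annotation([g], {"chr1": 500_000})


class TestCisBoundaries:
    def test_gap_exactly_10kb_is_a_pair(self, one_gene_annotation):
        lnc = _lnc([(39_000, 39_500), (39_700, 40_000)])  # ends 10 kb before gene
        (pair,) = predict_cis([lnc], one_gene_annotation)
        assert pair.distance_bp == 10_000
        assert pair.cis_category == "upstream"

    def test_gap_10001_is_not_a_pair(self, one_gene_annotation):
        lnc = _lnc([(38_999, 39_500), (39_700, 39_999)])
        assert predict_cis([lnc], one_gene_annotation) == []

    def test_downstream_relative_to_gene_strand(self, one_gene_annotation):
        lnc = _lnc([(55_000, 55_400), (55_600, 56_000)])  # 3' of a + gene
        (pair,) = predict_cis([lnc], one_gene_annotation)
        assert pair.cis_category == "downstream"
        assert pair.distance_bp == 1_000

    def test_upstream_downstream_flip_for_minus_strand_gene(self):
        g = _ref("G1", "-", [(50_000, 50_600), (53_000, 54_000)])
        ann = build_annotation([g], {"chr1": 500_000})
        left = _lnc([(40_000, 40_500), (40_700, 41_000)])
        right = _lnc([(55_000, 55_400), (55_600, 56_000)], tid="L2")
        pairs = {p.lnc_id: p.cis_category for p in predict_cis([left, right], ann)}
        assert pairs == {"L1": "downstream", "L2": "upstream"}

    def test_overlap_categories_have_distance_zero(self, one_gene_annotation):
        same = _lnc([(50_500, 51_000), (51_200, 51_500)], strand="+")
        opp = _lnc([(50_500, 51_000), (51_200, 51_500)], strand="-", tid="L2")
        pairs = {p.lnc_id: p for p in predict_cis([same, opp], one_gene_annotation)}
        assert pairs["L1"].cis_category == "sense_overlap"
        assert pairs["L2"].cis_category == "antisense"
        assert pairs["L1"].distance_bp == pairs["L2"].distance_bp == 0


def _brute_force_cis(lncs, ann, window=10_000):
    pairs = set()
    for t in lncs:
        ls, le = t.span
        for g in ann.genes.values():
            if g.chrom != t.chrom:
                continue
            gs, ge = g.span
            if le <= gs:
                gap, side = gs - le, "left"
            elif ge <= ls:
                gap, side = ls - ge, "right"
            else:
                gap, side = 0, "overlap"
            if gap > window:
                continue
            if side == "overlap":
                cat = "sense_overlap" if g.strand == t.strand else "antisense"
            else:
                cat = ("upstream"
                       if (side == "left") == (g.strand == "+") else "downstream")
            pairs.add((t.transcript_id, g.gene_id, cat, gap))
    return pairs


class TestCisRecovery:
    def test_planted_cis_set_recovered_exactly(self, universe, assembly_by_id):
        retained, _ = run_cascade(universe.assembly, universe.matrix,
                                  universe.sequences)
        pairs = predict_cis([assembly_by_id[t] for t in retained],
                            universe.annotation)
        got = {(p.lnc_id, p.gene_id, p.cis_category) for p in pairs}
        assert got == universe.truth.cis_truth

    def test_matches_all_pairs_brute_force(self, universe, assembly_by_id):
        lncs = [assembly_by_id[t] for t, f in universe.truth.filter_fate.items()
                if f == "retained"]
        pairs = predict_cis(lncs, universe.annotation)
        got = {(p.lnc_id, p.gene_id, p.cis_category, p.distance_bp) for p in pairs}
        assert got == _brute_force_cis(lncs, universe.annotation)

    def test_category_counts_sum_to_total(self, universe, assembly_by_id):
        lncs = [assembly_by_id[t] for t in universe.truth.lnc_class]
        totals = cis_totals(predict_cis(lncs, universe.annotation))
        assert totals["total"] == sum(
            totals[c] for c in ("upstream", "downstream", "antisense", "sense_overlap")
        )


class TestPearson:
    def test_perfect_positive(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # deviations (-1.5,-.5,.5,1.5) vs (-1.5,.5,-.5,1.5): r = 4/5
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(100):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            xd, yd = x - x.mean(), y - y.mean()
            expected = (xd @ yd) / np.sqrt((xd @ xd) * (yd @ yd))
            assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_scale_and_translation_invariance(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r = pearson(x, y)
        assert pearson(3 * x + 7, 0.5 * y - 2) == pytest.approx(r, abs=1e-12)
        assert pearson(y, x) == pytest.approx(r, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])


class TestPredictTrans:
    def _frames(self, lnc_cols, gene_cols, n=12, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        return (pd.DataFrame(lnc_cols, index=idx),
                pd.DataFrame(gene_cols, index=idx), rng)

    def test_exact_threshold_is_excluded(self):
        # r(x, y) is exactly 0.95 by construction: y = 0.95*x + sqrt(1-0.95^2)*z
        # with z orthogonal to x and both standardized
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        z = rng.normal(size=12)
        x = (x - x.mean()) / x.std()
        z = z - z.mean() - ((z - z.mean()) @ x) / (x @ x) * x
        z = z / z.std()
        y = 0.95 * x + np.sqrt(1 - 0.95**2) * z
        assert pearson(x, y) == pytest.approx(0.95, abs=1e-12)
        lnc, gene, _ = self._frames({"L1": x}, {"G1": y})
        assert predict_trans(lnc, gene) == []

    def test_just_above_threshold_is_emitted(self):
        x = np.arange(12, dtype=float)
        lnc, gene, _ = self._frames({"L1": x}, {"G1": x, "G2": -x})
        pairs = predict_trans(lnc, gene)
        assert {(p.gene_id, p.sign) for p in pairs} == {
            ("G1", "positive"), ("G2", "negative")
        }

    def test_sample_mismatch_rejected(self):
        lnc = pd.DataFrame({"L1": [1.0, 2, 3]}, index=["a", "b", "c"])
        gene = pd.DataFrame({"G1": [1.0, 2, 3]}, index=["a", "b", "d"])
        with pytest.raises(ValidationError):
            predict_trans(lnc, gene)

    def test_constant_profile_skipped_not_raised(self, rng):
        x = rng.normal(size=12)
        lnc = pd.DataFrame({"L1": x}, index=[f"s{i}" for i in range(12)])
        gene = pd.DataFrame({"G1": np.ones(12), "G2": x},
                            index=[f"s{i}" for i in range(12)])
        pairs = predict_trans(lnc, gene)
        assert [(p.gene_id,) for p in pairs] == [("G2",)]

    def test_planted_recall_and_r_values_match_brute_force(self, universe):
        """Recall >= 0.95 on planted pairs; every emitted r recomputed to 1e-12."""
        retained = [t for t, f in universe.truth.filter_fate.items()
                    if f == "retained"]
        lnc = np.log2(universe.matrix.values[retained])
        gene = np.log2(universe.matrix.values[
            [t.transcript_id for t in universe.reference_transcripts]])
        gene.columns = [c[:-3] for c in gene.columns]
        pairs = predict_trans(lnc, gene)
        got = {(p.lnc_id, p.gene_id, p.sign) for p in pairs}
        truth = universe.truth.trans_truth
        assert len(got & truth) / len(truth) >= 0.95
        for p in pairs:
            assert p.r == pytest.approx(
                pearson(lnc[p.lnc_id], gene[p.gene_id]), abs=1e-12
            )
        totals = trans_totals(pairs)
        assert totals["total"] == totals["positive"] + totals["negative"]


class TestTotalsFromPrintedCounts:
    def test_cis_category_sum(self):
        totals = cis_totals({"upstream": 25_846, "downstream": 27_008,
                             "antisense": 14_375, "sense_overlap": 3})
        assert totals["total"] == 67_232

    def test_trans_sign_split(self):
        totals = trans_totals({"positive": 225_537, "negative": 823_038})
        assert totals["total"] == 1_048_575
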