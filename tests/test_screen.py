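"""Screening cascade: threshold boundaries, ORF scan oracle, planted fates."""

import numpy as np
import pandas as pd
import pytest

from lncpipe import (
    ExpressionMatrix,
    ScreenConfig,
    TranscriptModel,
    filter_coding_potential,
    filter_exon_count,
    filter_expression,
    filter_length,
    filter_novelty,
    run_cascade,
    scan_orfs,
)
from lncpipe.errors import ConfigError, LookupError_
from lncpipe.screen import OrfStats, removal_counts


def _tx(exons, code="u", tid="T1"):
    return TranscriptModel(tid, tid, "chr1", "+", tuple(exons), code, "assembly")


def _matrix(values_by_tid):
    df = pd.DataFrame(values_by_tid, index=["S1_1", "S1_2", "S2_1", "S2_2"])
    return ExpressionMatrix(df)


class TestExonAndLengthFilters:
    @pytest.mark.parametrize(
        "n_exons,expected", [(1, False), (2, True), (7, True)]
    )
    def test_exon_count_boundary_inclusive_at_two(self, n_exons, expected):
        exons = [(i * 200, i * 200 + 100) for i in range(n_exons)]
        ok, value = filter_exon_count(_tx(exons))
        assert ok is expected and value == n_exons

    @pytest.mark.parametrize(
        "exons,expected_len,passes",
        [
            ([(0, 100), (200, 300)], 200, False),  # exactly 200 fails (strict >)
            ([(0, 100), (200, 301)], 201, True),
            ([(0, 150), (300, 400)], 250, True),
        ],
    )
    def test_length_strictly_greater_than_200(self, exons, expected_len, passes):
        ok, value = filter_length(_tx(exons))
        assert value == expected_len and ok is passes


class TestNoveltyFilter:
    @pytest.mark.parametrize("code,passes", [("=", False), ("u", True),
                                             ("i", True), ("x", True), ("o", True),
                                             ("j", False)])
    def test_default_known_codes(self, code, passes):
        ok, _ = filter_novelty(_tx([(0, 100)], code=code))
        assert ok is passes

    def test_known_codes_override(self):
        ok, _ = filter_novelty(_tx([(0, 100)], code="x"), known_codes={"=", "x"})
        assert ok is False

    def test_missing_class_code_fails_with_flag(self):
        ok, value = filter_novelty(_tx([(0, 100)], code=None))
        assert ok is False and value == "missing"


class TestExpressionFilter:
    def test_half_fpkm_in_one_sample_passes(self):
        m = _matrix({"T1": [0.5, 0.0, 0.0, 0.0]})
        ok, _ = filter_expression(_tx([(0, 300)]), m)
        assert ok

    def test_below_half_everywhere_fails(self):
        m = _matrix({"T1": [0.49, 0.49, 0.49, 0.49]})
        ok, value = filter_expression(_tx([(0, 300)]), m)
        assert not ok and value == 0.49

    def test_min_samples_quantifier(self):
        m = _matrix({"T1": [0.6, 0.6, 0.0, 0.0]})
        ok, _ = filter_expression(_tx([(0, 300)]), m, min_samples=3)
        assert not ok

    def test_absent_transcript_raises(self):
        m = _matrix({"T1": [1, 1, 1, 1]})
        with pytest.raises(LookupError_):
            filter_expression(_tx([(0, 300)], tid="T2"), m)


def _brute_force_orfs(seq):
    """Every in-frame ATG..first-stop span, by direct enumeration."""
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    spans = []
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for j in range(start, len(seq) - 2, 3):
            if seq[j : j + 3] in stops:
                if "N" not in seq[start : j + 3]:
                    spans.append((start, j + 3))
                break
    return spans


class TestScanOrfs:
    @pytest.mark.parametrize(
        "seq,longest",
        [
            ("ATGAAATAA", 9),
            ("CCCATGTAACCC", 6),
            ("", 0),
            ("ATGAAAAAA", 0),  # no stop, no ORF
            ("ATGNNNTAA", 0),  # N-containing span skipped
        ],
    )
    def test_known_sequences(self, seq, longest):
        assert scan_orfs(seq)[0] == longest

    def test_matches_exhaustive_enumeration_on_random_sequences(self, rng):
        for _ in range(200):
            n = int(rng.integers(50, 2001))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            spans = _brute_force_orfs(seq)
            longest, count, frame = scan_orfs(seq)
            assert longest == max((e - s for s, e in spans), default=0)
            assert count == len(spans)
            if spans:
                best_frames = {s % 3 for s, e in spans if e - s == longest}
                assert frame in best_frames

    def test_longest_orf_divisible_by_three(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            assert scan_orfs(seq)[0] % 3 == 0


class TestCodingFilter:
    def test_boundary_below_default_passes(self):
        orf = OrfStats("T1", 299, 1, 0)
        ok, _ = filter_coding_potential(_tx([(0, 400)]), orf)
        assert ok

    def test_boundary_at_default_fails(self):
        orf = OrfStats("T1", 300, 1, 0)
        ok, _ = filter_coding_potential(_tx([(0, 400)]), orf)
        assert not ok

    def test_external_coding_call_vetoes_short_orf(self):
        orf = OrfStats("T1", 120, 1, 0)
        ok, value = filter_coding_potential(
            _tx([(0, 400)]), orf, external_scores={"T1": {"CPC": "coding"}}
        )
        assert not ok and "coding" in str(value)

    def test_unknown_tool_tag_rejected(self):
        orf = OrfStats("T1", 120, 1, 0)
        with pytest.raises(ConfigError):
            filter_coding_potential(
                _tx([(0, 400)]), orf, external_scores={"T1": {"mystery": "coding"}}
            )

    def test_unanimous_noncoding_passes(self):
        orf = OrfStats("T1", 120, 1, 0)
        ok, _ = filter_coding_potential(
            _tx([(0, 400)]), orf,
            external_scores={"T1": {"CPC": "noncoding", "PFAM": "noncoding"}},
        )
        assert ok


class TestCascade:
    def test_planted_universe_retains_exactly_the_planted_lncrnas(self, universe):
        retained, traces = run_cascade(
            universe.assembly, universe.matrix, universe.sequences
        )
        expected = {t for t, f in universe.truth.filter_fate.items() if f == "retained"}
        assert set(retained) == expected
        counts = removal_counts(traces)
        assert sum(counts.values()) == len(universe.assembly) - len(expected)

    def test_empty_input_gives_empty_output(self, universe):
        retained, traces = run_cascade([], universe.matrix, universe.sequences)
        assert retained == [] and traces == {}

    def test_relaxed_thresholds_retain_everything(self, universe):
        cfg = ScreenConfig(
            min_exons=1, min_length=0, min_fpkm=0.0,
            novelty_enabled=False, coding_enabled=False,
        )
        retained, _ = run_cascade(
            universe.assembly, universe.matrix, universe.sequences, cfg
        )
        assert set(retained) == {t.transcript_id for t in universe.assembly}

    def test_trace_stops_at_first_failure(self, universe):
        _, traces = run_cascade(universe.assembly, universe.matrix, universe.sequences)
        for trace in traces.values():
            fails = [i for i, (_, ok, _) in enumerate(trace.step_results) if not ok]
            if fails:
                assert fails == [len(trace.step_results) - 1]
                assert not trace.retained
            else:
                assert trace.retained

    def test_monotone_in_fpkm_threshold(self, universe):
        previous = None
        for min_fpkm in (0.0, 0.5, 2.0, 10.0):
            retained, _ = run_cascade(
                universe.assembly, universe.matrix, universe.sequences,
                ScreenConfig(min_fpkm=min_fpkm),
            )
            if previous is not None:
                assert set(retained) <= previous
            previous = set(retained)

    def test_retained_set_is_order_independent(self, universe):
        fwd, _ = run_cascade(universe.assembly, universe.matrix, universe.sequences)
        rev, _ = run_cascade(
            list(reversed(universe.assembly)), universe.matrix, universe.sequences
        )
        assert set(fwd) == set(rev)
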