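"""Five-step lncRNA screening cascade with per-transcript provenance.

The cascade applies, in order: exon count >= 2, spliced length > 200 bp,
novelty of the assembly class code, FPKM >= 0.5 in at least one sample, and
coding potential. Coding potential is judged by an internal longest-ORF rule
(non-coding iff longest sense-strand ORF < 300 nt, i.e. < 100 aa) which can
be vetoed by externally supplied per-tool "coding" calls: a transcript is
kept only if every configured tool agrees it is non-coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import TranscriptModel
from .errors import ConfigError, LookupError_
from .expression import ExpressionMatrix

__all__ = [
    "FilterTrace",
    "OrfStats",
    "ScreenConfig",
    "filter_exon_count",
    "filter_length",
    "filter_novelty",
    "filter_expression",
    "scan_orfs",
    "filter_coding_potential",
    "run_cascade",
    "NOVEL_CLASS_CODES",
    "STEP_NAMES",
]

#: class codes treated as novel (kept) by the default novelty filter:
#: intergenic, intronic, exonic-antisense, sense-overlap
NOVEL_CLASS_CODES = frozenset({"u", "i", "x", "o"})

STEP_NAMES = ("exon_count", "length", "novelty", "expression", "coding_potential")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class FilterTrace:
    """Ordered step results for one transcript.

    ``step_results`` holds ``(step_name, passed, value)`` in cascade order;
    a transcript failing step *k* carries no results for later steps.
    """

    transcript_id: str
    step_results: list[tuple[str, bool, object]] = field(default_factory=list)
    retained: bool = False

    @property
    def first_failure(self) -> str | None:
        for name, ok, _ in self.step_results:
            if not ok:
                return name
        return None


@dataclass(frozen=True)
class OrfStats:
    transcript_id: str
    longest_orf_nt: int
    orf_count: int
    frame: int
    strand_scanned: str = "sense-only"


def filter_exon_count(t: TranscriptModel, min_exons: int = 2) -> tuple[bool, int]:
    """Step 1: keep multi-exon transcripts (exon count >= 2, inclusive)."""
    n = t.exon_count
    return n >= min_exons, n


def filter_length(t: TranscriptModel, min_length: int = 200) -> tuple[bool, int]:
    """Step 2: keep transcripts with spliced length strictly > 200 bp."""
    length = t.spliced_length
    return length > min_length, length


def filter_novelty(
    t: TranscriptModel, known_codes: frozenset | set | None = None
) -> tuple[bool, str]:
    """Step 3: drop transcripts matching known annotation.

    ``known_codes`` is the set of class codes counted as known; the default
    is every code except the novel set {u, i, x, o}. A missing class code
    fails with the distinct value ``"missing"``.
    """
    code = t.class_code
    if code is None:
        return False, "missing"
    if known_codes is None:
        return code in NOVEL_CLASS_CODES, code
    return code not in known_codes, code


def filter_expression(
    t: TranscriptModel,
    m: ExpressionMatrix,
    min_fpkm: float = 0.5,
    min_samples: int = 1,
) -> tuple[bool, float]:
    """Step 4: keep transcripts with FPKM >= 0.5 (inclusive) in enough samples.

    The paper-style threshold is inclusive at 0.5; the sample quantifier
    defaults to "at least one sample".
    """
    vals = m.transcript_values(t.transcript_id)
    n_over = int((vals >= min_fpkm).sum())
    return n_over >= min_samples, float(vals.max())


def scan_orfs(seq: str) -> OrfStats | tuple[int, int, int]:
    """Find ORFs on the three sense frames of a spliced transcript sequence.

    An ORF is an in-frame ATG ... first downstream stop (TAA/TAG/TGA), length
    in nt including the stop codon. Spans containing N are skipped. Returns
    ``(longest_orf_nt, orf_count, frame_of_longest)``.
    """
    seq = seq.upper()
    longest = 0
    count = 0
    best_frame = 0
    n = len(seq)
    for frame in range(3):
        open_starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                open_starts.append(i)
            elif codon in _STOPS:
                for s in open_starts:
                    if "N" in seq[s : i + 3]:
                        continue
                    count += 1
                    length = i + 3 - s
                    if length > longest:
                        longest = length
                        best_frame = frame
                open_starts = []
    return longest, count, best_frame


def orf_stats(transcript_id: str, seq: str) -> OrfStats:
    longest, count, frame = scan_orfs(seq)
    return OrfStats(transcript_id, longest, count, frame)


def filter_coding_potential(
    t: TranscriptModel,
    orf: OrfStats,
    external_scores: dict[str, dict[str, str]] | None = None,
    max_orf_nt: int = 300,
    allowed_tools: tuple[str, ...] = ("CPC", "PFAM"),
) -> tuple[bool, object]:
    """Step 5: declare non-coding by short ORF, vetoed by external tools.

    ``external_scores`` maps transcript_id -> {tool: call}; any tool calling
    the transcript "coding" fails it (non-coding must be unanimous). Without
    a veto, pass iff longest ORF < ``max_orf_nt`` (strict).
    """
    if external_scores is not None:
        calls = external_scores.get(t.transcript_id, {})
        allowed = {a.upper() for a in allowed_tools}
        for tool, call in calls.items():
            if tool.upper() not in allowed:
                raise ConfigError(f"unknown coding-potential tool tag {tool!r}")
            if str(call).lower() == "coding":
                return False, f"{tool}:coding"
    return orf.longest_orf_nt < max_orf_nt, orf.longest_orf_nt


@dataclass
class ScreenConfig:
    """Thresholds and switches for the screening cascade."""

    min_exons: int = 2
    min_length: int = 200
    known_codes: frozenset | None = None  # None -> all codes except {u,i,x,o}
    min_fpkm: float = 0.5
    min_samples: int = 1
    max_orf_nt: int = 300
    external_scores: dict | None = None
    novelty_enabled: bool = True
    coding_enabled: bool = True


def run_cascade(
    transcripts,
    matrix: ExpressionMatrix,
    sequences: dict[str, str],
    config: ScreenConfig | None = None,
) -> tuple[list[str], dict[str, FilterTrace]]:
    """Apply the five screening steps in order with short-circuit provenance.

    Returns the retained transcript ids (input order) and a FilterTrace per
    transcript. A transcript's trace stops at its first failing step.
    """
    cfg = config or ScreenConfig()
    retained: list[str] = []
    traces: dict[str, FilterTrace] = {}
    for t in transcripts:
        trace = FilterTrace(t.transcript_id)
        steps = [
            ("exon_count", lambda: filter_exon_count(t, cfg.min_exons)),
            ("length", lambda: filter_length(t, cfg.min_length)),
        ]
        if cfg.novelty_enabled:
            steps.append(("novelty", lambda: filter_novelty(t, cfg.known_codes)))
        steps.append(
            ("expression", lambda: filter_expression(t, matrix, cfg.min_fpkm, cfg.min_samples))
        )
        if cfg.coding_enabled:
            def _coding(t=t):
                seq = sequences.get(t.transcript_id)
                if seq is None:
                    raise LookupError_(
                        f"no sequence for transcript {t.transcript_id!r}"
                    )
                return filter_coding_potential(
                    t, orf_stats(t.transcript_id, seq), cfg.external_scores, cfg.max_orf_nt
                )

            steps.append(("coding_potential", _coding))

        ok = True
        for name, fn in steps:
            passed, value = fn()
            trace.step_results.append((name, passed, value))
            if not passed:
                ok = False
                break
        trace.retained = ok
        traces[t.transcript_id] = trace
        if ok:
            retained.append(t.transcript_id)
    return retained, traces


def removal_counts(traces: dict[str, FilterTrace]) -> dict[str, int]:
    """Number of transcripts removed at each step (first failure)."""
    counts = {name: 0 for name in STEP_NAMES}
    for tr in traces.values():
        f = tr.first_failure
        if f is not None:
            counts[f] += 1
    return counts
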