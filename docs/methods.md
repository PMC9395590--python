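# Methods

## Coordinate model

All internal coordinates are 0-based half-open; GTF/GFF3 I/O converts from
the files' 1-based closed convention exactly once at the boundary, so
overlap and distance arithmetic never carries ±1 corrections. Assembly
class codes follow the Cuffmerge/StringTie convention ("u" intergenic, "i"
intronic, "x" exonic-antisense, "o" sense-overlap, "=" known match);
unknown codes are preserved and treated as "known" by the novelty filter.
Chromosome names are taken verbatim, with no alias resolution.

## Screening cascade

Five predicates applied in a fixed order, each with its threshold exposed:

| step | rule | default | boundary |
|---|---|---|---|
| exon count | ≥ `min_exons` exons | 2 | 2 kept |
| length | spliced length > `min_length` bp | 200 | 200 removed |
| novelty | class code not "known" | known = all except {u,i,x,o} | missing code fails |
| expression | FPKM ≥ `min_fpkm` in ≥ `min_samples` samples | 0.5 in ≥ 1 | 0.5 kept |
| coding potential | longest ORF < `max_orf_nt`, no external veto | 300 nt | 300 removed |

Design choices that were genuinely open:

- The expression rule's sample quantifier is unstated in the field's usual
  phrasing ("FPKM ≥ 0.5"); we read it as *at least one sample* and expose
  `min_samples`.
- Coding potential uses a longest-ORF stand-in (< 300 nt ≈ 100 aa, the
  conventional lncRNA cutoff) rather than running CPC/Pfam binaries;
  external per-tool calls can be supplied as a TSV and any "coding" call
  vetoes retention (non-coding must be unanimous).
- ORFs are scanned on the three sense frames only (transcripts are
  stranded); an ORF is an in-frame ATG to its first downstream stop,
  length counted in nt *including* the stop codon; spans containing N are
  skipped; an ORF with no stop before the 3' end is not counted.

The retained *set* is order-independent (the steps are independent
predicates); only the provenance trace — which stops at the first failing
step — depends on order. Raising any threshold can only shrink the
retained set.

## Positional classification

Precedence: same-strand exonic overlap (≥ 1 bp between any lncRNA exon and
any reference exon) → `sense_overlap`; opposite-strand exonic overlap →
`antisense`; full containment in an intron with no exonic overlap →
`intronic`; otherwise `lincRNA`. Exonic evidence outranks intron
containment because base-level overlap is the stronger signal. Intron
containment admits either strand by default (`sense_intronic_only`
restricts it). Host ties break by largest aggregated exonic overlap, then
lexicographic gene id; for intronic hosts, by smallest containing intron.
Interval-tree indexes are a speed device only — tests require identity
with a per-base linear-scan oracle.

Class percentages are rounded half-up to one decimal; the denominator
defaults to the sum of the supplied counts but can be given explicitly
(a retained total can exceed the sum of the classified classes).

## Differential expression

No specific DE engine is claimed; the caller is a documented three-knob
stand-in chosen for testability on planted truth: Welch's t-test on
log2(FPKM + pseudocount) replicate values (pseudocount 0.1 guards log of
zero), BH adjustment *within* each comparison, and a fold-change gate.
log2FC is computed on stage-mean FPKM plus pseudocount, B relative to A. A
transcript is `up` iff log2FC ≥ +1 and q < 0.05 (`down` symmetric), so
up + down = DE total by construction. Zero-variance degenerate cases
resolve exactly (p = 1 if the group means agree, else 0). Venn regions are
computed by exact membership masks, never by inclusion–exclusion
approximations.

## Target prediction

*cis*: a pair is emitted for every gene whose span gap to the lncRNA span
is ≤ 10 kb (inclusive), not just the nearest. Distance is measured between
nearest span boundaries (not TSS-to-TSS). Non-overlapping pairs are
`upstream`/`downstream` relative to the **gene's** strand (a lncRNA on the
gene's 5′ side is upstream); span-overlapping pairs are `antisense` or
`sense_overlap` by relative strand with distance 0.

*trans*: all lncRNA × gene pairs with |Pearson r| strictly > 0.95,
computed across every sample (stage × replicate), not stage means
(replicate-level is the default; callers can pass stage means). The
package convention is to correlate log2 expression — on the linear FPKM
scale a perfectly mirrored log-profile cannot reach r = −1 (the
exponential transform breaks the symmetry), so log scale is the one on
which a correlation target is meaningful for both signs. Constant profiles
are skipped with a logged reason rather than failing the batch.

## Networks and enrichment

Networks are bipartite multigraphs (a lncRNA–gene pair may carry one cis
and one trans edge; duplicates on the same (lnc, gene, mode, category) are
dropped), restricted to DE lncRNAs and optionally to DE genes, with a
proximity re-filter for cis edges. Protein-interaction expansion is a
user-supplied interaction TSV merged as extra edges — no live database
queries. Exports (SIF, GraphML, edge-TSV with node sidecar) round-trip to
the identical edge set.

Enrichment is the plain upper-tail hypergeometric P[X ≥ k] with BH across
terms — not a length-bias (Wallenius) model, which would need a bias
estimate no desk-scale input provides. Term maps are two-column TSVs; the
universe is an explicit required argument because the natural choice (all
expressed vs all annotated genes) is study-specific.

## Assays

Anthocyanin content Q = (A530 − 0.25·A657)/M per gram fresh weight, per
the formula's symbols (A657 is the absorbance at 657 nm). Negative Q is
returned with a warning. 2^−ΔΔCt: ΔCt = Ct_target − Ct_reference per
sample, ΔΔCt anchored to a calibrator sample or stage (per-gene mean over
matching records; with a single calibrator record the calibrator's own
fold change is exactly 1). Replicate aggregation is mean ± SE; no
primer-efficiency correction.

## Synthetic universe

The generator emulates a four-stage (S1–S4), three-replicate staged fruit
transcriptome at desk scale. Defaults: 2 chromosomes × 600 kb, 24 genes
(three exons, 4.2 kb span) tiled one per 30 kb slot so every 10-kb window
is unambiguous; 20 planted lncRNAs (6 lincRNA, 4 antisense, 8 intronic, 2
sense-overlap — intronic-heavy, as reported for plant fruit
transcriptomes) and one decoy per screening filter, each violating exactly
its designated rule. Near lincRNAs exercise both flanks and the exact
10-kb boundary; far lincRNAs sit > 10 kb from every gene.

Expression is simulated directly on the FPKM scale (the decision surface
of every threshold) as 2^(baseline + stage effect + N(0, noise_sd)), with
baselines log2-uniform in [3, 7]. DE effects are single-stage shifts of
|log2FC| ~ U(2, 4); the recorded DE truth is derived from the realized
noise-free stage-mean profiles with the caller's default gate, so
latent-profile transcripts that genuinely cross the gate are labelled
truthfully. Planted trans pairs share a latent stage profile — a
standardized ramp in random stage order with amplitude
`noise_sd · sqrt(r/(1−r))`, so the expected log-scale Pearson correlation
equals `planted_trans_r` (default 0.99 at noise_sd 0.05). A fixed-spread
ramp (rather than i.i.d. stage draws) pins the latent variance, making the
planted correlation controlled by noise rather than by latent sampling
luck; in the noise-free limit the amplitude floor is 0.5 and |r| = 1
exactly. Low-expression decoys are drawn U(0.05, 0.45), always below the
0.5 FPKM threshold. lncRNA and decoy sequences are random nucleotides with
every ORF ≥ 300 nt broken by an in-frame stop (except the coding decoy,
which embeds a 600-nt ORF behind an ATG-free prefix). One integer seed
drives all randomness; identical configs give byte-identical output files.

What the generator does **not** emulate: read-level sampling noise
(FPKM is drawn, not derived from counts), length- or GC-dependent
quantification bias, isoform ambiguity (one transcript per gene),
overdispersion beyond log-normal noise, and correlated replicate effects.
Passing the planted-recovery suites therefore demonstrates the *decision
logic* (thresholds, geometry, set algebra, correlation gating) is correct,
not that the pipeline's statistical power matches any real study.

## Problem sizes and tolerances

The test suite and the acceptance script run the default universe (25
assembly transcripts, 24 genes, 12 samples), a 200-random-sequence ORF
oracle sweep (lengths 50–2,000), a 500-transcript classification oracle
sweep, 6 × 1,000-id Venn bitmask enumeration, and a 20-seed Monte-Carlo of
planted trans correlations — a few seconds in total. Arithmetic oracles
(Pearson, hypergeometric, 2^−ΔΔCt) are checked to 1e−12; planted DE
recovery uses sensitivity ≥ 0.9 and false-call rate ≤ 0.1 at noise_sd 0.1;
trans recall ≥ 0.95 at the default planted correlation.

## Known limitations

- The DE caller is a stand-in, not a clone of any assembler-specific
  quantification tool; real studies with raw counts should prefer a
  negative-binomial method and feed the resulting DE sets into the
  downstream steps.
- Cis distance is span-gap based; TSS-anchored definitions would shift
  distances for long genes.
- The novelty filter trusts the assembler's class codes; it performs no
  coordinate-level comparison with the reference.
- The hypergeometric enrichment ignores transcript-length selection bias.
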