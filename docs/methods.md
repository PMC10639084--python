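# Methods

## Problem setting

tRNAs are short (~72–95 nt), heavily modified RNAs. Direct RNA nanopore
sequencing reads them natively, but bulky modifications such as queuosine
(Q, a 7-deazaguanosine at the wobble position 34 of GUN-anticodon tRNAs)
perturb the ionic current and hence the basecaller's output: mismatches
(mostly miscalled as C), deletions, insertions, and a trail of errors on
the 5′ side of the modified base (sequencing proceeds 3′→5′, so the
neighbouring bases sense the modified base entering and leaving the pore).
`qtrna` detects such modifications by comparing per-position basecalling
error profiles between two conditions — one carrying the modification, one
not — rather than by interpreting the raw signal.

## Reference curation and coordinates

References are mature tRNA body sequences, deduplicated on identical bodies
(keeping the lexicographically smallest name), converted U→T to match
basecaller output, and flanked by the splint-adapter sequences ligated
during library preparation. Adapters are required user input (their design
is library-specific); empty adapters give a degenerate, unflanked
reference.

Coordinates are linear: body position *i* (0-based) maps to canonical
position `i − anticodon_start + 34`, anchoring the first anticodon base at
34. True Sprinzl numbering (with gaps and insertions) is deliberately not
modelled: anticodon-anchored display is what the comparative analysis
needs, and linear numbering is unambiguous and testable. Misplacing the
anchor would corrupt every downstream call, so anticodon resolution is
strict: an explicit 0-based `anticodon_start` takes precedence; otherwise
the annotated triplet must match exactly once within body indices 25–45;
anything else is an error. Internally all coordinates are 0-based
half-open (SAM convention); canonical labels appear only in outputs.

## Alignment and decoy significance

Reads are aligned to every reference with an exact affine-gap
Smith–Waterman (no seed-and-extend heuristics — tRNAs carry ~13
modifications on average, and the resulting mismatch load defeats
heuristic aligners). A gap of length L costs |open| + (L−1)·|extend|.
Default scores are match +2, mismatch −4, gap open −4, gap extend −2 —
conventional short-read-style values, fully overridable; all tests state
the scheme they use. Reads are assumed sense-stranded (direct RNA
sequencing is strand-specific), so no reverse-complement search is done.

Alignments of one read are ranked by score; equal scores share a rank and
all rank-1 hits are retained. Reads whose rank-1 hits land on more than
one reference are dropped by default (`keep_multimapped` retains them).

Significance is empirical: each read is also aligned *reversed* (not
complemented), which preserves length and nucleotide composition — the
determinants of a random local-alignment score — and the decoy score
distribution defines the smallest integer cutoff with at least the
requested fraction (default 0.95) of decoys strictly below it. The cutoff
is recomputed per input dataset. The kernel (numba-compiled) is verified
exactly against an independently written brute-force dynamic program.

Tie-breaking is deterministic so outputs are bit-reproducible: the best
cell is chosen as (maximal score, smallest reference end, smallest read
end) and traceback prefers match/mismatch over reference-gap over
read-gap, extension over re-opening. Scores are unaffected by this choice.

## Pileup conventions

Per reference position: coverage (reads whose alignment spans the
position, including deleted bases), base counts, deletion count, and
insertion count. Conventions that SAM leaves ambiguous are fixed as
follows: an insertion between reference indices i and i+1 is attributed to
index i (the 5′ flanking base) and counts once per read per junction
regardless of length; soft-clipped bases are ignored. The attribution is
applied identically in both conditions, so the comparative score is
insensitive to the choice. Rates follow
`mismatch = (cov − count[ref_base] − del)/cov`, `deletion = del/cov`,
`insertion = ins/cov`; positions with coverage below `min_cov` (default 10
per replicate — below that the comparative score is noise-dominated) are
reported missing.

## Comparative scoring (Mis + Del + Ins)

Each position is compared between conditions on three channels:

* **base channel** — 5-category counts (A, C, G, T, deletion) per replicate;
* **deletion channel** — (deleted, not deleted);
* **insertion channel** — (insertion, no insertion).

A channel is scored with a Dirichlet-multinomial likelihood ratio

    score = 2 [ ℓ(A; θ̂_A) + ℓ(B; θ̂_B) − ℓ(A∪B; θ̂_pooled) ],

where ℓ sums the Dirichlet-multinomial log-likelihood over replicate count
vectors (a pseudocount of 0.5 is added to every cell) and θ̂ are fitted
concentrations. Summing the likelihood over replicates — instead of
pooling counts — lets between-replicate variability temper the score.
The per-position total of the three channels is the Mis + Del + Ins score.
Scores are comparative; no p-values or multiple-testing correction are
attached, matching how such score tracks are read in practice.

Fitting: a method-of-moments estimate (mean replicate proportions scaled
by a common precision solved from the between-replicate overdispersion,
using population variance so that duplicating the replicate set leaves the
estimate unchanged) initializes the standard monotone fixed-point
iteration to the maximum-likelihood concentrations. The refinement was
adopted because the pure moment fit can sit far below the likelihood
optimum on strongly bimodal pooled data, which breaks the intended
cross-check against a generic numerical optimizer; the refined fit agrees
with that oracle to within a few percent while remaining deterministic.
The precision is clamped to [10⁻², 10⁶]; a single replicate, or identical
replicates, carry no overdispersion information and sit at the upper
clamp with proportions equal to the smoothed pooled frequencies. Negative
ratios (possible only through clamping or capped iteration) are clamped
to zero, the pooled fit canonicalizes replicate order so the score is
exactly symmetric in its arguments, and identical replicate sets score
exactly zero.

## Candidate calling and signature classification

Positions with total score at or above a threshold are merged into
contiguous regions; each region reports its extent, its peak (maximum
score, smallest position on ties) and whether it contains position 34. The
modified base need not be the peak — for preQ0 the neighbouring position
35 carries the larger error change — hence regions, not point calls. The
default threshold is empirical, Q3 + 3·IQR of the non-missing total scores
of that tRNA; a fixed numeric threshold can be supplied instead. Adapter
positions are tabulated but excluded from calling.

The empirical rule sits near the 99.8th percentile of the score's
chi-square-like null, so on a null comparison with many positions an
isolated single-position false region is statistically expected every few
tracks; the rule is an outlier heuristic, not a calibrated error-rate
control.

The wobble signature is classified from per-channel rate differentials
(modified minus unmodified, maximized over canonical 33–35):

| call | rule |
|---|---|
| Q_like | Δmis ≥ t_mis and Δdel ≥ t_del |
| preQ1_like | Δmis ≥ t_mis and Δdel < t_del |
| preQ0_like | Δins ≥ t_ins and Δmis < t_mis |
| unmodified | all three below their thresholds |
| ambiguous | otherwise, or insufficient coverage |

Defaults t_mis = 0.15, t_del = 0.10, t_ins = 0.10 were calibrated on the
simulator's preset effect sizes: the biology supplies ordering relations
(deletion gain separates Q from preQ1; insertion gain marks preQ0), not
universal cutoffs, so all three are configuration. The classifier reports
evidence; it does not adjudicate biology in borderline cases.

## Read simulator

The simulator emulates basecalled reads, not ionic current. It walks the
adapter-flanked reference 5′→3′, drawing per-base deletion and mismatch
events and per-junction insertions independently, then truncates the 5′
end of a fraction of reads (incomplete 3′→5′ sequencing loses 5′ bases).
Baseline defaults — 3% mismatch, 2% deletion, 1% insertion, 10% truncated
reads with geometric (mean 5) truncation length — are nanopore-plausible
round numbers and fully configurable. Quality strings are constant
placeholders; downstream analysis ignores them.

Signature presets override the baseline at canonical offsets from the
anchor (default 34):

* **Q** — offsets −1…+1: mismatch 0.45 with 0.8 of substitutions biased to
  C, deletion 0.30; trail offsets −6…−2: mismatch +0.10;
* **preQ1** — as Q but deletion 0.10;
* **preQ0** — insertion 0.25 at offsets 0 and +1 only;
* **null** — no overrides.

These encode the qualitative contrasts observed for the three
7-deazaguanine derivatives at desk-detectable effect sizes. The simulator
does not model homopolymer context, signal-level artifacts, quality
scores, or correlated errors, so passing tests demonstrate pipeline
correctness under this error model — not performance on real flow-cell
data. Replicate seeds derive deterministically from one master seed; the
FASTQ byte stream is identical across runs.

A synthetic reference factory provides tRNA-like references (random
72-nt bodies, anticodon at body index 33, the four Q-family anticodons
GUC/GUU/GUG/GUA on the first four references, fixed synthetic 24-nt
adapter stand-ins). These are synthetic constructs, not curated genomic
sequences.

## Problem sizes and numerical choices

Simulation-based checks use 300 reads per reference per replicate, 3
replicates per condition, and 1–10 seeds per scenario (1,000 reads across
10 references for the decoy-specificity check) — sizes at which every
effect the presets encode is detectable while a full test run stays in the
minutes range. Alignment scores are integers; score ties and traceback are
resolved deterministically; the acceptance script seeds every random
stream from its `--seed` argument.

## Known limitations

* Linear (non-Sprinzl) coordinates; no CCA-tail verification or
  mitochondrial tRNA handling.
* The comparative score is not calibrated as a test statistic; thresholds
  are heuristic and the empirical region threshold admits occasional
  single-position false regions on null data (see above).
* Realized post-alignment error rates are sequence-context dependent: a
  C-biased miscall adjacent to a reference C is often realigned as a
  deletion, so the same simulated error probabilities yield different
  observed mismatch/deletion splits on different templates (real templates
  show the same effect). The classifier thresholds are calibrated against
  the package's fixed synthetic reference set; on other templates the
  Q/preQ1 deletion differential can shift across t_del.
* Only the 7-deazaguanine signature family is classified; other
  modifications (m⁵C, Ψ, D, …) appear in score tracks but are not named.
* Partial modification stoichiometry is not quantified, and no single-read
  calls are made.
* parasail-style SIMD acceleration is not used; the numba kernel is exact
  but single-threaded.
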