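# qtrna

Detection of queuosine (Q) and its biosynthetic precursors preQ1 and preQ0
in tRNAs from basecalled nanopore direct RNA sequencing reads.

Queuosine is a bulky 7-deazaguanosine modification installed at the wobble
position (canonical position 34, the first anticodon base) of the four
GUN-anticodon tRNAs (Asp, Asn, His, Tyr). When a Q-modified tRNA transits a
nanopore, the basecaller makes characteristic mistakes at and around
position 34 — elevated mismatches (predominantly miscalled as C), deletions,
and a 5′ "trail" of errors. preQ1 produces a similar mismatch signature with
fewer deletions; preQ0 mainly elevates insertions. `qtrna` turns these error
signatures into modification calls by comparing two sequencing conditions
(e.g. modified vs unmodified cells) position by position.

## Pipeline

1. **Reference curation** (`qtrna.reference_curation`) — deduplicate tRNA
   sequences, convert U→T, flank each body with the 5′/3′ splint-adapter
   sequences used in library preparation, and anchor a linear coordinate
   system with the first anticodon base at position 34.
2. **Alignment** (`qtrna.read_alignment`) — every read and its *reversed*
   decoy (same length and base composition, the only determinants of a
   random local-alignment score) are aligned to all references by optimal
   affine-gap Smith–Waterman. Alignments are ranked by score (ties share a
   rank; all rank-1 hits kept) and a dataset-specific score cutoff is
   computed from the decoy score distribution so that a chosen fraction
   (default 95%) of decoys falls below it:
   specificity = TN / (TN + FP) on the decoy set.
3. **Pileup** (`qtrna.pileup_errors`) — per-position coverage, base
   composition, deletion and insertion counts; mismatch/deletion/insertion
   rates and base frequencies.
4. **Comparative scoring** (`qtrna.comparative_scoring`) — for each
   position and each error channel (base composition incl. deletions;
   deletion; insertion), a replicate-aware Dirichlet-multinomial
   likelihood-ratio score between the two conditions:
   `score = 2[ℓ(A; θ̂_A) + ℓ(B; θ̂_B) − ℓ(A∪B; θ̂_pooled)]`.
   The per-position sum of the three channels is the **Mis + Del + Ins
   score**; high values indicate a modification-induced basecalling change.
5. **Modification calling** (`qtrna.modification_calling`) — contiguous
   high-score runs are merged into candidate regions (peak + extent, since
   the error trail spreads the signal beyond position 34), and the
   wobble signature is classified as Q-like, preQ1-like, preQ0-like,
   unmodified or ambiguous from the per-channel rate differentials.
6. **Read simulation** (`qtrna.read_simulator`) — a configurable generator
   of basecalled-like reads with baseline nanopore error rates and
   preset modification signatures, so the whole pipeline is testable and
   reproducible without sequencer output.

## Worked example

Simulate a fully Q-modified vs unmodified experiment on four synthetic
Q-tRNAs and run the comparative pipeline:

```python
from qtrna import synthetic_trna_set
from qtrna.pipeline import run_two_condition_pipeline
from qtrna.modification_calling import call_candidates, classify_signature

refs = synthetic_trna_set(4, 4, seed=7)
res = run_two_condition_pipeline(
    refs, {r.name: "Q" for r in refs}, n_reads=300, replicates=3, seed=7
)
for site in call_candidates(res.scores):
    call = classify_signature(
        res.profiles["unmodified"][site.ref_name],
        res.profiles["modified"][site.ref_name],
    )
    print(site.ref_name, site.region_start, site.region_end,
          site.peak_position, round(site.peak_score, 1), call.call)
```

Output:

```
tRNA-Asn-GTT-syn 29 36 33 125.2 Q_like
tRNA-Asp-GTC-syn 28 35 35 127.3 Q_like
tRNA-His-GTG-syn 28 35 33 125.6 Q_like
tRNA-Tyr-GTA-syn 28 36 34 124.4 Q_like
```

Each Q-tRNA yields one candidate region spanning the anticodon: the region
covers the 5′ error trail (canonical ~28–36), contains the wobble position
34, peaks at a score two orders of magnitude above the null background
(~0–18), and classifies as Q-like (mismatch *and* deletion gain). The peak
need not sit exactly at 34 — neighbouring bases sense the modified base as
it transits the pore — which is why calls report a region.

The same stages are available from the shell:

```sh
qtrna simulate --preset Q --n-reads 300 --replicates 3 --seed 7 --out sim/
for f in unmodified_rep1 unmodified_rep2 unmodified_rep3 \
         modified_rep1 modified_rep2 modified_rep3; do
  qtrna align  --refs sim/references.fa --coords sim/coords.tsv \
        --reads sim/$f.fastq --specificity 0.95 --out $f.sam
  qtrna pileup --refs sim/references.fa --coords sim/coords.tsv \
        --sam $f.sam --out $f.tsv
done
qtrna compare --cond-a unmodified_rep1.tsv --cond-a unmodified_rep2.tsv \
      --cond-a unmodified_rep3.tsv --cond-b modified_rep1.tsv \
      --cond-b modified_rep2.tsv --cond-b modified_rep3.tsv --out scores.tsv
qtrna call --scores scores.tsv \
      --profiles-a unmodified_rep1.tsv --profiles-a unmodified_rep2.tsv \
      --profiles-a unmodified_rep3.tsv --profiles-b modified_rep1.tsv \
      --profiles-b modified_rep2.tsv --profiles-b modified_rep3.tsv \
      --out calls.tsv
```

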