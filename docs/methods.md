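# Methods

## Model of the signal

A ligation-based RNA-seq library preserves transcript 3′ ends, so a read
that runs off the end of the templated sequence into the poly(A) tail (or
a uridylated tail) accumulates bases the aligner soft-clips. `utail`
treats a terminal soft clip at the read's **biological 3′ end** as a
candidate non-templated tail:

- plus-strand alignment → the clip at the right CIGAR terminus, taken as
  stored;
- minus-strand alignment → the clip at the left terminus,
  reverse-complemented into the read's own 5′→3′ orientation (SAM stores
  sequences in reference orientation).

A clip at the biological 5′ end is never a tail and is ignored. Hard
clips carry no sequence; a terminal `H` outside a terminal `S` is
tolerated per the SAM specification. Insertions (`I`) are internal and
never treated as tails.

The oriented clip is classified by a four-way grammar over {A, U}
(sequencers report U as T; the internal alphabet is DNA and output
rewrites T→U): `A+` → poly(A), `U+` → oligo(U), `A+U+` → poly(A)U,
any other A/U-only string → mixed. Any character outside {A, T} —
including N — rejects the tail outright: tolerating N would silently
inflate the mixed class. `a_run` is the maximal leading A-run and `u_run`
the maximal trailing U-run, so for poly(A)U tails `a_run + u_run`
equals the tail length.

Because the reads are fragments, the observed `a_run` is a lower bound on
the true poly(A) tail length; the method does not estimate full tail
lengths, only the presence and composition of the 3′-most extension.

## Filters and their defaults

| parameter | default | rationale |
|---|---|---|
| min tail length | 4 nt | 1–3 nt clips are dominated by sequencing artefacts |
| min aligned anchor | 20 nt | a tail hanging off a tiny alignment is unreliable; vacuous for ≥100 nt reads |
| alignment filter | primary, mapped, with sequence | secondary/supplementary records duplicate or split the read |
| MAPQ / duplicates | not filtered | no evidence a threshold helps; opt-in flags exist |
| clip base quality | not filtered | opt-in `--min-clip-qual` masks low-quality clip bases to N (rejecting the tail) |
| per-gene detection threshold | ≥ 5 poly(A)+poly(A)U reads summed over replicates | below this, absence of poly(A)U is uninformative |
| max junction-to-feature distance | 1000 nt | avoids assigning intergenic artefacts; settable to unlimited |

Paired mates are scanned independently by default (fractions are
read-level); `--dedup-fragments` keeps one call per fragment, preferring
the longer tail, ties to mate 1.

## Feature assignment

Annotation (GFF3 or BED6) is held 0-based half-open internally; all I/O
converts at the boundary. The TES is the feature's 3′-most base in its own
orientation. A junction overlapping a feature is assigned to it even when
another feature's boundary is nearer (overlap beats proximity, matching
`bedtools closest` behaviour for reads inside genes); otherwise the
feature with minimal genomic distance wins, restricted by default to the
junction's strand, since a tail belongs to its own transcript's 3′ end.
Equidistant ties go to the lexicographically smallest feature id — a
deterministic rule where `bedtools` would report all ties. The signed TES
distance is `junction − TES` on plus-strand features and `TES − junction`
on minus-strand ones, so positive always means downstream.

## Summary statistics

- **Tailed fraction** = accepted tails / primary mapped reads.
- **Uridylation frequency** u = poly(A)U / (poly(A) + poly(A)U) over
  mRNA-assigned tails. This denominator reads u as "share of
  poly(A)-bearing tails that are uridylated"; an alternative denominator
  over all tailed reads is available (`--freq-denominator all-tailed`)
  since the headline percentage could be defined either way. An empty
  denominator yields a missing value, never 0.
- **Strain loss** = 100 · (1 − u_strain / u_baseline), with replicate
  frequencies averaged per strain *before* the ratio (per-replicate
  frequency with a spread is the natural replicate summary; pooling is a
  caller-side option by concatenating inputs).
- **TES-distance CDFs** use absolute distance over a 1000 nt window by
  default (signed curves by flag); the curve is evaluated at observed
  distances and reaches 1 at the window edge for in-window tails.
- **Expression correlation** is Pearson's r between log10(x+1)-transformed
  expression and tailed counts — count data spanning orders of magnitude
  motivate the log; the +1 keeps zeros finite but makes exactly
  proportional counts correlate at slightly below 1.
- Between-sample correlation matrices intersect gene sets first and
  operate on log10(count+1) vectors per read class (all / poly(A) /
  poly(A)U).

Every reported fraction carries its numerator and denominator.

## Simulator

The simulator emulates the structure of a fission-yeast-like experiment
at desk scale: a single chromosome with 60 non-overlapping single-exon
genes of 300–900 nt (90% mRNA, 10% ncRNA) separated by 200 nt padding,
60 nt single-end reads, per-gene expression log-normal (σ = 1). Its tail
model mirrors a wild-type library:

- tailed read probability 0.015 (≈1.5% of aligned reads);
- category mixture poly(A) 0.828, poly(A)U 0.102, oligo(U) 0.040,
  mixed 0.030 — chosen so poly(A)+poly(A)U = 93% of tailed reads and the
  uridylated share of poly(A)-bearing tails is 11%;
- uridine runs 1/2/3 nt with probabilities 0.6/0.3/0.1; adenosine runs
  geometric with mean 8, floored at the 4 nt acceptance threshold;
- poly(A)/poly(A)U junctions at the TES ± N(0, 20 nt); oligo(U) and mixed
  junctions uniform over gene bodies;
- optional per-base substitution error rate and antisense fraction
  (both 0 by default).

SAM records are emitted directly with authoritative CIGARs (no aligner),
so the truth table is exact; minus-strand records are stored
reverse-complemented with the clip on the left terminus. The ten genomic
bases downstream of every TES are forced to C/G so that, if a real aligner
is ever run on the fixture, the soft-clip boundary is unambiguous. All
sampling flows from one `numpy` generator per stage, seeded from the spec;
identical specs reproduce the SAM byte for byte. Mixed tails are sampled
by rejection until the string escapes the three pure grammars.

What the simulator does **not** model — spliced genes, overlapping or
nested features, indels, base-quality structure, PCR duplicates, genomic
A-stretches at the TES (internal priming lookalikes), partial-tail
fragmentation biases — bounds what green tests demonstrate: they verify
the pipeline's bookkeeping (orientation, coordinates, grammar, thresholds,
statistics) exactly, not its robustness to every artefact of real
libraries.

## Numerical and scale choices

Test and acceptance workloads use 10,000–50,000 fragments and 20,000
binomial tails per strain; at these sizes binomial/multinomial recovery
checks use 3-standard-deviation bands and the category-mixture
goodness-of-fit uses a chi-square test at α = 0.001. The per-gene
detection threshold is tested exactly at its boundary (5 retained, 4
dropped). Strain-loss arithmetic on frequencies 0.11 and 0.053 gives
51.8%; values computed from unrounded frequencies may differ in the first
decimal.

## Known limitations

- Uridylation frequency is read-level, not transcript-level; transcripts
  are weighted by their read counts.
- No correction for genomically templated A at the junction: a tail whose
  first bases could align is assigned by the aligner, not by `utail`, so
  results inherit the aligner's soft-clipping policy.
- Single-isoform TES per feature; alternative polyadenylation sites are
  not resolved.
- The closed biotype vocabulary maps unknown annotation biotypes to
  `other` rather than failing.
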