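# Methods

This note documents the models implemented in `riboverlap`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate.

## The designer

A translation-initiation motif is defined purely combinatorially: a
Shine-Dalgarno (SD) hexamer within `max_sd_mismatches` (default 1) plain
Hamming distance of the consensus `AGGAGG`, a spacer of 3–7 nt, then a
start codon (default `ATG` only; `GTG`/`TTG` can be enabled but weaker
non-canonical starts are not assumed for a *created* initiation site). No
thermodynamic RBS scoring or mRNA secondary-structure model is used:
candidates are meant to be re-ranked by a slower model or assayed
directly, and the combinatorial definition keeps genome-scale screens
tractable and reproducible.

### Search strategy

Enumerating all synonymous variants of a whole gene is hopeless (~3.2
codons per amino acid on average, so ~3.2^L variants). But whether a motif
can be created at a given position depends only on the codons its SD
hexamer and start codon overlap — at most five codons, always contained in
an 18-nt window (6 + 7 + 3 nt rounded up to codons). The implementation
therefore iterates over every alternate-frame start position and spacer
length, and enumerates recodings of exactly the constrained codons,
grouped into (SD-mismatch, amino-acid-cost) classes per codon. This visits
the same design space as brute-forcing every synonymous variant of a
sliding 18-nt window while skipping combinations that cannot matter; the
test suite proves the equivalence by exhaustively enumerating *all*
full-sequence synonymous variants of small genes and comparing motif
positions.

Per (start position, frame) only the best variant is kept: minimum
amino-acid cost, then fewest nucleotide edits, then the lexicographically
smallest recoding, then earliest SD and shortest spacer. The tie-break
order is a package convention chosen for determinism; nothing downstream
depends on it beyond reproducibility (reports are byte-identical across
runs and worker counts).

### Stringency and frame clearing

* **S0** — all edits synonymous in the existing frame. A new-frame stop
  codon that no synonymous recoding of the two codons beneath it can
  remove (without creating another stop or touching the motif) rejects
  the site with reason `irremovable_stop`.
* **S1** — one amino-acid change in total, spendable on motif creation or
  on one stop removal.
* **S2+** — one amino-acid change for the motif; irremovable stops are
  *reported* (`aa_changes_remaining`, with a list of suggested single-codon
  substitutions) rather than applied, because many alternative
  substitutions usually exist and the neutral one should be chosen by the
  experimenter.

After stop removal the clearer best-effort-optimises the new frame using
synonymous edits only, never spending amino-acid changes: competing
downstream initiation motifs are destroyed, mononucleotide runs longer
than 3 nt (frameshift hotspots) are broken, and rare codons in the new
frame are recoded. Failures here only clear flags, never reject. Motif
nucleotides are frozen once created — a legal edit that rewrites the SD
into a different accepted variant is not explored; this is a deliberate
simplification (the S2+ suggestion path and the pad logic cover the rare
cases it forecloses). The rare-codon set defaults to eight codons
markedly under-used in *E. coli* (`AGG AGA CGA CGG CTA ATA CCC TCG`) and
is injectable per organism.

The upstream gene's own terminal stop codon is never recoded. A stop it
forms in the *new* frame is handled by recoding the adjacent sense codon
when possible; otherwise the junction pad in `apply_overlap` (0–2
phasing nucleotides, default drawn from `GC`, swapped deterministically if
the junction would form a stop or a new start motif) absorbs it.

Coordinates are 0-based half-open everywhere, including output files
(stated in their headers). Only the sense strand is designed on;
ambiguity codes are rejected outright rather than expanded.

## The protection model

One mutation hits the costly upstream gene per replicate. With probability
`fs` it is a frameshift, otherwise a substitution; its position is uniform
over the gene. Effects:

* substitution — one amino-acid change in the upstream gene; in
  `protein_overlap` mode also one change in the downstream gene when it
  lands in the overlap; in `riboverlap` mode never (the overlap encodes
  only a non-functional N-terminal extension of the essential protein).
* frameshift at nt `x` — scrambles the `⌊(L − x)/3⌋` remaining upstream
  codons and, inside the overlap (the 3'-terminal `overlap_fraction` of
  the gene), shifts the downstream gene's entire frame
  (`⌊L_down/3⌋` changed codons). Treating a frameshift as "every
  downstream codon changed, fed through the same LOF model" is a
  modelling commitment: it makes frameshifts near-certainly inactivating
  except very close to the 3' end, which matches how polar mutations
  behave; no separate frameshift-deleteriousness parameter is introduced.

LOF given `n` changes: discrete stochastic — Bernoulli with probability
`1 − (1 − Pe)^n`; continuous deterministic — activity `(1 − Pe)^n`, LOF
when activity < 0.5. `Pe` is the mean deleteriousness of one amino-acid
substitution; defaults and grids use 0.1/0.3/0.5 (bacterial estimates sit
near the low end of the mutagenesis literature) and `fs` 0.1/0.3/0.7
(wild-type *E. coli* up to mismatch-repair-deficient strains). Synonymous
substitutions are not modelled separately — they are folded into `Pe`.
Nonsense substitutions in the new frame are likewise not modelled
(substitutions never harm the downstream gene in riboverlap mode).

Protection = (# replicates with both genes LOF)/(# with upstream LOF),
with a normal-approximation 95% binomial CI; zero upstream-LOF replicates
flag the result undefined rather than zero. Because the two LOF draws are
conditionally independent given the mutation, the discrete model also has
an exact closed form (a ratio of sums over mutation classes and
positions, `protection_exact`), which serves as the analytic oracle for
the Monte-Carlo path and as the cheap protection curve for the lifetime
simulation. Headline runs use two 1 kb genes and 100,000 replicates.
For the continuous model an alternative protection metric — the impact
dot product normalised by the upstream impact — is provided alongside the
thresholded ratio; the headline grids use the discrete model.

## The lifetime model

Selectable LOF mutations arrive as a Poisson process with rate `μN` per
generation (constant population size `N`; generations are
synchronous-equivalent: total divisions / N). Median time to the first
event: `ln(2)/(μN)`. A protection `p` removes the protected fraction from
the selectable pool (`μ → μ(1 − p)`), multiplying the median lifetime by
`1/(1 − p)`. Multi-gene circuits survive with probability
`e^{−Nt Σ μᵢ}`; the empirical simulation samples n genes from a screened
(length, best-overlap) pool, converts each gene's best overlap fraction
into a protection via the exact discrete curve at `Pe = 0.1`, and compares
median lifetimes with and without overlaps. The curve needs a frameshift
fraction; the default is `fs = 0.3`, the middle of the wild-type range.
The model is first-arrival only — no clonal interference, no fixation
dynamics.

## Fluctuation statistics

Escape fraction per population = (colonies on DOG+kanamycin × its
dilution)/(colonies on DOG × its dilution); zero-DOG populations are
excluded with a warning, fractions above 1 are kept but flagged. The
one-sided Mann-Whitney U test (overlap fractions lower than control) is
exact by enumeration of all C(n1+n2, n1) group assignments for
n1 + n2 ≤ 12 and a tie-corrected normal approximation (scipy) otherwise;
the exact branch is cross-checked against scipy on tie-free data. Effect
size: rank-biserial `r = 1 − 2U/(n₁n₂)`.

The expected number of mutational events per culture is estimated from
the median mutant count `r̃` with the Jones median estimator
`m = (r̃ − ln 2)/(ln r̃ − ln ln 2)`; the package also ships the
Lea-Coulson implicit-equation solution (`r̃/m − ln m = 1.24`, solved by
Brent's method) as an independent alternative, and the two agree within
15% for medians 5–50. The "fraction of mutations avoided" summary is
reported both as 1 − median(overlap)/median(control) and as the
mean-based variant, since the nonparametric test matches the median but
the convention is otherwise arbitrary. No full Luria-Delbrück MLE (MSS
algorithm) is implemented — only the median estimator is needed.

## Synthetic data

`fixtures` generates valid random CDSs (ATG start, stop-free body, TAA
stop, codon usage controllable), plants motifs with known answers
(overwriting whole codons with C-filled slack so the existing frame stays
stop-free — a plant guarantees a zero-edit *motif*, not a clearable
frame), and samples Luria-Delbrück mutant counts by spreading the
expected mutation number over discrete generations in proportion to
divisions, with clones doubling until plating. The samplers emulate the
*structure* real data would have, not its composition: no real codon-usage
table, no phenotypic lag or post-plating growth, no plate-count noise
beyond binomial plating. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated models, not
performance on any particular genome.

Problem sizes used in the test suite are chosen to keep the exhaustive
oracles exhaustive: full-variant enumeration runs on 10-codon genes with
bounded synonym products, protein-preservation checks on 1000 20-codon
genes, Monte-Carlo-versus-oracle comparisons at 2×10⁴ replicates within
3 standard errors, and the multi-gene lifetime property on a seeded
200-gene pool with 10⁴ replicates per circuit size.

## Known limitations

* Motif strength is combinatorial, not thermodynamic; a created motif may
  still initiate poorly in its structural context.
* The windowed/placement search cannot combine recodings whose constrained
  codons lie more than one window apart (none are needed for this motif
  definition).
* The published candidate counts for *galK* depend on the exact motif
  configuration of the original run, which is not fully specified;
  `scripts/galk_reproduction.py` sweeps the plausible configurations
  instead of asserting one.
* The protection model is sequence-free (positions and counts only); it
  does not know about domains, essential residues, or nonsense-mediated
  effects.
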