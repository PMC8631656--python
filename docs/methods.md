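# Methods

`transloscan` analyzes a single genomic locus — a focal gene such as the
sulfite-efflux pump gene *SSU1* in *Saccharomyces* yeasts — across a
collection of annotated genome assemblies, asking three questions: has a
chromosomal translocation replaced the gene's promoter, exactly where is
the junction, and do strains sharing the rearrangement also share the
haplotype that carries it? Two companion modules summarize the phenotype
(sulfite drop tests) and expression (qPCR) data that typically accompany
such a study. A synthetic-genome generator with planted ground truth backs
every stage, so the whole pipeline is testable without access to the
original assemblies.

## Promoter classification

For each strain the gene neighborhood around the focal ortholog is read
off the annotation, on the focal gene's coding strand. A strain is called
*ancestral* when its nearest upstream ortholog matches the reference
strain's nearest upstream ortholog and *translocated* otherwise; the
partner chromosome is the reference chromosome carrying the observed
upstream ortholog. Two distances are reported per strain: the intergenic
gap (previous gene's nearest end to focal start, minus one) and the
strand-aware start-to-start distance. Coordinates are 1-based inclusive
(GFF3 convention) everywhere; upstream offsets are converted explicitly at
the computation sites. Negative intergenic gaps (overlapping genes) are
clamped to zero.

## Breakpoint localization and microhomology

A translocated promoter window `w` (default W = 5000 bp, 5'→3', ending at
the base adjacent to the strand-aware gene start) is compared against the
two parental reference chromosomes: parent A, the focal chromosome whose
sequence should match the focal-proximal side, and parent B, the partner
chromosome matching the distal side. Each parent is anchored into window
coordinates by an exact 20-bp seed (successive seed positions are tried
stepping inward from the appropriate window end; ambiguous seeds are
skipped). With per-base match arrays `mA`, `mB`, the junction is the
changepoint `s` maximizing

    score(s) = Σ_{i<s} mB[i] + Σ_{i≥s} mA[i].

When the window matches its parents perfectly, the set of maximizing
switch points is exactly the microhomology tract — the short sequence
shared by both parents at the junction that makes the precise breakpoint
undecidable — and the reported ambiguity interval `[lo, hi]` has width
equal to the tract length. Under sequence divergence, single-base
coincidences (a substitution that happens to match the other parent) can
perturb the strict optimum by one point, so the ambiguity set then
includes every switch point within 2 score points of the optimum: the
changepoint analogue of a two-mismatch stop rule. The breakpoint offset is
reported at the interval's focal-proximal edge, in bp upstream of the gene
start. Calls are *unresolved* when a parent cannot be anchored or the best
switch point improves on "no switch" by fewer than 10 points (e.g. an
ancestral window), and *complex* when near-optimal switch points form
clusters more than 100 bp apart.

The localizer assumes the promoter window and the parents differ by
substitutions only; indel-containing assemblies would need an alignment
step in front of it, which is out of scope here.

## Motif retention

The ancestral promoter window is scanned for exact IUPAC matches of a
transcription-factor binding motif (default the Fzf1p site 5'-CTATCA-3'),
on both strands. Status is *absent* when the ancestral reference window
has no match; for a translocated strain a match is *retained* only when it
lies entirely on the focal-proximal side of the junction and *lost*
otherwise (a match straddling the junction is destroyed with it).

## K81 distances, shared blocks and the permutation test

Pairwise per-gene distances use the Kimura (1981) three-substitution-type
model, which distinguishes transitions (A↔G, C↔T), A↔T/G↔C transversions
and A↔C/G↔T transversions. With observed proportions P, Q, R:

    d = −(1/4)[ln(1−2P−2Q) + ln(1−2P−2R) + ln(1−2Q−2R)]

in expected substitutions per site. Any non-positive log argument flags
the pair as saturated; saturated genes are dropped from null pools with a
count kept in the result. Sites with N in either sequence are excluded.
The implementation is checked against brute-force site classification, the
JC69 closed form in the equal-class limit, and the independent
implementation in the R `ape` package (`dist.dna`, model "K81").

Ortholog pairs of equal length are compared positionally (the generator
produces substitution-only divergence, for which this is exact); unequal
lengths go through global Needleman–Wunsch alignment (match +1, mismatch
−1, gap open −4, gap extend −1) with gap columns excluded from counting.

The *shared block* walks outward from the focal gene (rank 0) in each
direction while the raw mismatch count is zero — identity, not a rounded
model distance — stopping at the first non-identical gene, a missing
ortholog, or the profile edge. Counts exclude the focal gene; the span is
the kb extent of the outermost identical genes on strain A coordinates.

Significance is assessed against a null of `n_windows` (default 1,000)
windows of `window_size` (default 20) consecutive shared orthologs,
sampled uniformly over valid start positions with replacement, each window
kept entirely outside an exclusion interval (normally the focal block).
Consecutive means consecutive in strain A gene order with the ortholog
present in both strains — a missing ortholog breaks a run, so windows never
silently bridge unassembled regions. The focal sample is the focal gene
plus its `window_size − 1` nearest shared orthologs by rank. The primary
statistic is the two-sided Mann–Whitney U of focal per-gene distances
against the pooled null distances, computed exactly (full null
distribution) when both samples have n ≤ 8 without ties, and by the
normal approximation with tie and continuity corrections otherwise. An
empirical window-mean p-value, (1 + #{null window means ≤ focal mean}) /
(n_windows + 1), is reported alongside.

Because null windows resample a finite set of genes with replacement, tie
corrections make the asymptotic p-value wiggle by a few percent between
otherwise equivalent configurations; the monotonicity property (more
background divergence never makes an identical focal block less
significant) therefore holds up to that jitter.

## qPCR relative expression

Per-gene standard curves are least-squares fits of Ct against log10 of
the dilution factor; the amplification efficiency is E = 10^(−1/slope)
(slope −3.3219 ⇔ E = 2), flagged when outside (1, 2.2]. Quantities are
10^((Ct − intercept)/slope), so unequal per-gene efficiencies are handled
exactly — ΔΔCt on cycles is not used. Per replicate, the target quantity
is normalized by the arithmetic mean of the two constitutive reference
genes (a geometric-mean switch is provided); per cell (strain × condition
× timepoint), replicate mean ± sd is reported and divided by the
calibrator strain's mean in the same cell, making the calibrator's own
ratio exactly 1 by construction. Cells missing a reference measurement
are flagged and excluded from ratios. Group comparisons use Welch's
t-test with Welch–Satterthwaite degrees of freedom; when no curve is
supplied a perfect-efficiency curve (E = 2) is assumed.

## Drop-test tolerance

Growth scores are ordinal 0–6 per MBS concentration on the grid 0–0.40
g/L in 0.05 steps (6 = the most dilute spot grew, 0 = nothing grew). A
strain's maximum tolerated MBS is the highest grid concentration with any
growth (score ≥ 1) — no minimum-dilution criterion is imposed — and is
undefined for all-zero rows, which are excluded from class means with a
count. Promoter classes are compared with Welch's t-test on per-strain
maxima (Student's pooled test behind a flag).

## Synthetic data

The generator emulates the study design the pipeline targets:

- **Reference genome**: uniformly spaced genes (default 3 chromosomes ×
  70 genes of 1 kb with 600 bp intergenic), uniform base composition (K81
  is composition-free), every gene carrying an ortholog label. The binding
  motif is planted at a fixed upstream offset (default 500 bp, within the
  focal intergenic region) after scrubbing chance motif hits from the
  promoter window, so motif truth is unambiguous.
- **Reciprocal translocation**: a k-bp microhomology tract is first
  written immediately 5' of both parental breakpoints *in the reference*
  (it is an ancestral feature of the two chromosomes, which is also what
  makes it detectable), and the bases flanking the tract are forced to
  differ between the parents so the planted junction ambiguity is exactly
  k bp. The distal segments are then exchanged and gene annotations
  remapped; total base content is conserved. The default offset of 339 bp
  upstream of the focal start falls in the intergenic promoter region.
- **Divergence**: each strain evolves from the ancestor under K81 with
  per-site independent substitutions; the three class probabilities follow
  from the model's closed-form transition probabilities at the requested
  branch length (expected substitutions/site), so the distance estimator
  recovers the branch length consistently. No rate heterogeneity and no
  indels are simulated.
- **Shared block**: strain A's gene sequences are copied into strain B
  over a configurable left/right extent around the focal gene, producing
  exact identity there (default 33 left + 21 right).
- **qPCR**: Ct = intercept + slope·log10(quantity) + Gaussian cycle noise
  (default sd 0.2, triplicates), reference genes constant across strains,
  plus a 10⁻¹–10⁻⁵ dilution series per gene.
- **Drop test**: per-strain maxima drawn around class means (default 52
  ancestral strains at 0.175, 10 VII^XVI at 0.375, 1 XI^XVI at 0.40 g/L,
  sd 0.025) and clipped at a per-class ceiling (0.20 g/L ancestral, 0.40
  translocated), then discretized to the grid; scores decay from 6 toward
  1 with concentration.

Every generator is a pure function of (config, seed); regenerated outputs
are byte-identical. What the generator does *not* emulate — assembly gaps
and errors, indels, rate heterogeneity, gene gain/loss, introgression,
annotation noise — bounds what passing tests show about real assemblies:
they validate the statistical machinery and the locus logic, not
robustness to assembly artifacts.

## Numerical and design choices

- Breakpoints are reported at the focal-proximal edge of the ambiguity
  interval; the edge convention is otherwise arbitrary.
- "Identical" for block delimitation means zero raw mismatches, so a
  single substitution breaks a block even when the model distance rounds
  to zero.
- Random windows use sampling with replacement over valid starts; per-
  ortholog distances are cached, so resampled genes cost nothing.
- The default test sizes (e.g. 100–200 replicates in the recovery tests,
  200-gene single-chromosome pairs for the permutation runs) were chosen
  to estimate the targeted rates with comfortable margins while keeping
  the suite quick on a single CPU.
- Degenerate inputs: identical constant samples give p = 1 in both the
  rank test and the t-tests; zero comparable sites raise; all-zero drop
  test rows are undefined rather than 0.

## Known limitations

- Partner-chromosome identification relies on the upstream gene being
  annotated in the reference; the fallback scans all non-focal reference
  chromosomes for the best-anchoring parent.
- The breakpoint localizer searches the forward strand of the partner
  chromosome only; an inverted translocated segment would come back
  unresolved.
- No harmonization across independent qPCR experiments is attempted; each
  dataset is normalized to its own calibrator.
- MIC-style interpolation between drop-test grid points is deliberately
  not performed; tolerance is always a grid value.
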