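# Methods

## Scoring model

The analysis treats a pooled negative-selection screen as a comparison of
guide frequency vectors between the start (T0) and end (Tend) of culture.

**T0 filter.** Guides with a T0 read count strictly below `min_t0_count`
(default 50) are flagged per condition and excluded from all downstream
scores. "49 is discarded, 50 is retained" is a deliberate strict-inequality
reading; the discard list is kept as an audit table and the count matrix is
never mutated. With T0 replicates a guide must clear the threshold in each
of them.

**Abundance.** Neither raw counts nor any external normalization are used;
abundance is the pseudocounted within-sample frequency
`(count + pc) / Σ (count + pc)` over the retained guides, with `pc = 0.5`.
Frequencies make log2FC invariant to sequencing depth, and the pseudocount
keeps fully depleted guides finite (a guide sequenced to zero at Tend still
gets a large negative, rather than undefined, score). The normalizing sum
runs over retained guides only, so discarded guides cannot distort the
denominator.

**log2FC and its sign.** `log2FC = log2(f_Tend / f_T0)`: depletion is
negative, and "robust depletion" means `log2FC < depletion_threshold`
(default −5.0, i.e. a ~32-fold relative loss). The alternative orientation
(start over endpoint) would flip the sign and make the depletion threshold
meaningless, so the end-over-start convention is fixed package-wide,
including the tiling module.

**Gene dependency score.** `GDS = mean(log2FC)` over a gene's unfiltered
guides — an unweighted arithmetic mean, no outlier trimming, no efficacy
weighting. A gene whose guides are all filtered in a condition is reported
`absent` with NaN, never as 0, because 0 is a meaningful value (neutrality).

**Robust-depletion counting.** For a set of conditions, a guide counts for
its gene only when its log2FC is below the threshold in *every* listed
condition and it is filtered in none of them.

**Differential dependency.** Per gene, `GDS_alt` and `GDS_ctrl` are
unweighted means over the two condition groups (each cell line is a
condition; lines are combined only at this step), and genes are ranked by
`ΔGDS = GDS_alt − GDS_ctrl` ascending with deterministic tie-breaks
(then by `GDS_alt`, then gene name). Classification is threshold-based,
not p-value-based, mirroring how such screens are read in practice:
ALT-selective iff `GDS_alt ≤ τ_ess` and `GDS_ctrl ≥ τ_neut`; pan-essential
iff both `≤ τ_ess`. The defaults `τ_ess = −2.0`, `τ_neut = −1.0` are
package choices (a 2.0 log2FC drop over 16 doublings ≈ s·e ≥ 0.125 for a
rare guide); they are configuration, not measured constants. No
multiple-testing machinery is applied because no test statistic is
computed; users wanting inferential calls should feed the count matrices
to MAGeCK/BAGEL-style tools instead.

**Control QC.** Non-targeting negatives should score near zero (pass:
|median| ≤ 0.5 per condition) and spike-in essentials should deplete
(pass: ≥ 50% of positive-control guides below the depletion threshold).
Both flag thresholds are configurable; libraries without controls yield a
"not evaluable" report rather than an error.

## Counting model

Counting is exact-match by construction: a read is scanned for the fixed
5′ flank (first occurrence wins), the window following the anchor is looked
up in the oligo dictionary, and a read with any mismatch in the oligo is
unassigned — never fuzzily rescued. Because libraries may mix 19- and
20-nt protospacers (the 5′ G rule then yields 20- and 21-nt oligos), the
lookup tries each oligo length present in the library, longest first, so a
longer oligo cannot be shadowed by a shorter one that happens to be its
prefix. Unassigned reads are tallied by cause (no anchor, too short, no
match); assigned + unassigned always equals reads processed. Reverse-
complement scanning exists behind a flag but is off by default, since
amplicon orientation is fixed by the primer design.

The oligo — the protospacer after the 5′ G rule — is the counting
reference, because the integrated cassette carries the prepended G.
Duplicate oligos are a load-time error rather than being merged: exact
matching cannot attribute reads between them.

## Forward simulator

The generative model, per condition:

1. **Initial representation.** Total cells = `cells_per_guide × n_guides`
   (default 1000/guide, matching the screen's transduction coverage at
   MOI ≈ 0.35; the MOI is carried as metadata and single integration is
   assumed). Cells are allocated by a multinomial draw with log-normally
   skewed guide weights (σ = 0.3 by default — typical plasmid-pool skew).
   An explicit `initial_frequencies` vector bypasses the draw for
   closed-form comparisons.
2. **Growth.** Cells with guide *g* multiply by `2^(1 − s·e)` per
   population doubling over `D = 16` doublings: *s* ∈ [0,1] is the
   per-gene, per-condition selection coefficient (0 neutral, 1 = no net
   growth relative to one extra doubling of neutral cells) and *e* ∈ [0,1]
   the per-guide knockout efficacy. The doubling clock is anchored to
   neutral cells, a good approximation while hits are a small mass
   fraction. Deterministic mode applies the recursion exactly; stochastic
   mode draws per-doubling Poisson offspring.
3. **Sequencing.** T0 and Tend counts are multinomial draws of
   `seq_depth` reads (default 10⁷ ≈ 2000 reads/guide) from the respective
   frequency vectors. `seq_depth = 0` is the expected-count sentinel: the
   emitted columns are the exact frequency vectors, used when checking the
   simulator against the closed form to 1e-9.

Randomness uses one child generator per (condition, stage), spawned from
the master seed via `SeedSequence` spawn keys, so adding a condition never
perturbs the streams of existing ones and identical configs reproduce
identical outputs bit-for-bit.

The closed-form expectation
`E[log2FC] = (1−s·e)D − log2(f0·2^((1−s·e)D) + (1−f0)·2^D)` assumes all
*other* guides are neutral; it is evaluated in log2 space
(`logaddexp2`) for stability and short-circuits the neutral case to an
exact 0. When a non-trivial mass of the library is depleted, every
neutral guide gains a small positive log2FC from renormalization (about
`−log2(1 − depleted T0 mass × (1 − 2^(−s·e·D)))`); with the default design
(20 planted genes ≈ 4% of guides) this is ≈ +0.06 and visible in the QC
medians.

**Default library design.** 455 target genes with per-gene guide counts
drawn as `4 + Binomial(10, 0.6)` (support 4–14, mean 10, matching the
screen's design band), exactly 100 non-targeting negatives
(sgNeg1–sgNeg100), and 5 guides against each of six spike-in essential
genes (PCNA, RPA3, CDK1, CDK9, TIP60, TTF2) with `s = 0.5` everywhere —
the per-spike-in guide count is a package choice. Protospacers are random
20-mers with unique oligos. Planted condition-selective genes default to
`s = 0.4`, efficacy 1, in the ALT arm only.

**Tiling scenario.** A 120-guide library spaced across a 3486-nt
(1162-codon) open reading frame; the gene carries `s = 1` and per-guide
efficacy encodes where knockout matters (0.5 inside planted domains, 0.05
elsewhere — residual cost of out-of-domain truncations). The shipped
domain map (JmjC, CXXC, PHD, F-box, LRR) is a synthetic, plausibly sized
fixture, not a curated annotation.

**What the simulator does not model.** PCR amplification bias, paired-end
layouts, quality-score realism, multi-guide integrations, selection-phase
(puromycin) death, copy-number artifacts, and guide-level off-target
effects. Passing tests therefore demonstrate correctness of the scoring
arithmetic and the detection logic under a faithful but idealized screen;
they do not certify performance on real data with those artifacts.

## Read layout

Simulated reads are `flank5 + oligo + flank3` truncated to `read_length`
(default 75 nt) with constant quality. The default flanks are a
U6-promoter tail ending just before the oligo's leading G and the start of
the sgRNA scaffold — fixtures standing in for a vector-specific amplicon
design, not reconstructions of any particular primer scheme. Substitution
errors are injected per base at `error_rate` (default 0).

## Numerical and degenerate-input choices

- Frequencies are asserted to sum to 1 within 1e-12 at every simulator step.
- A sample with zero total counts is an error (not silently pseudocounted).
- An empty FASTQ yields a zero column with a warning; a malformed record
  raises with its record index.
- Competition assays report an infinity sentinel (flagged) when the final
  %GFP is exactly 0.
- Paired t-tests with a constant nonzero difference return `p = 0` with an
  `exact_difference` flag instead of dividing by zero; the unpaired default
  is the pooled-variance Student test, with Welch behind a flag.
- Proportions report both the unrounded percent and the integer-rounded
  form used in figure text, plus a 95% Wilson interval.
- Domain ranking breaks ties by domain name; `differential_gds` ties break
  by `GDS_alt` then gene name, so outputs are byte-stable across runs.

## Problem sizes in tests and the acceptance script

Simulated screens use the full 455-gene design (~4700 guides) at 10⁷
reads/sample for calibration, recovery, and hit-detection checks; the
selection-coefficient recovery criterion (ŝ = −log2FC/16 within ±0.02 of
planted s·e ∈ {0.05, 0.1, 0.2, 0.3}) is asserted on the gene-level
estimator — the mean over a gene's ~10 guides, i.e. the GDS, plus the
per-gene median of per-guide estimates — since that is the pipeline's unit
of inference. FASTQ round-trips are exercised at 2 × 200k reads; exactness
of exact-match counting is size-independent. The T0-filter is brute-force
verified on 1000 random matrices.

## Known limitations

- Selectivity cutoffs and QC flag thresholds are conventions, not fitted
  quantities; sensitivity to them should be checked per dataset.
- The GDS is an unweighted mean and thus sensitive to single outlier
  guides for genes with few guides; the per-gene guide lists are retained
  in the output for auditing.
- Exact-match counting discards all reads with sequencing errors in the
  oligo; at realistic error rates a few percent of depth is lost, which is
  harmless for frequency ratios but matters if absolute counts are needed.
- Tiling assigns a guide by its cut-site codon, not by exon identity;
  guides cutting near domain boundaries inherit whichever side contains
  the codon.
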