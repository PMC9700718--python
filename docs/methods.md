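# Methods

## Data model and conventions

All signals live on fixed-width genomic bins (default 1 kb), 0-based
half-open, reported at bin start coordinates.  Strand-resolved counts
(`StrandBinTrack`) and single signed signals (`IndexTrack`) carry per-bin
validity masks; masked bins are excluded from every statistic and emitted
as absent intervals in bedGraph/wig output.  bedGraph and the binned CSV
are 0-based half-open; wig `fixedStep` output is 1-based per that
standard.

Moving averages span `2m + 1` bins (the bin plus `m` neighbours each
side), never cross chromosome boundaries, and **truncate** at chromosome
ends — telomeric bins average over the bins actually available rather than
being masked or wrapped, so smoothed profiles cover whole chromosomes.
Masked bins are skipped inside windows (the mean is over unmasked members
only), not zero-filled, because low-count masked regions would otherwise
bleed artefactual zeros into their neighbourhoods.  A window with no
unmasked member yields a masked bin.

All Z computations use the population (n) standard deviation; at
genome scale the n vs n−1 distinction is immaterial but one convention
must be fixed.  The "Z-shift" used for the initiation/fork indices and
windowed sums is Z(x) − Z(0) = x / sd, a pure rescaling that preserves
zero and sign; it is computed genome-wide over unmasked bins (not per
chromosome), and errors on zero-variance input rather than guessing.

## From reads to usage

R1 5′ ends mark rNMP positions.  Records that are unmapped, secondary,
supplementary, not read 1, or not in a proper pair are ignored.  A record
whose best alignment score does not strictly exceed its reported
second-best (`AS <= XS`) mapped equally well to multiple loci and is
excluded; records with no second-best tag are unique and kept.  Streams
without score tags are passed through with a warning (strict mode errors).
Duplicates are not collapsed.  Forward-mapped R1 reads count to the
Watson strand and reverse-mapped to Crick; because nothing in the data
fixes this polarity absolutely, a `flip_strands` switch produces the
opposite convention, and the simulator plus the initiation-gate sign
structure jointly validate the default.

Bins where the mutant library or the control library has fewer than 5 raw
counts on **both** strands are masked.  Depth normalisation divides each
strand by its library total computed over *all* bins (masking does not
change a library's sequencing depth).  Usage is the per-strand ratio of
normalised mutant to normalised control, left unscaled — downstream
indices use differences and ratios in which a global scale cancels or is
removed by the Z-shift.  Bins with zero normalised control are masked.

## Smoothing plans

Smoothing half-widths are grouped into named plans: `genome`
(usage m_pre = 30 before differencing, differential m_post = 15) for
whole-chromosome profiles, `meta` (7 and 7) for gene-anchored averages and
heat maps; RFD tracks are smoothed with m = 3 in both contexts, and raw
usage plots use m = 3.  Plans are explicit function arguments so replicate
comparisons always use matched smoothing.

## Index definitions

RFD, the initiation index with its four-way sign gate, the directional
fork indices with their two-way gates, and the coupling indices follow the
formulas in the README.  Numerical points worth recording:

- Gate-failing bins are set to 0, not masked, before the Z-shift, so the
  normalisation statistics cover the whole genome and the output is a
  continuous track with flat stretches between events.  The fork-index
  gates require the two differentials to share a sign (the conjunction
  form), not merely their sum.
- Ratio indices (RFD, CI) mask zero-denominator bins.  All are bounded in
  [−1, 1] before smoothing by construction.
- The fork-proportion conversion maps [mean − 3 sd, mean + 3 sd] of the
  unmasked RFD values — 99.7% of Gaussian data — linearly to [0, 100] %;
  values outside the range are clipped so proportions stay interpretable.

## Zones and outliers

An initiation zone is a maximal run of consecutive valid bins with
positive initiation index; runs end at masked bins.  The summit is the
leftmost bin attaining the maximum; the area is the summed index.  Default
thresholds are deliberately permissive (min_width = 3 bins, min_area = 0)
because no principled peak-calling threshold exists at this resolution;
both are explicit parameters.  Replicate concordance counts a zone as
reproduced when its interval overlaps a zone of every other replicate by
at least one bin (a summit-distance criterion is available); when
restricted to a top fraction, each replicate is ranked by zone area.

Coupling outliers use the two-sided Smirnov–Grubbs test:
G = max |x_i − mean| / s (sample sd) against the critical value
((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) point of Student's t on
n−2 df, applied iteratively with removal.  The test population is the set
of 100-kb window means of a coupling index within one chromosome (windows
chosen because reported uncoupled loci span 0.1–1 Mb; bin-level testing is
available), per direction and per replicate; windows significant in at
least two biological replicates merge into loci annotated with direction
and the sign of divergence.  Chromosomes with fewer than three usable
windows are skipped.  No cross-chromosome multiple-testing correction is
applied (the test is defined per chromosome).

Pearson correlations between index tracks are reported with a one-tailed
t-test p-value in the direction of the observed sign.

## Gene-anchored summaries

Meta-profiles average a track at bin-stepped offsets around TSS or TTS;
minus-strand genes are mirrored so positive offsets point downstream of
transcription, and direction-specific track pairs swap rightward/leftward
for minus-strand genes, yielding co-directional (CD) and convergent (CV)
categories.  Expression stratification uses rank-based quartiles computed
on the supplied gene set with stable-order tie-breaking; gene-length
analyses first keep the most transcriptionally active fraction (default
top 50%).  Scaled gene-body profiles resample each body to a fixed number
of relative slots, mirroring minus-strand genes and converting values to
the transcription frame (100 − v for fork-proportion tracks, −v for
signed tracks).  Window sums (0–30 kb upstream of TSS or downstream of
TTS, in transcription orientation) are Z-shifted; log FPKM is Z-scored
with FPKM = 0 genes floored one unit below the finite minimum and flagged
separately, since a pseudocount would silently reshape the distribution.

Zone-annotation partitioning assigns each zone base pair to one category
with precedence transcribed (FPKM > 0 protein-coding bodies) > 0–30 kb
flank > non-transcribed body > other; a priority order is required because
the categories overlap on real annotations, and the chosen order asks the
most specific question first.  Fractions sum to one.

## The replicon simulator

The generator emulates the study conditions at desk scale: origins fire
independently with per-origin efficiencies, all fired origins fire
simultaneously and forks move at equal constant speed, so a locus is
replicated rightward exactly when the nearest fired origin lies to its
left (ties split 0.5/0.5); cells with no fired origin are redrawn, as
every locus is replicated in every real cell cycle.  Simultaneous firing
keeps an exact subset-enumeration oracle tractable while still generating
every signal class the pipeline measures — RFD gradients, initiation and
termination peaks, coupling deviations.  It does not model firing-time
programmes (no replication-timing structure), chromatin-dependent origin
licensing, or fork-speed variation; conclusions about those features do
not follow from these tests.

Fork-direction probability is available three ways: `exact` subset
enumeration (≤ 20 origins), a closed-form `analytic` sum over
nearest-fired-origin events (identical values, O(k²), any origin count;
exact distance ties get explicit probability terms), and `montecarlo`
cell sampling.  The three agree to machine precision / binomial error and
cross-check one another in the tests.

Library expectations: a mutant library of depth `d` (expected reads per
bin, both strands) places Polε signal on the leading strand —
`d·((1−residual)·p_R + residual·(1−p_R))` on Watson, mirrored on Crick —
and Polα on the lagging strand, with `residual` (default 0.1, reflecting
that lagging-strand priming events far outnumber Polα's leading-strand
contribution) and a uniform `background` fraction.  The control is
uniform at `control_depth`.  Counts are independent Poisson draws.
Leading-strand uncoupling over an interval multiplies the leading-strand
Polε expectation of the chosen fork orientation by (1 − u); the residual
Polε incorporation on the other strand is a distinct synthesis event and
is not scaled, which is what confines the resulting coupling-index
deficit (−u/(2−u) at full fork occupancy) to the targeted orientation.

Default desk-scale conditions: one 10-Mb chromosome, 1-kb bins, 20
origins placed one per 500-kb slot with ±20% jitter, efficiencies uniform
on (0.05, 0.95), 200 reads per bin in each library.  Origin placement and
efficiencies are mirror-symmetric about the chromosome midpoint by
default: a real genome hosts thousands of replicons and balances
rightward and leftward replication almost exactly (genome-mean p_R = ½),
whereas a random 20-origin chromosome drifts a few percent from balance —
a finite-size artefact that per-strand depth normalisation would convert
into a spurious genome-wide RFD offset not present at real genome scale.
Mirroring preserves the large-genome property in the scaled-down fixture.

What passing tests show — and do not show.  The simulator produces ideal
libraries: Poisson noise only, uniform mappability, no GC or fragment-size
bias, no replication-timing structure, exact knowledge of the control.
Recovery of origins, efficiencies, fork directionality and injected
uncoupling under these conditions validates the computational pipeline,
not the robustness of Pu-seq to the biases of real sequencing data.

### Parameter recovery at desk scale

On the standard fixture, the combined RFD tracks the true `2·p_R − 1`
with RMSE ≈ 0.045.  The residual error is dominated by the m = 3 boxcar
blur across the step discontinuities of the simultaneous-firing truth
(each step of height h contributes ≈ 0.571·h² summed squared error), with
a minor Poisson-noise term; away from steps the per-bin error is ≈ 0.01.
For this comparison the fixture uses an idealised library (residual = 0,
background = 0), the regime in which the usage algebra makes RFD equal
`2·p_R − 1` exactly in expectation; a nonzero residual r compresses RFD by
(1 − 2r) by construction and would be a property of the library, not an
error of the estimator.  Zone summits recover origins of efficiency ≥ 0.4
within m_pre + m_post + 3 bins, and zone area ranks origin efficiency
with Spearman ρ > 0.95.
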