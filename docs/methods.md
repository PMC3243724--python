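# Methods

`pulscape` re-implements, as a tested library plus analysis drivers, the
computational procedures of a comparative study of glycan utilization in two
human gut *Bacteroides* (*B. thetaiotaomicron* and *B. ovatus*): detection
of polysaccharide utilization loci (PULs) from genome annotations,
cross-genome PUL orthology tiering, operon-level expression-induction
analysis, plate-reader growth phenotyping, and isothermal titration
calorimetry (ITC) binding analysis. This note records the models, the
tunable parameters and their defaults, the behaviour of the synthetic-data
generators, and the design choices made where the procedures were
underdetermined.

## PUL detection

A PUL is modelled as a contiguous gene run on one contig anchored on at
least one adjacent susC--susD homolog pair. Functional classes (susC, susD,
HTCS, ECF-sigma, CAZy families `GH:/PL:/CE:/CBM:<fam>`, `other`) arrive
with the annotation; no homology search is performed at this stage.
Coordinates are 0-based half-open internally; GFF3 I/O converts from the
1-based inclusive convention.

Detection parameters:

* `max_gap` (default 1 gene) -- the number of consecutive `other` genes a
  locus boundary may cross to reach the next PUL-class gene. Trailing
  `other` genes are never included.
* `merge_within` (default 5 genes) -- susC/susD anchor pairs at most this
  many genes apart belong to one locus, so tandem multi-susC loci (two
  susC/D pairs in one operon block) are reported as a single PUL.

Adjacency of the susC/susD pair means consecutive gene indices regardless
of strand; no published rule constrains the boundary expansion, so both
parameters are configurable and the defaults were chosen to reproduce
tandem-pair loci on the synthetic genomes. Regulator classification looks
for an HTCS gene inside the locus or within `regulator_window` (default 3)
genes of either boundary, then for an ECF-sigma gene under the same rule;
HTCS wins when both occur.

Guarantees: detection is per-contig (the result on a multi-contig
annotation equals the union of per-contig results), monotone in `max_gap`,
and deterministic (locus ids follow genome order).

## Orthology tiering

The orthology primitive is the reciprocal best hit (RBH): highest bit
score, ties broken by lower E-value then lexicographic subject id, both
directions, both passing the E-value cutoff (default 1e-10, reading the
quoted exponent cutoff as E <= 1e-10). Hit tables are consumed in BLAST
outfmt-6 form (only qseqid, sseqid, evalue, bitscore are used); a fallback
shared-k-mer protein scorer exists so synthetic benchmarks run without an
external aligner -- it tests the RBH logic, not alignment quality.

A locus in genome A is matched to a candidate in genome B by requiring the
RBH partners of both members of one of its susC/susD pairs to fall inside
the same B locus (the susD search verifies the susC hit). Candidates are
tiered:

* **homologous** -- per-locus homologous gene counts equal, orientation
  conserved, and >= `min_syntenic` (default 3) syntenic flanking genes;
* **probably homologous** -- similar gene counts, with the same flanking
  requirement, but inverted orientation or unequal counts;
* **unique** -- everything else, including loci with no candidate.

Two conventions had to be fixed because an RBH map is a bijection: the
count of gene pairs linking two specific loci is automatically equal on
both sides, so "numbers of homologous genes" are computed per locus as the
number of member genes with an RBH partner anywhere in the other genome
(these can differ when a locus carries extra genes homologous to regions
outside its partner locus). "Similar numbers" is operationalised as
|nA - nB| <= ceil(0.25 * max(nA, nB)); the fraction is configurable and
recorded in every report. Flanking synteny is counted over `flank_window`
(default 5) genes on each side of both loci as the longest order-preserving
chain of RBH pairs, totalled across both sides (block-reversed flanks score
via the reversed chain); flank strand agreement is not required.

Tier assignments are symmetric under swapping the two genomes, and on
synthetic pairs the homologous count is non-increasing (median over seeds)
in the rate at which conserved flanking genes are eroded.

## Expression induction

Signals are normalized expression values (linear scale is assumed; the
report header flags this choice) with a glucose minimal-medium reference
column (`MM-G`). Fold-changes are signed: s/r when s >= r, else -(r/s), so
magnitudes are >= 1 and a single >= 10-fold magnitude cutoff counts both
induced and repressed genes. Operons are maximal same-contig, same-strand
runs with intergenic gaps <= `max_intergenic_bp` (default 150 bp, a
standard stand-in for intergenic-distance operon prediction); the partition
covers every gene exactly once. Operon induction is the arithmetic mean of
member signed fold-changes (not a log-space mean, matching re-averaging of
normalized values), thresholded at the same cutoff. No multiple-testing
correction is applied -- the criterion is a pure fold-change threshold.

The regulated-gene summary counts genes passing the cutoff in at least one
condition of a condition set, takes direction from the condition of largest
magnitude, reports percentages to one decimal, and emits the three-way set
partition (upregulated in PULs / upregulated outside / downregulated) used
for Venn-style summaries. Note 268/280 = 95.7%, which prints as 96% under
integer rounding.

## Growth phenotyping

Quantification is deliberately two-point, not model-based: baseline = mean
of readings in the first `baseline_window_min` (500 min); Amin at the first
reading >= baseline x 1.10 (`rise_fraction` 0.10); Amax at the end of the
first exponential phase; rate = (Amax - Amin)/(Tmax - Tmin) in dA600/h;
density = Amax - Amin; wells with density < 0.1 are no-growth. Three points
needed fixing:

* the baseline "reading" over the first 500 min is taken as the window
  mean (configurable);
* the end of exponential phase is the first point where the smoothed
  derivative (5-point moving average) drops to <= 5% of its in-phase peak,
  handling polyphasic curves by stopping at the first phase;
* both the rise crossing and the slope drop must be sustained over
  `confirm_points` (default 3) consecutive readings. With 0.01-A600 read
  noise a single-reading rule false-triggers during lag roughly half the
  time; requiring three consecutive readings makes spurious calls
  negligible while leaving noiseless behaviour unchanged.

Replicate groups are summarised as mean +/- SD (n-1 denominator) and
compared by two-sided Student's t tests (pooled variance, matching the
named test; Welch is available), significance at p < 0.01. Mutant defects
are expressed as percent of the reference (wild-type) group's mean density;
the polysaccharide-vs-monosaccharide rate ratio is reported both from group
means and per replicate pair, since the published value does not say which
was used.

For planted logistic kinetics A(t) = A0 + amp/(1 + exp(-r(t - tm))), the
relevant truth is the *two-point* rate implied by the window rules, not the
inflection slope amp*r/4 (a secant over the rise is necessarily smaller).
The closed-form window -- exact baseline mean via the logistic integral,
threshold crossing, and the slope-fraction point p = (1 + sqrt(1 - f))/2 --
is evaluated on the continuous noise-free curve and stored in every truth
record next to the max slope and amplitude. Discrete estimates agree with
it to within ~2% at 10--15-min read intervals; the tests require 5%.

## ITC binding analysis

Binding follows the standard equilibrium description. One site class uses
the exact quadratic solution of M + L <=> ML; two independent site classes
solve the shared free-ligand mass balance with a bracketed root finder
(validated in the tests against an independent bisection solver to 1e-9
relative error). Injections dilute the cell continuously (perfusion cell):
after injecting dV into volume V0, cell-resident species scale by
d = exp(-dV/V0) and the syringe species accumulates as Cs(1 - d). The heat
of injection i is q_i = V0 * sum_s dH_s ([ML_s]_i - d_i [ML_s]_{i-1}) in
kcal -- complex carried out by the overflow releases no heat. Input heats
are assumed dilution-corrected; a constant per-injection offset can be
fitted as a nuisance parameter. `ligand_in_cell` mode swaps the species
roles in the mass balance (used for polysaccharide titrations, where the
macromolecule concentration is the well-defined one).

Fitting is bounded least squares over (ln Ka, dH, N) per site, with N
fixable (polysaccharide ligands of unknown molarity). Initialisation is
heuristic -- N from the molar ratio at the isotherm midpoint, dH from the
first-injection heat per mole injected, Ka from two c-value guesses -- with
10 seeded, jittered restarts; the best residual wins. Status calls: **NB**
(no binding) when the heat amplitude is within 3x a robust noise estimate
(median absolute deviation of first differences); **TLTF** (too low to fit)
when the fitted Ka falls below 5e2 M^-1. Derived quantities use
dG = -RT ln Ka with R = 1.9872e-3 kcal/(mol K) at 298.15 K and
TdS = dH - dG; they hold exactly for every fit by construction.

Two-site identifiability: the parameters sit on a degenerate ridge whenever
a single site class fits the data essentially as well, so after every
two-site fit a one-site fit is run and the result is flagged poorly
identifiable if the one-site residual is within a factor of two of the
two-site residual (or both are at the numerical floor), or if the fitted
Ka's land within 2x of each other. With Ka's >= 10x apart and a titration
that saturates the weak site (35 x 10 uL injections of 2.5 mM ligand into
100 uM protein, final molar ratio ~4.5), noiseless recovery is exact to
~1%; under 2% heat noise the weak-site parameters carry substantial
uncertainty, consistent with the large SDs printed for two-site fits in
the published table. The default one-site design (28 x 10 uL of 1 mM into
100 uM, ratio ~2) mirrors common VP-ITC practice.

The audit operation checks a fit table's internal identities row by row:
|dG + RT ln Ka| <= 0.06 kcal/mol (one-decimal printing tolerance) and
|dG - (dH - TdS)| <= 0.15 kcal/mol (three stacked one-decimal roundings).
On the bundled published table every printed dG is reproduced from its Ka
(max deviation 0.049 kcal/mol), while three rows -- glucotetraose C site 1
and both galactomannan sites -- carry printed dH - TdS values inconsistent
with dG beyond the rounding stack (by 0.20, 1.30, and 0.20 kcal/mol); the
1.3 kcal/mol case is almost certainly a typographical error in the source
table. The audit reports them as failures, which is its purpose.

## Synthetic data

Every generator is a pure function of (configuration, seed) and writes a
truth record sufficient to score downstream output.

* **Genome pairs**: planted loci are blocks of 5 conserved flanking genes,
  a PUL pattern (optional regulator, one or two susC/susD pairs, 2--5
  CAZymes), and 5 more conserved flanks, interleaved with unrelated filler
  (~200 genes) and globally shuffled in genome B. Shared loci keep order
  and strand; inverted loci are block-reversed with flipped strands; unique
  loci have no cross-genome homologs. Hit tables are emitted from the
  planting with scores decaying and E-values rising in the mutation rate
  (at rate 1 nothing passes the 1e-10 cutoff), plus weaker secondary and
  spurious hits to exercise best-hit selection. The flank-erosion rate is
  the per-gene probability that a conserved flanking gene in genome B is
  replaced by an unrelated gene; a mere local permutation of ten flank
  genes would leave an expected longest increasing subsequence above the
  3-gene synteny threshold and could not degrade the homologous tier, so
  erosion is modelled as replacement.
* **Expression**: log-normal baselines (sigma 0.8 around a median signal of
  200), planted operons multiplied by the effect size (default 50x, safely
  above the 10-fold cutoff) before multiplicative noise of CV 10%.
* **Plates**: logistic curves A0 = 0.10, amplitudes 0.5--1.0, logistic
  rates 0.008--0.02 /min, midpoints 900--1400 min, read every 10--15 min
  for 2400 min, additive Gaussian noise 0.01 A600; groups share kinetics
  across replicates; optional zero-amplitude (no-growth) and biphasic
  (second, later logistic) groups.
* **Titrations**: wrap the isotherm simulator with Gaussian heat noise
  (2% of the peak heat by convention in the benchmarks).

What passing these benchmarks does **not** show: the generators plant clean
block structure -- no partial locus rearrangements, paralog families,
probe-level microarray artefacts, plate edge effects, or baseline drift --
so recovery on them demonstrates correctness of the algorithms under the
stated statistical structure, not robustness to every artefact of real
GeneChip, plate-reader, or calorimetry data. Genome-scale published counts
(112 *B. ovatus* PULs, 28 shared loci, 280/259/353 regulated genes) require
the real assemblies and expression data and are not reproduced here; the
published summary tables bundled in `pulscape.datasets` are used only for
arithmetic audits (thermodynamic identities, rate ratios, percentage
checks).

## Problem sizes and numerics

Benchmarks use genomes of ~430 genes with 20 planted loci each, 20-seed
medians for stochastic properties, 50 titrations for the ITC recovery
study, and 10--50 curves for growth properties; these sizes make every
property estimate stable at desk scale. Root finding uses Brent's method
with 1e-14 relative tolerance; least squares runs to 1e-14 step/function
tolerance; all randomness flows through `numpy.random.default_rng` seeds;
ties everywhere break deterministically (score, then E-value, then id).

## Known limitations

* Functional classes are trusted input; misannotated susC/susD genes
  propagate directly into detection.
* Operon grouping is a distance heuristic, not a transcription-unit model.
* The two-point growth rate underestimates the instantaneous maximum
  growth rate by construction; values are comparable across wells analysed
  with the same rules, not absolute physiological rates.
* The ITC model covers one and two independent site classes only; no
  cooperative or sequential-site models, and no integration of raw power
  traces (inputs are integrated heats).
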