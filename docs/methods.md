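# Methods

This package implements the computational chain used to stratify high-grade
serous ovarian cancers (HGSOC) by mitochondrial metabolism and to relate
that stratification to genomic scars, outcome, and treatment response. All
stages run on synthetic cohorts with recorded ground truth; what passing
tests do and do not establish about real data is discussed at the end.

## OXPHOS stratification by consensus clustering

Samples are clustered on an electron-transport-chain (ETC) protein panel
(27 proteins from label-free proteomics, or the 5-protein western-blot
panel ATP5A/UQCR2/SDHB/COXII/NDUFB8). Each of 1000 iterations draws 80% of
samples without replacement and partitions the subsample by k-means
(Euclidean distance, 10 random restarts, best inertia kept; restarts are
not prescribed by the source protocol — they stabilize the consensus
estimate). The consensus matrix entry for a pair is its co-clustering
count divided by its co-sampling count; the diagonal is forced to 1 and a
pair never co-sampled (probability ≈ (1 − 0.8²)^1000 per pair) is set to 0
with a warning.

**Optimal k.** For each k in 2..6 we report the area A(k) under the
empirical CDF of off-diagonal consensus values, the relative change
Δ(k) = (A(k) − A(k−1))/A(k−1) (Δ at the smallest k is A itself), and the
proportion of ambiguous clustering, PAC = fraction of off-diagonal entries
in (0.1, 0.9). Selection defaults to the k minimizing PAC, with exact ties
broken toward the larger k: merging two true clusters can be perfectly
stable (PAC 0), but splitting a homogeneous cluster never is, so ties only
arise below the true k. We measured on clean two-group data that the
threshold reading of the delta-area rule ("largest k with Δ > 0.1")
systematically inflates k — splitting a homogeneous group still adds CDF
area (Δ = 0.49/0.31/0.14/0.07/0.04 for k = 2..6 on the default cohort,
which would select k = 4) — whereas PAC is decisive (0.0 at k = 2, ≥ 0.38
elsewhere). The delta rule remains available (`method="delta"`, threshold
config-exposed at 0.1) and all diagnostics are always reported. A
selection where even the best k leaves more than 20% of pairs ambiguous is
flagged low-confidence; structureless Gaussian data trips this flag while
genuinely clustered data sits near 0.

**Assignment and labeling.** The final partition cuts an average-linkage
hierarchy on 1 − consensus into k groups, renumbered by descending size.
For k = 2 the cluster with the larger mean panel score is labeled
high-OXPHOS; an exact tie labels the smaller cluster high, with a warning.
Missing panel values are imputed by per-protein median before clustering
(k-means needs complete vectors; the median is robust and
order-preserving). Heatmap ordering uses Ward linkage on Euclidean
distances over the panel.

Clustering runs on per-run standardized abundances by default; whether to
standardize first is exposed because centered-and-reduced panels are what
the labeling convention expects.

## Proteomic preparation

A peptide is retained iff its signal strictly exceeds 10,000 in at least
⌈0.05 · n_samples⌉ samples ("at least 5%" read as a ceiling; the floor is
strict). A protein is identified iff at least 2 retained *unique* peptides
map to it; its abundance is the per-sample sum of retained peptide
signals. Abundances are log-transformed (natural log; the base is
immaterial after z-scoring) and then standardized per acquisition run:
each protein column is centered and scaled to unit sample standard
deviation (n − 1 denominator, pinned by the two-value example
{1, 3} → ±1/√2) over non-missing entries, within each run. A
zero-variance column within a run becomes all-zero with a logged warning.
Whether the source protocol logged before standardizing is not stated;
log-then-standardize is the default and a flag (`log_transform`) exposes
the choice at the filtering step.

Scalar scores: mean ETC score = per-sample arithmetic mean over non-missing
panel proteins; WB-ETC score = mean over the five blot proteins of
band/actin (actin must be positive); carbonylation score =
carbonylated-protein signal / total-protein signal; IHC Hscore = staining
intensity (0–3) × percent positive cells.

## LST scar scoring and HR status

Input profiles are ordered, non-overlapping allele-specific segments
(total and major copy number per segment; 1-based inclusive SEG text on
disk, 0-based half-open internally). The DNA index is the length-weighted
mean total copy number divided by 2, so a uniform diploid genome scores
1.0 — the printed 1.3 boundary is only coherent on this cytometry-style
scale, since the raw "average copy number" would put every tumor near 2.
Ploidy is near-diploid below 1.3 and near-tetraploid at or above.

Smoothing iterates per chromosome to a fixpoint: equal-state neighbours
merge; an interstitial segment shorter than 3 Mb (strict, 1 Mb = 10⁶ bp)
whose state differs from both neighbours is removed — equal-state
neighbours then merge across the gap (lengths add), unequal neighbours are
each extended to the midpoint of the removed span so coverage is
conserved; a terminal short segment is dropped without extension (a
"variant region" is read as interstitial; terminal behaviour just needs to
be deterministic); a chromosome that is a single short segment is left
alone. Segments at or above 3 Mb are never removed.

An LST is a breakpoint — any change in total copy number *or* major allele
count, including copy-neutral allelic changes — whose flanking segments
are each at least 10 Mb. Counting is per chromosome (the protocol says
"chromosomal breakpoint"; the original signature publication counted per
arm, so per-arm counting with a centromere table remains a possible
extension, not implemented here). HR status: HRD iff the genome-wide LST
count reaches 15 (near-diploid) or 20 (near-tetraploid); otherwise HRP.
Sex chromosomes are not treated specially — chromosome labels are opaque
strings. Segments with missing allele counts are rejected at parse time.

## Synthetic cohorts

* **Proteomics** — log abundance = protein baseline + δ·1[high]·1[ETC] +
  run effect + N(0, 1) noise; run effects are N(0, 0.3); entries are
  masked missing uniformly at random. Defaults mirror the motivating
  cohort: 127 samples (53 low / 74 high), 27 ETC + 333 other proteins, two
  runs, 5% missingness, and δ = 2 s.d. — a strong but realistic subgroup
  shift for a panel-defining protein set (no noise model is printed for
  the real cohort; the log-normal form is the standard label-free
  assumption).
* **Copy-number scars** — exactly n state changes are placed with every
  inter-breakpoint segment ≥ 10 Mb and alternating states that differ in
  both copy numbers, so each breakpoint qualifies by construction; sub-3-Mb
  variant segments (at most one per host, inset ≥ 3 Mb from the host ends
  so no intermediate piece is itself filterable) are inserted strictly
  inside large segments and smoothing provably restores the host. The
  constructed count is therefore the exact ground truth, which the
  pipeline must recover seed for seed. Chromosome lengths default to a
  22-autosome human-scale genome.
* **Survival** — exponential event times; the high group carries the
  baseline hazard (median 60 months) and the low group's hazard is
  multiplied by the hazard ratio. Censoring is uniform on [0, T] with T
  solved from (1 − e^(−λT))/(λT) = censor rate, per group. A Gaussian
  score separated by 2 s.d. between groups is attached.
* **Foci imagery** — the generator emits a two-channel field: a nuclei
  channel carrying cell discs (level 0.5) and a foci channel carrying the
  nuclear bodies (level 0.9, radius 2 px) over a faint diffuse nuclear
  background (0.05), plus Gaussian noise, clipped to [0, 1]. Two channels
  are required for the printed thresholds to be jointly satisfiable: NB
  detection at 0.150 would otherwise always mask whole cells drawn bright
  enough (> 0.180) to be counted as cells. This mirrors the two-channel
  acquisition (nuclear stain vs immunofluorescence) behind the two-step
  quantification. Discs are placed by rejection sampling with no overlaps.
* **Growth** — V(t) = v0 · exp((growth − effect·treated)·t) with mean-one
  lognormal noise (σ² = ln(1 + cv²)); both arms share v0. Defaults: 8
  mice/arm, v0 = 100 mm³, growth 0.1/day, twice-weekly measurement over
  three weeks.

Every generator is bit-reproducible under a fixed seed.

## Foci quantification

Particles are 8-connected components of img > threshold; circularity is
4π·area/perimeter², with the perimeter from scikit-image's weighted
boundary estimator, clamped to 1 (a single-pixel particle with zero
estimated perimeter counts as round). Cells: threshold 0.180, area
strictly greater than 80 px, circularity > 0.4. Nuclear bodies: threshold
0.150, area 1–25 px inclusive, circularity > 0.6. Sizes are in pixels (no
spatial calibration is given; config-scalable). Note the boundary
estimator overshoots a smooth circle's perimeter by a few percent, so
digitized discs plateau near circularity 0.90 rather than approaching 1 —
far above both filters. Touching cells are not watershed-split; the
generator avoids overlaps, and real clumped fields would undercount.

## Survival analysis

Overall survival is (last news − diagnosis) in months (days/30.4375,
calendar-average convention). Relapse at 12 months is dichotomized
strictly before 12 months after the end of first-line treatment. KM
estimation and the log-rank test come from lifelines. The optimal cutoff
scans every midpoint between consecutive distinct scores whose split keeps
both groups at or above 10% of the cohort (the floor prevents degenerate
1-vs-rest splits), takes the minimal log-rank p (ties to the smaller
threshold), and always attaches a multiplicity caveat: the minimal p over
a scan is anti-conservative and no correction is applied, by design
fidelity to the source practice. The scan is invariant to monotone score
transformations.

## Tumor growth

V = a·b²/2 from caliper diameters (a major; swapped inputs are corrected
with a warning); RTV = Vn/V0; change to baseline =
((treated RTV / mean control RTV) − 1) × 100, evaluated at the final
common measurement day (the printed formula's "− 1 × 100" is read with
the subtraction binding first — literal precedence would confine values
to (−1, ∞), inconsistent with a percent waterfall). Whether per-mouse
change should use day-matched or end-of-study control means is not
specified; the final common day is used.

## Problem sizes and numerical choices

The consensus stage runs 1000 iterations over k = 2..6 on the 127-sample
cohort (~30 s on one CPU); recovery suites use 200 scar profiles, 100
imaging fields, and 100–500 survival simulations. Tolerances: per-run
standardization is checked to 1e-9; consensus matrices are exact rational
counts; LST arithmetic is integer base pairs (Mb = 1,000,000 bp, ≥ for
"at least", strict < for "below"). Degenerate inputs are defined above
(zero-variance columns, equal cluster means, zero cells, empty profiles)
rather than left to chance.

## Limitations

Synthetic cohorts have spherical Gaussian protein noise, independent
missingness, exponential hazards, and non-overlapping cells; real
proteomes have correlated proteins and structured missingness, real
hazards are not proportional across all scales, and real microscopy has
clumped nuclei and uneven illumination. Passing recovery tests shows the
algorithms implement their stated rules exactly and recover planted
structure under the stated noise — not that the biological classification
of any real cohort would be reproduced. Raw mass-spectrometry search,
SNP-array preprocessing into absolute copy numbers, transcriptomics,
metabolomics, and enrichment analyses are out of scope.
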