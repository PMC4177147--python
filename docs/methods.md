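# Methods

## The demographic model

A single panmictic population of men experiences one exponential size
change. Backwards in time from the present, with times in generations:

* `N(t) = EndN` for `0 ≤ t < t_end`;
* `N(t) = EndN·exp(−β(t − t_end))`, `β = ln(EndN/StartN)/Δ`, during the
  expansion of backward length `Δ`;
* `N(t) = StartN` earlier.

The four free parameters — `StartN`, `EndN`, expansion end time and
expansion duration — are expressed in men and years at the interface;
internally everything runs in generations (30 years each by default).
`Δ = 0` means an instantaneous size change and `StartN = EndN` a
constant population (the `β = 0` limit is handled analytically). Sizes
are *genetic effective* sizes of the male population: for a recently
expanded population they are far below census counts.

Genealogies follow the continuous-time haploid male coalescent: `k`
lineages merge at rate `C(k,2)/N(t)` per generation, with no
recombination (appropriate for the male-specific Y), no migration and
no selection. Waiting times are drawn by inverting the integrated
hazard in closed form within each epoch (exponential inversion in the
constant epochs, logarithmic in the growth epoch) and carrying residual
hazard across epoch boundaries; a property test checks the inversion
against brute-force numeric integration, and the simulator's means are
cross-checked against msprime under the same demography and against the
Kingman closed forms (`E[TMRCA] = 2N(1−1/n)`,
`E[total length] = 2N·Σ 1/k`) for constant size.

Mutations are infinite-sites Poisson: a branch of `ℓ` generations
carries `Poisson(ℓ·μ·L)` SNPs, `μ·L = 0.264` per generation at the
default constants (`L = 8.8×10⁶` callable nucleotides,
`μ = 3×10⁻⁸`/nt/generation). The mutation rate and generation time only
scale the time axis of the results: halving `μ` doubles every inferred
time.

## Tree statistics

Observed haplogroup trees carry integer SNP counts on branches;
simulated trees carry either generations or Poisson SNP counts. Every
tree is rescaled to total branch length 1.0 and summarised by:

* **r**, the singleton/shared ratio. Terminal branch length (singleton
  mass) over internal branch length (shared mass), with each internal
  branch down-weighted by one plus the internal branch length beneath
  its node, so shared variants deep in a structured clade count more
  heavily against star-likeness. The inner sum counts internal branches
  only; an `include_terminal_below` variant is available but off by
  default. A perfect star has no internal branches and `r = +∞`.
* **m** and **d**, the mean and population standard deviation of the
  pairwise coalescence depths over all `C(n,2)` tip pairs. On
  non-ultrametric SNP trees a pair's depth is the mean of the two
  MRCA-to-tip path lengths, which reduces to the node height in the
  ultrametric case. `d = 0` exactly on a star.

`r` is computed on the normalized tree (the `1 +` weighting makes it
scale-dependent), so the triple is invariant to rescaling all branches.

## Scoring and search

A scenario is scored by simulating `reps` genealogies (1,000 by
default), averaging each statistic over replicates, and taking the
average normalized delta (AND) between the averaged triple and the
observed one. Two numerical choices matter:

* **Statistics are computed on mutated SNP-count trees by default.**
  The three normalized statistics of raw genealogies are *exactly*
  invariant under jointly rescaling all sizes and times by a constant,
  so they cannot identify absolute scale; the Poisson discreteness of
  SNP counts — the same noise the observed trees carry — breaks the
  degeneracy and makes the SNP clock the absolute time reference.
  `mutate=False` scores raw genealogies instead, for sensitivity
  analysis.
* **The `r` average conditions on observability.** A replicate whose
  SNP tree has no shared variant has `r = ∞`; observed trees are only
  analysable because they do have shared SNPs, so such replicates are
  excluded from the `r` average (their fraction is reported per
  scenario) rather than poisoning or vetoing it.

The search sweeps a 4-D grid (5 values per axis by default; starting
ranges `StartN ∈ [1, 5000]` and `EndN ∈ [100, 10⁵]` geometric, end time
`∈ [0, TMRCA]` linear, duration `∈ [30 y, TMRCA]` geometric, all
overridable). Cells whose expansion would begin before the haplogroup's
TMRCA — estimated from the observed tree's mean root-to-tip SNP count
via the SNP clock — are excluded before simulation. Each round keeps a
conservative selection of the lowest AND values (everything within
`max(0.05, 1.5× round minimum)`, at least 5 cells) and re-grids around
them; because the well-fitting set is a curved ridge whose axis-aligned
bounding box need not shrink, every axis is additionally required to
contract to ≤ 0.8× its previous width, recentred on the
inverse-AND²-weighted mean of the kept cells, which makes the zoom
geometric. A final **mapping round** then evaluates a wide grid
spanning the scale family of every retained fit (sizes on 7-point
geometric axes, times on 9-point linear axes): its sub-0.05 cells form
the accepted set, so histograms, medians and 2.5–97.5 percentile
intervals (each accepted cell counted once) describe the full extent of
the fitting region rather than the arbitrary endpoint of the zoom. If
no cell anywhere reaches 0.05 the package reports the conservative
relative selection (within 1.5× the global minimum) flagged
`accepted_mode="relative"` — best fits among the ranges explored, not
an absolute statement of fit.

Per-cell RNG streams derive from `(seed, round, cell index)`, so whole
searches are reproducible and trivially parallelisable. At the default
sizes a full 1,000-replicate search runs in well under a minute on one
CPU, thanks to a vectorised batch path that computes all three
statistics from raw coalescent event streams without building tree
objects; a test asserts bit-level agreement between that path and the
explicit per-tree computation on shared event streams.

## Synthetic data and the packaged trees

The generator's two regimes encode the best-supported continental
models: Europe/R1b (`StartN = 2`, `EndN = 9500`, 325-year expansion
ending 12 KYA, 6 chromosomes) and Africa/E1b1a (`StartN = 40`,
`EndN = 2000`, 12 KY expansion ending 2 KYA, 8 chromosomes). Recovery
experiments draw an observed SNP tree from a regime (redrawing if it
carries no shared SNP, since such a tree is not analysable), run the
full search, and compare the accepted intervals with the generating
values.

The packaged haplogroup trees are **synthetic stand-ins**, not
transcriptions: draws from these regimes selected on structural
criteria only — R1b: six tips with exactly one internal branch of one
SNP uniting three chromosomes; E1b1a: eight tips, bifurcating except
one trifurcation; both: mean root-to-tip SNP count within 1.0–1.10× the
expansion-onset expectation (a haplogroup's TMRCA necessarily predates
its expansion), and among candidates the draw whose statistics lie
closest to the scenario's high-precision mean. The selection emulates
the published relationship between tree and model; it never consults
any downstream fit. What passing tests show is therefore internal
consistency of the pipeline on data generated by its own model — they
cannot certify the upstream steps this package does not implement
(sequencing, variant filtering, tree building), nor the adequacy of a
single-expansion panmictic model for real populations.

## Known limitations

* **A single 6–8 tip tree is a very noisy observation.** The AND
  between one draw's statistics and its own generating scenario's mean
  statistics has median ≈ 0.2 (African regime) to ≈ 0.5 (European
  regime) — far above the 0.05 acceptance cutoff. The accepted region
  therefore tracks the particular draw, not the generating process, and
  its 95% intervals are descriptions of the fitting region, not
  calibrated confidence sets; interval coverage of the generating
  parameters in recovery experiments is well below nominal, and the
  recovery test documents this shortfall.
* **The near-star regime is intrinsically contradictory under scenario
  averaging.** Any tree matching the R1b structure has `r` on the order
  of its total SNP count (~650), while the scenario *mean* `r` at the
  corresponding generating model is several-fold smaller, because
  replicates with a chance pre-expansion coalescence in the large final
  population contribute many shared SNPs. No scenario therefore reaches
  `AND < 0.05` against the R1b tree (the fit is reported in relative
  mode), and the best-fitting cells inflate `EndN` (suppressing
  pre-expansion coalescence) relative to the generating value.
* Residual scale freedom: SNP discreteness pins absolute scale only
  weakly for deep, well-resolved trees, so accepted mass can slide part
  of the way down the size/time scaling family, biasing size and
  duration medians low for the African fit.
* The model omits population structure, migration, selection and any
  second expansion; only one haplogroup is modelled per continent.
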