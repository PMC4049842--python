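# Methods

## Genotype networks

A window of k biallelic SNVs defines a genotype space of 2^k binary
haplotypes — structurally the k-dimensional hypercube Q_k, in which two
genotypes are adjacent when they differ at exactly one site.  The genotype
network of a sample is the subgraph of Q_k induced by the haplotypes
actually observed; phased diploid individuals contribute their two
haplotypes as separate entities, and node multiplicities are recorded but
do not enter any statistic (the properties are over distinct genotypes).

Four statistics are computed per network:

| statistic | definition | reading |
|---|---|---|
| `n_vertices` | distinct haplotypes (Nei's Dh count of types) | extension through genotype space |
| `avg_path_length` | mean shortest-path length over *connected* node pairs | genetic heterogeneity |
| `n_components` | maximal connected subgraphs, isolated nodes included | fragmentation |
| `avg_degree` | mean neighbour count over all nodes (isolated ⇒ 0), = 2·E/V | stability to point mutations |

plus the composite `vertices_per_component` (large, well-connected
networks score high).

**Disconnected pairs.** Average path length on a fragmented network is the
convention of the standard graph libraries: pairs in different components
enter neither numerator nor denominator, and a network with no connected
pair (single node, or all nodes isolated) has an *undefined* path length,
reported as missing (NaN in tables, omitted lines in tracks) — never as 0.

**Construction.** Each observed node's k single-bit flips are probed
against a hash index of the node set — O(V·k) expected instead of the
O(V²·k) all-pairs scan, which is retained as a brute-force oracle
(`build_network_bruteforce`) and asserted edge-for-edge identical in the
tests.  Nodes are packed into 64-bit integers (one bit per SNV), which
caps windows at 63 SNVs; the scan default is 11.

## Input protocol

From a phased VCF: non-SNV and multiallelic records, and any site with an
unphased or missing call among retained samples, are dropped and counted;
0 encodes the reference allele and 1 the alternative.  Two MAF filter
modes exist because the real-data and simulation protocols differ:
`global` (MAF over all haplotypes pooled ≥ threshold, default 0.01) and
`any_population` (site kept if it reaches the threshold in at least one
population — i.e. dropped only when rare everywhere).  The mode is a
required argument.  Missing genotypes are never imputed.  An optional
INFO-field coverage threshold is exposed but off by default, since VCFs
carry no standardized per-site coverage.

Coordinates are 1-based closed internally ("chr6:32507854-32508257"
style); emitted BED/bedGraph tracks are 0-based half-open per those
formats' conventions.

## Sliding-window scan

Windows hold a fixed number of SNVs (k = 11 by default) rather than a
fixed physical span, slide by `step` SNVs (default 1 — maximal overlap;
any coarser stride is a subsample of it), never span chromosomes, and drop
a trailing partial window.  Per window one network is built per population
plus one on all haplotypes pooled (GLOBAL).  Because the haplotypes of any
population are a subset of the pooled set, the GLOBAL node and edge sets
contain each population's (checked as an invariant).

Window covariables: physical span (bp) and the genetic-map distance in cM
between the first and last SNV, linearly interpolated from a 3-column map;
positions outside the map are extrapolated to the nearest endpoint and the
occurrences counted.  Windows are classified from their sites' functional
annotations as `coding` / `noncoding` / `both` / `no_annotation` (the last
excluded from class comparisons, since it has no interpretation).

Masking is generic: any BED intervals (assembly gaps, centromeres,
telomeres, Giemsa bands — whatever the analyst supplies); a window is
removed when at least one of its SNVs falls inside an interval.  Top
regions are the windows above an upper quantile of a chosen property
(default 0.999, ties included), merged when overlapping and ranked; the
report is a candidate list for manual inspection, which cannot be
automated away.

## Simulator

`simulate_neutral` samples a three-population history via msprime:
ancestral population (diploid Ne 12,500) splits 3,500 generations ago
into an African branch (Ne 12,500) and a bottlenecked out-of-Africa
founder branch (Ne 1,800), which splits 2,000 generations ago into
European and Asian branches growing exponentially from 1,000 founders to
10,000 at present.  The two split times are fixed study constants; the
sizes follow the structure of the calibrated human demographic models and
are all exposed in `SimulationConfig`.  Mutations use a binary 0/1 model
(mutation rate 1.25e-8/bp/gen, recombination 1e-8, region 50 kb by
default), and the simulation MAF filter (`any_population`, 0.01) is
applied unless disabled.  Seeds fully determine output; internal seeds are
derived from the config seed via `SeedSequence`.

`simulate_sweep` conditions a focal allele to sweep under genic selection
(s = 0.015) to frequency 0.99 at sampling time.  The engine's sweep model
supports a single panmictic deme, so sweep runs — and their matched
neutral controls — use `collapse_populations`: one deme whose size
defaults to 100,000 diploids, a present-day-scale effective size
reflecting recent human growth, with labels assigned in equal blocks.
Two modelling facts motivate this scale, established on replicate
experiments during development:

* the sweep's characteristic signature on filtered fixed-SNV-count
  windows — *more* vertices, *higher* path length and degree, *fewer*
  components — is produced by recombination during the sweep: escaped and
  recombinant haplotypes form ladders of mosaics one step apart, and
  hitchhikers are scattered across intermediate frequencies with weak
  pairwise LD, surviving the MAF filter where neutral rare variation does
  not.  With a small effective size during the sweep (e.g. 12,500) there
  is too little recombination per sweep duration and every direction
  reverses into a plain diversity trough;
* the signature also requires deep sampling: distinct haplotypes need only
  one carrier, so the recombinant ladder is visible at the full 15,000
  pooled haplotypes but is lost (and the directions again reverse) below
  roughly 10,000 — the same sample-size sensitivity the subsampling
  analysis demonstrates.

The scenario experiments therefore keep 5,000 haplotypes per population
and reduce *region length* (30 kb) and replicate count (50 pairs) for desk
scale.  The selected allele itself is inserted at the sweep position from
the marginal genealogy (the node whose leaf fraction is closest to the
target frequency) and is exempt from the MAF filter, being the
conditioning variant.  Failed sweep trajectories retry with fresh derived
seeds up to a bounded count, then raise.

What the generator does *not* emulate: recombination hotspots and gene
conversion (the engine cannot combine gene conversion with the sweep
model), migration after the splits, admixed populations, and any
base-sequence realism.  Passing scenario tests therefore demonstrate the
method's directional behaviour under a clean sweep, not calibrated human
genome expectations.

## Statistical experiments

* **Subsampling curves** — per population and pooled GLOBAL, haplotypes
  are drawn without replacement at sizes 5,000 … 100 (defaults), r = 5
  replicates, window-property means aggregated to mean ± SEM.  Within a
  replicate, one permutation is truncated at each size, so vertex counts
  are monotone per replicate, not only in expectation.  (Error bars in the
  classic presentation are 6×SEM; the raw SEM is returned.)
* **Correlations** — pairwise Pearson over windows, undefined values
  dropped pairwise, constant columns yielding NaN; optional log10 scale
  for the vertex count, which strengthens the size–degree relation.
* **ANCOVA** — windows above 1 cM are removed (recombination correlates
  with several properties); each property is fitted as
  `property ~ C(annotation_class) + recomb_cM` by OLS, without an
  interaction term (exposed as an option), separately per population.
  Reported: the class F-test, all pairwise class contrasts with Bonferroni
  correction (m = number of contrasts per property; never below the raw
  p), and covariable-adjusted class means ± 2 SEM at the mean
  recombination distance.  Classes with fewer than two windows are skipped
  with a warning.
* **Scenario comparison** — two-sided Mann–Whitney per property over
  window values (midranks, normal approximation with continuity
  correction; exact small-sample p below n = 25 per group), the direction
  of the median shift, and quantile–quantile pairs for plotting.  The
  paired experiment driver (`scenario_replicates`) simulates
  neutral/sweep pairs under identical settings except the sweep and feeds
  either pooled rank-sum tests or per-replicate paired tests.

## Numerical and design notes

* Properties are invariant to haplotype input order (hash-set
  construction, sorted reductions); determinism contracts are tested.
* The window quantile filter includes ties at the threshold, so "top 5 of
  100" can return more than 5.
* A window's packed representation makes per-window network construction
  O(H + V·k) for H haplotypes; scans at 15,000 haplotypes × ~650 windows
  run in seconds.
* Degenerate inputs: empty genotype lists, mixed lengths, non-binary
  strings, reversed site ranges, odd row counts for VCF export, and
  oversized subsamples all raise `ValueError` early; zero sites surviving
  filters returns an explicit empty matrix, not an error.
* Desk-scale problem sizes used by the test suite and the acceptance
  script (30 kb regions, 50 replicate pairs, 3 regions for the curves)
  were chosen once as the smallest sizes at which the directional effects
  are comfortably resolved by the paired designs.

## Known limitations

* The sweep model is panmictic; population-specific sweeps with ongoing
  structure are out of reach of the engine's sweep implementation.
* COSI-exact demographic reproduction is not attempted; only the split
  times and sweep parameters are treated as fixed.
* The component count's sweep response is the weakest of the four (as in
  the reference analysis) and needs the pooled window counts of the full
  paired experiment to resolve.
* Real-data headline numbers (specific top regions, chromosome-wide
  correlation coefficients) are properties of a particular dataset and are
  not reproduced by simulation; the package reproduces structure and
  direction.
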