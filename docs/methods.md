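# Methods

This note records the models implemented in `karyocin`, the defaults and
why, the numerical choices, and what the synthetic-data validation does and
does not establish.

## Karyotypes and derived metrics

A karyotype is a vector `c ∈ ℕ¹⁶` of whole-chromosome copy numbers over
chromosomes I–XVI. The bundled length table carries the R64 (SGD) reference
chromosome lengths in base pairs; any 16-entry table can be substituted.

- **Apparent ploidy** `P(c) = Σ cᵢLᵢ / Σ Lᵢ` is the DNA content relative to
  the haploid genome — what flow cytometry measures. It is linear in `c`
  and bounded by `min c` and `max c`. The unweighted alternative
  (`total chromosomes / 16`) is exposed as `mean_copy_number`; the
  length-weighted form is primary because DNA-content measurements weight
  chromosomes by length.
- **Basal ploidy** is the modal copy number. When the mode is tied (e.g.
  eight chromosomes at 1 and eight at 2) it is undefined and the strain is
  excluded from aneuploid-chromosome analyses; the exclusion is signalled by
  an exception rather than a silent default.
- **Aneuploid chromosomes** are those deviating from basal ploidy, gains
  and losses alike; "megabases in aneuploidy" counts each such chromosome's
  full length once.

## Karyotype calling (qPCR × FACS)

qPCR relative quantification uses `ratio = E^(Ct_calibrator − Ct_sample)`
with the per-cycle amplification factor `E` defaulting to 2.0 (perfect
doubling); per-probe efficiencies and the double-normalized ΔΔCt chain
(target vs endogenous control, sample vs calibrator) are available. Both
normalization conventions — an endogenous control probe or a reference
chromosome — compose through the same function; neither is privileged.

Integer calling minimizes

    Σᵢ wᵢ (s·rᵢ − cᵢ)²  +  λ (P(c) − P_FACS)²

jointly over the scale `s > 0` and integers `cᵢ ∈ [1, 3]`, subject to
`|P(c) − P_FACS| ≤ 0.15`. Given `c`, the optimal `s` is closed-form; given
`s`, the optimal `c` is per-chromosome rounding and piecewise constant in
`s`, so scanning the rounding breakpoints makes the joint search exact.
Design choices:

- The copy-number range 1–3 covers strains between 1N and 2N plus
  hyper-diploid deviants; it is configurable.
- The soft ploidy term (default `λ = 16`) treats the FACS estimate as a
  quantitative measurement rather than a gate only: a ploidy error is a
  genome-averaged copy-number error, so it is weighted like 16
  per-chromosome residuals of the same size. Without it, a single large
  qPCR excursion can pull the call to a wrong integer vector that still
  sits inside the ploidy window. `λ = 0` restores the gate-only form.
- Chromosomes whose scaled ratio ends ≥ 0.25 from the called integer are
  flagged as heterogeneous (non-integer population-average copy number);
  if no integer vector satisfies the ploidy window at all, the sample is
  "too heterogeneous" and the strain is excluded. The 0.15 window and 0.25
  flag threshold are defaults chosen to separate technical noise
  (≈ 6% per ratio at 0.15-cycle triplicate noise) from genuine mixtures;
  both are parameters.
- Calling is invariant to global rescaling of the ratio profile (absorbed
  by `s`).

Ploidy-stability classification compares the coefficient of variation of
the 12 G1 peaks (spore + 11 colonies) against a haploid control processed
identically: stable iff `CV ≤ control CV × factor` (factor default 1.0).
Obviously heterogeneous DNA profiles are pre-classified unstable via an
explicit override. MAD2:MAD1 ratios are binned to the nearest of
{0.5, 1, 1.5, 2} (the rational ratios reachable with gene copies 1–3; the
set is configurable) with a binary =0.5 / ≠0.5 split also exposed.

## Mis-segregation population simulator

Each generation every live cell divides; each of the 16 chromosomes
independently mis-segregates with probability `p`. Default granularity:
one homolog's sister pair nondisjoins, daughters receiving `c+1` and `c−1`
copies — the only reading that produces the single-chromosome gains and
losses observed from disomic chromosomes; the literal all-copies reading
(`2c` / `0`) is a configuration switch. At most one event per chromosome
per division. Daughters losing all copies of any chromosome die. When the
population exceeds the cap (default 100,000) it is downsampled uniformly
without replacement, checked after each full generation.

The implementation aggregates the population into counts per distinct
(karyotype, lineage) group: faithful divisions double a group, the number
of event divisions per group is Binomial with the exact ≥1-event
probability `1 − (1−p)¹⁶`, the event multiplicity follows the conditional
Binomial(16, p) distribution, and downsampling is multivariate
hypergeometric. This is exact in distribution with respect to the
cell-by-cell description (cross-checked in the tests against a naive
per-cell simulator) and makes 30 replicates at realistic caps run in
seconds. Lineage tracking opens a new lineage at every mis-segregation
event with its generation and parent, giving sampled colonies an exact
ancestry for root-linked event counts. Selection and growth-rate
differences between karyotypes are deliberately not modelled, so simulated
diversity slightly overstates what a competing culture would retain.

Seed karyotype for threshold runs: a random triploid-meiosis spore
(configurable); the per-replicate statistic is the fraction of live cells
whose karyotype differs from the seed, summarized as median and IQR over
30 replicates; extinct replicates are excluded from fractions and counted.

## Triploid-meiosis spores

A spore assigns each chromosome copy 1 or 2 with probability ½
independently. The expected apparent-ploidy histogram is built from 10,000
replicates of 41 spores (matching the observed sample size), reported as
per-bin mean ± SD with 0.1-wide bins on [1, 2]; the exact distribution from
all 2¹⁶ equally likely karyotypes serves as reference (mean exactly 1.5;
the distribution is symmetric about 1.5 because complementing a karyotype
maps ploidy `x` to `3 − x`). The observed-vs-expected comparison is a
two-sample Kolmogorov–Smirnov test against a large simulated pool (default
10⁵ spores); a one-sample-like mode against the exact enumeration is
available. Viability mechanisms are not modelled; the synthetic depletion
of mid-ploidy spores (rejection in [1.4, 1.6]) is a data feature for
validation, not a mechanism.

## Karyotype networks and CIN classes

Observed karyotypes (population row + colonies; duplicates collapsed into
frequency-weighted nodes) are connected by a network minimizing the total
number of copy-number change events — a minimum Steiner tree in the Hamming
graph, allowing unobserved median karyotypes when they reduce the total.

- **Exact route (≤ 5 distinct karyotypes, the typical 12-row instance):**
  enumerate Steiner topologies (trees over the terminals plus up to `t−2`
  internal nodes of degree ≥ 3, generated from Prüfer sequences and
  deduplicated under internal relabelling; 396 topologies at `t = 5`),
  solve per-chromosome unit-cost small parsimony (Sankoff) on each with
  terminal states fixed, and keep every cost-minimal topology. Multi-state
  columns (copies outside {1, 2}) use unordered unit-cost states. All
  co-optimal topologies are contracted to networks and deduplicated; ties
  within one topology's per-column labelling are broken deterministically
  toward the root-side state, so one canonical labelling per topology is
  reported rather than the full labelling multiset.
- **Heuristic route (> 5 distinct):** minimum spanning tree on Hamming
  distance, augmented by greedily inserting per-column majority vectors of
  node triples while they strictly reduce the spanning cost
  (median-joining), then splicing out unobserved pass-through nodes that
  add no parsimony value. The tests verify exactness of the exact route
  against an independent Dreyfus–Wagner dynamic program and spot-check the
  heuristic on instances the oracle can still handle.

CIN classification counts network edges incident to the founding
(population) karyotype: each such edge is one event regardless of how many
chromosomes changed on it, and changes the network attributes to a
deviant's own progeny are not charged to the founder. 0 events → S,
1 → MU, ≥ 2 → HU. With several co-optimal networks the class is reported
per network plus a consensus (None when they disagree). The
generation-label nuance of the class definitions (when a change was
observed) is carried as metadata only; the count-based rule decides.

## Statistics

Fisher's exact test is two-sided by the minimum-likelihood convention.
2×2 tables go through scipy; r×c tables are enumerated exactly over all
fixed-margin tables when the candidate count is below 2×10⁵, otherwise a
fixed-seed Monte Carlo permutation of category labels estimates the p-value
(with the +1 correction). Enrichment is the upper-tail hypergeometric
`P(X ≥ k)`. The pairwise imbalance scan tests, for each of the 120
chromosome pairs, enrichment of the unstable group among strains whose
copy ratio for the pair differs from 1, under either grouping
(HU vs S+MU, or MU+HU vs S); raw p-values are reported (no
multiple-testing correction by default, matching the exploratory use;
Benjamini–Hochberg can be applied downstream). Welch's t is two-sided
with Satterthwaite degrees of freedom. Growth rate is the least-squares
slope of log₂(count) vs time (generations/hour). Density profiles use a
Gaussian KDE (Silverman bandwidth), rescaled to peak at the class's share
of strains. α = 0.05 throughout.

## Synthetic data and what validation shows

The generator composes the spore and population simulators per strain
(rates drawn from {0, 10⁻⁴, 5×10⁻⁴, 10⁻³}; sampling time g20/g25/g30 chosen
inversely to apparent stability, mimicking the study design), samples 11
colonies uniformly from the final population, and inverts the ΔΔCt and
FACS models to produce raw-ish measurements: Ct triplicates with 0.15-cycle
Gaussian noise per replicate and G1 peaks with 2% CV. These noise defaults
are invented plumbing chosen so recovery is achievable but not trivial.
The population's qPCR profile is generated from the population-mean copy
numbers, so heterogeneity flagging is exercised on mixtures; colonies are
reported as the single cell that seeded them (colony-internal divergence
during outgrowth is ignored).

End-to-end validation pushes 60 strains through calling → network →
classification: rate-0 strains should come out S and rate-10⁻³ strains
MU/HU. Measured accuracy is 93–98% across generator seeds; the dominant
residual error is rate-10⁻³ strains none of whose 11 sampled colonies is a
deviant (the classification then correctly reflects the sample but not the
rate) — an irreducible feature of the 11-colony design, not of the
algorithms. Passing these tests shows the machinery is self-consistent
under the stated noise model; it does not certify performance on real data
with partial aneuploidies, recombination, probe-specific efficiencies or
selection during colony growth, none of which the generator emulates.

## Problem sizes and determinism

Simulation sizes used by the test suite and the acceptance script — a
10,000-cell population cap, 30 replicates, 60 synthetic strains — are the
package's working defaults for validation runs; the cap is a computational
control whose value does not materially affect deviant fractions (the
population simulator behaves identically in distribution above the cap
boundary), and the full 100,000 default remains in place for library use.
All stochastic components take explicit seeds and are bit-reproducible
given one; derived seeds are drawn below 2³¹.
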