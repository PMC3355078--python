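# karyocin

Karyotype dynamics and chromosome-instability (CIN) analysis for random
aneuploid budding yeast.

## The problem

Aneuploid *S. cerevisiae* strains — obtained as random meiotic products of a
homozygous triploid, so that each of the 16 chromosomes independently ends up
at copy number 1 or 2 — differ widely in how fast they gain and lose further
chromosomes. Measuring that instability requires a chain of inferences, none
of which is a single off-the-shelf computation:

1. **Karyotype calling.** Flow cytometry gives a population's apparent
   ploidy `P = Σ cᵢLᵢ / Σ Lᵢ` (the length-weighted mean copy number, from the
   G1 peak position relative to a haploid control) but not per-chromosome
   copies; qPCR gives relative chromosome stoichiometries `rᵢ` (via
   ΔΔCt, `ratio = E^(Ct_cal − Ct_sample)`) but only up to a global scale.
   `karyocin.calling` finds the integer vector `c` and scale `s` minimizing
   `Σ wᵢ (s·rᵢ − cᵢ)²` with the called ploidy agreeing with FACS, and flags
   chromosomes whose scaled ratio sits far from any integer
   (population heterogeneity).
2. **Karyotype networks.** Each strain contributes 12 karyotypes (the
   founding population sample + 11 colonies). Treating chromosomes as loci
   and copy numbers as alleles, `karyocin.network` reconstructs the most
   parsimonious network connecting them — a minimum Steiner tree in Hamming
   space, solved exactly by Steiner-topology enumeration with per-column
   Sankoff labelling for ≤ 5 distinct karyotypes, by a median-joining
   heuristic beyond. Every network edge incident to the founding karyotype
   is one CIN event; strains are classed S (0 events), MU (1) or HU (≥ 2).
3. **Stochastic simulators.** `karyocin.missegregation` grows a colony from
   one cell under a per-chromosome mis-segregation probability `p`
   (daughters receive `c+1`/`c−1` copies; nullisomic daughters die;
   populations over the cap are resampled) to ask when karyotypic deviants
   become detectable. `karyocin.meiosis` draws random triploid-meiosis
   spores and their apparent-ploidy distribution, with an exact 2¹⁶
   enumeration as reference.
4. **Association statistics.** `karyocin.stats` provides exact tests
   (two-sided Fisher by minimum likelihood, incl. r×c by enumeration;
   upper-tail hypergeometric enrichment and the 120-pair
   chromosome-imbalance scan), Welch's t, growth-rate regression, and
   peak-normalized kernel density profiles.
5. **Ground truth.** `karyocin.synthetic` generates the entire study —
   spores, populations with logged mis-segregation lineages, colonies, Ct
   tables, FACS peaks — so every stage can be validated against known
   parameters.

## Worked example

```python
import numpy as np
from karyocin import Karyotype, apparent_ploidy, build_network, KaryotypeMatrix
from karyocin.network import classify_cin

# a haploid that gained ChrIV: apparent ploidy rises by L_IV / Σ L
spore = Karyotype.from_iterable([2 if i == 3 else 1 for i in range(16)])
print(round(apparent_ploidy(spore), 3))          # 1.127

# population + 11 colonies, two of which lost the extra ChrIV copy
haploid = Karyotype.uniform(1)
rows = (spore.copies,) * 10 + (haploid.copies,) * 2
networks = build_network(KaryotypeMatrix(rows=rows, root_row=0))
calls, consensus = classify_cin(networks)
print(calls[0].n_root_events, consensus)         # 1 MU
```

Running `python analysis/02_simulate_missegregation.py --seed 1` prints,
among other rates:

```
g=20 rate=0.001: median deviant fraction 0.196 (IQR 0.174-0.213)
g=30 rate=0.0005: median deviant fraction 0.150 (IQR 0.140-0.171)
```

i.e. at a mis-segregation probability of 10⁻³ per chromosome per division,
more than 10% of cells carry a deviant karyotype within 20 generations, and
at 5×10⁻⁴ within 30 — the rationale for karyotyping colonies at g20–g30.

The numbered scripts under `analysis/` run the full study on synthetic data:
spore ploidy spectrum (01), deviant-fraction thresholds (02), synthetic
strain collection (03), calling + networks + CIN classification (04), and
the association statistics (05). Each writes its tables under `results/`.

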