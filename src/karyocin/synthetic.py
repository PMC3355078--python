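"""Synthetic study generator with known ground truth.

Emulates the full experimental design end to end: a random aneuploid spore
karyotype from triploid meiosis seeds each strain; the spore grows into a
population under a strain-specific chromosome mis-segregation rate (with
nullisomic death and population-cap resampling); 11 colonies are sampled
uniformly from the final population; the population and each colony yield
qPCR Ct tables (three technical replicates, Gaussian cycle noise) and FACS
G1-peak positions (multiplicative noise at a set CV) from which the calling
module can re-derive karyotypes.  Every mis-segregation lineage is logged, so
the number of root-linked events among the sampled colonies — what the
network reconstruction estimates — has an exact ground truth.

What the generator does not emulate: growth-rate competition between
karyotypes, colony-internal heterogeneity (a colony is reported as the
single cell that seeded it), partial/segmental aneuploidy, and qPCR
efficiency drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chromosomes import CHROMOSOMES, ChromosomeTable, default_table
from .karyotype import Karyotype, apparent_ploidy
from .meiosis import random_spore
from .missegregation import ROOT_LINEAGE, ColonyPopulation, simulate_colony

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticStrain",
    "generate_strain_collection",
    "generate_ct_table",
    "ratios_from_ct_table",
    "generate_facs_peaks",
]

#: Strain-level mis-segregation rates sampled in a default study.
DEFAULT_RATE_SET: tuple[float, ...] = (0.0, 1e-4, 5e-4, 1e-3)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study conditions for a synthetic strain collection."""

    n_strains: int = 27
    rate_set: tuple[float, ...] = DEFAULT_RATE_SET
    colonies_per_strain: int = 11
    population_cap: int = 100_000
    ct_noise_sd: float = 0.15  # cycles, per technical replicate
    facs_cv: float = 0.02
    amplification_efficiency: float = 2.0
    viability_dip: float = 0.0  # P(reject) for spores with ploidy in [1.4, 1.6]
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if any(not 0 <= r <= 1 for r in self.rate_set):
            raise ValueError("rates must be probabilities")
        if self.ct_noise_sd < 0 or self.facs_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0 <= self.viability_dip <= 1:
            raise ValueError("viability_dip must be a probability")

    def generations_for_rate(self, rate: float) -> int:
        """Sampling time point mimicking the study design: apparently stable
        strains are followed longest (g30), the most unstable sampled at g20."""
        if rate >= 1e-3:
            return 20
        if rate > 0:
            return 25
        return 30


@dataclass(frozen=True)
class SyntheticStrain:
    """One synthetic strain with its ground truth and raw-ish measurements."""

    strain_id: str
    true_rate: float
    generations: int
    seed_karyotype: Karyotype
    colony_karyotypes: tuple[Karyotype, ...]
    colony_lineages: tuple[int, ...]
    population_mean_copies: np.ndarray
    population_modal_karyotype: Karyotype
    true_root_events: int
    n_events_total: int
    n_redraws: int
    ct_tables: dict[str, pd.DataFrame]
    facs_peaks: dict[str, float]
    control_peaks: np.ndarray
    haploid_control_peak: float


def generate_ct_table(
    karyotype_or_copies: Karyotype | Sequence[float],
    noise_sd: float,
    efficiency: float = 2.0,
    *,
    rng: np.random.Generator,
    base_ct: float = 20.0,
    n_replicates: int = 3,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Ct table consistent with the given (possibly fractional) copy numbers.

    The calibrator is a haploid (copy number 1 for every probe), measured at
    ``base_ct`` cycles; a template with copy number ``c`` then crosses
    threshold ``log_E(c)`` cycles earlier, so noise-free relative
    quantification recovers ``c`` exactly.  Gaussian noise (``noise_sd``
    cycles) is added independently per technical replicate.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    copies = (
        np.asarray(karyotype_or_copies.copies, dtype=float)
        if isinstance(karyotype_or_copies, Karyotype)
        else np.asarray(karyotype_or_copies, dtype=float)
    )
    if copies.shape != (16,) or np.any(copies <= 0):
        raise ValueError("need 16 positive copy numbers")
    clean_ct = base_ct - np.log(copies) / np.log(efficiency)
    rows = []
    for i, chrom in enumerate(CHROMOSOMES):
        for rep in range(1, n_replicates + 1):
            ct = clean_ct[i] + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            rows.append(
                {
                    "sample_id": sample_id,
                    "probe_id": chrom,
                    "replicate": rep,
                    "ct": ct,
                }
            )
    return pd.DataFrame(rows)


def ratios_from_ct_table(
    ct_table: pd.DataFrame,
    efficiency: float = 2.0,
    base_ct: float = 20.0,
) -> np.ndarray:
    """Per-chromosome relative copy ratios from replicate-mean Ct values."""
    means = ct_table.groupby("probe_id")["ct"].mean()
    return np.array(
        [efficiency ** (base_ct - means[c]) for c in CHROMOSOMES]
    )


def generate_facs_peaks(
    ploidy: float,
    cv: float,
    n: int,
    *,
    rng: np.random.Generator,
    haploid_peak: float = 100.0,
) -> np.ndarray:
    """G1 peak positions proportional to apparent ploidy, noise at given CV."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    mean = haploid_peak * ploidy
    if cv == 0:
        return np.full(n, mean)
    peaks = rng.normal(mean, cv * mean, size=n)
    return np.clip(peaks, mean * 0.1, None)


def _root_branch(lineages, lineage_id: int) -> int:
    """The ancestor lineage whose parent is the root (the root-linked branch)."""
    lin = lineage_id
    while lineages[lin].parent_lineage != ROOT_LINEAGE:
        lin = lineages[lin].parent_lineage
    return lin


def generate_strain_collection(
    config: SyntheticStudyConfig,
    table: ChromosomeTable | None = None,
) -> list[SyntheticStrain]:
    """Generate a full synthetic strain collection with ground truth.

    Strain rates are drawn uniformly from ``config.rate_set``; extinct
    populations are re-drawn (counted in ``n_redraws``).  The optional
    viability dip rejects spores with apparent ploidy in [1.4, 1.6] with the
    configured probability, mimicking the depletion of mid-ploidy spores.
    """
    table = table or default_table()
    rng = np.random.default_rng(config.rng_seed)
    haploid_peak = 100.0
    strains: list[SyntheticStrain] = []
    for idx in range(config.n_strains):
        rate = float(rng.choice(config.rate_set))
        generations = config.generations_for_rate(rate)

        n_redraws = 0
        while True:
            spore = random_spore(rng)
            ploidy = apparent_ploidy(spore, table)
            if (
                config.viability_dip > 0
                and 1.4 <= ploidy <= 1.6
                and rng.random() < config.viability_dip
            ):
                continue  # inviable spore, dissect another
            colony = simulate_colony(
                spore,
                rate,
                generations,
                population_cap=config.population_cap,
                rng=rng,
                track_lineages=True,
            )
            if not colony.extinct:
                break
            n_redraws += 1

        cells = colony.sample_cells(config.colonies_per_strain, rng)
        colony_karyotypes = tuple(k for k, _ in cells)
        colony_lineages = tuple(lin for _, lin in cells)
        sampled_branches = {
            _root_branch(colony.lineages, lin)
            for lin in colony_lineages
            if lin != ROOT_LINEAGE
        }
        n_events_total = len(colony.lineages) - 1

        strain_id = f"syn{idx + 1:03d}"
        mean_copies = colony.mean_copy_numbers()
        ct_tables = {
            "population": generate_ct_table(
                mean_copies,
                config.ct_noise_sd,
                config.amplification_efficiency,
                rng=rng,
                sample_id=f"{strain_id}-pop",
            )
        }
        facs_peaks = {
            "population": float(
                generate_facs_peaks(
                    float(mean_copies @ table.weights()),
                    config.facs_cv,
                    1,
                    rng=rng,
                    haploid_peak=haploid_peak,
                )[0]
            )
        }
        for j, karyo in enumerate(colony_karyotypes, start=1):
            name = f"colony{j:02d}"
            ct_tables[name] = generate_ct_table(
                karyo,
                config.ct_noise_sd,
                config.amplification_efficiency,
                rng=rng,
                sample_id=f"{strain_id}-{name}",
            )
            facs_peaks[name] = float(
                generate_facs_peaks(
                    apparent_ploidy(karyo, table),
                    config.facs_cv,
                    1,
                    rng=rng,
                    haploid_peak=haploid_peak,
                )[0]
            )
        control_peaks = generate_facs_peaks(
            1.0, config.facs_cv, 12, rng=rng, haploid_peak=haploid_peak
        )

        strains.append(
            SyntheticStrain(
                strain_id=strain_id,
                true_rate=rate,
                generations=generations,
                seed_karyotype=spore,
                colony_karyotypes=colony_karyotypes,
                colony_lineages=colony_lineages,
                population_mean_copies=mean_copies,
                population_modal_karyotype=colony.modal_karyotype(),
                true_root_events=len(sampled_branches),
                n_events_total=n_events_total,
                n_redraws=n_redraws,
                ct_tables=ct_tables,
                facs_peaks=facs_peaks,
                control_peaks=control_peaks,
                haploid_control_peak=haploid_peak,
            )
        )
    return strains
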