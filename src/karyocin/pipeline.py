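"""End-to-end strain analysis: measurements -> karyotypes -> network -> CIN.

Glues the stages together the way the study design does: every sample of a
strain (population + 11 colonies) is karyotyped by combining its qPCR ratio
profile with its FACS apparent ploidy; the resulting 12-row matrix feeds the
parsimony network reconstruction; the CIN class is read off the root-linked
event count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .calling import KaryotypeCall, call_integer_karyotype
from .chromosomes import ChromosomeTable, default_table
from .karyotype import Karyotype
from .network import (
    CinClassification,
    KaryotypeMatrix,
    KaryotypeNetwork,
    build_network,
    classify_cin,
)
from .synthetic import SyntheticStrain, ratios_from_ct_table

__all__ = ["StrainAnalysis", "analyze_strain", "recovery_accuracy"]


@dataclass(frozen=True)
class StrainAnalysis:
    """Outcome of the full pipeline on one strain."""

    strain_id: str
    calls: tuple[KaryotypeCall, ...]
    networks: tuple[KaryotypeNetwork, ...] | None
    classifications: tuple[CinClassification, ...] | None
    consensus_class: str | None
    verdict: str  # "ok" | "too_heterogeneous"


def analyze_strain(
    strain: SyntheticStrain,
    table: ChromosomeTable | None = None,
    **calling_kwargs,
) -> StrainAnalysis:
    """Run calling + network reconstruction + CIN classification on a strain.

    Sample order is population first, then the colonies; the population row
    roots the network.  If any sample is too heterogeneous to call, the
    strain is excluded (verdict ``"too_heterogeneous"``), mirroring the
    study's handling of uncallable populations.
    """
    table = table or default_table()
    names = ["population"] + [
        f"colony{j:02d}" for j in range(1, len(strain.colony_karyotypes) + 1)
    ]
    calls = []
    for name in names:
        ratios = ratios_from_ct_table(strain.ct_tables[name])
        facs_ploidy = strain.facs_peaks[name] / strain.haploid_control_peak
        calls.append(
            call_integer_karyotype(ratios, facs_ploidy, table, **calling_kwargs)
        )
    if not all(c.ok for c in calls):
        return StrainAnalysis(
            strain.strain_id, tuple(calls), None, None, None, "too_heterogeneous"
        )
    matrix = KaryotypeMatrix(
        rows=tuple(c.karyotype.copies for c in calls),
        root_row=0,
        sample_ids=tuple(names),
    )
    networks = build_network(matrix)
    classifications, consensus = classify_cin(networks)
    return StrainAnalysis(
        strain.strain_id,
        tuple(calls),
        tuple(networks),
        tuple(classifications),
        consensus,
        "ok",
    )


def recovery_accuracy(
    strains: Sequence[SyntheticStrain],
    analyses: Sequence[StrainAnalysis],
) -> float:
    """Fraction of strains whose CIN class matches their true rate.

    A rate-0 strain should come out stable (S); a strain simulated with a
    positive mis-segregation rate should come out MU or HU.  Uncallable
    strains count as errors.
    """
    if len(strains) != len(analyses) or not strains:
        raise ValueError("need matching, non-empty strain/analysis sequences")
    hits = 0
    for strain, analysis in zip(strains, analyses):
        if analysis.verdict != "ok":
            continue
        predicted_stable = analysis.consensus_class == "S"
        truly_stable = strain.true_rate == 0
        hits += predicted_stable == truly_stable
    return hits / len(strains)
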