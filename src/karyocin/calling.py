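"""Karyotype calling from FACS ploidy plus qPCR chromosome stoichiometry.

Flow cytometry gives the total DNA content of a population (apparent ploidy,
relative to a haploid control run in parallel) but not individual chromosome
copy numbers; qPCR gives per-chromosome copy ratios relative to a calibrator
but only up to a global scale.  Combining the two pins down an integer
karyotype: we search for the global scale ``s`` and integer vector ``c``
minimizing the weighted squared mismatch between the scaled ratios and ``c``,
subject to the called karyotype's apparent ploidy agreeing with the FACS
estimate within a tolerance.

The module also classifies ploidy stability of a strain from the coefficient
of variation (CV) of the G1 peak positions of its spore + 11 colonies against
a haploid control processed identically, and bins MAD2:MAD1 qPCR ratios into
the rational classes implied by integer copy numbers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chromosomes import CHROMOSOMES, ChromosomeTable, default_table
from .karyotype import Karyotype, apparent_ploidy

__all__ = [
    "FacsProfile",
    "PloidyStabilityCall",
    "KaryotypeCall",
    "apparent_ploidy_from_facs",
    "relative_ratio_from_ct",
    "delta_delta_ct_ratio",
    "call_integer_karyotype",
    "classify_ploidy_stability",
    "mad_ratio_class",
]


@dataclass(frozen=True)
class FacsProfile:
    """Mode of the G1 peak of a DNA-content profile, with its haploid control."""

    sample_id: str
    g1_peak_position: float
    control_g1_peak: float

    def __post_init__(self) -> None:
        if self.g1_peak_position <= 0 or self.control_g1_peak <= 0:
            raise ValueError("G1 peak positions must be positive")


def apparent_ploidy_from_facs(profile: FacsProfile) -> float:
    """Apparent ploidy = G1 peak position / haploid-control G1 peak."""
    return profile.g1_peak_position / profile.control_g1_peak


def relative_ratio_from_ct(
    sample_ct: float, calibrator_ct: float, amplification_efficiency: float = 2.0
) -> float:
    """Relative template quantity from a Ct difference.

    Returns ``E**(calibrator_ct - sample_ct)`` where ``E`` is the per-cycle
    amplification factor (2.0 = perfect doubling).  Ct values should be
    technical-replicate means.
    """
    if amplification_efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1 fold/cycle")
    return float(amplification_efficiency ** (calibrator_ct - sample_ct))


def delta_delta_ct_ratio(
    target_sample_ct: float,
    target_calibrator_ct: float,
    reference_sample_ct: float,
    reference_calibrator_ct: float,
    amplification_efficiency: float = 2.0,
) -> float:
    """Double-normalized (NRQ / ddCt) relative quantity.

    Target-vs-endogenous-control and sample-vs-calibrator normalizations
    compose multiplicatively; the reference probe cancels loading differences.
    """
    target = relative_ratio_from_ct(
        target_sample_ct, target_calibrator_ct, amplification_efficiency
    )
    reference = relative_ratio_from_ct(
        reference_sample_ct, reference_calibrator_ct, amplification_efficiency
    )
    return target / reference


@dataclass(frozen=True)
class KaryotypeCall:
    """Result of integer karyotype calling.

    ``verdict`` is ``"ok"`` or ``"too_heterogeneous"`` (no integer vector
    matched the FACS ploidy within tolerance; such strains are excluded).
    ``heterogeneous`` flags chromosomes whose scaled ratio sits too far from
    any integer — non-integer population-average copy number.
    """

    karyotype: Karyotype | None
    scale: float | None
    residuals: np.ndarray | None
    heterogeneous: tuple[str, ...]
    verdict: str
    called_ploidy: float | None = None

    @property
    def ok(self) -> bool:
        return self.verdict == "ok"


def call_integer_karyotype(
    ratios: Sequence[float],
    facs_ploidy: float,
    table: ChromosomeTable | None = None,
    *,
    min_copy: int = 1,
    max_copy: int = 3,
    ploidy_tolerance: float = 0.15,
    residual_threshold: float = 0.25,
    ploidy_weight: float = 16.0,
    weights: Sequence[float] | None = None,
) -> KaryotypeCall:
    """Call an integer karyotype from 16 relative ratios and a FACS ploidy.

    Minimizes ``sum_i w_i (s * r_i - c_i)**2 + ploidy_weight *
    (apparent_ploidy(c) - facs_ploidy)**2`` jointly over the scale ``s`` and
    integer copy numbers ``c_i`` in ``[min_copy, max_copy]``, subject to
    ``|apparent_ploidy(c) - facs_ploidy| <= ploidy_tolerance``.  The soft
    ploidy term treats the FACS estimate as a quantitative measurement
    rather than a mere gate: a ploidy error is a genome-averaged copy-number
    error, so by default it is weighted like 16 per-chromosome residuals of
    the same size (``ploidy_weight=16``; set 0 to use the gate alone).
    Given ``c`` the optimal scale is closed-form, and the optimal assignment
    ``c(s)`` is per-chromosome rounding, piecewise constant in ``s``; the
    search therefore visits each rounding breakpoint interval once and is
    exact.

    Calling is invariant to a global rescaling of the ratio profile.
    """
    r = np.asarray(ratios, dtype=float)
    if r.shape != (16,):
        raise ValueError("need exactly 16 chromosome ratios")
    if np.any(r <= 0):
        raise ValueError("stoichiometry ratios must be positive")
    if not (0.5 <= facs_ploidy <= 4.0):
        raise ValueError("apparent ploidy outside plausible range 0.5-4")
    table = table or default_table()
    w = (
        np.ones(16)
        if weights is None
        else np.asarray(weights, dtype=float)
    )

    # Rounding breakpoints of c(s): s = (c + 0.5) / r_i.
    cuts = sorted(
        {
            (c + 0.5) / ri
            for ri in r
            for c in range(min_copy, max_copy)
        }
    )
    lo = min_copy / (2.0 * r.max())  # below: everything clamps to min_copy
    hi = (max_copy + 1.0) / r.min()
    edges = [lo, *[s for s in cuts if lo < s < hi], hi]

    best: tuple[float, np.ndarray, float] | None = None
    for a, b in itertools.pairwise(edges):
        s_mid = 0.5 * (a + b)
        c = np.clip(np.round(s_mid * r), min_copy, max_copy).astype(int)
        ploidy = apparent_ploidy(c, table)
        if abs(ploidy - facs_ploidy) > ploidy_tolerance:
            continue
        # optimal scale for this integer assignment, clamped to its interval
        s_opt = float((w * r * c).sum() / (w * r * r).sum())
        s_opt = min(max(s_opt, a), b)
        cost = float(
            (w * (s_opt * r - c) ** 2).sum()
            + ploidy_weight * (ploidy - facs_ploidy) ** 2
        )
        if best is None or cost < best[0] - 1e-12:
            best = (cost, c, s_opt)

    if best is None:
        return KaryotypeCall(
            karyotype=None,
            scale=None,
            residuals=None,
            heterogeneous=(),
            verdict="too_heterogeneous",
        )

    cost, c, s = best
    residuals = s * r - c
    flagged = tuple(
        CHROMOSOMES[i] for i in range(16) if abs(residuals[i]) >= residual_threshold
    )
    return KaryotypeCall(
        karyotype=Karyotype.from_iterable(c),
        scale=s,
        residuals=residuals,
        heterogeneous=flagged,
        verdict="ok",
        called_ploidy=apparent_ploidy(c, table),
    )


@dataclass(frozen=True)
class PloidyStabilityCall:
    """CV of the 12 strain G1 peaks vs the haploid-control CV."""

    cv_g1: float
    control_cv: float
    verdict: str  # "stable" | "unstable"
    overridden: bool = False

    @property
    def stable(self) -> bool:
        return self.verdict == "stable"


def _cv(values: np.ndarray) -> float:
    return float(values.std(ddof=1) / values.mean())


def classify_ploidy_stability(
    strain_peaks: Sequence[float],
    control_peaks: Sequence[float],
    *,
    tolerance_factor: float = 1.0,
    noisy_profile_override: bool = False,
) -> PloidyStabilityCall:
    """Classify a strain as ploidy stable/unstable from G1 peak variation.

    ``strain_peaks`` are the 12 G1 peak positions (original spore + 11
    colonies); ``control_peaks`` come from haploid colonies processed in
    parallel.  The strain is stable iff its CV is at most
    ``tolerance_factor`` times the control CV.  Strains with obviously
    heterogeneous, noisy DNA profiles are pre-classified unstable via the
    override flag.  The verdict is scale-free (multiplying all peaks by a
    constant changes nothing).
    """
    peaks = np.asarray(strain_peaks, dtype=float)
    control = np.asarray(control_peaks, dtype=float)
    if peaks.size != 12:
        raise ValueError("need exactly 12 strain G1 peaks (spore + 11 colonies)")
    if control.size < 2:
        raise ValueError("need at least 2 control G1 peaks")
    if np.any(peaks <= 0) or np.any(control <= 0):
        raise ValueError("G1 peak positions must be positive")
    cv = _cv(peaks)
    control_cv = _cv(control)
    if noisy_profile_override:
        verdict = "unstable"
    else:
        verdict = "stable" if cv <= control_cv * tolerance_factor else "unstable"
    return PloidyStabilityCall(
        cv_g1=cv,
        control_cv=control_cv,
        verdict=verdict,
        overridden=noisy_profile_override,
    )


#: MAD2:MAD1 ratio classes reachable with gene copy numbers in {1, 2, 3}.
DEFAULT_MAD_RATIO_CLASSES: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)


def mad_ratio_class(
    ratio: float, classes: Sequence[float] = DEFAULT_MAD_RATIO_CLASSES
) -> float:
    """Assign a measured MAD2:MAD1 copy ratio to its nearest rational class."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    classes = sorted(classes)
    return float(min(classes, key=lambda c: (abs(c - ratio), c)))


def mad_ratio_is_half(
    ratio: float, classes: Sequence[float] = DEFAULT_MAD_RATIO_CLASSES
) -> bool:
    """Binary split of MAD2:MAD1 ratios: class 0.5 vs any other class."""
    return mad_ratio_class(ratio, classes) == 0.5
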