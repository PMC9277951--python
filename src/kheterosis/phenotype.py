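"""K+ phenotype handling: content from flame-photometer readings, mid-parent
heterosis (MPH) per hybrid and timepoint, and strong/weak hybrid screening.

MPH(%) = 100 * (F1 - MP) / MP with MP = (P1 + P2) / 2, trait values being
replicate means. K+ content in percent of dry weight is C*V / (G*1e6) * 100
for an assay concentration C (ppm), volume V (mL) and dry weight G (g).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

TRAITS = ("k_content_percent", "biomass")


class PhenotypeError(ValueError):
    """Raised for invalid phenotype inputs or undefined heterosis."""


@dataclass(frozen=True)
class FlamePhotometerReading:
    """One flame-photometer assay: concentration C (ppm), volume V (mL), dry weight G (g)."""

    c_ppm: float
    v_ml: float
    g_dry: float

    def __post_init__(self) -> None:
        if self.c_ppm < 0:
            raise PhenotypeError("K+ concentration must be >= 0")
        if self.v_ml <= 0 or self.g_dry <= 0:
            raise PhenotypeError("volume and dry weight must be positive")


def k_content_percent(reading: FlamePhotometerReading) -> float:
    """K+ content as percent of dry weight: (C*V) / (G*1e6) * 100."""
    return reading.c_ppm * reading.v_ml / (reading.g_dry * 1e6) * 100.0


@dataclass
class PhenotypeRecord:
    """Replicate trait values of one genotype at one timepoint.

    Hybrids carry their parents' genotype names; inbreds leave them ``None``.
    """

    genotype: str
    timepoint: int
    trait: str
    replicate_values: Sequence[float]
    female_parent: str | None = None
    male_parent: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.replicate_values, dtype=float)
        if vals.size < 1:
            raise PhenotypeError(f"{self.genotype!r}: at least one replicate required")
        if self.trait == "k_content_percent" and ((vals < 0) | (vals > 100)).any():
            raise PhenotypeError(f"{self.genotype!r}: K+ content must lie in [0, 100] percent")
        self.replicate_values = vals.tolist()

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_values))

    @property
    def is_hybrid(self) -> bool:
        return self.female_parent is not None and self.male_parent is not None


@dataclass(frozen=True)
class HeterosisResult:
    """Mid-parent heterosis of one hybrid at one timepoint for one trait."""

    hybrid: str
    timepoint: int
    f1_mean: float
    mp: float
    mph_percent: float
    trait: str = "k_content_percent"


def mid_parent_heterosis(
    f1: PhenotypeRecord, p1: PhenotypeRecord, p2: PhenotypeRecord
) -> HeterosisResult:
    """MPH of one hybrid from the trio's records (replicate means first).

    Symmetric in the parents; requires matching trait and timepoint and a
    positive mid-parent mean.
    """
    for other in (p1, p2):
        if other.trait != f1.trait or other.timepoint != f1.timepoint:
            raise PhenotypeError(
                f"trait/timepoint mismatch between {f1.genotype!r} and {other.genotype!r}"
            )
    mp = (p1.mean + p2.mean) / 2.0
    if mp == 0:
        raise PhenotypeError(f"mid-parent mean of {f1.genotype!r} is zero; MPH undefined")
    if mp < 0:
        raise PhenotypeError(f"mid-parent mean of {f1.genotype!r} is negative")
    f1_mean = f1.mean
    return HeterosisResult(
        hybrid=f1.genotype,
        timepoint=f1.timepoint,
        f1_mean=f1_mean,
        mp=mp,
        mph_percent=100.0 * (f1_mean - mp) / mp,
        trait=f1.trait,
    )


def compute_mph(records: Iterable[PhenotypeRecord]) -> list[HeterosisResult]:
    """MPH for every hybrid record whose parents are present at the same
    timepoint and trait. Results ordered by (timepoint, hybrid)."""
    records = list(records)
    by_key = {(r.genotype, r.timepoint, r.trait): r for r in records}
    out: list[HeterosisResult] = []
    for r in records:
        if not r.is_hybrid:
            continue
        p1 = by_key.get((r.female_parent, r.timepoint, r.trait))
        p2 = by_key.get((r.male_parent, r.timepoint, r.trait))
        if p1 is None or p2 is None:
            missing = r.female_parent if p1 is None else r.male_parent
            raise PhenotypeError(
                f"hybrid {r.genotype!r} at day {r.timepoint}: parent {missing!r} has no record"
            )
        out.append(mid_parent_heterosis(r, p1, p2))
    out.sort(key=lambda h: (h.timepoint, h.hybrid))
    return out


def screen_hybrids(
    results: Iterable[HeterosisResult], timepoint: int, trait: str = "k_content_percent"
) -> tuple[str, str]:
    """Strongest and weakest heterosis hybrids at one timepoint for one trait.

    Ties break toward the lexicographically smaller hybrid id.
    """
    at_t = [r for r in results if r.timepoint == timepoint and r.trait == trait]
    if len(at_t) < 2:
        raise PhenotypeError(f"need >= 2 hybrids at timepoint {timepoint}, found {len(at_t)}")
    strongest = min(at_t, key=lambda r: (-r.mph_percent, r.hybrid))
    weakest = min(at_t, key=lambda r: (r.mph_percent, r.hybrid))
    return strongest.hybrid, weakest.hybrid


def one_way_anova_p(records: Sequence[PhenotypeRecord]) -> float:
    """Plain one-way ANOVA p-value across genotypes at one timepoint.

    A convenience check of genotype effect only; this is not the multiple
    range test used in classical K+ field-trial analyses.
    """
    if len(records) < 2:
        raise PhenotypeError("ANOVA needs >= 2 genotypes")
    groups = [np.asarray(r.replicate_values, dtype=float) for r in records]
    return float(stats.f_oneway(*groups).pvalue)
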