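"""Microbial growth, carbon use efficiency and turnover from ¹⁸O-H₂O labeling.

The ¹⁸O-H₂O method estimates microbial growth without adding a carbon
substrate: heavy-oxygen water is traced into newly synthesized DNA over a
short soil incubation.  From the total oxygen content of the DNA extract and
its ¹⁸O enrichment above an unlabeled control, the mass of DNA produced
during the incubation is inferred, converted to biomass carbon via the
sample's MBC/DNA ratio, and combined with the respiration rate measured on
the same incubation to yield carbon use efficiency

    CUE = G / (G + R),

the fraction of total carbon uptake allocated to growth.  Biomass-specific
rates (growth and respiration per unit microbial biomass carbon) and an
annualized biomass turnover rate (the fraction of the DNA pool newly
produced, scaled to a year) complete the chain.

All masses are in µg, soil-normalized quantities per g dry soil, and times
in hours.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: IUPAC 2021 standard atomic weights for the elements of DNA.
ATOMIC_WEIGHTS: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "P": 30.974,
    "S": 32.06,
}

#: Average elemental formula of DNA used to derive the oxygen mass fraction.
DNA_AVERAGE_FORMULA: dict[str, int] = {"C": 39, "H": 44, "O": 24, "N": 15, "P": 4}

#: Conventional oxygen mass percentage of DNA (from the average formula
#: C39H44O24N15P4); :func:`dna_oxygen_fraction` validates this constant.
DNA_OXYGEN_MASS_PERCENT: float = 31.21

#: Hours per year, used to annualize biomass turnover.
HOURS_PER_YEAR: float = 24.0 * 365.0


class InvalidLabelError(ValueError):
    """Raised when the soil-water ¹⁸O label enrichment is not positive."""


def dna_oxygen_fraction(formula: Mapping[str, int | float]) -> float:
    """Oxygen mass percentage of a molecule given its elemental formula.

    Parameters
    ----------
    formula
        Mapping of element symbol to atom count, e.g.
        ``{"C": 39, "H": 44, "O": 24, "N": 15, "P": 4}``.

    Returns
    -------
    float
        ``100 * mass(O) / mass(total)`` using standard atomic weights.
    """
    if not formula:
        raise ValueError("empty formula")
    total = 0.0
    oxygen = 0.0
    for element, count in formula.items():
        try:
            weight = ATOMIC_WEIGHTS[element]
        except KeyError:
            raise ValueError(f"unknown element symbol: {element!r}") from None
        if count < 0:
            raise ValueError(f"negative atom count for {element}")
        total += weight * count
        if element == "O":
            oxygen = weight * count
    if total == 0:
        raise ValueError("formula has zero total mass")
    return 100.0 * oxygen / total


def dna_produced(o_total: float, atpct_excess: float, atpct_label: float) -> float:
    """Mass of DNA (µg) newly produced during the incubation.

    ``o_total`` is the total oxygen content of the DNA extract (µg),
    ``atpct_excess`` the at% ¹⁸O enrichment of the labeled DNA above its
    paired control, and ``atpct_label`` the at% ¹⁸O of the final soil water.
    The 31.21 divisor is the oxygen mass percentage of average DNA.

    A negative excess (control above label) is instrument noise, not
    negative growth: it is clamped to zero with a logged warning.
    """
    if atpct_label <= 0:
        raise InvalidLabelError(f"atpct_label must be > 0, got {atpct_label}")
    if o_total < 0:
        raise ValueError(f"o_total must be >= 0, got {o_total}")
    if atpct_excess < 0:
        logger.warning(
            "negative at%% excess (%.4g) clamped to 0 (control above label)",
            atpct_excess,
        )
        atpct_excess = 0.0
    return (
        o_total
        * (atpct_excess / 100.0)
        * (100.0 / atpct_label)
        * (100.0 / DNA_OXYGEN_MASS_PERCENT)
    )


@dataclass(frozen=True)
class LabelingSample:
    """One incubation unit's isotope, biomass and respiration measurements.

    Attributes
    ----------
    sample_id : str
        Unique sample identifier; the labeled vial and its unlabeled control
        are paired under one id.
    o_total : float
        Total O in the DNA extract (µg).
    atpct_labeled, atpct_control : float
        at% ¹⁸O of the labeled-sample DNA and of the paired unlabeled
        control (natural abundance ≈ 0.2 at%).
    atpct_label_water : float
        at% ¹⁸O of the final soil water (nominal 20).
    t_hours : float
        Incubation duration (h).
    mbc : float
        Microbial biomass carbon (µg C g⁻¹ dry soil).
    dna_content : float
        Soil DNA content (µg g⁻¹ dry soil).
    respiration : float
        Respiration rate (µg C g⁻¹ dry soil h⁻¹).
    """

    sample_id: str
    o_total: float
    atpct_labeled: float
    atpct_control: float
    atpct_label_water: float
    t_hours: float
    mbc: float
    dna_content: float
    respiration: float

    def __post_init__(self) -> None:
        if self.o_total < 0:
            raise ValueError(f"{self.sample_id}: o_total must be >= 0")
        if self.t_hours <= 0:
            raise ValueError(f"{self.sample_id}: t_hours must be > 0")
        if self.mbc <= 0:
            raise ValueError(f"{self.sample_id}: mbc must be > 0")
        if self.dna_content <= 0:
            raise ValueError(f"{self.sample_id}: dna_content must be > 0")
        if self.respiration < 0:
            raise ValueError(f"{self.sample_id}: respiration must be >= 0")
        if self.atpct_control < 0:
            raise ValueError(f"{self.sample_id}: atpct_control must be >= 0")
        if self.atpct_label_water <= self.atpct_control:
            raise ValueError(
                f"{self.sample_id}: label water at% must exceed control at%"
            )

    @property
    def atpct_excess(self) -> float:
        """at% ¹⁸O enrichment of labeled DNA above its paired control."""
        return self.atpct_labeled - self.atpct_control


@dataclass(frozen=True)
class CueResult:
    """Derived metabolic quantities for one sample.

    ``cue`` is NaN when growth and respiration are both zero (0/0 is
    reported as missing, never as 0).  ``error`` carries the reason when a
    sample could not be processed; all numeric fields are then NaN.
    """

    sample_id: str
    dna_produced: float = math.nan  # µg DNA g⁻¹ dry soil
    f_dna: float = math.nan  # µg C per µg DNA
    growth: float = math.nan  # µg C g⁻¹ dry soil h⁻¹
    respiration: float = math.nan  # µg C g⁻¹ dry soil h⁻¹
    cue: float = math.nan  # dimensionless, [0, 1)
    rm: float = math.nan  # h⁻¹
    gm: float = math.nan  # h⁻¹
    mtr: float = math.nan  # yr⁻¹
    error: str | None = field(default=None, compare=False)


#: Column order for CueResult tables written to disk.
CUE_RESULT_COLUMNS = [
    "sample_id",
    "dna_produced",
    "f_dna",
    "growth",
    "respiration",
    "cue",
    "rm",
    "gm",
    "mtr",
]


def compute_cue(sample: LabelingSample) -> CueResult:
    """Run the full calculation chain for one sample.

    DNA produced is inferred from the isotope measurements; the MBC/DNA
    ratio converts it to biomass carbon; growth is the hourly rate over the
    incubation; CUE = growth / (growth + respiration); biomass-specific
    respiration and growth divide by MBC; the turnover rate annualizes the
    fraction of the DNA pool newly produced.
    """
    # O in the extract is assumed proportional to soil DNA, so the produced
    # DNA mass is already per g dry soil.
    dnap = dna_produced(sample.o_total, sample.atpct_excess, sample.atpct_label_water)
    f_dna = sample.mbc / sample.dna_content
    growth = f_dna * dnap / sample.t_hours
    denom = growth + sample.respiration
    cue = growth / denom if denom > 0 else math.nan
    rm = sample.respiration / sample.mbc
    gm = growth / sample.mbc
    mtr = dnap * HOURS_PER_YEAR / (sample.dna_content * sample.t_hours)
    return CueResult(
        sample_id=sample.sample_id,
        dna_produced=dnap,
        f_dna=f_dna,
        growth=growth,
        respiration=sample.respiration,
        cue=cue,
        rm=rm,
        gm=gm,
        mtr=mtr,
    )


def compute_cue_table(samples: Iterable[LabelingSample]) -> list[CueResult]:
    """Order-preserving :func:`compute_cue` over many samples.

    Per-sample failures are recorded on the result (``error`` field, NaN
    values) and logged, never fatal.  Duplicate sample ids are an error.
    """
    samples = list(samples)
    ids = [s.sample_id for s in samples]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate sample_id(s): {sorted(dupes)}")
    results: list[CueResult] = []
    for sample in samples:
        try:
            results.append(compute_cue(sample))
        except Exception as exc:  # noqa: BLE001 - per-row isolation contract
            logger.warning("sample %s failed: %s", sample.sample_id, exc)
            results.append(CueResult(sample_id=sample.sample_id, error=str(exc)))
    return results


def results_frame(results: Iterable[CueResult]) -> pd.DataFrame:
    """CueResult list as a DataFrame with deterministic column order."""
    rows = [{c: getattr(r, c) for c in CUE_RESULT_COLUMNS} for r in results]
    return pd.DataFrame(rows, columns=CUE_RESULT_COLUMNS)
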