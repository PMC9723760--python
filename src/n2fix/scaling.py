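"""qPCR censoring and scaling of symbiont-specific rates to volumetric rates.

nifH gene copies l^-1 from qPCR are censored against assay detection (LOD) and
quantitation (LOQ) limits, converted to cells l^-1 through a copies-per-cell
convention (1 for the UCYN-A1 symbiosis, 10 for UCYN-A2), and multiplied by the
measured single-cell rate to give each group's volumetric N2-fixation rate and
its percent contribution to the bulk community rate. Uncertainties propagate by
first-order product/quotient rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .isotope import BDL, DNQ, QUANTIFIED
from .single_cell import DEFAULT_DILUTION_FRACTION, dilution_correct

__all__ = [
    "QpcrMeasurement",
    "CopyNumberConvention",
    "GroupContribution",
    "censor_qpcr",
    "cells_from_nifh",
    "volumetric_group_nfr",
    "contribution_percent",
    "propagate_sd_product_quotient",
    "group_contribution",
]

#: Diazotroph groups targeted by the qPCR assays.
GROUPS = ("UCYN-A1", "UCYN-A2", "UCYN-B", "Trichodesmium", "Het-2", "gammaA")

#: fmol cell^-1 d^-1 * cells l^-1 -> nmol l^-1 d^-1
_FMOL_TO_NMOL = 1e-6


def censor_qpcr(copies: float, lod: float, loq: float) -> str:
    """Three-way censoring of a qPCR result.

    <= LOD is below detection (BDL); above LOD but below LOQ is detected, not
    quantified (DNQ); at or above LOQ is quantified.
    """
    if copies < 0:
        raise ValueError(f"copies must be >= 0, got {copies}")
    if not lod < loq:
        raise ValueError(f"need lod < loq, got lod={lod}, loq={loq}")
    if copies <= lod:
        return BDL
    if copies < loq:
        return DNQ
    return QUANTIFIED


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR assay x sample: nifH copies l^-1 with assay limits."""

    group: str
    copies_per_l: float
    sd: float = 0.0
    lod: float = 25.0
    loq: float = 200.0
    status: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        status = censor_qpcr(self.copies_per_l, self.lod, self.loq)
        if self.status and self.status != status:
            raise ValueError(
                f"declared status {self.status!r} inconsistent with copies/LOD/LOQ "
                f"({status!r})"
            )
        object.__setattr__(self, "status", status)


@dataclass(frozen=True)
class CopyNumberConvention:
    """nifH copies per cell, per group.

    Default 1 copy cell^-1 except the UCYN-A2 symbiosis at 10 (the high end of
    the reported polyploidy range; configurable).
    """

    copies_per_cell: dict[str, int] = field(
        default_factory=lambda: {"UCYN-A1": 1, "UCYN-A2": 10}
    )

    def __post_init__(self) -> None:
        for g, c in self.copies_per_cell.items():
            if int(c) != c or c < 1:
                raise ValueError(f"copies per cell must be a positive integer ({g}: {c})")

    def for_group(self, group: str) -> int:
        return int(self.copies_per_cell.get(group, 1))


@dataclass(frozen=True)
class GroupContribution:
    """One diazotroph group at one station: volumetric rate and % of bulk.

    All rates nmol N l^-1 d^-1; ``contribution_pct`` may exceed 100 when the
    scaled group rate overshoots the measured bulk rate. ``bulk_is_lod`` marks
    stations where the bulk rate was BDL and its LOD was used as denominator.
    """

    group: str
    cells_per_l: float
    volumetric_rate: float
    contribution_pct: float
    max_volumetric_rate: float
    max_contribution_pct: float
    volumetric_rate_sd: float = float("nan")
    contribution_pct_sd: float = float("nan")
    bulk_is_lod: bool = False


def cells_from_nifh(copies_per_l: float,
                    convention: CopyNumberConvention | int = 1,
                    group: str | None = None) -> float:
    """Cells l^-1 from nifH copies l^-1 under a copies-per-cell convention."""
    if copies_per_l < 0:
        raise ValueError("copies must be >= 0")
    if isinstance(convention, CopyNumberConvention):
        if group is None:
            raise ValueError("group required when passing a CopyNumberConvention")
        per_cell = convention.for_group(group)
    else:
        per_cell = int(convention)
        if per_cell < 1:
            raise ValueError("copies per cell must be >= 1")
    return copies_per_l / per_cell


def volumetric_group_nfr(single_cell_rate: float, cells_per_l: float) -> float:
    """Volumetric group rate (nmol N l^-1 d^-1) = per-cell rate x abundance."""
    if single_cell_rate < 0 or cells_per_l < 0:
        raise ValueError("inputs must be >= 0")
    return single_cell_rate * cells_per_l * _FMOL_TO_NMOL


def contribution_percent(group_rate: float, bulk_rate: float,
                         bulk_lod: float | None = None) -> float:
    """Group rate as percent of the bulk community rate.

    When the bulk rate is non-positive (BDL) the bulk LOD is used instead, if
    provided; the result is then an upper-bound style figure and callers should
    flag it.
    """
    if bulk_rate <= 0:
        if bulk_lod is None or bulk_lod <= 0:
            raise ValueError("bulk rate <= 0 and no usable LOD supplied")
        bulk_rate = bulk_lod
    return 100.0 * group_rate / bulk_rate


def propagate_sd_product_quotient(values, sds) -> float:
    """First-order SD of a product/quotient of independent terms.

    relative SD of the result = sqrt(sum of squared relative SDs); the caller
    multiplies by the result's magnitude. Returns the *relative* SD.
    """
    values = list(values)
    sds = list(sds)
    if len(values) != len(sds):
        raise ValueError("values and sds must have equal length")
    total = 0.0
    for v, s in zip(values, sds):
        if s < 0:
            raise ValueError("SDs must be >= 0")
        if v <= 0:
            if s == 0:
                continue
            raise ValueError(f"non-positive value {v} with nonzero SD {s}")
        total += (s / v) ** 2
    return math.sqrt(total)


def group_contribution(group: str,
                       single_cell_rate: float,
                       copies_per_l: float,
                       bulk_rate: float,
                       *,
                       single_cell_sd: float = 0.0,
                       copies_sd: float = 0.0,
                       bulk_sd: float = 0.0,
                       bulk_lod: float | None = None,
                       convention: CopyNumberConvention | None = None,
                       dilution_fraction: float = DEFAULT_DILUTION_FRACTION,
                       ) -> GroupContribution:
    """Full scaling chain for one group x station.

    Combines copies->cells, volumetric scaling, percent contribution, the
    dilution-corrected maxima and first-order propagated SDs into one record.
    """
    convention = convention or CopyNumberConvention()
    cells = cells_from_nifh(copies_per_l, convention, group=group)
    vol = volumetric_group_nfr(single_cell_rate, cells)
    bulk_is_lod = bulk_rate <= 0
    contrib = contribution_percent(vol, bulk_rate, bulk_lod=bulk_lod)
    max_rate = dilution_correct(single_cell_rate, dilution_fraction)
    max_vol = volumetric_group_nfr(max_rate, cells)
    max_contrib = contribution_percent(max_vol, bulk_rate, bulk_lod=bulk_lod)

    if single_cell_rate > 0 and copies_per_l > 0:
        rel_vol = propagate_sd_product_quotient(
            [single_cell_rate, copies_per_l], [single_cell_sd, copies_sd])
        vol_sd = vol * rel_vol
        denom = bulk_rate if not bulk_is_lod else (bulk_lod or float("nan"))
        rel_contrib = math.sqrt(rel_vol ** 2 + (bulk_sd / denom) ** 2) \
            if denom and denom > 0 else float("nan")
        contrib_sd = contrib * rel_contrib
    else:
        vol_sd = contrib_sd = 0.0

    return GroupContribution(
        group=group, cells_per_l=cells, volumetric_rate=vol,
        contribution_pct=contrib, max_volumetric_rate=max_vol,
        max_contribution_pct=max_contrib, volumetric_rate_sd=vol_sd,
        contribution_pct_sd=contrib_sd, bulk_is_lod=bulk_is_lod,
    )
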