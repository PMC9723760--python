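"""Isotope bookkeeping and bulk-community N2-fixation rates from 15N2-tracer incubations.

The central quantity is the atom% 15N of a nitrogen pool, A = 100 * 15N / (15N + 14N).
A tracer incubation enriches the dissolved-N2 source pool above natural abundance
(~0.3663 atom%); transfer of label into particulate nitrogen (PN) over the incubation
gives the volumetric N2-fixation rate through a two-pool isotope mass balance:

    rate = (A_PN_final - A_PN_t0) / (A_N2 - A_PN_t0) * [PN] / dt

Detection limits follow the convention of substituting a multiple of the analytical
standard deviation of reference (unenriched) atom% measurements for the observed
enrichment: the limit of detection (LOD) uses k_lod * sd, the minimum quantifiable
rate (MQR) uses k_mqr * sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "NATURAL_ABUNDANCE_ATOM_PCT",
    "IsotopeRatio",
    "TracerEnrichment",
    "BulkIncubation",
    "RateResult",
    "atom_percent_from_ratio",
    "ratio_from_atom_percent",
    "mix_source_pool",
    "bulk_nfr",
    "nfr_detection_limits",
]

#: Atom% 15N of atmospheric N2 (standard air), the default unenriched baseline.
NATURAL_ABUNDANCE_ATOM_PCT = 0.3663

#: Status labels shared across the package.
QUANTIFIED = "quantified"
DNQ = "DNQ"  # detected, not quantified: between LOD and MQR/LOQ
BDL = "BDL"  # below detection limit


@dataclass(frozen=True)
class IsotopeRatio:
    """A heavy-to-light isotope count ratio (15N/14N), dimensionless, >= 0."""

    r: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"isotope ratio must be >= 0, got {self.r}")

    @property
    def atom_percent(self) -> float:
        return atom_percent_from_ratio(self.r)


@dataclass(frozen=True)
class TracerEnrichment:
    """Composition of the incubation's dissolved-N2 source pool.

    A known volume of 15N2-enriched seawater (``v_enriched`` litres at
    ``a_enriched`` atom%) is added to ambient seawater (``v_ambient`` litres at
    natural abundance unless stated). Mixing is volume-weighted, assuming equal
    dissolved-N2 concentration per litre in both waters.
    """

    a_enriched: float
    v_enriched: float
    v_ambient: float
    a_ambient: float = NATURAL_ABUNDANCE_ATOM_PCT

    def __post_init__(self) -> None:
        if self.v_enriched < 0 or self.v_ambient <= 0:
            raise ValueError("volumes must be positive (v_enriched may be 0)")
        for name in ("a_enriched", "a_ambient"):
            a = getattr(self, name)
            if not 0.0 <= a <= 100.0:
                raise ValueError(f"{name} must be in [0, 100] atom%, got {a}")


@dataclass(frozen=True)
class BulkIncubation:
    """One bulk 15N2 incubation: start/end PN atom%, source pool, PN, duration.

    Units: atom% in percent; ``pn_conc`` in umol N l^-1; ``duration`` in days;
    ``sd_a_pn_ref`` is the SD of replicate reference (t0) atom% measurements and
    drives the detection limits.
    """

    a_pn_t0: float
    a_pn_final: float
    a_n2: float
    pn_conc: float
    duration: float
    sd_a_pn_ref: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("incubation duration must be > 0")
        if self.pn_conc <= 0:
            raise ValueError("PN concentration must be > 0")
        if self.sd_a_pn_ref < 0:
            raise ValueError("sd_a_pn_ref must be >= 0")


@dataclass(frozen=True)
class RateResult:
    """A volumetric rate with its detection limits and censoring status.

    ``rate`` is the reported rate (0 for BDL), ``raw_rate`` the signed
    mass-balance value kept for diagnostics; all in nmol N l^-1 d^-1.
    """

    rate: float
    lod: float
    mqr: float
    status: str
    raw_rate: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.lod > self.mqr:
            raise ValueError("LOD must not exceed MQR")


def atom_percent_from_ratio(r: float | IsotopeRatio) -> float:
    """Convert a 15N/14N count ratio to atom% 15N, ``100 r / (1 + r)``."""
    if isinstance(r, IsotopeRatio):
        r = r.r
    if r < 0:
        raise ValueError(f"isotope ratio must be >= 0, got {r}")
    return 100.0 * r / (1.0 + r)


def ratio_from_atom_percent(a: float) -> float:
    """Inverse of :func:`atom_percent_from_ratio`: ``a / (100 - a)``."""
    if not 0.0 <= a < 100.0:
        raise ValueError(f"atom% must be in [0, 100), got {a}")
    return a / (100.0 - a)


def mix_source_pool(t: TracerEnrichment) -> float:
    """Atom% 15N of the mixed dissolved-N2 source pool (volume-weighted mean)."""
    total = t.v_enriched + t.v_ambient
    if total <= 0:
        raise ValueError("total volume must be > 0")
    return (t.v_enriched * t.a_enriched + t.v_ambient * t.a_ambient) / total


def _mass_balance_rate(a_t0: float, a_final: float, a_n2: float,
                       pn_conc: float, duration: float) -> float:
    """Signed mass-balance rate in nmol N l^-1 d^-1 (PN given in umol N l^-1)."""
    if a_n2 <= a_t0:
        raise ValueError(
            f"source pool atom% ({a_n2}) must exceed t0 atom% ({a_t0}); "
            "rate is undefined otherwise"
        )
    return (a_final - a_t0) / (a_n2 - a_t0) * pn_conc / duration * 1000.0


def nfr_detection_limits(b: BulkIncubation, k_lod: float = 3.0,
                         k_mqr: float = 10.0) -> tuple[float, float]:
    """LOD and MQR in nmol N l^-1 d^-1.

    Each limit is the rate produced by an enrichment of ``k * sd_a_pn_ref``
    above the t0 atom%; both scale linearly with the reference SD and with PN.
    """
    if not 0 < k_lod <= k_mqr:
        raise ValueError("need k_mqr >= k_lod > 0")
    lod = _mass_balance_rate(b.a_pn_t0, b.a_pn_t0 + k_lod * b.sd_a_pn_ref,
                             b.a_n2, b.pn_conc, b.duration)
    mqr = _mass_balance_rate(b.a_pn_t0, b.a_pn_t0 + k_mqr * b.sd_a_pn_ref,
                             b.a_n2, b.pn_conc, b.duration)
    return lod, mqr


def bulk_nfr(b: BulkIncubation, k_lod: float = 3.0, k_mqr: float = 10.0) -> RateResult:
    """Bulk-community N2-fixation rate for one incubation, with censoring.

    Status is ``quantified`` at or above the MQR, ``DNQ`` between LOD and MQR,
    and ``BDL`` below the LOD. A final atom% below the t0 atom% (negative
    apparent enrichment) is reported as BDL with rate 0; the signed value is
    kept in ``raw_rate``.
    """
    raw = _mass_balance_rate(b.a_pn_t0, b.a_pn_final, b.a_n2,
                             b.pn_conc, b.duration)
    lod, mqr = nfr_detection_limits(b, k_lod=k_lod, k_mqr=k_mqr)
    if raw < 0:
        return RateResult(rate=0.0, lod=lod, mqr=mqr, status=BDL, raw_rate=raw)
    if raw < lod or raw == 0.0:
        status = BDL
    elif raw < mqr:
        status = DNQ
    else:
        status = QUANTIFIED
    return RateResult(rate=raw, lod=lod, mqr=mqr, status=status, raw_rate=raw)
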