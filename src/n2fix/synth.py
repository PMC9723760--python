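"""Seeded generator of synthetic survey datasets.

Emulates the data structure of a two-cruise coastal N2-fixation survey so the whole
analysis chain can be exercised and parameter recovery asserted without field data:

* hydrochemistry profiles (logistic nitracline, surface-warm temperature profile,
  chlorophyll maximum) — realism only, nothing is inferred from them;
* bulk 15N2 incubations, produced by forward-running the isotope mass balance from
  known true rates and adding Gaussian IRMS noise to the atom% measurements;
* nanoSIMS regions of interest with Poisson/binomial ion-count noise at known true
  per-cell rates, including unenriched reference cells;
* qPCR nifH abundances: correlated lognormal marginals for the two UCYN-A
  symbioses through a Gaussian copula (default Spearman rank correlation 0.71),
  multiplicative lognormal assay noise, and LOD/LOQ censoring.

Every table draws from its own RNG stream split from the master seed, so adding a
table never perturbs the others; the same seed yields byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotope import NATURAL_ABUNDANCE_ATOM_PCT, TracerEnrichment, mix_source_pool
from .scaling import censor_qpcr
from .single_cell import QuotaModel, cell_n_quota

__all__ = ["SurveyDesign", "generate_survey", "generate_nanosims_rois",
           "spearman_to_pearson"]

#: Biovolume ranges (um^3) per group and partner; chosen so whole-symbiosis N
#: quotas under the default QuotaModel fall inside the observed ranges
#: (2.6-27.7 fmol N for UCYN-A1, 49.3-159.8 fmol N for UCYN-A2 symbioses).
BIOVOLUME_RANGES = {
    "UCYN-A1": {"symbiont": (0.3, 1.0), "host": (2.0, 8.0)},
    "UCYN-A2": {"symbiont": (2.0, 5.0), "host": (20.0, 50.0)},
}


@dataclass(frozen=True)
class SurveyDesign:
    """Study design and true parameter field for one synthetic survey.

    Defaults follow the magnitudes of the emulated survey: surface bulk rates of
    a few nmol N l^-1 d^-1 decaying with depth, single-cell rates of ~6.6 (A1)
    and ~151 (A2) fmol N cell^-1 d^-1, lognormal nifH abundances around 1e5-1e6
    copies l^-1 with rank correlation 0.71 between the two symbioses, IRMS atom%
    SD 0.0005, 1e5 ion counts per ROI, 10% qPCR CV.
    """

    n_stations: int = 8
    depths: tuple[float, ...] = (2.0, 10.0, 30.0)
    # true bulk rate field: lognormal surface rate, exponential depth decay
    bulk_rate_log_mean: float = math.log(6.0)
    bulk_rate_log_sd: float = 0.6
    bulk_depth_scale_m: float = 40.0
    # true single-cell whole-symbiosis rates (fmol N cell^-1 d^-1)
    cell_rate_mean: dict = field(default_factory=lambda: {
        "UCYN-A1": 6.6, "UCYN-A2": 151.1})
    cell_rate_cv: float = 0.5
    symbiont_rate_share: float = 0.8  # fraction of symbiosis rate fixed in the symbiont
    n_associations: int = 6
    # abundances: lognormal log-mean/log-sd per group (natural log, copies l^-1)
    abundance_log_mean: dict = field(default_factory=lambda: {
        "UCYN-A1": math.log(3.0e5), "UCYN-A2": math.log(8.0e4),
        "Het-2": math.log(6.0e2), "Trichodesmium": math.log(60.0),
        "UCYN-B": math.log(25.0), "gammaA": math.log(2.0e2)})
    abundance_log_sd: dict = field(default_factory=lambda: {
        "UCYN-A1": 1.2, "UCYN-A2": 1.0, "Het-2": 1.5,
        "Trichodesmium": 1.5, "UCYN-B": 1.2, "gammaA": 1.8})
    rank_correlation: float = 0.71  # UCYN-A1 vs UCYN-A2 (Spearman)
    # assay / instrument noise
    irms_atom_pct_sd: float = 0.0005
    nanosims_counts_per_roi: float = 1.0e5
    qpcr_cv: float = 0.10
    qpcr_lod: float = 25.0
    qpcr_loq: float = 200.0
    # incubation setup
    pn_umol_l: float = 1.0
    duration_d: float = 1.0
    enriched_atom_pct: float = 15.0
    v_enriched_l: float = 0.1
    v_ambient_l: float = 1.1
    # when True, the true bulk rate equals the sum of the group volumetric rates
    bulk_from_groups: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rank_correlation <= 1.0:
            raise ValueError("rank correlation must be in [-1, 1]")
        for name in ("irms_atom_pct_sd", "qpcr_cv", "cell_rate_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nanosims_counts_per_roi <= 0:
            raise ValueError("nanosims_counts_per_roi must be > 0")
        if not 0.0 <= self.symbiont_rate_share <= 1.0:
            raise ValueError("symbiont_rate_share must be in [0, 1]")

    @property
    def source_pool_atom_pct(self) -> float:
        return mix_source_pool(TracerEnrichment(
            a_enriched=self.enriched_atom_pct, v_enriched=self.v_enriched_l,
            v_ambient=self.v_ambient_l))


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of the Gaussian copula that yields Spearman ``rho_s``.

    For a bivariate normal, rho_s = (6/pi) asin(r/2); inverted: r = 2 sin(pi rho_s / 6).
    """
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_nanosims_rois(true_atom_pct: float, total_counts: float, n_rois: int,
                           seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Simulate nanoSIMS ROI isotope measurements by binomial count statistics.

    Each ROI accumulates ``total_counts`` nitrogen ion counts (Poisson-varied
    around the target); heavy (15N) counts are binomial with the true atom
    fraction. Returns a frame with heavy/light counts, the measured 15N/14N
    ratio, and the derived atom%.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be > 0")
    if not 0.0 <= true_atom_pct < 100.0:
        raise ValueError("true_atom_pct must be in [0, 100)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    totals = rng.poisson(total_counts, size=n_rois).astype(np.int64)
    totals = np.maximum(totals, 1)
    heavy = rng.binomial(totals, true_atom_pct / 100.0)
    light = totals - heavy
    ratio = np.where(light > 0, heavy / np.maximum(light, 1), np.inf)
    atom_pct = 100.0 * heavy / totals
    return pd.DataFrame({
        "total_counts": totals, "heavy_counts": heavy,
        "r15_14": ratio, "atom_pct": atom_pct,
    })


def _atom_pct_for_rate(rate: float, quota: float, a_n2: float, a_t0: float,
                       duration: float) -> float:
    """Invert the per-cell mass balance: final atom% producing ``rate``."""
    return a_t0 + rate * duration / quota * (a_n2 - a_t0)


def _hydro_table(design: SurveyDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    sample_depths = (2.0, 10.0, 20.0, 30.0, 50.0, 75.0, 100.0, 150.0)
    for s in range(1, design.n_stations + 1):
        z_nit = rng.uniform(15.0, 45.0)  # nitracline depth
        t_surf = rng.uniform(14.0, 21.0)
        deep_no3 = rng.uniform(10.0, 25.0)
        p_offset = rng.uniform(0.0, 0.15)  # excess phosphate
        for z in sample_depths:
            nit = deep_no3 / (1.0 + math.exp(-(z - z_nit) / 8.0))
            po4 = nit / 16.0 + p_offset
            temp = t_surf - 6.0 / (1.0 + math.exp(-(z - z_nit) / 10.0))
            chl = 0.2 + 1.5 * math.exp(-0.5 * ((z - z_nit) / 10.0) ** 2)
            rows.append({
                "cruise": "SYN1", "station": str(s), "depth_m": z,
                "temp_c": round(temp, 3), "salinity": round(33.4 + rng.normal(0, 0.05), 3),
                "no3no2_umol_l": round(nit, 4), "po4_umol_l": round(po4, 4),
                "chl_ug_l": round(chl, 4),
            })
    return pd.DataFrame(rows)


def _true_rate_field(design: SurveyDesign, rng: np.random.Generator) -> dict:
    """True bulk surface rate per station (nmol N l^-1 d^-1)."""
    surf = np.exp(rng.normal(design.bulk_rate_log_mean, design.bulk_rate_log_sd,
                             size=design.n_stations))
    return {str(s + 1): float(surf[s]) for s in range(design.n_stations)}


def _qpcr_tables(design: SurveyDesign, rng: np.random.Generator,
                 stations_depths) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(stations_depths)
    r = spearman_to_pearson(design.rank_correlation)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    copies = {}
    for j, g in enumerate(("UCYN-A1", "UCYN-A2")):
        copies[g] = np.exp(design.abundance_log_mean[g]
                           + design.abundance_log_sd[g] * z[:, j])
    for g in ("Het-2", "Trichodesmium", "UCYN-B", "gammaA"):
        copies[g] = np.exp(rng.normal(design.abundance_log_mean[g],
                                      design.abundance_log_sd[g], size=n))
    rows, truth_rows = [], []
    for i, (station, depth) in enumerate(stations_depths):
        for g, vals in copies.items():
            true = float(vals[i])
            eps = rng.normal()
            measured = true * math.exp(design.qpcr_cv * eps
                                       - design.qpcr_cv ** 2 / 2.0)
            status = censor_qpcr(measured, design.qpcr_lod, design.qpcr_loq)
            rows.append({
                "cruise": "SYN1", "station": station, "depth_m": depth,
                "group": g, "copies_per_l": measured,
                "sd": design.qpcr_cv * measured,
                "lod": design.qpcr_lod, "loq": design.qpcr_loq,
                "status": status,
            })
            truth_rows.append({"station": station, "depth_m": depth,
                               "group": g, "true_copies_per_l": true})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def _incubation_tables(design: SurveyDesign, rng: np.random.Generator,
                       true_surface: dict,
                       group_volumetric: pd.DataFrame | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    a0 = NATURAL_ABUNDANCE_ATOM_PCT
    a_n2 = design.source_pool_atom_pct
    rows, truth_rows = [], []
    for s in range(1, design.n_stations + 1):
        st = str(s)
        for z in design.depths:
            if design.bulk_from_groups and group_volumetric is not None:
                sel = group_volumetric[(group_volumetric.station == st)
                                       & (group_volumetric.depth_m == z)]
                rate = float(sel.true_volumetric_nmol_l_d.sum())
            else:
                rate = true_surface[st] * math.exp(-z / design.bulk_depth_scale_m)
            af_true = a0 + rate * design.duration_d / (1000.0 * design.pn_umol_l) \
                * (a_n2 - a0)
            af = af_true + rng.normal(0.0, design.irms_atom_pct_sd)
            a0_meas = a0 + rng.normal(0.0, design.irms_atom_pct_sd)
            rows.append({
                "cruise": "SYN1", "station": st, "depth_m": z,
                "a_pn_t0_pct": a0_meas, "a_pn_final_pct": af,
                "a_enriched_pct": design.enriched_atom_pct,
                "v_enriched_l": design.v_enriched_l,
                "v_ambient_l": design.v_ambient_l,
                "pn_umol_l": design.pn_umol_l,
                "duration_d": design.duration_d,
                "sd_ref_pct": design.irms_atom_pct_sd,
            })
            truth_rows.append({"station": st, "depth_m": z,
                               "true_bulk_nmol_l_d": rate})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def _nanosims_tables(design: SurveyDesign, rng: np.random.Generator,
                     quota_model: QuotaModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    a0 = NATURAL_ABUNDANCE_ATOM_PCT
    a_n2 = design.source_pool_atom_pct
    rows, truth_rows = [], []
    stations = [str(s) for s in range(1, min(design.n_stations, 3) + 1)]
    for st in stations:
        for group, ranges in BIOVOLUME_RANGES.items():
            mean_rate = design.cell_rate_mean[group]
            for k in range(design.n_associations):
                assoc = f"{st}-{group}-{k}"
                total_rate = max(rng.normal(
                    mean_rate, design.cell_rate_cv * mean_rate), 0.05 * mean_rate)
                shares = {"symbiont": design.symbiont_rate_share,
                          "host": 1.0 - design.symbiont_rate_share}
                for partner, (lo, hi) in ranges.items():
                    biovol = rng.uniform(lo, hi)
                    quota = cell_n_quota(biovol, quota_model)
                    a_true = _atom_pct_for_rate(total_rate * shares[partner],
                                                quota, a_n2, a0, design.duration_d)
                    roi = generate_nanosims_rois(
                        a_true, design.nanosims_counts_per_roi, 1, seed=rng)
                    rows.append({
                        "cruise": "SYN1", "station": st, "group": group,
                        "association_id": assoc, "partner": partner,
                        "r15_14": float(roi.r15_14.iloc[0]),
                        "biovolume_um3": biovol, "is_reference": False,
                    })
                truth_rows.append({"station": st, "group": group,
                                   "association_id": assoc,
                                   "true_cell_rate_fmol_d": total_rate})
            # unenriched reference cells, both partners
            for partner, (lo, hi) in ranges.items():
                for k in range(4):
                    biovol = rng.uniform(lo, hi)
                    roi = generate_nanosims_rois(
                        a0, design.nanosims_counts_per_roi, 1, seed=rng)
                    rows.append({
                        "cruise": "SYN1", "station": st, "group": group,
                        "association_id": f"{st}-{group}-ref{k}",
                        "partner": partner,
                        "r15_14": float(roi.r15_14.iloc[0]),
                        "biovolume_um3": biovol, "is_reference": True,
                    })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def generate_survey(design: SurveyDesign,
                    quota_model: QuotaModel = QuotaModel()) -> dict[str, pd.DataFrame]:
    """Generate the full synthetic input-table bundle plus a truth table.

    Returns a dict with keys ``hydro``, ``incubations``, ``nanosims_rois``,
    ``qpcr``, ``truth_bulk``, ``truth_cells``, ``truth_qpcr``. Deterministic for
    a fixed design (including seed).
    """
    streams = np.random.SeedSequence(design.seed).spawn(4)
    rng_hydro, rng_inc, rng_nano, rng_qpcr = (np.random.default_rng(s)
                                              for s in streams)
    hydro = _hydro_table(design, rng_hydro)
    nanosims, truth_cells = _nanosims_tables(design, rng_nano, quota_model)
    qpcr, truth_qpcr = _qpcr_tables(
        design, rng_qpcr,
        [(str(s), z) for s in range(1, design.n_stations + 1)
         for z in design.depths])

    group_volumetric = None
    if design.bulk_from_groups:
        # true volumetric contribution of each group from true cell rates x true copies
        per_assoc = truth_cells.groupby(["station", "group"])[
            "true_cell_rate_fmol_d"].mean().reset_index()
        merged = truth_qpcr.merge(per_assoc, on=["station", "group"], how="inner")
        copies_per_cell = merged.group.map({"UCYN-A1": 1, "UCYN-A2": 10}).fillna(1)
        merged["true_volumetric_nmol_l_d"] = (
            merged.true_cell_rate_fmol_d * merged.true_copies_per_l
            / copies_per_cell * 1e-6)
        group_volumetric = merged

    incubations, truth_bulk = _incubation_tables(design, rng_inc,
                                                 _true_rate_field(design, rng_inc),
                                                 group_volumetric)
    return {
        "hydro": hydro, "incubations": incubations,
        "nanosims_rois": nanosims, "qpcr": qpcr,
        "truth_bulk": truth_bulk, "truth_cells": truth_cells,
        "truth_qpcr": truth_qpcr,
    }
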