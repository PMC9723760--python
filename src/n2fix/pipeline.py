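"""Orchestration: table-level stages, validation, and the end-to-end pipeline.

Each stage takes and returns pandas DataFrames with the package's column
contracts (see the table schemas below) so the numbered analysis drivers, the
CLI, and the tests all share one code path. ``run_pipeline`` chains the stages,
stamps every output row with a provenance hash of the configuration, and writes
UTF-8 CSV plus a one-line-per-stage run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hydro as hydro_mod
from .isotope import (BDL, NATURAL_ABUNDANCE_ATOM_PCT, BulkIncubation,
                      TracerEnrichment, atom_percent_from_ratio, bulk_nfr,
                      mix_source_pool)
from .scaling import CopyNumberConvention, censor_qpcr, group_contribution
from .single_cell import (DEFAULT_DILUTION_FRACTION, QuotaModel,
                          aggregate_symbiosis_rates, cell_n_quota,
                          single_cell_lod)

__all__ = [
    "RunConfig",
    "compute_bulk_rates",
    "compute_symbiosis_rates",
    "compute_contributions",
    "compute_profile_metrics",
    "run_pipeline",
    "validate_tables",
]

log = logging.getLogger("n2fix")

#: Required columns per input table.
SCHEMAS = {
    "incubations": ["cruise", "station", "depth_m", "a_pn_t0_pct",
                    "a_pn_final_pct", "a_enriched_pct", "v_enriched_l",
                    "v_ambient_l", "pn_umol_l", "duration_d", "sd_ref_pct"],
    "nanosims_rois": ["cruise", "station", "group", "association_id", "partner",
                      "r15_14", "biovolume_um3", "is_reference"],
    "qpcr": ["cruise", "station", "depth_m", "group", "copies_per_l", "sd",
             "lod", "loq"],
    "hydro": ["cruise", "station", "depth_m", "temp_c", "salinity",
              "no3no2_umol_l", "po4_umol_l", "chl_ug_l"],
}


@dataclass(frozen=True)
class RunConfig:
    """Constants and paths for one pipeline run; fully serialized for provenance."""

    natural_abundance_pct: float = NATURAL_ABUNDANCE_ATOM_PCT
    dilution_fraction: float = DEFAULT_DILUTION_FRACTION
    copies_per_cell: dict = field(default_factory=lambda: {"UCYN-A1": 1,
                                                           "UCYN-A2": 10})
    quota_a_coeff: float = 0.26
    quota_b_exp: float = 0.86
    quota_c_to_n: float = 6.3
    k_lod: float = 3.0
    k_mqr: float = 10.0
    mld_criterion: str = "temperature"
    mld_threshold: float = 0.2
    bdl_policy: str = "zero"
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "results"

    def quota_model(self) -> QuotaModel:
        return QuotaModel(self.quota_a_coeff, self.quota_b_exp, self.quota_c_to_n)

    def convention(self) -> CopyNumberConvention:
        return CopyNumberConvention(dict(self.copies_per_cell))

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _source_pool(row, natural_abundance: float) -> float:
    return mix_source_pool(TracerEnrichment(
        a_enriched=row["a_enriched_pct"], v_enriched=row["v_enriched_l"],
        v_ambient=row["v_ambient_l"], a_ambient=natural_abundance))


def compute_bulk_rates(incubations: pd.DataFrame,
                       config: RunConfig = RunConfig()) -> pd.DataFrame:
    """Append rate_nmol_l_d, lod, mqr, status to an incubations table."""
    out = incubations.copy()
    rates, lods, mqrs, statuses = [], [], [], []
    for _, row in out.iterrows():
        a_n2 = _source_pool(row, config.natural_abundance_pct)
        res = bulk_nfr(BulkIncubation(
            a_pn_t0=row["a_pn_t0_pct"], a_pn_final=row["a_pn_final_pct"],
            a_n2=a_n2, pn_conc=row["pn_umol_l"], duration=row["duration_d"],
            sd_a_pn_ref=row["sd_ref_pct"]), k_lod=config.k_lod, k_mqr=config.k_mqr)
        rates.append(res.rate)
        lods.append(res.lod)
        mqrs.append(res.mqr)
        statuses.append(res.status)
    out["rate_nmol_l_d"] = rates
    out["lod"] = lods
    out["mqr"] = mqrs
    out["status"] = statuses
    return out


def compute_symbiosis_rates(rois: pd.DataFrame, a_n2: float, duration_d: float,
                            config: RunConfig = RunConfig()) -> pd.DataFrame:
    """Station x group whole-symbiosis rates from a nanoSIMS ROI table.

    Reference (unenriched) ROIs of each partner type supply the t0 atom% and
    the per-cell detection threshold (mean + k_lod * SD). Partner rates are
    computed from each cell's own quota, floored at 0, summed per association,
    and aggregated to a station mean/SD under the configured BDL policy.
    """
    rois = rois.copy()
    if "atom_pct" not in rois.columns:
        rois["atom_pct"] = [atom_percent_from_ratio(r) for r in rois["r15_14"]]
    quota_model = config.quota_model()
    out_rows = []
    for (cruise, station, group), sub in rois.groupby(["cruise", "station", "group"]):
        refs = sub[sub.is_reference]
        cells = sub[~sub.is_reference]
        if cells.empty:
            continue
        thresholds, a_t0 = {}, {}
        for partner in ("symbiont", "host"):
            pref = refs[refs.partner == partner]["atom_pct"]
            if pref.empty:
                a_t0[partner] = config.natural_abundance_pct
                thresholds[partner] = config.natural_abundance_pct
            else:
                a_t0[partner] = float(pref.mean())
                thresholds[partner] = single_cell_lod(pref.to_numpy(),
                                                      k=config.k_lod)
        assoc_rates, assoc_status = [], []
        for assoc, acells in cells.groupby("association_id"):
            total = 0.0
            detected = False
            for _, c in acells.iterrows():
                p = c["partner"]
                quota = cell_n_quota(c["biovolume_um3"], quota_model)
                rate = (c["atom_pct"] - a_t0[p]) / (a_n2 - a_t0[p]) \
                    * quota / duration_d
                if c["atom_pct"] > thresholds[p]:
                    detected = True
                total += max(rate, 0.0)
            assoc_rates.append(total)
            assoc_status.append("quantified" if detected else BDL)
        agg = aggregate_symbiosis_rates(
            assoc_rates, assoc_status, bdl_policy=config.bdl_policy,
            dilution_fraction=config.dilution_fraction)
        out_rows.append({
            "cruise": cruise, "station": station, "group": group,
            "mean_rate": agg.rate, "sd": agg.sd, "n_cells": len(assoc_rates),
            "max_rate": agg.max_rate, "status": agg.status,
        })
    return pd.DataFrame(out_rows)


def compute_contributions(measured: pd.DataFrame,
                          config: RunConfig = RunConfig()) -> pd.DataFrame:
    """Volumetric group rates, % of bulk, and dilution-corrected maxima.

    ``measured`` has one row per station x group with columns cell_nfr_fmol_d,
    cell_nfr_sd, nifh_per_l, nifh_sd, community_nfr_nmol_l_d, community_nfr_sd
    and optional community_nfr_is_lod. When ``printed_*`` columns are present
    (transcribed report values), a ``consistent_with_printed`` flag records
    whether each printed derived cell matches the computation at its printed
    rounding — known-discrepant printed cells are surfaced, not silently used.
    """
    convention = config.convention()
    rows = []
    for _, m in measured.iterrows():
        is_lod = bool(m.get("community_nfr_is_lod", False))
        bulk = float(m["community_nfr_nmol_l_d"])
        gc = group_contribution(
            m["group"], m["cell_nfr_fmol_d"], m["nifh_per_l"],
            bulk_rate=0.0 if is_lod else bulk,
            bulk_lod=bulk if is_lod else None,
            single_cell_sd=m.get("cell_nfr_sd", 0.0),
            copies_sd=m.get("nifh_sd", 0.0),
            bulk_sd=m.get("community_nfr_sd", 0.0),
            convention=convention,
            dilution_fraction=config.dilution_fraction)
        row = {
            "cruise": m.get("cruise", ""), "station": m["station"],
            "group": m["group"], "cells_per_l": gc.cells_per_l,
            "volumetric_nmol_l_d": gc.volumetric_rate,
            "volumetric_sd": gc.volumetric_rate_sd,
            "contribution_pct": gc.contribution_pct,
            "contribution_pct_sd": gc.contribution_pct_sd,
            "max_cell_nfr_fmol_d": m["cell_nfr_fmol_d"] / (1 - config.dilution_fraction),
            "max_volumetric_nmol_l_d": gc.max_volumetric_rate,
            "max_contribution_pct": gc.max_contribution_pct,
            "bulk_is_lod": gc.bulk_is_lod,
        }
        if "printed_volumetric" in measured.columns:
            checks = {
                "printed_volumetric": gc.volumetric_rate,
                "printed_contribution_pct": gc.contribution_pct,
                "printed_max_cell_nfr": row["max_cell_nfr_fmol_d"],
                "printed_max_volumetric": gc.max_volumetric_rate,
                "printed_max_contribution_pct": gc.max_contribution_pct,
            }
            mismatches = []
            for col, computed in checks.items():
                printed = m.get(col)
                if printed is None or (isinstance(printed, float) and np.isnan(printed)):
                    continue
                if _round_like(computed, printed) != float(printed):
                    mismatches.append(col.removeprefix("printed_"))
            row["consistent_with_printed"] = not mismatches
            row["printed_mismatches"] = ";".join(mismatches)
        rows.append(row)
    return pd.DataFrame(rows)


def _round_like(value: float, printed) -> float:
    """Round ``value`` to the decimal precision ``printed`` is expressed at.

    ``printed`` should be the value as printed (a string like "0.15" or "6");
    a bare float falls back to its shortest repr, which cannot distinguish
    "6" from "6.0".
    """
    s = str(printed).strip()
    decimals = len(s.split(".")[1]) if "." in s else 0
    return round(value, decimals)


def compute_profile_metrics(hydro: pd.DataFrame,
                            config: RunConfig = RunConfig(),
                            rates: pd.DataFrame | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """P* per sample and per-station summary (MLD, depth-integrated quantities).

    Returns ``(samples, stations)``. Mixed-layer depth uses the configured
    criterion on the temperature column (or ``sigma_theta`` when present and
    the criterion is ``"density"``). Integrated chlorophyll is reported in
    mg m^-2; integrated rate (if ``rates`` given, with rate_nmol_l_d) in
    umol N m^-2 d^-1.
    """
    samples = hydro.copy()
    samples["p_star"] = [
        hydro_mod.p_star(p, n) for p, n in
        zip(samples["po4_umol_l"], samples["no3no2_umol_l"])
    ]
    station_rows = []
    for (cruise, station), sub in samples.groupby(["cruise", "station"]):
        sub = sub.sort_values("depth_m")
        row = {"cruise": cruise, "station": station,
               "n_depths": len(sub)}
        prof = sub.dropna(subset=["temp_c"])
        if config.mld_criterion == "density" and "sigma_theta" in sub.columns:
            pcol, crit = "sigma_theta", "density"
        else:
            pcol, crit = "temp_c", "temperature"
            prof = sub.dropna(subset=[pcol])
        if len(prof) >= 2:
            mld, flag = hydro_mod.mixed_layer_depth(
                prof["depth_m"], prof[pcol],
                threshold=config.mld_threshold, criterion=crit)
            row["mld_m"] = mld
            row["mld_flag"] = flag
        chl = sub.dropna(subset=["chl_ug_l"])
        if len(chl) >= 2:
            # ug l^-1 == mg m^-3 -> mg m^-2
            row["chl_mg_m2"] = hydro_mod.depth_integrate(
                chl["depth_m"], chl["chl_ug_l"])
        if rates is not None:
            rsub = rates[(rates.cruise == cruise) & (rates.station == station)]
            rsub = rsub.dropna(subset=["rate_nmol_l_d"]).sort_values("depth_m")
            if len(rsub) >= 2:
                row["nfr_umol_m2_d"] = hydro_mod.depth_integrate(
                    rsub["depth_m"], rsub["rate_nmol_l_d"])
        station_rows.append(row)
    return samples, pd.DataFrame(station_rows)


def validate_tables(bundle: dict[str, pd.DataFrame]) -> list[str]:
    """Diagnostics for an input-table bundle; empty list means well-formed."""
    issues: list[str] = []
    for name, df in bundle.items():
        required = SCHEMAS.get(name)
        if required is None:
            continue
        missing = [c for c in required if c not in df.columns]
        if missing:
            issues.append(f"{name}: missing columns {missing}")
            continue
        for col in df.columns:
            if col.startswith("a_") and col.endswith("_pct"):
                bad = df.index[(df[col] < 0) | (df[col] >= 100)].tolist()
                for i in bad:
                    issues.append(f"{name}: row {i}: {col} out of [0, 100)")
        if name == "hydro":
            for (cruise, station), sub in df.groupby(["cruise", "station"]):
                d = sub["depth_m"].to_numpy()
                if len(d) >= 2 and not np.all(np.diff(np.sort(d)) > 0):
                    issues.append(
                        f"hydro: station {station} ({cruise}): duplicate depths")
        if name == "qpcr":
            dup = df.duplicated(subset=["cruise", "station", "depth_m", "group"])
            for i in df.index[dup]:
                issues.append(f"qpcr: row {i}: duplicate (station, depth, group)")
            if "status" in df.columns:
                for i, r in df.iterrows():
                    expect = censor_qpcr(r["copies_per_l"], r["lod"], r["loq"])
                    if r["status"] and r["status"] != expect:
                        issues.append(
                            f"qpcr: row {i}: status {r['status']!r} "
                            f"inconsistent with limits ({expect!r})")
    return issues


def run_pipeline(bundle: dict[str, pd.DataFrame],
                 config: RunConfig = RunConfig(),
                 output_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Run every applicable stage over an input bundle.

    ``bundle`` maps table names (see SCHEMAS) to DataFrames. Returns a dict of
    output tables (``bulk_rates``, ``symbiosis_rates``, ``contributions``,
    ``profile_samples``, ``profile_stations``, ``associations``) — stages whose
    inputs are absent are skipped with a log line. If ``output_dir`` is given,
    tables are written as CSV with provenance columns.
    """
    issues = validate_tables(bundle)
    if issues:
        raise ValueError("input validation failed:\n" + "\n".join(issues))
    outputs: dict[str, pd.DataFrame] = {}

    incub = bundle.get("incubations")
    if incub is not None and len(incub):
        outputs["bulk_rates"] = compute_bulk_rates(incub, config)
        log.info("bulk-rates: %d incubations -> %d rates",
                 len(incub), len(outputs["bulk_rates"]))

    rois = bundle.get("nanosims_rois")
    if rois is not None and len(rois):
        if incub is None or not len(incub):
            raise ValueError("nanosims_rois given without incubations "
                             "(need source-pool enrichment and duration)")
        a_n2 = _source_pool(incub.iloc[0], config.natural_abundance_pct)
        duration = float(incub["duration_d"].iloc[0])
        outputs["symbiosis_rates"] = compute_symbiosis_rates(
            rois, a_n2, duration, config)
        log.info("single-cell: %d ROIs -> %d station/group rates",
                 len(rois), len(outputs["symbiosis_rates"]))

    qpcr = bundle.get("qpcr")
    if qpcr is not None and len(qpcr) and "symbiosis_rates" in outputs \
            and "bulk_rates" in outputs:
        measured = _assemble_measured(outputs["symbiosis_rates"], qpcr,
                                      outputs["bulk_rates"])
        if len(measured):
            outputs["contributions"] = compute_contributions(measured, config)
            log.info("scale: %d station/group contributions",
                     len(outputs["contributions"]))
    elif qpcr is None or not len(qpcr):
        log.warning("scale: qPCR table absent or empty; contributions skipped")

    hydro = bundle.get("hydro")
    if hydro is not None and len(hydro):
        samples, stations = compute_profile_metrics(
            hydro, config, rates=outputs.get("bulk_rates"))
        outputs["profile_samples"] = samples
        outputs["profile_stations"] = stations
        log.info("profiles: %d samples, %d stations", len(samples), len(stations))
        screen_cols = [c for c in ("temp_c", "no3no2_umol_l", "po4_umol_l",
                                   "chl_ug_l", "p_star") if c in samples.columns]
        pairs = [(a, b) for i, a in enumerate(screen_cols)
                 for b in screen_cols[i + 1:]]
        outputs["associations"] = hydro_mod.association_screen(samples, pairs)

    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = config.hash()
        for name, df in outputs.items():
            stamped = df.copy()
            stamped["config_hash"] = stamp
            stamped.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "run_config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2, default=str))
    return outputs


def _assemble_measured(symbiosis_rates: pd.DataFrame, qpcr: pd.DataFrame,
                       bulk_rates: pd.DataFrame) -> pd.DataFrame:
    """Join per-station symbiosis rates, qPCR abundances and bulk rates."""
    rows = []
    for _, sr in symbiosis_rates.iterrows():
        q = qpcr[(qpcr.station == sr.station) & (qpcr.group == sr.group)]
        q = q[q.get("status", "quantified") == "quantified"]
        b = bulk_rates[bulk_rates.station == sr.station]
        if q.empty or b.empty:
            continue
        q0 = q.sort_values("depth_m").iloc[0]
        b0 = b.sort_values("depth_m").iloc[0]
        is_lod = b0["status"] == BDL
        rows.append({
            "cruise": sr.cruise, "station": sr.station, "group": sr.group,
            "cell_nfr_fmol_d": sr.mean_rate, "cell_nfr_sd": sr.sd,
            "nifh_per_l": q0["copies_per_l"], "nifh_sd": q0["sd"],
            "community_nfr_nmol_l_d": b0["lod"] if is_lod else b0["rate_nmol_l_d"],
            "community_nfr_sd": 0.0,
            "community_nfr_is_lod": is_lod,
        })
    return pd.DataFrame(rows)
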