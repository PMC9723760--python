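"""Synthetic survey generator: determinism, copula correlation, noise structure,
and end-to-end parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from n2fix.pipeline import RunConfig, compute_bulk_rates, compute_symbiosis_rates
from n2fix.synth import (SurveyDesign, generate_nanosims_rois, generate_survey,
                         spearman_to_pearson)


def test_same_seed_identical_tables(survey, small_design):
    again = generate_survey(small_design)
    for name, df in survey.items():
        pd.testing.assert_frame_equal(df, again[name])


def test_different_seed_differs(small_design):
    other = generate_survey(SurveyDesign(n_stations=3, seed=21))
    assert not other["incubations"].equals(
        generate_survey(small_design)["incubations"])


def test_bundle_has_all_tables(survey):
    for name in ("hydro", "incubations", "nanosims_rois", "qpcr",
                 "truth_bulk", "truth_cells", "truth_qpcr"):
        assert name in survey and len(survey[name]) > 0


def test_noiseless_round_trip_recovers_bulk_exactly():
    design = SurveyDesign(n_stations=2, irms_atom_pct_sd=0.0, seed=5)
    tables = generate_survey(design)
    rates = compute_bulk_rates(tables["incubations"])
    merged = rates.merge(tables["truth_bulk"], on=["station", "depth_m"])
    assert np.allclose(merged.rate_nmol_l_d, merged.true_bulk_nmol_l_d,
                       rtol=1e-9)


class TestCopula:
    def test_spearman_pearson_mapping(self):
        assert spearman_to_pearson(0.0) == 0.0
        assert spearman_to_pearson(1.0) == pytest.approx(1.0)
        assert spearman_to_pearson(0.71) == pytest.approx(0.7266, abs=1e-3)

    def test_target_rank_correlation_achieved(self):
        """rho = 0.71 +/- 0.05 between the two symbioses at n = 500."""
        design = SurveyDesign(n_stations=167, seed=42)  # 167*3 depths > 500
        tables = generate_survey(design)
        q = tables["truth_qpcr"]
        a1 = q[q.group == "UCYN-A1"].sort_values(["station", "depth_m"])
        a2 = q[q.group == "UCYN-A2"].sort_values(["station", "depth_m"])
        n = min(len(a1), 500)
        rho, _ = stats.spearmanr(a1.true_copies_per_l.to_numpy()[:n],
                                 a2.true_copies_per_l.to_numpy()[:n])
        assert 0.66 <= rho <= 0.76

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError):
            SurveyDesign(rank_correlation=1.5)


class TestNanosimsRois:
    def test_zero_atom_pct_gives_zero_heavy_counts(self):
        rois = generate_nanosims_rois(0.0, 1e4, 50, seed=1)
        assert (rois.heavy_counts == 0).all()
        assert (rois.atom_pct == 0.0).all()

    def test_mean_within_binomial_se(self):
        true = 0.3663
        n, counts = 500, 1e6
        rois = generate_nanosims_rois(true, counts, n, seed=2)
        p = true / 100.0
        se_pct = 100.0 * np.sqrt(p * (1 - p) / counts) / np.sqrt(n)
        assert abs(rois.atom_pct.mean() - true) < 3 * se_pct

    def test_consistency_at_high_counts(self):
        rois = generate_nanosims_rois(0.3663, 1e9, 20, seed=3)
        assert rois.atom_pct.to_numpy() == pytest.approx(0.3663, abs=1e-3)


def test_censoring_fractions_realistic():
    """Rare-group abundances produce a meaningful BDL/DNQ fraction."""
    design = SurveyDesign(n_stations=30, seed=9)
    q = generate_survey(design)["qpcr"]
    frac = (q.status != "quantified").mean()
    assert 0.10 <= frac <= 0.60


def test_pipeline_recovery_with_survey_noise():
    """Median relative errors under survey-like noise: <10% bulk, <15% single-cell.

    200+ replicate incubations / associations across seeded synthetic surveys.
    """
    design = SurveyDesign(n_stations=70, seed=33)  # 210 incubations
    tables = generate_survey(design)
    rates = compute_bulk_rates(tables["incubations"])
    merged = rates.merge(tables["truth_bulk"], on=["station", "depth_m"])
    assert len(merged) >= 200
    rel = np.abs(merged.rate_nmol_l_d - merged.true_bulk_nmol_l_d) \
        / merged.true_bulk_nmol_l_d
    assert np.median(rel) < 0.10

    design2 = SurveyDesign(n_stations=3, n_associations=70, seed=34)
    t2 = generate_survey(design2)
    rois = t2["nanosims_rois"]
    cfg = RunConfig()
    a_n2 = design2.source_pool_atom_pct
    # per-association recovery: estimated whole-symbiosis rate vs truth
    from n2fix.isotope import atom_percent_from_ratio
    from n2fix.single_cell import cell_n_quota
    cells = rois[~rois.is_reference].copy()
    cells["atom_pct"] = [atom_percent_from_ratio(r) for r in cells.r15_14]
    cells["quota"] = [cell_n_quota(v, cfg.quota_model())
                      for v in cells.biovolume_um3]
    a0 = cfg.natural_abundance_pct
    cells["rate"] = (cells.atom_pct - a0) / (a_n2 - a0) * cells.quota \
        / design2.duration_d
    est = cells.groupby("association_id")["rate"].sum().reset_index()
    merged2 = est.merge(t2["truth_cells"], on="association_id")
    assert len(merged2) >= 200
    rel2 = np.abs(merged2.rate - merged2.true_cell_rate_fmol_d) \
        / merged2.true_cell_rate_fmol_d
    assert np.median(rel2) < 0.15


def test_contributions_sum_to_100_when_bulk_is_group_sum():
    """With the bulk rate constructed as the sum of group volumetric rates and
    noise disabled, estimated contributions sum to 100%."""
    design = SurveyDesign(n_stations=2, bulk_from_groups=True,
                          irms_atom_pct_sd=0.0, qpcr_cv=0.0,
                          nanosims_counts_per_roi=1e9, seed=8)
    tables = generate_survey(design)
    rates = compute_bulk_rates(tables["incubations"])
    truth_q = tables["truth_qpcr"]
    truth_c = tables["truth_cells"].groupby(["station", "group"])[
        "true_cell_rate_fmol_d"].mean().reset_index()
    for station in ("1", "2"):
        for depth in design.depths:
            bulk = rates[(rates.station == station)
                         & (rates.depth_m == depth)].rate_nmol_l_d.iloc[0]
            total_pct = 0.0
            for group, per_cell in (("UCYN-A1", 1), ("UCYN-A2", 10)):
                copies = truth_q[(truth_q.station == station)
                                 & (truth_q.depth_m == depth)
                                 & (truth_q.group == group)
                                 ].true_copies_per_l.iloc[0]
                cell_rate = truth_c[(truth_c.station == station)
                                    & (truth_c.group == group)
                                    ].true_cell_rate_fmol_d.iloc[0]
                vol = cell_rate * copies / per_cell * 1e-6
                total_pct += 100.0 * vol / bulk
            assert total_pct == pytest.approx(100.0, abs=0.5)
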