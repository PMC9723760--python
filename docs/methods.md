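# Methods

## Isotope mass balance

Both rate estimators are the same two-pool model: over an incubation of length
Δt, particulate nitrogen accrues ¹⁵N from a dissolved-N₂ source pool held at
constant atom% `A_N2`, so

rate = (A_final − A_t0) / (A_N2 − A_t0) · pool / Δt,

with the pool being bulk PN (µmol N l⁻¹; rates reported in nmol N l⁻¹ d⁻¹) or
a per-cell N quota (fmol N; rates in fmol N cell⁻¹ d⁻¹). The model assumes the
source pool is constant over the incubation (tracer consumption is negligible
relative to dissolved N₂), that the particulate pool turns over slowly relative
to Δt (linear accrual), and that isotopic fractionation is negligible at tracer
enrichments. Atom% is used throughout in percent; the natural-abundance
baseline defaults to 0.3663 atom% (standard air N₂) and is configurable —
surveys differ in how they measure their unenriched reference.

The source pool is a volume-weighted mean of enriched and ambient seawater.
This assumes equal dissolved-N₂ concentration per litre in the two waters; no
solubility (temperature/salinity) correction is applied. That is a known
limitation: a cold enriched-seawater batch mixed into warm ambient water can
shift `A_N2` by a few percent relative, which propagates linearly into the
rate.

### Detection limits

The LOD (MQR) is the rate produced by an apparent enrichment of k·SD above the
t0 atom%, where SD is the standard deviation of replicate reference atom%
measurements; k defaults to 3 (LOD) and 10 (MQR), the conventional choices,
and both are configurable. Rates below LOD report status `BDL` with the value
0 (the signed mass-balance value is retained in a diagnostics field — negative
apparent enrichment is never reported as a negative rate); rates between LOD
and MQR report `DNQ`. The per-cell rule mirrors this: a cell counts as
detected when its atom% exceeds mean + k·SD of the unenriched reference cells
of the same partner type.

## Single-cell chain

nanoSIMS regions of interest yield ¹⁵N/¹⁴N count ratios, converted to atom% by
100·r/(1+r). Quotas come from biovolume via C[pg] = a·V^b and a molar C:N
ratio; the defaults (a = 0.26, b = 0.86, C:N = 6.3) are a protist-style carbon
allometry and are **surrogate constants**: the quota model in the emulated
survey is cited, not printed, so the defaults were chosen once to place
whole-symbiosis quotas inside the observed ranges (2.6–27.7 fmol N for the
UCYN-A1 symbiosis, 49.3–159.8 fmol N for UCYN-A2) given the generator's
biovolume ranges, and are exposed as configuration for anyone with calibrated
values. Symbiont and host rates are computed independently from their own ROIs
and quotas and summed per association.

Associations below detection enter station means as zeros by default (policy
`zero`); policy `exclude` drops them. The field convention is genuinely
ambiguous here, which is why both are implemented — the choice changes station
means when detection is patchy, and outputs carry the n and status to make
that visible.

The isotope-dilution correction divides by (1 − dilution fraction); at the
default 75% dilution the corrected "maximum" rate is exactly 4× the measured
one. It is applied to rates, not atom% values.

## Scaling to the community

qPCR nifH copies l⁻¹ are censored three-way: ≤ LOD → BDL, < LOQ → DNQ,
otherwise quantified (boundary convention: equality with LOD censors, equality
with LOQ quantifies). Assay defaults are LOD 25 and LOQ 200 copies l⁻¹. DNQ
values are excluded from scaling by default (optional LOQ/2 imputation,
flagged). Copies become cells under a per-group copies-per-cell convention —
1 for UCYN-A1, 10 for UCYN-A2, the high end of the reported polyploidy range;
the UCYN-A2 figure is uncertain (and its assay cross-reacts with rarer
sublineages), so the convention is configurable and the dependence is linear.

Volumetric rate = per-cell rate × cells l⁻¹ × 10⁻⁶ (fmol → nmol); percent
contribution divides by the measured bulk rate, or by the bulk LOD (flagged)
where the bulk is below detection, and may legitimately exceed 100% — the two
estimates have independent errors. SDs propagate by first-order
product/quotient rules (relative SDs add in quadrature). Propagated SDs are
reported but are not regression-anchored: the parenthetical errors printed in
the emulated survey's contribution table could not be reproduced from its
printed inputs under any standard convention, so they are treated as
informative only.

### Reproduction of the surveyed contribution table

The packaged measured inputs reproduce, at printed precision, every derived
cell of the surveyed table except three volumetric entries that are
inconsistent with their own printed inputs (station 1 and station 7 UCYN-A2,
where the printed percent contribution matches the recomputed volumetric rate
rather than the printed one; and station 14 UCYN-A2, where the printed
volumetric value matches a 1-copy-per-cell reading while the printed percent
and maxima match the stated 10-copy convention). The engine flags these via
`consistent_with_printed` / `printed_mismatches` and keeps the recomputed
full-precision values. Similarly, six of 56 printed P* cells in the
hydrochemistry table disagree at printed rounding with their own printed
nutrient values (rounding from unrounded raw data); they are flagged, not
corrected.

Study-wide summaries of the emulated survey (group mean rates such as
6.6 ± 8.8 and 151.1 ± 112.7 fmol N cell⁻¹ d⁻¹, depth-integrated rate ranges,
Mann–Whitney U statistics on per-sample data) require the full cruise dataset,
which is not part of this package; they are not recomputed or asserted
anywhere.

## Hydrochemistry and statistics

P* = PO₄³⁻ − (NO₃⁻+NO₂⁻)/16 (µmol l⁻¹, may be negative; missing inputs
propagate). Nutrient/chlorophyll censoring stores BDL with numeric 0 plus a
flag — never a silent zero — and a raw mode keeps signed values, since surveys
commonly print small negatives. Depth integration uses the trapezoidal rule
with the shallowest value extended unchanged to 0 m and integration to the
deepest sample by default (configurable z_max, constant-extrapolated below the
deepest sample); 1 nmol l⁻¹ ≡ 1 µmol m⁻³ makes the metre-integral come out in
µmol m⁻² directly. The integration depth for areal rates is a genuine free
choice (euphotic depth vs deepest incubation); the default is the deepest
sample, and printed areal ranges are therefore not used as anchors.

Mixed-layer depth is the shallowest depth where the profile deviates from the
near-surface value by more than a threshold — Δσθ = 0.125 kg m⁻³ (common
oceanographic convention) when a density column is supplied, |ΔT| = 0.2 °C
otherwise — with linear interpolation between bracketing samples; an
unstratified profile returns the deepest sample, flagged.

Spearman ρ uses average ranks for ties; for n ≤ 8 the two-sided p-value is
exact, from the full permutation null of the observed values, otherwise the
large-sample approximation. Mann–Whitney U uses the exact null for small
tie-free samples. Both are cross-checked in the test suite against brute-force
enumeration oracles.

## Synthetic surveys

The generator emulates the statistical structure the estimators face, not the
ocean: true bulk rates are lognormal across stations (median 6 nmol N l⁻¹ d⁻¹,
log-SD 0.6) with exponential depth decay (40 m scale); true whole-symbiosis
cell rates centre on 6.6 (UCYN-A1) and 151.1 (UCYN-A2) fmol N cell⁻¹ d⁻¹ with
50% CV, split 80/20 between symbiont and host; abundances are lognormal with a
Gaussian copula linking the two UCYN-A symbioses at Spearman ρ = 0.71 (copula
Pearson r = 2·sin(πρ/6)); rarer groups are independent lognormals whose
defaults produce a realistic 10–30% censored fraction. Incubation atom% values
come from forward-running the mass balance from the true rates plus Gaussian
IRMS noise (SD 5 × 10⁻⁴ atom%); nanoSIMS ROIs draw heavy counts binomially
from Poisson-varied totals (10⁵ counts/ROI); qPCR applies 10% lognormal
measurement noise. The default source-pool setup (100 ml of 15 atom% enriched
seawater into 1.1 l ambient, 24 h, 1 µmol PN l⁻¹) sits mid-range of the
emulated survey's reported enrichments and implies LODs ≈ 1.2 nmol N l⁻¹ d⁻¹,
inside its reported LOD ranges.

Each table draws from its own RNG stream spawned from the master seed, so the
bundle is byte-reproducible and adding one table cannot perturb another. What
the generator does **not** emulate: real covariance between hydrography and
rates (the hydro table is decorative), bottle effects, DNA extraction
efficiency, assay specificity, or any circulation realism — so recovery tests
demonstrate correctness of the estimators under the assumed noise model, not
field accuracy.

Under these defaults the chain recovers true bulk rates with ~9% and true
single-cell rates with ~2% median relative error (200+ replicates; see
`analysis/06_parameter_recovery.py`), and the copula achieves its target rank
correlation within sampling error at n = 500. Problem sizes in the tests (70
stations × 3 depths for bulk recovery, 3 × 70 associations for single-cell,
167 stations for the correlation check) were chosen to give ≥ 200 replicates
per check while keeping the suite fast.

## Numerical conventions

Atom% in percent everywhere (never fractions); bulk rates nmol N l⁻¹ d⁻¹;
per-cell rates fmol N cell⁻¹ d⁻¹; areal rates µmol N m⁻² d⁻¹. Sample SD
(ddof = 1) for aggregation, 0 for a single value. Report tables round to the
printed precision of the values they mirror; full-precision values are always
retained alongside. Degenerate inputs raise (`a_N2 ≤ a_t0`, non-positive
biovolume or quota, single-depth integration without explicit extrapolation,
infeasible copula correlation) rather than returning sentinels, and censoring
states are explicit string columns, never sentinel numbers.
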