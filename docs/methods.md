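# Methods

This note documents the models, the defaults and the design choices behind
them, in the order the pipeline runs.

## Data model and units

Concentrations are strictly positive, with units fixed by matrix —
sediment in mg/kg dry weight, seawater in μg/L — and never converted.
Each station carries up to three replicate measurements per (season,
metal); replicates are combined to station means before any fitting
(`replicate_policy="mean"`, the default) or passed through untouched
(`"pooled"`). The two seasonal campaigns are always analyzed separately:
matched-pair comparisons of the underlying survey found significant
seasonal differences for every metal in sediment and for Cd and Cu in
seawater, so pooling would blur genuinely distinct exposure states.
Analytical detection limits are carried as reference metadata only; no
censoring model is applied because the encoded summaries report none of
the data as below-limit.

Sample SDs use the n−1 denominator (the convention of field-survey
reporting); a single value gets SD 0 by convention.

## Distribution families

Four right-skewed families on the positive reals serve both exposure data
and SSDs, with fixed parameterizations:

* log-normal(μ, σ): Φ((ln x − μ)/σ) — μ is a log-scale location and may be
  negative;
* log-logistic(α, β): F(x) = 1/(1 + (x/α)^(−β));
* Weibull(λ, k): F(x) = 1 − exp(−(x/λ)^k);
* Burr III(b, c, k): F(x) = (1 + (x/b)^(−c))^(−k), which nests the
  log-logistic at k = 1.

Fitting is maximum likelihood with the location fixed at zero, started
from moment estimates on the log scale (the log-normal MLE is closed
form). Non-convergence raises; it is never silently replaced by default
parameters. Burr III fits whose outer shape k leaves [10⁻², 10²] are
flagged as limit distributions and excluded from model rankings — the
known failure mode of Burr III on near-symmetric environmental
monitoring data.

Model selection mirrors the two workflows: exposure data are ranked by
the Kolmogorov–Smirnov p-value, SSDs by the Anderson–Darling p-value with
AIC breaking ties. The KS p is the naive asymptotic value by default —
anti-conservative when parameters are estimated, but it reproduces the
standard distribution-fitting workflow; a seeded parametric-bootstrap
option is available. AD p-values are parametric bootstrap by default
(B = 999 in the library, reduced to 199 in the drivers; each resample is
refitted before its A² enters the null sample) because no closed-form
null covers all four families with estimated parameters.

A consequence of the nesting worth knowing when reading rankings: Burr
III's maximized likelihood is never below the log-logistic's, so on true
log-logistic data it out-AICs the nested model whenever the likelihood
gain exceeds one unit — about 16% of replicates by the χ²₁ argument.
AIC-discrimination claims for the log-logistic are therefore meaningful
among the non-nesting families (where it wins ≳80% of n = 200 replicates
on its own data) and only as a majority once Burr III is included.

## Sediment track

Eri = Tri · C/Cri with the standard toxic response factors (As 10, Cd 30,
Cr 2, Cu 5, Hg 40, Pb 5, Zn 1) and lower-inclusive grade bands (40/80/
160/320 for Eri; 150/300/600 for RI). The default background levels Cri
follow Grade I marine sediment quality values — As 20, Cd 0.50, Cr 80,
Cu 35, Pb 60, Zn 150 mg/kg — as back-calculated from the bundled
scenario's risk factors. **Hg caveat:** the Hg default is 0.05 mg/kg,
the value consistent with the scenario's encoded risk factors, although
the nominal Grade I Hg limit is 0.20 mg/kg. The package does not assert
which value the original assessment intended; override via a custom
reference YAML if the nominal standard is wanted.

Monte Carlo refinement draws 100,000 concentrations (default) from the
selected distribution per metal and tabulates grade percentages; the
composite RI samples the seven metals independently (no dependence
structure is asserted by the data; a rank-correlation hook is out of
scope) with child seeds spawned in metal order so results are invariant
to mapping order. Grade percentages partition 100% exactly.

## Aquatic track

Screening keeps chronic endpoints (NOEC, MATC, LOEC — all entering
equally once admitted, matching the pooled record counts the scenario
encodes) at or above the group duration floors (≥1 d algae and
invertebrates; ≥4 d crustaceans, fish, mollusks, worms). Species-level
aggregation defaults to the geometric mean of each species' records
(standard SSD practice), with a `minimum` policy available; the policy is
recorded in the SSD metadata. Adequacy requires ≥8 species over ≥3
functional groups — the regulatory "eight families in three classes"
floor, expressed over functional groups because the data model carries no
Linnaean ranks.

HC₅ is the winning SSD's 5th percentile; PNEC = HC₅/SF with SF = 5. The
EEC defaults to the geometric mean of station values; an arithmetic
option exists because published HQ tables are typically consistent with
arithmetic means of the summarized data, and the package asserts neither
as the original authors' computation.

The JPC is evaluated on a uniform grid of 10,001 points over (0, 1):
C_x = Q_SSD(x), EXP(x) = 1 − F_exposure(C_x), with endpoint values
extended by their limits (EXP → 1 at 0⁺, → 0 at 1⁻). ORP is the trapezoid
integral — fast-converging because EXP is bounded and monotone (doubling
the grid moves ORP by < 10⁻⁴) — and carries an intrinsic endpoint
resolution of about half a grid cell (≈5·10⁻⁵), visible only in the
no-risk limit. An independent Monte Carlo oracle, the mean of
F_SSD(C) over exposure draws, estimates the same integral and
cross-checks the quadrature in the tests. ORP ≤ 0.05 is classified
acceptable, boundary inclusive, as is HQ = 1 exactly.

## Synthetic data generator

The generator emulates the published summaries of the western Laizhou
Bay survey — per-stratum range/mean/SD for 4 matrix × season
combinations × 7 metals, 10 sediment and 20 seawater stations with their
roster coordinates, 3 replicates, and per-functional-group toxicity
record counts (336 records in total, e.g. 123 for Cu) — and nothing
more. Station values are drawn from a normal law with the stratum mean
and SD, rejection-truncated to the printed range (generation aborts if
the window would accept < 1% of draws); the printed summaries are the
matching target, with no claim about the field data's true law — the
fitting stage chooses its own family downstream, exactly as the real
workflow does. One stratum (autumn seawater Hg) has its printed mean
equal to its printed range minimum, an artifact of rounding in the
source table, so scenario validation requires min ≤ mean ≤ max rather
than strict inequality.

Replicate-level jitter (2% relative SD, re-truncated to the stratum
range) is an invention: the source summaries never quantify analytical
repeatability, and the default replicate policy averages it away before
fitting. Species tolerances are drawn from declared "true" SSDs — per
metal a log-logistic with shape β = 2 (a mid-range slope for metal SSDs)
and scale α = HC₅ · 19^(1/β) anchored to the survey's reported HC₅
values, which serve as fixture inputs only, never as fitting targets.
Durations are drawn inside screening-compliant per-group ranges and the
endpoint mix is NOEC-heavy (70/15/15).

What passing tests on this synthetic data do **not** show: fidelity to
the real stations' spatial structure (no spatial correlation is
generated; geostatistical simulation is out of scope), the true
distributional shape of field concentrations beyond three summary
statistics, or the reported HC₅/ORP values themselves — those depend on
the original toxicity extraction, which is not deposited. Consequently
reported ORPs for the reference assessment are reproduced only in their
qualitative ordering on synthetic fixtures (a demonstration printed by
`analysis/03_aquatic_risk.py`), and the autumn Hg moderate-grade
probability is assessed as an order of magnitude: its per-scenario value
is strongly right-skewed (most realizations give ≈10⁻³–10⁻²%, occasional
ones 10⁻¹%), so the pipeline pools 20 scenario replicates to estimate
the unconditional probability (≈0.02–0.03%).

## Problem sizes and numerics

Default problem sizes are the scenario's own: 10/20 stations, 3
replicates, 100,000 Monte Carlo draws, 10,001-point JPC grid, AD
bootstrap B = 199 in the drivers. Quantile/cdf round trips hold to 10⁻⁹
relative tolerance across families; ties in the AD statistic are handled
by stable sorting; probability transforms are clipped away from 0 and 1
before logs. Degenerate inputs fail loudly: constant samples are
unfittable, empty summaries and mixed strata are rejected, and a missing
metal in the reference table or toxicity set is an error rather than a
silent skip.

## Known limitations

* Sediment Cri values are a back-calculated reference set, not a copy of
  the standard's table; the Hg entry is flagged above.
* Independence across metals in the RI Monte Carlo ignores any real
  spatial covariance between metal concentrations.
* The naive KS p-value is anti-conservative with estimated parameters;
  use the bootstrap option where calibration matters.
* SSDs mix endpoint types after screening; no acute-to-chronic
  extrapolation or interspecies correlation is modeled.
* The aquatic track evaluates metals singly; mixture risk is out of
  scope.
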