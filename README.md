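# ecorisk

Probabilistic ecological risk assessment of heavy metals (As, Cd, Cr, Cu,
Hg, Pb, Zn) in coastal sediments and seawater, built for environmental
scientists who want grade *probabilities* rather than single-point risk
verdicts. The package implements two complementary tracks over
station-chemistry data and ships a synthetic-data generator that encodes
the summary statistics of a two-season survey of western Laizhou Bay
(Bohai Sea), so the full pipeline runs end to end with no external data.

## The methods

**Sediment track.** The potential ecological risk factor of metal *i* is

    Eri = Tri · C⁰i / Cri

with `Tri` the toxic response factor (As 10, Cd 30, Cr 2, Cu 5, Hg 40,
Pb 5, Zn 1), `C⁰i` the measured sediment concentration (mg/kg dry weight)
and `Cri` a background reference level. The composite index is
`RI = Σ Eri`. Both are graded on lower-inclusive bands (Eri: 40/80/160/320,
RI: 150/300/600). On top of the classical point estimates, the package
fits a parametric distribution (Weibull, log-normal, log-logistic or
Burr III, selected by Kolmogorov–Smirnov p-value) to the station
concentrations and propagates 100,000 Monte Carlo draws through the index
arithmetic, reporting the probability of each risk grade.

**Aquatic track.** Chronic toxicity records (NOEC primary; MATC/LOEC as
supplements; duration floors ≥1 d for algae/invertebrates, ≥4 d for
crustaceans/fish/mollusks/worms) are collapsed to one tolerance per
species and fitted as a species sensitivity distribution (SSD), selected
by Anderson–Darling p-value with AIC tie-break. Its 5th percentile HC₅
gives `PNEC = HC₅ / SF` (SF = 5). The screening tier is the hazard
quotient `HQ = EEC/PNEC` (EEC = geometric mean of seawater values; HQ > 1
flags potential risk). The refinement tier is the joint probability curve:
`EXP(x) = 1 − F_exposure(Q_SSD(x))` plotted over the affected species
fraction *x*, whose area

    ORP = ∫₀¹ EXP(x) dx

is the overall risk probability (expected fraction of species whose
tolerance is exceeded); ORP ≤ 0.05 is deemed acceptable.

## Worked example

```bash
python analysis/01_simulate.py --seed 1        # synthetic survey data
python analysis/02_sediment_risk.py --seed 1   # sediment track
python analysis/03_aquatic_risk.py --seed 1    # aquatic track
```

The sediment step prints, per season and metal, the selected family, the
mean-concentration risk factor with its grade, and the Monte Carlo grade
probabilities (seed 1, excerpt):

```
        season metal       family  average_eri grade  p_low  p_moderate ...
autumn_2016_09    As log_logistic        5.199   low  100.0         0.0
autumn_2016_09    Hg      weibull       21.087   low  100.0         0.0
spring_2016_05    Cu        burr3        3.112   low  100.0         0.0

        season     ri grade  p_low  p_moderate  p_considerable  p_high
autumn_2016_09 41.533   low  100.0         0.0             0.0     0.0
spring_2016_05 29.412   low  100.0         0.0             0.0     0.0
```

Every stratum is low-risk; the seasonal composite indices (≈29 and ≈42)
sit far below the moderate band at 150. Autumn Hg is the one metal whose
fitted distribution can reach the moderate threshold — across scenario
replicates its moderate-grade probability averages ≈0.03%, invisible at
most single seeds (as here) but persistent in the pooled tail. The aquatic
step ends with the two verdict lines (seed 1):

```
HQ > 1 (screening tier): ['As', 'Cr', 'Cu', 'Pb', 'Zn']
ORP > 0.05 (refined tier): ['Cr', 'Cu', 'Zn']
```

i.e. the refined probabilistic tier clears As (and Pb), whose screening
quotient overstated the risk, while Cr, Cu and Zn remain above the 0.05
acceptability line.

The same computations are scriptable via the `ecorisk` CLI
(`ecorisk simulate|sediment|aquatic --help`) or directly from Python
(`ecorisk.sediment_assessment`, `ecorisk.aquatic_assessment`).

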