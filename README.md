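# lipolyzer

Quantification toolkit for in vitro lipid digestion experiments on edible
oils. It covers the complete desk-side computation chain of a digestion
study — everything that happens after the instruments have produced their
tabular output:

* **pH-stat titration analysis** — free-fatty-acid (FFA) release curves and
  initial lipolysis rates from cumulative NaOH consumption logs;
* **HPLC-ELSD quantification** — residual triacylglycerol (TAG) mass and
  lipolysis rates, total and per TAG species, via a power-law
  internal-standard calibration;
* **TAG species bookkeeping** — partition numbers, molar masses, plausible
  species enumeration from a bulk fatty-acid composition, and
  partition-number annotation of chromatogram peaks;
* **emulsion metrics** — Sauter mean droplet diameter (d32) and
  creaming/clarification rates from multiple-light-scattering scans;
* **a synthetic-data generator** that forward-models every one of those
  inputs with known ground truth, so each stage is verifiable end to end
  without laboratory data.

It is written for food scientists and lipidomics analysts who run pH-stat or
simulated intestinal digestion assays and want the arithmetic reproducible,
validated and scriptable.

## The model

**pH-stat.** With an sn-1,3 specific pancreatic lipase, each TAG yields two
titratable fatty acids, so the released fraction at time *t* is

    FFA(%) = V_NaOH(t) · m_NaOH / (w_lipid / M_lipid · 2) · 100

with V_NaOH the cumulative titrant volume (L), m_NaOH its molarity, w_lipid
the oil mass (g) and M_lipid the mean oil molar mass (g/mol), computed here
from the GC fatty-acid composition. The initial rate is the FFA released in
the first minute (µmol) divided by the cell volume (mL) and by 60 s, in mM/s.

**ELSD quantification.** An evaporative light-scattering detector responds
as a power law of analyte mass. With triundecanoin as internal standard (IS),
the calibration is A_TAG/A_IS = a (C_TAG/C_IS)^b, fitted by OLS on the
log-log scale. Inverting it and normalising to 150 mg of digested oil gives
the residual TAG mass m_TTGS, and the lipolysis rate after *t* minutes is

    rate(%) = (1 − m_TTGS(t) / m_TTGS(0)) · 100

in which the coefficient *a* cancels exactly — only the exponent *b*
matters. Substituting each species' peak area and calibration gives
per-species rates.

**TAG species.** On reversed-phase C18 columns TAG species elute in order of
the partition number PN = CN − 2·ND (total acyl carbons minus twice the
double bonds), which drives peak annotation: e.g. PN = 36 for CLn-CLn-CLn
(tri-conjugated-linolenoyl glycerol), PN = 42 for L-L-L (trilinolein).

**Emulsions.** d32 = Σ nᵢdᵢ³ / Σ nᵢdᵢ², and destabilisation rates are OLS
slopes (%/h) of the zone-averaged backscattering change — the top 3 mm
(creaming) and bottom 5 mm (clarification) of the scanned cell.

## Worked example

Generate a synthetic pomegranate-seed-oil (PGO) digestion under the default
study conditions and analyse it back:

```
$ lipolyzer simulate --oil PGO --seed 1 --mode total --out sim
$ lipolyzer phstat --log sim/titration.csv --molarity 0.05 \
      --oil-mass 0.3 --oil-mm 872.73
FFA release at end: 71.8 %
initial rate:       0.093 mM/s

$ lipolyzer quantify --t0 sim/peaks_0min.csv --tt sim/peaks_30min.csv \
      --calibration sim/calibration.json --total-curve PGO
total lipolysis rate: 66.5 %

$ lipolyzer emulsion --psd sim/psd.csv --scan sim/scan.csv
d32: 0.309 um
creaming rate:      +7.06 %/h
clarification rate: -2.12 %/h
```

Reading the numbers: after 10 min of pH-stat digestion 71.8% of the
titratable fatty acids have been released, at an initial release rate of
0.093 mM/s; ELSD quantification finds that 66.5% of the TAG mass was
hydrolysed in 30 min of simulated intestinal digestion; the emulsion has a
surface-weighted mean droplet diameter of 0.31 µm and is creaming at
7.06 %/h. These are exactly the generator's configured design points — the
analysis recovers the ground truth, which is the point of the round trip.

The same operations are available as a library (`lipolyzer.phstat`,
`lipolyzer.elsd`, `lipolyzer.emulsion`, `lipolyzer.species`,
`lipolyzer.synthetic`), and `lipolyzer report --config cfg.yaml` runs any
combination of stages and writes a JSON run report with input hashes.

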