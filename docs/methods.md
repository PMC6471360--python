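# Methods

This note documents the models implemented in `lipolyzer`, their
assumptions, the defaults that matter, and what the synthetic generator does
and does not emulate.

## pH-stat FFA release

The released-FFA fraction is computed directly from the titration log:
FFA(%) = V(t)·m / (w/M · 2) · 100. The factor 2 assumes an sn-1,3 specific
lipase that liberates two of the three fatty acids per TAG; it is exposed as
`ffa_per_tag` for sensitivity analyses but deliberately not made a routine
knob. Values above 100% are reported with a warning rather than clipped or
rejected — over-titration and residual sn-2 hydrolysis genuinely produce
them, and hiding them would mask a stoichiometry problem.

The oil molar mass M is derived from the GC fatty-acid composition by
treating FAME area % as acyl mole % (an excellent approximation for
C16–C18-dominated oils, where FID response per unit mass is nearly uniform
and the masses are nearly equal), renormalising over the identified acids,
and assembling a mean TAG: M = 3·(mean FFA mass) + glycerol − 3·H₂O. The
identified acids must cover ≥ 90% of the total area; below that the unknown
fraction would move M by more than the titration precision and the
computation refuses. Atomic masses are fixed 4-decimal IUPAC values in one
constants table so molar masses are bit-stable across platforms.

The initial rate uses the titrant volume at 60 s, linearly interpolated
between samples: automatic titrators log near-continuously, so linear
interpolation over one sampling interval is exact for practical purposes.
Whether to interpolate or take the nearest sample was an open choice;
interpolation was selected and is the documented behaviour.

## ELSD power-law quantification

The calibration A/A_IS = a(C/C_IS)^b is fitted by OLS on the log-log scale,
where the multiplicative detector noise becomes approximately additive and
homoscedastic; R² is reported on that scale. The fitting scale is a genuine
design choice (the calibration could also be fitted by nonlinear least
squares on the raw scale); the log-log fit is the default because it is
closed-form and matches the error structure, and `fit(method="nls")` offers
the raw-scale refinement seeded from the log-log estimate.

The lipolysis rate is obtained by substituting the mass relation into the
fractional-loss definition:

rate = (1 − [(A_t/A_IS,t)/(A_0/A_IS,0)]^(1/b) · (m_LP,t/m_a,t)/(m_LP,0/m_a,0)) · 100.

The coefficient a cancels algebraically, so the rate depends only on the
exponent b and the measured areas and masses — a property asserted by
randomised tests at 1e-12. Rates outside [0, 100] are physically impossible
and are reported with a warning instead of being clamped: a negative rate is
diagnostic of noise or a normalisation error, not a value to silently fix.

Peaks annotated "Unknown" are excluded from per-species rates but included
in the total-TAG area, since the total calibration was built against the
whole oil including unassigned species.

Per-species rates use that species' own calibration exponent. For a total
rate either the oil-level curve (default) or a species-level curve can be
supplied; both are accepted because published practice is ambiguous on which
exponent governs a mixed total.

## TAG species and annotation

PN = CN − 2·ND with CN and ND summed over the three acyls. TAG species are
positionally unordered multisets: no computation here distinguishes sn-1,3
from sn-2 placement, and the canonical acyl ordering makes labels and all
derived quantities permutation-invariant. Plausible species are enumerated
as all 3-multisets of fatty acids above an abundance threshold (C(k+2,3)
species for k acids); the tie-breaking abundance estimate is the multinomial
product of acyl fractions under a random-distribution assumption — a
heuristic for ordering within a PN group, not a prediction of the real TAG
profile (interesterified oils approach it; native oils do not). Annotation
assigns PN groups to peaks one-to-one in elution order, because PN increases
with retention on reversed-phase C18; surplus peaks become "Unknown" and
surplus PN groups are reported as a warning.

The conjugated linolenic acid entry is stored purely as (18 carbons, 3
double bonds, conjugated flag); its inconsistent trivial nomenclature in the
literature is not resolved here, and conjugation does not enter any formula
— it only tags the acid.

## Emulsion metrics

d32 is the exact ratio Σnd³/Σnd². Backscatter destabilisation rates average
ΔBS unweighted over the height samples inside a zone (the aggregation within
a zone is not standardised by instrument vendors; the unweighted mean is the
simplest defensible choice) and fit an OLS slope against time in hours —
markedly more noise-robust than an endpoint difference. The liquid level is
taken as the maximum scanned height, so the creaming zone is [max − 3 mm,
max] and the clarification zone [min, min + 5 mm].

## Synthetic generator

Every generator is the exact forward model of its analysis operation, so at
zero noise `analyze(generate(truth)) = truth` to ≤ 1e-9 — the round-trip
property the test suite leans on. All randomness flows from one seeded
`numpy` generator per call; identical configurations give byte-identical
outputs.

* **Titration**: first-order release FFA%(t) = F_max(1 − e^(−kt)), inverted
  through the pH-stat formula to a cumulative NaOH volume. First-order
  kinetics is the simplest curve with the fast-then-slow shape of real
  pH-stat runs; it is not a mechanistic claim about interfacial lipase
  kinetics. The per-oil defaults (F_max, k) — e.g. (94.0%, 0.60 min⁻¹) for
  soybean oil, (72.2%, 0.52 min⁻¹) for pomegranate oil — were solved so that
  the curve passes through both reference endpoints for each oil emulsion:
  the 10-min FFA release (93.8/71.8/85.4/92.2%) and the initial rate
  (0.134/0.094/0.118/0.124 mM/s).
* **Peak tables**: species masses at 0 min split the digested oil mass
  according to the oil's TAG profile; masses at t are decayed by the
  configured true rates; areas follow the forward power model with the
  stored (a, b) and mean-one lognormal multiplicative noise of configurable
  CV (detector response is positive and heteroscedastic, so lognormal is the
  natural noise family). The default calibrations are the reference curves:
  oil-level (0.4568, 1.4353), (0.9241, 1.4759), (0.32, 1.5251),
  (0.4538, 1.4306) for SBO/PGO/PHY/IO and species-level (67.518, 1.4217)
  L-L-L, (77.223, 1.4606) L-L-O, (443.75, 1.336) CLn-CLn-CLn,
  (169.09, 1.801) CLn-CLn-P; default true rates are the reference design
  points (totals 80.4/66.5/74.8/77.0%; species 77.1/75.5/65.3/70.3%).
  A "total" mode generates one aggregate TAG peak per oil with the oil-level
  curve; in species mode the summed species areas do not obey the oil-level
  power law (a sum of power laws is not a power law), which mirrors real
  chromatograms and is why the total and species analyses carry separate
  calibrations.
* **PSD**: lognormal diameters (default median chosen so the analytic
  d32 = median·e^(2.5σ²) equals each oil's reported droplet size at
  geometric SD 1.4, 20 000 particles, 40 log-spaced bins). A zero-width
  distribution degenerates to a single bin at the median.
* **Scan**: linear ΔBS ramps at the configured zone slopes (defaults are the
  reference rates, e.g. +7.06 / −2.12 %/h for PGO) plus optional white
  noise; 5-min intervals over 3 h, 23.5 mm height at 0.25 mm steps.

What the generator does **not** emulate: retention-time drift and peak
overlap, baseline and integration errors, DAG/MAG/FFA product peaks,
saturation or dropout of the detector, droplet coalescence dynamics, or
correlated titration noise. Passing the round-trip suites therefore
demonstrates that the arithmetic chain is self-consistent and
noise-tolerant at the configured CV — not that the pipeline is robust to
every artefact of real instruments.

## Numerical choices and problem sizes

Calibration fits require ≥ 3 strictly positive points (log of zero is the
only hard failure mode). The noise-robustness suite uses 200 replicates at
1% area CV (mean absolute rate error ≤ 1 percentage point); the PSD
consistency check uses 2·10⁵ particles; both finish in seconds and the
statistics are stable well below those sizes. Zero peak area maps to zero
mass and a 100% rate; zero initial mass is an error. The acceptance script
reruns the species-rate recovery with the caller's seed; at zero noise the
result is seed-independent by construction, which the determinism tests
verify.

## Known limitations

* Peak areas are inputs; there is no chromatogram integration or
  retention-time alignment.
* Per-species quantification assumes the 0-min and t-min tables describe
  the same sample lineage and identical annotation labels.
* The mean-molar-mass conversion inherits the FAME-area ≈ mole-fraction
  approximation; for oils with abundant short-chain acids a proper response
  correction would be needed.
* R² values of external calibrations are carried as metadata only; they are
  not recomputable without the underlying dilution-series areas.
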