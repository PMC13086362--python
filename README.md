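# paleoherd

Quantitative reconstruction of caprine herding seasonality from
archaeological remains: sequential intra-tooth stable-isotope modelling,
C₃/C₄ diet mixing, bone-collagen statistics, mortality/taphonomy profiling
with Bayesian credibility intervals, and ZooMS (collagen peptide mass
fingerprinting) sheep/goat identification — as one tested, reproducible
Python package with seeded synthetic-data generation for every input it
consumes.

It is written for zooarchaeologists and stable-isotope paleoecologists who
need the statistical core of a multi-proxy herding study to be scriptable,
auditable and testable, rather than spread across spreadsheets.

## The models

**Birth seasonality from intra-tooth δ¹⁸O.** Sequential enamel samples
drilled from the occlusal surface toward the enamel-root junction (ERJ)
record the annual cycle of ingested meteoric water.  Each tooth's δ¹⁸O
sequence is fitted by least squares with the seasonal cosine

    δ¹⁸O(x) = A·cos(2π(x − x₀)/X) + M

where `x` is distance from the ERJ (mm), `X` the period (mm of crown per
annual cycle), `A = (max−min)/2` the amplitude (‰), `M = (max+min)/2` the
mean, and `x₀` the position of the δ¹⁸O maximum.  The normalised ratio
`x₀/X ∈ [0,1)` removes tooth-size variability and is the proxy for season
of birth, classified circularly against reference bands from modern herds
of known birthing season.  Optional damping (`A·e^{(x−X_B)/X_A}`) and
linear-drift (`+ p·x`) terms are available as model flags.  Sequences with
very low amplitude, no sinusoidal pattern, no clear maximum, or a missing
ERJ are screened out before fitting.

**Diet-climate phase shift.** Paired δ¹⁸O and δ¹³C series are fitted
jointly as sinusoids `A·sin(2πd/D + Ψ) + M` sharing one period `D`;
the phase shift `(Ψ_C − Ψ_O)·180/π mod 360` quantifies the seasonal timing
of the diet signal (≈180° = opposition: the dietary carbon maximum at the
δ¹⁸O winter minimum).  Specimens of one pattern group are pooled with
shared period and phases and free per-specimen means.

**C₃/C₄ diet mixing.** Tissue end-members are built from modern plant δ¹³C
values (+1.5‰ Suess correction; +14.1‰ diet→enamel enrichment ε*; +5.0‰
diet→collagen offset); a sample's %C₄ is the linear interpolation between
the pure-C₃ and pure-C₄ end-members (enamel defaults −11.58‰/+4.18‰,
collagen −20.3‰/−6.3‰), clipped to [0,100] with an explicit flag.

**Mortality profiles.** Death counts over the ordered Payne age classes
A–I get a Dirichlet(counts + prior) posterior; equal-tailed credibility
intervals for class proportions and the survivorship curve come from
seeded Monte-Carlo draws, cross-checked against analytic Beta marginals.
Taphonomy statistics (per-flag Wilson intervals, Marean completeness,
MAU%, density-mediated-attrition correlation) quantify assemblage
integrity.

**ZooMS.** Raw MALDI-ToF collagen fingerprints are baseline-corrected,
Savitzky–Golay smoothed and peak-picked (S/N ≥ 3.5 with a relative-height
floor); sheep vs goat is called from the diagnostic COL1α2 757(+16)
markers (Ovis m/z 3017.4/3033.4, Capra 3077.4/3093.4) within ±0.5 Da.

## Worked example

The `analysis/` drivers run the full workflow on a synthetic demo site
(10 teeth in three diet-pattern groups, 18 collagen samples, 48 aged
mandibles, 10 MALDI spectra), regenerated deterministically from one
master seed:

```sh
cd analysis
python 01_simulate_site.py     # writes inputs under scratch/site/
python 02_identify_taxa.py
python 03_birth_seasonality.py
python 04_phase_shift_diet.py
python 05_collagen_statistics.py
python 06_mortality_taphonomy.py
python 07_full_run.py          # same stages through the pipeline layer
```

Output (abridged) and what it means:

```
ZooMS genus calls: {'Ovis': 9, 'Capra': 1}        # all 10 match the generator truth
modelled 10/10 sequences
fitted periods X: 20.1-27.7 mm; x0/X range 0.36-0.85
median |x0/X - truth| = 0.002                     # birth position recovered
season calls: {'spring': 7, 'autumn': 3}          # two birthing seasons
pattern A.1: phase shift 192 deg over 3 specimens (D = 23.4 mm)
pattern A.2: phase shift 181 deg over 3 specimens
pattern A.3: phase shift 184 deg over 4 specimens # diet in opposition to d18O
winter C4 peak by pattern (%): A.1 4.6, A.2 9.4, A.3 32.7
18/18 samples pass QC (C:N 3.15-3.34)
d13C mean -17.6 +/- 0.7 permil; d15N mean 7.4 +/- 0.6 permil
Pearson r = -0.05 (p = 0.84)                      # C and N vary independently
aged mandibles: 48; classes present: CDEFGHI      # youngest classes absent
butchery: 17.1% [13.7, 21.0]                      # Wilson 95% interval
density attrition: rho = -0.02 (p = 0.95) -> no-attrition
```

The phase shifts near 180° with winter-only C₄ peaks are the signature of
summer grazing in pure-C₃ (highland) pasture and winter grazing on mixed
lowland vegetation; the spring/autumn split of `x₀/X` indicates two
birthing seasons.

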