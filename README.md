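# retphen

Multimodal retinal phenotyping for genotype × age mouse cohorts.

`retphen` implements the complete analysis layer of a 5xFAD vs wild-type
ageing study (6, 12 and 17 months): dark-adapted full-field ERG waveform
decomposition, OCT retinal-layer morphometry, DAB immunohistochemistry
percent-area quantification, BCA/ELISA standard-curve quantification with
Aβ-per-protein normalization, and the genotype × age cohort statistics that
tie the endpoints together.  A first-class synthetic-cohort generator
produces every input family with known ground truth, so each stage is
testable end to end without animal data.

## The models at the core

**Photoreceptoral P3.**  The leading electronegative limb of the
dark-adapted ERG is modelled by the delayed-Gaussian saturation function

    P3(i, t) = −RmP3 · (1 − exp(−i·S·(t − td)²)),   t > td

with flash energy *i* (cd·s/m²), saturated amplitude RmP3 (μV), sensitivity
S and delay td (ms).  One (RmP3, S, td) triple is fitted as an ensemble
across the leading edges of the brightest flashes and subtracted from each
trace, exposing the P2–OP complex.

**Oscillatory potentials.**  OPs are isolated with a zero-phase
frequency-domain band-pass whose half-power (−3 dB) points sit exactly at
50 and 180 Hz; the complement of the filter output is the smooth bipolar
P2.  P2 amplitude vs energy is summarized by the Naka-Rushton function
V(i) = Vmax·i/(i + K), reporting Vmax (μV) and sensitivity −log₁₀K.

**Scotopic threshold response.**  The ganglion-cell-dominated pSTR is the
mean positive peak over the three dimmest flashes (−4.90, −5.01,
−5.31 log cd·s/m²).

**Morphometry and quantification.**  OCT layer thicknesses follow the
derivation identities IPL = GCC − RNFL and ORT = TRT − GCC.  Stain burden
is the percentage of image pixels inside a fixed hue–saturation–intensity
gamut; Aβ is expressed as pg per mg total protein via invertible standard
curves.  Every endpoint is analysed with a genotype × age two-way ANOVA
(Type III), Bonferroni-corrected genotype contrasts within each age,
Lilliefors/KS normality screening, and percent-of-6-month-WT normalization.

## Worked example

```python
from retphen.simulate import ErgTruth, simulate_series
from retphen.erg import decompose_series

truth = ErgTruth(rm_p3=400.0, s=2.0e-3, td=4.0, vmax=500.0, k=0.05)
series = simulate_series(truth, seed_or_rng=1, noise_sd=5.0)
params = decompose_series(series)
print(f"RmP3 {params.rm_p3:6.1f} μV   Vmax {params.vmax:6.1f} μV")
print(f"P2 sensitivity {params.p2_sensitivity:5.3f} log (cd·s/m²)⁻¹")
print(f"pSTR {params.pstr_amplitude:5.2f} μV at {params.pstr_implicit_time:.1f} ms")
```

prints

```
RmP3  399.6 μV   Vmax  500.2 μV
P2 sensitivity 1.298 log (cd·s/m²)⁻¹
pSTR 25.04 μV at 111.1 ms
```

i.e. the decomposition recovers the programmed component truths (RmP3
400 μV, Vmax 500 μV, K = 0.05 → sensitivity 1.301, pSTR 25 μV at 110 ms)
to within the noise of a single recording.

The same chain runs from the shell:

```bash
retphen simulate --seed 17 --out cohort/          # all four input families
retphen erg  --input cohort/inputs/waves.csv      --out analysis/
retphen oct  --input cohort/inputs/boundaries.csv --out analysis/
retphen all  --seed 17 --out full_run/            # simulate → analyse → stats
```

Outputs are tidy CSV tables plus a `stats.json` report (ANOVA effects,
post hoc contrasts, normality screens per endpoint) and a run manifest
with the seed and configuration hash.

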