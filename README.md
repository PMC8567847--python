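# baleendo

Pregnancy histories from baleen: isotope chronologies, enzyme-immunoassay
reduction and progesterone profiling for whale baleen plates.

## The problem

Basic reproductive parameters of baleen whales — pregnancy rates, calving
intervals, failed pregnancies — are nearly impossible to observe directly.
Baleen offers a way in: the keratinous plates grow continuously from the
gumline, so a single plate archives several years of the whale's physiology
with roughly monthly resolution. Steroid hormones and stable isotopes are
locked into the keratin as it grows. In humpback whales (*Megaptera
novaeangliae*), whose plates reach only ~65 cm, a plate still spans ~3–4
years — enough to capture a complete inter-calving interval.

`baleendo` is for conservation physiologists and stranding-response
analysts who have per-position measurements from a necropsied plate
(progesterone in ng/g, δ¹⁵N/δ¹³C in ‰) plus whatever metadata exists
(sighting history, foetal length at necropsy) and want dated, reproducible
pregnancy calls.

## The method

1. **Chronology.** Whales alternate between summer feeding and winter
   fasting, so tissue δ¹⁵N oscillates annually along the plate. After a
   centred 5-point moving average, local maxima at least 5 cm apart are
   annual markers: each inter-peak distance is one year's baleen growth
   rate (BGR, cm/yr). The gumline ("zero cm", newest tissue) is dated to
   the day before the whale was found dead (or an explicitly back-dated
   death date); the date at position *p* follows from integrating 1/rate,
   with the per-cycle rates used between peaks and the mean rate beyond
   them (365.25-day years).

2. **Assay reduction.** Optical densities from a competitive progesterone
   EIA are mapped to pg/ml through a four-parameter logistic standard
   curve (valid 25–3200 pg/ml), with bench-faithful triage: % bound < 5%
   → re-dilute one step (1:4 → 1:16 → 1:64), duplicate CV > 10% →
   re-assay. The methanol-extraction mass balance (75.0 mg powder, 4.00 ml
   solvent, 3.00 ml aliquot, 0.50 ml reconstitution) converts to ng
   progesterone per g baleen.

3. **Profiles and calls.** Within-plate z-scores are
   (x − mean)/SD (sample SD). A pregnancy is called from a contiguous
   elevation at least 100% above baseline lasting more than 10 months of
   baleen growth; a qualifying single sample is a spike, anything shorter
   is a short elevation (luteal phase, estrous, pseudopregnancy or early
   failed pregnancy — indistinguishable by design). Conceptions are dated
   from elevation onset, or back-dated from necropsy foetal length through
   a monotone foetal-growth model; births project one gestation
   (default 12 months) forward, and successive births give calving
   intervals.

4. **Statistics.** Progesterone is compared between pregnancy states with
   a REML linear mixed model (random whale intercept; the per-position
   intercept of the stated design is aliased with the residual and
   constrained to zero), significant when |t| > 2 and p < 0.05.

5. **Simulation.** A forward generator grows plates with known ground
   truth (life-history events, growth rates, hormone kernel, isotope
   cycle, assay noise, spikes), so every stage is validated by parameter
   recovery — no field data required.

## Worked example

Simulate a ~3.5-year plate (18 cm/yr, one completed pregnancy conceived
January 1999 plus one ongoing at death, 10% assay CV) and fit it:

```python
import datetime as dt
import baleendo as b

plate, truth = b.deposit_plate(b.SimScenario(seed=11))
whale = b.WhaleRecord("SIM", sex="female", date_found=dt.date(2001, 7, 6))
res = b.BaleenPregnancyModel(plate, whale).fit()
print(res.summary())
```

```
Baleen pregnancy analysis — SIM
====================================================
config hash: c47c824a803a
zero-cm date: 2001-07-05
d15N peaks (cm): 6, 24, 42, 60
cycle growth rates (cm/yr): 18, 18, 18
mean growth rate: 18.0 cm/yr
baseline [full_plate_mean]: 319.37 ng/g
baseline [full_plate_median]: 142.09 ng/g
baseline [nonpregnant_mean]: 224.37 ng/g
calling baseline (run-excluded): 125.30 ng/g
elevation runs: 4
  0-4 cm  2001-04-15..2001-07-05  4.0 mo  peak 526 ng/g (320% above)  -> short_elevation
  10-10 cm  2000-12-14..2000-12-14  1.3 mo  peak 574 ng/g (358% above)  -> spike
  18-18 cm  2000-07-05..2000-07-05  1.3 mo  peak 530 ng/g (323% above)  -> spike
  28-42 cm  1999-03-06..1999-12-15  10.7 mo  peak 789 ng/g (530% above)  -> full_term_pregnancy
pregnancy calls: 1
  conception 1999-03-06 -> birth 2000-03-06 [hormone_profile]
```

Reading this: three δ¹⁵N peaks spacings give an 18 cm/yr growth rate; the
28–42 cm elevation lasts 10.7 months above twice the (iteratively
run-excluded) baseline of 125 ng/g, so it is called a full-term pregnancy
with conception in early 1999 — the simulator's true conception was
1999-01-15 and birth 2000-01-15, recovered to within ~7 weeks. The 0–4 cm
elevation is the second pregnancy, truncated at death after ~4 months and
therefore (correctly) left as a short elevation; the single-sample
excursions are flagged as spikes. Passing the necropsy `foetal_length_cm`
in the `WhaleRecord` would date that ongoing pregnancy too.

The same pipeline runs from the shell:

```bash
baleendo simulate --seed 11 --out-dir sim
baleendo report --plate sim/SIM_plate.csv --whales whales.csv --whale-id SIM
```

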