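# myowork

Regional myocardial work estimation for dyssynchronous heart failure and
cardiac resynchronization therapy (CRT), from time-resolved LV endocardial
surfaces and ventricular pressure.

Regional myocardial work — the area of the local stress–strain loop over
one heart beat — redistributes under left bundle branch block (LBBB): the
early-activated septum shortens before pressure rises, is stretched back
while pressure is high (net *negative* work, work done **on** the septum),
and the late-activated LV free wall performs abnormally high work. The
size of the negatively-working septal region, and its reduction after
CRT, track reverse ventricular remodeling. Because wall stress cannot be
measured in patients, this package implements the *simplified* estimation
chain that needs only surface motion and a pressure trace:

* **strain** — endocardial area strain per triangulated patch,
  `RS_CT(v,t) = A(v,t)/A(v,0) − 1`, averaged within AHA 17 segments;
* **stress** — five surrogates of increasing simplification: catheter LV
  pressure (`P_LHC`), Laplace wall stress `σ = P·r_eff/(2h)` with
  end-diastolic (`WS_ED`) or time-varying (`WS_TV`) segmental shape
  (`r_eff = r_c·r_l/(r_c + r_l)` from an axisymmetric ellipsoid fit), and
  a generic pressure waveform, unscaled (`P_gen`) or scaled to the
  patient's peak pressure (`P_gen_scaled`);
* **work** — signed loop area `W = −∮σ dε` (counter-clockwise positive;
  figure-8 loops give the net signed area), stroke work from the PV loop,
  total wall work and mechanical efficiency η;
* **regional metrics** — coefficient of variation of work (COVW),
  negative-work fractions of the LV and septum (surface `S_f_*` or
  volume `V_f_*` weighted), upper-quartile high-work fraction;
* **cohort statistics** — responder classification (echo: >10 % ESV
  reduction; clinical: ≥1 NYHA class improvement), t-tests / two-way
  ANOVA, metric–outcome regression, and a knock-out sensitivity procedure
  that substitutes one input parameter at a time by its cohort mean;
* **synthetic data** — a generator of dyssynchronous-LV mesh sequences,
  pressure waveforms and whole cohorts with a planted linear relation
  between baseline septal negative work and reverse-remodeling outcome,
  so the entire pipeline is testable without clinical data.

## Worked example

`examples/01_single_patient_work_map.py` generates one severely
dyssynchronous synthetic patient and runs all five stress surrogates:

```
method           COVW  S_f_LVNW  S_f_STNW  V_f_LVHW
P_LHC           0.822     0.139     0.459     0.250
WS_ED           0.855     0.139     0.459     0.249
WS_TV           0.903     0.151     0.499     0.249
P_gen           0.836     0.142     0.466     0.250
P_gen_scaled    0.836     0.142     0.466     0.250

EDV 189 mL, ESV 137 mL (EF 28 %)
stroke work      0.438 J
total wall work  0.535 J (generator truth map, kJ/m^3 x wall volume)
efficiency eta   0.818
```

Nearly half of the septal surface performs net negative work at this
severity, while only ~14 % of the whole LV does; `P_gen` and
`P_gen_scaled` rows are identical because every metric is invariant under
uniform positive scaling of the work map. The other examples classify the
bundled published eight-patient CRT cohort (4/8 echo, 7/8 clinical, 4/8
combined responders; baseline age 66±11 y, QRSd 145±22 ms, EF 28±7 %),
recover a planted metric→outcome R² of 0.70, and show that knocking out
the dyssynchrony parameters — but not geometry, pressure or wall
thickness — collapses that correlation (R² 0.90 → 0.35).

A thin CLI wraps the same library for shell use:

```sh
myowork simulate --out data --n-patients 8 --seed 7
myowork analyze  --data data --out results
myowork report   --data data --metrics results/metrics.csv --out report
myowork knockout --data data --out ko
```

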