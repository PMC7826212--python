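# riscreen

Retention-index based screening and quantitation of multi-pesticide
residues for targeted GC–QQQ-MS/MS assays.

## The problem

Targeted GC-MS/MS residue methods monitor each pesticide by two MRM ion
pairs (precursor > product at a set collision energy) inside a narrow
retention-time window. Setting up such a method for dozens of compounds
normally requires running every reference standard to locate its retention
time — expensive, and impossible when a standard (e.g. a single pyrethroid
stereoisomer) cannot be purchased. Retention *indices* solve this: on the
Kovats scale anchored to n-alkanes, compound retention is instrument- and
run-independent, so a database RI plus one cheap n-alkane calibration run
predicts every retention time. `riscreen` implements this workflow for an
89-entry panel (74 pesticides, several as 2–4 resolved isomers, plus a
fenthion-d6 internal standard) over an n-alkane C9–C33 ladder:

1. **Calibrate** — fit the piecewise-linear RI↔RT map from an alkane
   ladder run, or reconstruct the ladder robustly from (RI, RT) pairs.
2. **Annotate** — predict a retention time for every panel entry from its
   database RI.
3. **Screen** — match detected peaks to entries by predicted-RT window
   plus both MRM transitions; isomers sharing identical transitions are
   told apart purely by elution order and deviation-minimising assignment.
4. **Quantify** — matrix-matched / internal-standard calibration curves,
   vial-to-herb unit conversion, LOD/LOQ, recovery, precision and
   stability statistics.

A seeded synthetic-data engine generates Gaussian MRM chromatograms for a
40-sample herb survey so every stage is testable without instrument data.

## The model

For a temperature-programmed run, the linear (van den Dool–Kratz)
retention index of a compound eluting at time *t* between the C*n* and
C*n+1* alkanes (times *t_n*, *t_{n+1}*) is

    RI(t) = 100·n + 100·(t − t_n) / (t_{n+1} − t_n)

Retention-time prediction is the exact inverse on the same ladder. Ladder
reconstruction from observed (RI, RT) pairs is a monotonicity-constrained
least-squares problem over the node times with a small second-difference
penalty, solved by bounded linear least squares; robust mode iteratively
reweights pairs with Tukey's bisquare to reject typographically
inconsistent table rows. Quantitation uses ordinary least squares
`y = a·x + b` of response vs vial concentration (µg/L), LOD/LOQ at S/N
3:1 and 10:1, and recovery `100·(C − A)/B`.

## Worked example

```python
from riscreen import predict_retention_time, compute_retention_index
from riscreen.synthetic import reference_ladder_fit
from riscreen.pipeline import RunConfig, run_pipeline

fit = reference_ladder_fit()
print(f"ladder fitted from {fit.ri.size} (RI, RT) pairs; "
      f"{int((~fit.used).sum())} rejected as inconsistent")
print(f"predicted RT for procymidone (RI 2086): "
      f"{predict_retention_time(fit.ladder, 2086):.3f} min")
print(f"measured RI of a peak at 6.017 min: "
      f"{compute_retention_index(fit.ladder, 6.017):.0f}")

report = run_pipeline(RunConfig(seed=1))   # simulate + screen + quantify
print("detected pesticides:", ", ".join(report.detected_pesticides))
```

prints

```
ladder fitted from 146 (RI, RT) pairs; 34 rejected as inconsistent
predicted RT for procymidone (RI 2086): 14.613 min
measured RI of a peak at 6.017 min: 1244
detected pesticides: Chlorpyrifos, Fipronil, Procymidone
```

The fitted C9–C33 ladder places procymidone (database RI 2086) at
14.613 min — the prediction the screening window is centred on — and maps
a 6.017-min apex back to RI 1244 (dichlorvos). The simulated 40-sample
survey run flags exactly the three pesticides whose residues the packaged
study design contains; `report.results_frame()` then holds per-sample
herb concentrations in µg/kg (e.g. ≈3741 µg/kg procymidone in sample
CX19 at seed 1, vs. a design truth of 3712.16).

The same stages are exposed on the command line via the `riscreen`
entry point (`riscreen run`, `riscreen calibrate`, `riscreen panel`,
`riscreen peaks`, `riscreen screen`, `riscreen schedule`,
`riscreen simulate`; see `riscreen --help`).

## Layout

- `riscreen.ri_core` — retention-index arithmetic and ladder fitting
- `riscreen.pesticide_db` — panel data model, I/O, isomer grouping
- `riscreen.chromatogram` — MRM traces, peak detection, integration, S/N
- `riscreen.screening` — RT-window screening, isomer resolution, MRM
  time-segment scheduling, study summaries
- `riscreen.quantitation` — calibration, unit conversion, validation stats
- `riscreen.synthetic` — packaged method tables and seeded simulators
- `riscreen.pipeline` / `riscreen.cli` — orchestration and command line

See `docs/methods.md` for the modelling choices and their rationale.
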