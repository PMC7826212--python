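# Methods

This note records the models, parameter choices and numerical decisions
behind `riscreen`, and what the synthetic-data tests do and do not
demonstrate.

## Retention-index model

The toolkit uses the *linear* retention index (van den Dool–Kratz):
between bracketing n-alkanes C*n* and C*n+1*, RI is a linear function of
retention time, `RI(t) = 100·n + 100·(t − t_n)/(t_{n+1} − t_n)`. The
logarithmic (Kovats) form is appropriate only for isothermal runs; the
assay this package models uses a multi-ramp temperature program, for which
the linear form is standard. The RI→RT map is the exact piecewise-linear
inverse, so round-tripping is exact to floating point (tested to 1e−9
min), and alkane nodes anchor exactly at 100·n.

Outside the terminal alkanes the terminal segment is continued linearly
for up to ±50 RI units, with a warning; beyond that a range error is
raised. The margin is generous relative to need: all panel RIs
(1248–3060) lie well inside the C9–C33 span.

## Ladder reconstruction

When the alkane run itself is unavailable, node retention times are
estimated from observed (RI, RT) pairs. The model is linear in the node
times (each pair contributes its piecewise-linear hat weights), so the fit
is a bounded linear least-squares problem:

- **Monotonicity** is enforced by reparametrising nodes as a first node
  plus positive gaps (≥ 1e−3 min) and solving with `scipy.optimize.
  lsq_linear` (BVLS).
- **Identifiability**: RI regions not covered by any pair leave nodes
  free; a second-difference penalty on the node sequence (weight 1e−5)
  selects the locally-linear continuation there. The weight is kept about
  three orders of magnitude below the data scale so that observed pairs
  dominate wherever they exist; noiseless synthetic ladders are recovered
  to < 1e−6 min.
- **Robustness**: printed RI tables contain occasional typographical
  errors (a digit wrong in one column). Robust mode runs iteratively
  reweighted least squares with Tukey's bisquare (c = 4.685) on a MAD
  residual scale floored at 0.003 min — about the print precision of the
  tabulated times — so that rows inconsistent with the consensus mapping
  by more than a few hundredths of a minute get zero weight without any
  hand editing. Duplicated RI values are averaged before fitting.

The packaged panel's canonical ladder is reconstructed from the shipped
retention table. Both printed couples of every row — (database RI,
predicted RT) and (measured RI, measured RT) — are samples of the single
instrument ladder that generated the table, so the reconstruction pools
all of them (178 pairs; 146 after duplicate-RI averaging). This is a
deliberate design choice: the measured-RI column alone is internally
contradictory in one elution region at the ~0.1 min level (adjacent rows
flagged `suspect` in the fixture), and no estimator can decide from that
column alone which of the mutually inconsistent rows is right. With the
pooled fit, the reconstructed ladder reproduces the printed predicted-RT
column from the database RIs to ≤ 0.03 min everywhere. Suspect rows are
flagged, never silently corrected.

## Panel bookkeeping

Entry names follow the source tables; a trailing `-<digit>` suffix marks
resolved isomer peaks, and collapsing it maps the 88 non-internal-standard
entries to 74 unique pesticides. "Lindane" is stored under its synonym
"γ-BHC" (same CAS identity) to avoid double counting. The `class` column
reproduces the panel's declared composition — 31 organophosphorus, 27
organochlorine, 16 pyrethroid — as a monitoring-group label: the
organochlorine group is the 27 classical OC residues, the pyrethroid group
is the 12 chemical pyrethroids plus four late-eluting miscellaneous
residues carried with them (chlorfenapyr, flumetralin, bromopropylate,
quizalofop-ethyl), and the remaining fungicides/herbicides ride with the
organophosphates. It is a bookkeeping label, not an IUPAC classification.

## Peak model and detection

- Synthetic peaks are Gaussian with σ = 0.02 min (a typical capillary-GC
  width; the source method reports none) sampled at 0.005 min/point
  (≈3.3 Hz), adequate for σ ≈ 0.015–0.03 min peaks.
- Detection smooths with a fixed 5-point moving average for apex finding
  only; integration always uses raw intensities (trapezoidal, above a
  linear baseline between the peak boundaries), decoupling detection
  sensitivity from area accuracy. Boundaries sit at the surrounding minima
  of the smoothed trace or at baseline return.
- Noise is estimated as 1.4826 × the median absolute deviation of
  baseline points — robust to stray spikes, unlike peak-to-peak noise.
  S/N is baseline-corrected apex height over this scale.

Because the original instrument's integrator and noise estimator are not
documented, published LOD/LOQ and R² values are carried as fixture
metadata, not recomputed targets.

## Screening

A panel entry is hit when a quantifier-transition peak lies within
±`rt_window` of its predicted RT, and confirmed when a qualifier peak
co-elutes (apex agreement ≤ 0.01 min) inside the same window. The default
window is ±0.05 min: verified prediction deviations are ≤ 0.02 min, so a
2.5× margin absorbs matrix-induced shifts while still excluding
neighbours ≥ 0.1 min away. Ion-ratio confirmation (default ±30% relative,
common residue-guideline practice) is opt-in and disabled when no
reference ratios exist — presence of both m/z transitions at the predicted
RT is the primary rule.

Entries sharing identical ion pairs (cypermethrin/cyfluthrin isomers, the
DDT family, BHC isomers …) are distinguished solely by retention: within
each shared-transition group, observed apexes are assigned to predictions
by an order-preserving matching that first maximises the number of
in-window matches and then minimises total absolute deviation (ties break
toward the earlier-eluting prediction). The dynamic programme is tested
against exhaustive enumeration of all order-preserving matchings.

MRM time segmentation clusters the ±window intervals of all transitions;
each overlap-connected cluster becomes one acquisition segment (no
transition window may straddle a boundary), boundaries snap to a 0.01-min
grid, and per-segment concurrency is checked against the instrument limit.

## Quantitation

Curves are OLS response-vs-vial-concentration (µg/L). Both response modes
are supported — raw peak area (the default, matching how the published
regression equations are printed) and area ratio to the fenthion-d6
internal standard (the described procedure); the ambiguity in the source
is surfaced rather than resolved. Isomer entries of one pesticide pool
their confirmed quantifier areas before inversion. Herb concentrations
follow `µg/kg = µg/L × volume_mL / mass_g × dilution`, defaults 3.0 g /
1 mL / 1 (so vial µg/L = 3 × herb µg/kg). Estimates below the curve's LOD
report ND; between LOD and LOQ, `below_LOQ` (ND is defined by the
detection limit only). LOD = 3·noise/height-slope and LOQ =
10·noise/height-slope, so LOQ/LOD ≡ 10/3 by construction. One survey
sample's chlorpyrifos level implies a vial concentration (~1460 µg/L)
above the nominal 5–400 µg/L calibrated range; the configurable
`dilution_factor` exists for exactly that case, and the default pipeline
extrapolates the line linearly.

## Synthetic studies: what they emulate

The simulator inverts the quantitation model: design herb concentration →
vial concentration → response via the pesticide's calibration line →
Gaussian quantifier peak at the entry's measured RT (+ jitter), with the
qualifier at a fixed 0.5 ion ratio, an always-present internal-standard
peak, per-transition time-segmented traces (so absent compounds produce
noise-only channels), and optional decoy matrix peaks kept ≥ 0.15 min
from every panel RT so that acceptance runs stay deterministic in their
outcome. Noise defaults: baseline level 100 counts with σ = 20, area CV
1.5% (lognormal, chosen to keep the published precision/stability RSD
ranges plausible, not to reproduce them), RT jitter σ = 0.005 min (which
reproduces the ≤ 0.02 min observed deviation band by construction).
Not-detected cells in the packaged survey design mean concentration 0,
not a censored small value.

Per-sample RNGs are spawned from the design seed via
`numpy.random.SeedSequence`, making whole studies bit-reproducible.

What passing tests show: the pipeline is self-consistent — it recovers
designed concentrations (median relative error < 2% at the packaged noise
levels over 20 seeded studies of 40 samples each, chosen to keep the full
acceptance run under a couple of minutes on one core) and raises no false
positives among 86 absent pesticides. What they do not show: performance
under real matrix effects, co-elution with true interferents, tailing
peaks, carryover, or retention drift between batches — none of which the
generator models.

## Known limitations

- No deconvolution of genuinely co-eluting peaks; a single apex can
  satisfy at most one panel entry.
- The mzML/vendor-format layer is out of scope; traces are long-format
  CSV.
- Published LOD/LOQ, R², precision and stability figures depend on raw
  instrument data that was never released; they are fixture values and
  plausibility bounds here, not reproduced quantities.
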