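# Methods

## The analysis model

A respirometry titration experiment records chamber oxygen concentration
`[O2](t)` (μM) at a fixed sampling rate while a titrant (ADP in the
reference protocol) is added in steps. Under the assumptions that (i) within
one step the respiration rate is constant, so the O2 trace is locally
linear, and (ii) the instrument noise sits on the concentration reading, not
on the rate, the per-step rate is estimated by ordinary least squares on the
samples inside the step's region of interest:

    v = -slope · 60        [nmol O2 · ml⁻¹ · min⁻¹]

(the ×60 converts the per-second slope to the per-minute convention; 1 μM
O2 ≡ 1 nmol/ml, and the conversion is applied only to time-argument traces).
OLS is the maximum-likelihood estimator under assumption (ii) and is
unbiased; no chamber-leak/background correction is applied before the fit.

The concentration dependence of the rate is modeled as Michaelis–Menten with
a basal term,

    v(c) = V₀ + Vmax · c / (Km + c)

because permeabilized-preparation experiments respire measurably at zero
titrant. V₀ is the basal rate, Vmax the amplitude *above* basal (the total
maximum V₀ + Vmax is exposed as `vtotal` in the summary view), Km the
apparent affinity / dissociation constant in mM. The classic two-parameter
law is available with `basal=False` (`--no-basal`). The fit is bounded
nonlinear least squares (scipy trust-region reflective, all tolerances
1e-12) with the deterministic initialization V₀ ← rate at the smallest
concentration, Vmax ← max(rate) − V₀, Km ← median positive concentration.
There are no random restarts, so a fit is exactly reproducible; the
optimizer is a descent method, so the final residual sum of squares never
exceeds that of the initialization. Repeated concentrations enter as
separate points (no pre-averaging), preserving degrees of freedom.

Two summary statistics accompany the fit: the minimal and maximal measured
ROI rates, and the flux control ratio

    FCR = (vmax_measured − vmin) / vmax_measured ∈ [0, 1],

the stimulated fraction of the maximal measured flux. "Flux control ratio"
is used with several formulas in the field (vmin/vmax_measured is another
common one); this package fixes the definition above and stores vmin and
vmax_measured, so any alternative ratio is a one-line SQL view away.

## Regions of interest

ROIs are half-open intervals `[lo, hi)` of the argument axis, so adjacent
regions never share a sample and a partition of a trace reproduces it
exactly. The automatic splitter creates one ROI per protocol event,
from `event + settle` to the next event (trace end for the last), labeled
with the parsed agent name and concentration. Two windowing parameters
matter:

* `settle` (s, default 30): dead time after a titration while the chamber
  mixes and the slope steadies. The synthetic generator is piecewise linear,
  so recovery there is exact for any settle value; on real traces the
  default is a typical magnetic-stirrer mixing time and should be tuned to
  the hardware.
* `min_width` (s, default 60): windows narrower than this are skipped with a
  warning — a handful of samples gives a meaningless slope.

Annotation texts are parsed with the grammar `<agent> <number> [uM|mM]`
(default mM; μM converted); anything unparseable keeps its full text as the
label with no concentration and is simply excluded from the kinetic fit,
never dropped from the record. Manual ROIs are unconstrained and may
overlap; editing a ROI deletes its downstream results, which are recomputed
on the next analysis run (current-state semantics, no result history).

## Synthetic data generator

The generator emulates the titration protocol: for each concentration `c`
the true rate is `v(c) = V₀ + Vmax·c/(Km+c)`; O2 declines linearly at
`−v(c)/60` μM/s during that step, continuous across steps, with i.i.d.
Gaussian noise (sd `noise_sd`, default 0) added to the O2 samples; one event
marks each step start. Defaults define the reference experiment: V₀ = 10,
Vmax = 90 nmol·ml⁻¹·min⁻¹, Km = 0.3 mM, concentrations
0/0.05/0.1/0.3/1/2 mM (0 = baseline, spanning ~Km/6 to ~7·Km), 300 s steps,
1 Hz sampling, 2.0 ml chamber. The stochastic checks use `noise_sd` =
0.5 μM, a realistic polarographic-sensor noise figure. `o2_start` defaults
to 1800 μM so the six-step reference protocol ends with O2 to spare; the
generator refuses protocols that would drive O2 negative. (Hyperoxygenated
chambers are standard practice for long titrations; if a lower, air-saturated
start is wanted, shorten the steps.)

What the generator deliberately does **not** emulate: mixing transients
after each addition (steps are ideally piecewise linear), sensor drift and
chamber leak, back-diffusion at low O2, autocorrelated noise, and O2
dependence of respiration near anoxia. Passing the recovery tests therefore
demonstrates that the estimator chain is correct and unbiased under the
stated noise model — not that real traces are free of systematic effects;
on real data the settle window and visual ROI checks carry that burden.

## Store and normalization

All state lives in a relational store (single-file SQLite by default; any
engine reachable by connection string would satisfy the same contract). Core
tables `experiment`, `roi` and the `iocbio` schema-version table are created
by `init`; analysis modules own their result tables (`roi_stats`,
`roi_linear`, `mm_fit`, `rate_summary`), keyed by ROI or experiment and
replaced on re-run. The experiment ID is the SHA-256 digest of the raw file
bytes: byte-identical inputs map to one experiment row, which is the entire
import-deduplication mechanism. Raw samples are stored in a narrow
`raw_trace(experiment_id, trace_name, argument, value)` table (plus
`event`, `config`, `trace_channel`), so an experiment can be re-loaded from
the store alone and views/exports can reach the raw data.

Normalization is done by views, not application code:

* `protein_content`: Cp = mean(successful sample-batch readings) −
  mean(successful buffer-batch readings). Failed readings are excluded, not
  zeroed; a sample with no successful reading is absent from the view rather
  than NULL-propagated. A negative Cp is emitted as-is (a data-quality
  signal) and excluded downstream.
* `experiment_summary`: every rate × Vc / (Vs · Cp) → nmol O2·min⁻¹·mg⁻¹;
  Km and FCR carried over unchanged; rows with missing links or Cp ≤ 0
  are absent.

Schema migrations are forward-only and recorded per component in `iocbio`;
a store written by newer code is refused rather than modified. The read-only
toggle (default off in the library, `--read-only` in the CLI) blocks every
mutating verb; the SQL export additionally runs under a sqlite authorizer
that denies anything but reads regardless of the toggle.

## Numerical choices and degenerate inputs

* Sample (n−1) standard deviation; sd omitted (not 0) for single-sample
  segments.
* r² omitted for zero-variance responses (slope 0, rate 0 still reported):
  the coefficient of determination is undefined there and reporting 0 or 1
  would be actively misleading.
* A degenerate design (all argument values equal) or an empty segment is an
  error for the fit modules; in the pipeline such a ROI is recorded with a
  failed status and does not abort the other ROIs.
* The Michaelis–Menten fit requires ≥ 3 distinct concentrations, at least
  one positive; a flat response converges to Vmax ≈ 0 with Km unidentified,
  flagged by the converged bit rather than masked.
* Floats in the raw-text dialect are written with `repr`, so a write/read
  round trip is bit-exact and the content-hash experiment ID is stable.

## Problem sizes

The test suite and acceptance script use the reference protocol (1801
samples per experiment, 6 ROIs) and 100 seeded noisy replicates for the
stochastic recovery check; the whole suite runs in well under a minute on a
single core. These sizes match a real oxygraph session (a titration is tens
of minutes at ~1 Hz), so nothing is scaled down relative to practice.

## Known limitations

* Only time-argument traces are analyzed by the shipped modules; the model
  layer accepts spatial arguments but no spatial analyzer is provided.
* No vendor file importers: hardware output must be converted to the text
  dialect (a deliberate boundary; converters are trivial to script).
* No confidence intervals on the kinetic parameters, no Hill/cooperativity
  alternatives, no model comparison.
* Single-user store semantics; no audit history (current-state model).
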