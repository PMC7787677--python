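# kinetrace

Headless, reproducible analysis of kinetic data traces, built for the
workflow common to respirometry, fluorescence and similar bench experiments:
a recorded trace is split into regions of interest (ROIs), each region is
fitted independently (primary analysis), and the per-region results are
combined into per-experiment kinetic parameters (secondary analysis). Every
intermediate — raw samples, ROIs, fit results, normalization metadata — is
kept in a relational store, so a finished analysis can be audited or re-run
end-to-end with nothing but the database file.

The shipped module set targets **oxygraph respirometry titrations**: the
chamber O2 concentration `[O2](t)` (μM) declines while a titrant (e.g. ADP
around permeabilized cardiomyocytes) is added stepwise. For each titration
step the respiration rate is the negative slope of the O2 trace,

```
v = -d[O2]/dt · 60      (nmol O2 · ml⁻¹ · min⁻¹)
```

estimated by ordinary least squares inside the step's ROI, and the rate vs
concentration response is fitted with a Michaelis–Menten relationship with a
basal term,

```
v(c) = V₀ + Vmax · c / (Km + c)
```

by bounded nonlinear least squares, giving the basal rate V₀, the apparent
maximal stimulated rate Vmax (amplitude above basal) and the apparent
affinity (dissociation constant) Km. The per-experiment summary also reports
the minimal/maximal measured rates and the flux control ratio
`FCR = (vmax_measured − vmin) / vmax_measured`. Database views normalize
rates by chamber volume, sample volume and protein content:
`rate · Vc / (Vs · Cp)` in nmol O2·min⁻¹·mg protein⁻¹, with protein content
Cp computed in-database from tagged assay batches (sample mean − buffer
mean, failed readings excluded).

The analysis machinery is plugin-based: modules of four types (program
arguments, database schema, data import readers, primary/secondary
analyzers) are discovered at startup from the built-in set and from
user-provided folders, so other experiment kinds can be supported without
touching the core.

## Worked example

Generate a synthetic 6-step ADP titration with known kinetics (V₀ = 10,
Vmax = 90 nmol·ml⁻¹·min⁻¹, Km = 0.3 mM; 0.5 μM measurement noise), run the
full pipeline, and inspect the fit:

```sh
$ kinetrace simulate --noise 0.5 --seed 42 -o exp1.tsv
wrote exp1.tsv (experiment d22c7e6613f7...) and exp1.tsv.truth.json

$ kinetrace --db lab.db run exp1.tsv
database   ok  modules=1
import     ok  experiment_id=d22c7e6613f7deab... duplicate=False count=1
split      ok  count=6
primary    ok  count=6 failed=0
secondary  ok  count=1

$ kinetrace --db lab.db analyze d22c7e6613f7deab...
primary: 6 result(s)
mm_fit: v0=10.0051 vmax=89.9766 km=0.299699 rss=0.000127 n=6 converged=True
rates: vmin=9.99987 vmax_measured=88.2595 fcr=0.8867
```

The trace was cut into 6 ROIs (one per titration step, skipping a 30 s
settling window after each addition), each ROI's O2 slope became a rate, and
the Michaelis–Menten fit recovered the generator's parameters to ~0.1%
despite the noise. `fcr = 0.8867` says that 88.7% of the maximal measured
flux is ADP-stimulated. Re-running `kinetrace run exp1.tsv` is a no-op
import (the experiment ID is a content hash of the raw file) followed by a
recomputation that replaces, not duplicates, the result rows.

Enter normalization metadata and export the summary view (chamber volume
2.0 ml, sample volume 0.05 ml, protein batches giving Cp = 2.0 mg/ml):

```sh
$ kinetrace --db lab.db meta add-sample d22c7e6613f7deab... heart42 \
      --chamber-volume 2.0 --sample-volume 0.05
$ kinetrace --db lab.db meta add-protein assay-0711 2.0
$ kinetrace --db lab.db meta add-protein assay-0711 2.2
$ kinetrace --db lab.db meta add-protein buffer-0711 0.1
$ kinetrace --db lab.db meta link-protein heart42 assay-0711 buffer-0711
$ kinetrace --db lab.db export --query "SELECT * FROM experiment_summary" --shape long
experiment_id,sample_id,variable,value
d22c7e6613f7deab...,heart42,km,0.299698713834061
d22c7e6613f7deab...,heart42,fcr,0.8866992550537498
d22c7e6613f7deab...,heart42,v0,200.10166158345916
d22c7e6613f7deab...,heart42,vmax,1799.532920365025
d22c7e6613f7deab...,heart42,vtotal,1999.634581948484
...
```

Rates are now per mg protein (`10.005 · 2.0 / (0.05 · 2.0) ≈ 200.1`), while
Km and FCR pass through the view unchanged. The same tables are available
from Python via `kinetrace.Store`, and the whole pipeline via
`kinetrace.run_pipeline(path_or_id, store)`.

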