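# tmepre

Anti-PD1 immune-checkpoint blockade helps only a fraction of colorectal
cancer patients, and microsatellite status (MSI vs MSS) alone does not
explain who.  A tumor has two well-documented routes to anti-PD1 resistance:
too few tumor-infiltrating CD8+ T cells, or CD8+ T cells that are present but
terminally exhausted.  `tmepre` implements a two-component transcriptomic
model that scores both routes from bulk gene expression and predicts
anti-PD1 response, for computational biologists working with normalized
(log2-scale) colorectal expression cohorts.

## The model

Two nearest-centroid signatures are derived from a training cohort with known
MSI status:

* **TME1 (T-cell infiltration)** — contrasts MSI tumors whose CD8A expression
  lies strictly above the 40th percentile of CD8A within MSI tumors (high
  infiltration) against MSS tumors below it (no high infiltration).
* **TME2 (T-cell responsive state)** — within the high-infiltration MSI
  tumors, contrasts tumors with both inhibitory receptors PD1 (*PDCD1*) and
  TIM3 (*HAVCR2*) strictly below their medians (infiltrate can still respond)
  against tumors with both strictly above (terminally exhausted).

For each contrast, genes are chosen by stability selection: repeated
stratified 10-fold partitions, a Welch *t*-test per round, and retention of
genes ranked in the top 60 *p*-values in at least 80% of 200 rounds (CD8A
itself is excluded from the infiltration signature).  Selected genes feed a
nearest-centroid score on standardized expression,

    score(x) = ( ‖z − c_neg‖ − ‖z − c_pos‖ ) / |genes|,   z = (x − μ)/σ,

with the score cutoff placed at the minimum training-positive score so no
potential responder is missed (sensitivity 1).  A tumor is a predicted
**responder** when it passes both cutoffs; nonresponders carry a mechanism
label (*insufficient_infiltration* or *terminal_exhaustion*).  For cohorts on
a different platform, a rank-based rule replaces the trained cutoffs: a
sample is a nonresponder when its TME1 score is in the cohort's lowest
quartile, or in the highest quartile with a below-median TME2 score.

Supporting statistics include the relative range coverage
ω = (max score_subgroup − min score_subgroup)/(max score_all − min score_all),
a CD8-restricted TME2 read-out for purified T-cell data (nine genes: CCL5,
CD2, CD48, CD84, FAM78A, HCST, IL21R, HAVCR2, PDCD1), log-rank / Cox survival
comparison of the predicted classes, and Stouffer Z-combination of cohort
*p*-values.

Because public colorectal anti-PD1 expression cohorts are scarce, the package
ships a synthetic-cohort generator that plants the exact structure the model
assumes (latent infiltration and nested exhaustion programs, marker genes,
MSI/MSS composition, optional survival tied to predicted class), so the whole
derivation can be exercised and tested without downloads.

## Worked example

```python
from tmepre import (SimulationConfig, StabilityParams, build_tmepre,
                    classify_training_cohort, score_samples, simulate_cohort)

cfg = SimulationConfig(seed=11)          # 131 MSI / 284 MSS, 1000 genes
expr, ann, truth = simulate_cohort(cfg)

model = build_tmepre(expr, ann,
                     StabilityParams(n_rounds=200, seed=21),
                     StabilityParams(n_rounds=200, seed=22))
print("TME1 signature:", len(model.tme1.genes), "genes")
print("TME2 signature:", len(model.tme2.genes), "genes")

scores = score_samples(model, expr)
result, summary = classify_training_cohort(model, scores, ann)
for stratum, s in summary.items():
    print(f"{stratum}: {s['pct_responders']}% responders, "
          f"{s['pct_insufficient_infiltration']}% insufficient infiltration, "
          f"{s['pct_terminal_exhaustion']}% terminal exhaustion")
```

prints

```
TME1 signature: 20 genes
TME2 signature: 8 genes
MSI: 44.3% responders, 20.6% insufficient infiltration, 35.1% terminal exhaustion
MSS: 33.1% responders, 56.0% insufficient infiltration, 10.9% terminal exhaustion
```

The infiltration signature recovers exactly the 20 planted infiltration-
program genes of this cohort (never CD8A); the exhaustion-state signature
picks up PDCD1, HAVCR2 and planted exhaustion genes.  Responder percentages
reflect the generator's planted prevalences combined with the deliberately
permissive sensitivity-1 cutoffs, and the mechanism split shows how MSS
nonresponders are dominated by insufficient infiltration while MSI
nonresponders divide between the two resistance routes.

The same pipeline is available from the shell:

```sh
tmepre simulate --config sim.yaml --out-dir cohort/
tmepre derive   --matrix cohort/matrix.tsv --annotations cohort/annotations.tsv \
                --params params.yaml --out model.json
tmepre score    --model model.json --matrix cohort/matrix.tsv --out scores.tsv
tmepre predict  --mode validation --model model.json --matrix cohort/matrix.tsv \
                --out predictions.tsv
tmepre evaluate --predictions predictions.tsv --annotations cohort/annotations.tsv \
                --out report.json
```

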