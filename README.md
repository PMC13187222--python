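# scalenet

Questionnaire optimization and validation for two-group Likert data.

`scalenet` is a scientific Python package for developing and validating a
short self-report scale that separates two groups — for example a
clinical-trait group and a matched comparison group. It implements the
complete five-stage workflow used in modern psychometric scale
development:

1. **Network-based item reduction.** Items with pairwise correlations
   above 0.70 form a weighted graph; walktrap community detection and
   degree/eigenvector centralities describe its structure, and four
   complementary strategies (community representatives, isolated
   discriminators, central hubs, top discriminators by Cohen's *d*) are
   combined into a reduced item set.
2. **Exploratory factor analysis for ordinal items** — KMO and Bartlett
   factorability checks, parallel analysis with principal-axis
   eigenvalues, principal axis factoring, direct oblimin rotation, TLI
   and RMSEA (with 90% CI), and regression factor scores with their
   reliability.
3. **Cross-group measurement invariance** on polychoric correlations:
   configural, metric, and scalar models estimated by diagonally weighted
   least squares, compared by ΔCFI (rule: drop ≤ 0.01) and ΔRMSEA.
4. **Discriminative validation** — Welch *t*, pooled-SD Cohen's *d*,
   Mann–Whitney AUC, the Youden-optimal cutoff (midpoint threshold grid),
   and sensitivity/specificity/accuracy; HC3-robust regression for
   covariate checks.
5. **Ordinal confirmatory factor analysis** — DWLS on polychorics with
   optional error covariances, CFI/TLI/RMSEA/SRMR, and McDonald's ω.

A first-class **synthetic-data module** generates two-group ordinal
responses from a graded factor model (correlated normal factors, normal
residuals, per-item thresholds, reverse-coded items, optional planted
measurement non-invariance) and can calibrate per-item latent shifts to
hit any target observed-scale Cohen's *d*, so the entire pipeline is
testable end-to-end without any external data. See `docs/methods.md` for
the models and estimation details.

## Worked example

```python
import numpy as np
from scalenet import (PipelineConfig, run_pipeline)
from scalenet.pipeline import _fixture_config

# A study-shaped simulation: 65 items, 7-point scales, two correlated
# factors (r = .58), item discriminations spanning d = 0.80-2.44,
# 196 cases vs 196 comparisons, items 6/13/21/55 reverse-coded.
cfg, truth = _fixture_config("sample1_like", seed=7)

bundle = run_pipeline(PipelineConfig(
    input=cfg,
    stages=("item_selection", "efa", "validity", "extended"),
    seed=7,
))
sel, efa, val = (bundle.stages[k] for k in ("item_selection", "efa", "validity"))
print(f"selected {len(sel['selected'])} of 65 items; "
      f"alpha {sel['alpha_full']:.3f} -> {sel['alpha_selected']:.3f}, "
      f"mean d {sel['mean_d_full']:.2f} -> {sel['mean_d_selected']:.2f}")
print(f"parallel analysis: {efa['parallel_n_factors']} factors, "
      f"KMO = {efa['kmo']:.2f}")
print(f"group separation: d = {val['cohens_d']:.2f}, AUC = {val['auc']:.3f}, "
      f"Youden cutoff {val['youden_threshold']} "
      f"(sens {val['sensitivity']:.2f}, spec {val['specificity']:.2f})")
```

Output:

```
selected 18 of 65 items; alpha 0.989 -> 0.975, mean d 1.61 -> 2.13
parallel analysis: 2 factors, KMO = 0.98
group separation: d = 3.40, AUC = 0.985, Youden cutoff 90.5 (sens 0.95, spec 0.95)
```

Read: the network-based reduction kept 18 of 65 items while retaining 99%
of the full scale's internal consistency and *raising* the average
per-item discrimination from 1.61 to 2.13 SD; the reduced sum score
separates the groups almost perfectly (AUC 0.985), with the optimal
sum-score cutoff at 90.5 (half-integer because thresholds sit at
midpoints between observed sums).

A command-line interface mirrors the library:

```bash
scalenet simulate --fixture sample1_like --seed 7 --out data/
scalenet run --config cfg.json
scalenet score --items items.json --responses data/sample1_like.csv
```

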