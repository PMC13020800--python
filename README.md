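# chronotopo

Analysis toolkit for **duration-tuned cortical maps** ("chronomaps"): neural
populations in parietal, premotor and frontal cortex respond maximally to
specific sub-second stimulus durations, and nearby locations on the cortical
surface prefer similar durations. `chronotopo` implements the full
vertex-wise analysis chain used to characterize such maps from
condition-wise fMRI response amplitudes, together with a synthetic-data
generator so every stage can be exercised — and validated against planted
ground truth — without any imaging data.

It is aimed at researchers modeling tuned BOLD responses (pRF-style
analyses) and at anyone needing spatial-autocorrelation summaries (Moran's
I, variograms) of values living on a surface patch.

## The model

Each surface vertex is modeled as a population receptive field (pRF) over
stimulus duration, invariant to stimulus position:

```
beta(d) = baseline + gain · exp( −(d − μ_d)² / (2 σ_d²) )
```

* `μ_d` — duration preference: the duration evoking the largest response (s)
* `σ_d` — sensitivity: the tuning width (s)
* `gain`, `baseline` — response scaling in percent signal change; a fitted
  `gain ≤ 0` is a *negative pRF* and the vertex is excluded

The model is fitted per vertex to the 24 condition amplitudes (6 comparison
durations 0.2–0.8 s × 4 spatial positions) in two stages: an exhaustive grid
search over `(μ_d, σ_d)` with gain/baseline solved in closed form, then
bounded Nelder–Mead refinement of the vertices whose grid fit explains at
least 10% of the variance.

Downstream statistics operate on the fitted preference field:

* **Local/global Moran's I** with conditional-permutation significance and
  HH/LL/HL/LH quadrant classification of each vertex against its neighbors.
* **Empirical variograms** (Matheron semivariance, 2 mm bins, z-scored
  input) with the *nugget* (short-distance variance fraction) and *range*
  (distance at which the total variance is first reached).
* **Preference categories** — short (0.2–0.32 s), mid-short (0.32–0.44),
  medium (0.44–0.56), mid-long (0.56–0.68), long (0.68–0.8) — summarized per
  ROI, plus OLS gradients of any ROI summary along an occipital→frontal
  hierarchy rank.
* **Behavior linkage**: logit psychometric fits yield each subject's point
  of subjective equality (PSE); Kendall τ-b between PSEs and regional median
  preferences, mapped through `z(τ) = atanh(sin(πτ/2))`, quantifies where
  preferences track the perceptual category boundary.
* **Long-range structure**: Kendall τ-b matrix of regional preferences
  across subjects, converted to row-Euclidean distances and clustered with
  complete linkage into a dendrogram.

## Worked example

Simulate a two-region patch — a "parietal-like" region with a planted
full-range preference gradient and a "frontal-like" region tuned tightly to
the 0.5 s category boundary — then fit the pRF model and summarize:

```python
import numpy as np, pandas as pd
from chronotopo import synthetic_data as sd, prf_model as pm
from chronotopo import spatial_stats as ss, topography_analysis as ta

stim = pm.StimulusSpec()
blocks = [sd.RoiBlock("parietal_like", 100, "IPS"),
          sd.RoiBlock("frontal_like", 100, "AI")]
patch = sd.make_patch(10, 20, 2.0, blocks)
# ... plant a gradient field in one block, a boundary field in the other
# (see chronotopo.pipeline.build_patch_and_truth for the one-call version),
# forward-simulate betas at 0.05 psc noise, then:
field = pm.fit_field(betas, patch, stim)

valid = field.valid_mask
k = ss.moran_neighborhood_size(
    [np.count_nonzero(patch.roi[valid] == r) for r in pd.unique(patch.roi)])
w, _ = ss.knn_weights(patch, k, restrict="hemisphere", subset=valid)
moran = ss.local_morans_i(field.mu_d[valid], w, n_perm=999, seed=4)
quad = ss.summarize_quadrants(moran, patch.roi[valid])
print(ta.summarize_roi(field, quadrants=quad,
                       ordering={"parietal_like": 1, "frontal_like": 2})
      [["roi", "median_mu", "frac_medium", "ll_minus_hh"]].to_string(index=False))
```

Output:

```
valid vertices: 199 / 200
median |mu_hat - mu_true|: 0.0033 s
          roi  median_mu  frac_medium  ll_minus_hh
parietal_like   0.509957     0.210526     0.010101
 frontal_like   0.499347     0.940000     0.000000
```

Reading this: the fit recovers planted preferences to a few milliseconds at
realistic noise; the gradient region's median sits mid-range with only ~21%
of vertices in the medium category (preferences span the whole range) and a
balanced mix of low-low and high-high spatial associations, while the
boundary region is overwhelmingly medium-tuned around 0.5 s. This is the
qualitative contrast between a duration-*readout* map and a category-
*boundary* representation.

The same chain runs end-to-end from one JSON config:

```bash
chronotopo run --config cfg.json --out results_dir --seed 1
```

writing TSV/JSON outputs for every stage plus a manifest with content
hashes (identical config + seed ⇒ identical hashes).

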