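# Methods

This note records the statistical model, the defaults, and the numerical
choices made in `rsfdebias`, with the reasoning behind each.

## 1. Model

### Species process

Habitat selection is modelled as an inhomogeneous point process whose
intensity depends log-linearly on habitat covariates `x`:

    logit π(s) = β₀ + βᵀ x(s)

The RSF is estimated by use–availability logistic regression: presence
points (response 1) against availability points (response 0). Availability
rows receive a large frequency weight **W = 100** ("infinitely weighted
logistic regression"), which makes the logistic likelihood converge to the
point-process likelihood; the slope estimates β are then interpretable as
selection coefficients, while the intercept is an artefact of the
presence/availability ratio and is not interpreted.

### Observer process

Opportunistic records arise from the species process *thinned* by an
observation probability that depends on accessibility covariates `z`:

    logit α(s) = γ₀ + γᵀ z(s)
    ψ(s) = α(s) · π(s)        (intensity of opportunistic records)

γ is estimated by a logistic contrast of opportunistic records (1) against
telemetry locations (0). Telemetry samples π directly, so covariates whose
distribution differs between the two point sets do so because of the
observers, not the species. Assumptions: telemetry animals are exchangeable
with the animals generating opportunistic records; accessibility covariates
`z` capture the bias; `x` and `z` may overlap (distance to roads typically
appears in both).

### Correction

Draw `n_candidates` uniform points in the (buffered) telemetry minimum
convex polygon, then keep a weighted subsample of size
`3 × n_opportunistic` without replacement, with weights proportional to the
fitted observer intensity. Presences and availability then share the same
accessibility distortion, which cancels from the use–availability contrast;
the corrected RSF estimates the species' β even for habitat covariates
correlated with accessibility.

## 2. Defaults and why

| Parameter | Default | Rationale |
|---|---|---|
| background weight W | 100 | Large enough that estimates are within Monte-Carlo error of the W→∞ limit (verified against a large unweighted availability fit); small enough for stable IRLS. |
| candidate pool | 100,000 | Dense enough that the weighted subsample resolves the observer surface on study-area-sized polygons. |
| corrected availability | 3 × presences | With weighting, a modest multiple suffices; tests confirm estimates are stable in the pool size, not the multiple. |
| uniform availability | 10 × presences | Standard choice for unweighted designs; 10× vs 30× shifts estimates by < 0.05 in tests. |
| telemetry thinning | 5 h | Reduces serial autocorrelation of GPS fixes toward independent draws from π. |
| season / hours | Jun 22 – Sep 22, 08:00–22:00 (inclusive) | Restrict both data sources to a common season and daylight window so the two point sets sample the same process. |
| coordinate uncertainty | < 400 m kept | Records at or above 400 m uncertainty are coarser than the covariate rasters resolve. |
| super-observer rule | drop observers with > 50 % of records | A single dominant observer's personal route becomes the "observer model"; the rule is applied once, after the uncertainty filter. |
| MCP buffer | 10 km (map units) | Keeps opportunistic records from just outside the telemetry range while excluding distant, unrepresentative ones. |
| log transform | log(d + ε), ε = 1 % of the layer's positive range | Distance covariates are right-skewed; ε keeps zero distances finite without dominating the scale. Slope-like layers are excluded. |

## 3. The synthetic landscape generator

The simulation experiment (`rsfdebias.simulate`) builds landscapes intended
to emulate a temperate study region, on a 200 × 200 grid by default:

- **distance to roads** — distance to a random diagonal-ish line segment;
- **distance to settlements** — distance to a map corner;
- **forest** (30 % cover) and **nice viewpoints** (10 %) — modified random
  clusters, giving spatially aggregated binary habitat;
- **altitude** — a smoothed Gaussian random field;
- **hidden gradient** — constructed to correlate with distance to roads at
  r = −0.80 but absent from the observer model, to test whether the
  correction helps covariates it never saw.

All continuous layers are rescaled to [0, 1] so coefficients are comparable.
Species truth: intercept −7, forest 2.5, altitude −2, distance-to-roads 4.5,
hidden gradient 3. Observer truth: distance-to-roads −6, distance-to-
settlements −3, viewpoints +1, no intercept. Telemetry (500 points) is
drawn ∝ π, opportunistic records (300) ∝ α·π.

Cluster proportions, the segment geometry and the field smoothing were fixed
a priori as plausible landscape summaries; replicate-level estimates (and
therefore means over replicates) are sensitive to them, while the
qualitative outcomes — the naive sign flip on distance to roads, its
correction, and the error reduction on the hidden gradient — are not.

The generator does **not** emulate: observer heterogeneity (a single α
surface for all observers), temporal structure, detection ≠ presence
(every encounter is recorded), or movement constraints in telemetry
(fixes are independent draws).

## 4. Numerical choices

- **Odds, not probabilities, as subsampling weights.** The observer fit is
  a case–control contrast, so its intercept depends on the arbitrary
  telemetry/opportunistic ratio; when it is large, fitted *probabilities*
  saturate near 1 and carry almost no contrast. The fitted *odds*
  exp(γ̂₀ + γ̂ᵀ z) are proportional to the observer intensity regardless of
  the intercept, so candidates are weighted by exp(η̂ − max η̂) (the shift is
  a no-op for relative weights and prevents overflow).
- **Weighted sampling without replacement** uses exponential keys
  (key drawn as Exponential(1)/w per candidate; keep the n smallest), an
  exact one-pass scheme.
- **Logistic fitting** uses IRLS with frequency weights. Perfect separation
  is escalated from a warning to a `SeparationError`; callers may retry with
  a small ridge penalty (`ridge_penalty`), implemented as penalised IRLS on
  the slopes only. Constant columns are dropped with a zero coefficient
  rather than producing an unidentifiable fit.
- **Grids** store row 0 at the bottom; cell centres at
  (x₀ + (j + ½)·cell, y₀ + (i + ½)·cell). Rasters round-trip through `.tif`
  (geometry in a JSON tag) or ESRI ASCII `.asc`; nodata is −9999.
- **Availability domains.** Corrected availability is drawn in the
  (buffered) *telemetry* MCP — the region where the observer model is
  supported. Naive availability for the opportunistic model uses the MCP of
  *all* observed locations (telemetry + opportunistic pooled), so that when
  observer bias is absent the naive and corrected designs are exchangeable;
  this equivalence is asserted in the test suite.
- **Point sampling from a weight surface** picks cells by weighted
  multinomial and jitters uniformly within the cell, giving continuous
  coordinates with the correct cell-level intensity.

## 5. Limitations

- The correction inherits the observer model's covariates: bias driven by
  anything outside `z` (e.g. a hidden trail network) is not removed, though
  correlated hidden drivers are partially absorbed.
- Telemetry and opportunistic records must sample the same population in
  the same season; the filters enforce this only coarsely.
- Estimates at the single-study scale are stochastic: with 300 presences,
  replicate standard deviations near 1 on the road coefficient are normal.
  Conclusions should rest on replicated runs or on confidence intervals,
  both of which the pipeline reports.
- Uncertainty in γ̂ is not propagated into the corrected RSF's standard
  errors; reported SEs condition on the fitted observer surface.
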