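# apexds

Line-transect abundance estimation for aerial double-observer surveys whose
detection peaks **off** the transect line — the situation in Alaskan brown
and black bear surveys flown with small two-person aircraft, where the strip
beneath the plane is obscured and detection is highest at an apex distance
of roughly 100–125 m.

`apexds` implements the estimator family these surveys are analysed (and
argued) with, plus the synthetic surveys needed to study their biases:

* **CDS** — conventional distance sampling with a half-normal
  g(x) = exp(−x²/2σ²) (left-truncated at the apex) or a **two-piece normal**
  g(x) = exp(−(x−θ)²/2σ₁²) for x ≤ θ, exp(−(x−θ)²/2σ₂²) beyond, which models
  both sides of the apex θ;
* **MCDS** — covariates acting on the detection scale,
  σₖ(z) = σₖ·exp(βᵀz);
* **MRDS** — mark–recapture distance sampling: double-observer capture
  histories fit by a conditional logistic likelihood estimate *absolute*
  detectability, under **full independence** (observers independent at every
  distance) or **point independence** (independent only at the apex, where
  the distance model supplies the shape and the mark–recapture model the
  scale: P_a(z) = p̂•(θ̂, z)·μ̂(z)/w, with μ = ∫₀ʷ g the effective strip
  half-width);
* abundance by the Horvitz–Thompson sum N̂ = (A/a)·Σᵢ sᵢ/P̂_a(zᵢ) over
  detected groups of size sᵢ, with delta-method and transect-bootstrap
  variances including the between-transect encounter-rate component;
* a **survey simulator** (detection apex, imperfect apex detection,
  shared-frailty heterogeneity, covariates, availability, hotspot transects,
  stratified designs) and a known-population **stake-transect** generator;
* a benchmark harness reproducing the published comparisons: the 17–21 %
  negative bias of CDS against MRDS on five Alaskan bear surveys, and the
  full-independence < CDS < point-independence ordering on a known
  population of 150 stakes.

## Worked example

```python
import warnings
from apexds import fit_mrds, fit_cds, simulate_survey
from apexds.simulate import bear_scenario

obs, design, truth = simulate_survey(bear_scenario(seed=42))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    pi  = fit_mrds(obs, design, ds_covariates=("cover",), independence="point")
    cds = fit_cds(obs, design, "two_piece_normal", left_truncation=0.0)
print(truth["n_individuals"], round(pi.abundance, 1), round(pi.theta, 1),
      round(pi.mean_apex_p, 3), round(cds.abundance, 1))
```

prints

```
1729 2054.9 106.3 0.92 1868.3
```

— a survey with a true population of 1729 bears yields 156 detected groups;
the point-independence MRDS fit estimates an apex of 106.3 m (truth 110 m)
and a mean apex mark–recapture probability of 0.92 (truth ≈ 0.87–0.9), and
its abundance estimate 2054.9 (SE ≈ 224) brackets the truth, while the
conventional two-piece fit, which assumes certain detection at the apex,
centers about 10 % low over repeated surveys.

The `examples/` directory holds one short script per capability
(simulation, CDS/MCDS fitting with AIC and goodness of fit, MRDS with
bootstrap, the stake study, the published-survey bias table); each prints
its numbers with a line on what they mean.  A thin command-line interface
mirrors the library:

```bash
apexds simulate --seed 7 --out survey
apexds fit --model mrds-pi --obs survey_observations.csv \
    --transects survey_transects.csv --config examples/config_template.yaml \
    --out report.json
apexds bench --experiment stake-ordering --replicates 200 --seed 1
```

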