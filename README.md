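# nestlingqg

Quantitative genetics of nestling plumage colour from cross-fostered
full-sib dyads.

Juvenile carotenoid-based colouration (the yellow breast plumage of tit
nestlings, quantified as hue, saturation and brightness) is shaped by
genes, rearing environment and diet. A cross-fostering experiment —
swapping half of each brood between paired nests ("dyads") — separates
these sources: nest-of-origin resemblance is genetic (plus early
maternal effects), nest-of-rearing resemblance is environmental.
`nestlingqg` implements the full analysis chain for such designs, for
behavioural ecologists and quantitative geneticists who want a tested,
reproducible pipeline rather than a one-off script:

* RGB colour measurements → hue/saturation/brightness phenotypes and
  measurement repeatability (one-way ANOVA ICC);
* a synthetic-data generator emulating the cross-fostered dyad design
  (sex-specific origin effects with cross-sex covariance, rearing, dyad
  and residual components, optional extra-pair-paternity contamination);
* univariate and bivariate Gaussian mixed models fitted by Gibbs
  sampling with inverse-Wishart priors (V = 1, ν = 1.002);
* derived genetic parameters with 95% highest-posterior-density (HPD)
  intervals, computed per posterior draw:

      H²   = 2·V_O / (V_O + V_R + V_D + V_Res)        (full-sib ×2 correction)
      r_mf = COV_MF / √(V_OM · V_OF)                   (cross-sex genetic correlation)

* DIC-based random-effect selection (DIC = D̄ + pD, conditional
  deviance) and a prior-doubling robustness check.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

Simulate a study-scale population (25 dyads → 50 nests, here 662
nestlings) and run the full pipeline for the hue trait:

```python
from nestlingqg.cli import PipelineConfig, run_pipeline
from nestlingqg.simdata import SimConfig
from nestlingqg.gibbs import MCMCSettings

config = PipelineConfig(
    simulation=SimConfig(n_dyads=25, seed=7),
    traits=("hue",),
    mcmc=MCMCSettings(n_iterations=6000, burn_in=1000, thinning=5, seed=7),
    output_dir="demo_run",
)
artifacts = run_pipeline(config)
```

`demo_run/report.csv` then contains (excerpt):

```
trait      model     parameter  estimate   hpd_low  hpd_high
  hue univariate      V_origin  0.218083  0.076150  0.395283
  hue univariate    V_residual  3.068080  2.749990  3.409370
  hue univariate            H2  0.115932  0.042700  0.208544
  hue  bivariate    V_origin_F  0.177392  0.056672  0.325401
  hue  bivariate    V_origin_M  0.610946  0.165719  1.179740
  hue  bivariate COV_origin_MF -0.043647 -0.250782  0.134319
  hue  bivariate          H2_M  0.202703  0.053296  0.378657
  hue  bivariate          H2_F  0.175389  0.062254  0.313019
  hue  bivariate          r_mf -0.132832 -0.626882  0.364158
```

Reading this: hue is weakly heritable (univariate H² ≈ 0.12, HPD
0.04–0.21), and the cross-sex genetic correlation is indistinguishable
from zero (r_mf ≈ −0.13, HPD −0.63–0.36) while clearly below unity —
male and female hue are genetically decoupled in this simulated
population. The DIC table (`demo_run/dic_hue.csv`) ranks random-effect
structures:

```
     random_effects        dbar        pD         DIC  delta_DIC
     origin+rearing 2622.026756 43.605315 2665.632071   0.000000
origin+rearing+dyad 2621.377997 45.717198 2667.095195   1.463124
             origin 2638.726626 31.145188 2669.871814   4.239743
             (none) 2689.943430  4.856321 2694.799751  29.167680
```

The same stages are available from the shell (`nestlingqg simulate`,
`colour`, `fit`, `derive`, `compare`, `report`, `run-all`).

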