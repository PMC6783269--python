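# finbody

Analysis of **fin–body coordination in climbing larval zebrafish**, built as
a reusable Python library with a synthetic swim generator so the whole
pipeline runs without any recorded data.

Larval zebrafish climb in the water column by combining two effectors: they
pitch the body nose-up to redirect thrust (a *posture change*, r, measured
between 75 and 25 ms before a bout's peak speed), and they beat the pectoral
fins to generate lift, visible as an *attack angle* γ — the difference
between the swim trajectory and the body posture at peak speed. How much
lift a larva recruits per degree of body rotation is a compact description
of its motor coordination, and it changes systematically with development,
with loss of vestibular (utricular) input, and with cerebellar
Purkinje-cell lesions. This package is for researchers in behavioral
neuroscience / neuroethology who want to apply or probe that analysis.

## The model

Attack angle saturates as a function of posture change and is fit with a
logistic,

    γ(r) = γ₀ + γ_max / (1 + exp(−k (r − r₀)))

with the centre defined through a rise position r_rise (where the curve
reaches 1/8 of its upper asymptote):

    r₀ = r_rise + (1/k) · ln( 7(γ_max + γ₀) / (γ_max − 7γ₀) )

* **fin-body ratio** = maximal slope of the sigmoid = k·γ_max/4
  (dimensionless; larger = more fin-dominated climbing)
* **fin bias** = slope / (1 + slope) ∈ [0, 1), the fraction of a steering
  command allocated to the fins; the generative model bounds the
  attack-angle : posture-change ratio at α/(1−α).
* For lesion-like data a **double sigmoid** γ_p(r) = γ(r) + χ·γ_max /
  (1 + exp(k(r + r₀))) adds a limb reflected about the vertical axis,
  capturing lift recruited during nose-down steering.

Fits use unbounded Levenberg–Marquardt least squares; one-parameter fits
free only k with the shape parameters fixed at pooled means
(γ₀ = −2.97°, γ_max = 17.02°, r_rise = −1.11°). Uncertainty comes from a
case-resampling bootstrap (percentile CIs).

Around the models sit: 40 Hz bout segmentation (speed > 5 mm/s, 13 Hz merge
rule, interpolated crossings), kinematic features (trajectory, attack
angle, posture change, displacement, inter-bout metrics, acceleration
alignment), and the statistics used with them (exact binomial chance-level
tests, conflicting-action proportions with bootstrap CIs, Theil–Sen
shallow-climb slopes, equal-count binning, clutch-level group tests).

## Worked example

```python
from finbody import bootstrap_fit, fin_bias, generate_bout_table, preset

p = preset("3wpf")                      # 3 weeks post-fertilization
bouts = generate_bout_table(p, n_bouts=3000, seed=2)
fit = bootstrap_fit(bouts["posture_change_deg"], bouts["attack_angle_deg"],
                    variant="one_param", n_reps=500, seed=3)
```

Running `python examples/02_fit_coordination_sigmoid.py` (the script above)
prints:

```
n = 3000 bouts, one-parameter fit (shape fixed at pooled means)
steepness k        = 2.708 1/deg
fin-body ratio     = 11.52  (bootstrap 95% CI 9.55-14.50)
fin bias           = 0.92
R^2                = 0.154
```

The 3 wpf preset generates bouts whose coordination sigmoid has maximal
slope 12.01; the fitted ratio 11.52 with CI 9.55–14.50 brackets it, and the
fin bias 0.92 says a climb's attack angle can reach roughly nine times its
posture change — fin-dominated climbing. The low R² is expected: individual
bout attack angles are noisy around the coordination curve.

The other scripts in `examples/` walk through segmentation of rendered
epochs (`01`), the developmental trend of the fin bias across the four age
presets (`03`), decoupled vestibular-mutant and lesion statistics (`04`),
and the generative fin-bias command split (`05`). A thin CLI wraps the same
stages:

```sh
finbody simulate --preset 1wpf --n-bouts 500 --seed 1 --out bouts.csv
finbody fit --bouts bouts.csv --variant one_param --boot-reps 500
finbody reproduce --out runs/demo --seed 1
```

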