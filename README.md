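# rbpnoise

Quantitative modeling of stochastic gene expression in a synthetic
*E. coli* circuit regulated by a **protein translation factor**: the
bacteriophage MS2 coat protein (MS2CP), fused to eBFP2 and expressed
from an IPTG-inducible PLlac promoter, binds an RNA hairpin on a
constitutively transcribed sfGFP mRNA and blocks ribosome progression.
Sublethal tetracycline (TC) slows growth and perturbs the translation
machinery, coupling global physiology into the circuit.

The package is for systems/synthetic biologists who want to model,
simulate, and fit this class of circuit: it provides the deterministic
transfer functions with growth-rate coupling, the analytic
three-component noise decomposition with Gamma-distribution
predictions, a Langevin trajectory simulator, a synthetic
flow-cytometry data generator, and the full parameter-inference chain
— each piece testable against the others.

## Model

Mean expression follows Hill-Langmuir transfer functions,

```
⟨eBFP2⟩ = αx(μ) · (ρx + (IPTG/θi)^ni) / (1 + (IPTG/θi)^ni)
⟨sfGFP⟩ = αy(μ) · (1 + ρy (⟨eBFP2⟩/θx(μ))^nx) / (1 + (⟨eBFP2⟩/θx(μ))^nx)
```

with growth rate μ = μ0 / (1 + TC/θc).  Growth couples in three ways:
maximal expressions pick up the relative translation rate
λ(μ) ∝ (ε1−μ)/(ε2−μ) (ribosome over-production under translation
inhibitors), the binding constant θx is volume-corrected as
e^{δ(μ0−μ)}θx, and protein synthesis rates obey SR = mean × μ.

The noise (squared coefficient of variation) of each gene decomposes
additively into **extrinsic** (constant plateau η²), **intrinsic**
(Fano factor over mean, β/⟨p⟩) and **regulation** noise (½ × squared
transfer-function slope × upstream variance / mean²).  Single-cell
fluorescence follows a Gamma law with shape 1/CV² and scale
mean·CV².  A four-variable Langevin system (mRNA + protein of both
genes, colored extrinsic/regulation noise, propensity-scaled white
intrinsic noise) reproduces these moments in simulation.

## Worked example

```sh
python examples/noise_decomposition.py
```

prints, for the fitted parameter set of the characterized circuit
(bundled; TC = 0):

```
  IPTG |      regulator CV2 (ext+int+reg) |         target CV2 (ext+int+reg)
     0 | 0.353 = 0.246+0.107+0.000        | 0.131 = 0.127+0.002+0.002
    50 | 0.802 = 0.246+0.076+0.480        | 0.181 = 0.127+0.004+0.050
   100 | 0.508 = 0.246+0.044+0.218        | 0.236 = 0.127+0.026+0.084
  1000 | 0.270 = 0.246+0.024+0.000        | 0.239 = 0.127+0.109+0.003

regulation-noise peaks: regulator 0.491 at 55 uM, target 0.113 at 77 uM
-> buffering ratio 4.35x
```

Reading: the regulator's noise peaks sharply in the dose-response
transition (fluctuations of LacI activity propagate through the steep
transfer function), while the translationally controlled target stays
much quieter everywhere — its regulation-noise peak is ~4× lower.
That buffering is the central quantitative signature of control at the
translation step: the target mRNA is abundant and constitutively
transcribed, so upstream fluctuations are not amplified by
transcription.

Other examples: `dose_response.py` (44-fold repression across the IPTG
gradient), `growth_coupling.py` (synthesis-rate extrema at μ ≈ 0.47
and 0.65 h⁻¹), `simulate_trajectories.py` (Langevin vs analytic
moments), `recover_parameters.py` (end-to-end inference on synthetic
cytometry data).

A thin CLI wraps the same library calls:

```sh
rbpnoise simulate --outdir out --seed 1
rbpnoise analyze --outdir out --events out/events.csv --growth out/growth.csv
```

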