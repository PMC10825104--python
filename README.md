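# mdifkit

Quantification of the cerebral metabolic rate of glucose (CMRGlu) from
dynamic [¹⁸F]FDG PET normally requires arterial blood sampling to measure
the plasma input function. `mdifkit` implements a non-invasive alternative:
a **model-derived input function (MDIF)** obtained by analytically inverting
the irreversible two-tissue compartment model (2TCM) applied to the
whole-brain time-activity curve (TAC), with the four whole-brain rate
constants estimated jointly with regional kinetics by **simultaneous
estimation (SIME)**, anchored by one or two late venous samples.

The package is aimed at PET kinetic-modelling researchers. It provides:

- the forward irreversible 2TCM and its closed-form inversion (the MDIF),
- MDIF-SIME and the classic exponential-input (IDIF) SIME comparator,
- standalone weighted 2TCM fitting, Patlak analysis, CMRGlu conversion,
  and error-propagation CV of K_i,
- HYPR-style denoising and k-medoids clustering of voxel TACs to build
  functionally distinct region TACs for SIME,
- a built-in noiseless simulation study (theoretical input function, six
  regional TACs with distinct kinetics, whole-brain TAC, anchors) and a
  voxelized phantom generator,
- a `mdifkit` command-line interface covering the whole pipeline.

## The model

The irreversible 2TCM describes tissue activity as

```
C_PET(t) = (1 − V_b) (K₁/k_f) (k₃ + k₂ e^(−k_f t)) ∗ C_p(t) + V_b C_b(t),
```

with influx K₁ (mL/g/min), efflux k₂ (min⁻¹), phosphorylation k₃ (min⁻¹),
blood volume fraction V_b (mL/g), k_f = k₂ + k₃, and whole-blood activity
C_b = R·C_p for blood-to-plasma ratio R. Solving this relation for C_p with
the whole-brain TAC C_wb on the left gives the MDIF:

```
C_p(t) = 1/(R V_b) [ C_wb(t)
         + (1−V_b)/(R V_b) K₁ ( (k₃−α₂)/(α₂−α₁) e^(−α₂ t)
                              − (k₃−α₁)/(α₂−α₁) e^(−α₁ t) ) ∗ C_wb(t) ],
```

where α₁,₂ = a ∓ √(a² − b), a = ½((1−V_b)/(R V_b)·K₁ + k_f) and
b = (1−V_b)/(R V_b)·K₁·k₃. The four whole-brain parameters are found by
minimizing the joint residual over n region TACs plus anchor terms,

```
RSS = Σⱼ Σᵢ (Cⱼ_fit(tᵢ) − Cⱼ(tᵢ))² + Σₖ (C_p(tₖ) − Cₖ)²,
```

i.e. 4n + 4 free parameters (28 at n = 6), versus 4n + 7 for the
exponential-input SIME. Net clearance is K_i = K₁k₃/(k₂+k₃); CMRGlu =
K_i · [glucose] / lumped constant (0.52).

## Worked example

Recover the input function of the built-in noiseless simulation study and
re-estimate all regional kinetics with it:

```python
import numpy as np
from mdifkit import SimeProblem, fit_sime_mdif, fit_standalone, make_weights, compare_curves
from mdifkit.simulate import reference_simulation

aif, regions, wb, anchors = reference_simulation()
problem = SimeProblem(wb_tac=wb, region_tacs=regions, anchors=anchors, R=1.0, mode="mdif")
result = fit_sime_mdif(problem, seed=0)

p = result.wb_params
print(f"whole-brain: K1={p.K1:.3f} k2={p.k2:.3f} k3={p.k3:.3f} Vb={p.Vb:.3f}")
print("AUC ratios (MDIF / true AIF):",
      {k: round(v, 4) for k, v in compare_curves(result.input_function, aif).auc_ratios.items()})

weights = make_weights(wb.grid, wb)
ki = [100 * fit_standalone(t, result.input_function, weights=weights, R=1.0).params.Ki
      for t in regions]
print(f"regional Ki: {np.mean(ki):.2f} +/- {np.std(ki, ddof=1):.2f} mL/100 g/min")
```

prints

```
whole-brain: K1=0.090 k2=0.117 k3=0.066 Vb=0.067
AUC ratios (MDIF / true AIF): {'0-5': 1.0, '5-10': 1.0, '10-30': 1.0, '30-60': 1.0}
regional Ki: 3.26 +/- 0.89 mL/100 g/min
```

The whole-brain rate constants are recovered at their generating values,
the recovered input function is indistinguishable from the true one in
every AUC window, and the regional net-clearance summary is
3.26 ± 0.89 mL/100 g/min. The same flow is available from the shell:

```sh
mdifkit simulate study --out sim/
mdifkit sime --mode mdif --tacs sim/tacs.csv --wb-label WB \
             --anchors sim/anchors.csv --R 1.0 --out sime.json
mdifkit pipeline --mode mdif --out report/
```

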