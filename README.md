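# qenspol

Analysis toolkit for **polarized quasi-elastic neutron scattering (QENS)**
of proteins in solution: separation of coherent and incoherent dynamic
structure factors from spin-flip/non-spin-flip channels, empty-can and
buffer reduction, resolution-convolved Lorentzian fitting with a
simplest-model-first selection ladder, diffusion/width extraction, and
q-range diagnostics that locate where coherent scattering contaminates an
unpolarized measurement.  A first-class synthetic-data module generates
polarized channel pairs with known ground truth, so every stage of the
chain is testable end to end.

## The problem

An unpolarized QENS experiment measures the *total* dynamic structure
factor S_tot(q, ω) = S_inc(q, ω) + S_coh(q, ω), but protein dynamics are
usually modeled as if the signal were purely incoherent.  The deuterated
buffer and the protein's hydration layer contribute coherent scattering
whose S(q) peaks near q ≈ 2 Å⁻¹ (the D₂O structure-factor maximum) and
which survives buffer subtraction.  Fitted to an incoherent model, this
q-dependent contamination mimics global diffusion: the quasi-elastic
half-width Γ(q) acquires a spurious linear rise with q².  Neutron
polarization analysis (NPA) separates the channels — 2/3 of the
spin-incoherent intensity flips the neutron spin, coherent scattering
does not — via

    S_inc = 3/2 · sf        S_coh = nsf − 1/2 · sf        S_tot = nsf + sf

and the separated incoherent data reveal the true, q-independent internal
dynamics.

## Models

Per q slice, data are fit by weighted least squares with the instrument
resolution R(ω) convolved in:

* **EISF model** — `amp·[A₀(q)·δ(ω) + (1−A₀(q))·L(ω; Γ)] ⊗ R + bkg(ω)`,
  where A₀(q) is the elastic incoherent structure factor and L a
  unit-area Lorentzian of HWHM Γ; the model for locally confined internal
  motion.
* **Two-Lorentzian model** — `[amp₁·L(Γ₁) + amp₂·L(Γ₁+Γ₂)] ⊗ R + bkg(ω)`,
  global diffusion (Γ₁) plus internal dynamics riding on it (Lorentzian
  widths add under convolution); no elastic line.

Width analysis across q: Γ = ħDq² (simple diffusion, ħ = 0.6582119
meV·ps), Γ = ħDq²/(1 + Dq²τ) (jump diffusion), or an inverse-variance
weighted mean Γ̄ (confined dynamics).  The ladder accepts the EISF model
only if its median reduced χ² < 2 **and** Γ(q) shows no q² trend at 2σ.

Two diagnostics bound the safe q range for unpolarized analysis: the
largest q at which the buffer's coherent/incoherent S(q) ratio stays
below 0.5, and the turning point of the sigmoidal sample/buffer
integrated-intensity ratio.

## Worked example

```python
from qenspol.pipeline import run_pipeline

res = run_pipeline(seed=0, out_dir="runs/demo")
for kind, rep in res["selections"].items():
    print(kind, "->", rep.chosen)
print("q_max (0.5 rule):", round(res["qrange"].q_max_ratio, 3),
      "  sigmoid turning point:", round(res["qrange"].q_turning, 3))
w = res["widths"]["incoherent"]["elastic_constant"]
print("incoherent internal HWHM:", round(w.gamma_bar, 4), "±",
      round(w.gamma_bar_err, 4), "meV")
```

prints

```
incoherent -> elastic_lorentzian
total -> two_lorentzian
q_max (0.5 rule): 1.15   sigmoid turning point: 1.168
incoherent internal HWHM: 0.064 ± 0.0001 meV
```

The separated incoherent data are described by the EISF model with a
q-independent internal width of 0.064 meV, while the total data force the
two-Lorentzian model — the coherent bump masquerading as diffusion.  Both
q-range diagnostics land at q ≈ 1.15 Å⁻¹, and refitting the total data
below that cutoff (`res["qlimited"]`) brings its effective diffusion
coefficient back into agreement with the incoherent result.

The same stages are available from the shell:

```
qenspol run --seed 0 --out runs/demo
qenspol simulate --out sim && qenspol separate sim/solution_nsf.txt sim/solution_sf.txt --flipping-ratio 20
```

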