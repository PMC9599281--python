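# idpkit

Analysis toolkit for comparing sequence variants of intrinsically
disordered proteins (IDPs) — in particular Glu/Asp (glutamate vs
aspartate) variants of small acidic IDPs — across the experiments and
simulations typically brought to bear on them:

- **Sequence composition**: amino-acid enrichment of a disordered query
  set against a folded background, with sequence-level bootstrap
  confidence intervals and taxonomy stratification.
- **NMR chemical shifts**: secondary chemical shifts
  (SCS = δ_observed − δ_random-coil) and the fractional-helicity
  statistic of a residue window.
- **Binding**: combined ¹H/¹⁵N chemical-shift perturbations
  (CSP = √(ΔδH² + 0.1 ΔδN²)), the single-site quadratic binding
  isotherm, and a two-stage affinity scheme for titrations that do not
  reach saturation — fit K_D and Δδ_max on the reference protein, then
  fit variants globally with Δδ_max fixed and report the K_D
  fold-change.
- **Global dimensions**: iterative Guinier fits of SAXS curves with the
  IDP cutoff rule q_max·R_g = 0.9; Stejskal–Tanner diffusion-decay fits
  and dioxane-referenced hydrodynamic radii.
- **Conformational ensembles**: exp(V/kT) reweighting of statically
  biased (metadynamics-style) ensembles, per-frame Cα radius of
  gyration, a hydrogen-bond-energy secondary-structure dictionary
  (α/3₁₀/π helices), weighted helix censuses, 8.5 Å Cα contact maps and
  log-ratio difference maps, block-averaging error estimates, and a
  coarse one-bead-per-residue Debye scattering forward model with
  reduced-χ² model/data comparison.

Every analysis has a matching synthetic-data generator with known
ground truth (`idpkit.synth`), so the full pipeline is testable without
downloads: sequence populations with controlled residue frequencies,
noisy titrations from the exact isotherm, backbone ensembles with a
tunable transient helix grown by an along-chain Markov chain,
Guinier/Debye curves and diffusion decays.

## Worked example

A declarative config drives simulate → analyze runs:

```ini
[run]
stages = simulate_titration, fit_binding, simulate_scattering, guinier
seed = 7
outdir = out

[simulate_titration]
kd_um = 380
kd_variant_um = 1900
delta_max = T39:0.8,L40:0.6
noise_sd_ppm = 0.005

[simulate_scattering]
rg_nm = 2.0
noise_frac = 0.02
```

```sh
idpkit run --config pipeline.ini
```

prints (abridged):

```json
{
  "fit_binding": {
    "K_D_uM": 378.34,
    "delta_max_ppm": {"T39": 0.794, "L40": 0.601},
    "variant_K_D_uM": 1912.06,
    "fold_change": 5.054
  },
  "guinier": {"Rg_nm": 1.9974, "q_max_used": 0.4420, "n_points": 41}
}
```

Reading: a titration simulated with K_D = 380 µM and 0.005 ppm CSP
noise is fitted back to 378 µM; the variant, simulated 5-fold weaker,
comes back as a 5.05-fold change with the reference Δδ_max held fixed —
the scheme that stays well-posed when titrations cannot be saturated.
The Guinier stage recovers R_g = 2.0 nm from a noisy synthetic curve,
with the fitted window respecting q_max·R_g ≤ 0.9.

Individual subcommands (`compose`, `scs`, `helicity`, `csp-fit`,
`dosy`, `guinier`, `ensemble`, `simulate`) expose each stage on its
own; see `idpkit --help`.

As a library:

```python
from idpkit import synth, ensemble as ens

model = synth.HelixModel(n_residues=30, helix_region=(8, 23),
                         p_nucleate=0.3, p_stay=0.9, seed=0)
e = synth.gen_ensemble(model, n_frames=128)
e.bias = synth.gen_bias(e)                # metadynamics-like static bias
census = ens.helix_census(e)              # weighted per-residue helicity
cmap = ens.contact_map(e, cutoff=8.5)     # weighted Cα contact frequencies
```

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline's main computations from
scratch on seeded synthetic data — composition enrichment, the
two-stage binding fit, fractional helicity, Guinier/Debye scattering,
the diffusion/R_H chain, and the weighted-ensemble census — printing a
summary of the recovered quantities and writing the result file to
`--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the statistical models, default parameters
and units, what the synthetic generators do and do not emulate, and the
numerical choices (optimizer scaling, plateau detection, tie-breaks).
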