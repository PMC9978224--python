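# mlmoshape

Multi-level multi-organ particle-based statistical shape modeling.

Anatomical structures rarely come alone: a spine is a stack of vertebrae,
an ankle is several tarsal bones, a hip is a pelvis and a femur. A
statistical shape model of such a complex has to capture two very
different kinds of variation at once — the *morphology* of each organ and
the *relative pose* of the organs within the complex — and the usual
remedy, one PCA over all particles of all organs, entangles them.
`mlmoshape` optimizes dense correspondence particles over an ensemble of
multi-organ surface meshes with the two sources of variation
disentangled, and analyzes the result with multilevel component analysis
(MLCA). It is written for researchers in computational anatomy and
morphometrics who work with segmented surface meshes.

## The model

Each subject n contributes K triangle meshes; organ k carries M_k
correspondence particles, M = Σ_k M_k. Every particle splits exactly into

    x  =  z̄_n  +  (x − z̄_{n,k})  +  (z̄_{n,k} − z̄_n)
         offset     within-organ       between-organs

with z̄_{n,k} the organ's particle centroid and z̄_n the global centroid.
Correspondence is optimized by minimizing, in alternating within/between
phases,

    Q = α_W Σ_k H(Z_k^W) + α_B H(Z^B) − Σ_{n,k} H(X_{n,k}),

where H(Z_k^W) and H(Z^B) are Gaussian entropies ½ Σ log(λ + α_reg) of the
within and between covariances (3M_k × 3M_k and 3K × 3K — the between
statistics never grow with particle count), and H(X_{n,k}) is a Parzen
estimate of each surface's sampling entropy whose maximization spreads
particles uniformly. The classic entangled objective
Q = α H(Z) − Σ H(X) over the shared 3M-dimensional shape space, and the
per-organ single-structure objective, are included as baselines. All
gradients are exact derivatives of the estimated entropies (verified
against finite differences in the test suite), updates are
tangent-projected and snapped back to the surfaces, and runs are
bit-reproducible from a seed.

After optimization, `fit_mlca` fits one PCA per within subspace and one
for the between subspace — K+1 mutually orthogonal subspaces — so that
between-mode sweeps translate organs rigidly without touching any organ's
centered shape, and within-mode sweeps deform organs without moving their
centroids. Model quality is measured per subspace by compactness,
leave-one-out generalization and specificity, plus a ray-cast joint
coverage-area measurement for articulating surfaces.

## Worked example

The built-in synthetic benchmark generates multi-object "subjects" made of
Gielis supershapes: object k has k+2 lobes and one chi-squared-drawn shape
exponent (the only morphology factor), and the object centroids lie on a
parabola y = a·x² with a ~ U(0, 0.001) (the only pose factor).

```python
import numpy as np
import mlmoshape as ms

cfg = ms.EnsembleConfig(seed=11)            # N=20 subjects, K=3 objects
subjects, manifest = ms.generate_synthetic_ensemble(cfg)
subjects, _ = ms.center_ensemble(subjects)

ocfg = ms.OptimizerConfig(particles_per_organ=[128, 128, 128],
                          mode="mlmo", seed=5)
system, trace = ms.optimize(subjects, ocfg)

model = ms.fit_mlca(system)
for k, wm in enumerate(model.within):
    share = wm.eigenvalues[0] / wm.eigenvalues.sum()
    print(f"object{k}: dominant within modes ="
          f" {ms.dominant_mode_count(wm.eigenvalues)}, mode-1 share = {share:.4f}")
bshare = model.between.eigenvalues[0] / model.between.eigenvalues.sum()
print(f"between:  dominant modes ="
      f" {ms.dominant_mode_count(model.between.eigenvalues)},"
      f" mode-1 share = {bshare:.4f}")
```

Output (a few minutes on one CPU):

```
object0: dominant within modes = 1, mode-1 share = 0.9863
object1: dominant within modes = 1, mode-1 share = 0.9998
object2: dominant within modes = 1, mode-1 share = 0.9996
between:  dominant modes = 1, mode-1 share = 0.9995
```

Each within spectrum and the between spectrum concentrate in a single
mode — the optimizer recovered exactly the one morphology factor per
object and the one pose factor that the generator planted, instead of
smearing them across entangled modes.

The same pipeline is available from the shell:

```bash
mlmoshape generate-synthetic --out ens/
mlmoshape optimize --meshes ens/ --mode mlmo --out particles/
mlmoshape analyze --particles particles/ --out analysis/
mlmoshape metrics --particles particles/ --out metrics/
mlmoshape run --out experiment/          # all of the above in one go
```

See `docs/methods.md` for the model details, parameter meanings and
numerical choices.

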