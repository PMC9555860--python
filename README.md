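# gradflex

Task-modulated cortical gradients from informational connectivity.

`gradflex` is a Python toolkit for asking how the principal gradient of
cortical organisation — the axis separating unimodal sensory-motor cortex
from transmodal default-mode regions — flexes with cognitive demand in
parcellated, trial-resolved fMRI pattern data. It implements four analysis
stages and the inference machinery that connects them:

1. **Informational connectivity.** Each parcel's representational geometry
   is summarised by its between-trial multivoxel pattern-similarity matrix
   (within-run trial pairs excluded); connectivity between parcels `i, j`
   is the correlation of their similarity structures,
   `IC_ij = corr(vec(S_i), vec(S_j))`, a second-order measure that is
   sensitive to shared representational states rather than shared
   time courses. A conventional time-series correlation matrix is provided
   as the control.
2. **Gradient decomposition.** Connectivity matrices are (optionally row
   sparsified,) converted to a cosine affinity between connectivity
   profiles, and decomposed with PCA. Condition-specific gradients are
   sign-aligned to a template before their per-parcel scores are
   subtracted, giving difference maps such as strong-minus-weak
   association trials.
3. **Neural dimensionality.** For each trial and each searchlight (or
   parcel), participants' patterns are stacked into a participants x
   voxels matrix and the dimensionality is the smallest number of
   principal components whose cumulative variance exceeds a criterion
   (default > 0.90, with 0.60/0.75 robustness checks).
4. **Second-order RSA and mediation.** A semantic model (inter-participant
   correlation of association-strength ratings) is correlated with a brain
   model (inter-participant correlation of local similarity structures) at
   every location; the resulting alignment map is tested with a Mantel
   permutation of participants, and a bootstrap mediation asks whether the
   gradient's relation to alignment runs through the dimensionality
   difference (indirect effect `a*b`, proportion mediated `a*b / c`).

Spatially autocorrelated map-to-map correlations are tested with spin
permutations (random rotations of the spherical parcel centroids).

Because the kind of participant-level data this targets is typically not
publicly shareable, the package ships a first-class synthetic-data
generator (`gradflex.synth`) that plants all four effects — a latent
gradient, its modulation by association strength, per-condition latent
rank, and rating-brain coupling — with ground truth emitted alongside
every dataset, so each stage's recovery can be measured.

## Worked example

```python
import gradflex as gf

spec = gf.SyntheticSpec(seed=11)                 # 31 participants, 144 trials,
ds = gf.simulate_dataset(spec)                   # 3 runs, 100 parcels
cfg = gf.AnalysisConfig(seed=7, n_spin=1000, n_boot=1000, rsa_n_perm=1000)
gf.run_pipeline(cfg, dataset=ds, out_dir="out")
print(open("out/report.md").read())
```

Key lines of the report produced by this exact invocation:

```
- first gradient variance ratio: 0.772
- semantic (strong - weak) vs reference gradient: r = 0.812, spin p = 0.0070
- (weak - strong) vs reference gradient: r = 0.520, spin p = 0.0050
- FDR-significant locations: 10
- indirect a*b = 0.0358, 95% CI [0.0173, 0.0573]
- proportion mediated = 0.875
```

Reading: the first gradient explains ~77% of the informational-connectivity
variance and the strong-minus-weak gradient difference tracks the planted
axis (r = 0.81, significant against the rotation null); the weak-minus-
strong dimensionality contrast recovers all ten rank-modulated parcels and
also tracks the axis; the rating-coupled parcels are detected by the
second-order RSA; and the gradient-alignment relation is largely mediated
by the dimensionality difference (indirect-effect CI excludes zero).

A command-line interface wraps the same stages:

```bash
gradflex simulate --seed 3 --out sim/     # NIfTI atlas + TSV behaviour + patterns
gradflex run --seed 7 --out out/          # full pipeline on synthetic data
gradflex report --out out/
```

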