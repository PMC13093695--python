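# niikit

Diffusion-based neuroinflammation imaging (NII) for multi-shell diffusion
MRI: per-voxel inversion of a multi-compartment signal model, a
conventional DTI comparison arm, and voxelwise permutation/TFCE group
statistics — with synthetic phantom and cohort generators so the whole
pipeline can be validated end-to-end without patient data.

## Who this is for

Researchers analysing white-matter microstructure in clinical cohorts
(the motivating application is myalgic encephalomyelitis / chronic
fatigue syndrome versus matched controls) who want putative inflammation
markers — cellularity and edema fractions — rather than only tensor
anisotropy, and who need the accompanying group inference to be
permutation-exact.

## The model

Each voxel's signal is a linear combination of anisotropic tensor
compartments and an isotropic diffusivity spectrum:

    S_k = s0 [ Σ_i f_i e^{−b_k λ⊥i} e^{−b_k (λ∥i − λ⊥i) cos²ψ_ik}
               + Σ_j w_j e^{−b_k D_j} ]

Fitting inverts this per voxel — fiber directions from a DTI/stick-dictionary
step, diffusivities by a particle-swarm/Nelder–Mead global search with the
linear weights solved by NNLS inside the objective (a regularized-NNLS
dictionary solver is included as the reference method).  Derived indices:

| index | meaning |
|---|---|
| NII-RF | restricted fraction, D ≤ 0.3 μm²/ms (cellularity) |
| NII-HR | hindered share of non-restricted isotropic signal, 0.3 < D ≤ 2.5 (edema) |
| NII-FF | fiber fraction (apparent axonal density) |
| NII-AD/RD/MD/FA | tensor metrics of the fiber compartments |

Group comparisons and metric–score regressions are voxelwise GLMs with
nuisance covariates (sex, age, BMI, MET, depression, anxiety), corrected
by the permutation distribution of the maximum TFCE statistic
(Freedman–Lane residual permutation, two-tailed).  See
[docs/methods.md](docs/methods.md) for assumptions, identifiability
limits of two-shell acquisitions, and all defaults.

## Worked example

Simulate a small two-region phantom on the emulated 97-volume protocol
(8 b0 + 27 directions at b = 1000 + 62 at b = 2500 s/mm²), fit it, and
summarize:

```bash
niikit simulate-phantom --seed 2 --shape 2 --out phantom/
niikit fit-nii --dwi phantom/dwi.nii.gz --bval phantom/dwi.bval \
       --bvec phantom/dwi.bvec --mask phantom/mask.nii.gz --out fits/
niikit metrics-summary --maps-dir fits/ --mask phantom/mask.nii.gz \
       --out summary.tsv
```

`summary.tsv` (half the phantom is generated with FF = 0.8, half 0.5, so
the mask-mean fiber fraction is 0.65; the near-zero NMSE shows the fitted
model reproduces the noise-free signals):

```
metric      mean                    sd                      n_voxels
nii_AD      1.7000060081481934      4.947544766764622e-06   8
nii_FA      0.7990226745605469      2.86102294921875e-06    8
nii_FF      0.6499983072280884      0.14999538660049438     8
nii_HR      1.0                     0.0                     8
nii_MD      0.7666689157485962      4.172325134277344e-07   8
nii_NMSE    1.091141754727687e-08   8.328379763611338e-09   8
nii_RD      0.30000039935112        3.069639205932617e-06   8
nii_RF      0.058847036212682724    0.058847036212682724    8
```

Both regions were generated with an axial diffusivity of 1.7 and radial
0.3 μm²/ms, which the fit recovers to ~10⁻⁵; the restricted-fraction
column illustrates the two-shell band-split degeneracy discussed in the
methods note (true region values 0 and 0.2, fitted mean 0.06).

A cohort study runs the same way from `simulate-cohort` through
`stats-glm` (which writes t, TFCE and 1−p maps plus a cluster table) and
`stats-demographics` (chi-square for sex, Wilcoxon rank sum otherwise).
The Python API mirrors the CLI: `make_phantom`, `fit_nii_volume`,
`make_cohort`, `permutation_fwe`, …

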