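# objdim

Voxel-wise encoding of behaviour-derived object dimensions.

A long-standing question in visual neuroscience is whether object
responses in higher visual cortex are organised around discrete
categories (faces, bodies, scenes) or around continuous, behaviourally
relevant dimensions. `objdim` implements the analysis toolkit for the
dimensional view: it models each voxel's response to object images as a
weighted combination of 66 interpretable, non-negative object dimensions
derived from human similarity judgements, and then interrogates the
resulting weight maps. It is aimed at computational neuroimaging
researchers who want to run, extend, or stress-test this family of
encoding analyses without the original multi-terabyte fMRI dataset: a
first-class synthetic generator reproduces the statistical structure the
analysis assumes, with ground truth for every recovery claim.

## What it implements

- **Synthetic study generator** — sparse non-negative embedding,
  session-structured designs with repeated images, voxels with
  sparse/dense/no tuning on a 3-D lattice, HRF-convolved BOLD series,
  noise at controlled SNR or noise ceiling (`objdim.synth`).
- **Embedding extension** — per-dimension ridge regression from image
  features to dimension values, CV-selected penalties (`objdim.embed`).
- **Single-trial encoding** — OLS fit of the 66 dimensions
  (y<sub>v</sub> = Xβ<sub>v</sub> + ε), leave-one-session-out CV,
  permutation p-values, Benjamini–Hochberg FDR, noise ceiling
  nc = σ²<sub>signal</sub>/(σ²<sub>signal</sub>+σ²<sub>noise</sub>) from
  repeated images, and nc-corrected R² (`objdim.trial`).
- **Parametric modulation** — onset + 66 mean-centred modulators on the
  time series, a 20-kernel double-gamma HRF library, fractional ridge
  regression (the penalty is parameterized by the retained coefficient-
  norm fraction f = ‖β(λ)‖/‖β<sub>OLS</sub>‖), per-voxel hyperparameter
  selection by 12-fold between-session CV (`objdim.modulation`,
  `objdim.ridge`, `objdim.hrf`).
- **Regional tuning profiles** — rectified ROI-mean weight profiles,
  most-representative-image ranking by cosine similarity,
  inter-participant consistency (`objdim.profiles`).
- **Representational sparseness** — mask-renormalized smoothing, the
  Hoyer statistic s(x) = (√n − ‖x‖₁/‖x‖₂)/(√n − 1) on rectified weight
  vectors, z/p against a noise-pool null (voxels with CV R² < 10⁻⁴),
  cluster discovery (`objdim.sparseness`).
- **Variance partitioning** — AUC-selected diagnostic dimensions,
  mutual orthogonalization, unique/shared/combined cross-validated R²
  for the dimension vs category models (`objdim.partition`).
- **Pipeline** — `run_pipeline(RunConfig(...))` chains the stages and
  writes TSV/NIfTI artifacts plus a reproducibility manifest
  (`objdim.pipeline`, `objdim.io`).

See `docs/methods.md` for the models, defaults, numerical choices and
known limitations (including a calibration caveat on the permutation
null), and `examples/` for one short narrative script per capability.

## Worked example

`examples/05_sparseness_mapping.py` simulates 216 voxels (a compact blob
of sparsely tuned voxels, a blob of densely tuned voxels, and a detached
slab of unresponsive voxels), fits the parametric-modulation model, and
maps sparseness:

```
sparse voxels: median s = 0.717, median z = +4.37
 dense voxels: median s = 0.073, median z = -23.55
 noise voxels: median s = 0.506, median z = +0.12
noise pool size: 88 voxels
clusters found (p < 0.05, >= 5 voxels): 1
top cluster: 33 voxels, peak z = 5.79
```

Reading these numbers: the Hoyer statistic s is 1 when a voxel responds
to a single dimension and 0 when it weights all 66 equally. The planted
sparse blob scores high (s ≈ 0.72) and sits far above the noise-pool
null (z ≈ +4.4), the densely tuned blob sits far below it, and
unresponsive voxels centre on z ≈ 0 by construction. Cluster discovery
recovers the sparse blob as the single supra-threshold cluster — the
synthetic analogue of localizing category-selective regions from
sparseness maps alone.

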