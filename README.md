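# mmconn

Individual multi-modal brain connectivity from structural MRI and FDG-PET,
for studies of conversion from mild cognitive impairment (MCI) to
Alzheimer's disease.

Morphological and metabolic brain networks are usually estimated at the
group level, which makes them useless as per-patient biomarkers. `mmconn`
implements a construction that yields one network per subject from a single
pair of images, by borrowing statistical strength from an independent
auxiliary cohort of AD and normal-control (NC) subjects:

1. **Bagged regional PCA.** For each of T stratified bootstrap resamples of
   the auxiliary cohort, per-region, per-modality principal components are
   trained (top S eigenvectors of the regional voxel covariance). A target
   subject projected onto all T replicate bases yields, per modality and PC
   index i, a matrix X_i ∈ R^(T×K) over the K atlas regions.
2. **Multi-task sparse regression.** For each target region k, its column
   y = X_i[:, k] is regressed on all other regions with the column zeroed,
   one task per modality, under an l2,1 (group-lasso) penalty:

   min_W ½ Σ_m ‖y^m − X^m w^m‖² + λ Σ_j ‖W_j·‖₂,  λ = ratio × λ_max

   Whole rows of W are zeroed jointly across modalities, so a neighbour is
   selected only if it predicts the target in both the structural and the
   metabolic channel.
3. **Binary-to-decimal edge weights.** Repeating this for the top S PCs
   gives a K×S binary support matrix per target region; each regressor's
   S-bit pattern (PC 1 = most significant bit) is read as a binary number
   and normalized by 2^S − 1. The result is an asymmetric K×K network with
   edge weights in {0, 1/(2^S−1), …, 1}.

The package also implements the matching evaluation protocol — leave-one-out
cross-validation with nested two-step feature selection (pooled-t filter to
the top 20%, linear SVM-RFE with a scheduled step size, inner 5-fold search
of the SVM cost over 2^β) — plus edge-wise two-sample t tests with
Benjamini–Hochberg FDR control and the usual cohort-table statistics. A
synthetic-cohort generator with planted group effects and planted
cross-regional couplings makes the whole pipeline testable without imaging
data; see `docs/methods.md` for the model and its limits.

## Worked example

Run a small simulated study end to end (simulate → train basis → project →
build networks → classify → edge-wise group difference):

```python
from mmconn import (Coupling, SimulationConfig, SelectionConfig)
from mmconn.pipeline import PipelineConfig, run_pipeline

sim = SimulationConfig(K=12, voxels_per_region=(8, 12),
                       group_sizes=(10, 10, 8, 8), effect_size=1.5,
                       couplings=(Coupling(0, 1, 2.0, 2.0),), seed=7)
cfg = PipelineConfig(simulation=sim, T=20, S_grid=(3,), lambda_grid=(0.5,),
                     selection=SelectionConfig(c_betas=tuple(range(-4, 5))),
                     seed=11)
manifest, grid = run_pipeline(cfg)
print(grid.to_string(index=False))
```

prints

```
 lambda_ratio  S  accuracy  sensitivity  specificity      auc  peak_fraction
          0.5  3    0.4375          0.5        0.375 0.328125            0.4
```

one row per (λ, S) grid cell: the leave-one-out peak accuracy, sensitivity
(pMCI, i.e. converters, is the positive class), specificity, and the AUC of
the pooled decision values, together with the feature fraction at which the
peak occurred. At this 16-subject toy scale the classifier sits at chance —
the point of the example is the mechanics and the provenance:
`manifest.stage_hashes` records a content hash per stage, so an identical
config and seed replays bit-for-bit. See `docs/methods.md` for what the
synthetic study can and cannot show.

The same pipeline is available from the shell:

```sh
mmconn simulate --seed 20191115 --out study/
mmconn train-basis --aux study/aux_cohort.h5 --T 50 --S 5 --seed 1 --out study/basis.npz
mmconn build-network --target study/target_cohort.h5 --basis study/basis.npz \
       --lambda-ratio 0.7 --out study/networks/
mmconn run-all --seed 11 --out study/run/
```

Cohorts live in one HDF5 container (group per modality, dataset per region)
with a tab-separated metadata sidecar; networks and edge statistics are
exported as TSV with region-id headers.

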