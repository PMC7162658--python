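# connfp

Cross-species connectivity-fingerprint matching as a reusable, tested
pipeline. Given one species' seed regions and another species' voxels, the
package:

1. **parcellates** a structure from a tracer connectome (z-scored
   injection x voxel strengths, voxel-voxel correlation, average-linkage
   hierarchical clustering, silhouette model selection, Dice comparison of
   parcellations);
2. **conditions** resting-state timeseries (linear detrend, running-median /
   MAD despiking, zero-phase Butterworth bandpass) and summarises
   multi-voxel seeds by their principal eigenvariate;
3. builds **seed-to-target connectivity fingerprints** (Pearson r, optional
   Fisher r-to-z), robust-mean (20% trimmed) templates, and tests
   fingerprint uniqueness by within-subject label-exchange permutation on
   the Manhattan distance;
4. **matches** every voxel of the other species against the templates:
   per-subject similarity z-maps, one-sample sign-flip permutation tests
   with TFCE (threshold-free cluster enhancement) family-wise correction,
   multi-label voxel assignment with "unassigned" status, a
   minimum-statistic conjunction isolating voxels significantly *different*
   from every template, and weighted-seed whole-brain maps with
   cluster-extent FDR;
5. **localises** voxel sets against probabilistic atlases
   (distribution-based assignment quotients, per-structure volume-fraction
   tables).

A first-class synthetic-data module (`connfp.synthdata`) generates tracer
matrices with planted voxel clusters, multi-subject multi-species
timeseries with controlled fingerprints (closed-form expected
correlations), and probabilistic atlases — so every stage is testable with
known ground truth and no external downloads.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (calibration and
planted-truth-recovery simulations); it takes several minutes. The rest of
the suite runs in seconds.

## CLI

```bash
connfp --help
connfp simulate   --spec sim.yaml --out simdir/         # synthetic data + ground truth
connfp preprocess --input ts.nii.gz --output out.nii.gz --tr 1.0 --low 0.01 --high 0.25
connfp parcellate --connectome tracer_matrix.csv --out parc --kmin 2 --kmax 10
connfp fingerprint --seed seeds.csv --targets targets.csv --out fp.csv
connfp match      --stack zmaps4d.nii.gz --out stats --n-perm 10000 --alpha 0.05
connfp localise   --cluster mask.nii.gz --atlas atlas4d.nii.gz --out quotients.csv
connfp run        --config run.yaml --out outdir/       # full two-species comparison
```

`connfp run` takes a YAML file with a `pipeline` section (see
`connfp.pipeline_io.PipelineConfig`; defaults: 10,000 permutations, alpha
0.05, TFCE E=0.5 / H=2 / 6-connectivity, voxel p 0.001 with cluster-extent
FDR 0.05) and `source` / `target` species simulation sections. Outputs are
NIfTI maps (t, corrected p, unassigned, significantly-different), CSV
reports (templates, distance tests, volume fractions) and a JSON manifest
recording seeds and input hashes so reruns are bit-identical.

The Python API mirrors the stages: `connfp.pipeline_io.run_comparison`
orchestrates conditioning → fingerprints → templates → voxelwise matching →
group TFCE inference → classification → conjunction → localisation for two
in-memory datasets.

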