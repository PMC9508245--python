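# connvar — inter-subject variability of multimodal brain connectomes

How much does a cortical region's connectivity differ between people, and is
that variability consistent across imaging modalities? `connvar` implements a
complete analysis pipeline for this question, built for connectomics
researchers who have per-subject region × region connectivity matrices
(structural, from diffusion tractography; functional, e.g. MEG amplitude-
envelope correlations) and want region-wise variability maps with honest
uncertainty and multiplicity control.

## The statistic

For subjects *m*, *n* with connectivity matrices *S^m*, *S^n* (R × R, one row
per region), the inter-subject distance of region *r* for the pair
*p = (m, n)* is the cosine distance between the region's connectivity
profiles:

    Dist_subj(p, r) = 1 − ⟨S^m(r,:), S^n(r,:)⟩ / (‖S^m(r,:)‖ ‖S^n(r,:)‖)

and the region's inter-subject variability (ISV) is the mean over all
N(N−1)/2 subject pairs:

    ISV(r) = (1 / C(N,2)) Σ_p Dist_subj(p, r)

For two-session functional data, within-subject between-session distances
Dist_ses(m, r) are computed the same way and regressed out of Dist_subj
(predictor for pair (m, n): the mean of the two subjects' session
distances), so that measurement noise does not masquerade as between-subject
variability. ROI size is regressed out of the ISV map, clusters are
aggregated by unweighted means, and uncertainty comes from bootstrapping the
pair rows of Dist_subj.

Around this core the package provides:

- **Connectome construction** — QuickBundles-style streamline trimming
  (flip-invariant mean pointwise distance, 20 mm threshold, clusters of < 3
  discarded), streamline counting, the 50-streamline threshold with row
  normalization to connection probabilities, and cost-efficiency-guided
  proportional thresholding of functional matrices.
- **Cross-modal correspondence** — per-cluster Spearman correlation between
  the two modalities' subject-pair distance vectors, with family-wise error
  control by a max-statistic permutation test that relabels *subjects*
  (Mantel-style), respecting the dependence between pairs sharing a subject.
- **Microstructure PCA** — seven tract metrics (ICVF, ODI, FR, FA, MD, AD,
  RD) sampled along streamlines (median of medians), z-scored per subject,
  pooled PCA with sign anchoring, and per-ROI component maps.
- **Spatial-autocorrelation-corrected map correlation** — variogram-matched
  surrogate maps on geodesic distance as the null for comparing cortical
  maps, alongside the (inflated) naive permutation p-value.
- **Group comparisons** — two-sided label-permutation tests of mean ISV
  between ROI groups (e.g. multiple-demand core / penumbra / non-MD), with
  Bonferroni correction.
- **Synthetic cohorts** — generators for every input (spherical atlas,
  sparse distance-dependent streamline counts with region-dependent
  variability σ(r), two-session functional matrices with per-subject noise
  levels, coupled cross-modal cohorts, 2-factor microstructure tables,
  Gaussian-random-field cortical maps), so the whole pipeline is testable
  without any imaging data.

## Worked example

```python
import numpy as np
import connvar as cv

# a synthetic atlas and a two-session functional cohort whose regional
# variability rises linearly from sigma = 0.1 to 0.5
parc = cv.make_parcellation(R=60, K=6, seed=0)
spec = cv.CohortSpec(
    n_subjects=12, parc=parc,
    sigma_profile=np.linspace(0.1, 0.5, 60),
    session_noise=0.3, n_sessions=2, seed=0,
)
cohort = cv.make_meg_cohort(spec)
session1 = [c[0] for c in cohort]
session2 = [c[1] for c in cohort]

model = cv.ConnectomeISV(session1, parc, session2=session2, modality="functional")
res = model.fit(bootstrap=2000, seed=1)
print(res.summary())
```

```
Inter-subject variability of connectivity
==========================================
subjects: 12   pairs: 66   ROIs: 60
modality: functional   intersession-corrected: True   size-regressed: True
intersession fit: slope=0.2391 intercept=0.6031

 cluster       isv  n_rois  boot_median  boot_ci_lo  boot_ci_hi
       2 -0.048631       9    -0.048731   -0.053873   -0.043627
       3 -0.055522      11    -0.055544   -0.061458   -0.049345
       1 -0.001107      13    -0.001135   -0.006080    0.003567
       5  0.038778       7     0.038720    0.029435    0.048398
       4  0.034772       9     0.034755    0.029331    0.039992
       0  0.043492      11     0.043498    0.037409    0.049740
```

The positive intersession slope (0.24) shows the correction at work: subject
pairs whose members have noisier recordings sit further apart, and that
component is removed before averaging. Cluster ISV values are residuals
after ROI-size regression, so they are centered near zero; the clusters
whose ROIs carry the largest planted σ (clusters 0, 4, 5; mean σ 0.43,
0.40, 0.37) come out above the low-σ clusters (2, 3; mean σ 0.18, 0.20),
with non-overlapping bootstrap intervals.

Every analysis is also available as a model object
(`CrossModalCorrespondence`, `MicrostructurePCA`) or a function
(`sa_corrected_correlation`, `permutation_group_test`), and as a CLI:

```bash
connvar simulate --modality meg --n-subjects 12 --out cohort/
connvar isv --modality meg --cohort cohort/meg_manifest.json \
        --parcellation cohort/parcellation.tsv --bootstrap 5000 --seed 7 --out isv.tsv
connvar run --config pipeline.json   # config-driven end-to-end run
```

## Layout

```
src/connvar/
  parcellation.py    atlas model, geodesic distances, cross-resolution maps
  synthetic.py       cohort and fixture generators
  connectome.py      trimming, counting, thresholding, efficiency
  isv.py             the ISV estimator and ConnectomeISV / ISVResults
  crossmodal.py      cluster-level cross-modal correspondence with FWE
  microstructure.py  metric sampling, pooled PCA, ROI component maps
  spatial.py         variograms, surrogate maps, SA-corrected correlation
  groups.py          ROI-group permutation comparisons
  pipeline.py        config-driven end-to-end runner
  cli.py             `connvar` command-line interface
docs/methods.md      model assumptions, parameter choices, limitations
```
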