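# spectralbeads

Image analysis for multiplexed bioassays on spectrally encoded hydrogel
beads. In these assays each bead carries an embedded ratiometric barcode —
lanthanide nanophosphor (LNP) species such as Dy, Sm and Tm mixed at designed
ratios against an invariant Eu reference — and analytes (e.g. peptides) are
linked one-to-one to codes. After incubation with a fluorescently labelled
probe, a single multi-channel image stack per stage position contains
everything needed: a bright-field image in which beads appear as dark rings,
~9 narrow-band emission channels that encode the barcode, and one or more
fluorescence channels in which bound probe forms a thin bright ring at each
bead's perimeter.

`spectralbeads` turns those images into per-bead and per-code binding data:

1. **Find** beads by adaptive Gaussian thresholding (block 15 px, offset 11)
   of the bright-field image and a seeded watershed that uniquely splits
   touching beads, yielding whole/core/ring/background region masks with
   morphology-based filtering (area within 50–150% of the accepted bead
   size, eccentricity ≤ 0.65).
2. **Unmix** the emission channels per pixel by ordinary least squares,
   `A·X = B`, where `A` is the channels × references spectrum matrix
   (LNP species + background; e.g. 9 × 5), `B` the channels × pixels
   intensities, and `X` the per-species weights; ratio images divide each
   variable species by the invariant reference.
3. **Extract** per-bead medians (code ratios over the core, probe
   fluorescence over the ring with local background subtraction from each
   bead's own annulus) and remove bead-like non-beads whose invariant-LNP or
   unmixed-background levels deviate > 2 SD from the mean.
4. **Decode** by registering the observed ratio cloud onto the designed
   target codes with a trimmed iterative-closest-point affine fit
   (cost Δ = (Σ(T_new−T_old)² + Σ(o_new−o_old)²)/(ΣT_new² + Σo_new²)),
   then classifying beads with a supervised full-covariance Gaussian mixture
   (means initialized at the targets, σ₀ = 10⁻⁵), reporting per-bead
   probabilities, missing codes, confidence ellipses and the silhouette
   score.
5. **Analyze**: per-code statistics of the background-subtracted signal and
   QC report data (size and per-code histograms, cross-talk correlations,
   per-bead image tiles).

A seeded synthetic scene generator (`spectralbeads.synth`) renders this
exact imaging model with a ground-truth manifest, so the entire pipeline is
testable without microscope data.

## Worked example

Render a 48-code library (4 Dy × 4 Sm × 3 Tm ratio levels, 10 beads/code)
and run the full pipeline on it:

```python
from spectralbeads.cli import load_config, run_pipeline

config = load_config(None, {"simulate": True, "sim_beads_per_code": 10,
                            "sim_image_shape": [640, 640]})
out = run_pipeline(config, "scratch/demo", seed=2)
print(out["decode_qc"])
print(out["code_summary"].head(3))
```

prints

```
{'n_iterations': 2, 'icp_converged': True, 'clusters_found': 48,
 'missing_codes': [], 'silhouette': 0.7491869664099994}
   code  n_beads        mean      median         sd          q1          q3
0   0.0        9  498.766259  496.436931  23.971546  492.736928  506.496610
1   1.0        8  506.808204  510.818329  18.712833  496.582593  522.243178
2   2.0        8  507.387623  504.474681  14.633225  495.389241  521.040415
```

i.e. the ICP converged in 2 iterations, all 48 designed code clusters were
found with none missing, the cluster silhouette is 0.75, and the per-code
table gives the kept-bead count (8–10 of the 10 rendered per code survive
the 2-SD filter) and the background-subtracted Cy5 binding signal per code —
the generator's true ring signal is 500 ± 20 counts, so per-code means near
500 are the expected recovery after local background subtraction.

The same pipeline runs from the shell on a folder of OME-TIFFs:

```bash
spectralbeads simulate --out scratch/sim --seed 1 --beads-per-code 5
spectralbeads find --folder scratch/sim --pattern 'scene_(\d+)\.ome\.tif' \
    --out scratch/found
```

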