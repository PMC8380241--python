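# mnflow

Automated scoring of the cytokinesis-block micronucleus (CBMN) assay from
imaging-flow-cytometry-style single-cell images, end to end:

1. **synthimg** — seeded synthetic data: two-channel (nuclear fluorescence +
   brightfield) 64×64 16-bit cell images for all nine phenotype classes
   (mono/bi/tri/tetranucleate ± micronucleus, other/unscorable), laboratory
   rendering profiles (stain gain, blur, illumination tilt, noise), and full
   dose–response experiments with a known ground-truth benchmark dose.
2. **ingest** — the interchange format (two-page 16-bit TIFF + CSV manifest),
   min/max illumination rescaling, centre crop/zero-pad to 64×64, and
   single-cell gating (brightfield area 200–500 µm², aspect ratio 0.75–1.0,
   gradient-RMS focus score 55–80; all bounds inclusive).
3. **deepflow** — the nine-class dual-path ("Inception"-style) convolutional
   classifier, implemented in pure NumPy (no GPU or DL framework needed):
   im2col convolutions, batch norm, max/average pooling, softmax head; ADAM
   with cross-entropy, L2 1e-4, batch size 88, initial learning rate 5e-3
   dropping ×0.9 every 5 epochs; reflection/rotation/translation/90–110 %
   scaling augmentation; fully seeded and reproducible.
4. **evalmetrics** — human-vs-network confusion matrix with per-class
   precision / false-discovery rate / sensitivity / false-negative rate,
   overall accuracy, and stratified 60/40 train–test splitting.
5. **mnstats** — binucleated-cell micronucleus frequencies and the
   significance framework: log10 transform, Shapiro–Wilk + Bartlett
   pretests, then one-sided Dunnett (or Dunn many-to-one with Šidák
   correction) versus vehicle control, starred at p < 0.05 / 0.01 / 0.001.
6. **bmd** — covariate benchmark-dose analysis with the EFSA/PROAST
   exponential and Hill families: lognormal error, likelihood-ratio ladder
   for level-specific variance/background/potency (steepness and maximum
   always shared), BMD at CES 50 % with two-sided 90 % profile-likelihood
   confidence intervals per covariate level.

## Command line

```bash
mnflow simulate --out data/ --n-cells 2000 --lab site_a --seed 1
mnflow ingest --manifest data/manifest.csv --pixel-size 0.33 --out gated/ --gates default
mnflow train --manifest gated/manifest.csv --config train.yaml --out model.npz --seed 1
mnflow score --model model.npz --manifest gated/manifest.csv --out scores.csv
mnflow evaluate --model model.npz --manifest test/manifest.csv --report report.csv
mnflow dose-response --scores scores.csv --out freq.csv --stats stats.csv
mnflow bmd --freq freq.csv --covariate scoring_method --family both --ces 0.5 --out bmd.json
mnflow run --config pipeline.yaml --workdir out/ --seed 1   # full pipeline
```

`mnflow run` drives everything from one YAML config (sections: `simulate`,
`gating`, `network`, `training`, `bmd`, plus `global_seed`); every stage's
seed is fanned out deterministically from the global seed and reruns with
the same config produce byte-identical artifacts.

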