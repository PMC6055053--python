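# spectrafuse

Low-level (centralized) fusion of Raman spectroscopic and MALDI mass
spectrometric imaging data.

Both modalities are brought onto a common spatial grid by landmark-based
affine co-registration, preprocessed separately (Raman: cosmic-spike removal,
SNIP fluorescence-background subtraction, vector normalization; MALDI: SNIP
chemical-noise background, per-pixel m/z phase correction, peak picking,
mass-relative ppm binning, TIC normalization), then balanced with a weighting
coefficient equal to the ratio of the two blocks' matrix l1-norms and
column-concatenated for a joint mean-centered PCA.  The quality of a block
weighting is judged by how slowly the cumulative proportion of explained
variance rises with the number of principal components; a weighting sweep
records that curve over a coefficient grid.

A phantom generator (`spectrafuse.synthetic`) produces paired Raman (25 µm
pitch) and MALDI (75 µm pitch) maps on mutually rotated grids with known
abundance fields, exact landmarks, isotope envelopes, per-pixel m/z jitter,
fluorescence baselines, cosmic spikes, chemical background and Poisson noise.
One component is MALDI-only and low-energy by construction: an unweighted
fusion buries it, the l1-ratio-weighted fusion exposes it in the first three
principal components.

## Command line

```bash
# generate the phantom fixtures
spectrafuse synth --seed 42 --outdir fixtures/

# all-in-one run: coregister -> preprocess -> weight -> fuse -> evaluate
spectrafuse run --raman fixtures/raman.csv --maldi fixtures/maldi.csv \
    --landmarks fixtures/landmarks.csv --outdir out/

# individual stages
spectrafuse preprocess-raman --input raman.csv --out raman_proc.csv
spectrafuse preprocess-maldi --input maldi.csv --out maldi_proc.csv
spectrafuse coregister --source raman.csv --target maldi.csv \
    --landmarks lm.csv --out raman_on_maldi.csv
spectrafuse fuse --raman raman_proc.csv --maldi maldi_proc.csv \
    --weight auto --out fused.csv
spectrafuse evaluate sweep --raman raman_proc.csv --maldi maldi_proc.csv \
    --weights 1:20 --outdir out/
```

`spectrafuse run` writes `report.json` (block norms, weighting coefficient,
explained variances), the resolved `config.yaml`, cumulative-variance and
cross-correlation CSVs, an RGB score composite and, if configured, the
weighting-sweep surface.  Runs are deterministic for a fixed seed and config.

Configuration is a YAML file mirroring the defaults in
`spectrafuse/config.py` (`snip.*`, `raman.*`, `maldi.*`, `fuse.weight`,
`evaluate.*`); unknown keys are rejected.

## Data formats

- **wide CSV**: row 1 is `x,y` followed by the channel axis (cm⁻¹ or Da);
  each further row is one pixel (x, y in µm, then intensities).
- **imzML**: continuous-mode read/write plus processed-mode reading as
  per-pixel peak lists; positions are grid indices converted to µm via the
  pixel-size parameters.
- **landmarks**: 4-column CSV `x_src,y_src,x_tgt,y_tgt` (µm), at least 3
  non-collinear rows.

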