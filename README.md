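# mrcquant

Quantitative analysis for **molecular-recruitment-colocalization (MRC)**
live-cell imaging. In an MRC experiment a *bait* protein is recruited to a
genomic repeat locus (e.g. via dCas9–SunTag), where it forms bright
diffraction-limited puncta; a *prey* protein that interacts with the bait is
co-recruited and forms colocalized puncta in a second channel. The same
platform is used to nucleate biomolecular condensates at designated loci and
to probe their material state by FRAP and single-particle tracking.

`mrcquant` implements the downstream quantification for people running (or
reviewing) such experiments:

- **Spot detection** — Laplacian-of-Gaussian puncta detection inside nuclear
  masks, per-cell spot counts and population statistics.
- **SNR and binding proxy** — per-spot signal-to-noise ratio
  `SNR = (peak − background mean) / background SD`, with the background taken
  from a 3–4 µm disk around the spot excluding labelled spots; the bait/prey
  SNR ratio over matched pairs serves as a relative proxy for binding
  capability.
- **Colocalization** — greedy nearest-neighbour spot matching across
  channels, per-cell colocalization percentages, plus pixel-wise Pearson and
  Manders coefficients.
- **Condensate morphometrics** — threshold segmentation, area, perimeter and
  `circularity = 4π·area/perimeter²` (1 for a perfect circle), log-normalized
  area distributions, condensate-versus-punctum classification.
- **FRAP analysis** — control-based drift correction, pre/post-bleach
  standardization, fractional recovery
  `R_fract(t) = (R_norm(t) − R_norm(0)) / (1 − R_norm(0))`, and a
  single-exponential fit `R_fract = A(1 − e^{−t/τ})` with mobile fraction A,
  time constant τ and `%recovery = 100·A`.
- **Single-particle MSD** — trajectory linking, time-averaged mean squared
  displacement, effective diffusion from `MSD = 4·D_eff·Δt`, anomalous
  exponent α, and inside/outside-condensate group comparisons.
- **Statistics & pipeline** — Welch t-tests, one-way ANOVA with Tukey HSD and
  compact-letter display, and a seeded end-to-end pipeline producing
  reproducible JSON reports.

Because raw microscopy from such experiments is rarely shareable, the package
ships a first-class **synthetic-microscopy module** that renders nuclei,
Gaussian-PSF puncta, soft-edged condensates, FRAP traces and random-walk
trajectories with known ground truth, so every stage is verifiable end to
end.

## Worked example

```python
import numpy as np
from mrcquant.simulate import SimulationConfig, generate_cell_image
from mrcquant.spots import detect_spots
from mrcquant.coloc import match_spots, spot_snr, snr_ratio_stat

# 15 cells, 2 bait spots each; 80% of bait spots get a prey partner at
# 0.7x the bait amplitude
cfg = SimulationConfig(n_cells=15, image_shape=(256, 256), spots_per_cell=2,
                       coloc_fraction=0.8, prey_to_bait_ratio=0.7, seed=11)
stack, mask, truth = generate_cell_image(cfg)
bait = detect_spots(stack, mask, channel=0, threshold_k=5)
prey = detect_spots(stack, mask, channel=1, threshold_k=5)
print(f"detected {len(bait)} bait and {len(prey)} prey spots in 15 cells")

pcts, pairs = [], []
for cid in range(1, 16):
    b = [s for s in bait if s.cell_id == cid]
    p = [s for s in prey if s.cell_id == cid]
    if not b:
        continue
    res = match_spots(b, p, max_dist_um=0.3)
    pcts.append(res.coloc_percent)
    for bs, ps, _ in res.pairs:
        mb = spot_snr(stack, bs, exclusion_spots=bait + prey)
        mp = spot_snr(stack, ps, exclusion_spots=bait + prey)
        pairs.append((mb, mp))
stat = snr_ratio_stat(pairs)
print(f"colocalization: {np.mean(pcts):.1f}% +/- {np.std(pcts, ddof=1):.1f}%"
      f" (n = {len(pcts)} cells)")
print(f"SNR ratio (bait/prey): {stat.mean:.2f} +/- {stat.sd:.2f}"
      f" (n = {stat.n} pairs)")
```

Output:

```
detected 30 bait and 25 prey spots in 15 cells
colocalization: 83.3% +/- 24.4% (n = 15 cells)
SNR ratio (bait/prey): 1.33 +/- 0.05 (n = 25 pairs)
```

All 30 generated bait spots are found; 25 of them were given prey partners
(p = 0.8), all of which are detected and matched, so the per-cell
colocalization average reflects the generation probability. The SNR ratio of
~1.4 mirrors the configured prey/bait amplitude ratio of 0.7 (the PSF tail of
the spot slightly raises the local background estimate, so the ratio is a
relative, not absolute, readout — which is how it should be interpreted).

The same stages are exposed on the command line:

```
mrc-quant simulate cells --seed 3 --out sim/
mrc-quant spots --in sim/cells.tif --mask sim/mask.tif --channel 0 --out out/
mrc-quant run --config config.yaml --out report/
```

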