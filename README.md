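# truecoloc

Automatic *true colocalization* analysis for dual-channel fluorescence
microscopy images.

Determining whether two fluorescent labels genuinely occupy the same pixels
— and which pixels those are — is a standard task in cell biology (is a
kinase in the mitochondria? do two receptors co-internalize?).  Whole-image
statistics fall short: Pearson's correlation coefficient

```
r = Σ(S1ᵢ − S̄1)(S2ᵢ − S̄2) / √(Σ(S1ᵢ − S̄1)² · Σ(S2ᵢ − S̄2)²)
```

can sit at zero or below while a real colocalized population hides inside
the image, and the Manders fractions `m1`, `m2` need a hand-picked
threshold.  `truecoloc` instead classifies pixels iteratively from the
product of their per-pixel contributions to `r` and to the Manders overlap
coefficient `R = Σ S1ᵢS2ᵢ / √(Σ S1ᵢ² · Σ S2ᵢ²)` (the *mixed map*): each
round takes the pixels at ≥ 80% of the map's maximum as colocalizing (and
≤ 80% of a negative minimum as anti-colocalizing), rebuilds the map on the
remainder, and stops when > 1% of a round's classifications are background
(zero intensity in either channel).  The final mask is the round at which
the area under the in-mask-`R`-vs-round curve reaches 86% of its total.
The procedure needs no visual threshold and works even when the overall
`r` is negative.

The package also provides:

- per-pixel **contribution maps** for `r`, `R`, `m1`, `m2` (each sums
  exactly to its coefficient) to see *where* colocalization lives;
- a **block-scrambling significance test** for `R` (and `r`): one channel's
  pixels or PSF-sized blocks are permuted to build the null distribution of
  random overlap, and a Student-t fit turns it into a probability;
- **synthetic image generators** with ground truth (pixel-sized objects at
  5–30% density; 220-pixel circle objects) and a benchmark grid;
- a **Costes automatic-threshold baseline** (orthogonal regression +
  threshold walk) for comparison;
- **time-lapse kinetics**: per-frame, photobleaching-normalized `m1`
  series for protein translocation into a marker-defined compartment.

## Worked example

```python
import numpy as np
from truecoloc import (
    ImagePair, SimConfigA, ScrambleConfig, simulate_pixel_objects,
    run_colocalization, evaluate_detection, significance_test, pearson_r,
    subtract_background,
)

# a 160x160 synthetic pair: 10% object density per channel, half of the
# green objects deliberately colocalized, uniform noise in [10, 30]
noisy, truth = simulate_pixel_objects(SimConfigA(
    density_green=0.10, density_red=0.10, coloc_fraction=0.5, rng_seed=7))

# subtract the noise ceiling so background is exactly zero, then classify
pair = ImagePair(subtract_background(noisy.s1, 30),
                 subtract_background(noisy.s2, 30))
result = run_colocalization(pair)
m = evaluate_detection(result.coloc_mask, truth.truth_mask)
sig = significance_test(pair, ScrambleConfig(rng_seed=7))
```

This prints (via the obvious `print` statements):

```
rounds run           : 44 (stop: background_limit)
selected round       : 16
overall r            : 0.462
in-mask R            : 0.991
m1, m2               : 0.422, 0.415
true coloc fraction  : 5.00% of pixels
detected fraction    : 3.32%
precision / recall   : 0.949 / 0.630
observed R = 0.507, scrambled mean = 0.083 (sd 0.0068), P = 1.0000 -> significant: True
```

Reading it: the run took 44 classification rounds before the background
rule fired, and the area rule picked the mask from round 16.  The whole
image correlates at `r = 0.462`, but inside the selected mask the overlap
is near-perfect (`R = 0.991`) — the mask has isolated the genuinely
colocalized population (precision 0.95 against the ground truth) and
carries 42% of each channel's total intensity (`m1`, `m2`).  The observed
overlap `R = 0.507` sits far above the scrambled null (mean 0.083), so the
colocalization is significant at the 0.95 criterion.

## Command line

```sh
truecoloc coloc --channel1 green.tif --channel2 red.tif \
    --background1 12 --background2 9 --significance --outdir out/
truecoloc simulate --scheme circles --seed 1 --outdir sim/
truecoloc benchmark --replicates 5 --out benchmark.csv
truecoloc significance --channel1 g.tif --channel2 r.tif --block 3
truecoloc kinetics --protein-stack gfp.tif --marker-stack mito.tif \
    --method algorithm --out kinetics.csv
```

`coloc` writes the colocalization mask (8-bit TIFF), the r/R/m1/m2
contribution maps (32-bit float TIFF), a per-round CSV and a JSON summary;
runs with the same inputs and seed are byte-identical.

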