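# mpmtools

Automated image analysis for 3D microphysiological models — hydrogel
co-cultures of cancer and endothelial cells imaged by (non-confocal)
fluorescence microscopy. Screening experiments produce thousands of
Z-stacks per plate; `mpmtools` turns them into three phenotypic
readouts per well and timepoint without manual annotation:

* **Cell coverage area.** Pixel intensities of a Z-projection are
  modelled as a two-component Gaussian mixture (dark background, bright
  cells). Pixels above the cutoff `mu_fg + lambda * sigma_fg` count as
  cells; coverage is cell area divided by the well area, delimited by a
  superellipse `|x/a|^n + |y/b|^n = 1` fitted around the Canny edges of
  the well rim (centred-circle fallback).
* **Cancer invasion depth.** A small residual CNN scores every Z-plane
  for in-focus (invaded) cells; a plane with probability >= 0.5 is
  invaded, and depth is `deepest_invaded_index * z_step_um` measured
  from the top plane where cells are seeded.
* **Microvessel network statistics.** A vesselness image (U-Net-style
  segmenter for projections, Sato tubeness for Z-stacks) is reduced to
  an embedded graph by discrete-Morse ridge extraction with
  persistence-based noise cancellation, pruned (leaf branches < 10 um)
  and smoothed. Branches are counted by persistent homology: filtering
  the network by `f(x) = -d(x, root)` grows it from the leaves toward
  the root; each leaf births a bar, the shorter branch dies at every
  merge (elder rule), and each bar's persistence `d - b` is the length
  of one branch. Cyclic networks are first reduced to the shortest-path
  tree from the network centre.

Everything runs on synthetic, exactly ground-truthed fixtures generated
by `mpmtools.synthetic_fixtures`, so the package installs, trains and
validates with no external data.

## Worked example

```python
import numpy as np
from mpmtools.synthetic_fixtures import VesselFixtureSpec, make_vessel_fixture, true_network_stats
from mpmtools.vessel_seg import ProbabilityMap, refine_probability_map
from mpmtools.morse_graph import MorseParams, extract_morse_skeleton, prune_and_filter, smooth_branches
from mpmtools.topology_stats import network_statistics

spec = VesselFixtureSpec(n_branches=8, snr=5.0, seed=1001, image_size=256,
                         branch_length_um=(30, 150), pixel_size_um=2.5)
image, truth, _ = make_vessel_fixture(spec)
print(true_network_stats(truth))

refined = refine_probability_map(ProbabilityMap(image=np.clip(image, 0, 1)))
graph = extract_morse_skeleton(refined, MorseParams(), pixel_size_um=2.5)
graph = smooth_branches(prune_and_filter(graph, MorseParams()), 5)
stats, barcode = network_statistics(graph)
print(stats)
```

prints

```
{'branch_count': 8, 'total_length_um': 860.0}
NetworkStats(branch_count=9, total_length_um=860.35, mean_branch_length_um=95.59, tree_length_um=860.35)
```

— the planted 860 um of vessel length is recovered to 0.05% and the
branch count to within one (a noise-induced extra short branch
survives pruning here); the bar persistences of the barcode are the
individual branch lengths, and `tree_length_um` equals their sum
exactly.

## Command line

```bash
mpmtools print-config                 # dump the YAML run configuration
mpmtools coverage --input-dir plates/ --output-dir results/
mpmtools invasion --input-dir plates/ --output-dir results/
mpmtools vessels  --input-dir plates/ --output-dir results/
mpmtools fixtures --kind vessel --seed 1 --out-dir fixtures/
mpmtools train --task invasion --seed 1
```

Filenames are parsed by a configurable regex capturing well, timepoint,
Z-index and channel; physical units (um/px and Z step) come from the
config file, never from image metadata.

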