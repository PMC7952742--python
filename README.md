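# wt2map

Water-T2 (wT2) mapping of skeletal muscle from multi-echo spin-echo
(MESE) MRI, for quantitative muscle imaging in neuromuscular disease
(e.g. muscular dystrophies), where wT2 is a marker of disease activity
and fat replacement confounds naive T2 fitting.

The echo train of a fat-infiltrated muscle voxel mixes a short-T2 water
signal with a long-T2 fat signal and is further distorted by transmit
(B1) inhomogeneity and the slice profile of the RF pulses. `wt2map`
simulates the acquisition with the extended phase graph (EPG) formalism
— CPMG echo trains including all stimulated-echo pathways, integrated
over a Shinnar-LeRoux slice profile of hanning-windowed sinc pulses,
with a two-compartment water+fat model (T1 water/fat = 1400/365 ms,
single-peak fat T2 = 151 ms) — and estimates per-voxel parameters by
dictionary matching: every combination on a (wT2, FF, B1) grid
(default 60 × 101 × 20 = 121,200 entries) is simulated, L2-normalized,
and the best match per voxel is the argmax of the correlation matrix

    C = S × D,

where S holds the normalized voxel signals (one voxel per row) and D
the dictionary columns. The fit can optionally be **constrained** by a
fat-fraction map from an independent water-fat acquisition, aligned
purely through image-header geometry: the search is then restricted to
the given FF per voxel, which stabilizes wT2 at high fat fractions and
with shortened echo trains. Double- and mono-exponential least-squares
fits are included as sequence-agnostic fallbacks, plus a digital
phantom with known ground truth and the ROI-level quality indicators
(pooled SD, intrasubject SD, FF error vs reference, group means).

## Worked example

Generate the built-in phantom (eight tissue inserts, wT2 25–45 ms,
FF 0–0.6, B1 gradient 0.8–1.2, Rician noise at SNR 50) and fit it with
a reduced dictionary:

```python
import numpy as np
from wt2map import (SequenceParams, PhantomSpec, make_phantom, default_profile,
                    build_grid, build_dictionary, SignalMatrix,
                    match_unconstrained, roi_summary)

seq = SequenceParams()                      # 17 echoes, 10.9 ms, TR 4100 ms
profile = default_profile(seq)              # hanning-sinc SLR profile, TBW 2
truth = make_phantom(PhantomSpec(seed=42), seq, profile)

grid = build_grid(wt2_steps=15, b1_steps=10, ff_steps=26)
dictionary = build_dictionary(grid, seq, profile)

mask = truth.region_labels > 0
signals = SignalMatrix.from_volume(truth.mese.volume, mask)
maps = match_unconstrained(signals, dictionary, truth.mese.spatial_shape,
                           affine=truth.mese.affine)

table = roi_summary(maps, truth.region_labels, subject="phantom")
print(table[["roi", "n_voxels", "mean_wt2", "sd_wt2", "mean_ff"]]
      .round(3).to_string(index=False))
```

prints

```
 roi  n_voxels  mean_wt2  sd_wt2  mean_ff
   1       372    24.309   2.614    0.013
   2       372    30.853   3.088    0.104
   3       372    35.461   2.958    0.203
   4       372    40.588   6.096    0.295
   5       372    45.530   5.892    0.397
   6       372    31.037   5.624    0.496
   7       372    36.855   7.686    0.599
   8       372    40.127   3.230    0.052
```

Each row is one insert: the ROI-mean wT2 recovers the true values
(25, 30, 35, 40, 45, 30, 35, 40 ms) to within a fraction of a
millisecond up to moderate fat fractions, and the mean FF tracks the
true fractions (0, 0.1, ..., 0.6, 0.05). The within-ROI SD of a few ms
is the voxelwise noise floor of the three-parameter match at SNR 50.
(Insert 6, FF 0.5, shows the growing wT2 uncertainty at high fat
content that the FF constraint is designed to remove.)

The same pipeline is available from the shell:

```sh
wt2map phantom --out phantom/ --seed 42
wt2map fit phantom/mese.nii.gz --out maps/ --method epg \
       --ff-map phantom/ff.nii.gz --echoes 5
wt2map stats subjects.csv --out stats/
```

`fit` accepts a DICOM series directory or a 4D NIfTI with a JSON
echo-time sidecar, writes `wt2_ms`, `ff_fraction`, `b1_fraction` and
`correlation` NIfTI maps plus a provenance sidecar, and exposes the
grid (`--wt2-steps`, `--b1-range`, ...), the fat T2 (`--fat-t2`, or
`auto` with `--fat-roi`), echo truncation (`--echoes`), custom slice
profiles (`--slice-profile`, `--pulse-tbw`,
`--refocusing-width-factor`) and masking options.

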