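# Reduced behavioural feature catalogue

One averaged vector per well per recording period. Units are pixels and
seconds unless noted; divide by `px_per_mm` for physical units. Period
suffixes `_prestim`, `_bluelight`, `_poststim` are appended on
concatenation.

| feature | definition |
|---|---|
| length | median midline arc length over frames, averaged over tracks |
| width_midbody | median (area / length) per track |
| curvature_head | mean absolute curvature, first 20% of the midline |
| curvature_neck | 20–40% span |
| curvature_midbody | 40–60% span |
| curvature_hips | 60–80% span |
| curvature_tail | 80–100% span |
| speed | mean centroid speed (px/s) |
| frac_fw / frac_bw / frac_st | fraction of defined-mode frames in each motion mode |
| speed_fw / speed_bw / speed_st | mean centroid speed conditioned on the mode |

Curvature is the unsigned turn angle per arc length along the midline
polyline (rad/px). Body-part spans follow the usual multi-worm-tracker
conventions. The aggregation, QC, normalisation, statistics and
classification machinery is width-agnostic: any per-period catalogue
satisfies the same contracts (3 × width after period concatenation).
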