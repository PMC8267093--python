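# usvkit

Analysis toolkit for mouse ultrasonic vocalizations (USVs): call detection
from ultrasonic audio, per-call acoustic parameters, variable clustering,
k-means call typing, bout-aware call-type transition matrices, and the group
statistics that go with them — together with a synthetic USV generator that
provides exact ground truth, so every stage of the pipeline can be verified
end to end without any external recordings.

## Who this is for

Researchers quantifying rodent vocal behaviour: courtship and social USVs of
laboratory mice (50–72 kHz calls recorded at ≥ 250 kHz), compared across
experimental groups — here the four-group design of control and
testosterone-propionate (TP) treated females and males.

## What it computes

**Detection.** A deterministic spectral detector: magnitude-squared STFT
(512-sample Hann window, 128-sample hop at 250 kHz), per-bin median noise
floor, band-limited SNR thresholding (30–110 kHz, 10 dB default) with run
merging (3 ms) and minimum duration (5 ms), then per-call frequency contours
via in-band peak picking with parabolic sub-bin interpolation.

**Acoustic parameters.** Twelve per-call features from the frequency contour
f₁…fₙ: duration (ms); frequency dynamic `max f − min f`; delta frequency
`fₙ − f₁`; mean frequency; frequency TV `Σ|fᵢ₊₁ − fᵢ|` (total variation);
mean frequency TV `TV/(n−1)`; linearity index `TV / dynamic`; number of
modulations (prominence-filtered extrema of the smoothed contour); number of
jumps (inter-frame steps > 10 kHz); minimum, maximum and peak frequency.
The per-animal call count (voc number) is the 13th variable for clustering.

**Variable clustering.** Divisive oblique principal-component clustering of
the 13 variables: split the cluster whose correlation-matrix second
eigenvalue is ≥ 1 by quartimax-rotating its first two principal components,
reassign variables until stable, and score each final cluster by its first
principal component.

**Call typing.** z-score the 12 features, k-means with k = 10 (k-means++,
best of 25 restarts), remove the noise cluster (shortest duration and
smallest frequency dynamic), renumber the remaining 9 types by descending
centroid peak frequency, and tabulate per-animal type occurrence
probabilities.

**Transitions.** Per animal, calls are ordered by onset; an inter-call
interval of more than 2 s ends a bout. Within-bout bigram counts (self
transitions included) give per-animal joint-frequency matrices, averaged
unweighted within groups; edges above 5% form the transition graph
(exported as CSV and Graphviz DOT).

**Statistics.** Kruskal-Wallis with tie correction and Steel-Dwass all-pairs
comparisons (studentized-range reference); MANOVA with Roy's largest root
θ = λ_max(E⁻¹H) and the upper-bound F = θ·df₂/df₁ with df₁ = max(p, k−1),
df₂ = N − k − df₁ + (k−1); Tukey-Kramer HSD; compact letter displays.

## Worked example

Draw calibration calls from two group presets and recover their acoustic
parameters from the synthesized contours:

```python
import numpy as np
from usvkit import default_presets, sample_calls, features_frame

presets = default_presets()
rng = np.random.default_rng(0)
for group in ("control_female", "tp_female"):
    _, contours = sample_calls(presets[group], 500, rng, archetype_scale=False)
    feats = features_frame(contours)
    print(group)
    print(feats[["duration_ms", "mean_freq_hz", "min_freq_hz",
                 "max_freq_hz", "delta_freq_hz"]].mean().round(1).to_string())
```

prints

```
control_female
duration_ms         44.6
mean_freq_hz     54429.0
min_freq_hz      50004.3
max_freq_hz      58690.4
delta_freq_hz      455.6
tp_female
duration_ms         47.7
mean_freq_hz     65177.4
min_freq_hz      58090.0
max_freq_hz      72508.8
delta_freq_hz     5308.0
```

— the TP-treated preset calls ~10 kHz higher with a strongly rising contour
(delta ≈ +5.3 kHz), the control preset lower and nearly flat, matching each
preset's configured group means to well under 1%.

Clustering the 13 variables on a simulated multi-animal call table:

```python
import pandas as pd
from usvkit import VarClus, attach_voc_number, simulate_session

all_feats, animals = [], []
for i, group in enumerate(presets):
    for a in range(3):
        rng = np.random.default_rng(100 + 10 * i + a)
        n = int(rng.integers(120, 220))
        contours, _ = simulate_session(f"{group}_{a}", presets[group], n, rng)
        all_feats.append(features_frame(contours))
        animals += [f"{group}_{a}"] * n
feats = pd.concat(all_feats, ignore_index=True)
print(VarClus(attach_voc_number(feats, animals)).fit().summary())
```

recovers the canonical structure — a frequency-modulation cluster
(frequency dynamic, frequency TV, mean frequency TV, linearity index,
nb modulation, nb jumps), a call-frequency cluster (mean/min/max/peak
frequency), and duration/slope variables — with every final second
eigenvalue below 1.

## Command line

```bash
usvkit simulate --out sim/ --seed 1                    # synthetic cohort
usvkit detect --wav session.wav --out calls.csv        # detection + features
usvkit varclus --calls calls.csv --out clusters.json
usvkit classify --features calls.csv --k 10 --seed 17 --out typed.csv --model model.json
usvkit transitions --calls typed.csv --out trans/
usvkit run-all --cohort cohort.yaml --seed 1 --out report/
```

`run-all` writes `table1.csv` (12 features × 4 groups, mean ± SEM with
letter displays), `clusters.json` + `cluster_scores.csv`, `typed.csv`,
`occurrence.csv` + `manova.json`, per-animal and per-group transition
matrices with edge lists, and a `manifest.json` with SHA-256 digests of
every output. Reports are byte-reproducible for a fixed seed.

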