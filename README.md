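# cohgraph

Functional brain-network analysis of clinical EEG through spectral
coherence and weighted graph theory.

`cohgraph` is aimed at researchers comparing scalp-EEG functional
connectivity between clinical groups — for example a two-way cohort of
subjects with and without Tuberous Sclerosis Complex (TSC) crossed with
presence or absence of an Autism Spectrum Disorder (ASD) diagnosis. It
implements the full chain from raw multichannel recordings to a grid of
age-adjusted group-effect p-values, and ships a synthetic cohort
generator with controllable connectivity structure so that every stage
can be validated end to end without patient data.

## The method

**Connectivity.** On the standard clinical 19-channel 10-20 montage, the
connectivity of an electrode pair is the magnitude-squared coherence

MSC(f) = |P_xy(f)|² / (P_xx(f) · P_yy(f)) ∈ [0, 1],

estimated by Welch's method (2-s Hann windows, 50% overlap) separately
within each artifact-free segment — segments are never concatenated,
because stitching across recording gaps injects spurious high-frequency
power. Per subject and frequency band ϕ the pair value is the
segment-length-weighted average, averaged over the in-band bins:

C = mean_{f∈ϕ} [ Σᵢ Lᵢ·Coh(Sᵢ, f) / Σᵢ Lᵢ ]

with Lᵢ the length of segment i. Default bands: theta (4–8 Hz), lower
alpha (8–10 Hz), upper alpha (10–12 Hz). Three summaries condense the
19×19 matrix: the mean over all 171 pairs; the ratio of homologous
inter-hemispheric over intra-hemispheric (non-midline) means; and the
ratio of long-range (grid distance ≥ 3) over short-range (2 ≤ d < 3)
means, with neighboring pairs (d < 2) excluded for volume conduction.

**Graph topology.** The coherence matrix defines a fully weighted
undirected graph on the 19 electrodes. Edge weight w maps to a
functional distance d = −ln w (perfect synchrony → 0, incoherence → ∞).
The package computes the characteristic path length L (mean shortest
functional distance over pairs), the global efficiency E (mean inverse
shortest distance; finite even for disconnected graphs), and the mean
Onnela weighted clustering coefficient.

**Resilience.** Targeted attack removes the k strongest nodes (node
strength = summed coherence weights), random failure removes uniform
random k-subsets; both report E_damaged/E_baseline for k = 1…5. Hub
concentration is the normalized degree of the three strongest nodes.

**Group model.** Every derived measure y is fit with the additive
two-way ANCOVA

y = ȳ + β_ASD·ASD + β_TSC·TSC + β_age·age

(OLS, coefficient t-tests, df = n − 4, raw two-sided p-values). Support
routines cover the one-tailed callosal-disconnection validation test,
subgroup post-hoc t-tests, and Fisher/t demographic contrasts.

## Worked example

```python
import numpy as np
from cohgraph import (SyntheticCohortSpec, generate_subject,
                      band_coherence_matrices, build_graph, graph_metrics,
                      mean_coherence, inter_intra_ratio, long_short_ratio,
                      targeted_attack)
from cohgraph.montage import build_standard_montage

montage = build_standard_montage()
spec = SyntheticCohortSpec(segment_length_range=(30.0, 60.0),
                           n_segments_range=(3, 4))
rec = generate_subject(spec, asd=0, tsc=0, age=8.0,
                       rng=np.random.default_rng(42), montage=montage)
mats = band_coherence_matrices(rec)
m = mats["lower_alpha"]
g = build_graph(m, nodes=montage.names)
gm = graph_metrics(g)
ta = targeted_attack(g, k_max=3)
```

prints (via the obvious `print` calls):

```
3 segments, 150 s total
mean coherence      0.279
inter/intra ratio   0.385
long/short ratio    0.443
path length L       1.360
clustering C        0.245
global efficiency E 0.913
targeted attack E_k/E_0: [0.973 0.936 0.915] removing ['Cz', 'C4', 'Fz']
```

A mean lower-alpha coherence of 0.28 and a long/short ratio well below 1
are typical resting values; the functional path length of 1.36 and
efficiency 0.91 describe a well-integrated network, and removing the
three strongest hubs (here the fronto-central electrodes) costs this
control-profile subject about 9% of its global efficiency.

The same chain runs from the shell on EDF files or synthetic cohorts:

```sh
cohgraph simulate --out cohort/ --seed 7
cohgraph run-all --out results/ --seed 7
cohgraph graph --matrix results/coherence_matrices/S000_lower_alpha.csv
```

`run-all` writes per-subject coherence matrices, the cohort measure
table, the per-measure ANCOVA coefficient table, the condition × band
p-value grid, and a manifest that makes the run byte-reproducible.

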