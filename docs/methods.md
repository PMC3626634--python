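# Methods

This note records the models, estimators, parameter choices and known
limitations behind `cohgraph`, in the order the pipeline runs.

## Montage and pair geometry

The 19 clinical 10-20 electrodes are placed on a signed integer grid
(Fp1 at (−1, 2) … O2 at (1, −2); midline column x = 0). All pair
classifications derive from plain Euclidean distance on this grid:

* d < 2 — *neighbor*: excluded from the range ratios because adjacent
  scalp electrodes are dominated by volume conduction;
* 2 ≤ d < 3 — *short range* (this half-open band, which also catches
  d = √5 and √8, keeps the three classes an exhaustive partition);
* d ≥ 3 — *long range*; 3 is 75% of the maximum aligned inter-electrode
  distance (4, e.g. T3–T4).

The grid reproduces every distance the classification rules rely on and
yields fixed counts — 171 pairs total: 50 neighbor, 62 short, 59 long;
8 homologous inter-hemispheric mirror pairs; 56 intra-hemispheric
non-midline pairs — which the tests pin after brute-force enumeration.
Whether diagonal steps should count differently is not decidable from
the classification rules alone; the integer-grid Euclidean metric is a
declared choice consistent with all of them.

## Preprocessing

Fixed, deterministic order: load → resample → notch → band-pass →
average reference → segment.

* Mixed native sampling rates are harmonized to a configurable target
  (default 250 Hz, polyphase resampling) before filtering.
* Band-pass 1–70 Hz: linear-phase windowed-sinc (Hamming), transition
  width 25% of the lower edge, applied forward-backward (zero phase) so
  the coherence phase structure is untouched. In-band sinusoids are
  preserved within 5%, the 60 Hz notch (IIR, Q = 30, forward-backward)
  attenuates mains by far more than 20 dB, and sub-1-Hz drift is
  suppressed; the tests check all three against the designed responses.
* Average reference: each sample minus the instantaneous cross-channel
  mean (idempotent; channel mean exactly zero).
* Segments shorter than one Welch window are dropped; subjects whose
  retained total falls below 120 s of awake artifact-free data are
  rejected with a reason code. An optional amplitude veto per segment
  (µV threshold) exists as plumbing and is off by default.

Semi-automated (ICA-based) artifact rejection requires human review and
is out of scope; segment boundaries are taken as given (CSV sidecar).

## Coherence estimation

Welch settings — 2-s Hann windows, 50% overlap, constant detrend, only
whole windows inside a segment — give 0.5 Hz resolution: ≥ 8 in-band
bins for theta and 4 for each alpha sub-band. Bands are half-open
[low, high) so adjacent bands never share a bin.

Per-subject band coherence of a pair is the segment-length-weighted
average of per-segment MSC, then averaged over in-band bins. Because the
integrand is bounded by 1, the band summary uses the band *mean* (the
integral divided by bandwidth); a raw integral over frequency would
leave the value outside [0, 1].

Two estimator properties matter for interpretation:

* Welch MSC is positively biased by roughly 1/(number of windows); with
  independent channels the estimate decays toward this floor as the
  recording grows. Short segments therefore contribute little weight
  *and* the bias is acknowledged in tolerance choices.
* The weighted average is linear in per-segment MSC, which is itself
  nonlinear in the window count. Duplicating a segment leaves the result
  exactly unchanged (weights cancel); splitting one segment into halves
  changes it only within estimator variance. The exact-arithmetic path
  is tested with phase-coded deterministic signals whose per-segment MSC
  is known in closed form.

## Graphs and topology

Edges carry coherence weights in [0, 1]; distances are d = −ln w with
w = 0 mapped to infinity (a genuine non-edge) and w = 1 to zero distance
(floored at ε = 1e−12 so inverse distances stay finite at 1/ε; in
practice estimated coherences of distinct channels never reach 1). All
171 edges are retained — no thresholding or binarization. Shortest paths
use Dijkstra on the dense distance matrix; tests verify equality with a
brute-force Floyd–Warshall to 1e−12 and with networkx.

Clustering uses the Onnela geometric-mean form with *unnormalized*
weights, C_i = Σ_{j,h}(w_ij w_ih w_jh)^{1/3} / (k_i(k_i−1)), since
coherence is already bounded by 1; nodes with fewer than two neighbors
contribute 0. The variant choice is pinned here because the generic
"weighted clustering" label covers several normalizations (the common
library form divides by the graph maximum weight, which would make the
measure depend on a single strongest edge).

Closed forms used as test anchors: a uniform complete graph of weight c
has L = −ln c, E = 1/(−ln c) (direct edges dominate for c > e⁻², since
any relay costs at least twice the direct distance) and clustering c.

## Resilience

"Highly connected" means node *strength* (summed incident weights);
binary degree is constant (18) on a fully weighted graph and carries no
information. Targeted attack ranks nodes once on the intact graph and
removes the top k simultaneously (k = 1…5 by default, matching the
reported removal depths); ties break by montage order. A sequential
re-ranking mode exists behind a flag. Random failure averages the
efficiency ratio over seeded uniform k-subsets (default 1000
replicates); on a 7-node graph the k = 2 mean is verified against the
exhaustive 21-subset average. Damaged-graph efficiency is computed over
remaining-node pairs only, and resilience is reported relative to the
intact baseline, which removes overall-level differences between
subjects. Hub concentration is strength of the rank-r node over total
strength, r = 1…3.

## Group model

The two-way ANCOVA y = ȳ + β_ASD·ASD + β_TSC·TSC + β_age·age is an
ordinary Gaussian linear model fit by OLS with coefficient t-tests
(df = n − 4, two-sided). No interaction term is included — the model is
deliberately additive, so an effect confined to one subgroup is probed
separately: the post-hoc subgroup t-test first adjusts the measure for
the *other* condition and age (OLS residuals), then compares the two
subgroups carrying the condition. Under a purely additive world the
adjusted subgroups coincide in expectation and the test stays calm;
without the adjustment any additive effect of the other condition would
masquerade as a subgroup difference. The callosal-disconnection
validation uses a one-tailed pooled t-test (disconnection group lower).
Undefined measure values (zero-denominator ratios are returned as NaN,
never clipped) are excluded listwise per measure with counts logged. No
multiple-testing correction is applied across the measure × band grid —
the measures are strongly correlated and the joint correction is
unknown — and outputs label all p-values as raw.

## Synthetic cohorts

Channels mix band-limited (3–13 Hz, covering the analysis bands) unit
variance Gaussian sources with fixed within-segment gains plus white
sensor noise — stationary within segments by construction, matching the
coherence assumptions. Sources: one global carrier (elevated gain at
fronto-central hub electrodes Fz/Cz/Pz/C3/C4), one per hemisphere
(midline loads on both), one local source per electrode shared with its
grid neighbors. Expected pair MSC follows in closed form from the gains
and the in-band noise floor, which gives the estimator tests an analytic
oracle.

Defaults define the emulated study conditions: subgroup sizes
46/29/16/14 (control, TSC-only, ASD-only, TSC+ASD), ages uniform on
0.7–20 y, 250 Hz, 4–8 segments of 30–90 s. Coupling gains
(global 0.8, hemispheric 0.5, local 0.6, hub boost 0.5) and the sensor
noise scale (2.5) were chosen together, analytically, so that (a) mean
band coherence sits in the realistic resting range (~0.25), and (b) the
in-band noise floor is large enough that a global gain scaling moves
coherence appreciably — without (b), MSC is purely structural and a
"global underconnectivity" effect would be invisible by construction.

Group effects:

* TSC multiplies all shared gains by 0.85 → global underconnectivity,
  longer paths, lower clustering and efficiency.
* ASD moves shared power from the long-range carriers (×0.8 on gains)
  into the local sources per channel (power-preserving), flattens the
  hub profile halfway toward uniform, then applies one uniform gain
  rescaling solved by root finding so the expected mean coherence
  equals the subject's no-ASD counterpart. The contrast is thus purely
  distributional: lower long/short ratio, flatter hubs, higher targeted
  attack resilience, *unchanged* mean coherence. (The solve is exact
  except at extreme ages where MSC saturates in the gain scale; the
  residual mean gap there is below 1% and the nearest bound is used.)
* Age multiplies shared gains by (1 + 0.01·age) — a maturational
  coherence increase absorbed by the model's age covariate.
* The ACC (absent corpus callosum) variant removes every source shared
  across hemispheres — the global carrier is folded into the
  hemispheric sources (intra-hemispheric structure approximately
  preserved; pairs that shared a midline local source lose that one
  term) — so homologous-pair coherence drops to the estimator floor.

Effect sizes are calibration choices that make recovery and power tests
meaningful; nothing ties them to clinical effect magnitudes. Per-subject
randomness uses counter-based substreams of the cohort seed, so a
subject's data do not depend on cohort ordering.

What the generator does *not* emulate: eye-blink/muscle artifacts,
epileptiform discharges, volume-conduction head geometry, 1/f spectral
background, non-stationarity within segments. Passing tests therefore
demonstrate correctness of the estimators and the recoverability of
injected effects, not clinical validity on real EEG.

## Problem sizes in tests and the acceptance script

Signal-level simulations run scaled-down cohorts (6–8 subjects per
subgroup, 2–4 segments of 20–40 s) — the package's own choice of
validation sizes; model calibration runs 2000 table-level null
replicates; the disconnection check uses the full 16-vs-46 group sizes
with shortened recordings over 20 seeds. The end-to-end dissociation
cohort is 8 subjects per subgroup with 100 random-failure replicates.

## Known limitations

* Coherence is sensitive to volume conduction; the neighbor exclusion
  mitigates but does not remove it. Phase-lag index or partial directed
  coherence are deliberate non-goals.
* With 19 electrodes, nodes do not correspond to well-defined
  functional brain regions; topology measures describe the sensor-space
  network.
* EDF export writes plain 16-bit EDF with one-second records (a partial
  trailing second is zero-padded; segment boundaries live in a CSV
  sidecar, so padding never enters the analysis).
* The ANCOVA models a binary diagnosis; severity scores, medication and
  epilepsy covariates are not modeled.
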