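# Methods

This note documents the models and procedures implemented in `ieegnet`, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical decisions a maintainer would want recorded.

## Connectivity estimation

Recordings are split into non-overlapping 1-second windows (trailing partial
windows dropped). Band coherence uses multitaper spectra with **NW = 2 and
K = 3 DPSS tapers** per window: with 1-s windows this gives a ±2 Hz spectral
concentration, appropriate for the 10-Hz-wide beta (15–25 Hz) and low-gamma
(30–40 Hz) analysis bands. Magnitude-squared coherence is formed per
frequency bin from taper-averaged cross- and auto-spectra and averaged over
the in-band bins (the simplest unbiased band summary). The patient-level
adjacency is the **entrywise median across windows**; for an even window
count the median is the midpoint mean.

Two estimator variants exist deliberately:

* `coherence_band` + `median_adjacency` — the pipeline recipe. Per-window
  msc with K tapers carries the usual small-sample bias: for independent
  signals its expectation is ≈ 1/K (≈ 0.33 at the default K = 3). The median
  over windows inherits this floor. The bias is monotone in the true
  coherence, so rankings, strengths and D_rs are unaffected in practice.
* `pooled_coherence` — cross-spectra pooled over *all* windows and tapers.
  This estimator is consistent: it converges to the true msc — the closed
  form (SNR/(1+SNR))² for a shared source — as the window count grows, and
  is what the calibration tests check (±0.05 of 0.25 at SNR 1 with 600
  windows).

Broadband cross-correlation applies a zero-phase 4th-order Butterworth
5–115 Hz bandpass and a 60 Hz notch (Q = 30), z-scores each channel per
window, and takes the maximum absolute normalized cross-correlation over
lags within **±100 ms** (biased normalization, so values stay in [0, 1] and
long-lag spurious maxima are excluded). Zero-variance channels in a window
produce zero-valued edges for that window and are logged. No artifact
rejection is performed: the intended inputs are artifact-free interictal
clips, and synthetic data are clean by construction.

Only grey-matter contacts enter networks; non-GM contacts are removed once,
before all analyses, and recorded in an exclusion log. Contacts flagged
resected but localized to white matter are likewise removed (and noted); an
alternative policy of retaining WM contacts that overlap an atlas region
would retain slightly more nodes, but a uniform GM-only rule is simpler and
reproducible.

## Distance model (DC)

Edge weight versus internodal Euclidean distance is modeled per modality and
edge class with the rational polynomial

    w(d) = (p1 * d + p2) / (d + q1),

fit by least squares with a **multi-start** strategy: 20 starts with q1
initialized log-uniformly on [1, 200] mm; given q1 the model is linear in
(p1, p2), which are initialized by linear least squares; joint refinement
uses trust-region least squares with q1 bounded below by −min(d) + ε so the
pole stays outside the data range. Best SSE wins, ties break toward the
smallest |q1|. Constant-weight input returns an exactly constant fit,
flagged. Fits **pool edges across patients within modality and edge class**
(four curves when both modalities are present: ECoG S-S/S-D/D-D and SEEG
D-D); per-patient fitting exists but is off by default — pooling matches the
four-curve correction design and stabilizes the weakly identified
asymptote p1. Residuals r_ij = A_ij − w_class(d_ij) are signed and **not**
re-clipped.

Identifiability note: with 200 edges and edge noise of SD 0.02, median
relative parameter errors are ≈ 5–8 % when distances span the cohort's
realistic internodal range (≈ 5–130 mm for bilateral implants); restricting
to ≤ 100 mm degrades p1 (the large-d asymptote) to ≈ 10 %.

## Graph metrics

Node strength s_i = Σ_j A_ij; normalized strength is the within-patient
z-score (sample SD; constant strengths yield zeros with a warning).
Community detection maximizes Newman–Girvan modularity at resolution γ = 1
(configurable) with a Louvain local-moving + aggregation scheme, best of
100 seeded runs, ties to the first-found. Distance-corrected networks have
negative edges; quality then uses the asymmetric signed extension
Q = Q⁺ − (v⁻/(v⁺+v⁻))·Q⁻, which rewards positive within-community weight
and penalizes negative within-community weight without letting the (smaller)
negative part dominate. The participation coefficient uses the positive part
of the adjacency for signed networks, keeping P_i ∈ [0, 1); isolated nodes
get P_i = 0. Per-patient participation is summarized by both the median
(headline) and the mean across nodes; the two summaries are reported side by
side because either convention is defensible.

## D_rs and cohort statistics

D_rs is the normalized Mann–Whitney U statistic over (resected, spared)
strength pairs with midrank tie handling, oriented so that *weaker* resected
tissue gives *high* values. This makes D_rs(s) + D_rs(−s) = 1 an exact
identity and D_rs equal to the ROC area for classifying spared nodes as the
stronger class — both are tested against independent implementations.

Group comparisons are two-sided and unadjusted (an FDR helper exists but is
off by default): Wilcoxon rank-sum (exact for tie-free samples up to n = 20,
otherwise normal approximation with tie correction), Wilcoxon signed-rank
(zeros dropped; exact for n ≤ 25 without ties), Fisher's exact test
(point-probability two-sided), and Pearson correlation with a t-test
p-value. The exact-vs-approximate regime is recorded in each result.

## Condition pipeline (DC → UL → AR)

Conditions compose in the order distance correction, then unilateral
restriction, then atlas reduction; each stage's D_rs is reported. The
resection hemisphere is the majority hemisphere of resected nodes; an exact
50/50 split is an error (degenerate for temporal-lobe-style cohorts), and
any minority-side resected nodes dropped by UL are counted and logged, never
silently discarded. Atlas reduction averages all contact-level edges between
each pair of ROIs (within-ROI edges are discarded), marks a ROI resected iff
it contains at least one resected contact, and is idempotent. A stage error
becomes a recorded skip reason and later conditions fall back to the last
successful stage.

## Synthetic cohort generator

The generator exists so that every pipeline stage can be validated against
known truth; its defaults emulate the reference study conditions.

**Geometry.** A toy head space in mm: hemisphere is the sign of x; |x| < 35
counts as mesial. A fixed synthetic atlas of 24 named regions (hemisphere ×
anterior/mid/posterior × superior/inferior × cortical/mesial) replaces image
registration and plays the role of a volumetric atlas. ECoG defaults: 8×8
grid at 10 mm pitch, two 6-contact strips (one contralateral), two 8-contact
depth shafts targeting the mesial anterior-inferior region — 92 contacts,
≈ 88 in grey matter with ≈ 12 depth-GM contacts. SEEG defaults: ten
12-contact shafts at 4 mm pitch (three contralateral) — 120 contacts, ≈ 90
GM after the default 25 % white-matter fraction among depth contacts. These
counts match a typical surgical cohort's reported node counts. Surgical
targets grow along a fixed ROI spread order starting at the mesial
anterior-inferior region; all contacts in target ROIs are flagged resected
(WM ones are later excluded and logged).

**Planted connectivity.** True weights are
f_class(distance) + depth-elevation (D-D edges) + community bonus +
resection shift (edges incident to resected nodes) + Gaussian edge noise,
clipped to [0, 0.95]. Defaults: rational decay (0.08, 12, 25) for every
class (giving beta-band-coherence-like values ≈ 0.4 at 5 mm falling to
≈ 0.16 at 100 mm); depth–depth elevation **0.1** (depth contacts record more
coherent local fields); community contrast 0.06 over hemisphere × an/post
blocks; edge noise SD 0.02 (ECoG) / 0.03 (SEEG) — the extra SEEG
heterogeneity mirrors the higher residual variance of depth-only sampling.

**Resection effects.** The per-patient resection shift is
`shift[modality] + 0.02 · (n_rois − 2.5)` with shifts +0.03 (ECoG) and
−0.02 (SEEG), and target sizes of 2–4 ROIs (ECoG, resection-like) vs 1–3
ROIs (SEEG, ablation-like). This plants, at design time, the three
phenomena the pipeline must recover: resected cortex relatively strong in
ECoG (D_rs < 0.5), focal targets relatively weak in SEEG (D_rs > 0.5), and
a negative correlation between D_rs and the number of resected ROIs. The
magnitudes were chosen once to produce gaps of the same order as the
reference cohort's and verified with a single pilot run, then frozen.

**Signals.** Channels are jointly Gaussian mixtures of shared band-limited
sources plus independent noise. The per-edge mixing inverts the two-channel
closed form msc = (SNR/(1+SNR))²: on unit-power channels the normalized
in-band cross-spectrum between i and j is set to √w_ij. Sampling uses the
equivalent frequency-domain factorization — R = I + offdiag(√W) is
eigen-factorized (clipped to the nearest PSD matrix when the requested
matrix is not jointly realizable, which renormalizes weights slightly) and
applied to white spectra shaped by a smooth band-limited gain plus a 1 %
broadband noise floor. This is distributionally identical to summing
per-edge shared sources but costs O(N²T) per patient. Exactness holds for
two channels (msc = w); for dense networks the *tested* contract is rank
agreement: Spearman ≥ 0.8 between the estimated band-coherence adjacency
and the planted truth at default settings. Default recordings are 5 min at
256 Hz (a configurable stand-in for hour-long clinical segments); the
generator refuses durations under 60 s.

**What the generator does not emulate:** anatomically realistic head
geometry or forward models, seizures and interictal spikes, artifacts,
nonstationarity, volume conduction and common-reference effects, and
1/f-shaped broadband spectra. Passing tests therefore demonstrate that the
*pipeline* recovers planted effects of realistic size through the full
signal path — not that real ECoG/SEEG differences are of any particular
magnitude.

## Problem sizes used in validation

The replicate-cohort checks (modality gap, focality correlation, DC
efficacy) run 20 independent cohorts of 16 ECoG + 17 SEEG patients each,
with full default layouts and effect sizes but 60-second recordings — the
generator's minimum duration, at which per-edge estimation noise is already
far smaller than the planted node-level effects. Estimator-calibration
checks use 600 windows (closed-form agreement) and 300 windows (bias
floor); Louvain is validated against exhaustive partition enumeration on
100 random graphs of up to 8 nodes (best-of-100 runs must reach the global
maximum in ≥ 95 %).

## Known limitations

* The published surgery-type and MRI contingency p-values of the reference
  cohort are not reproduced by a standard two-sided Fisher's exact test on
  the printed counts (0.0104 vs 0.0033 and 1.0 vs 0.75; the sex table's
  0.49 does reproduce). The implementation keeps the standard test; the
  corresponding validation assertions fail by design and are documented.
* Whether distance fits should pool across patients or be per-patient is an
  open design point in the field; pooling is the default here and the
  alternative is exposed but untested at cohort scale.
* The signed-modularity treatment of distance-corrected networks and the
  mean-vs-median participation summary are documented conventions rather
  than field standards; both alternatives are computed where cheap.
* Coherence values from the median-of-windows pipeline are biased upward by
  the K-taper floor; comparisons across configurations with different K are
  not meaningful unless the pooled estimator is used.
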