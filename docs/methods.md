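# Methods

This note documents the models, conventions, and numerical choices behind
`hyladelim`, and what its synthetic benchmarks do and do not demonstrate
about real field data.

## Genetic distances

Uncorrected p-distance is the fraction of mismatching sites among sites
where *both* sequences carry an unambiguous base (pairwise deletion).
Complete deletion would throw away columns globally and change every
denominator when one ragged sequence is added; pairwise deletion keeps
each pair's denominator explicit and is the convention in standard
distance software. Ambiguity codes other than N are treated like N
(excluded): exclusion can never create a spurious mismatch. Pairs sharing
fewer than 200 compared sites trigger a warning — short mitochondrial
fragments are a known source of artifactually low inter-clade distances
(the clade-F case in this complex rested on a 506 bp 16S fragment).

Clade summaries report mean, sample SD (n−1), and range over sequence
pairs; intra-clade cells use distinct pairs only and singleton clades get
no intra entry. `n_comparisons` counts sequence pairs (published tables of
this kind are ambiguous between specimens and pairs; pairs are what the
statistics are computed over, so that is what is reported and labelled).

Divergence categories are half-open bins: [0, 3%) low, [3%, 5%] moderate,
(5%, 7%] high, (7%, 1] very high. The verbal bins in the literature
overlap at their edges; the binding rule for delimitation is the strict
"> 3.0%" candidate threshold, which these bins respect.

## Clustering and evidence integration

Candidate lineages are formed by single-linkage agglomeration on
*inter-clade mean* distances (not minima, not all tip pairs): the
published argument proceeds at the level of clade means, and single
linkage is the transitive closure of the "≤ threshold" relation, making
the result order-independent and monotone in the threshold. The linkage
is a documented, configurable choice.

"Covariation between genetic and non-genetic data" is operationalised
minimally: a group is CCS iff at least one available non-genetic character
set (acoustic or morphological) is diagnostic ("distinct"); UCS iff both
are unavailable; DCL otherwise. Overrides — such as keeping clade F as a
tentative candidate on branch-length grounds — are never inferred: they
are explicit inputs with free-text rationales recorded verbatim in the
result, because no quantitative criterion for such judgments exists.

## Call synthesis and feature extraction

The synthesizer renders each pulse as a carrier sinusoid gated by a
raised-cosine window of width `pulse_duty × pulse_period` (default duty
0.7), pulses contiguous within a note, notes separated by silent gaps.
Within a note, pulse amplitudes ramp to a single maximum at ~60% of the
note so rise time is well defined. Default sample rate 44100 Hz: with a
1024-point FFT this reproduces the 43.1 Hz analysis resolution used in
the original Raven workflow.

Extraction thresholds (all in `AcousticConfig`):

| parameter | default | why |
|---|---|---|
| envelope smoothing | 2 ms | removes carrier ripple (≥ 2 kHz carriers) without merging pulses ≥ 5 ms apart |
| pulse threshold | 10% of call max | well below any published note amplitude ratio |
| min pulse separation | 2 ms | fastest published pulse rates are ~150/s (6.7 ms) |
| note gap | 20 ms | published inter-note distances are 14–51 ms; intra-note pulse intervals ≤ 10 ms |
| Type I rule | ≥ 0.06 s AND ≥ 8 pulses | separates published Type I ranges (≥ 0.08 s, ≥ 10.8 pulses) from Type II (≤ 0.05 s, ≤ 6 pulses) |
| FFT | 1024-point Hann, 50% hop | resolution convention above; window/overlap are this package's choices and are recorded in output metadata |
| bandwidth floor | −20 dB re frame peak | the original bandwidth measurements state no power floor; configurable |
| frame floor | −30 dB re loudest frame | see below |

Dominant frequency is the mean of the argmax frequency at exactly three
frames — beginning, middle, end of the call — mirroring the original
variable definition rather than a whole-call average. One decision the
manual workflow never needed: a frame centred in a silent inter-note gap
has a degenerate spectrum, so "beginning/middle/end" is taken over the
frames whose total power is within 30 dB of the loudest frame. Note
onsets/offsets are first/last pulse times padded by half the local pulse
period; rise times are measured from onset to the envelope maximum within
the span.

Degenerate inputs: silence raises `NoCallDetected`; calls shorter than one
FFT window are an error; candidate pulses closer than the minimum
separation are merged with a warning.

## PCA and tests

The call-variable PCA is on the **correlation** matrix (published
percent-variance values equal eigenvalue/5 × 100, which identifies the
convention); columns are standardised with sample SD, components with
eigenvalue strictly > 1 are retained, and each loading column's
largest-magnitude entry is made positive so loadings tables reproduce
across runs. Eigenvalues must sum to the number of variables and
loadings reconstruct the correlation matrix to 1e−8 (tested).

Group comparisons use Welch's unequal-variance t-test. The published df
values (df = 9 for n = 8 vs 185; df = 12 for n = 12 vs 185) are only
consistent with Welch–Satterthwaite, which is why the pooled test is not
offered as a default. No multiple-testing correction is applied by
default, matching the original analysis; a Holm option exists. A worked
check: clade I (26.0 ± 0.9, n = 8) vs clade C (23.8 ± 1.5, n = 185) gives
t = 6.53, df = 8.78 → 9. Most other published t values are not recoverable
from rounded summary tables and are not used as anchors. (The published
text gives PC II's variance as 26.62% while the corresponding table prints
24.62; only 24.62 is consistent with the printed eigenvalue 1.23 and
cumulative 76.44%, so the table value is treated as correct.)

## Geographic ranges

Extent of occurrence is the convex hull of the occurrence points. Area is
computed with the discrete spherical polygon-area formula on the WGS84
**authalic sphere** (R = 6371.0072 km) — an equal-area treatment chosen
because the original GIS projection is unstated and area should be
projection-honest and reproducible; the method is recorded in the range
report. A planar mode exists for toy or already-projected coordinates.
Published km² values are not numeric targets: they depend on occurrence
sets and a projection that were never published. The degraded fraction is
exact rational arithmetic rounded to one decimal, so published area pairs
reproduce their printed percentages exactly. The Red List suggestion is
deliberately minimal — DD with ≤ 1 locality or missing area, LC at
≥ 20,000 km² (criterion B1's Vulnerable bound) with < 50% degradation,
otherwise "review" — and is advisory only.

## Synthetic data: what it does and does not show

Alignments evolve under Jukes–Cantor on a star topology (root → clade
ancestor → tips). JC is the minimal model with a closed-form link between
path divergence and expected p-distance, p = ¾(1 − e^(−4d/3)), so
simulation targets are analytic; a star suffices because every downstream
stage consumes only pairwise distances. Per-clade root-to-tip paths are
calibrated to the published clade-mean matrix by linear least squares on
JC-inverted means. The published matrix is *not* additive — sister pairs
like A–B are close to each other but ~10% from everything else — so the
fitted targets deviate from the printed means by ~2 points RMS; simulated
alignments are checked against the fitted targets (within 3 binomial SE at
the simulated length), which is the attainable guarantee.

Default fixture sizes: 1200-site alignments, 4 tips per clade (2 for the
rarest), 4 males per clade with ~5% jitter on call parameters, 12-point
occurrence clouds — small enough that the full pipeline runs in about a
second while every statistical check retains power.

The generators omit several features of real data: indels and alignment
error, rate heterogeneity across sites, background noise and overlapping
callers in recordings, frequency modulation within pulses, measurement
error in SVL, and spatial sampling bias. Passing round-trip tests
therefore demonstrates that the *pipeline logic* is correct under its own
assumptions, not that the default thresholds are optimal for noisy field
recordings — those should be tuned per dataset via `AcousticConfig`.

## Reproducibility

Every stochastic operation takes a single integer seed
(`numpy.random.default_rng`); fixture generation and full pipeline runs
are byte-identical under a fixed seed (tested). Stage outputs are plain
delimited text so any stage can be inspected or replaced; a manifest
records configuration, versions, and seed for each run.
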