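# Methods

## Ion mass model

Monoisotopic atomic masses are hard-coded (IUPAC/CODATA values to six
decimals) for C, H, N, O, S, P, F, Cl, Br, I and Na; there is no runtime
element-database dependency. Ion m/z under a charge configuration with
hydrogen shift ΔH ∈ {0, ±1, ±2} and unit charge q is

    m/z = Σᵢ nᵢ·mᵢ + ΔH·m(H) − q·m(e)

with m(e) = 0.000549 Da included deliberately: it is negligible at nominal
resolution but not at the 10 ppm / 0.02 Da matching tolerances the annotation
step uses (0.5–1 ppm at low m/z). Nominal m/z is round-half-up.

Written annotations of the form "[X − H] − H⁻" are interpreted as the neutral
formula X minus one hydrogen atom, then deprotonated — i.e. the [M−2H]⁻
configuration applied to X; "[X + H] + H⁺" maps symmetrically to [M+2H]⁺.
Annotations carrying a −2H shift before deprotonation (net −3H) are computed
by shifting the neutral formula first; such species lie outside the six
configurations and therefore cannot appear in predicted-ion tables (see
below). Configurations that would drive the hydrogen count negative are
infeasible and skipped.

## Combinatorial fragmenter

Only bonds between heavy atoms are breakable; bonds to hydrogen never break
(hydrogen variation is entirely delegated to the charge configurations).
Depth 1 deletes each single bond: a non-ring bond yields two fragments, a ring
bond yields a connected ring-opened intermediate that retains the parent
formula. Depth 2 applies one further deletion inside every depth-1 structure
(including ring-opened intermediates, which is how ring fragments arise).
Structures are deduplicated by heavy-atom subset, keeping the smallest depth;
sequential two-step deletion is provably equivalent to exhaustive deletion of
all 1- and 2-subsets of bonds followed by connected-component extraction, and
the test suite checks exactly that equivalence against a brute-force oracle.

Predicted-ion tables emit, for each unique fragment formula plus the intact
parent, the three polarity-appropriate configurations, deduplicated by
(formula, configuration) and sorted by m/z. Ring-opened intermediates are not
emitted as ions themselves — they share the parent's formula and are
indistinguishable by m/z.

Consequences worth knowing: fragments reachable only through hydrogen
rearrangements beyond ±2 H, or through positive-mode hydrogen *loss*
([X−H]⁺), are structurally absent from the tables. Of the seventeen
internally consistent reference annotations for the three model compounds,
eleven appear in the depth-2 tables at their exact theoretical m/z and six do
not (the [X−H]⁺ species at nominal 99, the net −3H species at 143 and 159,
and three odd-hydrogen sucralose formulas at 71, 87 and 101); this partition
is frozen and asserted in the tests. Raw bond dissociation is used without
neutral-loss rules; recall against rule-based predictors may differ.

## Spectral processing

Centroiding splits a profile spectrum into segments (points above baseline
separated by ≤ 0.05 Da), finds local maxima per segment, bounds each maximum
by its neighboring valleys, and reports the intensity-weighted mean m/z with
the region's apex intensity (summed intensity is available via a switch;
apex keeps Score 3 interpretable as a fraction of precursor intensity). The
procedure is idempotent on stick spectra because isolated points form
singleton segments.

XICs sum centroided intensity inside target ± tolerance (default 10 ppm) per
scan. The apex is the global maximum (earliest RT on ties); AUC is the
trapezoidal integral over the contiguous region where intensity stays ≥ 5% of
the apex. "Neighboring the apex" for MS2 selection means RT inside that same
region, falling back to ±0.5 min for degenerate windows. Master intensity of
an MS2 event is the precursor XIC intensity at the nearest MS1 scan. Per
fragmentation mode, the top three MS2 scans by master intensity are kept.

mzML 1.1 is read and written directly (lxml; uncompressed or zlib, 32/64-bit
float arrays, standard CV terms). HCD events carry the beam-type CID CV term
plus collision energy; UVPD events carry the UVPD CV term plus a "reaction
time" user parameter in ms, since the controlled vocabulary has no standard
term for it.

## Annotation and scores

Both tolerances must hold simultaneously (relative 10 ppm AND absolute
0.02 Da by default; a loose 1 Da pre-filter mode exists as an option). Each
peak takes the minimum-|error| ion; exact ties break toward the lower
theoretical m/z; output is ordered by peak m/z. Tightening either cutoff can
only remove matches (tested as a property).

Scores: 1 = matched/theoretical, 2 = matched/experimental, 3 = matched
intensity / precursor MS1 intensity. n_exp counts peaks after precursor
removal when that option is active. Score 3 is not clamped and can exceed 1.
Degenerate denominators yield 0 with a flag (scores 1–2) or an error
(score 3, which is undefined without a positive precursor intensity).

The four-group classification is a documented operational rule, not a claim
of fidelity: a technique "fragments well" when its best mode reaches
score 3 ≥ 0.01 with ≥ 2 matched fragments; the HCD/UVPD boolean pair selects
the group. Both thresholds are configurable.

Mass-error summaries use the maximum-likelihood normal fit (sample mean,
biased-variance sd); with fewer than two matches the fit is skipped and
flagged.

## Chemical-space selection

Fingerprints are 1024-bit path-based (extended) fingerprints; identical
canonical structures give identical bit vectors. The Tanimoto distance matrix
is symmetric with zero diagonal; an all-zero fingerprint pair is defined as
distance 0 and logged.

k-means needs a vector space, so each compound is embedded as its row of the
distance matrix (what the common R idiom computes when a `dist` object is
coerced into `kmeans`); a PAM-style k-medoids mode operating on the distances
directly is available for comparison. Restarts default to 10, best inertia
kept, all seeded. The elbow is located automatically as the point of maximum
discrete curvature — the candidate k farthest from the chord joining the
endpoints of the normalized WCSS curve.

The SOM is a 10×10 rectangular grid trained with a Gaussian neighborhood
(radius decaying linearly from half the grid size to 0.5), learning rate
decaying linearly 0.05 → 0.01, and 100·n presentation steps by default; these
defaults are declared choices, not inferred from any reference analysis.
Training is fully deterministic under a fixed seed.

## Synthetic runs: what they emulate and what they do not

The generator reproduces the acquisition design: MS1 full scans 100–800 m/z,
MS2 scans 50–500 m/z, one MS2 event per fragmentation mode per MS1 cycle
(HCD CE 20/35/60, UVPD 25–800 ms), a Gaussian elution profile (default apex
10 min, σ 0.15 min, sampled every 0.05 min/cycle), planted fragments at their
exact theoretical m/z with per-mode relative intensities, optional residual
precursor in MS2, Gaussian ppm jitter on m/z, multiplicative intensity noise,
and optional profile-mode rendering (Gaussian m/z peaks, σ 0.01 Da sampled at
0.0025 Da). Everything derives from one seed.

Not emulated: co-elution and chromatographic tailing, isotope patterns
(optional hook, off by default), adducts beyond the six configurations,
detector saturation, and electron-detachment physics of negative-mode UVPD.
Passing tests therefore demonstrate correctness of the processing chain on
idealized peaks, not robustness to real matrix effects.

Problem sizes used in the validation suite: planted-template clustering uses
5 templates × 20 compounds (disjoint 60-bit templates, 2% bit flips);
mass-error calibration uses 500 matches at 5 ppm jitter collected with a
25 ppm (5σ) window so the fitted sd is not truncated by the match cutoff;
the fragmenter oracle covers 25 molecules of ≤ 8 heavy atoms plus 50 random
acyclic molecules.

## Known limitations

- Depth is capped at 2; deeper cascades (relevant for long UVPD reaction
  times) multiply table sizes and are out of scope.
- The matcher annotates each peak with one best ion; co-isobaric predicted
  ions within tolerance are collapsed to the nearest.
- The intensity cut-off below which a compound would be dropped in a real
  campaign is exposed as configuration without a validated default.
- k selection by maximum curvature can be unstable when the WCSS curve is
  nearly linear; the full curve is always returned for inspection.
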