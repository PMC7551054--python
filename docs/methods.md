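# Methods

This note documents the models, parameter choices and numerical conventions
behind `bromonet`, and what the synthetic benchmark does and does not show.

## Mass and isotope model

All mass arithmetic rests on a single hard-coded table of NIST monoisotopic
isotope masses and natural abundances (C, H, N, O, S, Br, Na, Cl, P).
Monoisotopic masses use the principal isotope of each element. Positive-ion
m/z subtracts one electron mass (0.000549 Da) per charge; protonation adds
1.007276 Da per charge and sodiation 22.989218 Da. This bookkeeping is what
reproduces four-decimal reference values such as 858.3032 for the
protonated mono-brominated depsipeptide ion C39H53N7O10Br — omitting the
electron correction misses by ~0.5 mDa.

Isotopologue patterns are exact convolutions of elemental isotope
distributions (binary exponentiation per element), with centroids merged
within a tolerance of **0.01 Da** — the scale of a Q-TOF centroid width, so
near-coincident isotopologues (e.g. ⁸¹Br vs ¹³C₂ at Δ8.5 mDa) merge the way
a mid-resolution instrument would report them. Peaks below 1e-4 of the base
peak are truncated and the base peak is scaled to 1. The un-truncated
distribution sums to unit probability (checked to 1e-6).

**Bromine-count inference** compares the observed pattern against
hydrocarbon surrogates CcH2cBr_b (b = 0..max) matched to the observed
monoisotopic mass, after collapsing both onto integer-Da offsets; the L2
intensity distance decides, with ties to the smaller count (parsimony). The
surrogate's carbon envelope is only an approximation of a peptide's A+1
profile, but the decision is dominated by the A+2 signature (one Br makes
the A+2 peak ~0.97 of the base, two Br invert the pattern into ~1:2:1),
which is why the classifier stays >99% correct at 5% intensity noise.

**Formula enumeration** searches all element-count combinations within
bounds (defaults C≤60, H≤100, N≤15, O≤20, Br≤3 — generous enough for every
compound in the library while keeping the search in the tens of
milliseconds), solving the hydrogen count from the mass residual.
Candidates must fall within the ppm tolerance (default 5 ppm), carry the
bromine count fixed from the isotope pattern, and (by default) have
non-negative ring-plus-double-bond equivalents; they are ranked by |ppm|,
then fewer heteroatoms. The ppm sign convention is
(observed − calculated)/calculated.

## Depsipeptide fragmentation

A compound is modeled as an acyl-chain formula plus an ordered residue list
with the macrolactone on the (N-terminal) threonine; the neutral cyclic
formula is the plain element-wise sum, i.e. the acyl formula is defined
net of the water consumed by ring closure. Ile and Leu are collapsed to the
composite residue Xle throughout, since low-energy CID cannot distinguish
them.

Ring opening is data, not code: an `OpeningRule` carries the N-side and
C-side terminal mass deltas, which must cancel (hydrogen-transfer opening).
Two rules ship by default:

* **ester-bond** — cleavage of the macrolactone ester; acid/alcohol
  partition, both deltas zero.
* **thr-O-C** — cleavage of the threonine O–C bond, modeled as a
  dehydrated N-side (dehydro-Thr, −18.0106 Da) with the water on the
  C-side (+18.0106 Da). The exact hydrogen bookkeeping of this opening is
  a convention; keeping it in data means it can be corrected without code
  changes.

Singly protonated ladder ions follow acylium-style bookkeeping:

    b_k = acyl + Σ res[1..k] − H2O + δ_N + 1.00728
    y_k = Σ res[n−k+1..n] + H2O + δ_C + 1.00728

which yields the complementarity b_k + y_{n−k} = [M+H]⁺ + 1.00728 for every
k and opening — the invariant annotators use — and reproduces the free-acid
y ions (y1 = 132.1019 for Xle, y2 = 246.1448 for Asn-Xle). Each fragment
also carries its explicit elemental formula, and an independent
formula-level computation agrees with the ladder masses to 1e-4 Da. Only
b/y series are modeled; a/x and internal ions are out of scope because they
contribute few assignable peaks in these spectra.

The **aryl-polyene elimination ion** — the base peak of bromoalterochromide
spectra — is configured per compound (bare m/z, or a formula when known)
rather than derived, because its elemental composition is not established
at the level of the rest of the model. The library carries 210.9567 for the
mono-brominated A/D series and values offset by the Br−H (77.9105) and C₂H₂
(26.0157) steps for the di-brominated and B-series compounds; these
derived values are a package choice, flagged as synthetic in the fixture.

## Spectra, features and alignment

MGF is the interchange format (parsed with pyteomics; written by a small
deterministic writer with 4-decimal m/z so that repeated runs are
byte-identical). Sample and group metadata travel as `key=value` tokens in
TITLE. The MS² signal floor of 5.0e2 counts is applied by the pipeline on
read; the MS¹ floor of 5.0e3 counts doubles as the presence threshold for
provenance calls.

Isotope grouping links co-eluting peaks (|ΔRT| ≤ 0.20 min) whose spacings
match a single ¹³C (+1.00336), ¹³C₂ (+2.00671) or ⁸¹Br (+1.99795) step
within 0.005 Da; chains connect transitively, the feature sits at the
lightest member, and the cluster's intensity pattern feeds the
bromine-count classifier. Permitting arbitrary step combinations would
blanket near-integer spacings and over-merge, which is why only single
steps are edges.

Join alignment processes features in descending intensity (ties by m/z):
each joins the nearest open row within 0.02 Da and 0.2 min by combined
normalized distance, or founds a new row. The procedure is greedy but
deterministic, and recovers the true correspondence exactly when jitter is
well inside the tolerances.

## Molecular networking

The modified cosine allows a peak pair to match directly or shifted by the
precursor mass difference (fragment tolerance 0.02 Da), weights pairs by
the product of square-root intensities, and solves the one-to-one matching
**exactly** as a rectangular linear assignment (scipy). Exactness matters:
greedy matching can be suboptimal on ambiguous pairings, and the test suite
holds the implementation to brute-force enumeration. The score is the
optimal matched weight normalized by the product of √-intensity norms,
hence in [0, 1] with self-similarity exactly 1.

Edges require cosine > 0.70 and at least 5 matched peaks ("more than 4"),
after which each node retains its 10 strongest edges (an edge survives if
it ranks in either endpoint's top-10). Molecular families are connected
components. The fragment tolerance and top-k are not stated for the
original analysis; 0.02 Da and 10 are the conventional feature-based
networking defaults and are configurable.

## Dereplication and analog calling

Nodes are dereplicated against the known-compound library by precursor m/z
within 5 ppm, over protonated and sodiated adducts. Edge mass offsets
between annotated and unannotated nodes are classified against the offset
table (CH₂, C₂H₂, Br−H, Na−H; tolerance 0.02 Da); nodes that receive a
classified hypothesis relay as secondary references, and unclassified nodes
relay anonymously, so a chain known → CH₂ analog → dibrominated CH₂ analog
resolves fully and two unassigned nodes one Br−H step apart are still
compared. A node can therefore carry several chemically valid hypotheses
(e.g. a dibrominated D compound is both the CH₂ homolog of the dibrominated
A compound and the Br−H analog of the mono-brominated D compound); all are
reported.

A new-analog verdict additionally requires fragment evidence: theoretical
fragments of the reference model, optionally shifted by the hypothesized
offset chain, must match at least **6** observed peaks (one observed peak
per fragment, conflicts resolved to the smallest error), and the precursor
must sit within 5 ppm of the offset-corrected reference. The
6-fragment bar is the automated stand-in for manual curation of hits and
deliberately exceeds the network's own 5-matched-peak edge bar.

Provenance classes per feature: present in the medium control → `control`;
otherwise presence in monoculture and/or interaction samples yields
`shared`, `monoculture-only` or `interaction-only`, with presence meaning
any member sample at or above the MS¹ threshold.

## Synthetic benchmark: what it emulates, and what it does not

The simulator plants the twelve library depsipeptides (A/A′, B/B′, their
dibrominated forms, and the D/D′ series treated as unknowns) across a
six-sample layout — one monoculture, four interaction testers (*C.
albicans*, *A. fumigatus*, *S. aureus*, *E. coli*), one medium control —
with the depsipeptides shared between monoculture and interactions and
interaction intensities scaled ×3, matching the qualitative observation
that production intensifies during interactions. Fragment intensities are
log-normal (median 2e4, σ = 0.7 log-units; the source analysis reports no
intensity distributions, only that the elimination ion is the base peak,
which the simulator enforces with an 8× boost); noise peaks (10 per
spectrum) are uniform in m/z with exponential intensities (scale 500,
i.e. below ten times the MS² floor); m/z jitter is Gaussian at 3 ppm;
MS¹ isotope intensities carry 5% multiplicative noise. Decoy compounds
(8 random spectra) rotate through interaction-only, monoculture-only and
control provenances. All randomness derives from one seed; outputs are
byte-identical across runs.

Passing on this benchmark demonstrates the *mechanism* — family formation,
offset classification, fragment verification, provenance logic — under
controlled noise. It does not demonstrate performance on real vendor data:
chromatographic peak shapes, co-isolation chimeras, in-source fragments,
adduct diversity beyond H/Na, and instrument-specific artifacts are not
simulated, and the original study's network-scale totals depend on its raw
data deposit and upstream feature extraction, which are outside this
package's scope. At the default 3 ppm jitter, roughly 5–10% of replicate
spectra fall outside the 5 ppm verification window by chance; this is the
designed behavior of the curation thresholds, not a defect, and is why
recovery criteria are stated per-instance at ≥ 95% rather than 100%.

## Problem sizes

The standard benchmark uses one sample per group (68 spectra, 20 features),
500 spectrum pairs for the matching-oracle check, and 200 simulated
clusters per bromine count for the classifier check; the full test suite
runs in well under a minute. These sizes were chosen as the smallest at
which every mechanism is exercised with comfortable statistical margins;
all of them scale linearly upward through the configuration objects.

## Known limitations

* Positive ion mode only; no multiply charged fragments and no fine
  isotope structure.
* The elimination-ion composition is configuration, not prediction.
* Ile/Leu (and other isobaric substitutions) are indistinguishable by
  design; identifications are spectrum-level, not stereochemical.
* The thr-O-C opening's hydrogen bookkeeping is an editable convention.
* Dereplication is precursor-mass-based (plus fragment verification for
  depsipeptide models); formula-only library entries (e.g. the siderophore
  bisucaberin) cannot be fragment-verified.
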