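# Methods

This note documents the models, parameters and numerical choices behind
`telomap`: what the simulator emulates, how molecules are aligned and
classified, how the readouts are defined, and what the package's tests do
and do not demonstrate about real optical-map data.

## Coordinate and data conventions

All coordinates are 0-based base-pair floats along a molecule or reference
map; intervals are half-open. A reference arm map is anchored with the
chromosome terminus (the telomere-proximal edge) at its maximal coordinate
(`chrom_end_pos == map_length_bp`). Telomere lengths are kilobases. All
dispersion statistics are sample (n−1) standard deviations.

## Reference model

Real subtelomeric maps are hg38-derived; the package generates synthetic
stand-ins with the same statistical character. Defaults: 41 arms (the
human arm sequence minus the acrocentric short arms 13p/14p/15p/21p/22p,
which carry no mappable subtelomere, plus the pseudoautosomal XpYp/XqYq
ends), 300 kb maps, 9 kb mean nick spacing — approximating Nt.BspQI
density — and 1.5 kb minimum resolvable spacing. Inter-label gaps are
exponential conditioned on the minimum (a min-shifted exponential, so the
mean gap equals the requested mean exactly). Labels are laid down from
the chromosome end inward with a fixed 6 kb terminal gap: the terminal
repeat region contains no nickase sites, and anchoring the distal-most
label at a known small offset is what lets a classifier distinguish "the
chromosome end was reached" from "the fiber was truncated".

## Simulator

Per arm, Poisson(`mean_molecules_per_arm`, default 30 — the assay's
typical per-arm coverage at ~60× throughput) molecules are drawn; each is
assigned a category from the profile's mixture fractions and built
geometrically:

* **END_TEL** — a subtelomeric window ending at the terminus plus a
  terminal telomere label of intensity `k·T(1+ε)` placed at the fiber end.
* **TFE** — the window truncated exactly at the terminus, no telomere
  label.
* **FUSION_ITS_PLUS / MINUS** — a ≥150 kb subtelomeric fragment joined at
  the terminus to a partner fragment (≥40 kb), with (ITS+) or without
  (ITS−) a telomere cluster at the junction. With probability 0.5 the
  partner is another arm's reversed subtelomere (any arm, so same-arm
  fusions arise at rate 1/41); otherwise it carries an unmapped random
  label pattern, conditioned on ≥2 labels — an unlabeled fragment would
  not be recognizable as a fused fragment by any map-based method.
* **ECTR** — telomere-only fibers emitted additionally at
  `ectr_per_100_molecules` per 100 arm-anchored molecules; they are exempt
  from the >150 kb fiber-loading floor.

Backbones are uniform 150–400 kb (fusions 220–420 kb so both fragments
stay alignable). Molecules are flipped end-to-end with probability 0.5.

Noise is applied last: Gaussian label sizing error (default sd 250 bp),
per-label dropout (0.10), Poisson false nick labels (1 per 100 kb),
multiplicative Gaussian intensity noise (CV 0.10) — typical optical-map
error magnitudes, exposed in the profile YAML — and a 0.1 kb telomere
detection floor below which no telomere label is emitted. Noisy label
positions are snapped to the 0.1 bp precision of the file dialect.
Telomere lengths for categories defined by a *detected* telomere (END_TEL,
ITS+, ECTR) are drawn truncated at the floor, because published category
fractions are fractions of observed categories.

The intensity calibration constant k = 1000 units/kb is arbitrary (only
the product k·T is observable) and shared with the classifier's
calibration model, making the length readout exactly invertible.

### Cell-line profiles and tail calibration

Packaged profiles transcribe published genome-wide readouts for six cell
lines: category percentages (fusion/ITS+, fusion/ITS−, TFE; END_TEL takes
the remainder), end-telomere and ITS+ mean ± sd lengths, ECTR abundance
("high" in ALT+ lines, rendered as 15 per 100 molecules, giving ECTRs
roughly a quarter to a third of total telomeric sequence mass; absent in
TEL+/senescent lines), and the share of measured telomeres above 15 kb.

Telomere lengths follow a lognormal body moment-matched to the reported
mean ± sd, plus an optional heavy lognormal tail (default median 20 kb,
σ=0.6, spanning the 45–65 kb maxima reported for ALT+ lines). The tail
weight is solved by monotone bisection so that the pooled
measured-telomere population — end telomeres and internal ITS+ telomeres,
weighted by their mixture fractions, the ITS+ body contributing its own
intrinsic mass — carries the line's reported >15 kb share. When that
target lies below the body's intrinsic mass (SK-MEL-2, UMUC3, IMR90-S),
the calibration is infeasible and the profile uses no tail; the realized
mass then exceeds the report by up to ~1 percentage point, a known
limitation of a lognormal body under the published moments.

Two reported values required judgment. For UMUC3 the printed sd (2.8 kb on
a 3.1 kb mean), the printed CV (0.8) and the statement that no UMUC3
telomere exceeds 15 kb are mutually inconsistent under any lognormal body;
the profile follows the CV (sd = 2.5 kb), which is also what keeps a TEL+
line's sampled CV reliably below 1. For the TEL+/senescent lines the
super-long tail component uses median 16 kb, σ=0.25, matching their
reported maxima (14.75–23.5 kb) rather than the ALT-scale tail. The
reported mixture sd values are treated as describing the realized mixture;
profile bodies match the reported end-telomere moments and the genome-wide
CV is emergent — checked by the tests, never imposed.

## Alignment

Absolute positions of a molecule within an arm are unknown, so matching
compares successive label gaps (interval agreement), the standard optical
map approach. A chain of matched (molecule, reference) label pairs is
feasible when each consecutive gap pair agrees within
`max(abs_tol, rel_tol·Δref)` (defaults 500 bp, 0.12 — about 3 sd of the
differenced sizing error at typical spacing); the score is
`match_bonus·n_matched − miss_penalty·(skipped reference labels) −
extra_penalty·(skipped molecule labels)` (3/1/1) with free end gaps on both
sequences. The dynamic program over label pairs (numba-compiled, lookback
6 labels) is exactly equivalent to exhaustive enumeration over monotone
matchings, which the tests verify on all instances up to 8×8 labels.
Acceptance floors: ≥8 matched labels and score ≥15; failing both sides of
an arm is a valid "no alignment" outcome.

Because single exponential gaps are not distinctive, candidate arms are
pre-screened by consecutive-gap 3-grams: each molecule gap triple is
checked against every arm's reference triples in both reading directions
(tolerance slightly looser than the DP's), arms are ranked by supported
triples with an orientation hint, and the DP visits candidates in rank
order, stopping early on a near-complete chain or after 6 non-improving
candidates (16 max). The exhaustive path (`align_to_arm`, or
`candidate_arms=None`) bypasses the screen entirely.

Split alignment is greedy: the best accepted alignment is found, its
molecule span masked, and the flanking label blocks get one more pass —
at most two segments, since the assay's fusions are two-part. Ties
between arms break by score, then lexicographic arm id, then forward
orientation.

## Classification

Telomere labels are merged into clusters across gaps ≤3 kb; cluster
length is `total_intensity / k`, clamped to the 110 kb detection ceiling,
and intensities below the 0.1 kb floor read as undetected. An alignment
provides *end context* when its distal matched reference label lies within
20 kb of the chromosome terminus (`end_window_bp`); the molecule is read
in the primary (best-scoring) end-context alignment's orientation, so the
terminus points distal. Then, with a telomere cluster distal to the last
matched label:

* ≥10 kb of molecule (`internal_min_flank_bp`) **and** ≥1 nick label
  beyond the cluster → **FUSION_ITS_PLUS** (the telomere is internal);
* otherwise → **END_TEL** (the telomere is terminal).

With no detectable cluster, the unmatched continuation decides:

* ≥10 kb continuation containing ≥1 nick label → **FUSION_ITS_MINUS**;
* a 5–20 kb label-free overhang → **TFE** — the lower bound
  (`tfe_min_overhang_bp`) keeps fibers truncated right at the last label
  from being called TFE, the upper bound (the end window) rejects
  overhangs running implausibly far past the projected terminus;
* anything else → **UNCLASSIFIED**.

Molecules with no accepted alignment but a detectable telomere cluster are
**ECTR**; aligned molecules without end context are UNCLASSIFIED — a
deliberate abstention, since truncated fibers must not inflate the TFE
percentage, the assay's key zero-versus-nonzero discriminator. A fusion
whose two segments are both end-anchored is a sighting of each arm's end
and is recorded once per arm (twice under one arm for same-arm fusions);
per-molecule genome statistics still count it once.

Under the default noise model about 3–5% of molecules per category abstain
(mostly alignment-floor or end-context failures, approximately
category-independent, so percentages stay unbiased), and confusions among
called categories stay below 1–3% per category.

## Readouts and the ALT caller

Per arm: counts and percentages of the four arm-anchored categories,
overall mean ± sd and maximum of telomere length with TFE/ITS− entered as
0 kb, end-telomere mean ± sd (END_TEL only — the reported weighted-mean
arithmetic supports excluding ITS+ measurements, and the choice is
configurable), ITS+ mean, and per-arm CV (undefined, and excluded from
median-CV summaries, when the arm's mean is 0). Genome-wide: the same
pooled over unique molecules, plus the share of measured telomeres
(END_TEL + ITS+) above 15 kb, the share of arms whose longest telomere
exceeds 10 kb, ECTR and unclassified counts.

Welch's two-tailed unequal-variance t-test (Welch–Satterthwaite degrees of
freedom) serves all between-line comparisons of per-arm vectors over
shared arms; two zero-variance samples with equal means — e.g. TFE
percentages of two TEL+ lines, all zero — report t=0, p=1. No
multiple-testing correction is applied.

The ALT caller votes on five flags: fusion/ITS+ ≥1%, fusion/ITS− ≥0.25%,
TFE ≥1%, CV ≥1, super-long share ≥0.5%; ≥3 of 5 → ALT_positive. Each
threshold sits between the observed ALT+ minima (8.6 / 0.5 / 6.3 / 1.1 /
1.0%) and the TEL+/senescent maxima (0 / 0 / 0 / 0.8 / 0.4%), and the
3-of-5 vote keeps any single noisy readout from flipping the call. ECTR
abundance is reported but not voted on, since it is unquantified for TEL+
lines in the source data.

## Problem sizes and determinism

Simulation-based tests run at the study's own scale — ~2000 arm-anchored
molecules, i.e. the default 41 arms at up to 50 molecules/arm — with
fixed seeds throughout; every simulation consumes a single
`numpy.random.Generator`, so identical (profile, reference, seed) produce
byte-identical molecule sets. The 20-seed, six-profile end-to-end sweep
verifies ALT calls and the CV>1 / CV<1 separation on every run. The
acceptance script raises per-arm coverage (200–400/arm) for stochastic
percentage targets purely as Monte-Carlo variance reduction on the same
population quantities. Statistical checks on stochastic quantities use
3-standard-error bounds.

## What the simulation does and does not show

The generator reproduces the category mixture, length distributions,
intensity proportionality, coverage and label-noise structure the analysis
assumes, so passing tests demonstrate that the pipeline recovers known
truth under those assumptions — parameter recovery, not biological
validation. Real data differ in ways the simulator ignores: hg38
subtelomeres have locus-specific, non-exponential label patterns,
segmental duplications and cross-arm homology (making arm assignment
genuinely harder than for synthetic maps); fragile-site breakage truncates
fibers non-uniformly; intensity-to-length calibration drifts across runs;
ECTR size/topology is heterogeneous (and circular vs linear, single- vs
double-stranded species are indistinguishable to the assay); and real
per-arm appendix values derive from deposited data not reproduced here.
Between-line p-values from simulations correspond to the published tests
in kind, not in value.
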