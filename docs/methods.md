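# Methods

## The model

`ddadia` treats a metabolomics experiment as two parallel observations of
the same set of compounds. Each compound *c* has a true precursor m/z, a
retention time, and a fragment spectrum. The DIA channel observes every
compound but measures its spectrum chimerically: fragments of co-eluting
compounds are superimposed. The DDA channel observes only a subset of
compounds but measures clean spectra. The method's premise is that
structural relatedness — shared fragments, possibly offset by the precursor
mass difference — is reliable in the DDA channel and can be transferred to
the DIA channel by graph connectivity.

Assumptions the implementation makes explicit:

* **Charge is ignored.** Precursor masses are treated as observed m/z
  (negative-mode, singly-charged regime); no deisotoping or adduct grouping.
* **Retention time is in minutes** everywhere internally; MGF
  `RTINSECONDS` is converted on read. This keeps the RT tolerances in the
  units they are quoted in (0.05 min).
* **Feature tables are trusted upstream output.** Peak picking and
  alignment (MS-DIAL-style) happen before this package; their extraction
  parameters (mass slice width 0.1 Da, sigma window 0.5) are recorded in
  the preprocess config for provenance but never reapplied.

## Modified cosine

Candidate fragment pairs match **directly** (|m/z difference| ≤ τ_frag) or
**shifted** (|m/z difference − Δ| ≤ τ_frag, Δ the precursor difference);
shifted matching is active only when |Δ| > τ_frag, since otherwise its
window duplicates the direct one, and a pair qualifying both ways is counted
once, as direct, to prevent double counting. Pair weight is
(I_a I_b)^p with p = 0.5: square-root weighting tempers the dominance of
base peaks and is the common networking practice; p is exposed in
`ScoreConfig`.

The production score uses greedy one-to-one selection (descending weight,
ties broken by smaller |m/z difference|, then lower peak index in each
spectrum), normalised by the Euclidean norms of p-powered intensities.
Greedy is the behaviour of the networking tools practitioners run, and it is
cheap; the exact maximum-weight assignment (`max_assignment_score`, solved
with `scipy.optimize.linear_sum_assignment`) ships as a reference routine.
Greedy can only under-score relative to the exact optimum, and equals it
whenever no peak has two competing candidate partners; both properties are
asserted in the test suite, with a brute-force enumeration as a second,
independent check at small peak counts.

Symmetry is guaranteed structurally: the two spectra are put in canonical
(spectrum-id) order before assignment, so tie-breaking cannot depend on
argument order. Empty spectra (e.g. after the abundance cutoff) score 0 with
0 matches and are excluded from networking as flagged isolated nodes.

## Networking and component selection

All unordered pairs are scored (optionally restricted to a maximum
precursor shift; unlimited by default, matching a networking run with the
precursor-window filter off). An edge survives at score > 0.7 and ≥ 4
matched peaks by default. Both comparisons are configurable
(`score_strict`, `matched_strict`) because prose like "above 0.7 and more
than four matched peaks" is ambiguous against the usual tool semantics of
"min matched peaks"; the defaults here are score strictly above, matches
at-least.

An optional per-node top-k rule (an edge must rank in the top k by score
for **both** endpoints) reproduces the GNPS topology filter; it is off by
default and proven side-effect-free (never adds edges, never alters scores).

Components are labelled by a union-find over sorted feature ids; labels are
assigned 0, 1, … in order of each component's smallest member id, making
every export a pure function of the graph. Singletons are kept (minimum
cluster size 1): they can never pass the component filter, but they remain
visible in exports.

Component selection keeps components with **more than three nodes and at
least three edges** (so a 4-node path qualifies; a 3-node triangle does
not). Both minima and both strict/inclusive readings are configurable.

## Cross-mode merge and retention

Selected DDA features are inserted into the DIA table. A DDA and a DIA
feature are tolerance-matched when |Δm/z| ≤ 0.01 Da and |ΔRT| ≤ 0.05 min —
the same tolerances the upstream alignment used, since no separate merge
tolerance is defined anywhere. With several matches, all are recorded and
the smallest normalised distance √((Δmz/τ_mz)² + (Δrt/τ_rt)²) is flagged
primary (ties broken by feature id). Unmatched DDA features are still
inserted: they may link through MS² similarity.

The combined network is **rebuilt** from the merged table, each feature
represented by its own-mode spectrum. Rebuilding (rather than overlaying
DIA features onto the frozen DDA network) is the default because it lets
DIA-DIA similarity contribute to component structure; the network over any
feature subset can still be built directly, so overlay-style analyses
remain possible. Tolerance-matched pairs receive parallel "match" edges
with null score/matched count, kept distinct from similarity edges in all
exports (GraphML is written as a multigraph) so the two relation types can
be styled separately in Cytoscape.

A feature is **retained** when it has at least one opposite-mode neighbour
over similarity or match edges (`cross_witness="any"`). Match edges count
as witnesses because a tolerance-matched pair is the strongest possible
cross-mode evidence — the same ion seen twice; a `similarity_only` mode is
provided for sensitivity analyses. Retained features carry their witness
sets, so every retention decision is auditable.

## The synthetic generator

`simgen` emulates what makes the paired-acquisition problem hard:

* **Families** of `members_per_family` compounds share a scaffold of
  `scaffold_peaks` fragments whose intensities dominate member-specific
  peaks (median ratio ≈ 25:1). Diagnostic fragments dominating a compound
  class's spectra is what makes molecular families cluster in practice;
  with this ratio, intra-family modified cosines sit around 0.85–0.9 and
  inter-family pairs near 0, so the planted structure is recoverable but
  not trivial. One family can carry a fixed anchor scaffold
  (300.9980 / 255.0646 / 169.0130 Da, a polyphenol-like diagnostic triple)
  so the documented example shows a recognisable cluster.
* **DDA coverage** is an exact per-family fraction:
  `round(members_per_family × dda_coverage)` members, drawn without
  replacement, get a DDA feature and a clean DDA spectrum. An exact
  fraction (rather than an i.i.d. coin per feature) keeps every family's
  DDA anchor at the nominal rate, which is the regime the method is
  designed for; per-feature Bernoulli sampling would conflate the method's
  behaviour with sampling noise in the benchmark itself.
* **DIA chimerism**: every compound yields a DIA feature; its spectrum
  receives `round(dia_contamination × n_peaks)` additional fragments drawn
  from compounds within ±0.1 min, intensity-scaled by U(0.2, 0.8) —
  additive, never replacing true peaks.
* **Decoys** are DIA-only features with unrelated random spectra.
* **Measurement noise**: observed m/z jittered by N(0, 0.003 Da), RT by
  N(0, 0.01 min), intensities by a lognormal factor — so cross-mode
  tolerance matching succeeds for almost all, not all, pairs, and the
  similarity fallback path is genuinely exercised.

Ground truth marks, for every feature, its family (or decoy status), its
compound, and its opposite-mode counterpart. **Evaluation** counts as
planted positives all features of families with at least one DDA-acquired
member. This is deliberately a family-level, not compound-level, notion:
recovering DIA ions whose *family* — not necessarily the ion itself — was
anchored in DDA is precisely the point of the method, so a compound-level
truth would misclassify the method's intended discoveries as false
positives. Decoys and members of DDA-free families are negatives.
Component purity is the mean, over components with retained members, of the
largest single-family share.

What the generator does **not** emulate: chromatographic peak shapes,
isotope envelopes, adducts or in-source fragments, intensity-dependent
precursor selection in DDA, and m/z-dependent mass error. Passing the
benchmark therefore shows that the graph logic, tolerances and bookkeeping
behave correctly under realistic noise and chimerism — not that the
pipeline is robust to every artefact of real acquisitions.

## Numerical and formatting choices

* All range bounds inclusive; intensity cutoffs are "keep if ≥".
* Peaks colliding at identical m/z are merged by summing intensities, so
  m/z values are unique keys.
* Exports format m/z to 6 decimals (1 µDa, far below any tolerance), RT to
  4; round-trips are asserted at that precision and repeated runs are
  byte-identical.
* Degenerate inputs: empty spectra are flagged and isolated, empty
  retention and empty component selections are valid results with warnings,
  a zero-spectrum network build is an error.

## Problem sizes

The default benchmark is 10 families × 8 members with 20 decoys — 150
features, 130 spectra-bearing pairs, ~11 000 pairwise scores — chosen so
that each family is large enough for component selection to be meaningful
while the full pipeline, the clean variant and all property suites (1000
greedy-vs-exact pairs, 100-spectrum monotonicity sweeps, 50 random
component-filter graphs) complete in seconds.

## Known limitations

* The greedy assignment can differ from the exact optimum on dense
  conflict structures; the gap is measured, not hidden, via the reference
  solver.
* Annotation stops at ranked candidates; it does not attempt
  structure-level identification, molecular-formula assignment, or the
  manual curation a final compound list requires.
* Real acquisitions with deviating column chemistry or mass accuracy will
  need the tolerances adjusted; defaults mirror one specific instrument
  configuration.
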