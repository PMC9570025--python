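# Methods

## Scope and model

`venomsig` operates downstream of the wet lab and of third-party
predictors: signal peptides, transcript quantification (TPM), BLAST hits
and search-engine scores are *inputs*, consumed as annotation tables.
The package's own contributions are (i) the precursor maturation
grammar, (ii) the monoisotopic mass model with amidation/disulfide
corrections, (iii) the replicate-consensus treatment of MALDI-TOF peak
lists, (iv) the evidence-combination rule producing up/down-in-males
calls, and (v) a generative model of all inputs with planted truth.

## Mass model

Masses are monoisotopic throughout; the instrument context is
reflector-mode MALDI-TOF on crude venom, where peptides appear as singly
protonated ions. Residue masses are derived at full floating-point
precision from elemental compositions (CODATA element masses), not from
a rounded lookup table, so the residue-sum route and the
elemental-composition route agree to machine precision; the test suite
additionally cross-checks against Biopython's `molecular_weight`.
Constants: water 18.010565 Da, proton 1.007276 Da, amidation −0.984016 Da
(−O +N +H), disulfide −2.015650 Da per bridge (−2 H).

Disulfide connectivity is not modelled; only counts matter for mass, and
all cysteines are assumed paired (`⌊#Cys/2⌋` bridges). This matches the
stated bridge counts of the reference peptides (three cystines for the
six-cysteine toxins, two for the four-cysteine novel compound).

The packaged reference masses are reproduced within 0.1 Da but show a
systematic offset of +0.02–0.04 Da, consistent with the original
calculation having used a slightly different amidation convention
(≈−1.008 Da rather than the exact amide delta). The 0.1 Da test
tolerance absorbs this; the offset is noted, not corrected for.

Ambiguous residues (B, Z, X, U, O) are rejected with the offending
position rather than averaged: a venom precursor with an ambiguous call
cannot yield a trustworthy mass prediction.

## Maturation grammar

Coordinates are 0-based half-open; `signal_end` is the index of the
first mature-chain residue. Cleavage sites are maximal K/R runs of
length 1–3 (longer runs, not observed in this precursor family, are
treated as tribasic over their three C-terminal residues and logged).
Two deliberate asymmetries:

* **Single Lys is not a cleavage point.** Monobasic
  proprotein-convertase cleavage in these precursors occurs after Arg;
  treating every lone Lys as a site would fragment Lys-rich mature
  toxins. Lone Lys runs are still *reported* by `find_basic_sites`
  (kind `monobasic`) for completeness.
* **The "quadruplet" motif** is implemented operationally: a monobasic
  Arg preceded by a ≥3-residue spacer, with the mature peptide on the
  C-terminal side (N-terminal release) or, when the Arg terminates the
  mature region, with one trailing basic residue trimmed from the mature
  side. The literature definition behind the motif is not restated in
  the source material; this reconstruction is the single rule that
  reproduces both quadruplet-processed reference peptides, and both are
  covered by tests. In practice the C-terminal case is equivalent to
  dibasic cleavage at the adjacent K+R pair.

Amidation is set only when a terminal Gly is consumed — either the
chain's own terminus (`FULL_CHAIN_GLY_AMIDE`) or a Gly immediately
preceding a cleavage site — never otherwise; this is property-tested.
`AUTO` enumerates all applicable strategies (full chain first, then
site-based N→C) and collapses duplicate (sequence, amidation) products.
Inapplicable strategies return empty results with a logged reason, so
enumeration never raises mid-run.

Allelic variants are encoded in-sequence as a single `X/Y` position and
expanded before processing; more than one marker is rejected (not
observed, and multi-site phasing would be guesswork).

## Consensus signals and matching

Within one specimen group, all peak-list signals are pooled, sorted,
and chained into a cluster while consecutive gaps are ≤ the cluster
tolerance (greedy single linkage; deterministic and permutation-
invariant). A cluster's occurrence fraction counts distinct supporting
spectra over the group's spectra; the default retention threshold is
0.5, applied **per group** (the alternative reading — across all
spectra of the study — can be obtained by pooling before the call, but
per-group is what a presence/absence contrast between groups needs).
The centroid is the unweighted mean of member m/z values; intensities
are carried only for reporting, never for calls.

No matching tolerance is stated in the source material. Defaults are
0.15 Da for cross-spectrum clustering and 0.2 Da for prediction-to-
consensus matching, reflecting externally calibrated reflector MALDI-TOF
accuracy over m/z 3000–10,000; both are `RunConfig` knobs. Matching is
inclusive at the boundary, and within one group the nearest centroid
wins.

## Evidence combination

* PSM filter: strict inequalities (−10lgP > 30, coverage > 7%) and a
  signal peptide are required; the filter is a subset operation and
  idempotent.
* Redundant precursors (identical mature chain) collapse to the
  highest-scoring representative.
* Classification maps the best accepted homology hit's description
  through a keyword table (toxin/channel/La1/AKTx → neurotoxin;
  antimicrobial/non-disulfide bridge → AMP; inhibitor → protease
  inhibitor; `-ase` words → enzyme; else other); no accepted hit →
  novel. Tox-Prot hits are searched permissively (E < 0.1) but count for
  classification only below 1e−5. One reference row is a documented
  manual override (a paralog of a sodium-channel toxin whose best hit is
  an AMP): the fixture carries the published class label, which takes
  precedence over the keyword rule.
* Expression contrast: `male_up` iff TPM♂ > fold·TPM♀ (default fold 2;
  the source reports direction only, and every reference row exceeds
  2-fold). Gland enrichment requires both telson TPMs above the
  gland-free control. There are no replicates, hence no test statistic —
  the contrast is descriptive by design.
* Final call: conjunction of the MALDI pattern (primary) and the
  expression direction. Juveniles contribute MALDI evidence only (no
  juvenile transcriptome exists). When the two layers disagree the call
  is `unspecific` — the strictest reading of the published evidence
  hierarchy.

## Synthetic data

The generator states a world mirroring the study design: 2 males,
4 females, 4 juveniles, 2 replicate extractions each (20 spectra);
specific peptides present only in their favoured group's spectra.
Defaults, chosen once: detection probability 0.95 for a present planted
peptide (prominent fingerprint signals are highly reproducible), 0 for
absent; m/z jitter SD 0.05 Da; 5 spurious uniform peaks per spectrum
over m/z 800–10,000; TPM log-normal around 500 with log-SD 1.5 (spanning
the observed ~5–60,000 range), 50-fold enrichment for specific
precursors, per-tissue log-normal noise of log-SD 0.5, negative control
at 2% of baseline; PSMs pass the quality filter unless a failure
fraction is requested (quality noise is not part of the stated noise
model). Sequence backgrounds are uniform over residues apart from the
enforced motifs — no attempt to model real venom composition statistics.

Two generator-level design choices make planted truth identifiable:
mature cores of site-processed classes contain no K/R (so the planted
site is the first), and planted [M+H]+ values are rejection-sampled to
be ≥1 Da apart (so presence calls cannot cross-match). A green
end-to-end test therefore establishes the pipeline's correctness under
the stated noise model, not robustness to mass coincidences, convertase
site ambiguity, or real-world intensity effects.

All randomness flows from one `numpy` generator seeded explicitly; the
same seed yields byte-identical output bundles.

## Numerical and degenerate-input choices

* Empty peak lists are accepted (a failed spectrum is data, not an
  error); empty consensus inputs yield empty outputs.
* `-` or empty cells in TPM columns mean "not detected" and map to 0;
  negative TPM is an error.
* Single-linkage chaining bounds the *gap*, not the cluster radius; at
  the default jitter (0.05 Da SD) clusters stay well within the match
  tolerance, but pathological chains are possible in principle — the
  invariants tested are monotonicity in the occurrence threshold,
  permutation invariance and ordering, not a radius bound.
* Tie-break in matching: smallest |Δm| within a group; report rows are
  sorted by precursor id for determinism.

## Known limitations

* Signal peptides must be annotated; the package does not re-predict
  them.
* Only +1 charge states and monoisotopic masses; no isotope envelopes,
  no MS2.
* The quadruplet rule is a reconstruction (see above) and is flagged as
  such; precursors processed by other convertase chemistries would need
  an explicit strategy annotation.
* One reference row (an allelic La1-like peptide) has printed allelic
  masses whose difference (14.09 Da) is inconsistent with its annotated
  D/E substitution (14.016 Da); it is carried in the fixture but
  excluded from mass-reproduction tests.
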