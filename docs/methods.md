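# Methods

## The screening model

A fusion tag can rigidly replace ICL3 only if its own terminal helices
can continue TM5 and TM6. The screen reduces that requirement to four
per-chain measurements:

1. **Helix retrieval.** Helices come from the file's secondary-structure
   records when present (HELIX / `struct_conf`), clipped to residues
   actually in the coordinates. Files without annotation (typically
   predictor output) fall back to a Cα-only geometric assignment:
   residue *i* is helical iff the Cα(i)–Cα(i+2), (i+3) and (i+4)
   distances all fall inside windows centred on ideal α-helix values
   (5.5 ± 0.6, 5.3 ± 0.6, 6.4 ± 0.7 Å), and maximal runs of ≥ 4
   helical residues become segments. This is the same style of distance
   criterion as Cα-only assigners like P-SEA; the windows are
   conventional plumbing, deliberately forgiving, and every report
   records which retrieval path was used. Note the rule is
   forward-looking: the last four residues of a helix have no complete
   window and are not marked helical, so geometric segments end four
   residues earlier than the visual helix. This is irrelevant to the
   screen (annotation is preferred for experimental entries) but
   matters when interpreting junction-helicity fractions.

2. **Terminal-helix gate.** The first and last helix of the chain must
   be distinct, each ≥ `min_helix_len` = 8 residues, and start/end
   within `max_terminal_offset` = 5 residues of the respective chain
   terminus (both termini; requiring only one would not give the
   double-helical connection the design needs). Offsets are counted in
   observed polymer residues. Failures carry machine-readable reasons
   (`too_short_N`, `offset_C`, `single_helix`, …).

3. **Separation and angle.** The separation is the Cα–Cα distance
   between the chain-terminal-most helix ends — first residue of the
   N-helix, last residue of the C-helix — because those are the atoms
   that splice onto TM5/TM6. (The alternative inner-ends reading is
   available via `anchors="inner"`.) The angle is direction-aware
   between N→C axis vectors, so antiparallel is θ → 180°, not
   |cos θ| → 1. Hard gates: separation within 10 ± 8 Å, θ ≥ 140°.
   Neither tolerance is canonical; both are explicit config echoed into
   every report so a pure-threshold screen is reproducible.

4. **Score.** Survivors are ranked by
   `max(0, 1 − |d − 10|/8) · max(0, (θ − 90)/90)`, a separable linear
   ramp that is 1 exactly at (10 Å, 180°), monotone in each argument,
   and zero outside the gate support. It is a ranking device, not a
   probability.

### Helix axis fit

The axis direction is estimated from the Cα second-difference
(curvature) vectors, which for a helix point radially inward — exactly
perpendicular to the axis. The axis is therefore the least-variance
(smallest singular) direction of the curvature-vector cloud, sign-fixed
to point N→C. This recovers the true axis of an ideal helix to machine
precision at any length ≥ 4 residues, whereas the dominant principal
direction of the Cα positions themselves carries an O(1/n) tilt (≈ 2°
at 12 residues) from the axial–radial cross-covariance of an incomplete
final turn — enough to blur an antiparallel gate. Near-collinear
segments (mean curvature below 1e−6 Å) fall back to the positional
principal direction. Fit quality is reported as the RMS perpendicular
distance of the Cα atoms to the axis line (≈ 2.3 Å, the Cα radius, for
real helices).

## Structure handling

- Only model 1 of multi-model files is kept: screening geometry must be
  single-conformer.
- Alternate locations resolve to the highest-occupancy atom, ties to
  the alphabetically first altloc, making every downstream report
  byte-reproducible.
- Author numbering + insertion code is the public coordinate system;
  0-based indices never appear in outputs.
- Non-standard polymer residues (MSE …) stay polymer and map to
  one-letter codes through the tabulated parent-residue table,
  unknown → X.
- The deposited oligomer count is read from assembly records
  (REMARK 350 / `pdbx_struct_assembly`); absent records leave it
  "unknown" — the screen never assumes monomericity. Unknown metadata
  never silently passes or fails a chain: curation flags are
  pass/fail/unknown, and "unknown" does not veto a candidate.
- Chains are screened individually even in multi-chain entries, with
  the oligomer flag carrying the entry-level concern; dropping whole
  entries would hide recoverable monomers.

## Chimera design

Entry = last retained receptor residue before the tag, exit = first
retained after it, both in receptor author numbering, so replacing loop
residues 235–244 is exactly (entry 234, exit 245). Given a declared
ICL3 span, default candidates are the five residues ending at the span
start − 1 and the five starting at span end + 1 — fully overridable,
since real designs choose junction points case by case. Tag mutations
address tag numbering and must change the sequence (a no-op mutation is
rejected as a likely coordinate error). Expression-cassette elements
(signal peptides, purification tags) are outside the chimera core.

## Model triage

Junction windows cover k = 4 residues on each side of a splice point
(one helical turn plus one residue; config). Per window the package
reports the helical fraction (1.0 ⇔ continuous), the mean Cα B-factor
column (the dominant predictor convention for per-residue confidence,
0–100), Cα RMSD to a reference receptor over an author-number identity
mapping with a declared offset (mismatches are errors, never silent
drops), and tag–receptor heavy-atom contacts below 3.0 Å with chain
separation ≥ 3 residues. The 3.0 Å default sits well below van der
Waals contact, so each hit is an unambiguous potential clash; a
vdW-overlap mode was considered and deferred. Models rank by
(both junctions continuous, fewer clashes, higher mean junction
confidence, lower RMSD), with the construct name as a stable tiebreak.
Membrane/micelle clashes are out of scope — there is no membrane plane
in the model.

## Synthetic fixtures

Fixtures use textbook ideal-helix constants (1.5 Å rise, 100°/residue,
2.3 Å radius) so every expected value has a closed form; they model no
particular protein. Hairpins place the C-helix so the anchor Cα pair is
separated by exactly the requested distance, encode the built helix
spans as file annotation, and use straight 3.8 Å-spaced connectors for
loops and terminal pads (collinear equal spacing can never satisfy the
helix distance windows simultaneously, so connectors are non-helical by
construction). Mock fusion models trace one continuous ideal helix;
"broken" junctions displace the four residues before the splice
boundary onto an extended offshoot, which under the forward-looking
assignment rule leaves exactly the boundary-side half of the 8-residue
window helical (fraction 0.5). Planted clashes add a single CB atom
radially outward at the requested distance from a receptor Cα; at the
default cutoff the nearest legitimate Cα pairs are ≥ 5 Å apart, so the
planted contact is the only one. The seeded corpus mixes planted
positives with negatives that each violate exactly one named criterion
(helix length, offset, separation, angle, exclusion keyword, deposited
oligomer), and is byte-identical across runs with the same seed.

What the fixtures do not emulate: side chains beyond the planted CB,
backbone atoms other than Cα, Ramachandran validity, crystallographic
disorder, or realistic predictor confidence profiles. Passing tests
therefore demonstrate the correctness of the measurements and the
screen logic, not robustness to the full messiness of deposited
entries.

## Problem sizes and determinism

The test suite and the acceptance script run on generated inputs of
modest size — hairpins of tens of residues, corpora of ~10 files,
separation scans of 37 grid points — chosen because every quantity they
probe (thresholds, argmax locations, counts) is scale-free. All
randomness flows through explicit seeds; screening reports and fixture
corpora are byte-identical across repeated runs.

## Known limitations

- Geometric helix assignment is Cα-only; it cannot distinguish α- from
  3₁₀-helix and shortens helices by four residues at the C-end (see
  above).
- "Alignment scores" of predictor pipelines may include predictor
  internal metrics (pAE and friends); only Cα RMSD is implemented.
- Thermophile provenance and known binding partners are user-supplied
  annotations; the package does not infer them from taxonomy or from
  complex entries.
- The screen reproduces the automatable part of candidate curation;
  literature judgement (solubility, expression track record) remains
  manual by design.
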