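# helixtag

Tools for inventing GPCR fusion-tag fiducials by geometry: mine protein
structures for candidate tags with suitably placed terminal α-helices,
enumerate receptor–tag chimeras across an ICL3 junction matrix, and
triage predicted fusion models for junction rigidity, conformational
preservation and steric clashes.

## The problem

Antagonist-bound GPCRs are poor cryo-EM targets: at ~45 kDa with
flexible loops they provide neither the mass nor the rigid features
particle alignment needs. A proven remedy is to graft a soluble protein
domain — a fiducial tag — into intracellular loop 3 (ICL3), the loop
between transmembrane helices TM5 and TM6, so that the tag's N- and
C-terminal helices continue TM5 and TM6 as unbroken helices. For that to
work the tag's terminal helices must already sit in the right geometry:
long enough to splice into, close enough to the chain termini, roughly
**antiparallel** (N→C axis vectors at an angle θ near 180°), and with an
end-to-end Cα separation near **10 Å** — the gap between the cytoplasmic
ends of TM5 and TM6.

`helixtag` makes that screen, the construct design that follows it, and
the model triage that selects the final construct, reproducible:

1. **Screen** (`candidate_screen`): for every polymer chain of every
   structure file, after removing waters and ligands, find the helices
   (file annotation, else Cα distance geometry), gate on

   - terminal helix length ≥ 8 residues,
   - ≤ 5 residues between each helix and its chain terminus,
   - end-to-end Cα separation within 10 ± 8 Å,
   - inter-axis angle θ ≥ 140°,

   and rank survivors by a continuous score

   `score = max(0, 1 − |d − d₀|/Δd) · max(0, (θ − θ_min)/(180 − θ_min))`

   with d₀ = 10 Å, Δd = 8 Å, θ_min = 90°, which is 1 exactly at
   (10 Å, 180°). Membrane/designed-protein keywords and deposited
   oligomeric state are carried as curation flags; unknown metadata is
   reported as unknown, never guessed.

2. **Design** (`fusion_design`): name junctions in receptor author
   numbering — *entry* = last retained residue before the tag, *exit* =
   first retained residue after it — and enumerate an entry × exit
   matrix of chimeras `receptor[..entry] + tag + receptor[exit..]`,
   conventionally 5 × 5 flanking the ICL3 span, with optional tag point
   mutations.

3. **Assess** (`model_assessment`): for each predicted model of a
   chimera (per-residue confidence in the B-factor column), measure
   junction helicity over 8-residue splice windows, mean junction
   confidence, Cα RMSD to a reference receptor conformation
   (least-squares superposition via the SVD of the cross-covariance,
   with reflection guard), and tag–receptor heavy-atom clashes below
   3.0 Å; rank models by (continuity, clashes, confidence, RMSD).

A fixture generator (`synthetic_fixtures`) builds ideal helices,
hairpins and mock fusion models with exactly known geometry, so the
whole pipeline is tested without downloading a single structure.

## Worked example

Designing the span-replacing control construct for an A2A-like receptor
numbered 2–316, with a 106-residue tag inserted in place of loop
residues 235–244:

```python
from helixtag import (NumberedSequence, splice_sequence, FusionSpec,
                      enumerate_constructs, default_junction_candidates)

rec = NumberedSequence("A2AR", ("MA" * 200)[:315], first_auth_num=2)
tagseq = list("LK" * 53); tagseq[71] = "R"
tag = NumberedSequence("BLAC", "".join(tagseq))

c = splice_sequence(rec, tag, entry=234, exit=245, mutations=[(72, "S")])
print(c.name, len(c.sequence), c.deleted_span, c.junction_n, c.junction_c)

entries, exits = default_junction_candidates(235, 244)
print(entries, exits, len(enumerate_constructs(FusionSpec(rec, tag, entries, exits))))
```

prints

```
A2AR_BLAC_e234_x245 411 (235, 244) 233 340
(230, 231, 232, 233, 234) (245, 246, 247, 248, 249) 25
```

i.e. entry 234 / exit 245 deletes exactly residues 235–244; the chimera
is 233 receptor + 106 tag + 72 receptor = 411 residues with the tag
spanning chimera positions 234–339; and the default 5 × 5 junction
matrix yields 25 constructs. The `mutations=[(72, "S")]` argument applies
an R72S substitution at tag position 72 before splicing.

From the shell, the same stages run as:

```sh
helixtag fixtures --out corpus/ --corpus 10 --positives 3 --seed 7
helixtag screen   --input corpus/ --out report.tsv
helixtag design   --receptor r.fasta --tag t.fasta --icl3 235:244 \
                  --receptor-first-num 2 --mutation 72:S --out design/
helixtag assess   --model model.pdb --constructs design/constructs.tsv \
                  --reference ref.pdb --out assessment.tsv
```

The screen report is a TSV with `#` header lines echoing every
threshold, one row per chain with pass/fail/unknown flags for each
criterion, the measured geometry, and the score; identical inputs give
byte-identical reports.

## Scope

The package covers the in-silico pipeline only: no structure prediction
(predicted models are inputs), no membrane/micelle modelling, no
expression, binding-kinetics or cryo-EM processing stages, and no
automated literature curation — thermophile provenance and known
binding partners enter through a user-supplied annotation table.
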