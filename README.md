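# ncranno

Homology-based annotation of non-coding RNAs (ncRNAs) in fragmented draft
genome assemblies — the kind of early, unscaffolded assembly where most
contigs are shorter than a kilobase and the target species is far from any
well-annotated relative.  Since ncRNAs are typically <200 nt and
unspliced, such assemblies are annotatable, but no single search method is
sensitive enough: distant homologs of snRNAs, snoRNAs and miRNAs routinely
escape default-parameter sequence search.

`ncranno` is a library (with a thin CLI) for biologists and method
developers who want that multi-evidence annotation protocol as tested,
reusable code:

- **Sensitivity-tuned search ensemble** — nine blastn-style scoring
  strategies (word size 7, match/mismatch +5/−4 and +4/−5, expectation
  cutoffs up to 1000, plus the blastn default) run as exact word seeding,
  ungapped X-drop extension and banded affine (Gotoh) extension, with
  Karlin–Altschul statistics `E = K·m·n·e^{−λS}` solved per scheme.
- **Rule-based candidate filtering** — keep alignments covering ≥40 % of
  the query, longer than 20 nt, at ≥75 % identity; merge nearby same-strand
  hits up to 125 % of the query length; extend to query length ±10 nt.
- **Profile HMMs** — per-family models scanned over the genome, Gumbel
  calibration on shuffled windows, envelope regions reported at E ≤ 0.01.
- **Miniature covariance models** — SCFGs over the seed's consensus
  secondary structure scored by CYK (global in model, local in sequence),
  calibrated on shuffled nulls; hits accepted when bitscore ≥ gathering
  threshold (GA), E < 0.01 and ≥70 % model coverage; final curation
  re-scores every locus with 300 nt flanks and demands bitscore
  strictly above GA.
- **Contamination screen** — contigs matching a bacterial reference at
  E<1e−10 / identity>75 % / length>20, or covered ≥70 % at ≥80 % identity,
  are removed before annotation.
- **Shuffle-null performance** — per strategy × RNA class confusion
  matrices from 1000 shuffled queries per family; sensitivity
  `TP/(TP+FN)`, specificity `TN/(FP+TN)`.
- **Dollo parsimony** — gene-family gain/loss histories on a rooted
  species tree (each family gained once, lost freely), with hard
  ancestral constraints, per-edge event counts and group-specific family
  sets (e.g. colonial vs solitary tunicates).
- **Synthetic benchmark generator** — fragmented genomes (GC 0.36, ≥80 %
  of contigs sub-kilobase) with planted homologs at controlled identity,
  pseudogenized copies and contaminant contigs, plus a machine-readable
  truth table, so the whole pipeline is testable without downloads.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

Dollo gain/loss reconstruction on the bundled 12-species bilaterian
topology (`examples/04_dollo_gain_loss.py`):

```
$ python examples/04_dollo_gain_loss.py
let7-like: gained at Bilateria, lost on no edges
mir-col: gained at Ascidiacea, lost on ['Ciona'] edges
mir-sol: gained at Tunicata, lost on ['Bsc', 'Dvex'] edges
snoZ-like: gained at Craniata, lost on no edges

families present per ancestral node:
                families
node
Bilateria              1
Chordata               1
Tunicata               2
Ascidiacea             3
Craniata               2
...

edges with events (gains/losses):
        parent      child  gains  losses
    Olfactores   Tunicata      1       0
      Tunicata Ascidiacea      1       0
    Ascidiacea        Bsc      0       1
Aplousostolido       Dvex      0       1
Aplousostolido      Ciona      0       1
    Olfactores   Craniata      1       0

colonial-specific: ['mir-col']; solitary-specific: ['mir-sol']; shared: []
```

`let7-like`, present in every leaf, is reconstructed as a single gain at
the root with no losses; `mir-col`, present only in the two colonial
ascidians, gains at their common ancestor (Ascidiacea) and is lost once
toward the solitary *Ciona* clade under the single-gain (Dollo) rule,
while `mir-sol` costs two losses in the colonial species.  The per-node
counts obey `count(child) = count(parent) + gains − losses` on every
edge.

The other examples cover the search ensemble on a diverged planted copy
(`01`), the full annotation pipeline on a synthetic genome with per-stage
counts and a families/loci summary table (`02`), and shuffle-null
sensitivity/specificity for one strategy (`03`).

A shell entry point mirrors the library:
`ncranno simulate | screen | search | validate | annotate | evaluate | dollo`,
driven by a single YAML config for the full pipeline.

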