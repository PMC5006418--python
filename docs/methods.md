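# Methods

`ncranno` annotates non-coding RNAs in fragmented draft genome assemblies
by homology, combining three search routes — an ensemble of
sensitivity-tuned word-seeded local-alignment strategies, profile hidden
Markov models, and miniature covariance models — with a rule-based
filtering and curation protocol, a contamination screen, shuffle-null
performance estimation, and Dollo-parsimony comparative analysis.  This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Local alignment ensemble

Each query is searched against both strands of the genome with nine
scoring schemes: eight sensitivity-tuned settings (match/mismatch rewards
+5/−4 or +4/−5, word size 7, gap costs from 3/5 to 25/10, expectation
cutoffs from 10 to 1000) and the blastn default (+1/−3, word size 11).
Unstated expectation cutoffs in the tuned set default to 10, the default
row's value, and every preset is overridable through the run
configuration.  The theoretical-frequency column of the published
parameter table is stored as informational metadata only; it enters no
computation, because its original definition is not reproduced here and
the standard Karlin–Altschul target frequency (the expected identity of
optimal alignments, `sum_i p_i^2 e^{lambda r}`) already gives ≈0.99 for
the default scheme and ≈0.65 for +5/−4.

The algorithm is exact word seeding (N never seeds), ungapped X-drop
extension on the diagonal, then banded affine-gap (Gotoh) extension with
traceback for identity bookkeeping.  Defaults: X-drop `20·r`, band 40
columns, and a gapped-extension trigger of six match-equivalents of
ungapped surplus with the 50 best ungapped segments per strand always
extended — the trigger is a speed device for genome-scale scans and is
irrelevant on small inputs, where everything is extended.  Ties between
equal-scoring extensions resolve toward the shorter alignment through the
traceback order.  E-values use `E = K·m·n·exp(−lambda·S)` with `n` the
two-strand genome size; `lambda` is the unique positive root of
`sum p_i p_j e^{lambda s_ij} = 1` (bisection to 1e−9), and `K` uses the
geometric-series approximation
`K = lambda·|E[S]|·e^{−lambda r}/(1−e^{−lambda(r−q)})`, which reproduces
the tabulated ungapped `K ≈ 0.71` for +1/−3 on uniform background to about
1.5 %.  The gapped `lambda` is approximated by the ungapped one, so
E-values rank and threshold rather than estimate literal probabilities.

## Candidate filtering

An alignment survives iff it covers ≥40 % of the query (inclusive), is
longer than 20 columns (strict), and is ≥75 % identical (inclusive).
Same-query alignments on one contig and strand merge greedily
left-to-right when their genomic gap is ≤30 nt (proximity is otherwise
unquantified; 30 nt is small relative to ncRNA query lengths and keeps
typical merged spans under the cap) and the merged hull stays within
125 % of the query length;
merged score is the member sum and merged identity the match-weighted
mean.  The coverage rule is applied before merging and re-checked after.
Surviving hits are extended, centered on the hit, to the query length
(asymmetric only when clipped by contig ends), padded by 10 nt flanks, and
near-duplicate regions from different queries of one family (≥90 %
reciprocal overlap) collapse into a single candidate that accumulates its
supporting species and strategies.

## Profile HMMs

Models are built per family from the seed alignment: match columns are
those with <50 % gaps, emissions and transitions are Laplace-smoothed
counts (+1), and the null model is the seed's residue composition.
Alignment is local on both sides: uniform entry `1/M` into any match
state, a constant per-node exit probability (0.05, certain exit at the
last node) carved out of each match state's outgoing mass.  The genome is
scanned in windows of twice the model length at single-model-length
stride on both strands; a fast Viterbi pass prefilters windows with a
100-fold E-value margin and survivors are rescored with the forward
algorithm.  E-values come from a maximum-likelihood Gumbel fit to scores
of (by default 1000) mononucleotide-shuffled genome windows, scaled by
the number of scanned windows; the fit is censored below the null-score
median so the tail — the only part an E-value extrapolates — drives the
scale parameter (a plain bulk fit demonstrably overestimates the tail and
inflates E-values by orders of magnitude).  Hits at E ≤ 0.01 are merged when windows
overlap, and the reported envelope is the maximal region with
forward–backward posterior ≥0.5 of being generated by the model.

## Miniature covariance models

The consensus structure of the seed defines a guide tree: paired match
columns become MATP nodes emitting 16-way joint distributions (this is
where covariation earns its keep), unpaired columns MATL/MATR nodes,
multiloops BIF nodes.  Emissions take +1 pseudocounts; split-state usage
counts (match/left-only/right-only/delete per node) set the transition
preferences, with a fixed 0.02 insert probability per available insert
state and 0.5 insert self-loop — a deliberate simplification of fully
counted transition paths that keeps single-row seeds well-defined.  An
optional taxon filter drops rows before counting (for clade-specific model
variants); topology always comes from the structure line, and a structure
pair spanning a dropped column is an error.

Scoring is CYK, global in the model and local in the sequence: the
best-scoring subsequence parsed by the complete grammar is reported and
flanks are left to the null model.  Sequences longer than `4·clen` are
scored in 50 %-overlapping windows of that size.  Calibration scores (by
default 1000) mononucleotide shuffles of the consensus, fits a Gumbel by
maximum likelihood censored below the median (tail-weighted, as above),
and sets `E(S) = n_search·exp(−lambda_evd(S−mu))` with
`n_search = 2·genome_length/clen`.  The gathering threshold GA
defaults to the maximum null score plus 2 bits; an externally supplied GA
is never touched.  Full Infernal machinery (local ends, truncated hits,
banded filters, Inside scores) is deliberately out of scope: the package
embodies the validation protocol — GA / E<0.01 (strict) / ≥70 % model
coverage, coverage measured as matched consensus positions over `clen` —
not the Infernal implementation.

Overlap resolution merges same-family overlaps to their coordinate hull
(keeping the best score) and keeps the best hit across families (bitscore,
then smaller E-value, then lexicographic family id).  Final curation
re-extracts each locus with 300 nt flanks, re-scores, and emits it only at
E<0.01 with bitscore strictly greater than GA — the screening rule is
inclusive (bitscore ≥ GA) while curation applies the strict inequality, so
a hit scoring exactly at the threshold survives screening but not the
re-score; loci at contig edges are curated on the clipped window and
flagged.

## Contamination screen

Two rules against a contaminant reference set, both using alignment
identity (no separate similarity measure is defined): (A) any alignment
with E<1e−10, identity >75 % and length >20 nt flags the contig; (B) a
merged alignment footprint covering ≥70 % of the contig at ≥80 %
match-weighted identity flags it.  Footprints count overlapping
alignments once.  Flagged and clean contigs partition the input, and the
screen runs before any annotation stage.

## Shuffle-null performance

Per strategy and RNA class: TP are truth loci recovered by a passing
candidate at ≥50 % reciprocal overlap (reciprocal overlap is this
package's operational definition of a detected locus); FN the remainder;
FP the number of shuffled query sequences (mononucleotide Fisher–Yates by
default, exact dinucleotide-preserving Altschul–Erickson available for
structure-biased nulls) that still yield a passing candidate — shuffles
receive exactly the treatment real queries get, so an optional validator
applies covariance-model validation to null candidates as the full
pipeline would; TN the remaining shuffles.
Sensitivity `TP/(TP+FN)` and specificity `TN/(FP+TN)` propagate NaN on
empty denominators.

## Dollo parsimony

Each family is gained exactly once — at the most recent common ancestor of
its presence leaves — and lost on any number of edges; a node is present
iff it lies on a path from the gain to a presence leaf.  This minimizes
losses under the single-gain rule (checked against exhaustive enumeration
in the tests).  Hard constraints encode published ancestral knowledge and
override parsimony: a forced presence above the gain relocates the gain to
the common ancestor of everything forced or observed; a constraint
contradicting an observation is an error.  Edge summaries satisfy
`count(child) = count(parent) + gains − losses` on every edge.  The
bilaterian species topology ships as an editable Newick fixture with named
internal nodes (Bilateria, Chordata, Olfactores, Tunicata, Craniata, …).

## Synthetic benchmark

The generator emulates the statistical shape of the assembly the pipeline
targets: i.i.d. background at GC 0.36; log-normal contig lengths (median
450 nt, sigma 0.75, truncated to [200 nt, 25 kb]) so ≥80 % of contigs are
sub-kilobase; planted copies derived from the seed consensus with an exact
edit trace (substitution count solved from the sampled indel counts, so
realized identity hits the target up to rounding); pseudogenized copies
truncated to 40–70 % length with extra substitutions; contaminant contigs
copied from a synthetic bacterial-like reference at 95–100 % identity.
Default family sizes follow typical ncRNA classes (snRNA-like 100 nt,
miRNA-precursor-like 80 nt, snoRNA-like 72 nt), with 10-row seed
alignments at 8 % row divergence and compensatory stem mutations.

The benchmark problem sizes used by the test suite and the acceptance
script are a 2 Mb genome, three families with ten copies each at 85 %
planted identity (20 % pseudogenes), 1000-shuffle calibrations and
1000 shuffled nulls per family, with the shuffle-null specificity
evaluated for the default strategy and strategy 7 (the best-performing
tuned setting) as representatives of the ensemble; the divergent-copy
(65–75 % identity) comparison of the ensemble against the default runs on
smaller dedicated replicates.

What passing does and does not show: the generator's i.i.d. background has
no repeats, no dinucleotide correlation and no compositional
heterogeneity, its families are single hairpins rather than real ncRNA
structures, and its query "species" are mutational variants of one
consensus.  Recovery and specificity on this benchmark therefore validate
the decision logic and its thresholds, not sensitivity on real genomes,
where repeat-derived false positives (notably for rRNA) and deeply
diverged families are the dominant difficulties.

## Known limitations

- E-values from the ungapped-lambda approximation and short-tail Gumbel
  fits are ranking devices; absolute calibration is inherited from the
  null-model choices above.
- The CM has no local-end or truncated-hit states, so family instances
  split across contig boundaries score poorly; in highly fragmented
  assemblies this is mitigated only by the short length of most ncRNAs.
- Transition probabilities in the CM are usage-count marginals, not
  per-row path counts.
- The Dollo reconstruction reports one minimal history; ties among
  equally parsimonious loss placements do not arise under the
  path-presence rule, but alternative histories with the same cost on
  multifurcations are not enumerated.
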