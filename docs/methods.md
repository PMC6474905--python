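# Methods

This note records the models the package implements, the conventions it
fixes where the field leaves a choice open, and what its synthetic-data
checks do and do not demonstrate.

## Region partitioning

ITS amplicons are partitioned by anchoring a 5.8S reference (140–190 nt)
with a semi-global alignment (match 2, mismatch −1, gap −5/−1; unaligned
amplicon tails free). Boundaries sit at the reference's first and last
aligned columns; ITS1 and ITS2 are everything 5′ and 3′ of them. The
anchor must reach 80% identity (configurable) or partitioning fails —
better to refuse than to misassign regions. When PCR primers are
supplied, flanking 18S/26S tails beyond the primer matches are trimmed
first. Coordinates are 0-based half-open throughout; only reports print
lengths.

The packaged default anchor is a **synthetic** 163-nt sequence (the
length and GC of a conserved plant 5.8S); it exists so the pipeline is
runnable out of the box and for simulated data, which writes its own true
anchor. Real analyses should supply a curated 5.8S, or GenBank records
whose ITS feature annotations already carry the partition.

GC content is computed over unambiguous bases only (ambiguity codes drop
out of numerator and denominator); presentation rounding is half-up to
one decimal, and group means are taken on unrounded values. Half-up
(rather than banker's) rounding matches how barcoding tables are
typeset.

## Alignment

Pairwise alignment is global Needleman–Wunsch with affine (Gotoh) gap
costs; defaults match 1, mismatch −1, gap open −4, extend −1 (the open
cost covers the gap's first residue). Traceback ties resolve
diagonal → up → left, making output deterministic. The multiple aligner
is progressive: pairwise K2P distances feed an NJ guide tree whose join
order drives profile–profile dynamic programming (column scores are
mean pairwise substitution scores; gaps contribute nothing). This is a
deliberate, reproducible re-specification — replicating any particular
GUI aligner exactly is a non-goal, and variable-site counts downstream
inherit a mild dependence on the alignment heuristic.

A column is polymorphic iff it carries ≥ 2 distinct states; a gap counts
as a state (indel polymorphism), ambiguity codes never do. A
substitutions-only toggle exists. Per-region counts use the partition of
a designated reference row projected through its alignment gaps.

## K2P distances

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), with P and Q the observed
transition/transversion proportions over compared sites. Pairwise
deletion is the default (sites drop only for pairs missing them);
complete deletion is available. The two policies bracket what
distance-matrix software typically reports. Saturation (1 − 2P − Q ≤ 0 or
1 − 2Q ≤ 0) yields NaN with a warning at the matrix level rather than
aborting; NJ refuses matrices containing NaN with an instruction to
re-estimate. Distances are kept at full precision internally and rounded
(half-up, 3 decimals) only when printed.

## Trees and support

NJ is the standard Saitou–Nei agglomeration; Q-criterion ties break
toward the lowest taxon-index pair, so results are order-independent in
the presence of ties. Negative branch lengths are clamped to zero with
the deficit moved to the sibling edge, and logged.

Parsimony uses Fitch small-parsimony scoring (gaps and ambiguity codes
are missing data — they force no changes) with unique-column collapsing
for speed, and a hill-climbing NNI search from the NJ tree: strictly
improving moves accepted in a deterministic scan order, stopping at the
first local optimum. Parsimony trees report topology and support only;
branch lengths are not estimated.

Support values are nonparametric bootstrap proportions with B = 1000 by
default: columns resampled with replacement, the tree rebuilt per
replicate, each internal edge of the point tree annotated with the
percentage of replicates containing its bipartition. This replaces the
interior-branch t-test some desktop packages offer; bootstrap proportions
are the widely understood support measure and live on the same 0–100
scale. All stochastic operations take an explicit seed; there is no
wall-clock seeding anywhere.

Rooting places the root at the midpoint of the out-group's pendant edge.

## ITS2 structure features

Structures are consumed as Vienna dot-bracket or CT input (the output of
any external predictor); the built-in folder is a Nussinov
maximum-base-pairing scheme (minimum hairpin loop 3, deterministic
leftmost-first traceback) provided as a simple offline fallback — it
maximizes pair count, not free energy, and is not a substitute for
thermodynamic or homology-based prediction.

The four-helix decomposition walks the exterior (central) loop 5′→3′:
each emanating stem plus everything distal is one arm, numbered I–IV by
attachment order. Per arm: stem length is the total base pairs along the
main stack path (first child at each branch); the loop count tallies
bulges, internal loops and hairpin loops over the whole arm (multibranch
loops separate helices and are not counted). Structures with ≠ 4 arms
warn; missing arms pad as (0, 0, 0), extras are truncated.

Published structure comparisons measure helix *angles* from drawings; no
formula exists, so the package fixes one: every central-loop element
(unpaired base or helix attachment) occupies an equal arc of 360°, a
helix sits at its arc midpoint, and Helix I anchors 0°. Raw angle values
are therefore a convention; what the pipeline validates is the behavior
of their *clustering*, which is what consumes them. Loop "shape" has no
defined metric and is reduced to loop count.

Feature vectors are fixed-order 12-vectors [angles I–IV, stem lengths
I–IV, loop counts I–IV], in degrees, base pairs and counts.

## Feature clustering

Block (Manhattan) distance with between-groups linkage — the SPSS name
for average linkage (mean over all cross-pair distances), implemented
with the Lance–Williams update and a smallest-leaf-index tie-break so
output is permutation-invariant even with tied (e.g. zero) distances.
Scaling is off by default, matching direct use of measured values; a
min–max option exists because degrees otherwise dominate base-pair and
count features in the Manhattan sum. Average linkage on a metric gives
monotone merge heights; dendrograms serialize as ultrametric Newick with
a cluster merged at height h placed at age h/2.

## Synthetic data

The sequence generator evolves an ITS1–5.8S–ITS2 amplicon along a fixed
or random (Yule-shape) tree under K2P with transition/transversion rate
ratio kappa (default 2), using closed-form substitution probabilities per
branch. Defaults mirror the amplicon the analyses expect: region lengths
230/163/246 nt, GC 53%, the 5.8S at 0.1× the spacer rate. Optional
deletions (Poisson events, geometric lengths, default mean 2 nt) are
confined to the spacers, mimicking how rDNA length variation leaves the
5.8S intact; insertions are not modeled. A single explicitly seeded RNG
drives everything; runs are reproducible bit-for-bit.

The structure generator emits dot-bracket strings realizing requested
stem lengths, loop counts and angles *exactly* under the extractor's
conventions (stems split into loop-count segments by 1-nt bulges; angles
laid out on the smallest equal-arc grid realizing them, 15° multiples
always feasible). Generator and extractor are mutual inverses on the
feature subspace, which is what makes the structure pipeline testable
end to end.

What passing synthetic tests show: the estimators and algorithms are
correct under their own model (K2P sites are i.i.d. within regions, no
rate heterogeneity beyond the three region classes, no recombination or
concerted-evolution effects, structures are clean four-helix hands).
What they do not show: robustness to alignment error on hard real data,
model misspecification, or degraded/chimeric sequences.

## Problem sizes and checks

The verification suite works at desk scale, chosen to keep the whole run
in minutes: exhaustive oracles for alignment (sequences ≤ 6 nt, every
alignment enumerated), parsimony (5 taxa, all 15 unrooted topologies,
plus a brute-force internal-state enumeration for Fitch itself), and
folding (≤ 12 nt, all nested pairings); stochastic checks use 200
replicates × 5 kb for distance recovery at d ∈ {0.01, 0.05, 0.1, 0.2}
(mean within 5% of truth) and 100 seeded 6-taxon simulations for NJ
topology recovery (interior branches 0.02, pendant 0.05 — divergence
comparable to the within-section distances the printed matrix shows).
The accession-based reproduction check needs a one-time GenBank fetch
(`scripts/fetch_genbank.py`) and is the only check that cannot run from a
fresh offline checkout.

## Known limitations

* The progressive aligner has no iterative refinement; deep or
  indel-rich datasets deserve a dedicated MSA tool, whose output the rest
  of the pipeline accepts as aligned FASTA.
* Only K2P is implemented; no other substitution models or model
  selection.
* MP search is NNI-only hill climbing; it can stop in local optima on
  large trees (exhaustively verified correct at 5 taxa).
* The fallback folder ignores thermodynamics entirely.
* Angles depend on the stated equal-arc convention; absolute values are
  not comparable to hand-measured drawings, though relative geometry and
  downstream clustering are.
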