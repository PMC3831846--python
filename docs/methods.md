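# Methods

`alutrack` reimplements, as a tested pipeline, the comparative-genomics
workflow used to characterize very young Alu (SINE) subfamilies: finding
diagnostic mutations shared across copies, naming the nested subfamilies
they define, scanning genomes with short signatory sequences, tracing
source/master copies on rooted trees, dating subfamilies by non-CpG
mutation density, and classifying insertion polymorphism. Because the
real substrate (a reference genome plus population-scale variant calls)
is far beyond desk scale, the package ships a retrotransposition
simulator with full ground truth; every statistical claim the test-suite
makes is a property checked against that truth or against an independent
oracle.

## The column frame

All analyses run on consensus-anchored elements: each copy is globally
aligned (affine gaps; match +1, mismatch −1, gap open −5, gap extend −1 —
standard DNA defaults) to its subfamily consensus, and its bases are
indexed by 1-based consensus position, with insertions keyed to the
preceding consensus position. This replaces both BLAST (the reporting
threshold `min_report_score`, default 25, stands in for an e-value
cutoff) and a progressive multiple alignment; it is exact for the
homologous-column questions asked here and deterministic. Insertions are
canonicalized to their rightmost equivalent placement, so an inserted T
following a consensus T is reported after the consensus position (the
"200+T" convention). Ties in the alignment DP are broken diagonal > up >
left.

Poly-A handling: the 3' tail is removed by scanning 10-nt windows from
the 3' end while ≥80% A (then consuming the remaining A-run); the longest
internal A-rich window run (≥8 nt at ≥80% A) is excised as the middle
linker. Elements are "full-length" when coverage starts by consensus
position 5, ends within 5 positions of the consensus end, and contains at
most 30 deleted columns (configurable); the threshold operationalizes
"full-length or near full-length".

## Consensus models and diagnostics

A consensus model carries a sequence (no poly-A tail), its accumulated
diagnostic sites, a derived CpG mask (both positions of every CG
dinucleotide), and A-rich linker coordinates. Diagnostic edits
(substitution, insertion, tandem duplication) are applied in descending
position order; inherited site and linker coordinates are re-expressed on
the derived frame. Registry YAML files define subfamily chains; edit
positions are interpreted on the parent's frame, which is the convention
that keeps the canonical Yb coordinates (246–252 duplication defining
Yb8; 174 C→G for Yb9; 259 G→A on the Yb8 frame for Yb8a1; 200+T for
Yb11) literal. The bundled sequences are synthetic stand-ins (a 311-nt
Alu-like consensus and a 120-nt toy), generated once under the constraint
that those coordinates carry the correct reference states; the real AluY
consensus can be supplied by the user in the same YAML schema.

The published Yb9 site is quoted both as position 174 and 274 depending
on numbering convention; the registry defaults to 174 and the position is
plain config.

## Simulator

The simulator implements a master-gene / stealth-driver amplification
model in continuous time (million years, My):

- Active copies spawn daughters by a Poisson process (Gillespie
  exponential waiting times over the summed per-copy rates). A daughter
  inherits its parent's sequence *at the birth time* and becomes a
  stealth driver with probability `stealth_activation_prob`.
- All copies accumulate substitutions at `non_cpg_rate`
  (default 0.0015/site/My = 0.15%/My, the neutral rate for primate
  intergenic DNA). Positions in the founder's CpG mask, while their C/G
  context is intact, mutate at `cpg_multiplier` (default 6) times the
  neutral rate, with the excess flowing through the C→T/G→A deamination
  channel; non-elevated substitutions are uniform over the alternatives.
  At most one substitution per site is drawn per inter-event interval
  (second-hit probability ~(rate·Δt)², negligible here).
- Scheduled subfamily events inject a diagnostic edit into a designated
  copy (`latest:<subfamily>` resolves to the most recently born member at
  event time) and may set its transposition rate — a copy that "mutated
  and then actively transposed".
- Genome planting writes each copy (optionally 5'-truncated, geometric
  length; with a poly-A tail, Poisson length around 12) onto a random
  background chromosome at uniform non-overlapping positions and random
  strand. Copies overwrite the background rather than shifting
  coordinates, so the emitted annotations locate them exactly.

Everything is driven by one seed; identical parameters give
byte-identical outputs.

What the simulator deliberately omits: target-site duplications,
endonuclease site preference, gene conversion, recombination, and source
interruption. Consequently, passing recovery tests demonstrate the
statistical machinery is correct under neutral divergence with known
genealogy — not that the pipeline is robust to gene conversion or
annotation error in real genomes.

An important property of master-gene genealogies, verified empirically
and load-bearing for test design: every copy's lineage back to the
founder spans the whole timeline regardless of its birth time, so
divergence from the founder consensus estimates the *founding* age; but
mutations on the shared master trunk are inherited by whole cohorts, so
the sampling variance of a single-master cohort's mean density is far
larger than binomial. Age-recovery checks therefore use cohorts of
independent founder copies (`n_founders`), where the binomial standard
error is exact.

## Subfamily discovery

Candidate diagnostic sites are consensus positions (or insertion keys)
where one non-consensus state is shared by at least `min_carriers`
(default 2) elements, skipping A-rich linker columns; CpG positions are
flagged but kept. Elements are partitioned by their combination of
candidate-site states; combinations are organized by diagnostic-set
inclusion. Naming: a set extending the deepest trunk subfamily by one
diagnostic increments the trunk numeral (Yb9 → Yb10 → Yb11); any other
set is parent + lineage letter + number of extra diagnostics (Yb8 → Yb8a1;
sibling lineages take successive letters). "Nesting violations" —
elements carrying a site without its prerequisites (sites co-carried by
≥90% of that site's carriers) — are reported, not fatal; they are the
fingerprint of reverse mutation or gene conversion.

Signatory sequences are conserved windows around a call's newest
diagnostic: 30 nt for substitutions, 24 nt for insertions, centered and
clamped at consensus ends, shrunk away from A-rich columns and from
columns under 99% conserved in the profile (error below 12 nt). Genome
scans slide the signature over both strands allowing `max_mismatch`
(default 1) mismatches *except* at the diagnostic offset, which must
match exactly; overlapping hits are deduplicated. A consistency property
holds by construction and is tested: hits of a nested subfamily's
signature fall inside elements that also carry the parent signature.

## Trees, sources, clock test

Distances between anchored elements (p, JC69 or K2P over shared gap-free
columns; ≥50 shared positions required) feed canonical neighbour joining
with deterministic smallest-label tie-breaking; negative branch lengths
are clamped to zero. Trees are rooted on the midpoint of the subfamily
consensus' pendant edge. Fitch ancestral states (ties resolved
A<C<G<T<'-', preferring the parent's state) give the reconstruction of
the root-adjacent ingroup node; the source copy of a cluster is the leaf
closest to that reconstruction (ties → smaller label, flagged low
confidence), with driver classes master (≥100 offspring) and stealth
(≥10) following the narrative thresholds.

Limitation, measured on simulations: under neutral divergence the master
and its late-born offspring are equidistant from the root reconstruction
in expectation, so source attribution is reliable only while post-birth
divergence is low (young bursts). In the acceptance regime (0.2 My burst,
~120 offspring) the true master ranks first in ≳90% of replicates;
failures occur exactly when the master carries a private mutation while
some daughter is still clean. The same degeneracy makes exact best-hit
score ties pervasive on young cohorts: the omission rule (elements whose
top two scores tie exactly cannot be attributed and are dropped) can then
omit everything, and the pipeline's tracking stage falls back to one
cluster per called subfamily. Cross-family best-hit attribution (which
parent-subfamily copy founded a child subfamily) carries signal only when
offspring are few and well spread, because a child's later-born siblings
tie the founding copy in expectation; the test-suite exercises it in that
regime.

The molecular-clock test computes JC69 likelihoods by Felsenstein pruning
on site patterns (gapped columns excluded). The free model optimizes all
branch lengths (L-BFGS-B, bounds [1e-8, 5]); the clock model
parameterizes node heights as a root height and per-node proportions,
tips at height zero. The free model is re-polished from the clock
optimum so lnL_free ≥ lnL_clock holds structurally. The statistic
2(lnL_free − lnL_clock) is referred to chi-square with n − 2 degrees of
freedom (13 free identifiable lengths vs 7 heights for n = 8). Calibration
uses coalescent-shaped clock trees of height 0.06 substitutions/site and
300 sites — deep enough for the asymptotics, shallow enough for the Alu
regime; measured type-I error at alpha = 0.05 is ~0.05 over 1,000
replicates, and a 10× accelerated pendant branch is rejected in well over
half of replicates. JC69 is the minimal defensible model since the
original clock analyses do not name one.

## Age estimation

For a subfamily's (by default full-length) members, over covered,
non-gap, non-CpG, non-A-rich columns excluding the subfamily's own
diagnostic positions (definitional, not post-founding): density =
mismatches / bases; age = density / neutral rate (0.0015/site/My). Both
the unrounded age and the age implied by the density rounded to two
decimals of a percent are reported, because published figures mix the two
conventions (0.32% → 2.15 My uses the unrounded density; 0.29% → 1.93 My
and 0.26% → 1.73 My the rounded one; 0.107% → 0.71 My the printed
three-significant-figure density). `verify-paper` recomputes all four
from the published counts — 166/51,562; 43/14,625; 5/1,904; 4/3,720 —
and checks each against its reported value. CpG status is taken from the
subfamily consensus (the ancestral CpG context), not from each element;
indel columns are not counted unless `count_indels` is set.

## Polymorphism

An insertion is polymorphic when both breakpoints fall within
`tolerance_bp` (default 100, typical SV-callset breakpoint imprecision)
of a variant interval's breakpoints on the same chromosome — breakpoint
proximity, not reciprocal overlap, and monotone in the tolerance.
Population tallies treat unascertained cells conservatively: an insertion
is population-specific only if present in exactly one population and
ascertainably absent in every other.

## Problem sizes

The default test-suite and the acceptance script use: 200 additive
matrices (≤12 taxa) for NJ; 500 string pairs (≤6 nt) against exhaustive
alignment enumeration; 100 six-leaf trees against brute-force parsimony;
1,000 clock replicates (8 leaves × 300 sites); 20 cohorts of 50
independent 318-nt copies per true age in {0.5, 1, 2, 4} My; one planted
two-level subfamily history (~140 copies) for discovery; and 20
master-burst replicates (~120 offspring) for source attribution. These
sizes give the oracles exact coverage and the stochastic checks standard
errors well inside their acceptance bands.
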