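# Methods

This note records the models implemented in `septevo`, the conventions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the design decisions taken where more than one reasonable
choice existed.

## Septin identification

A candidate passes if its annotated domains intersect
{`P-Loop_NTPase`, `CDC3`, `CDC_septin`} (the *domain route*), or else if its
sequence carries at least two distinct G boxes and no conflicting domain
(`LysM`, `DNA_binding`). The domain route takes precedence and ignores
motif evidence entirely, which is what lets divergent septins (the budding
yeast Cdc3 situation: recognized domain, unrecognizable boxes) through.

G-box patterns default to the canonical Ras-superfamily motifs — G1/Walker A
`[AG]x{4}GK[ST]`, G3 `Dx{2}G`, G4 `[NT]KxD` — and are overridable per run.
Because G3 is short and common, hits must form an ordered chain
(G1 < G3 < G4 by start position) within a configurable span (default 400
residues, the scale of one GTPase domain). Among all consistent chains the
scanner keeps the one with the most boxes, breaking ties toward the
earliest positions; this is a bounded exhaustive search over the first 16
matches per box. Both the ordering and the span constraint are assumptions;
they are exposed as parameters rather than baked in.

## Group assignment

For each Group, the assigner walks upward from each anchor leaf to the
largest clade containing no anchor of any other Group and labels every leaf
in it. Nested or overlapping claims are impossible under this rule (a
foreign anchor inside a candidate clade blocks it), and the implementation
raises on any violation rather than resolving it silently. Leaves outside
every anchored clade are `UNCLASSIFIED`.

## Reconciliation

Conventions: species branches are identified by their child node's label;
the root has a stem branch; depth is counted in edges from the species root.
The gene tree is mapped by the standard LCA map. An internal gene node is a
duplication iff its image equals the image of at least one child. Losses on
a gene edge (p → c) are `depth(M(c)) − depth(M(p)) − 1` if p is a
speciation and `depth(M(c)) − depth(M(p))` if p is a duplication; each loss
is attributed to the off-path sibling branch of a species node the edge
passes through silently.

Rearrangement: edges whose child support falls below the threshold
(default 0.90; Newick supports > 1 are read as percentages) are contracted,
and every polytomy is resolved by exhaustive enumeration of rooted binary
topologies over its children. Resolutions decompose independently per
polytomy because a polytomy root keeps its LCA image under any resolution,
so the cost contribution of each polytomy is local. Polytomies above 7
children (10 395 resolutions) raise an explicit error rather than fall back
to a heuristic: at desk scale, correctness is preferred to coverage.
All co-optimal reconciliations are returned (default cap 32, deterministic
lexicographic order), and the per-branch copy-number profile is their
arithmetic mean; duplication and loss costs are both 1 by default and
configurable.

Copy counting: a gene edge covers the species branches its reconciled
existence interval spans — from (exclusive) the parent's image when the
parent is a speciation, or from (inclusive) the parent's image when it is a
duplication, down to the child's image, excluding the child's branch when
the child is itself a duplication (its out-edges cover that branch
instead). The gene root contributes a lineage from the species-root stem
down to its image. On a congruent single-copy family this yields exactly 1
on every branch.

## Ancestral states (Mk)

Presence/absence of each Group evolves under
`Q = [[−q01, q01], [q10, −q10]]` with the closed-form 2×2 transition
matrix. Likelihoods use Felsenstein pruning with per-node rescaling;
missing states (`?`) contribute (1, 1). The root prior is uniform
(0.5, 0.5) by default — the convention of the Mesquite-style analyses this
mirrors — with a stationary-prior option. Characters are fitted
independently (one per Group) or pooled.

Fitting maximizes the log-likelihood over log-rates within [1e−8, 1e3]
(bounded scalar search plus L-BFGS-B from 5 log-spaced starts; MK2 is
additionally seeded from the best equal-rates point, which guarantees the
nesting lnL(MK2) ≥ lnL(MK1) that the Wilks test requires). "Proportional
likelihood" is the normalized marginal posterior at each node from an
up-down pass, not a joint reconstruction; a node is "resolved" when one
state exceeds 0.95. The MK1-vs-MK2 test statistic 2ΔlnL is referred to
χ² with df = 1; the null value q01 = q10 is interior to the MK2 parameter
space, so no boundary correction applies.

Calibration and recovery checks run at study designs chosen for
identifiability: rate recovery uses 1000 characters at (q01, q10) =
(0.3, 0.6) on a 22-taxon tree of depth 3 (a few expected changes per
character — rates are poorly identified on much shallower trees), and the
Wilks calibration uses 500 replicates of 100 characters at q = 0.8 on a
16-taxon tree of depth 2, a regime where the asymptotic χ² reference is
accurate.

## Conservation

Column score = (1 − gap fraction) · JSD(column distribution, background),
with JSD in log base 2 and λ = 0.5, bounded by 1. The background defaults
to the amino-acid frequencies underlying BLOSUM62 (uniform available); the
pseudocount is 1e−7. "Window size of one" in the scorer this mirrors is
interpreted as *no flank smoothing*; a Capra–Singh ±w window (centre weight
0.5, flanks sharing 0.5) is implemented and off by default. All-gap columns
score 0. Ambiguous residues (X) are treated as gaps. Reference mapping is
the bijection between columns where the reference is ungapped and residue
numbers 1..L; positions are compared to named motif/region intervals
(inclusive ends) supplied by the user — the package ships no hard-coded
region coordinates.

## Interface contacts

Contact rule: atoms i, j on opposite chains are in contact iff
`d(i, j) ≤ r_i + r_j + probe` with probe = 0.5 Å, boundary inclusive —
a deterministic, oracle-checkable surrogate for dot-surface probe contact
detection. Backbone–backbone pairs (atom names N, CA, C, O) closer than
`r_i + r_j` are discarded as modelling clashes. Van der Waals radii come
from a fixed element table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.10,
P 1.80 Å), overridable. Hydrogens are used if present in the input but
never added, so results on real structures approximate hydrogenated
contacts — a documented limitation.

Atom pairs collapse to residue pairs (keeping the minimal gap), residues to
per-structure interface sets. Across taxa, each taxon's residue numbers are
mapped to reference coordinates through its alignment row (unmappable
residues are dropped); for each (reference position, interface type) the
interacting-taxon count is taken per crystal template and the maximum over
templates of that interface compared to the threshold — consensus iff
≥ 10 of 17 taxa by default. Consecutive consensus positions at most 3 apart
(configurable) merge into one "interacting group" interval; the delimitation
rule is an explicit assumption.

Logo matrices report per-Group residue frequencies at chosen reference
positions plus an information content of `max_bits − H` (Shannon entropy in
bits). `max_bits` defaults to 2.0 to match the package's test contract;
set 4.32 (= log₂ 20) for the conventional amino-acid logo scale.

PDB I/O is deliberately minimal: fixed-column ATOM/HETATM records, first
model only, altloc blank or 'A'; chains must number exactly two.

## Synthetic data

All generators draw from a single `numpy` Generator seeded per call;
identical configuration and seed give byte-identical outputs.

* **Species tree** — pure-birth (Yule) with the root age rescaled to
  1350 Myr, the constrained age of the opisthokont ancestor. Ultrametric by
  construction.
* **Gene families** — a linear birth–death process (defaults
  dup = loss = 5 × 10⁻⁴ events/lineage/Myr, giving a handful of events per
  family on the default tree) runs along each species branch; lineages
  bifurcate at speciations; one-sided extinctions are suppressed so the
  emitted tree contains only realized speciation and duplication nodes, each
  recorded in the truth with its species branch, as is every loss.
* **Characters** — exact simulation of the 2-state chain from its
  stationary root distribution; true states recorded at every node. The
  pipeline demo instead derives presence/absence from the simulated gene
  families so that reconciliation and ancestral states describe one history.
* **Proteome** — planted septins (three boxes + domain), borderline
  septins (two boxes, no domain), decoys (≤ 1 box) and conflicting-domain
  decoys, 15/5/70/10 by default. Backgrounds are drawn from an 18-letter
  alphabet without D and K, which makes every G-box pattern impossible
  outside planted motifs — so perfect precision/recall on this fixture is a
  property of the filter logic, not a sampling accident. The cost of that
  guarantee is unrealistic residue composition; conservation scores on
  these sequences are structurally sensible but not naturalistic.
* **Dimer structures** — one carbon pseudo-atom per residue on two parallel
  chains 10 Å apart (5 Å residue spacing, ±0.05 Å seeded jitter); planted
  positions for the template's interface type sit at 3.8 Å across chains,
  every non-planted inter-chain pair ≥ ~6 Å, comfortably outside the 3.9 Å
  contact radius. A dropout table removes chosen planted contacts from a
  chosen number of taxa to exercise the consensus threshold.

What passing on these fixtures shows: the decision rules, event counting,
likelihood machinery and consensus logic are correct on inputs whose truth
is known. What it does not show: robustness to alignment error, indels,
compositional bias, non-ultrametric trees, incomplete proteomes or homology
-modelling error, none of which the generators emulate.

## Reproducibility

`report.json` and every data output are byte-stable for a fixed
configuration and seed. Wall-clock timings appear only in `report.txt` and
the log, which are excluded from the byte-identity contract. Problem sizes
in the test suite (22-taxon trees, 100-protein proteomes, 85 structures,
500-replicate calibrations, exhaustive checks to 6–8 leaves) were chosen as
the smallest designs that still exercise each property convincingly.
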