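# Methods

## The procedure

`phageneck` annotates and classifies the structural (head–neck–tail)
module of tailed bacteriophages in four stages.

**1. Strict homology expansion.** Homology evidence enters exclusively
as profile–profile comparison results: per (query, target) pair a
homology probability and a percent identity, both on the 0–100 scale.
Each of the protein classes — head: MCP, TermL; neck: Portal, the
Type-specific Ad/Hc/Tc connection families, Ne1, gpW; tail: MTP, Sheath
— is expanded from its reference seeds by breadth-first transitive
closure over hits with probability ≥ the strict threshold (default
90%); every accepted protein is re-probed until a fixed point. Because
membership is the closure of the thresholded hit graph, the result does
not depend on probe order; the accepting probability recorded for a
protein is the maximum over in-edges from the final member set, which is
likewise order-free. Head and tail classes stop here: only the
connection classes get a relaxed pass. Cross-class claims are resolved
after expansion (highest accepting probability wins; exact ties go to
the lexicographically first class label, with a diagnostic), and within
a phage each class keeps a single protein — a second candidate in a
connection class is a violation of the single-copy control and is
reported, not silently merged.

**2. Distance-model learning.** For each neck Type and ordered class
pair, the signed inter-gene distance — rank(b) − rank(a) in gene-count
units, adjacent downstream = +1 — is collected over all genomes carrying
both strict detections. The model stores the mean, the sample standard
deviation (ddof = 1; a single observation gives SD 0), and the tolerated
distance mean + 2·SD, kept real-valued: the canonical integer tolerances
arise from the data, not from a rounding rule. Genomes are treated as
linear gene lists (no circular wrap-around) and distances are in gene
ranks, not base pairs; strand is not modelled.

**3. Context-constrained relaxed search.** The expansion is repeated at
the relaxed threshold (default 70%). A new candidate is accepted only
if, for *every* already-detected partner class in the same phage, the
signed distance has the canonical direction and magnitude at most the
tolerated distance (conjunction over partners). A phage with no strict
anchor cannot validate candidates; they are rejected and logged. Two
positional special cases complete Type 1: (a) in phages with Hc1 and
Tc1 but no Ad1, a gpW-family hit at ≥ 95% probability is accepted as the
adaptor replacement when it lies 6–7 genes upstream of Hc1 and 9 ± 1
upstream of Tc1 (the phage stays Type 1); (b) an Ne1 homolog is accepted
at strict probability anywhere, or at relaxed probability when its gene
lies strictly between Hc1 and Tc1. Finally, in phages missing exactly
one class of their Type, undetected proteins whose profiles were built
from fewer than 5 source sequences and whose rank fits the tolerated
matrix are flagged for human review — never auto-accepted.

**4. Typing, scoring, clustering.** The Type with the most detected
Type-specific classes wins (gpW fills the Ad1 slot for evidence
counting), subject to the minimum-evidence rule: ≥ 2 connection proteins
for Types 1–2, ≥ 1 for Types 3–4. An Ad1 alone gives the recognizable
but unclusterable `type1_like`; a tie between Types yields `unassigned`
with a diagnostic. Morphology follows from Type and sheath presence;
a sheath in a Type 3/4 phage is reported as a contradiction while the
morphology stays Podoviridae. Pairwise module similarity is
Score = Proba + 0.1·Identity per shared component, averaged over the
classes detected in both phages; components in one phage only are
ignored, and a pair with no shared component is *missing* (distinct from
zero). The per-Type N×N matrix (diagonal at the maximal 110) is
clustered by WPGMA on Euclidean distances between matrix rows; merge
heights are cluster distance / 2, which makes the tree ultrametric.
Queries are placed in the reference cluster with the highest mean
pairwise similarity, ties going to the lowest cluster index with a
warning.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| strict threshold | 90 | % probability | expansion acceptance; high enough that no positional gate is needed |
| relaxed threshold | 70 | % probability | context-gated pass; alone it admits spurious homologs, hence the distance gate |
| gpW threshold | 95 | % probability | the adaptor-replacement call rides on a fixed positional window, so it demands near-certain homology |
| tolerated distance | mean + 2·SD | gene ranks | positional gate; ±2σ keeps essentially all true arrangements while excluding remote placements |
| low-support cutoff | < 5 | sequences | profiles from fewer source sequences cannot support profile–profile detection |
| identity weight | 0.1 | — | identity (≤ 100) contributes ≤ 10 points, discriminating only where probability saturates |
| minimum evidence | 2 / 1 | proteins | Types 1–2 / Types 3–4 classification floor |

The signed-direction check in the distance gate and the symmetrization
of the hit relation (P(a,b) := max of the two directions, identity from
the winning direction) are both on by default and switchable in
`RunConfig` — whether the original procedure enforced either is not
derivable from its description, so both readings are available; the
defaults are the stricter ones. Ne1 counts toward the completeness
display but not toward the ≥ 2 minimum, a deliberately conservative
reading of the classification rule, which predates Ne1's inclusion in
the module description.

## The synthetic universe

The generator (`phageneck.synthetic`) emits what the method needs to be
tested against ground truth without any external database: ordered
genomes whose neck blocks follow the canonical templates (Type 1
Ad1-Hc1-Ne1-Tc1, optionally with extra gap genes between Ne1 and Tc1
drawn from a configurable distribution; Type 2 consecutive Ad2-Hc2-Tc2;
Type 3 Ad3-x-Hc3; Type 4 Ad4) embedded among 15–30 decoy genes, plus an
all-vs-all hit table, per-profile metadata and the planted truth.

Default conditions, chosen once as the regime the method targets:

* within-family probabilities above the strict threshold — U(97,100)
  within a planted cluster, U(90,95) across clusters of a Type,
  U(92,100) for seed links — so strict detection succeeds while cluster
  structure stays visible in the scores;
* 15% of Ad/Hc/Tc members demoted to U(70,89) hits: detectable only
  through the context-constrained pass (a phage whose every neck gene is
  demoted has no strict anchor and legitimately stays undetected);
* threshold-straddling decoy hits (U(70,89)) planted on genes more than
  6 ranks away from the neck block, to exercise the positional gate;
* identities decaying with planted-cluster distance: U(25,60) within a
  cluster, U(10,25) across, U(1,15) for noise — the 10–25% band mirrors
  the identity range typical of remote homologs, which is exactly why
  the score needs the probability term;
* sub-threshold cross-family noise hits (U(5,50)), and 5% of profiles
  marked low-support (< 5 sequences);
* a corpus of 16/4/6/2 phages of Types 1–4 (Type 1 dominant, as in real
  collections) with 4/1/2/1 planted clusters; sizes are scaled to desk
  runtimes and are arguments everywhere they matter.

Sequences are random amino-acid strings of class-typical lengths (Ne1
56–231 residues, reflecting its documented size versatility); they are
cosmetic, since homology flows through the hit table. One
`numpy.random.default_rng(seed)` drives every draw, making output
byte-reproducible per seed.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: sequence evolution (no substitution model; the
hit table is drawn, not computed from alignments), asymmetric search
probabilities, profile-quality artefacts beyond the low-support count,
genome rearrangements beyond the gap knob, non-canonical neck layouts
(real collections contain documented exceptions that this package only
flags), and the scale and heterogeneity of a real profile database.
Perfect planted-cluster recovery in tests reflects the block separation
configured above, not a guarantee on real corpora.

The six worked-example fixtures reproduce the documented compositions of
SPP1, λ, HK97, T4, P22 and Φ29 at canonical gene spacing (λ: gpW six
genes upstream of Hc1, nine upstream of Tc1, no Ad1). Reference proteins
that are themselves seeds appear under their seed ids and carry a hit to
their own family profile, as they would in a real reference collection.

## Numerical and degenerate-input choices

* Probabilities and identities stay on the 0–100 percent scale
  throughout; duplicate (query, target) records keep the maximum
  probability.
* A hit without an identity figure scores identity 0 but carries a flag
  surfaced in reports.
* Tolerated distances are never rounded; boundary acceptance is
  inclusive (|d| ≤ tolerated), and the low-support cutoff is strict
  (< 5; exactly 5 is not flagged).
* WPGMA uses scipy's `weighted` linkage on `pdist` of matrix rows
  (diagonal included by default; both the diagonal-free and the direct
  110 − score distance are available as modes). Leaves are sorted
  lexicographically before linkage so ties break deterministically.
* De novo cluster counts come from the largest gap between successive
  merge distances (midpoint threshold; a gap-free profile is one
  cluster); rebuilding a known classification can instead request an
  exact cluster count per Type.
* Phages with missing similarity cells are pruned (sparsest first) and
  reported before clustering, which requires a complete matrix.
* Degenerate inputs error early: empty proteomes, duplicate protein
  ids, non-consecutive ranks, out-of-range percentages, fewer than two
  phages to cluster. A ≥ 95% ACGTN sequence triggers a nucleotide-input
  warning, not an error.

## Limitations

* Gene-rank distances ignore intergenic base pairs and strand; the
  positional model is as coarse as gene order.
* The Type precedence rule under genuinely mixed-Type evidence is a
  majority heuristic, labelled as such in diagnostics; mixed evidence is
  not expected in clean data.
* Exceptional arrangements (e.g. adaptors beyond the tolerated range
  with family support) are flagged for review, never auto-accepted, so
  recall on such phages depends on a human in the loop.
* Cluster placement requires the query to share at least one scored
  component with the reference; a query with a private component set is
  reported unplaced rather than forced into a cluster.
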