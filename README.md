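# phageneck

Detection and classification of the **head–neck–tail module** of tailed
bacteriophages (*Caudovirales*) from ordered proteomes and
profile–profile remote-homology evidence.

More than 96% of isolated phages are tailed: an icosahedral head packed
with dsDNA, a tail that delivers it, and — between them — the *neck*:
the portal channel plus the head-to-tail connection proteins (adaptor
**Ad**, head-closure **Hc**, tail-completion **Tc**, and the small neck
protein **Ne1**). These connection proteins are among the most divergent
in phage genomes (pairwise identities often 10–20%), so single-marker
classifications routinely lose them. `phageneck` finds them anyway by
combining two signals:

1. **Iterative remote-homology expansion.** Starting from functionally
   characterized reference proteins (SPP1 gp15/gp16/gp16.1/gp17, λ gpW,
   HK97 gp6, T4 gp13/gp14/gp15, P22 gp4/gp10, Φ29 gp11, plus
   structure-based head/tail seeds), each protein class is grown by
   breadth-first transitive closure over profile–profile hits with
   probability ≥ 90%, every newly accepted protein becoming a new probe.
2. **Gene-context constraints.** The strictly detected neck genes sit at
   strongly conserved relative positions. Per neck Type and ordered
   class pair (i,j), the signed inter-gene distance d(i,j) = rank(j) −
   rank(i) is learned as mean μ and standard deviation σ, giving a
   *tolerated distance* μ + 2σ. The search is then repeated at a relaxed
   70% threshold, and a candidate is accepted only if its position is
   consistent (canonical direction, |d| within tolerance) with **every**
   already-detected partner. Special rules handle λ-like necks (a gpW
   adaptor replacement at ≥ 95% probability, 6–7 genes upstream of Hc1
   and 9 ± 1 upstream of Tc1) and the Ne1 superfamily (strict
   probability anywhere, or relaxed probability strictly between Hc1 and
   Tc1). Low-support profiles (< 5 source sequences) are only ever
   *flagged* for review, never auto-accepted.

The detected composition assigns each phage one of four **neck Types**
— Type 1 (SPP1-like: Ad1-Hc1-Ne1-Tc1), Type 2 (T4-like: Ad2-Hc2-Tc2),
Type 3 (P22-like: Ad3-x-Hc3), Type 4 (Φ29-like: Ad4) — requiring at
least two connection proteins for Types 1–2 and one for Types 3–4. Type
plus sheath presence yields the morphology: Type 1 is *Siphoviridae*
(no sheath) or *Myoviridae* (sheath), Type 2 *Myoviridae*, Types 3–4
*Podoviridae*.

Within a Type, phages are clustered by the divergence of their whole
module. Each shared component pair scores

    Score = Proba + 0.1 · Identity        (0 … 110)

where `Proba` is the profile–profile homology probability (%) and
`Identity` the percent sequence identity — the 0.1 weight lets identity
discriminate only once the probability saturates at 100%. Scores are
averaged over the components detected in *both* phages (components seen
in one only are ignored), the N×N matrix of averaged scores is clustered
by **WPGMA** on Euclidean distances between matrix rows, and cutting the
dendrogram yields the Clusters. A query phage is placed in the reference
cluster with the highest mean similarity to its members.

## Inputs

* an **ordered proteome** per phage: a multi-FASTA of amino-acid
  sequences whose record order equals gene order on the genome (record
  *i* gets rank *i*) — the order is used by the analysis and must be
  preserved;
* a **homology source**: a TSV hit table
  (`query_id  target_id  probability  identity`, percent scales) or
  parsed profile–profile search reports (HHR dialect) via
  `phageneck.parse_search_report`;
* optionally a **reference bundle** (detections, distance models, trees,
  cluster labels) built with `build-reference`, for query placement.

Profile construction itself (PSI-BLAST against nr, secondary-structure
prediction) is upstream of this package; its outputs are consumed
through the hit-table contract.

## Worked example

The six reference phages ship as generated fixtures:

```
$ python -c "from phageneck.synthetic import generate_worked_examples; \
             generate_worked_examples().write('worked')"
$ phageneck build-reference --corpus worked/genomes --hits worked/hits.tsv \
      --metadata worked/profile_metadata.yaml --out ref
classified 6/6 phages; bundle in ref

$ phageneck classify --fasta worked/genomes/SPP1.fasta \
      --hits worked/hits.tsv --reference ref --out report
phage: SPP1
neck type: 1
morphology: Siphoviridae
completeness: 1.00
cluster: 1
```

`neck type: 1` means SPP1 carries the full SPP1-like connection
(Ad1-Hc1-Ne1-Tc1); `completeness: 1.00` says all four canonical Type 1
components were found; with no sheath detected the morphology is
*Siphoviridae*. The report directory holds the per-gene map with the
accepting probabilities:

```
$ cat report/gene_map.tsv
rank    protein_id   class   probability
1       SPP1_gp2     TermL   100.0
2       SPP1_gp6     Portal  100.0
3       SPP1_gp13    MCP     95.0
4       SPP1_gp15    Ad1     100.0
5       SPP1_gp16    Hc1     100.0
6       SPP1_gp16.1  Ne1     100.0
7       SPP1_gp17    Tc1     100.0
8       SPP1_gp17.1  MTP     95.0
```

plus `assignment.json` (Type, morphology, evidence, cluster placement
with per-cluster mean similarities, diagnostics), inter-gene distance
warnings, the nearest-reference-protein table and the reference tree in
Newick. A λ-like genome (gpW + Hc1 + Tc1, no Ad1) classifies as Type 1
through the gpW rule; a genome with no detectable connection protein
exits with status 3 ("no head-to-tail connection detected"), the
expected outcome for non-tailed phages.

Synthetic ground-truthed universes for benchmarking come from
`phageneck simulate --seed N` or `phageneck.generate_universe`
(Type-structured genomes among decoys, noisy hits, planted clusters; see
`docs/methods.md`).

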