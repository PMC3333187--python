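# Methods

## Model and assumptions

`tetrabin` rests on the standard premise of compositional phylogenetics:
oligonucleotide usage is a genome-wide signature, and the compositional
distance between two sequences grows, on average, with the divergence time
of their source organisms. Two consequences shape the design:

- **Fragments, not genomes.** Composition varies *within* a genome
  (horizontally acquired islands, repetitive protein families), so each
  1,000 bp reference fragment carries its own vector and a read is matched
  against fragments. Comparisons are also fairer between roughly
  equal-length sequences than between an 800 bp read and a whole-genome
  average.
- **Distance caps specificity.** A large distance to the *closest*
  reference fragment is evidence that the read's organism diverged high in
  the tree (or is unrepresented); assigning it at genus would be
  overreach. The threshold table converts d_min into the most specific
  admissible rank (TL) per read-length class, because short reads have
  noisier vectors and need laxer cutoffs.

The Manhattan metric on the 4-mer simplex is bounded by 2, symmetric, and
cheap; all thresholds are expressed in it.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `fragment_length` | 1000 bp | reference window size |
| `min_fragment_length` | 500 bp | trailing windows shorter than this are discarded — their vectors are too noisy to be useful |
| `k` | ⌊√N⌋, capped at 2048 | k-means cluster count; √N balances the centroid scan against the in-cluster scan |
| `strand` | `forward` | 4-mer counting mode; `symmetric` adds each window's reverse complement. Indexes record the mode and refuse mismatched queries, since the two vector spaces are incomparable. The printed thresholds apply to forward mode |
| `epsilon` | 0.01 | closest-subset band: retain fragments with d ≤ d_min/(1−ε) |
| `a` | 2 (0 for reads <150 bp) | normalization damping weight; integer, ≥0 |
| `tau` | 0.80 | convergence threshold on the normalized proportion |

Threshold table (distance vs most specific rank), total over [0, 2], with
boundary values resolving to the less specific rank (half-open intervals):

| read class | genus | family | class |
|---|---|---|---|
| ≥600 bp ("Sanger") | <0.28 | 0.28–0.32 | ≥0.32 |
| 300–599 bp | <0.35 | 0.35–0.41 | ≥0.41 |
| 150–299 bp | <0.43 | 0.43–0.51 | ≥0.51 |
| <150 bp | <0.6 | ≥0.6 | — |

The table, `tau`, `epsilon`, and `a` are configuration (YAML-overridable);
this package consumes them rather than re-deriving them from training
sequences. Read lengths are mapped to classes at the midpoints between the
four nominal technology lengths (600/300/150), since off-nominal lengths
need *some* rule and the nominal values anchor it.

## Normalization

Reference databases over-represent cultivable and commercially interesting
clades. When a read from a sparsely represented taxon pulls in stray
fragments from an over-sequenced clade, raw majority voting favors the
abundant clade. The damping

    N_i ∝ P_i / (1 + a·log10(1 + R_i))

(where P_i is the taxon's share of the closest subset and R_i its share of
the whole database, both in percent) down-weights abundant taxa
*logarithmically*, so damping saturates: a taxon at R=60% is divided by
~4.6, not 120, and genuinely dominant signals still win. a = 0 is exactly
the identity (implemented as a short-circuit, not a renormalization).
Equal R across taxa cancels under renormalization, leaving N = P. The form
sits behind a `formula_id` registry so alternative damping functions can
be plugged in without touching the pipeline.

The representation table R is computed from **fragment** counts per rank,
not genome counts: fragments are the unit of the closest-subset vote, and
long genomes bias exactly in proportion to their fragment count.

## Rank ladder and sparse lineages

The ladder is species < genus < family < order < class < phylum <
superkingdom < root. Real (NCBI-style) lineages skip ranks; a taxon whose
lineage lacks, say, family is *bucketed* under its nearest present ancestor
for both the representation table and the per-read proportions, so sparse
lineages are never silently dropped from the vote. "root" and
"cellular-organisms"-style top nodes collapse into a single root that is
never reported: a read converging only there is unassigned. The most
specific TL the threshold table emits is genus, so species-level calls are
never produced.

## Numerical and tie-breaking choices

- Boundary distances resolve to the less specific rank (bisect on
  half-open intervals): conservative, and consistent at every cut.
- An exact tie on the winning normalized proportion escalates to the next
  rank instead of picking arbitrarily — assignments stay seed-independent.
- Centroid ties in the cluster scan resolve to the lowest cluster index.
- With d_min = 0 the subset cutoff d ≤ d_min/(1−ε) = 0 retains exactly the
  zero-distance fragments.
- Reads with no valid 4-mer window (shorter than 4 usable bases, or all
  ambiguous) are reported as `too_short`, and
  assigned + unassigned + too_short always equals the input count.
- k-means uses scikit-learn's Lloyd algorithm with k-means++ and a fixed
  recorded seed; centroids are recomputed as exact member means after
  fitting. Rebuilding with identical inputs and seed is bit-identical.
- The convergence comparison uses an absolute 1e-9 guard so that a
  proportion mathematically equal to 100·τ passes despite rounding.

## Synthetic data: what it emulates and what it does not

Genomes are sampled from order-3 Markov chains, one model per genus,
derived by recursively perturbing a near-uniform root model with
multiplicative lognormal noise (σ = 0.30 per rank step) and renormalizing.
Distance between two genera therefore accumulates with the tree distance
to their lowest common ancestor — verified empirically in the tests as a
strictly increasing mean distance in LCA rank.

Each synthetic genome is a forward-sampled half followed by its reverse
complement. Real prokaryotic genomes code on both strands and obey
Chargaff's second parity rule, so both orientations of a clade's
composition occur among its fragments; a single-strand Markov draw lacks
that property, and under forward-only counting reverse-strand reads would
look compositionally alien to their own genome — an artifact of the
generator, not of real data.

Default study scale: 4 phyla × 2 × 2 × 2 × 2 = 64 genera, one 200 kb
genome each → 12,800 reference fragments, k = 113. This builds and
classifies thousands of reads in seconds on one CPU while keeping every
rank of the taxonomy populated with at least two siblings, which is what
the escalation logic needs to be exercised meaningfully.

Read simulation is substitution-only (i.i.d. per base, uniform over the
other three bases), uniform over genomes, positions, and strands. Not
emulated: indels and homopolymer errors (454-style), quality-correlated
error rates, coverage bias, inter-genome mosaicism (HGT), plasmids, and
the rank-sparsity of real NCBI lineages (the synthetic taxonomy is
rank-complete; sparsity is covered by hand-built fixtures). Passing the
synthetic acceptance runs therefore demonstrates the *mechanics* of the
pipeline — search, thresholding, normalization, escalation, scoring — not
field accuracy on real metagenomes, which depends on reference coverage
and genuine compositional overlap between clades.

A note on distance scales: two independent 1,000 bp fragments of the
*same* genome sit ~0.5 apart in Manhattan distance from multinomial
sampling noise alone (256 coordinates estimated from ~997 windows), far
above the 0.28 genus threshold. Reads still achieve sub-threshold d_min
because a read *overlaps* its source genome's fragment grid — shared
windows cancel exactly — which is why nearest-fragment distance, not
fragment-to-fragment distance, is the quantity the thresholds govern. In
the default study, error-free 800 bp reads from represented genomes land
at d_min ≈ 0.16–0.50 depending on how the read straddles the grid, giving
a mix of genus/family/class TLs, all on the correct lineage.

## Leave-clade-out validation

`make_leaveout` marks whole clades (any rank) as absent from the
reference while their genomes remain read sources, and labels each read
with a representation status (`known`, `genus_unknown`, `phylum_unknown`,
…) at the coarsest removed rank covering it. The scorer groups assignments
into correct/wrong/unassigned, correct further into specific (phylum or
below) vs non-specific (above phylum), and can break all categories down
by representation status. This reproduces, at toy scale, the
modified-reference design used to evaluate classifiers on "novel" taxa:
reads from removed genera should escalate to correct coarser ranks rather
than bind to wrong genera.

## Known limitations

- Clustering prunes the search: the nearest centroid's cluster may miss
  the globally closest fragment. The k = 1 configuration is exact and is
  the oracle baseline in the tests; at default k the effect was not
  measurable on the synthetic study (identical accuracy), but no bound is
  claimed for adversarial compositions.
- The normalization form is one member of a family with the stated
  properties (logarithmic, bounded damping, identity at a = 0); the
  registry exists precisely because the "right" form is an empirical
  question the package does not settle.
- Threshold values are consumed as configuration calibrated for forward
  strand counting and the four classical read-length classes; they are not
  re-derived, and no claim is made for other k-mer sizes or metrics.
- One genome per genus in the synthetic collection: within-genus,
  between-genome variation is not modeled there (the thresholds' genus
  band is exercised by read-vs-own-genome distances instead).
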