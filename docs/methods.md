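# Methods

This note records the models and procedures implemented in `panmash`, the
parameters that matter, the design choices made where the design was open,
and the limits of what the synthetic-data tests demonstrate.

## Sketching and Mash distance

Genomes are compared through bottom-s MinHash sketches of canonical k-mers.
Each k-mer and its reverse complement are packed into 2-bit integer codes and
collapsed onto the smaller of the two encodings, so a genome and its reverse
complement sketch identically; windows containing a non-ACGT base are skipped
and counted. Codes are avalanched through a splitmix64 finalizer seeded with
a fixed constant — the hash is deliberately not configurable, so sketches are
bit-reproducible across runs and platforms. K-mers are pooled across contigs
and never span a contig boundary.

The Jaccard index j of two k-mer sets is estimated from the bottom-s values
of the merged sketch, and converted to distance D = −ln(2j/(1+j))/k, an
estimate of per-base divergence (≈ 1 − ANI). Defaults: k = 21, s = 1000.
j = 0 diverges under the formula and is capped at D = 1.0 to keep the metric
bounded for clustering; j = 1 gives exactly 0. The estimator's accuracy is
governed by s: the suite checks that at s ≥ 10× the distinct k-mer count the
estimate equals the exact Jaccard index computed by brute force, and that at
s = 1000 on 10 kb sequences at 5% divergence the error stays within 0.015.

A practical saturation limit follows from these defaults: at pairwise
divergence d the expected shared-hash count in a 1000-hash sketch is roughly
1000·(1−d)^21/(2−(1−d)^21), about 17 at d = 0.15 but under 5 at d = 0.2.
Beyond d ≈ 0.2 individual pairs stochastically report the capped distance
1.0, so distances in that regime carry little information beyond "far".

## Quality triage

Genomes pass three gates in order: CheckM-style completeness/contamination
(must exceed 90% complete, stay below 5% contaminated — both strict),
assembly level (complete or chromosome assemblies are HQ), and fragmentation
(drafts with more than 100 contigs or N50 under 100 kb are LQ; the rest MQ).
Boundary semantics are strict and every threshold is a config key, so the
inclusive variants are one config edit away. HQ + MQ form the analysis set;
a genome failing CheckM is LQ regardless of assembly level.

## Two-level Mash-clustering

Each genome is represented by its row of the distance matrix and partitioned
by K-means (50 restarts, fixed seed). Candidate cluster counts (default
2–20, truncated to n−1) are scored by the average silhouette computed with
the *precomputed Mash distance* as the metric — not Euclidean distance on
rows — because the silhouette should reflect the genomic distance being
interpreted; a config switch restores the Euclidean variant. The chosen k
maximises average silhouette; exact ties (within 1e−9) fall back to the
largest second difference of the inertia curve ("adjusted inertia" is used
only here, and boundary counts with an undefined second difference are
treated as neutral), then to the smaller k. A degenerate all-zero distance
submatrix defines silhouettes as 0, which routes the structureless case to
the min-k fallback.

Genomes with silhouette below the cutoff (default 0.4, applied identically
at both levels) are dropped and the round repeats, up to max_rounds = 10;
if every genome would drop, the run aborts ("no stable clustering"). The
final round is the assignment: every retained genome's silhouette clears
the cutoff by construction. Cluster labels are renumbered 1..k by
decreasing size (then first occurrence), formatted `M<i>` at the primary
level and `M<i>_<j>` at the secondary level. Secondary clustering runs the
same machinery independently inside each primary cluster; clusters with
fewer than 3 genomes, or with no silhouette-stable substructure, pass
through unsplit as `M<i>_1` with a warning.

A Pearson-correlation distance between matrix rows (1 − r; defined as 1 for
zero-variance rows) and its Ward leaf ordering are produced for heatmap and
dendrogram display only — they do not influence the assignment. This split —
K-means drives assignment, hierarchical ordering drives display — resolves
the tension between the two clustering descriptions the workflow combines.

## Species network

Genomes without a reference species label are joined by an edge when
1 − D strictly exceeds 0.95, a standard species threshold (strict reading:
D = 0.05 exactly yields no edge). Louvain modularity communities (resolution
1.0, fixed seed) become novel species `MASH_sp_<n>`, numbered by smallest
member id for determinism; isolated genomes are singleton species. Connected
components are reported alongside as the coarser partition for users who
prefer it when a component contains weakly linked subgroups.

## GCF regrouping and distribution

A family is known when any member BGC has knownclusterblast similarity
strictly above 80% (config-exposed). When members hit several MIBiG
accessions above threshold, one accession is assigned by majority of
above-threshold hits, ties broken by higher mean similarity then
lexicographically — a deterministic rule for a case the upstream tools leave
open. Known families sharing an accession merge; unknown families pass
through untouched, since without a reference their apparent diversity
cannot be tested. Distinct MIBiG entries encoding the same compound are
*not* auto-merged (compound identity is external knowledge); an
accession→compound map can be supplied to merge at compound level.

Similarity bands default to <50 / 50–80 / >80 (the banding used for
per-type breakdowns); BGCs without a MIBiG hit count toward the lowest
band. Custom bands must be non-overlapping.

Families with at least 5 member BGCs (min_bgcs) are profiled across
Mash-clusters: abundance in a cluster is the fraction of its genomes
carrying ≥ 1 member; a family present in all clusters is common, in exactly
one unique, otherwise accessory. Families below the size floor, or present
only in dropped genomes, stay unassigned; dropped-genome carriers are
tallied separately. UpSet-style overlap counts are emitted per cluster
combination.

## BGC synteny and backbone

BGCs are ordered per genome by (contig, start), ties by end then id;
overlapping regions warn but keep start order. The synteny graph is a
multigraph with adjacency edges between chromosomal neighbours (never across
contigs — contig breaks carry no ordering evidence, which is why backbone
detection defaults to complete assemblies) and similarity edges from either
regrouped-family co-membership or a supplied pairwise distance list under a
0.3 cutoff.

Backbone detection takes the families present in at least min_presence
(default 1.0) of the genomes, projects each genome's order onto them
(multi-copy families collapse to first occurrence and are flagged), and
takes the projection of the reference genome — most BGCs, ties to the
lexicographically smallest id — as the consensus. Chromosomes are treated as
linear with arbitrary stored orientation: a projection may match the
consensus forwards or fully reversed, and each genome's orientation is
chosen to maximise pairwise order agreement. If any projection still
disagrees, the family involved in the most pairwise order conflicts is
removed (ties lexicographic) and the check repeats. The greedy rule is
documented behaviour: the exact maximum consistent subset is exponential,
and for the realistic failure mode — a single transposed family — greedy
removal provably excludes exactly the moved family. No circular rotation is
attempted; plasmid-borne BGCs enter as separate short paths.

Variable regions return, per genome, the BGCs strictly between two backbone
anchors in that genome's orientation; non-adjacent anchors warn and span the
intermediate backbone families. Dot plots place one point per pair of
same-family BGCs across two genomes.

## Synthetic data: what it emulates and what it does not

The generator plants the statistical structure the analysis assumes. A root
sequence is mutated down a three-level hierarchy with substitutions only —
no indels or rearrangements — so pairwise divergence tracks the configured
rates cleanly and Mash distance tracks divergence. Divergence parameters are
expected *pairwise* substitution fractions per level; centres are offset by
half the increment at each level so the planted pairwise means come out at
the configured values.

Defaults (the package's reference study conditions): 0.01 within a
subcluster, 0.04 within a primary cluster, 0.15 between primary clusters,
0.30 root-to-outlier. On the ANI scale these read ≈ 99% within species-like
subclusters, ≈ 96% within a primary cluster and ≈ 85% across clusters —
within-species, species-complex and intra-genus scales respectively. The
between-cluster value is deliberately kept below the k = 21 / s = 1000
saturation limit discussed above so that between-cluster distances remain
informative rather than collapsing to the 1.0 cap; outliers, by contrast,
are placed beyond saturation on purpose (they should read as "far from
everything", including each other). Population defaults are 3 primary ×
2 secondary × 8 genomes + 3 outliers at 50 kb — desk-scale genomes chosen so
a full 20-seed recovery study runs in about a minute and a half.

BGC inventories give every genome the backbone families in fixed order;
variable families are inserted between fixed anchor pairs per secondary
cluster (presence probability 0.5) and are never allowed to be universal
within a primary cluster — if sampling makes one universal, one presence is
removed — so the planted backbone is exactly the universally conserved set.
Split known families are the regrouping test-bed: one compound emitted under
several labels in different subclusters, all sharing one MIBiG accession at
similarity drawn from U(81, 100); unknown families draw U(0, 50) or carry no
hit. Placement interleaves across primary clusters so a split compound also
stays non-universal per primary wherever more than one primary exists (with
a single primary cluster this is impossible and universality is accepted).
Setting the insertion probability to zero suppresses all insertions
including split families, leaving pure backbone inventories.

What passing tests therefore show: the pipeline recovers planted structure
when groups are separated at these ANI scales, removes exactly the planted
outliers, repairs label-splitting of known families, and reads conserved
order through insertions, deletions and whole-genome reversals. What they do
not show: robustness to indels, recombination, horizontal transfer, chimeric
assemblies, uneven group sizes at real-collection scale, BGC-boundary errors
or contig fragmentation — real-data effects the generator does not model.

## Numerical and reproducibility choices

All randomness flows from explicit seeds (simulation, K-means, Louvain);
rerunning any stage with the same seed reproduces byte-identical tables.
K-means uses 50 restarts to stabilise a stochastic assignment. Distance
matrices are validated on construction (symmetry, zero diagonal, [0, 1]
range); BGC tables are validated on read with the offending line number, and
coordinates normalise to 0-based half-open. The acceptance script derives
all sub-seeds from a single `--seed` argument and recomputes every reported
quantity at run time; its problem sizes (20 clustering seeds at 51 genomes,
20 backbone seeds, 5 sketch replicates at 10 kb) are the same reference
conditions used throughout the test suite.

## Known limitations

Sketching is in-memory and aimed at desk-scale to mid-size collections, not
streaming metagenome-scale inputs. K-means on distance-matrix rows embeds
genomes in an n-dimensional space that grows with the collection; the
row-space geometry degrades when many distances sit at the saturation cap.
Backbone conflict resolution is greedy, not exact. The species step assigns
one species per community and does not attempt to reconcile conflicting
reference labels. Upstream outputs (BGC calls, family labels, MIBiG
similarities, completeness/contamination) are consumed as given; none are
recomputed from sequence.
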