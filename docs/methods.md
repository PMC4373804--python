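# Methods

## Scope and model

`hapcol` analyses the geographic distribution of organelle haplotypes
across an archipelago under one central assumption: **each haplotype
originated by mutation on a single island**, after which it had the whole
archipelago available for dispersal.  Everything downstream — the
network, the ancestrality ranking, the colonization metrics — is a
deterministic function of the haplotype × island incidence structure and
(where available) the haplotype sequences.  The locus is treated as
non-recombining and maternally inherited (mitochondrial or plastid), so
identical sequences genuinely share descent.

## Haplotype collapsing

Sequences are uppercased, `U→T`, and validated against the IUPAC
alphabet.  A trimming step removes low-quality flanks (the packaged
example trims a 279 bp fragment by its first 62 positions to a 217 bp
analysis window).  Identical ingroup sequences collapse to one haplotype;
counting is per island after alias resolution (the default alias map
merges Baltra into Santa Cruz, reflecting their recent land bridge).
Haplotype labels follow first occurrence, outgroups first; labels are
presentational, and tests rely only on the partition, never on names.

Ambiguity handling is a genuine design choice because there is no field
convention for defining haplotypes from sequences containing N/IUPAC
codes. Two policies are provided and named explicitly rather than
silently picking one:

* `exclude` (default): any ingroup sequence with a non-ACGT character in
  the analysis window is dropped, with a warning.  Reproducible and
  conservative; loses samples.
* `collapse-compatible`: an ambiguous sequence merges into the unique
  unambiguous haplotype it matches at all resolved sites; zero or
  multiple candidates → excluded with a warning.  Keeps samples but can
  merge a true rare variant into a common haplotype.

## Pairwise distances

Substitution (Hamming) distances count only positions where both
sequences carry an unambiguous canonical base, so gaps and ambiguity
codes never create spurious differences.  Distances are exact integer
counts; no evolutionary-model correction is applied, appropriate for the
intra-specific divergences (a handful of substitutions) this method is
meant for.

## Network construction

The network is a deterministic **minimum-spanning-network** variant:

1. sort candidate haplotype pairs by (distance, lexicographic id pair);
2. sweep distance levels in ascending order; within a level, retain every
   pair that joins two groups not yet connected *at the start of that
   level* — so equal-distance alternative connections between the same
   groups are all kept, producing loops;
3. expand each retained k-step connection into a path through k − 1
   inferred intermediate nodes (`m1`, `m2`, … in creation order), which
   carry no sequence because multiple consistent intermediate sequences
   may exist;
4. flag every node on a cycle as homoplasious (loop = ambiguity in the
   mutational pathway, e.g. recurrent mutation), rather than breaking the
   tie arbitrarily.

The connection limit `max_steps` is a plain configuration parameter,
default unlimited: a single-species dataset should yield one connected
network.  The classical statistical-parsimony 95 % connection-limit
probability is deliberately **not** re-derived; a fixed step limit makes
the behaviour explicit and testable, and the probabilistic limit's main
role (excluding distant outgroups from the network) is covered by
computing outgroup distances directly (below).

Retention by level-frozen connectivity is equivalent to the
threshold-graph characterization — a pair at distance d is retained iff
its endpoints are disconnected in the graph of all pairs closer than d —
and the test suite checks the implementation against an independent
brute-force oracle built on that characterization (pure BFS, no shared
code), across random sequence sets and an exhaustive sweep of tiny binary
ones.

Classification: node degree 0 → isolated, 1 → tip, ≥ 2 → interior
(counting edges to inferred intermediates too).  Lineages are connected
components, optionally after removing an explicit cut set of edges.

## Ancestrality ranking

Interior, widely distributed haplotypes are expected to be old under
coalescent theory; tips are young.  Haplotypes are ranked by the
lexicographic key

1. mutation steps to the nearest outgroup haplotype (ascending) — raw
   pairwise distance, not graph path length, so it is defined even when
   the outgroup lies beyond `max_steps`;
2. number of connections to other observed haplotypes (descending);
3. islands occupied, then samples carried (descending);

ties broken by haplotype id and flagged.  Without an outgroup the first
criterion is omitted and the report is marked "no-outgroup mode".

## Colonization metrics

For a species occupying n of I archipelago islands with H haplotypes:

* **chorological minimum** = n − 1.
* **maximum potential events** = H × (I − 1).  I is per-record (a study
  may deliberately restrict the archipelago subset it considers) and is
  never inferred from the archipelago's name.
* **inferred events**, three rules, always co-reported:
  * `shared_count`: haplotypes on ≥ 2 islands.
  * `per_haplotype_spanning` (headline default): Σ over haplotypes on
    k ≥ 2 islands of (k − 1).  This realizes "one event per island beyond
    the origin" at event granularity; for random incidence matrices it
    equals the number of occupied (haplotype, island) cells minus the
    number of haplotypes, which the tests exploit as an independent
    oracle.
  * `spanning_plus_components`: the spanning count plus (C − 1), where C
    is the number of connected components of the occupied-island graph
    whose edges are shared haplotypes.  Island groups that share no
    haplotype still required at least one connecting colonization each;
    on the packaged carpenter-bee matrix this adds exactly one event
    (the eastern pair shares nothing with the central-western group),
    giving 9 events and a success of 9/132 ≈ 0.068.
  No single rule is claimed canonical: published compilations are not
  explicit about theirs, and the three rules bracket the reasonable
  readings.  Externally published event counts are used verbatim under
  the rule name `external`.
* **colonization success** = inferred / maximum potential, full precision
  retained, displayed rounded half-up to 3 decimals.  The cross-species
  report sorts by full-precision success, so two species that round to
  the same display value still order deterministically.

## Synthetic data generator

The simulator is forward-time and agent-free: one haploid Wright–Fisher
deme of fixed size per island.  Each generation every individual (i)
copies a uniformly chosen parent from its deme, (ii) mutates each site
independently with the per-site rate (finite sites, equal rates,
recurrent and back mutation allowed — deliberately, since recurrent
change is what produces network loops), and (iii) with the migration
probability emigrates to a uniformly chosen other island.  Every
inter-island move is logged with generation, source, destination and
haplotype; the haplotype genealogy (parent links + origin island) is
recorded at mutation time.  The true event count replays the log: a move
counts iff it brings a haplotype to an island where it had never yet
occurred.  Because every sampled (haplotype, island) presence implies a
logged first arrival, sharing-based inference is provably a lower bound
on the true count, and the tests assert exactly that.

Randomness is a single seed expanded into per-generation substreams
(`numpy` `SeedSequence.spawn`), making event order stable and reruns
byte-identical.  Final sampling draws a fixed number of individuals per
occupied island without replacement (exhaustively where demes are
smaller).

### The galapagos-like preset

Defaults: 9 islands, founding deme on Isabela, deme size 60, 600
generations, migration probability 1 × 10⁻³ per individual per
generation, mutation rate 1 × 10⁻⁵ per site per generation, 217 bp
locus, 13 samples per island (~117 total).  Rationale: deme size and
generations put the per-island coalescent time well inside the run
length; the scaled diversity 2 N_total μ L ≈ 2.3 yields on the order of
a dozen sampled haplotypes; migration is rare enough that most
haplotypes stay where they arose yet frequent enough that all nine
islands are colonized from the single founding deme.  Across seeds the
preset's sampled haplotype count (roughly 7–17) and single-island
haplotype fraction (roughly 0.6–0.9) bracket the carpenter-bee reference
values (12 haplotypes, 9/12 single-island); the test suite checks the
bracketing as a range condition, not an equality.

What the generator does **not** emulate: geographic distance (migration
is island-uniform, not stepping-stone by proximity), demographic growth
or bottlenecks after founding, selection, island age differences, and
palaeogeographic island fusion.  Passing tests therefore demonstrate
that the inference chain recovers truth under the model's own
assumptions — not that those assumptions hold for any particular real
archipelago.

## Numerical and degenerate-input choices

* Rounding is decimal half-up (not banker's), applied only at display.
* All tabular outputs are UTF-8 TSV with sorted, deterministic row
  order; re-running a pipeline with the same config is byte-identical.
* Degenerate inputs fail loudly and early: empty alignments, unequal
  lengths, unknown islands, negative incidence cells, zero-haplotype
  records, zero potential events and missing cut edges all raise typed
  errors naming the offending record where possible.
* Problem sizes in the test suite are kept small by design — haplotype
  sets of ≤ 6 sequences for exhaustive/brute-force comparisons, tens of
  simulator replicates for the stochastic trend checks — sizes at which
  the independent oracles are exact and the whole suite runs in well
  under a minute of compute per module.

## Known limitations

* The network builder targets intra-specific data (few substitutions);
  it computes all O(n²) pairwise distances and is not meant for
  thousands of haplotypes.
* Inferred intermediates carry no sequences, so a path through them
  cannot be further decomposed site by site.
* The ancestrality ranking is a heuristic ordering of coalescent
  expectations, not a rooted inference with support values.
* With `collapse-compatible` ambiguity handling, a truly novel variant
  whose differing site is ambiguous will be silently absorbed into an
  existing haplotype; use `exclude` when that risk matters.
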