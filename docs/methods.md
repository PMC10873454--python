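# Methods

`xynrin` implements the desk-side analyses used to study why some fungal
GH10 xylanases stay folded and active at pH 2: residue interaction networks
from 3D structures, surface charge profiling, conservation-based
differential-residue classification with mutant design, and cluster-level
statistics on interaction censuses and phylogenetic branch lengths.  This
note records the models, conventions, defaults and known limitations.

## Residue interaction network

The network has residues as nodes and non-covalent contacts as edges.  Six
edge types are detected by pure distance criteria on heavy atoms:

| type | atoms compared | rule (default) |
|---|---|---|
| hydrogen bond | donor-capable N/O vs acceptor-capable N/O | d ≤ 3.5 Å |
| Van der Waals | side-chain heavy atoms + Cβ | d ≤ r_i + r_j + 0.5 Å |
| disulfide | Cys SG vs Cys SG | d ≤ 2.5 Å |
| ionic | Asp/Glu carboxylate O, C-term OXT vs Lys NZ, Arg NE/NH1/NH2, His ND1/NE2, N-term N | d ≤ 4.0 Å |
| π–π stacking | ring centroid vs ring centroid | d ≤ 6.5 Å |
| π–cation | ring centroid vs Lys NZ / Arg guanidinium centroid | d ≤ 5.0 Å |

Conventions, and why:

* **Heavy atoms only, no angle terms.** Homology models rarely carry
  hydrogens and angle criteria introduce model-dependent sensitivity; the
  cutoffs above are distance-only, so absolute counts may differ from
  detectors that add orientation filters.  Angle filters are deliberately
  out of scope.
* **Donor/acceptor assignment** uses a fixed per-residue table of standard
  chemistry (backbone N donor except proline mid-chain, backbone O/OXT
  acceptor, Ser/Thr/Tyr hydroxyls both, amide and guanidinium/imidazole
  nitrogens donors, carboxylate and amide oxygens acceptors).
* **Van der Waals is restricted to side-chain atoms plus Cβ** so the VdW
  census does not simply mirror the covalent backbone.  Radii: C 1.70,
  N 1.55, O 1.52, S 1.80 Å, fixed in the config and echoed in output
  metadata.  The retained contact per pair is the one with the smallest
  surface gap d − r_i − r_j.
* **Sequence separation ≥ 2** within a chain (i, i±1 excluded) so covalent
  neighbours are not counted; inter-chain pairs are always eligible.
* **One edge per (residue pair, type)** at the minimal qualifying
  distance; a pair may carry several types (a disulfide-range SG–SG
  contact, for example, is always also a VdW contact).  Per-type counts are
  therefore additive and `n_edges = Σ per_type`.
* **Histidine** participates as an aromatic ring (toggleable) but not as a
  π-cation cation by default — its protonation state is ambiguous at the
  pH values of interest.  Tryptophan contributes both the pyrrole and the
  benzene ring; a pair of residues is still counted once.
* The **census** reports edges, nodes (residues in ≥ 1 edge), their ratio
  (reported as missing when there are no nodes), per-type counts, and
  unordered one-letter aromatic pair counts (F-F, F-Y, …) for the stacking
  edges.

Detection is k-d-tree accelerated; the test suite holds every detector to
an independently written all-pairs brute-force oracle, exactly, over
randomized structures.

## Solvent accessibility and charge profiles

SASA uses Shrake–Rupley sphere sampling with a probe of 1.4 Å and a
deterministic golden-spiral lattice (default 960 points per atom); no
random numbers, so results are bit-stable.  Because a fixed world-frame
lattice is not rotation-invariant, coordinates are first posed in a
canonical frame — centroid at the origin, axes aligned to the principal
axes of the heavy-atom cloud with a third-moment sign convention — making
SASA invariant under rigid motion of the input up to eigendecomposition
round-off (well below 1e-6 relative).  The fallback for degenerate clouds
(fewer than 3 atoms, or exactly symmetric ones) is the input frame.

A residue is *surface* when its relative SASA (residue SASA divided by the
Tien et al. 2013 theoretical maximum for its type) reaches 0.25.  The
threshold, probe and reference table are conventions, not measurements:
published counts based on an unspecified surface definition can only be
compared qualitatively, and the threshold is configurable (re-run at
0.20/0.30 for sensitivity).

Charge profiles count acidic (D, E) and basic (R, K, H — histidine counted
basic) residues and their ratio (missing when no basic residues), over the
whole chain and again restricted to surface residues when flags are given.

## Differential residues, regions and mutants

Given an alignment, a reference enzyme, an acid-stable query and the
query's homolog cluster (the query must be listed among the cluster
members), every column where the query differs from the reference is
classified: **group A** when all cluster members differ from the reference
at that column, **group B** when only a proper subset does.  Gap policy: a
gap in the reference or a member counts as differing for that member; a
gap in the query leaves the column classified but yields no mutable
position.  All sequence positions in reports are 1-based ungapped query
positions.

Substitution-set mutants write the reference residue at selected query
positions (the back-to-reference designs used to probe which differential
residues carry acid stability): all positions, group A, group B, and
N-/C-terminal halves (first ⌈k/2⌉ of the sorted positions to the N half,
or an explicit sequence midpoint).  Mutant design is idempotent and
composes: group A then group B equals all positions at once.

Spatially enriched regions of a residue set are single-linkage connected
components under a Cβ (Cα for Gly) distance cutoff of 10 Å, discarding
components smaller than 3.  Both parameters are explicit surrogates for
what was originally a visual circling of clustered residues, and are
recorded in output metadata.

## Cluster statistics

Two-sample contrasts follow the F-test-then-t-test scheme: a two-sided
variance-ratio F-test (larger variance in the numerator) at α = 0.05
selects the pooled (Student) t-test when equal variances are not rejected
and Welch's otherwise; both two-sided.  Degenerate inputs: two
zero-variance samples with equal means give t = 0, p = 1; with different
means, p = 0.  Multi-cluster results are summarized as a compact letter
display (greedy insertion by descending mean; clusters sharing a letter
are not significantly different pairwise).  No multiple-testing correction
is applied across the pairwise tests, matching the plain p < 0.05
convention; correct upstream if needed.

Clade branch statistics locate each clade's MRCA (the clade's leaf set
must be monophyletic) and report the mean over all edge lengths strictly
within the MRCA subtree — internal and terminal edges, excluding the
MRCA's own parent edge.  Because "average branch length" is ambiguous, the
mean tip-to-MRCA depth is always co-reported as the alternative reading.

## Synthetic data: what it emulates and what it does not

The generators provide planted ground truth for every stage:

* **Structures** place rigid, idealized residue templates (literature bond
  lengths to within a few hundredths of an Å) so each planted pair
  realizes its interaction at `cutoff − margin` and each decoy at
  `cutoff + margin` (default margin 0.3 Å, 0.2 Å in the recovery checks).
  Units sit on a 30 Å grid — beyond twice the largest cutoff — so ground
  truth is exactly the within-unit contacts, including the contacts a
  geometry necessarily implies (a disulfide is always also a VdW contact;
  a tight salt bridge also satisfies the hydrogen-bond rule).  Random
  structures for oracle testing drop the isolation and pack random
  templates into a 30 Å box.  These fixtures have no realistic backbone
  connectivity, packing density or secondary structure: passing tests
  demonstrate detector correctness and invariances, not biological realism
  of any census value.
* **Alignments** plant group-A columns (all five cluster members differ
  from the reference) and group-B columns (the number of differing
  members, query included, uniform in 1..n−1); all other columns are
  identical, so planted truth is unambiguous.  Real alignments have
  correlated columns and gaps; the gap policy is exercised by unit tests,
  not by the generator.
* **Charge sequences** have exact planted D/E, R/K/H and neutral counts.
* **Trees** draw exponential edge lengths (mean = `base_rate`, default
  0.15 substitutions/site to resemble protein-family trees) over random
  per-clade topologies joined on a backbone, with one clade's mean
  multiplied (the fast-clade analogue).

The emulated study conditions are two clusters of five enzymes — matching
the five-member acid-stable cluster contrasted against its relatives — with
the stable cluster carrying 3 extra planted F-F stacking pairs per
structure over a seed-varying 0–2 baseline (so within-cluster variance is
non-zero and the t-test well-defined); a 5-member cluster alignment; and a
4-clade tree with a 6× faster fourth clade.

## Numerical choices

* Cutoff comparisons are ≤ with no tolerance band; planted fixtures keep
  0.2 Å away from every boundary, so floating-point order effects cannot
  flip an edge.
* Edges are ordered deterministically (chain, residue number, type);
  reports contain no timings or timestamps, so identical configs produce
  byte-identical report directories.
* All generator randomness flows from a single seeded NumPy generator per
  fixture; seeds are recorded in manifests.
* The acceptance script sizes its simulations for a single CPU: 50
  planted-recovery fixtures, 25 alignments, 10,000 null t-test
  simulations, 40 tree replicates.

## Known limitations

* Absolute interaction counts depend on conventions (atom tables, no angle
  terms, separation rule) and will not numerically match detectors that
  choose differently; cross-cluster *contrasts* are the supported use.
* The surface definition is a convention; surface-restricted counts are
  qualitative.
* His protonation, altloc ensembles (only one conformer is kept) and NMR
  multi-model aggregation are out of scope.
* The accession-based worked example (differential-residue count between
  Xyn10RE CAD34597.1 and Xyn10A Y699_04481, published value 82) needs the
  two public sequences supplied locally (`data/accessions/`); they are not
  redistributed, and the pairwise-alignment route (BLOSUM62, -11/-1 gaps)
  may count slightly differently from a hand-curated multiple alignment
  over mature sequences.
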