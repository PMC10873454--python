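# xynrin

Structural-bioinformatics toolkit for the question of why some fungal GH10
xylanases — industrially important endo-β-1,4-xylanases with an (α/β)₈
barrel fold — remain stable at pH 2 while close relatives unfold.  It is
aimed at enzyme engineers and computational structural biologists who want
to compare acid-stable and acid-labile homolog clusters and design
back-to-reference mutants.

The package implements, as a tested pipeline over synthetic or real inputs:

* **Residue interaction networks** (`xynrin.rin`) — six geometric contact
  types between residues: hydrogen bonds (donor N/O to acceptor N/O,
  d ≤ 3.5 Å), Van der Waals (side-chain atoms + Cβ, d ≤ rᵢ + rⱼ + 0.5 Å),
  disulfides (SG–SG ≤ 2.5 Å), ionic bonds (opposite charged-group atoms
  ≤ 4.0 Å), π–π stacking (ring centroids ≤ 6.5 Å, with F-F / F-Y pair
  labels) and π–cation (centroid to cation point ≤ 5.0 Å) — plus the
  network census: edges, nodes, edge/node ratio, per-type and per-pair
  counts.
* **Surface charge profiles** (`xynrin.surface`) — deterministic
  Shrake–Rupley SASA, relative-SASA surface classification (rSASA ≥ 0.25,
  Tien et al. 2013 reference areas), and acidic (D, E) / basic (R, K, H)
  counts and ratios, whole protein vs surface only.
* **Differential residues and mutant design** (`xynrin.diffres`) — against
  a reference enzyme, alignment columns where an acid-stable query differs
  are classified *group A* (all cluster members also differ, 5/5) or
  *group B* (only a subset, ≤ 4/5); substitution-set mutants write the
  reference residue back at chosen positions; group-A positions are
  clustered into spatially enriched regions (single linkage on Cβ, 10 Å).
* **Cluster statistics** (`xynrin.clusterstats`) — two-sample contrasts by
  the F-test-then-t-test scheme (pooled vs Welch, two-sided, α = 0.05),
  compact letter displays across clusters, and per-clade mean branch
  lengths from a Newick tree (MRCA subtree mean, with mean tip depth
  co-reported).
* **Synthetic data with planted truth** (`xynrin.synthetic`) — structures
  with interactions planted at controlled distances to each cutoff,
  alignments with planted A/B columns, charge-composition sequences, and
  trees with clade rate contrasts; everything downstream is testable
  without downloads.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Build a toy structure with one planted contact of every type and a decoy
per type, then census it:

```python
from xynrin.rin import IType, build_rin
from xynrin.synthetic import FixtureSpec, PlantSpec, make_structure_fixture

spec = FixtureSpec(seed=1, planted=[PlantSpec(t) for t in IType],
                   n_decoys=1, n_filler=3)
structure, truth = make_structure_fixture(spec)
edges, census = build_rin(structure)
print(census.n_edges, census.n_nodes, census.per_type["PIPI"],
      census.pipi_pairs)
```

prints

```
8 14 1 {'F-F': 1}
```

— 8 edges over 14 residues: the six planted contacts, plus two Van der
Waals contacts implied by disulfide-range SG–SG geometry (one from the
planted disulfide, one from its decoy), and one F-F stacking pair.  The
decoys, placed 0.3 Å outside their cutoffs, are correctly absent.

The numbered drivers under `analysis/` run the full study on synthetic
inputs and narrate their findings:

```sh
python analysis/01_simulate_study.py      # two clusters x 5 structures, MSA, tree
python analysis/02_interaction_census.py  # RIN census; F-F contrast significant
python analysis/03_charge_profiles.py     # SASA + charge profiles per scope
python analysis/04_differential_residues.py  # group A/B, mutants, regions
python analysis/05_clade_rates.py         # clade mean branch lengths
python analysis/06_worked_example.py      # real accessions (needs downloads)
```

For example, `02_interaction_census.py` reports that only the stacking
metrics separate the clusters (`pipi_FF: t=-4.33 p=0.0025 SIGNIFICANT`),
while hydrogen bonds, Van der Waals and ionic counts do not — the planted
analogue of an acid-stable clade enriched specifically in Phe-Phe stacking.
`05_clade_rates.py` recovers the fast clade (`cluster IV vs others: 0.824
vs 0.101, 0.084, 0.094`).

A console script `xynrin` exposes the same stages
(`xynrin rin --pdb FILE`, `xynrin surface --pdb FILE`, `xynrin diffres ...`,
`xynrin stats compare|clades ...`, `xynrin simulate ...`,
`xynrin pipeline run --config YAML`).

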