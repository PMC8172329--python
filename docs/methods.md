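# Methods

## Model

A protein sequence is compared to others through a fixed-length numerical
descriptor rather than an alignment. The descriptor has three blocks.

**Cone-based graphical curves.** Each physicochemical property index
assigns one real value to each of the 20 standard amino acids. Sorting
the amino acids ascending by that value (ties broken by ascending
one-letter code, so layouts are reproducible) assigns cone index
i = 1…20, and the amino acids are placed on the unit circle of a right
circular cone's base plane at height 1: φ(Ωᵢ) = (cos 2πi/20, sin 2πi/20, 1).
The last-sorted amino acid sits at angle 2π, i.e. (1, 0, 1). Each of the
400 ordered pairs is placed a quarter of the way along the chord from its
first vertex to its second; the self-pair therefore coincides with its
vertex. A sequence s₁…s_N extends a path from the origin P₀ = (0,0,0):
the step for residue i adds that residue's vertex plus the sum of pair
points weighted by the dipeptide frequencies of the prefix s₁…sᵢ
(overlapping adjacent pairs, the standard dipeptide convention).

Two frequency conventions are implemented. The default, `count`, uses raw
occurrence counts; since the prefix of length i contains i − 1 dipeptide
occurrences and every mapped point has z = 1, the z-coordinate obeys the
closed form zᵢ = i(i+1)/2, which the tests assert exactly. The `relative`
mode divides counts by the i − 1 windows (zᵢ = 2i − 1 for i ≥ 2). Count
mode is the default because it is the simpler literal reading of
"frequency" and admits the exact closed form; both modes are tested and
selectable everywhere a curve is built.

**L/L matrix and spectral descriptor.** For the N path points P₁…P_N
(the origin is a starting anchor, not a residue, and is excluded), the
L/L matrix divides each pairwise Euclidean distance by the arc length
along the path between the same points; the diagonal is zero. Because z
strictly increases, consecutive points are distinct, every off-diagonal
entry lies in (0, 1], and entries for consecutive points equal 1 exactly.
The matrix is symmetric and nonnegative, so its largest eigenvalue equals
its spectral radius; dividing by N removes the length bias. One
normalized eigenvalue per property forms the graphical block. The curve
depends only on each property's rank ordering of the amino acids, never
on the magnitudes — two properties inducing the same ordering produce
identical descriptors, which the implementation exploits by caching per
ordering.

**Composition statistics.** Amino-acid composition (AAC) is the
20-vector of residue counts over N, indexed alphabetically A…Y.
Dipeptide composition (DPC) is the 400-vector of overlapping pair counts
over N − 1, indexed first-letter-major (AA, AC, …, YY). The N − 1
denominator makes DPC a probability vector (the standard convention).
Both blocks sum to 1 for every sequence.

With the canonical 158-property configuration the fused vector
[graphical | AAC | DPC] has 158 + 20 + 400 = 578 dimensions; smaller
property sets shrink only the first block.

**Phylogeny.** The dataset's feature matrix is column-centered and
reduced by PCA (no unit-variance scaling by default; a `scale` flag is
provided). The component count is configurable; the default keeps 95%
cumulative explained variance. Component signs are fixed so each
component's largest-magnitude loading is positive, making scores — and
everything downstream — reproducible across platforms. Cosine distance
d(i,j) = 1 − cos(xᵢ, xⱼ) feeds single- or complete-linkage agglomerative
clustering (both monotone, so merge heights never invert). Trees are
exported as ultrametric Newick (leaves at height 0, branch length =
parent height − child height); flat clusterings cut the last k − 1
merges; clustering accuracy against taxonomic labels is the
Hubert–Arabie adjusted Rand index.

## Property indices

AAindex1 flat files are parsed honoring the I-line header order
(A/L R/K …). Records containing any missing ("NA") value are skipped —
they cannot induce a total ordering — and counted; among records with
bitwise-identical 20-value vectors only the first in file order is kept.
Exact equality is used for duplicate detection because any tolerance
would need an arbitrary threshold and break reproducibility. A plain-text
accession list can pin the retained set and its order, so a published
selection can be reproduced exactly from the corresponding database
release. The package bundles a small synthetic AAindex-format fixture
(7 records: 5 usable, one NA-bearing, one exact duplicate) so the whole
suite runs without any download; it is generated data, not database
content.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `freq_mode` | `count` | dipeptide weighting in the path recursion (`count` or `relative`) |
| property set | 158 indices | one cone/descriptor per index; synthetic seeded sets stand in when no AAindex file is supplied |
| `n_components` | 95% variance | PCA score dimension (pin explicitly to reproduce a published setting, e.g. 28) |
| `scale` | off | unit-variance scaling before PCA |
| `linkage` | `single` | agglomeration rule (`single` or `complete`) |
| `k` | number of label classes | flat-cut cluster count |
| sanitization | `strip` | non-standard residues (B, J, O, U, X, Z, gaps, stops) removed with a warning; `reject` aborts instead |

## Numerical choices

- Leading eigenvalues use a dense symmetric solve (`eigvalsh`) up to
  2000×2000 and Lanczos above; both converge far below the 1e-10
  relative tolerance the tests require.
- Linkage is delegated to scipy's deterministic implementations. Tied
  merge candidates are resolved by scipy's internal order rather than a
  leaf-index rule; ties have measure zero for real-valued cosine
  distances, and merge heights are unaffected either way.
- Degenerate inputs fail loudly: empty sequences, sequences shorter than
  2 (no dipeptide, no L/L matrix), all-zero feature rows under cosine
  distance, duplicate sequence IDs, non-permutation cone orders, and
  out-of-range PCA or cut parameters all raise with the offending item
  named.
- The pipeline is a pure function of its inputs: identical FASTA,
  property set and flags give bit-identical feature matrices, Newick
  strings and ARI values.

## Synthetic data

The generators emulate the shape of the published evaluation datasets
(tens of single-domain sequences, globin-like lengths) without their
content:

- i.i.d. sequences: residues drawn from a given composition (uniform by
  default), lengths uniform in 120–180 aa;
- protein families: independent random ancestors of length 150 with
  members derived by per-site substitution at rate 0.1 — enough
  divergence to be nontrivial, little enough that family structure is
  recoverable;
- property sets: i.i.d. standard-normal 20-vectors, which induce
  distinct amino-acid orderings with probability one.

These fixtures exercise every contract of the pipeline, but random
sequences have no conserved motifs, domain architecture or phylogenetic
signal beyond the planted family structure. Passing tests therefore
demonstrate correctness of the computation, not biological performance
on real protein families; published clustering accuracies can only be
checked after fetching the corresponding public accessions and the
AAindex release (the acceptance tests look for those files under
`tests/data/` and skip otherwise).

## Limitations

- Property values are used only through their rank ordering of the amino
  acids; magnitudes are discarded by construction.
- Only single and complete linkage are offered; no bootstrap support,
  neighbor-joining or likelihood trees.
- DPC and the path recursion need N ≥ 2; length-1 sequences are
  rejected rather than padded.
- Feature extraction is O(properties × N²) time with one N×N matrix in
  memory at a time; very long sequences (N ≫ 10⁴) are slow, and the
  descriptor is not designed for them.
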