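# Methods

## Model

A protein–ligand complex is represented by 36 element-specific bipartite
digraphs (protein {C, N, O, S} × ligand {C, N, O, S, P, F, Cl, Br, I}),
built from all heavy-atom cross pairs within a cutoff (default 12 Å,
closed ball). Hydrogens are excluded; so are atoms outside the whitelists
(with a logged count). Each retained pair carries one directed edge:

- **weight** μ = Φ(r; η_pl) ∈ (0, 1], with Φ a generalized Lorentz
  (1/(1+(r/η)^ν)) or generalized exponential (exp(−(r/η)^κ)) kernel and
  η_pl = τ·(r_vdw(p)+r_vdw(l)) from the bundled Bondi radius table;
- **direction** from the lower-Pauling-electronegativity atom to the
  higher (exact ties: protein → ligand, a deterministic convention);
- **filtration value** f = 1 − μ ∈ [0, 1), so close contacts are born
  early and the interval grid ending at 1 covers the whole range.

The edge weight is the pair's own kernel term rather than any
row-normalized correlation; the summed rigidity index (the sum of the μ's)
is exposed separately as a diagnostic (`fri_digraph.rigidity_index`).

Directed flag complexes use the all-pairs clique rule: (w0, …, wk) is a
simplex iff (wi, wj) is an edge for *every* i < j (the directed 3-cycle
contains no 2-simplex). A simplex's filtration value is the maximum over
its edges (vertices at 0) — the standard flag-complex convention, which
keeps sublevel sets face-closed. Reciprocal edge pairs are legal distinct
1-simplices in the generic engine; the molecular front-end never produces
them. Within each dimension simplices are sorted lexicographically on
their (stringified) vertex tuples, making all matrices bit-reproducible.

## Persistent Laplacian

Chain groups are real, with the simplex basis declared orthonormal.
For nested complexes K_a ⊆ K_b, the persistent boundary in dimension k+1
acts on {c ∈ C_{k+1}(b) : ∂c ∈ C_k(a)}. Its matrix D is computed by
splitting the rows of B_{k+1}(b) into those indexed by k-simplices present
in K_a ("inside") and the rest ("outside"), taking an SVD-orthonormal
null-space basis Z of the outside block, and forming (inside block)·Z.
Orthonormality of Z is mandatory: the spectrum of D Dᵀ is otherwise
basis-dependent. Then

    L_k(a,b) = D Dᵀ + B_k(a)ᵀ B_k(a),

indexed by the k-simplices of K_a. For a = b, Z is the identity and the
ordinary directed flag Laplacian is recovered. On the bipartite molecular
digraphs there are no 2-simplices, so L1(a,b) reduces structurally to the
down term B1(a)ᵀB1(a) and L0(a,b) to the sublevel graph Laplacian at b —
the generic code path handles this through zero-shaped matrices rather
than special cases.

Numerical choices: sparse assembly, dense symmetric eigensolvers
(`scipy.linalg.eigvalsh`; the per-element-pair matrices stay in the
hundreds of rows). Zero tolerance defaults to 1e−8 × max(1, λ_max);
eigenvalues within −tol are clipped to 0 and anything more negative
raises. Symmetry is checked to 1e−9 relative before decomposition. The
zero-eigenvalue count is the (persistent) Betti number; the test suite
checks this against an exact homology computation done in rational
arithmetic (sympy matrix ranks), deliberately free of floating-point
tolerances, on all random digraphs of ≤ 7 vertices it generates.

## Features

Ten statistics per spectrum, in fixed order: min nonzero (Fiedler value),
max, sum, mean, median, variance, std (these five over eigenvalues
strictly above the zero tolerance), count of positive eigenvalues, sum of
squares, zero count. Empty spectra give ten zeros; an all-zero spectrum
zeros everything except the zero count. Medians of even-sized sets are
midpoint means. The full vector iterates kernel → element pair (protein
C, N, O, S outer; ligand C, N, O, S, P, F, Cl, Br, I inner) → interval
((0,0.8), (0.8,0.85), (0.85,0.9), (0.9,0.95), (0.95,1)) → dimension
k ∈ {0, 1} → statistic: 3600 values per kernel, concatenated across
kernels. The two dimensions are the homological dimensions whose Betti
numbers (components and loops) the intervals were chosen to capture; each
interval (a, b) maps to the persistent Laplacian L_k(a,b) on the sublevel
complexes at a and b, not to snapshot Laplacians at the endpoints.
Feature columns that are exactly zero across a whole dataset can be
dropped (`drop_all_zero_columns`), which records the surviving labels for
reproducibility.

## Scoring

A GBDT regressor (xgboost, single-threaded `hist`, fully deterministic
given seed) maps features to affinity. Defaults: 10000 trees, learning
rate 0.01, depth 7, subsample 0.8, early stopping (50 rounds) on an
internal 10% validation split — all overridable. Evaluation reports
Pearson R_p and RMSE in label units; repeated holdout over n seeds
(default 20) reports mean/best R_p with the RMSE of the run closest to
the mean; shuffled 5-fold CV supports kernel hyperparameter selection.
Labels declared as pKd/pKi are converted to kcal/mol by the factor
−1.3633 (2.303·RT at 298 K). Train/test id overlap is a hard error, as is
a feature-schema hash mismatch at prediction time.

## Synthetic data

`synthetic_fixtures` provides the deterministic study conditions used by
the tests: transitive tournaments (the directed 4-clique worked example)
and directed cycles for the spectral engine, and random complexes for the
molecular pipeline — 50 protein atoms uniform in a 24 Å box with
composition C 62 / N 16 / O 20 / S 2 %, 10 ligand atoms Gaussian-clustered
(σ = 2 Å) at the box center with a drug-like element mix including rare
halogens. These sizes keep one complex at roughly the atom count of a
binding pocket and give contact counts that vary strongly across seeds.
The planted affinity is a linear function of per-protein-element contact
counts within the cutoff (weights C 0.1, N 0.3, O −0.2, S 0.5, arbitrary
affinity units), plus Gaussian noise with σ = 10 % of the signal spread —
so the attainable correlation is known by construction and end-to-end
recovery (held-out Pearson ≥ 0.95 at n = 1000) demonstrates that the
spectral features encode the interaction geometry. What the fixtures do
*not* emulate: bonded structure, sterics, conformational correlation
between protein and ligand, or any physical affinity scale; passing tests
show the machinery is sound, not that real PDBbind performance follows.
The end-to-end check uses 1000 complexes with an 800/200 split and a
3000-tree early-stopped GBDT, sized so the whole suite stays interactive.

## Known limitations and open choices

- MOL2 parsing reads only the TRIPOS ATOM block (element from the SYBYL
  type column); bonds, charges and substructures are ignored by design.
- PDB handling keeps the first model and Biopython's highest-occupancy
  altloc; chain/cleaning policies beyond that are out of scope.
- Whether the filtration parameter should be μ (superlevel) or 1 − μ
  (sublevel) is a convention; sublevel on 1 − μ was fixed once, and all
  interval semantics follow it.
- Eigenvectors, harmonic representatives, and persistence barcodes are
  not computed; only spectra are exposed.
- The PDBbind benchmark pipeline (featurize → train → cv over the refined
  /core sets) is fully scriptable through the CLI but requires the
  external PDBbind download and substantial compute; it is not part of
  the test suite.
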