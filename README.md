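# pdfl

Persistent directed flag Laplacian (PDFL) features and machine-learned
scoring for protein–ligand binding affinity.

Protein–ligand interactions are asymmetric: polarization pulls electron
density toward the more electronegative partner. Standard topological
descriptors (Vietoris–Rips persistent homology, undirected persistent
Laplacians) discard that directionality. This package models a complex as a
family of *directed* interaction networks and summarizes their multiscale
spectral geometry into fixed-length feature vectors for a gradient-boosted
regression scorer. It is aimed at researchers building structure-based
scoring functions and at anyone who needs persistent directed flag
Laplacian spectra for general weighted digraphs.

## The method

1. **Element-specific digraphs.** All heavy atoms of the complex are split
   by element — protein {C, N, O, S} × ligand {C, N, O, S, P, F, Cl, Br, I}
   — giving 36 bipartite graphs over atom pairs within a 12 Å cutoff. Each
   cross pair (p, l) gets one directed edge pointing from the lower to the
   higher Pauling electronegativity, weighted by a flexibility–rigidity
   index (FRI) kernel

       μ = Φ(‖r_p − r_l‖; η_pl),   η_pl = τ (r_vdw(p) + r_vdw(l)),

   with Φ either generalized Lorentz, Φ(r; η) = 1 / (1 + (r/η)^ν), or
   generalized exponential, Φ(r; η) = exp(−(r/η)^κ). The edge enters the
   filtration at 1 − μ, so strong contacts are born early.

2. **Directed flag complexes.** A directed k-clique is an ordered vertex
   tuple (w0, …, wk) with an edge (wi, wj) for every i < j; the set of all
   directed cliques is the directed flag complex dFl(G). Sublevel sets of
   the filtration give a nested family dFl(G_a) ⊆ dFl(G_b) for a ≤ b.

3. **Persistent directed flag Laplacians.** With real chain groups C_k and
   boundary operators ∂_k (alternating sums of faces), the k-th persistent
   Laplacian of a filtration pair (a, b) is

       L_k(a,b) = D D^T + B_k(a)^T B_k(a),

   where D represents ∂_{k+1} restricted to the b-chains whose boundaries
   lie in the a-complex, in an orthonormal basis. L_k(a,b) is symmetric
   PSD; its zero-eigenvalue multiplicity is the persistent Betti number
   β_k(a,b), and its nonzero spectrum tracks non-topological shape change.

4. **Features and scoring.** For each kernel × element pair × interval
   ((0,0.8), (0.8,0.85), (0.85,0.9), (0.9,0.95), (0.95,1)) × dimension
   k ∈ {0,1}, ten spectral statistics are recorded (Fiedler value, max,
   sum/mean/median/variance/std of positive eigenvalues, positive count,
   sum of squares, zero count): 36·5·2·10 = 3600 features per kernel.
   A GBDT regressor maps features to affinity, evaluated by Pearson R_p and
   RMSE with repeated holdout and shuffled 5-fold cross-validation.

## Worked example

The transitively oriented complete digraph on four vertices {a, b, c, d}
is the smallest complex directed flag complex: 4 vertices, 6 edges, 4
directed 3-cliques, and one 4-clique. Its Laplacian spectra are known in
closed form. With the edge list

```
a b 0
a c 0
a d 0
b c 0
b d 0
c d 0
```

```sh
$ pdfl spectra clique.edges --max-dim 3 --out spectra.tsv
INFO pdfl: wrote 4 spectra rows to spectra.tsv (simplex counts [4, 6, 4, 1])
$ cat spectra.tsv
0	0	0	1.11022302463e-16	4	4	4
1	0	0	4	4	4	4	4	4
2	0	0	4	4	4	4
3	0	0	4
```

Each row is `k  a  b  eigenvalues…`. L0's spectrum {0, 4, 4, 4} has one
zero eigenvalue (β0 = 1: a single connected component) and Fiedler value 4;
L1, L2, L3 have no zeros (β1 = β2 = β3 = 0: no loops or voids), and the
alternating sums agree: 4 − 6 + 4 − 1 = 1 = β0 − β1 + β2 − β3.

Featurizing a synthetic complex from the bundled generator:

```python
>>> from pdfl import KernelSpec, featurize_complex
>>> from pdfl.synthetic_fixtures import FixtureSpec, random_complex
>>> complex_, label = random_complex(FixtureSpec(seed=7))
>>> fv = featurize_complex(complex_, [KernelSpec("L", beta=2.0, tau=1.0)])
>>> len(fv), int((fv.values != 0).sum()), round(label, 2)
(3600, 981, 22.9)
>>> fv.labels[2], fv.values[2]
('Lb2t1|C-C|0-0.8|dim0|sum', 20.0)
```

The label reads: Lorentz kernel (ν = 2, τ = 1), protein-C/ligand-C
digraph, interval (0, 0.8), dimension 0, sum of positive eigenvalues —
here 20, twice the number of C–C contact edges alive at filtration 0.8.

Real structures go through the same pipeline:

```sh
pdfl featurize --protein 10gs_protein.pdb --ligand 10gs_ligand.mol2 --out 10gs.csv
pdfl train --features all.csv --manifest labels.csv --out-model model.json
pdfl cv --features all.csv --manifest labels.csv -k 5
```

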