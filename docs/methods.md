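# Methods

`mitotox` models how single-walled carbon nanotubes (SWCNTs) perturb the
mitochondrial F0-ATPase: graph-topological descriptors of the nanotubes
feed linear Nano-QSTR toxicity models, while an anisotropic elastic
network of the receptor produces perturbation-response maps whose
geometric complexity is quantified by box-counting fractal dimensions.
This note records the models, the parameter choices that matter, the
numerical conventions, and what the synthetic-data generators do and do
not emulate.

## Nanotube graphs

A tube is specified by its Hamada (chiral) indices `(n, m)` — zigzag when
`m = 0`, armchair when `m = n`, chiral otherwise — plus a length in
translational unit cells and an optional carboxyl functionalization.
Indices are canonicalized to `n ≥ m`; a tube and its mirror enantiomer
`(m, n)` share one bond graph.

The graph is the quotient of the graphene honeycomb lattice by the
roll-up vector `C = n·a1 + m·a2`. Lattice sites are enumerated in exact
integer arithmetic (axial coordinate `t` along the translation vector
`T`, circumferential coordinate `c` along `C`), so membership in the
fundamental domain `c ∈ [0,1)`, `t ∈ [t0, t0 + n_cells)` is decided
without floating-point tolerance. One translational cell holds
`4(n² + nm + m²)/gcd(2n+m, 2m+n)` carbons (e.g. `4n` for armchair
`(n,n)`).

The axial cut offset `t0` matters: an arbitrary plane through the lattice
leaves singly-coordinated atoms at the open ends. The builder tries every
midpoint between consecutive atom layers (a finite, ordered candidate
set) and keeps the first cut in which every atom retains at least two
bonds; for chiral windings where no planar cut achieves this, the best
cut is taken and dangling atoms are pruned. Open tubes therefore always
have rim degree 2 and interior degree 3. Tubes are uncapped and
hydrogen-depleted; rim carbons carry one implicit hydrogen (sp²
convention), which only the E-state descriptor consumes.

Carboxylation attaches `-COOH` fragments (heavy atoms C, O, O; hydroxyl O
carries the implicit H) to rim carbons — by default two groups on the
rim pair at maximal graph distance (ties broken by lowest atom id),
mimicking tip oxidation of acid-treated tubes. Requests beyond the rim
capacity fail loudly.

Defaults: `n_cells = 3` for single-tube work (descriptor values depend on
tube length, so every output records the cell count used); the
whole-45-set computations in the pipeline and in the discrimination test
use `n_cells = 1`, which keeps the largest chiral tubes (hundreds of
atoms per cell) tractable while exercising identical code paths.

## Topological descriptors

* **GNar** — geometric mean of vertex degrees, computed as
  `exp(mean(log d_i))`. The raw Narumi index (the plain product of
  degrees) overflows beyond a few hundred atoms and could not produce
  coefficients on the scale of the published models; its logarithm is
  exposed as a secondary output. `GNar = d` exactly on d-regular graphs.
* **MAXDP** — maximal positive E-state variation. Kier–Hall intrinsic
  states `I = ((2/L)²·δv + 1)/δ` with principal quantum number `L`,
  valence electrons minus implicit hydrogens `δv`, and sigma degree `δ`;
  field perturbation `ΔI_i = Σ_j (I_i − I_j)/(d_ij + 1)^k` over all atom
  pairs with BFS topological distances `d_ij`, attenuation `k = 2`
  (configurable). `MAXDP = max(0, max_i ΔI_i)`; the `ΔI` are pairwise
  antisymmetric and sum to zero. Parameters are tabulated for C, N, O;
  other elements raise a descriptive error.
* **PW2–PW5** — Randić path/walk shape indices: per-atom ratio of
  self-avoiding path count to walk count of the same length (orders 2–5;
  order 1 is identically 1 and not offered), averaged over atoms. Walks
  come from sparse adjacency powers; paths from depth-limited DFS (order
  ≤ 5 bounds the recursion). Paths are a subset of walks, so the index
  lies in `[0, 1]`; atoms with no walk of the requested length contribute
  zero.
* **LOC** — lopping centric index: iteratively delete all degree ≤ 1
  vertices (one simultaneous sweep per step), record the class sizes
  `n_k`, count the never-pruned cyclic core as one final class, and
  return the Shannon entropy `−Σ (n_k/nSK)·log₂(n_k/nSK)` in bits. The
  entropy is non-negative by construction; classical lopping is defined
  for trees only, and treating the cyclic core as a terminal class is the
  natural extension (a pristine tube has no terminal vertices at all,
  hence `LOC = 0`).

All four are invariants of the abstract graph; tests verify them under
random atom relabelling.

## Nano-QSTR models

Two published linear models are shipped verbatim:

    f(FEB_1) = −8.24425·GNar + 0.614121·MAXDP − 2.87142      (pristine)
    f(FEB_2) = −1005.47·GNar − 1401.69·PW5 − 139.55·LOC − 2326.4  (carboxyl)

The 45-row observed/predicted tables behind them are packaged as CSV
fixtures with their printed train/validation split (34/11). The
statistics block (R², adjusted R², sums of squares, F, p) is rebuilt from
observed/predicted columns with `SS_model` about the mean of the observed
response and degrees of freedom `p` and `n − p − 1`; on the packaged
tables this reproduces every printed statistic to printed precision.
Because the original Dragon descriptor values for each tube are not
recoverable (the software's exact parameterization and tube geometry are
unknown), table reproduction works from the printed predictions;
refitting from descriptors computed here is a separate, clearly labelled
mode (`fit_ols`), backed by statsmodels OLS.

The 70/30 split rounds the training count half up in exact rational
arithmetic (45 rows → 32 training); an explicit assignment vector
reproduces the published 34/11 labels. The applicability domain is the
Williams construction: leverages from the hat matrix of the training
design, threshold `h* = 3(p+1)/n_train`, standardized residuals from the
training residual SD (ddof `p+1`), a row lying outside when `h > h*` or
`|standardized residual| > 3`. The printed p-value "0" is computed as the
F survival probability (≈10⁻¹²) and reported in full.

## Elastic network and perturbation response scanning

Nodes are receptor Cα atoms (or any coarse-grained selection); springs
follow either a hard cutoff (`H_ij = −(γ/s_ij²)·dd'` for `s_ij` below the
cutoff, with `d = r_j − r_i`) or a distance-weighted rule
(`−dd'/s^(p+2)`, default `p = 2`, all pairs). Diagonal super-elements are
the negative row sums, making the 3N×3N Hessian symmetric positive
semi-definite with exactly six rigid-body null modes when connected.
Defaults follow the published setup (`γ = 0.5`, cutoff 4 Å), but 4 Å is
far below the conventional Cα range — consecutive Cα sit near 3.8 Å, so
4 Å barely strings the chain together and real structures fragment. The
package warns on disconnection and documents 13 Å as the conventional
alternative (the pipeline default).

The covariance is the eigendecomposition pseudo-inverse excluding modes
below `10⁻⁸ ×` the largest eigenvalue; more than six excluded modes
triggers the disconnection warning but still returns a result.

Perturbation response scanning applies unit forces at each node i — the
three coordinate axes plus `n_forces` seeded random unit directions — and
records the response of node j as the root-mean-square over forces of
`‖C_ji·f‖`. RMS (not arithmetic-mean) aggregation is deliberate: over the
axes alone it equals `‖C_ji‖_F/√3`, which is exactly invariant under
rigid rotation of the structure, whereas a plain mean over a fixed frame
is not (measured deviation ~0.16 on a test helix). Ligand binding is
modelled by appending coarse-grained ligand nodes under the same spring
rule; receptor labels are preserved so the receptor submap can be
compared against the unbound control. A ligand with no receptor contact
provably leaves the receptor submap unchanged (decoupled blocks), which
is both warned about and tested.

Maps export as CSV plus min–max-scaled 8-bit grayscale PNG with a sidecar
JSON recording the scaling, seed and spring parameters.

## Fractal dimensions

Maps are thresholded (Otsu by default, or a fixed value; black = above
threshold = high perturbation; constant images are rejected). Three sets
are measured: the border (pixels with an opposite-colored 4-neighbor),
black∪border, and white∪border — the border set tracks interface
complexity, the unions the overall coverage. The published verbal
assignment of the two union dimensions to "white background"/"black
background" is ambiguous; this triple is the concrete reading that
reproduces the reported qualitative ordering (border ≈ 1.3–1.45, unions
≈ 1.85).

Box counting uses origin-anchored grids without offset averaging
(simplest reproducible convention; trailing partial boxes are counted),
box sizes defaulting to powers of 2 from 2 up to a quarter of the image
side, at least four sizes required. The dimension is the least-squares
slope of `log N(ε)` versus `log(1/ε)` with its r². Oracles: a pixel line
gives 1, a filled square 2 and the level-5 Sierpinski carpet
`log 8/log 3 ≈ 1.8928` with exact self-similar counts
`N(3^k) = 8^(5−k)`. The published per-complex FD values depend on the
authors' docking poses and image rendering and are not reproducible from
first principles; the known-dimension oracles take their place. Matrices
smaller than ~128 px are upsampled nearest-neighbour before analysis in
the pipeline (upsampling shifts slopes by < 0.05, which is tested).

## Synthetic data

The generators provide every input without downloads, as pure functions
of `(config, seed)`:

* **Helix receptor** — ideal α-helix Cα trace (rise 1.5 Å, radius 2.3 Å,
  twist 100°/residue: canonical values), consecutive Cα distance
  `√(rise² + (2r·sin(twist/2))²) ≈ 3.83 Å`, serialized as a valid
  poly-alanine PDB. The spacing deliberately straddles the two cutoff
  regimes: connected at 13 Å and at the published 4 Å, disconnected just
  below (3.5 Å), exercising the warning path.
* **Ligand blobs** — seeded uniform points in a 3 Å sphere, a stand-in
  for coarse-grained docked ligands.
* **Fractal images** — line, filled square, Sierpinski carpet with
  closed-form dimensions; the carpet sits between the reported border
  (~1.45) and union (~1.85) values, making it a discriminating oracle.
* **QSTR datasets** — descriptors drawn uniformly from realistic ranges
  (GNar ∈ [1,3], MAXDP ∈ [0,30], PW5 ∈ [0,1], LOC ∈ [0,4]), response a
  known linear combination plus Gaussian noise (default n = 45 rows
  matching the study set, σ = 0.5); the generating coefficients ride
  along for recovery tests.

What passing tests on these synthetics do **not** show: real receptor
topology (the F0 c-ring is a multi-chain β/α assembly, not a single
helix), real docking poses, real Dragon descriptor values, or
experimental inhibition responses. They establish that the machinery is
correct (exact oracles, invariances, calibration), not that the published
per-structure numbers re-emerge from scratch.

## Numerical choices and limitations

* Lattice membership, split rounding: exact rational arithmetic.
* Zero-mode threshold: relative `10⁻⁸`; eigendecomposition via `eigh`.
* Degenerate inputs rejected with typed errors: empty graphs, coincident
  ENM nodes, constant images/responses, rank-deficient designs,
  over-capacity carboxylation.
* Estimator calibration (3-standard-error coverage of true coefficients
  over 500 seeded replicates) is assessed per coefficient; the expected
  per-coefficient coverage is ≈99.7%.
* Descriptor values for the authors' specific tubes are unknowable
  (their software parameterization is unstated), so model *refits* from
  computed descriptors will not reproduce the printed coefficients; only
  the printed tables' internal statistics are reproducible, and are.
* Runtime-relevant problem sizes, chosen as package defaults: 20-residue
  helices for ENM property checks, level-5 carpet (243²) for fractal
  oracles, 1-cell tubes for whole-set descriptor sweeps, 500 replicates
  for calibration.
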