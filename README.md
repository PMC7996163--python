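# mitotox

Computational nanotoxicity modelling of carbon-nanotube inhibition of the
mitochondrial F0-ATPase (the oligomycin-sensitive c-ring of ATP
synthase). The package is aimed at computational toxicologists and
structural bioinformaticians who want a tested, scriptable version of the
full modelling chain:

1. **Nanotube graphs** — finite single-walled carbon nanotubes built from
   Hamada indices `(n, m)` (zigzag `m = 0`, armchair `m = n`, chiral
   otherwise), pristine or tip-carboxylated, as hydrogen-depleted
   molecular graphs.
2. **Topological descriptors** — Narumi geometric index (GNar), maximal
   positive E-state variation (MAXDP), Randić path/walk shape indices
   (PW2–PW5) and the lopping centric index (LOC).
3. **Nano-QSTR models** — the two published linear toxicity models

       f(FEB_1) = −8.24425·GNar + 0.614121·MAXDP − 2.87142
       f(FEB_2) = −1005.47·GNar − 1401.69·PW5 − 139.55·LOC − 2326.4

   with their 45-tube datasets, training/validation split, full
   regression statistics blocks and a leverage-based (Williams)
   applicability domain.
4. **Elastic network + perturbation response scanning** — anisotropic
   3N×3N Hessians over Cα networks (`H_ij = −(γ/s²)·(r_j−r_i)(r_j−r_i)ᵀ`
   under a cutoff, or distance-weighted `−dd'/s^(p+2)`), pseudo-inverse
   covariances, and N×N local perturbation-response (LPRS) maps for
   unbound versus ligand-bound receptor states.
5. **Fractal analysis** — box-counting dimensions of the binarized maps
   (border, black∪border, white∪border), the slope of `log N(ε)` against
   `log(1/ε)`.
6. **Synthetic data** — seeded generators for ideal helix receptors,
   ligand blobs, known-dimension fractal images and linear-model QSTR
   datasets, so everything runs without downloads.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
from mitotox import NanotubeSpec, build_nanotube_graph, compute_descriptors, pristine_model
from mitotox.qstr import load_published_dataset, report_for_subset

spec = NanotubeSpec(8, 0, n_cells=3)          # zigzag tube, three unit cells
graph = build_nanotube_graph(spec)
desc = compute_descriptors(graph)
print(f"{spec.category} ({spec.n},{spec.m}) x{spec.n_cells}: {graph.nsk} heavy atoms")
print({k: round(v, 4) for k, v in desc.as_dict().items()})
print("f(FEB_1) =", round(pristine_model().predict(desc), 4))

rep = report_for_subset(load_published_dataset("pristine"), "training", 2)
print(f"R2={rep.r_squared:.6f}  adjR2={rep.adjusted_r_squared:.6f}  "
      f"F={rep.f_statistic:.5f}  MSEres={rep.mse_residual:.6f}")
```

prints

```
zigzag (8,0) x3: 96 heavy atoms
{'GNar': 2.804, 'MAXDP': 0.7225, 'PW5': 0.1838, 'LOC': 0.0}
f(FEB_1) = -25.5443
R2=0.830731  adjR2=0.819811  F=76.07038  MSEres=0.510725
```

The (8,0) tube — the geometry used for the docking ligands — has 96
heavy atoms over three cells, a degree geometric mean of 2.80 (between
the rim's 2 and the interior's 3), a small positive E-state variation
from the rim CH carbons and zero centric entropy (a tube has no terminal
vertices to prune). Feeding the descriptors to the pristine model gives
its toxicity-scale response. The last line rebuilds the pristine model's
statistics block from the packaged 34 training rows of the published
observed/predicted table: every statistic matches the printed values
(R² 0.830731, F 76.07035, ...) to printed precision. Note that descriptor
values depend on tube length (`n_cells`) and on the original software's
parameterization, so predictions from descriptors computed here are on
the models' scale but are not the authors' per-tube values.

The same stages are scriptable from a shell:

```sh
mitotox build-nanotube --n 8 --m 0 --cells 3 --out tube.json
mitotox descriptors --graph tube.json --out tube_desc.csv
mitotox simulate helix --seed 7 --n-residues 30 --out sim/
mitotox enm-prs --pdb sim/helix.pdb --cutoff 13 --seed 7 --out maps/
mitotox fractal --map maps/lprs_unbound.png --out fd.json
mitotox run --out runs/demo --seed 7      # tables + full synthetic pipeline
```

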