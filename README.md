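# sesnet

Neural level-set construction of solvent-excluded molecular surfaces (SES)
from atom point clouds.

The SES — the boundary of the region a 1.4 Å water probe cannot reach while
rolling over a molecule's van der Waals spheres — is the standard dielectric
boundary of implicit-solvent electrostatics. Classical constructions are
geometric and expensive; `sesnet` instead treats the surface implicitly
through a level-set field y(g) on a 3D lattice (positive outside the solute,
negative inside, surface at the zero crossing) and trains a small neural
network to predict y at any grid point from its local atomic environment.
The package is aimed at researchers in molecular modelling who want a
self-contained, reproducible sandbox for this class of method: oracle
labeling, feature extraction, training, surface extraction and evaluation are
all first-class, scriptable pieces.

## The method

For a molecule A = {(a_i, r_i)} and grid point g, the feature vector stacks
the k = 24 nearest atoms as (a_j − g, r_j) slots sorted by distance — 96
numbers that are exactly translation invariant and carry no dependence on the
grid spacing s. A three-layer MLP ϕ(x; θ) (96–64–32–1, ReLU) is fit by
mini-batch gradient descent to ground-truth level-set values

- labeled by a classical two-pass rolling-probe scheme on the lattice:
  points within `r_atom + r_probe` of an atom are solvent-inaccessible;
  those re-covered by a probe centered at an accessible point are carved
  back out (reentrant regions); the rest form the SES interior;
- with magnitude = clamped signed Euclidean distance to the opposite region.

The surface ∂Ω is read out by linear interpolation along grid edges where
y changes sign. Agreement between surfaces is scored with the symmetric-mean
Chamfer Distance (CD, Å, lower is better) and the F-score at a 0.15 Å hit
radius (1 is perfect); field regression quality with R² and MAE. Because the
features never see the lattice constant, one trained model can be evaluated
at any spacing — grid robustness is the method's selling point.

## Worked example

`examples/01_oracle_surface.py` labels a two-atom molecule whose crevice a
water probe cannot enter:

```
grid: (56, 47, 47) = 123704 points at 0.35 Å
interior grid points: 1201
surface samples extracted at the zero crossing: 920
level-set value midway between the atoms: -1.00 Å
negative midpoint value = the crevice is probe-inaccessible (reentrant SES)
```

The midpoint between the atoms lies outside both van der Waals spheres, yet
its level-set value is negative: the probe cannot reach it, so it belongs to
the SES interior — the reentrant geometry that makes the SES harder than a
union of spheres.

`examples/04_end_to_end_pipeline.py` trains on 8 synthetic cluster molecules
and evaluates 2 held-out ones (a scaled-down protocol, ~1 minute):

```
held-out means: {
  "cd": 0.2418945008485642,
  "f": 0.3018300549290414,
  "mae": 0.027985441003394625,
  "r2": 0.9361474038711224,
  ...
}
s = 0.55 Å: CD = 0.245 Å, F(0.15) = 0.299
s = 0.95 Å: CD = 0.269 Å, F(0.15) = 0.314
CD degradation across spacings: 9.7 %
```

Held-out R² ≈ 0.94 says the network predicts level-set values it never saw;
the nearly flat CD across spacings shows the same model transferring between
lattices. The full protocol (20 training molecules, longer training; see
below) reaches held-out R² ≈ 0.99 and F(0.15) ≈ 0.72.

Other examples: `02_features_and_model.py` (feature construction and network
capacity), `03_surface_metrics.py` (CD vs F-score behavior under different
sampling densities).

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
sesnet synth --preset cluster --n-atoms 40 --seed 1 --out mol.pqr
sesnet label --pqr mol.pqr --spacing 0.55 --resolution 0.3 --out field.dx
sesnet surface --field field.dx --out surf.xyz
sesnet eval --pred surf.xyz --ref ref.xyz --radius 0.15 --json report.json
```

plus `featurize`, `train`, `predict`, `sweep` and `demo`. Molecules are read
from PQR (radii from the file) or PDB (radii from a Bondi-style table);
fields are OpenDX scalar grids; surfaces are XYZ or ASCII PLY point clouds.

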