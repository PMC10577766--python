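"""Train a small level-set regressor on one molecule and check its fit.

Each grid point is described by its 24 nearest atoms — displacement vector and
radius per neighbor, 96 numbers — and a 96-64-32-1 network regresses the
signed clamped distance to the SES. Here the network just overfits a single
labeled molecule, which verifies capacity rather than generalization.
"""

import sesnet as sn
from sesnet import model as mdl

mol = sn.generate_synthetic("cluster", n_atoms=12, seed=7)
grid = sn.make_grid(mol, spacing=0.5)
field = sn.label_level_set(mol, grid, sn.ProbeParams(1.4))

feats, y = sn.feature_dataset(field, mol, k=24, subsample=2000, seed=0, balanced=True)
print(f"dataset: {feats.rows.shape[0]} samples × {feats.d} features")

config = mdl.TrainingConfig(
    learning_rate=3e-3, epochs=400, batch_size=256, optimizer="adam",
    validation_fraction=0.0, seed=0,
)
params, history = sn.train(sn.init_model(64, 32, seed=0), (feats, y), config)

y_hat = sn.forward(params, feats)
print(f"network parameters: {params.n_parameters}")
print(f"final training MSE: {history.train_loss[-1]:.2e}")
print(f"R² on the fitted points: {sn.r_squared(y, y_hat):.4f}")
print(f"MAE on the fitted points: {sn.mae(y, y_hat):.4f} Å")
print("R² near 1 and MAE well below the 0.5 Å grid spacing = the map is learnable")
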