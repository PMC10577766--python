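"""Score the agreement of two surface point clouds with Chamfer Distance and F-score.

The oracle SES of a helix is extracted at two grid spacings; both are labeled
through the same fine internal lattice, so they sample one underlying surface
at different densities. The example also shows how the two metrics react
differently to sampling density: Chamfer Distance averages nearest-neighbor
distances and stays small, while the F-score at a 0.15 Å hit radius drops as
soon as one cloud is sampled more coarsely than the hit radius.
"""

import sesnet as sn

mol = sn.generate_synthetic("helix", n_atoms=9, seed=0)

clouds = {}
for s in (0.35, 0.75):
    grid = sn.make_grid(mol, spacing=s)
    field = sn.label_level_set(mol, grid, sn.ProbeParams(1.4), resolution=0.3)
    clouds[s] = sn.extract_surface(field)
    print(f"s = {s} Å: {clouds[s].n_points} surface points")

cd = sn.chamfer(clouds[0.75], clouds[0.35])
f, pr, rc = sn.fscore(clouds[0.75], clouds[0.35], r=0.15)
print(f"Chamfer Distance between the two samplings: {cd:.4f} Å")
print(f"F-score at 0.15 Å hit radius: {f:.3f} (precision {pr:.3f}, recall {rc:.3f})")
print("CD stays well below the coarse spacing: both grids trace one surface;")
print("recall is low because a 0.75 Å sampling leaves gaps wider than the 0.15 Å")
print("hit radius — comparisons at a fixed radius should use like-for-like grids")
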