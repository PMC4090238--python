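"""Out-of-jurisdiction origin-risk map for a target region.

Runs the full pipeline on the 'mixed' fixture scenario: synthetic trips
-> segment table -> transition model -> phi simulation -> per-external-
cell summed risk into the target polygon, with hotspot classification.
"""

import json
import tempfile
from pathlib import Path

from campnet import (
    GridSpec,
    Jurisdiction,
    SeasonModel,
    build_travel_matrix,
    classify_risk,
    estimate_phi,
    jurisdiction_origin_risk,
    make_fixture,
    preprocess,
    read_trips,
    scale_to_transition,
)

with tempfile.TemporaryDirectory() as tmp:
    paths = make_fixture("mixed", seed=11, out_dir=tmp)
    trips = read_trips(paths["trips"])
    grid = GridSpec.from_json(Path(paths["grid"]).read_text())
    table = preprocess(trips, grid, season=SeasonModel())
    model = scale_to_transition(build_travel_matrix(table))
    risk = estimate_phi(model, sims_per_origin=5000, seed=11)
    target = Jurisdiction.from_polygon(
        "target", json.loads(Path(paths["target"]).read_text()), grid, risk.nodes
    )
    risk_map = classify_risk(jurisdiction_origin_risk(risk, target))

print(f"external origin cells with risk: {len(risk_map.values)}")
n_hot = sum(1 for v in risk_map.labels.values() if v == "moderate-high")
print(f"moderate-high hotspots (phi > 1e-4): {n_hot}")
print("top 5 origin cells (cell id, summed phi):")
for cell, v in list(risk_map.values.items())[:5]:
    lon, lat = grid.cell_center(cell)
    print(f"  {cell}  ({float(lon[0]):7.2f}, {float(lat[0]):5.2f})  {v:.4f}")
# Each value is the summed phi from one external 15 km cell into all cells of
# the target region: the relative chance that camper travel carries a pest
# from that cell into the jurisdiction.
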