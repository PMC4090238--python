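import numpy as np
import pytest

from campnet import SegmentTable, build_travel_matrix, scale_to_transition


def random_network(rng: np.random.Generator, n_nodes: int, edge_prob: float = 0.12):
    """Random sparse directed travel table with lognormal weights."""
    entries = {}
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < edge_prob:
                entries[(i, j)] = float(rng.lognormal(1.0, 1.0))
    if not entries:  # guarantee at least one segment
        entries[(0, 1 % n_nodes or 1)] = 1.0
    return SegmentTable(entries)


@pytest.fixture(scope="session")
def chain_model():
    """Three-cell chain 1→2→3 with p = 0.5 on each link."""
    table = SegmentTable({(1, 2): 1.0, (2, 3): 1.0})
    return scale_to_transition(build_travel_matrix(table), safety=0.5)


@pytest.fixture(scope="session")
def fixture_bundles(tmp_path_factory):
    """One generated bundle per scenario, shared across tests."""
    from campnet import make_fixture

    root = tmp_path_factory.mktemp("bundles")
    return {
        sc: make_fixture(sc, seed=11, out_dir=root / sc)
        for sc in ("two_state_local", "hub_and_spoke_distant", "mixed")
    }


@pytest.fixture(scope="session")
def pipeline_results(fixture_bundles):
    """Full preprocess→simulate→summarise run for every scenario bundle."""
    import json
    from pathlib import Path

    from campnet import (
        GridSpec,
        Jurisdiction,
        SeasonModel,
        classify_risk,
        estimate_phi,
        jurisdiction_origin_risk,
        preprocess,
        read_trips,
    )

    out = {}
    for sc, paths in fixture_bundles.items():
        trips = read_trips(paths["trips"])
        grid = GridSpec.from_json(Path(paths["grid"]).read_text())
        meta = json.loads(Path(paths["meta"]).read_text())
        table = preprocess(trips, grid, season=SeasonModel())
        model = scale_to_transition(build_travel_matrix(table))
        risk = estimate_phi(model, sims_per_origin=5000, seed=11)
        jur = Jurisdiction.from_polygon(
            "target", json.loads(Path(paths["target"]).read_text()), grid, risk.nodes
        )
        risk_map = classify_risk(jurisdiction_origin_risk(risk, jur))
        out[sc] = {
            "grid": grid,
            "meta": meta,
            "model": model,
            "risk": risk,
            "jurisdiction": jur,
            "risk_map": risk_map,
        }
    return out
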