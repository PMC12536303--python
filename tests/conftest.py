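"""Shared fixtures: small phantoms reused across test modules.

All randomness is seeded through the phantom specs, so every fixture is
deterministic; heavyweight phantom chains are session-scoped.
"""
import numpy as np
import pytest
from hypothesis import settings

import octamorph as om

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

LX = 5000.0 / 128.0  # default lateral pixel pitch, µm


def four_tube_vessels():
    """Four straight tubes along the fast axis with half-integer pixel radii
    (footprints 7, 5, 7, 5 rows -> exact ground-truth widths)."""
    return [
        om.straight_vessel((0, 10, 120), (127, 10, 120), radius_um=3.5 * LX),
        om.straight_vessel((0, 26, 140), (127, 26, 140), radius_um=2.5 * LX),
        om.straight_vessel((0, 42, 110), (127, 42, 110), radius_um=3.5 * LX),
        om.straight_vessel((0, 56, 150), (127, 56, 150), radius_um=2.5 * LX),
    ]


@pytest.fixture(scope="session")
def vessel_spec():
    return om.PhantomSpec(seed=5, vessels=four_tube_vessels())


@pytest.fixture(scope="session")
def vessel_chain(vessel_spec):
    """Full angiography chain on the standard vessel phantom."""
    series = om.generate_speckle_frames(vessel_spec)
    truth = om.ground_truth(vessel_spec)
    volume = om.assemble_volume(series)
    angiogram = om.enface_mip(volume, (40, vessel_spec.n_depth))
    return {"spec": vessel_spec, "series": series, "truth": truth,
            "volume": volume, "angiogram": angiogram}


@pytest.fixture(scope="session")
def flat_layer_bscan():
    """Mean B-scan + ground truth of a default two-layer phantom (seed 11)."""
    spec = om.PhantomSpec(n_positions=4, seed=11)
    series = om.generate_speckle_frames(spec)
    truth = om.ground_truth(spec)
    y = series.n_positions // 2
    return {"spec": spec, "bscan": series.mean_bscan(y),
            "surface_true": truth.surface_z[y], "dej_true": truth.dej_z[y]}


@pytest.fixture()
def three_site_config(tmp_path):
    """Pipeline config for a three-site phantom subject (dict form)."""
    def site(thickness, contrast=1.0, vessels=None):
        entry = {
            "n_positions": 32,
            "epithelium_thickness_um": thickness,
            "dej_contrast": contrast,
        }
        if vessels:
            entry["vessels"] = vessels
        return {"phantom": entry}

    tube = lambda y, z, r: {"line": {"start": [0, y, z], "end": [127, y, z]},
                            "radius_um": r}
    vessels = [tube(8, 120, 3.5 * LX), tube(22, 140, 2.5 * LX)]
    return {
        "subject_id": "phantom-A",
        "group": "control",
        "seed": 77,
        "sites": {
            "labia_majora": site(300.0, vessels=vessels),
            "interlabial_sulci": site(200.0, vessels=vessels),
            "labia_minora": site(120.0, vessels=vessels),
        },
        "report": {"outdir": str(tmp_path / "out")},
    }
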