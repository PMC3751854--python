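import numpy as np
import pandas as pd
import pytest

from t2plaque import phantom as ph
from t2plaque import segmentation as seg

# Inter-reader AHA plaque-type cross-classification of 37 carotid arteries
# (rows: multicontrast CMR; columns: T2 maps + TOF).
TABLE1 = np.array([
    [10, 4, 0, 0, 0, 0],
    [1, 6, 0, 0, 0, 0],
    [0, 1, 7, 1, 0, 1],
    [0, 0, 0, 2, 0, 0],
    [0, 0, 1, 0, 2, 0],
    [0, 0, 0, 0, 0, 1],
])


@pytest.fixture(scope="session")
def table1():
    from t2plaque.stats import AgreementTable, AHA_CATEGORIES

    return AgreementTable(categories=AHA_CATEGORIES, counts=TABLE1.copy())


@pytest.fixture(scope="session")
def small_spec():
    """Compact noisy phantom used across modules (fast to fit)."""
    return ph.PhantomSpec(
        grid_shape=(48, 48),
        lumen_center=(24.0, 24.0),
        lumen_radius_px=6.0,
        wall_thickness_px=5.0,
        component_blobs=[
            ("lrnc", (24.0, 32.5), 2.0),
            ("recent_iph", (15.5, 24.0), 1.8),
            ("calcification", (24.0, 15.5), 1.6),
        ],
        muscle_center=(40.0, 40.0),
        muscle_radius_px=5.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    """(phantom, noisy stack, te) for the compact spec."""
    p = ph.build_phantom(small_spec)
    stack, te = ph.simulate_series(p, small_spec)
    return p, stack, te


@pytest.fixture(scope="session")
def noisefree_bundle(small_spec):
    import dataclasses

    spec = dataclasses.replace(small_spec, noise_sd=0.0)
    p = ph.build_phantom(spec)
    stack, te = ph.simulate_series(p, spec)
    return p, stack, te


@pytest.fixture(scope="session")
def default_model():
    """Class model at the in-vivo per-class T2 parameters."""
    return seg.ClassModel()


@pytest.fixture()
def training_table():
    rng = np.random.default_rng(314)
    rows = []
    for cls, (m, s) in dict(lrnc=(37, 5), fibrous=(56, 9), recent_iph=(107, 25)).items():
        for v in rng.normal(m, s, 100):
            rows.append(dict(class_label=cls, t2_ms=max(v, 1.0)))
    return pd.DataFrame(rows)
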