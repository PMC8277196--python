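import numpy as np
import pytest

from punctakit import AcquisitionParams, TruthSpec, generate_cell


@pytest.fixture
def noiseless_acq():
    return AcquisitionParams(noise_model="none")


@pytest.fixture(scope="session")
def noiseless_cell():
    """One default noiseless cell shared across read-only tests."""
    acq = AcquisitionParams(noise_model="none")
    stack, truth = generate_cell(TruthSpec(), acq, seed=11)
    return stack, truth, acq


def match_planted(truth, table, tol_um: float = 1.0):
    """Pair planted puncta with detected rows by nearest centroid.

    Returns a list of (record, row) for every planted punctum whose
    nearest detection lies within ``tol_um``.
    """
    det = table.df[["centroid_x_um", "centroid_y_um"]].to_numpy()
    out = []
    for p in truth.puncta:
        if det.size == 0:
            continue
        d = np.hypot(det[:, 0] - p.centroid_um[0], det[:, 1] - p.centroid_um[1])
        i = int(d.argmin())
        if d[i] < tol_um:
            out.append((p, table.df.iloc[i]))
    return out
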