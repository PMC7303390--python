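import numpy as np
import pytest

from connfp.connectomes import ConnMatrix, ParcelWeightField, StreamlineSet, devectorize_edges


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture
def hand_streamlines():
    """Hand-computable SC fixture: 3 streamlines, 3 single-voxel parcels.

    Endpoint parcel pairs are (1,2), (1,2), (1,3) with lengths 10, 20,
    30 and constant QA 0.5, so the aggregates are NS(1,2)=2, NS(1,3)=1,
    ML(1,2)=(10+20)/2=15, ML(1,3)=30, QA=0.5 on every connected edge.
    Returns (StreamlineSet, ParcelWeightField).
    """
    polys = [
        np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),                  # 1-2, len 10
        np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 0.0], [10.0, 0.0, 0.0]]),  # 1-2, detour
        np.array([[0.0, 0.0, 0.0], [0.0, 30.0, 0.0]]),                  # 1-3, len 30
    ]
    # stretch the detour so the second streamline's length is exactly 20
    h = np.sqrt(10.0 ** 2 - 5.0 ** 2)  # 2*sqrt(5^2+h^2) = 20
    polys[1][1] = [5.0, h, 0.0]
    qa = [np.full(len(p), 0.5) for p in polys]
    labels = np.zeros((12, 32, 2), dtype=int)
    labels[0, 0, 0] = 1
    labels[10, 0, 0] = 2
    labels[0, 30, 0] = 3
    field = ParcelWeightField.from_labels(labels, voxel_size=1.0)
    return StreamlineSet(polys, qa), field


@pytest.fixture
def matrix_from_edges():
    def _make(vec, n, labels=None, kind="FCz"):
        labels = labels or [f"P{i + 1}" for i in range(n)]
        return ConnMatrix(devectorize_edges(np.asarray(vec, float), n), labels, kind)
    return _make
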