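import numpy as np
import pytest

import negmar as nm


@pytest.fixture(scope="session")
def tiny_geom() -> nm.ScanGeometry:
    """Small geometry for dense-matrix oracles."""
    return nm.ScanGeometry(
        n_views=12, n_bins=24, bin_spacing=1.0, n_pixels=16, pixel_spacing=1.0
    )


@pytest.fixture(scope="session")
def test_geom() -> nm.ScanGeometry:
    return nm.make_test_preset()


@pytest.fixture(scope="session")
def demo_case(test_geom):
    """Seeded beam-hardened phantom shared across tests."""
    sino, truth, metal = nm.make_demo_case(7)
    raw = nm.fbp(sino, test_geom)
    return {"sino": sino, "truth": truth, "metal": metal, "raw": raw}


@pytest.fixture(scope="session")
def mar_run(demo_case, test_geom):
    """One full MAR run at the default protocol (beta 1, 500 iterations)."""
    result, raw = nm.reconstruct_mar(demo_case["sino"], test_geom, nm.MarConfig())
    return {"result": result, "raw": raw}


def dense_matrix(op, in_shape, out_shape):
    """Materialize a linear operator column by column (basis-vector probe)."""
    n_in = int(np.prod(in_shape))
    n_out = int(np.prod(out_shape))
    mat = np.empty((n_out, n_in))
    basis = np.zeros(in_shape)
    flat = basis.ravel()
    for j in range(n_in):
        flat[j] = 1.0
        mat[:, j] = op(basis).ravel()
        flat[j] = 0.0
    return mat
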