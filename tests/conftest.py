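import numpy as np
import pytest
import scipy.sparse as sp

from tmezone import synthetic
from tmezone.model import CellTable, PanelGenes


@pytest.fixture(scope="session")
def small_tissue():
    """A compact tissue: one 120 µm nest in a 400 µm field, 3000 cells."""
    spec = synthetic.TissueSpec(
        field_size=(400.0, 400.0),
        n_cells=3000,
        nests=(synthetic.Nest(200.0, 200.0, 120.0),),
        seed=11,
    )
    return synthetic.generate_tissue(spec)


@pytest.fixture()
def tiny_table():
    """Four hand-placed cells over a 3-gene panel."""
    genes = PanelGenes(("GA", "GB", "GC"))
    counts = sp.csr_matrix(
        np.array([[2, 0, 1], [0, 3, 0], [10, 0, 0], [0, 0, 0]])
    )
    return CellTable(
        cell_ids=["c1", "c2", "c3", "c4"],
        x=np.array([5.0, 15.0, 5.0, 95.0]),
        y=np.array([5.0, 5.0, 95.0, 95.0]),
        area=np.array([100.0, 50.0, 100.0, 80.0]),
        counts=counts,
        genes=genes,
    )


def random_blob_mask(rng: np.random.Generator, ny: int, nx: int) -> np.ndarray:
    """Random connected-ish blob mask with at least one true cell."""
    n_seeds = rng.integers(1, 4)
    mask = np.zeros((ny, nx), dtype=bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for _ in range(n_seeds):
        cy, cx = rng.integers(0, ny), rng.integers(0, nx)
        r = rng.integers(2, max(3, min(ny, nx) // 3))
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    # roughen the boundary
    noise = rng.random((ny, nx)) < 0.05
    mask ^= noise & mask
    if not mask.any():
        mask[ny // 2, nx // 2] = True
    return mask
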