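import numpy as np
import pytest

import spotpower as spw


@pytest.fixture(scope="session")
def small_dataset():
    """Two-condition simulated dataset, 60 genes with a 1-log2FC DEG block."""
    design = spw.SimulationDesign(
        n_genes=60,
        n_slices_per_condition=2,
        spots_per_slice=40,
        baseline_mean=2.0,
        dispersion=2.0,
        de_fraction=0.2,
        logfc_values=1.0,
        seed=42,
    )
    return design, spw.simulate_dataset(design)


@pytest.fixture(scope="session")
def monotone_records():
    """Synthetic power records from a known monotone truth pi * tanh(beta)."""
    rng = np.random.default_rng(0)
    n = 500
    pi = rng.uniform(0.02, 0.6, n)
    beta = rng.uniform(0.0, 3.0, n)
    y = np.clip(pi * np.tanh(beta) + rng.normal(0, 0.02, n), 0.0, 1.0)
    return pi, beta, y


@pytest.fixture
def toy_visium_dir(tmp_path):
    """Hand-written 3-gene x 4-spot Space Ranger text fixture."""
    (tmp_path / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n"
        "3 4 6\n"
        "1 1 5\n1 2 1\n2 2 3\n2 4 2\n3 3 7\n3 4 1\n"
    )
    (tmp_path / "features.tsv").write_text(
        "ENSG01\tGeneA\nENSG02\tGeneB\nENSG03\tGeneC\n"
    )
    (tmp_path / "barcodes.tsv").write_text("AAAC-1\nAAAG-1\nAACT-1\nAATC-1\n")
    (tmp_path / "tissue_positions.csv").write_text(
        "barcode,in_tissue,array_row,array_col,pxl_row,pxl_col\n"
        "AAAC-1,1,0,0,10.0,20.0\n"
        "AAAG-1,1,0,1,10.0,120.0\n"
        "AACT-1,1,1,0,96.0,70.0\n"
        "AATC-1,1,1,1,96.0,170.0\n"
    )
    return tmp_path
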