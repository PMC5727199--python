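import numpy as np
import pandas as pd
import pytest

from tubahdr.design import BarcodeDesign, CodonUsageTable
from tubahdr.simulate import PlasmidPool, simulate_plasmid_pool


@pytest.fixture(scope="session")
def design() -> BarcodeDesign:
    return BarcodeDesign()


@pytest.fixture(scope="session")
def uniform_table() -> CodonUsageTable:
    return CodonUsageTable.uniform()


@pytest.fixture(scope="session")
def fixture_table() -> CodonUsageTable:
    from importlib.resources import files

    return CodonUsageTable.from_tsv(
        files("tubahdr.data") / "synthetic_codon_usage.tsv")


@pytest.fixture(scope="session")
def pool(design) -> PlasmidPool:
    """A medium-depth simulated plasmid pool shared across tests."""
    return simulate_plasmid_pool(design, depth=300_000, seed=11)


@pytest.fixture(scope="session")
def uniform_pool(design) -> PlasmidPool:
    """One read of every (variant, barcode): exactly uniform representation,
    with WT given 4 reads per barcode to honor the 4x pool construction."""
    barcodes = list(design.iter_barcodes())
    frames = []
    from tubahdr.design import enumerate_variants

    for v in ["WT"] + enumerate_variants():
        frames.append(pd.DataFrame({
            "variant": v, "barcode": barcodes,
            "reads": 4 if v == "WT" else 1}))
    return PlasmidPool(pd.concat(frames, ignore_index=True))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
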