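import numpy as np
import pytest

from mangonir.data import LabeledDataset, ReferenceRecord, Spectrum, WavelengthGrid
from mangonir.synthetic import (
    CLASS_SUMMARY,
    GeneratorConfig,
    SpectralForwardModel,
    generate_dataset,
)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def class_means():
    """Published per-class mean parameter quadruples."""
    return {
        cls: {name: stats[2] for name, stats in params.items()}
        for cls, params in CLASS_SUMMARY.items()
    }


@pytest.fixture(scope="session")
def small_dataset():
    """Low-noise synthetic dataset, 12 scans per class."""
    return generate_dataset(GeneratorConfig(n_per_class=12, seed=11))


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate_dataset(
        GeneratorConfig(n_per_class=12, seed=5),
        forward_model=SpectralForwardModel.noiseless(),
    )


@pytest.fixture
def tiny_dataset(grid):
    """Three handcrafted scans with reference records, for I/O tests."""
    rng = np.random.default_rng(0)
    spectra, refs = [], []
    for i, cls in enumerate((80, 90, 100)):
        spectra.append(Spectrum(f"m{i}", i % 4 + 1, rng.uniform(0.2, 1.0, len(grid))))
        refs.append(
            ReferenceRecord(
                sample_id=f"m{i}",
                location=i % 4 + 1,
                TA=1.0,
                SSC=10.0,
                firmness=3.0,
                starch=5.0,
                maturity=cls,
            )
        )
    return LabeledDataset(grid=grid, spectra=spectra, references=refs)
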