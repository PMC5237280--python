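import numpy as np
import pytest

from strokemrs.core import Cohort, SpectrumRecord, default_axis


def make_record(
    intensities,
    spectrum_id="s1",
    animal_id="1",
    label="non_infarcted",
    region="non_infarcted",
    phase="healthy",
    split="unassigned",
    normalized=False,
    axis=None,
):
    intensities = np.asarray(intensities, dtype=float)
    if axis is None:
        axis = default_axis(intensities.size)
    return SpectrumRecord(
        animal_id=animal_id,
        spectrum_id=spectrum_id,
        region=region,
        phase=phase,
        label=label,
        split=split,
        ppm_axis=axis,
        intensities=intensities,
        normalized=normalized,
    )


def make_matrix_cohort(X, y, splits=None, normalized=True, animal_ids=None):
    """Wrap a data matrix as a Cohort (one animal per row by default)."""
    X = np.asarray(X, dtype=float)
    axis = default_axis(X.shape[1])
    records = []
    labels = list(dict.fromkeys(y))
    for i, (row, lab) in enumerate(zip(X, y)):
        records.append(
            make_record(
                row,
                spectrum_id=f"s{i}",
                animal_id=str(i + 1) if animal_ids is None else str(animal_ids[i]),
                label=lab,
                region="non_infarcted",
                phase="healthy",
                split="unassigned" if splits is None else splits[i],
                normalized=normalized,
                axis=axis,
            )
        )
    cmap = {r.spectrum_id: r.spectrum_id for r in records}
    return Cohort(records, labels, cmap)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gaussian_blobs():
    """Three well-separated spherical Gaussian classes in 4 dimensions."""
    r = np.random.default_rng(7)
    centers = np.array(
        [[0.0, 0.0, 0.0, 0.0], [8.0, 8.0, 0.0, 0.0], [0.0, 8.0, 8.0, 0.0]]
    )
    X = np.vstack([c + r.normal(0, 0.5, size=(20, 4)) for c in centers])
    y = np.repeat(["a", "b", "c"], 20)
    return X, y
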