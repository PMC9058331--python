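import numpy as np
import pandas as pd
import pytest

from irhisto.core import Pathology, SpectraTable, TissueClass, WavenumberAxis
from irhisto.synthetic import DEFAULT_AXIS


@pytest.fixture
def axis() -> WavenumberAxis:
    return DEFAULT_AXIS


def make_table(
    spectra: np.ndarray,
    axis: WavenumberAxis = DEFAULT_AXIS,
    sample_id="s0",
    pathology=Pathology.NORMAL,
    tissue_class=TissueClass.BACKGROUND,
    rows=None,
    cols=None,
) -> SpectraTable:
    """Build a SpectraTable around a spectra matrix with simple metadata."""
    spectra = np.atleast_2d(spectra)
    n = spectra.shape[0]
    width = max(1, int(np.ceil(np.sqrt(n))))
    if rows is None:
        rows = np.arange(n) // width
    if cols is None:
        cols = np.arange(n) % width
    sample_ids = [sample_id] * n if isinstance(sample_id, str) else list(sample_id)
    pathologies = (
        [str(pathology)] * n
        if isinstance(pathology, (str, Pathology))
        else [str(p) for p in pathology]
    )
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "pathology": pathologies,
            "tissue_class": str(tissue_class),
            "row": rows,
            "column": cols,
        }
    )
    return SpectraTable(axis, meta, spectra)


@pytest.fixture
def table_factory():
    return make_table
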