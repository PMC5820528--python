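import numpy as np
import pandas as pd
import pytest

from crossdis.io_formats import StudyDataset


def make_dataset(values: np.ndarray, genes: list | None = None,
                 n_control: int | None = None) -> StudyDataset:
    """Wrap a probes × samples array as a StudyDataset (first half control)."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    nc = n_control if n_control is not None else n_samples // 2
    samples = [f"C{i}" for i in range(nc)] + [f"D{i}" for i in range(n_samples - nc)]
    probes = [f"p{i}" for i in range(n_probes)]
    genes = genes if genes is not None else [f"GENE{i}" for i in range(n_probes)]
    expr = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                        columns=samples)
    groups = pd.Series(["control"] * nc + ["disease"] * (n_samples - nc),
                       index=samples, name="group")
    probe_map = pd.Series(genes, index=expr.index, name="gene", dtype=object)
    return StudyDataset(expr, groups, probe_map)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
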