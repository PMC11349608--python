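import numpy as np
import pandas as pd
import pytest

from trbrep.annotate import Repertoire
from trbrep.germline import load_bundled_reference


@pytest.fixture(scope="session")
def ref():
    return load_bundled_reference()


@pytest.fixture(scope="session")
def engine(ref):
    from trbrep.annotate import AnnotationEngine

    return AnnotationEngine(ref)


def make_repertoire(freqs, sample_id="S", group=None, total=10_000, v_call="TRBV16",
                    j_call="TRBJ2-1", clinical=None):
    """Repertoire with synthetic single-V/J clonotypes at given frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    counts = np.rint(freqs * total).astype(int)
    counts = np.maximum(counts, 1)
    table = pd.DataFrame(
        {
            "cdr3_aa": [f"CASS{i:05d}F" for i in range(len(freqs))],
            "v_call": v_call,
            "d_call": None,
            "j_call": j_call,
            "count": counts,
            "frequency": counts / counts.sum(),
        }
    )
    return Repertoire(sample_id, group, table, int(counts.sum()), clinical or {})
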