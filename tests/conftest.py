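import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_pair(rng):
    """A seeded full-column-rank 6x3 / 5x3 matched pair (raw arrays)."""
    d1 = rng.normal(size=(6, 3))
    d2 = rng.normal(size=(5, 3))
    return d1, d2


@pytest.fixture
def small_profile_tsv(tmp_path):
    path = tmp_path / "profile.tsv"
    path.write_text(
        "chrom\tstart\tend\tn_probes\tgc\tPA\tPB\n"
        "chr1\t0\t1000\t5\t0.40\t1.5\t-0.5\n"
        "chr1\t1000\t2000\t5\t0.55\t0.0\t2.0\n"
        "chr2\t0\t1000\t3\t0.60\t-1.0\t0.25\n"
    )
    return path


@pytest.fixture
def clinical_tsv(tmp_path):
    path = tmp_path / "clinical.tsv"
    path.write_text(
        "patient_id\tos_months\tos_event\tpfs_months\tstage\tplatinum\n"
        "PA\t24.5\t1\t10.0\tII\t1\n"
        "PB\t36.0\t0\t\tIII\t0\n"
        "PC\t12.0\ttrue\t6.0\t1\t\n"
        "PD\t60.0\tfalse\t60.0\t\t1\n"
    )
    return path
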