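import numpy as np
import pandas as pd
import pytest

from methylmr.datatypes import MethylationMatrix
from methylmr.simulate import default_config, make_cell_reference, simulate_study


@pytest.fixture(scope="session")
def study():
    """Default paper-scale synthetic study (45/46, 21 chordee, 9 severe)."""
    return simulate_study(default_config(seed=7))


@pytest.fixture(scope="session")
def cell_reference():
    return make_cell_reference(48, seed=12345)


def toy_methylation(beta: np.ndarray, probe_ids=None, sample_ids=None,
                    probe_class="cg", snp_flag=False, chrom="1",
                    detection_p=None, bead_fail=None) -> MethylationMatrix:
    """Small hand-built methylation matrix for QC tests."""
    n_probes, n_samples = beta.shape
    probe_ids = probe_ids or [f"cg{i:08d}" for i in range(1, n_probes + 1)]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(n_samples)]
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)
    classes = [probe_class] * n_probes if isinstance(probe_class, str) else probe_class
    flags = [snp_flag] * n_probes if isinstance(snp_flag, bool) else snp_flag
    manifest = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 1000 * (1 + np.arange(n_probes)),
            "probe_class": classes,
            "snp_flag": flags,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    det = (
        pd.DataFrame(detection_p, index=probe_ids, columns=sample_ids)
        if detection_p is not None
        else pd.DataFrame(0.001, index=probe_ids, columns=sample_ids)
    )
    bead = (
        pd.DataFrame(bead_fail, index=probe_ids, columns=sample_ids)
        if bead_fail is not None
        else pd.DataFrame(False, index=probe_ids, columns=sample_ids)
    )
    return MethylationMatrix(beta_df, manifest, det, bead)
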