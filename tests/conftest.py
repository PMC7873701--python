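import numpy as np
import pandas as pd
import pytest

from plexquant import QuantMatrix


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the default desk-scale study conditions,
    shared by the recovery and smoke acceptance tests."""
    from plexquant.benchmarks import fold_change_recovery

    outdir = tmp_path_factory.mktemp("default_run")
    result = fold_change_recovery(outdir, seed=17)
    return result, outdir


def make_quant_matrix(values, channels=None, genotypes=None, tissue="brain"):
    """Small QuantMatrix helper for unit tests."""
    values = np.asarray(values, dtype=float)
    n_prot, n_ch = values.shape
    channels = channels or [f"ch{i}" for i in range(n_ch)]
    genotypes = genotypes or ["WT"] * (n_ch // 2) + ["KO"] * (n_ch - n_ch // 2)
    design = pd.DataFrame(
        {
            "tissue": [tissue] * n_ch,
            "genotype": genotypes,
            "replicate": list(range(1, n_ch + 1)),
        },
        index=pd.Index(channels, name="channel"),
    )
    frame = pd.DataFrame(
        values, index=[f"P{i:03d}" for i in range(n_prot)], columns=channels
    )
    return QuantMatrix(frame, design)
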