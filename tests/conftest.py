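import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from reverseq.core import CountMatrix, SampleDesign

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_counts(values, genes=None, samples=None) -> CountMatrix:
    values = np.asarray(values)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                                    columns=samples))


def make_design(arms, samples=None, timepoints=None) -> SampleDesign:
    samples = samples or [f"S{j + 1}" for j in range(len(arms))]
    data = {"arm": arms}
    if timepoints is not None:
        data["timepoint"] = timepoints
    return SampleDesign(pd.DataFrame(data, index=pd.Index(samples, name="sample")))


def contrast_frame(genes, log2fc, qvalue, pvalue=None):
    """Hand-built contrast table for stages consuming DE output."""
    log2fc = np.asarray(log2fc, dtype=float)
    qvalue = np.asarray(qvalue, dtype=float)
    if pvalue is None:
        pvalue = qvalue / 2.0
    return pd.DataFrame(
        {"base_mean": np.full(len(genes), 100.0), "log2fc": log2fc,
         "lfc_se": np.full(len(genes), 0.2), "stat": log2fc / 0.2,
         "pvalue": np.asarray(pvalue, dtype=float), "qvalue": qvalue},
        index=pd.Index(genes, name="gene"),
    )
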