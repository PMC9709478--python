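import numpy as np
import pandas as pd
import pytest

from trtscreen.annotation import GeneModel
from trtscreen.quantify import ExpressionMatrix
from trtscreen.screen import call_trt
from trtscreen.simulate import config_from_preset, simulate_cohort


def gm(gene_id, chrom, start, end, strand, biotype=None):
    return GeneModel(gene_id, chrom, start, end, strand, biotype)


def make_expr(data: dict, index, library_sizes=None) -> ExpressionMatrix:
    """ExpressionMatrix from a {sample: values} dict over a feature index."""
    fpkm = pd.DataFrame(data, index=pd.Index(index, name="feature_id"), dtype=float)
    if library_sizes is None:
        library_sizes = pd.Series(1_000_000, index=fpkm.columns)
    return ExpressionMatrix(fpkm, pd.Series(library_sizes, index=fpkm.columns))


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(config_from_preset("tiny", seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """Default study conditions: 40 patients, 20 controls, ~500 candidate
    pairs, 50 planted read-through pairs."""
    return simulate_cohort(config_from_preset("default", seed=1))


@pytest.fixture(scope="session")
def default_screen(default_cohort):
    c = default_cohort
    return call_trt(c.pairs, c.expr, c.patient_ids, c.control_ids)
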