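import numpy as np
import pandas as pd
import pytest

from isomark import (find_essential_genes, predict_biomarkers, select_cohort,
                     worked_fixture)
from isomark.datatypes import TRANSCRIPT, ExpressionSet


def make_expression(values, samples=None, parents=None, biotypes=None):
    """Small helper: build a transcript-level ExpressionSet from a dict."""
    tpm = pd.DataFrame(values).T if isinstance(values, dict) \
        else pd.DataFrame(values)
    if samples is not None:
        tpm.columns = samples
    ids = tpm.index.astype(str)
    ann = pd.DataFrame({
        "parent_gene": parents if parents is not None
        else [f"g_{t}" for t in ids],
        "biotype": biotypes if biotypes is not None
        else ["protein_coding"] * len(ids),
        "level": TRANSCRIPT}, index=ids)
    return ExpressionSet(tpm.astype(float), ann)


@pytest.fixture(scope="session")
def worked():
    """The deterministic documentation dataset."""
    expr, ess, meta, truth = worked_fixture()
    return expr, ess, meta, truth


@pytest.fixture(scope="session")
def worked_run(worked):
    """Screen + biomarker prediction on the documentation dataset."""
    expr, ess, meta, truth = worked
    cohort = select_cohort(meta, sites={"kidney"})
    screen_res = find_essential_genes(expr, ess, cohort)
    pred = predict_biomarkers(expr, screen_res.sens, cohort,
                              truth.essential_kd)
    return screen_res, pred, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
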