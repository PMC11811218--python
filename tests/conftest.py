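import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from kbcomp import (
    ConditionKey,
    ExpressionMatrix,
    SyntheticConfig,
    generate_dataset,
    run_analysis,
)

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

# a scaled-down study with the same planted structure as the defaults
SMALL_CONFIG = dict(
    n_background_peaks=200,
    n_genes=1500,
    n_peaks_per_cluster=(60, 80, 30),
    n_ifn_independent_genes=40,
    n_program_genes=30,
    n_ifn_dependent_genes=20,
    n_induced_other_genes=50,
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SyntheticConfig(seed=11, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-scale synthetic dataset (generator defaults, seed 0)."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    ds = default_dataset
    return run_analysis(
        ds.peaks, ds.expression, ds.annotation,
        program_genes=ds.truth.program_genes,
    )


def expression_from_cpm(cpm: pd.DataFrame, keys: list[ConditionKey],
                        gene_names: pd.Series | None = None) -> ExpressionMatrix:
    """Hand-crafted expression matrix: columns of ``cpm`` are matched 1:1 to
    ``keys``; counts mirror the CPM values (only CPM is read downstream)."""
    labels = [k.label() for k in keys]
    cpm = cpm.set_axis(labels, axis=1)
    if gene_names is None:
        gene_names = pd.Series(
            [f"G{i}" for i in range(len(cpm))], index=cpm.index
        )
    return ExpressionMatrix(
        counts=cpm.copy(), cpm=cpm, conditions=dict(zip(labels, keys)),
        gene_names=gene_names,
    )


def rna_key(genotype, time_h, stimulus="CpG"):
    stim = "none" if time_h == 0 else stimulus
    return ConditionKey(genotype, stim, float(time_h), "RNA")
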