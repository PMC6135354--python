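import numpy as np
import pandas as pd
import pytest

from pepdiff.io import PeptideQuantTable, SampleDesign


def make_peptide_table(values, proteins, samples=None, peptides=None, **meta):
    """Build a PeptideQuantTable from a 2-D array and a protein list."""
    values = np.asarray(values, dtype=float)
    n_pep, n_samp = values.shape
    peptides = peptides or [f"pep{i}" for i in range(n_pep)]
    samples = samples or [f"S{j}" for j in range(n_samp)]
    idx = pd.Index(peptides, name="peptide")
    kwargs = {}
    for key in ("protein_probability", "idotp"):
        if key in meta:
            kwargs[key] = pd.Series(meta[key], index=idx, dtype=float)
    return PeptideQuantTable(
        intensities=pd.DataFrame(values, index=idx, columns=samples),
        proteins=pd.Series(list(proteins), index=idx, name="protein"),
        **kwargs,
    )


def make_design(n_per_group=5, names=("group0", "group1")):
    samples = [f"{nm}_{i}" for nm in names for i in range(n_per_group)]
    return SampleDesign(
        pd.DataFrame(
            {
                "group": np.repeat([0, 1], n_per_group),
                "group_name": np.repeat(list(names), n_per_group),
            },
            index=pd.Index(samples, name="sample"),
        )
    )


@pytest.fixture
def design10():
    return make_design(5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
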