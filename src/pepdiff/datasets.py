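"""Bundled reference data.

``load_pig_liver_differential`` returns the published differential-protein
results of a two-breed pig liver label-free LC-MS comparison (two groups of
five animals; group 0 = Duroc-type breed, group 1 = Large White-type
breed): per protein the reported group-mean rolled-up abundances, fold
change, direction, and the stability/significance P values.  Used as a
worked-example oracle for the fold-change arithmetic and in the README
example.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_pig_liver_differential() -> pd.DataFrame:
    """Published 25-protein differential-abundance table (see module docstring)."""
    ref = resources.files("pepdiff") / "data" / "pig_liver_differential.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
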