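"""Fold changes, the joint decision rule, and the final results table.

A protein is declared differentially abundant between the two groups when
all of the following hold at level alpha (default 0.10, inclusive):

* stability P_st <= alpha,
* significance P_si <= alpha,
* beta != 0 (it carries weight in the classification), and
* the sign of beta is consistent with the fold-change direction: the group
  coded 1 being up (FC < 1) requires beta > 0, and vice versa.

Fold change is computed on the rolled-up log2-derived scale as
FC = 2^(mean_group0 - mean_group1), so FC > 1 means higher abundance in the
group coded 0.  The report is sorted by ascending fold change, ties broken
by protein id.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import IntegrityError
from .io import ProteinQuantTable, SampleDesign

logger = logging.getLogger(__name__)


def group_means(P: ProteinQuantTable, d: SampleDesign) -> pd.DataFrame:
    """Per-protein arithmetic mean abundance in each group (missing excluded).

    Proteins with no present value in an entire group are excluded with a
    warning.  Columns: ``mean_group0``, ``mean_group1``.
    """
    ab = P.abundances[d.samples]
    g = d.groups
    m0 = ab.loc[:, g[g == 0].index].mean(axis=1)
    m1 = ab.loc[:, g[g == 1].index].mean(axis=1)
    out = pd.DataFrame({"mean_group0": m0, "mean_group1": m1})
    bad = out.isna().any(axis=1)
    if bad.any():
        logger.warning(
            "protein(s) excluded from group means (missing in an entire group): %s",
            list(out.index[bad]),
        )
        out = out.loc[~bad]
    return out


def fold_change(mean_a: float | np.ndarray, mean_b: float | np.ndarray):
    """FC = 2^(mean_a - mean_b) on the log2-derived abundance scale."""
    return 2.0 ** (np.asarray(mean_a, dtype=float) - np.asarray(mean_b, dtype=float))


def decide_differential(
    p_st: float, p_si: float, beta: float, fc: float, alpha: float = 0.10
) -> tuple[bool, str]:
    """Joint decision rule and direction for one protein.

    Returns ``(differential, direction)`` with direction one of
    ``"group_0_up"``, ``"group_1_up"`` or ``"indeterminate"`` (FC exactly 1).
    A protein at FC exactly 1 with significant P values is never declared:
    its direction cannot be assigned.
    """
    if fc > 1:
        direction = "group_0_up"
        sign_ok = beta < 0
    elif fc < 1:
        direction = "group_1_up"
        sign_ok = beta > 0
    else:
        return False, "indeterminate"
    diff = (p_st <= alpha) and (p_si <= alpha) and (beta != 0) and sign_ok
    return diff, direction


def build_results_table(
    P: ProteinQuantTable,
    d: SampleDesign,
    validation: pd.DataFrame,
    alpha: float = 0.10,
    all_proteins: bool = False,
) -> pd.DataFrame:
    """Assemble the differential-abundance report.

    One row per protein declared differential (or per validated protein if
    ``all_proteins``), sorted ascending by fold change with ties broken by
    protein id.  Columns: ``protein``, ``peptides``, ``mean_group0``,
    ``mean_group1``, ``FC`` (two decimals in written output), ``direction``
    (the up-regulated group's name), ``P_st``, ``P_si``, ``differential``.
    """
    means = group_means(P, d)
    common = means.index.intersection(validation.index)
    if len(common) == 0:
        raise IntegrityError("validation results and group means share no protein")
    means = means.loc[common]
    v = validation.loc[common]
    fc = fold_change(means["mean_group0"], means["mean_group1"])
    names = d.group_names
    rows = []
    for prot, f in zip(common, fc):
        diff, direction = decide_differential(
            v.at[prot, "P_st"], v.at[prot, "P_si"], v.at[prot, "beta"], f, alpha
        )
        rows.append(
            {
                "protein": prot,
                "peptides": int(P.n_peptides.get(prot, 0)),
                "mean_group0": means.at[prot, "mean_group0"],
                "mean_group1": means.at[prot, "mean_group1"],
                "FC": f,
                "direction": {
                    "group_0_up": names[0],
                    "group_1_up": names[1],
                    "indeterminate": "indeterminate",
                }[direction],
                "P_st": v.at[prot, "P_st"],
                "P_si": v.at[prot, "P_si"],
                "differential": diff,
            }
        )
    out = pd.DataFrame(rows)
    if not all_proteins:
        out = out.loc[out["differential"]]
    out = out.sort_values(["FC", "protein"], kind="mergesort").reset_index(drop=True)
    return out


def write_results_table(report: pd.DataFrame, path) -> None:
    """Write the report TSV with FC and P values at their reporting precision."""
    df = report.copy()
    for col, fmt in (("FC", "%.2f"), ("mean_group0", "%.4f"), ("mean_group1", "%.4f"),
                     ("P_st", "%.4g"), ("P_si", "%.4g")):
        if col in df.columns:
            df[col] = df[col].map(lambda x, fmt=fmt: fmt % x)
    df.to_csv(path, sep="\t", index=False)
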