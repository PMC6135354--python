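"""Synthetic label-free peptide-level datasets with known ground truth.

The generator emulates the statistical shape of a small two-group label-free
LC-MS study: two groups of five samples, ~200 proteins each supported by at
least two peptides (mean just over five, ~1,040 peptides in total),
log-normal MS1 intensities, a 12.5% minority of truly differential proteins,
per-sample location shifts (loading / session drift, removed by
normalization), and per-peptide ionization offsets (removed by the z-score
rollup).  On the log2 scale a cell is

    log2 intensity = mu_g + delta_g * group(s) + o_p + c_s + eps,

with mu_g the protein baseline, delta_g the signed group effect (zero for
non-differential proteins), o_p the peptide offset, c_s the sample shift and
eps ~ Normal(0, noise_sd^2).  Cells are masked missing completely at random
at ``missing_rate``.  Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, IntegrityError
from .io import PeptideQuantTable, SampleDesign


@dataclass
class SimulationConfig:
    """Study-shape parameters of the generator.

    ``peptides_per_protein_mean`` is the mean of the shifted-Poisson count
    ``2 + Poisson(mean - 2)``, so every protein has at least two peptides;
    the default 5.2 gives ~1,040 peptides over 200 proteins.  Effects are
    injected at the protein level and inherited by all of a protein's
    peptides; the signed shift ``effect_size_log2`` applies to the group
    coded 1.  ``baseline_mean``/``baseline_sd`` set the log2-scale protein
    baselines (2^20 ~ 10^6, a typical MS1 area magnitude).
    """

    n_per_group: int = 5
    n_proteins: int = 200
    peptides_per_protein_mean: float = 5.2
    frac_differential: float = 0.125
    effect_size_log2: float = 2.0
    noise_sd_log2: float = 0.5
    sample_shift_sd: float = 0.5
    peptide_offset_sd: float = 2.0
    missing_rate: float = 0.05
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    group_names: tuple[str, str] = ("group0", "group1")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if self.peptides_per_protein_mean < 2:
            raise ConfigError("peptides_per_protein_mean must be >= 2")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ConfigError("frac_differential must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        for name in ("noise_sd_log2", "sample_shift_sd", "peptide_offset_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted: signed effects, sample shifts, peptide offsets."""

    effects: pd.Series  # protein -> signed delta (0 for non-differential)
    sample_shifts: pd.Series
    peptide_offsets: pd.Series

    @property
    def differential_proteins(self) -> pd.Index:
        return self.effects.index[self.effects != 0]


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[PeptideQuantTable, SampleDesign, GroundTruth]:
    """Draw one synthetic dataset; returns (peptides, design, truth).

    Intensities are on the linear MS1 scale (the pipeline's expected input);
    the same seed always yields byte-identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = 2 * cfg.n_per_group
    sample_ids = [f"{name}_{i + 1}" for name in cfg.group_names for i in range(cfg.n_per_group)]
    groups = np.repeat([0, 1], cfg.n_per_group)
    design = SampleDesign(
        pd.DataFrame(
            {
                "group": groups,
                "group_name": np.repeat(list(cfg.group_names), cfg.n_per_group),
            },
            index=pd.Index(sample_ids, name="sample"),
        )
    )

    proteins = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    n_true = int(round(cfg.frac_differential * cfg.n_proteins))
    true_idx = rng.choice(cfg.n_proteins, size=n_true, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_true)
    delta = np.zeros(cfg.n_proteins)
    delta[true_idx] = signs * cfg.effect_size_log2

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_proteins)
    n_pep = 2 + rng.poisson(cfg.peptides_per_protein_mean - 2, size=cfg.n_proteins)
    prot_of_pep = np.repeat(np.arange(cfg.n_proteins), n_pep)
    total_pep = int(n_pep.sum())
    peptide_ids = [f"pep{i + 1:05d}" for i in range(total_pep)]

    o_p = rng.normal(0.0, cfg.peptide_offset_sd, size=total_pep)
    c_s = rng.normal(0.0, cfg.sample_shift_sd, size=n_samples)
    eps = rng.normal(0.0, cfg.noise_sd_log2, size=(total_pep, n_samples))

    log2_int = (
        mu[prot_of_pep][:, None]
        + delta[prot_of_pep][:, None] * groups[None, :]
        + o_p[:, None]
        + c_s[None, :]
        + eps
    )
    intens = 2.0 ** log2_int
    if cfg.missing_rate > 0:
        mask = rng.random((total_pep, n_samples)) < cfg.missing_rate
        intens[mask] = np.nan

    table = PeptideQuantTable(
        intensities=pd.DataFrame(
            intens, index=pd.Index(peptide_ids, name="peptide"), columns=sample_ids
        ),
        proteins=pd.Series(
            [proteins[i] for i in prot_of_pep], index=pd.Index(peptide_ids, name="peptide"),
            name="protein",
        ),
    )
    truth = GroundTruth(
        effects=pd.Series(delta, index=pd.Index(proteins, name="protein"), name="delta"),
        sample_shifts=pd.Series(c_s, index=pd.Index(sample_ids, name="sample"), name="shift"),
        peptide_offsets=pd.Series(
            o_p, index=pd.Index(peptide_ids, name="peptide"), name="offset"
        ),
    )
    return table, design, truth


def evaluate_recovery(report: pd.DataFrame, truth: GroundTruth) -> dict:
    """Score a differential report against the planted truth.

    Returns sensitivity (declared true / planted true), the count of false
    discoveries, and direction accuracy on the true positives.  A planted
    delta > 0 raises the group coded 1, so the declared up-group must be the
    second group name for direction credit (and conversely).
    """
    declared = report.loc[report["differential"], "protein"] if "differential" in report else report["protein"]
    declared = pd.Index(declared)
    unknown = declared.difference(truth.effects.index)
    if len(unknown):
        raise IntegrityError(f"report names proteins absent from the truth: {list(unknown)}")
    true_set = truth.differential_proteins
    tp = declared.intersection(true_set)
    fp = declared.difference(true_set)
    sensitivity = len(tp) / len(true_set) if len(true_set) else float("nan")

    dir_correct = 0
    for prot in tp:
        fc = float(report.loc[report["protein"] == prot, "FC"].iloc[0])
        planted_up1 = truth.effects[prot] > 0
        observed_up1 = fc < 1
        dir_correct += planted_up1 == observed_up1
    return {
        "sensitivity": sensitivity,
        "false_discoveries": int(len(fp)),
        "direction_accuracy": dir_correct / len(tp) if len(tp) else float("nan"),
        "n_declared": int(len(declared)),
    }
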