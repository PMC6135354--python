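"""End-to-end orchestration: peptide table in, differential report out.

The stage order is fixed: confidence filter -> log2 -> central-tendency
normalization -> minimum-peptide filter -> ZRollup -> hyperparameter tuning
-> full fit -> LOO/permutation validation -> report.  The peptide-count
filter runs on the peptide table (before rollup), which retains exactly the
proteins that would show >= min_peptides supporting peptides afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .differential import build_results_table
from .io import (
    PeptideQuantTable,
    SampleDesign,
    filter_identification_confidence,
    filter_min_peptides,
    summarize_identifications,
)
from .preprocess import central_tendency_normalize, log2_transform, zrollup
from .splsda import SplsdaConfig, fit_splsda, scores_plot_data, tune_splsda
from .validation import StabilityValidator, ValidationConfig


@dataclass
class RunConfig:
    """All stage settings plus the seeds that make a run reproducible.

    ``seed`` is the single user-facing seed; the stage seeds default to
    values derived from it (fold_seed = seed, perm_seed = seed + 1) and can
    be pinned individually for audits.
    """

    min_protein_prob: float = 0.9
    min_idotp: float = 0.9
    min_peptides: int = 2
    norm_center: str = "median"
    rollup_center: str = "median"
    min_samples_present: int = 1
    nonpositive: str = "to-missing"
    alpha: float = 0.10
    n_permutations: int = 1000
    seed: int = 0
    fold_seed: int | None = None
    perm_seed: int | None = None
    eta_grid: tuple | None = None
    k_grid: tuple | None = None
    scale_x: bool = True

    def splsda_config(self) -> SplsdaConfig:
        kwargs = {"fold_seed": self.fold_seed if self.fold_seed is not None else self.seed,
                  "scale_x": self.scale_x}
        if self.eta_grid is not None:
            kwargs["eta_grid"] = tuple(self.eta_grid)
        if self.k_grid is not None:
            kwargs["k_grid"] = tuple(self.k_grid)
        return SplsdaConfig(**kwargs)

    def validation_config(self) -> ValidationConfig:
        return ValidationConfig(
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            perm_seed=self.perm_seed if self.perm_seed is not None else self.seed + 1,
        )


def run_pipeline(
    peptides: PeptideQuantTable, design: SampleDesign, cfg: RunConfig | None = None
) -> dict:
    """Run every stage and return all artifacts keyed by name.

    Keys: ``summary`` (identification counts), ``normalized`` (peptide
    table), ``norm_params``, ``proteins`` (rolled-up table), ``eta``, ``K``,
    ``cv_error_grid``, ``fit``, ``fitted_proteins``, ``scores``,
    ``validation`` (per-protein results) and ``report``.
    """
    cfg = cfg or RunConfig()
    t = filter_identification_confidence(peptides, cfg.min_protein_prob, cfg.min_idotp)
    summary = summarize_identifications(t)
    t = log2_transform(t, nonpositive=cfg.nonpositive)
    t, norm_params = central_tendency_normalize(t, center_statistic=cfg.norm_center)
    t = filter_min_peptides(t, cfg.min_peptides)
    prot = zrollup(t, cfg.min_samples_present, cfg.rollup_center)

    splsda_cfg = cfg.splsda_config()
    eta, K, cv_grid = tune_splsda(prot, design, splsda_cfg)
    fit, fitted_proteins = fit_splsda(prot, design, eta, K, cfg.scale_x)
    scores = scores_plot_data(fit, prot, design)

    validator = StabilityValidator(eta, K, cfg.validation_config(), cfg.scale_x)
    validation = validator.fit(prot, design).results_
    report = build_results_table(prot, design, validation, cfg.alpha)
    return {
        "summary": summary,
        "normalized": t,
        "norm_params": norm_params,
        "proteins": prot,
        "eta": eta,
        "K": K,
        "cv_error_grid": cv_grid,
        "fit": fit,
        "fitted_proteins": fitted_proteins,
        "scores": scores,
        "validation": validation,
        "report": report,
    }
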