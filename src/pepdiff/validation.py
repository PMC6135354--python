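"""Stability and significance testing of sPLS-DA protein selection.

Sparse selection on ten samples is fragile, so a selected protein is only
trusted if (a) it keeps being selected when single samples are dropped and
(b) neither its selection frequency nor its coefficient magnitude is
reproduced by chance under group-label permutation.

Two permutation P values are computed per protein, both with the add-one
estimator P = (1 + #{null >= observed}) / (B + 1), which is a valid
permutation P value and bounded below by 1/(B+1):

* stability ``P_st``: the observed leave-one-out (LOO) selection frequency
  against the LOO frequencies obtained on label-permuted datasets;
* significance ``P_si``: |beta| from the full-data fit against its
  permutation distribution.

Proteins with beta = 0 carry no weight in the classification: they are
flagged and can never be declared differential, and their ``P_st``/``P_si``
follow from the same formulas (an observed frequency of 0 gives P_st = 1 by
convention).

The hyperparameters (eta, K) are frozen at the values tuned on the full
observed data for every LOO subset and every permutation unless
``retune_per_resample`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, IntegrityError
from .io import ProteinQuantTable, SampleDesign
from .splsda import SPLSDAClassifier, SPLSDACV, SplsdaConfig, design_matrix


@dataclass
class ValidationConfig:
    """Permutation-test settings.

    ``n_permutations`` (B) label permutations are drawn uniformly with
    replacement from the arrangement space (duplicates and the identity
    arrangement are kept: with 5+5 samples there are only 252 distinct
    balanced arrangements, so duplicates are unavoidable at B = 1000).
    """

    n_permutations: int = 1000
    alpha: float = 0.10
    perm_seed: int = 0
    retune_per_resample: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")


def _fit_arrays(X: np.ndarray, y: np.ndarray, eta: float, K: int, scale: bool) -> SPLSDAClassifier:
    k_cap = min(K, len(y) - 1, X.shape[1])
    return SPLSDAClassifier(eta=eta, n_components=k_cap, scale=scale).fit(X, y)


def _loo_frequencies(X: np.ndarray, y: np.ndarray, eta: float, K: int, scale: bool) -> np.ndarray:
    n, p = X.shape
    counts = np.zeros(p)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = _fit_arrays(X[mask], y[mask], eta, K, scale)
        counts += clf.selected_
        mask[i] = True
    return counts / n


def loo_selection_frequencies(
    P: ProteinQuantTable, d: SampleDesign, eta: float, K: int, scale_x: bool = True
) -> pd.Series:
    """Per-protein selection frequency over the n leave-one-out refits."""
    Xdf, y = design_matrix(P, d)
    if len(y) < 3:
        raise IntegrityError("leave-one-out needs at least 3 samples")
    freq = _loo_frequencies(Xdf.to_numpy(), y, eta, K, scale_x)
    return pd.Series(freq, index=Xdf.columns, name="f_orig")


def permutation_null(
    P: ProteinQuantTable,
    d: SampleDesign,
    eta: float,
    K: int,
    cfg: ValidationConfig,
    scale_x: bool = True,
    splsda_cfg: SplsdaConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Null records from B label permutations: LOO frequencies and betas.

    Each permutation applies the identical procedure used on the observed
    labels — a full-data fit (beta vector) and the n LOO refits (selection
    frequency vector) — to a uniformly drawn rearrangement of the group
    codes.  Bit-for-bit reproducible given ``perm_seed``.
    """
    Xdf, y = design_matrix(P, d)
    X = Xdf.to_numpy()
    rng = np.random.default_rng(cfg.perm_seed)
    B = cfg.n_permutations
    p = X.shape[1]
    freqs = np.zeros((B, p))
    betas = np.zeros((B, p))
    for b in range(B):
        y_perm = rng.permutation(y)
        if cfg.retune_per_resample:
            cv = SPLSDACV(splsda_cfg).fit(X, y_perm)
            eta_b, k_b = cv.eta_, cv.k_
        else:
            eta_b, k_b = eta, K
        betas[b] = _fit_arrays(X, y_perm, eta_b, k_b, scale_x).coef_
        freqs[b] = _loo_frequencies(X, y_perm, eta_b, k_b, scale_x)
    cols = Xdf.columns
    return (
        pd.DataFrame(freqs, columns=cols),
        pd.DataFrame(betas, columns=cols),
    )


def _check_matched(obs_index: pd.Index, null_df: pd.DataFrame) -> None:
    if not obs_index.equals(null_df.columns):
        raise IntegrityError("observed and null protein sets do not match")


def stability_test(f_orig: pd.Series, null_freqs: pd.DataFrame, cfg: ValidationConfig) -> pd.Series:
    """P_st = (1 + #{b: f_perm_b >= f_orig}) / (B + 1); f_orig = 0 gives P_st = 1."""
    _check_matched(f_orig.index, null_freqs)
    B = len(null_freqs)
    exceed = (null_freqs.to_numpy() >= f_orig.to_numpy()[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (B + 1.0)
    p[f_orig.to_numpy() == 0] = 1.0
    return pd.Series(p, index=f_orig.index, name="P_st")


def significance_test(
    beta_obs: pd.Series, null_betas: pd.DataFrame, cfg: ValidationConfig
) -> tuple[pd.Series, pd.Series]:
    """P_si on |beta| plus the zero-weight flag.

    Returns ``(P_si, zero_weight)``; flagged proteins (beta_obs = 0) have no
    weight in the classification and are barred from differential calls
    downstream regardless of P.
    """
    _check_matched(beta_obs.index, null_betas)
    B = len(null_betas)
    obs = np.abs(beta_obs.to_numpy())
    exceed = (np.abs(null_betas.to_numpy()) >= obs[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (B + 1.0)
    zero = pd.Series(beta_obs.to_numpy() == 0, index=beta_obs.index, name="zero_weight")
    return pd.Series(p, index=beta_obs.index, name="P_si"), zero


class StabilityValidator:
    """Runs the full validation protocol on a protein table.

    ``fit`` computes, at fixed (eta, K): the full-data beta vector, the
    observed LOO selection frequencies, the permutation null, and the two P
    values.  Results land in ``results_`` (one row per fitted protein).
    """

    def __init__(
        self,
        eta: float,
        K: int,
        config: ValidationConfig | None = None,
        scale_x: bool = True,
        splsda_config: SplsdaConfig | None = None,
    ) -> None:
        self.eta = eta
        self.K = K
        self.config = config
        self.scale_x = scale_x
        self.splsda_config = splsda_config

    def get_params(self, deep: bool = True) -> dict:
        return {
            "eta": self.eta,
            "K": self.K,
            "config": self.config,
            "scale_x": self.scale_x,
            "splsda_config": self.splsda_config,
        }

    def fit(self, P: ProteinQuantTable, d: SampleDesign) -> "StabilityValidator":
        cfg = self.config or ValidationConfig()
        Xdf, y = design_matrix(P, d)
        full = _fit_arrays(Xdf.to_numpy(), y, self.eta, self.K, self.scale_x)
        beta_obs = pd.Series(full.coef_, index=Xdf.columns, name="beta")
        f_orig = loo_selection_frequencies(P, d, self.eta, self.K, self.scale_x)
        null_freqs, null_betas = permutation_null(
            P, d, self.eta, self.K, cfg, self.scale_x, self.splsda_config
        )
        p_st = stability_test(f_orig, null_freqs, cfg)
        p_si, zero = significance_test(beta_obs, null_betas, cfg)
        self.estimator_ = full
        self.null_freqs_ = null_freqs
        self.null_betas_ = null_betas
        self.results_ = pd.DataFrame(
            {
                "f_orig": f_orig,
                "beta": beta_obs,
                "P_st": p_st,
                "P_si": p_si,
                "zero_weight": zero,
            }
        ).rename_axis("protein")
        return self


def validate(
    P: ProteinQuantTable,
    d: SampleDesign,
    eta: float,
    K: int,
    cfg: ValidationConfig | None = None,
    scale_x: bool = True,
) -> pd.DataFrame:
    """One-call validation: returns the per-protein results table."""
    return StabilityValidator(eta, K, cfg, scale_x).fit(P, d).results_
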