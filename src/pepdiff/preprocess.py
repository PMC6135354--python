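"""Quantitative preprocessing: log2, central-tendency normalization, ZRollup.

The chain is fixed: raw MS1 intensities are log2-transformed, per-sample
location differences (loading, ionization-session drift) are removed by a
single additive shift per sample, and peptide rows are rolled up to protein
abundances by z-score scaling each peptide's profile across samples and
averaging the scaled peptides within a protein.  Rolled-up abundances are
therefore *relative* quantities on a z-like scale; absolute protein amounts
are not recoverable.

Missing cells are ignored (never imputed) in every center, scale and
average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DegenerateSampleError, PepdiffError
from .io import PeptideQuantTable, ProteinQuantTable

logger = logging.getLogger(__name__)

_CENTER_FUNCS = {"median": np.nanmedian, "mean": np.nanmean}


def log2_transform(t: PeptideQuantTable, nonpositive: str = "error") -> PeptideQuantTable:
    """Replace every present intensity by its base-2 logarithm.

    ``nonpositive`` controls cells that are 0 or negative on the linear
    scale: ``"error"`` raises naming the offending cell, ``"to-missing"``
    masks them as missing.  The missingness pattern is otherwise unchanged.
    """
    vals = t.intensities.to_numpy(dtype=float, copy=True)
    bad = vals <= 0
    bad &= ~np.isnan(vals)
    if bad.any():
        if nonpositive == "error":
            i, j = np.argwhere(bad)[0]
            raise PepdiffError(
                f"non-positive intensity at peptide {t.intensities.index[i]!r}, "
                f"sample {t.intensities.columns[j]!r}; use nonpositive='to-missing' to mask"
            )
        if nonpositive != "to-missing":
            raise ConfigError(f"nonpositive must be 'error' or 'to-missing', got {nonpositive!r}")
        vals[bad] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(vals)
    return t.with_intensities(
        pd.DataFrame(out, index=t.intensities.index, columns=t.intensities.columns)
    )


@dataclass
class NormalizationParams:
    """Central-tendency normalization settings and the fitted offsets.

    ``center_statistic`` is the per-sample location statistic equalized
    across samples; ``target`` is what it is equalized to (the grand center
    of all samples before adjustment, or zero).  ``per_sample_offset`` holds
    the additive log2-scale shift applied to each sample, recorded so a run
    can be audited and reproduced exactly.
    """

    center_statistic: str = "median"
    target: str = "grand_central"
    per_sample_offset: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.center_statistic not in _CENTER_FUNCS:
            raise ConfigError(f"center_statistic must be 'median' or 'mean', got {self.center_statistic!r}")
        if self.target not in ("grand_central", "zero"):
            raise ConfigError(f"target must be 'grand_central' or 'zero', got {self.target!r}")


class CentralTendencyNormalizer:
    """Per-sample additive normalization on the log2 scale.

    scikit-learn-style transformer over :class:`PeptideQuantTable`: ``fit``
    learns one offset per sample so the chosen center statistic of present
    values is equal across samples; ``transform`` applies the offsets.

    Parameters
    ----------
    center_statistic : {"median", "mean"}
        Location statistic equalized across samples.  Median is the default:
        it is robust to the heavy right tail of peptide intensities.
    target : {"grand_central", "zero"}
        Value the per-sample centers are shifted to. ``grand_central`` keeps
        the table on its original overall scale.
    """

    def __init__(self, center_statistic: str = "median", target: str = "grand_central") -> None:
        self.center_statistic = center_statistic
        self.target = target

    def get_params(self, deep: bool = True) -> dict:
        return {"center_statistic": self.center_statistic, "target": self.target}

    def set_params(self, **params) -> "CentralTendencyNormalizer":
        for k, v in params.items():
            if k not in ("center_statistic", "target"):
                raise ConfigError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, t: PeptideQuantTable) -> "CentralTendencyNormalizer":
        params = NormalizationParams(self.center_statistic, self.target)  # validates
        center = _CENTER_FUNCS[params.center_statistic]
        vals = t.intensities.to_numpy(dtype=float)
        if np.isnan(vals).all(axis=0).any():
            empty = [s for s, col in zip(t.samples, vals.T) if np.isnan(col).all()]
            raise DegenerateSampleError(f"samples with no present values: {empty}")
        centers = center(vals, axis=0)
        grand = center(vals) if params.target == "grand_central" else 0.0
        self.offsets_ = pd.Series(grand - centers, index=t.intensities.columns, name="offset")
        self.params_ = NormalizationParams(self.center_statistic, self.target, self.offsets_)
        return self

    def transform(self, t: PeptideQuantTable) -> PeptideQuantTable:
        return t.with_intensities(t.intensities + self.offsets_)

    def fit_transform(self, t: PeptideQuantTable) -> PeptideQuantTable:
        return self.fit(t).transform(t)


def central_tendency_normalize(
    t: PeptideQuantTable, center_statistic: str = "median", target: str = "grand_central"
) -> tuple[PeptideQuantTable, NormalizationParams]:
    """Normalize a log2-scale peptide table; returns the table and the fitted offsets."""
    norm = CentralTendencyNormalizer(center_statistic, target)
    out = norm.fit_transform(t)
    return out, norm.params_


class ZRollup:
    """Peptide-to-protein rollup by z-score scaling and averaging.

    Each peptide's profile across samples is scaled as
    ``z = (x - center(x)) / sd(x)`` (center per ``center_statistic``, sd with
    the n-1 denominator), removing peptide-specific location (ionization
    efficiency) and scale.  A protein's abundance in a sample is the mean of
    its peptides' scaled values over present cells.  Peptides whose profile
    has zero or undefined scale (constant, or fewer than two present values)
    carry no relative information and are excluded from the average with a
    logged warning; a protein whose every peptide is excluded is dropped.

    Parameters
    ----------
    center_statistic : {"median", "mean"}
        Peptide-profile center.  Median is the default.
    min_samples_present : int
        Minimum number of contributing peptides for a protein/sample cell;
        cells with fewer become missing.
    """

    def __init__(self, center_statistic: str = "median", min_samples_present: int = 1) -> None:
        self.center_statistic = center_statistic
        self.min_samples_present = min_samples_present

    def get_params(self, deep: bool = True) -> dict:
        return {
            "center_statistic": self.center_statistic,
            "min_samples_present": self.min_samples_present,
        }

    def set_params(self, **params) -> "ZRollup":
        for k, v in params.items():
            if k not in ("center_statistic", "min_samples_present"):
                raise ConfigError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, t: PeptideQuantTable) -> ProteinQuantTable:
        if self.center_statistic not in _CENTER_FUNCS:
            raise ConfigError(
                f"center_statistic must be 'median' or 'mean', got {self.center_statistic!r}"
            )
        if self.min_samples_present < 1:
            raise ConfigError("min_samples_present must be >= 1")
        center = _CENTER_FUNCS[self.center_statistic]
        vals = t.intensities.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            centers = center(vals, axis=1, keepdims=True)
            n_present = (~np.isnan(vals)).sum(axis=1)
            sds = np.full(vals.shape[0], np.nan)
            ok = n_present >= 2
            sds[ok] = np.nanstd(vals[ok], axis=1, ddof=1)
        usable = ok & (sds > 0)
        if not usable.all():
            skipped = t.intensities.index[~usable].tolist()
            logger.warning(
                "%d peptide(s) with zero/undefined scale excluded from rollup: %s",
                len(skipped), skipped[:10],
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (vals - centers) / sds[:, None]
        z[~usable] = np.nan

        zdf = pd.DataFrame(z, index=t.intensities.index, columns=t.intensities.columns)
        grouped = zdf.groupby(t.proteins)
        abundance = grouped.mean()
        contributing = grouped.count()
        abundance = abundance.mask(contributing < self.min_samples_present)

        n_pep = t.peptides_per_protein()
        dropped = abundance.index[abundance.isna().all(axis=1)]
        if len(dropped):
            logger.warning("protein(s) dropped (no usable peptides): %s", list(dropped))
            abundance = abundance.drop(index=dropped)
        self.excluded_peptides_ = t.intensities.index[~usable]
        return ProteinQuantTable(abundances=abundance, n_peptides=n_pep.loc[abundance.index])


def zrollup(
    t: PeptideQuantTable, min_samples_present: int = 1, center_statistic: str = "median"
) -> ProteinQuantTable:
    """Roll a normalized log2-scale peptide table up to protein abundances."""
    return ZRollup(center_statistic, min_samples_present).fit_transform(t)
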