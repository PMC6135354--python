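"""Domain tables and delimited-text I/O.

The pipeline consumes the tabular output of an upstream identification /
MS1-quantification chain (search engine, protein inference, then MS1 peak
area extraction).  Upstream spectrum-level formats (mzXML, pepXML) are not
parsed here; the converter contract is the column layout documented on
:func:`read_peptide_table` and :func:`read_design`.

Missing intensities are empty cells on disk and ``NaN`` in memory.  Zero is
a valid measured value and is preserved as such: label-free data distinguish
"not detected" from "low".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EmptyTableError, FormatError, IntegrityError

logger = logging.getLogger(__name__)

#: Non-sample columns recognised in a peptide table, in on-disk order.
PEPTIDE_META_COLUMNS = ("peptide", "protein", "protein_probability", "idotp")


@dataclass(frozen=True)
class SampleDesign:
    """Two-group sample layout: sample ids, 0/1 group codes, group names.

    The group coded 0 is the reference group (its mean comes first in fold
    changes); the group coded 1 is the one the classifier's linear score
    points toward.
    """

    table: pd.DataFrame  # index: sample id; columns: group (int 0/1), group_name

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate sample ids in design: {dup}")
        codes = set(t["group"].unique().tolist())
        if codes != {0, 1}:
            raise IntegrityError(
                f"design must contain exactly the two group codes 0 and 1, got {sorted(codes)}"
            )
        counts = t["group"].value_counts()
        if (counts < 2).any():
            raise IntegrityError(
                "each group needs >= 2 samples (leave-one-out and group means require it); "
                f"got sizes {counts.to_dict()}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        """0/1 group code per sample, in design order."""
        return self.table["group"]

    @property
    def group_names(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for code in (0, 1):
            names = self.table.loc[self.table["group"] == code, "group_name"].unique()
            out[code] = str(names[0])
        return out

    def y(self) -> np.ndarray:
        """Group codes as a float response vector (0/1), design order."""
        return self.table["group"].to_numpy(dtype=float)


@dataclass
class PeptideQuantTable:
    """Peptide x sample intensity matrix plus the peptide-to-protein map.

    ``intensities`` is indexed by peptide id with one float column per
    sample; NaN marks a missing cell.  Each peptide maps to exactly one
    protein (upstream inference resolves shared peptides; ambiguous rows are
    rejected at parse time).  Optional identification-confidence scores ride
    along: ``protein_probability`` (protein-level posterior) and ``idotp``
    (isotope dot product of the MS1 envelope match).
    """

    intensities: pd.DataFrame
    proteins: pd.Series
    protein_probability: pd.Series | None = None
    idotp: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate peptide ids: {dup}")
        if not self.proteins.index.equals(idx):
            raise IntegrityError("protein map index does not match intensity rows")
        for name, col in (("protein_probability", self.protein_probability), ("idotp", self.idotp)):
            if col is not None and not col.index.equals(idx):
                raise IntegrityError(f"{name} index does not match intensity rows")

    @property
    def peptides(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_peptides(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_proteins(self) -> int:
        return int(self.proteins.nunique())

    def peptides_per_protein(self) -> pd.Series:
        """Distinct-peptide count per protein."""
        return self.proteins.groupby(self.proteins).size()

    def subset(self, peptide_ids: pd.Index) -> "PeptideQuantTable":
        """Row subset preserving order of ``peptide_ids``."""
        return PeptideQuantTable(
            intensities=self.intensities.loc[peptide_ids],
            proteins=self.proteins.loc[peptide_ids],
            protein_probability=None
            if self.protein_probability is None
            else self.protein_probability.loc[peptide_ids],
            idotp=None if self.idotp is None else self.idotp.loc[peptide_ids],
        )

    def with_intensities(self, values: pd.DataFrame) -> "PeptideQuantTable":
        """Same metadata, new intensity matrix (same shape and labels)."""
        if not values.index.equals(self.intensities.index) or not values.columns.equals(
            self.intensities.columns
        ):
            raise IntegrityError("replacement intensities must keep the same labels")
        out = PeptideQuantTable.__new__(PeptideQuantTable)
        out.intensities = values
        out.proteins = self.proteins
        out.protein_probability = self.protein_probability
        out.idotp = self.idotp
        return out


@dataclass
class ProteinQuantTable:
    """Protein x sample rolled-up abundance matrix (relative, log2-derived scale)."""

    abundances: pd.DataFrame  # index: protein id; columns: samples
    n_peptides: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_peptides is None:
            raise IntegrityError("n_peptides is required")
        if not self.n_peptides.index.equals(self.abundances.index):
            raise IntegrityError("n_peptides index does not match abundance rows")
        if (self.n_peptides < 1).any():
            raise IntegrityError("every protein must have n_peptides >= 1")

    @property
    def proteins(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundances.columns)


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect in ("\t", "tsv"):
        return "\t"
    if dialect in (",", "csv"):
        return ","
    if dialect is not None:
        raise FormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_peptide_table(path: str | Path, dialect: str | None = None) -> PeptideQuantTable:
    """Read a peptide quantification table from TSV (default) or CSV.

    Required columns: ``peptide``, ``protein``, then one numeric column per
    sample.  Optional columns ``protein_probability`` and ``idotp`` are
    recognised by name.  Blank intensity cells become missing values, not
    zeros.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype={"peptide": str, "protein": str})
    for col in ("peptide", "protein"):
        if col not in df.columns:
            raise FormatError(f"peptide table {path} is missing required column {col!r}")
    if df["peptide"].duplicated().any():
        dup = df.loc[df["peptide"].duplicated(), "peptide"].unique().tolist()
        raise IntegrityError(f"duplicate peptide ids in {path}: {dup}")
    df = df.set_index("peptide")
    sample_cols = [c for c in df.columns if c not in PEPTIDE_META_COLUMNS]
    if not sample_cols:
        raise FormatError(f"peptide table {path} has no sample columns")
    intens = df[sample_cols].astype(float)
    if np.nanmin(intens.to_numpy(), initial=0.0) < 0:
        raise IntegrityError(f"negative intensity in {path}; MS1 areas must be >= 0")
    return PeptideQuantTable(
        intensities=intens,
        proteins=df["protein"],
        protein_probability=df["protein_probability"].astype(float)
        if "protein_probability" in df.columns
        else None,
        idotp=df["idotp"].astype(float) if "idotp" in df.columns else None,
    )


def write_peptide_table(t: PeptideQuantTable, path: str | Path, dialect: str | None = None) -> None:
    """Write a peptide table; missing cells become empty fields."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.DataFrame(index=t.intensities.index)
    df["protein"] = t.proteins
    if t.protein_probability is not None:
        df["protein_probability"] = t.protein_probability
    if t.idotp is not None:
        df["idotp"] = t.idotp
    df = pd.concat([df, t.intensities], axis=1)
    df.to_csv(path, sep=sep, index_label="peptide", float_format="%.10g")


def read_design(path: str | Path, dialect: str | None = None) -> SampleDesign:
    """Read the sample design: columns ``sample``, ``group`` (0/1), ``group_name``."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype={"sample": str, "group_name": str})
    for col in ("sample", "group", "group_name"):
        if col not in df.columns:
            raise FormatError(f"design table {path} is missing required column {col!r}")
    df["group"] = df["group"].astype(int)
    return SampleDesign(df.set_index("sample"))


def write_design(d: SampleDesign, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    d.table.to_csv(path, sep=_sep_for(path, dialect), index_label="sample")


def write_protein_table(p: ProteinQuantTable, path: str | Path, dialect: str | None = None) -> None:
    """Write a rolled-up protein table: ``protein``, ``n_peptides``, sample columns."""
    path = Path(path)
    df = pd.concat([p.n_peptides.rename("n_peptides"), p.abundances], axis=1)
    df.to_csv(path, sep=_sep_for(path, dialect), index_label="protein", float_format="%.10g")


def read_protein_table(path: str | Path, dialect: str | None = None) -> ProteinQuantTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype={"protein": str}).set_index("protein")
    if "n_peptides" not in df.columns:
        raise FormatError(f"protein table {path} is missing required column 'n_peptides'")
    n_pep = df["n_peptides"].astype(int)
    return ProteinQuantTable(abundances=df.drop(columns=["n_peptides"]).astype(float), n_peptides=n_pep)


def filter_identification_confidence(
    t: PeptideQuantTable, min_protein_prob: float = 0.9, min_idotp: float = 0.9
) -> PeptideQuantTable:
    """Keep rows passing both identification-confidence thresholds (inclusive).

    ``protein_probability`` is a protein-level posterior from the inference
    engine; ``idotp`` scores the MS1 isotope-envelope match per peptide.  A
    threshold whose column is absent is skipped with a logged notice, so the
    operation is the identity on tables without confidence columns.
    """
    for name, thr in (("min_protein_prob", min_protein_prob), ("min_idotp", min_idotp)):
        if not 0.0 <= thr <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1], got {thr}")
    keep = pd.Series(True, index=t.intensities.index)
    if t.protein_probability is not None:
        keep &= t.protein_probability >= min_protein_prob
    else:
        logger.info("protein_probability column absent; protein-level filter skipped")
    if t.idotp is not None:
        keep &= t.idotp >= min_idotp
    else:
        logger.info("idotp column absent; peptide-level filter skipped")
    return t.subset(t.intensities.index[keep])


def filter_min_peptides(t: PeptideQuantTable, min_peptides: int = 2) -> PeptideQuantTable:
    """Keep proteins supported by at least ``min_peptides`` distinct peptides."""
    if min_peptides < 1:
        raise ConfigError(f"min_peptides must be >= 1, got {min_peptides}")
    counts = t.peptides_per_protein()
    kept_proteins = counts.index[counts >= min_peptides]
    keep = t.proteins.isin(kept_proteins)
    if not keep.any():
        raise EmptyTableError(
            f"no protein has >= {min_peptides} peptides; the pipeline cannot proceed"
        )
    return t.subset(t.intensities.index[keep])


def summarize_identifications(t: PeptideQuantTable) -> dict:
    """Identification summary: peptide and protein counts and their ratio.

    ``mean_peptides_per_protein`` is reported to one decimal, the resolution
    conventionally used when quoting identification depth.
    """
    if t.n_peptides == 0:
        raise EmptyTableError("cannot summarize an empty peptide table")
    n_pep, n_prot = t.n_peptides, t.n_proteins
    return {
        "n_peptides": n_pep,
        "n_proteins": n_prot,
        "mean_peptides_per_protein": round(n_pep / n_prot, 1),
    }
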