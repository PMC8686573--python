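"""Input data model, validation, and delimited-table I/O.

A pooled CRISPR knockout screen is described by three tables:

``counts``
    sequence_ID x sgRNA matrix of raw readcounts (nonnegative, NaN = masked).
``sequence_map``
    one row per sequenced sample: ``sequence_ID``, ``cell_line_name``,
    ``pDNA_batch``, ``days`` (since infection) and an optional ``library``
    label.  Plasmid-pool (pDNA) measurements are flagged either by
    ``cell_line_name == "pDNA"`` or by ``days == 0``; both conventions are
    accepted.
``guide_map``
    one row per sgRNA: ``sgrna``, ``gene``.  Each sgRNA must target exactly
    one gene; multi-targeting reagents are rejected outright because the
    combined effect of simultaneous knockouts is not modeled.

Matrices are read and written as comma-separated text with a header row and
row labels in the first column (tab-separated when the filename ends in
``.tsv``), matching the conventions of the public DepMap-style datasets.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("chronokit")

PDNA_LABEL = "pDNA"

SEQUENCE_MAP_COLUMNS = ("sequence_ID", "cell_line_name", "pDNA_batch", "days")
GUIDE_MAP_COLUMNS = ("sgrna", "gene")

#: default library label used when the sequence map carries no ``library`` column
DEFAULT_LIBRARY = "default"


class ScreenDataError(ValueError):
    """Base class for malformed screen inputs."""


class MultiTargetGuideError(ScreenDataError):
    """An sgRNA is annotated as targeting more than one gene."""


class MissingPDNAError(ScreenDataError):
    """A pDNA batch referenced by late-time-point samples has no pDNA row."""


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled matrix (first column = row label, header = column labels)."""
    try:
        return pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except OSError as err:
        raise OSError(f"could not read matrix from {path!r}: {err}") from err


def write_matrix(matrix, path: str | Path) -> None:
    """Write a labeled matrix so that ``read_matrix`` round-trips it exactly.

    Accepts a DataFrame or any object with a ``.data`` DataFrame attribute
    (e.g. :class:`GeneEffectMatrix`).  NaN entries are preserved as empty
    fields.  Row and column labels must be unique.
    """
    frame = getattr(matrix, "data", matrix)
    if not frame.index.is_unique or not frame.columns.is_unique:
        raise ScreenDataError(f"matrix labels must be unique to write {path!r}")
    try:
        frame.to_csv(path, sep=_sep_for(path))
    except OSError as err:
        raise OSError(f"could not write matrix to {path!r}: {err}") from err


@dataclasses.dataclass
class GeneEffectMatrix:
    """Cell-line x gene matrix of fitness effects r_cg.

    ``r_cg`` is the fractional change in growth rate of line ``c`` when gene
    ``g`` is fully knocked out (per day; 0 = no effect, negative = growth
    inhibition).  ``normalization`` records the post-processing state:
    ``"raw"`` (as fitted), ``"globally_scaled"`` (nonessential/essential
    control medians mapped to 0/-1) or ``"cn_corrected"``.
    """

    data: pd.DataFrame
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.normalization not in ("raw", "globally_scaled", "cn_corrected"):
            raise ValueError(f"unknown normalization state {self.normalization!r}")
        if not self.data.index.is_unique or not self.data.columns.is_unique:
            raise ScreenDataError("gene effect matrix labels must be unique")

    @property
    def cell_lines(self) -> pd.Index:
        return self.data.index

    @property
    def genes(self) -> pd.Index:
        return self.data.columns


def validate_copy_number(cn: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell-line x gene copy number matrix in log2(x+1) units.

    Relative copy number x >= 0 implies log2(x+1) >= 0; negative entries are
    rejected.  Genes absent from the matrix are imputable to 1 (normal
    ploidy, since log2(1+1) = 1) via :func:`align_copy_number`.
    """
    if not cn.index.is_unique or not cn.columns.is_unique:
        raise ScreenDataError("copy number matrix labels must be unique")
    values = cn.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        bad = cn.columns[np.nanmin(values, axis=0) < 0][:5].tolist()
        raise ScreenDataError(
            f"copy number must be log2(x+1) >= 0; negative values in genes {bad}"
        )
    return cn


def align_copy_number(cn: pd.DataFrame, cell_lines, genes) -> pd.DataFrame:
    """Subset/expand a copy number matrix to the given labels.

    Genes with no copy number data are assumed to have normal ploidy and are
    assigned the value 1 (log2(1+1)); NaN entries are likewise imputed to 1.
    Cell lines must all be present.
    """
    validate_copy_number(cn)
    missing_lines = [c for c in cell_lines if c not in cn.index]
    if missing_lines:
        raise ScreenDataError(f"copy number matrix lacks cell lines {missing_lines[:5]}")
    out = cn.reindex(index=cell_lines, columns=genes)
    n_missing = int(out.isna().to_numpy().sum())
    if n_missing:
        logger.info("imputing %d missing copy number entries to normal ploidy (1)", n_missing)
    return out.fillna(1.0)


@dataclasses.dataclass
class ScreenData:
    """Validated bundle of counts, sequence map and guide map."""

    counts: pd.DataFrame
    sequence_map: pd.DataFrame
    guide_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.sequence_map = self.sequence_map.copy()
        if "library" not in self.sequence_map.columns:
            self.sequence_map["library"] = DEFAULT_LIBRARY
        self.validate()

    # -- convenience views ------------------------------------------------
    @property
    def is_pdna(self) -> pd.Series:
        sm = self.sequence_map
        return (sm["cell_line_name"] == PDNA_LABEL) | (sm["days"] == 0)

    @property
    def pdna_map(self) -> pd.DataFrame:
        return self.sequence_map[self.is_pdna]

    @property
    def replicate_map(self) -> pd.DataFrame:
        """Sequence map rows for late (non-pDNA) measurements."""
        return self.sequence_map[~self.is_pdna]

    @property
    def cell_lines(self) -> list:
        return sorted(self.replicate_map["cell_line_name"].unique())

    @property
    def genes(self) -> list:
        return sorted(self.guide_map["gene"].unique())

    def guide_genes(self) -> pd.Series:
        """sgRNA -> gene, ordered like the counts columns."""
        mapping = self.guide_map.set_index("sgrna")["gene"]
        return mapping.reindex(self.counts.columns)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        counts, sm, gm = self.counts, self.sequence_map, self.guide_map
        for col in SEQUENCE_MAP_COLUMNS:
            if col not in sm.columns:
                raise ScreenDataError(f"sequence map is missing column {col!r}")
        for col in GUIDE_MAP_COLUMNS:
            if col not in gm.columns:
                raise ScreenDataError(f"guide map is missing column {col!r}")
        if not counts.index.is_unique:
            raise ScreenDataError("counts has duplicated sequence_IDs")
        if not counts.columns.is_unique:
            raise ScreenDataError("counts has duplicated sgRNA columns")

        multi = gm.groupby("sgrna")["gene"].nunique()
        offenders = multi.index[multi > 1].tolist()
        if offenders:
            raise MultiTargetGuideError(
                "sgRNAs annotated with multiple target genes are not supported; "
                f"offending sgRNAs: {offenders[:5]}"
            )
        if gm["sgrna"].duplicated().any():
            dupes = gm.loc[gm["sgrna"].duplicated(), "sgrna"].tolist()
            raise ScreenDataError(f"guide map lists sgRNAs more than once: {dupes[:5]}")

        unmapped = counts.columns.difference(gm["sgrna"])
        if len(unmapped):
            raise ScreenDataError(
                f"counts columns missing from guide map: {unmapped[:5].tolist()}"
            )
        unknown_seq = counts.index.difference(sm["sequence_ID"])
        if len(unknown_seq):
            raise ScreenDataError(
                f"counts rows missing from sequence map: {unknown_seq[:5].tolist()}"
            )
        if sm["sequence_ID"].duplicated().any():
            dupes = sm.loc[sm["sequence_ID"].duplicated(), "sequence_ID"].tolist()
            raise ScreenDataError(f"duplicated sequence_IDs in sequence map: {dupes[:5]}")

        days = pd.to_numeric(sm["days"], errors="coerce")
        if days.isna().any():
            bad = sm.loc[days.isna(), "sequence_ID"].tolist()
            raise ScreenDataError(f"non-numeric 'days' for sequences {bad[:5]}")
        if (days < 0).any():
            bad = sm.loc[days < 0, "sequence_ID"].tolist()
            raise ScreenDataError(f"negative 'days' for sequences {bad[:5]}")
        self.sequence_map["days"] = days

        is_pdna = self.is_pdna
        late = sm[~is_pdna]
        if (late["days"] <= 0).any():
            bad = late.loc[late["days"] <= 0, "sequence_ID"].tolist()
            raise ScreenDataError(
                f"non-pDNA sequences must have days > 0; offending: {bad[:5]}"
            )
        # keep only sequence-map rows whose sequences were actually measured
        measured = sm["sequence_ID"].isin(counts.index)
        if not measured.all():
            logger.info(
                "dropping %d sequence map rows without counts", int((~measured).sum())
            )
            self.sequence_map = self.sequence_map[measured]
            sm = self.sequence_map
            is_pdna = self.is_pdna
            late = sm[~is_pdna]

        pdna_batches = set(sm.loc[is_pdna, "pDNA_batch"])
        needed = late.groupby("pDNA_batch").size()
        without = [b for b in needed.index if b not in pdna_batches]
        if without:
            raise MissingPDNAError(
                f"pDNA batches with no pDNA measurement: {without[:5]}"
            )
        if late.empty:
            raise ScreenDataError("no late-time-point (non-pDNA) sequences present")

        values = counts.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            rows = counts.index[np.nanmin(values, axis=1) < 0][:5].tolist()
            raise ScreenDataError(f"negative readcounts in sequences {rows}")
        # counts stored as floats so masked entries can be NaN
        self.counts = counts.astype(float)

    def copy(self) -> "ScreenData":
        return ScreenData(
            counts=self.counts.copy(),
            sequence_map=self.sequence_map.copy(),
            guide_map=self.guide_map.copy(),
        )


def load_screen_data(
    counts_path: str | Path,
    sequence_map_path: str | Path,
    guide_map_path: str | Path,
) -> ScreenData:
    """Load and validate the three screen input tables from delimited files."""
    counts = read_matrix(counts_path)
    sequence_map = pd.read_csv(sequence_map_path, sep=_sep_for(sequence_map_path))
    guide_map = pd.read_csv(guide_map_path, sep=_sep_for(guide_map_path))
    return ScreenData(counts=counts, sequence_map=sequence_map, guide_map=guide_map)
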