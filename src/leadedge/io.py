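"""Readers and writers for the flat text formats the pipeline touches.

Cell tables, spot tables, ligand-receptor tables and survival tables are
tab-separated files read into pandas DataFrames with a validated schema.
Expression matrices travel as MatrixMarket triplets (genes x cells on disk,
the CellRanger orientation) next to plain-text gene and cell identifier
lists, and are held in memory as :class:`anndata.AnnData` (cells x genes).
Gene sets use the GMT convention: one set per tab-separated line, fields
``name<TAB>description<TAB>member...``.

All parse errors name the file and the offending column or line.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

CELL_TABLE_REQUIRED = ("cell_id", "roi_id", "x", "y")
#: Optional per-cell annotation columns preserved on round trips.
CELL_TABLE_OPTIONAL = ("region", "cell_type", "fb_subtype")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (order-preserving, deduplicated)."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if len(set(self.members)) != len(self.members):
            deduped = tuple(dict.fromkeys(self.members))
            object.__setattr__(self, "members", deduped)


@dataclass
class LRDatabase:
    """Curated ligand -> receptor gene pairs.

    ``pairs`` has columns ``ligand``, ``receptor``, ``pair_id`` with unique
    pair ids (default id ``LIGAND_RECEPTOR``).
    """

    pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["ligand", "receptor", "pair_id"]
        )
    )

    def __post_init__(self) -> None:
        required = {"ligand", "receptor", "pair_id"}
        if not required.issubset(self.pairs.columns):
            raise FormatError(f"LRDatabase requires columns {sorted(required)}")
        if self.pairs["pair_id"].duplicated().any():
            raise ValidationError("pair_ids must be unique")
        for col in ("ligand", "receptor"):
            if (self.pairs[col].astype(str).str.len() == 0).any():
                raise ValidationError(f"empty gene symbol in column '{col}'")

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, pair_id: str) -> tuple[str, str]:
        row = self.pairs.loc[self.pairs["pair_id"] == pair_id]
        if row.empty:
            raise ValidationError(
                f"pair '{pair_id}' is not queryable in the ligand-receptor "
                "database"
            )
        r = row.iloc[0]
        return str(r["ligand"]), str(r["receptor"])


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def read_cell_table(path: str | Path, marker_names: list[str]) -> pd.DataFrame:
    """Read a segmented single-cell table.

    Expects a tab-separated file with header columns ``cell_id``, ``roi_id``,
    ``x``, ``y`` plus one column per marker.  Marker intensities must be
    non-negative and coordinates finite.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    t = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "roi_id": str})
    for col in (*CELL_TABLE_REQUIRED, *marker_names):
        if col not in t.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if not np.isfinite(t[["x", "y"]].to_numpy(dtype=float)).all():
        raise ValidationError(f"{path}: non-finite coordinate in x/y")
    markers = t[list(marker_names)].to_numpy(dtype=float)
    if (markers < 0).any():
        bad = [m for m in marker_names if (t[m] < 0).any()]
        raise ValidationError(
            f"{path}: negative intensity in marker column(s) {bad}"
        )
    if t.groupby("roi_id")["cell_id"].apply(lambda s: s.duplicated().any()).any():
        raise ValidationError(f"{path}: duplicated cell_id within an roi_id")
    return t


def write_cell_table(t: pd.DataFrame, path: str | Path) -> None:
    t.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_mtx(directory: str | Path) -> ad.AnnData:
    """Read a MatrixMarket expression directory into AnnData (cells x genes).

    The directory must contain ``matrix.mtx`` (genes x cells), ``genes.tsv``
    and ``barcodes.tsv``.  Duplicate gene symbols are disambiguated by
    suffixing an ordinal (``SYM``, ``SYM-1``, ``SYM-2`` ...).
    """
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    genes = directory / "genes.tsv"
    cells = directory / "barcodes.tsv"
    for f in (mtx, genes, cells):
        if not f.exists():
            raise FormatError(f"{f}: file does not exist")
    m = sp.csr_matrix(scipy.io.mmread(mtx))
    gene_names = genes.read_text().split()
    cell_names = cells.read_text().split()
    if m.shape != (len(gene_names), len(cell_names)):
        raise FormatError(
            f"{mtx}: matrix is {m.shape[0]}x{m.shape[1]} but identifier lists "
            f"have {len(gene_names)} genes and {len(cell_names)} cells"
        )
    adata = ad.AnnData(
        X=m.T.tocsr(),
        obs=pd.DataFrame(index=pd.Index(cell_names, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
    )
    if adata.var_names.duplicated().any():
        adata.var_names_make_unique(join="-")
    return adata


def write_expression_mtx(adata: ad.AnnData, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(X.T))
    (directory / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")


# ---------------------------------------------------------------------------
# spot tables
# ---------------------------------------------------------------------------

@dataclass
class SpotTable:
    """A spatial-transcriptomics section.

    ``spots`` holds one row per spot: ``spot_id``, integer array coordinates
    ``row``/``col``, physical ``x``/``y`` (um), and per-cell-type
    deconvolution fractions in columns ``frac_<type>`` (each in [0, 1],
    summing to <= 1 per spot).  ``expr`` is the spot x gene count matrix with
    ``expr.obs_names`` aligned to ``spots['spot_id']``.
    """

    spots: pd.DataFrame
    expr: ad.AnnData

    def __post_init__(self) -> None:
        required = {"spot_id", "row", "col"}
        if not required.issubset(self.spots.columns):
            raise FormatError(f"SpotTable requires columns {sorted(required)}")
        if self.spots.duplicated(subset=["row", "col"]).any():
            raise ValidationError("duplicated array coordinates in spot table")
        frac_cols = self.fraction_columns()
        fr = self.spots[frac_cols].to_numpy(dtype=float)
        if (fr < 0).any() or (fr > 1).any():
            raise ValidationError("deconvolution fractions must lie in [0, 1]")
        if (fr.sum(axis=1) > 1 + 1e-6).any():
            raise ValidationError("deconvolution fractions sum to > 1")
        if list(self.expr.obs_names) != list(self.spots["spot_id"]):
            raise ValidationError("expr.obs_names must match spots['spot_id']")

    def fraction_columns(self) -> list[str]:
        return [c for c in self.spots.columns if c.startswith("frac_")]


def read_spot_table(directory: str | Path) -> SpotTable:
    """Read ``spots.tsv`` plus a MatrixMarket expression triplet."""
    directory = Path(directory)
    path = directory / "spots.tsv"
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    spots = pd.read_csv(path, sep="\t", dtype={"spot_id": str})
    expr = read_expression_mtx(directory)
    return SpotTable(spots=spots, expr=expr)


def write_spot_table(st: SpotTable, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    st.spots.to_csv(directory / "spots.tsv", sep="\t", index=False)
    write_expression_mtx(st.expr, directory)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line has {len(parts)} fields, "
                "expected name, description and at least one member"
            )
        name, desc, *members = parts
        members = [m for m in members if m]
        sets.append(GeneSet(name=name, description=desc,
                            members=tuple(dict.fromkeys(members))))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description or "na", *s.members]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# ligand-receptor tables
# ---------------------------------------------------------------------------

def read_lr_table(path: str | Path) -> LRDatabase:
    """Read a delimited ligand/receptor pair table.

    ``pair_id`` defaults to ``LIGAND_RECEPTOR``; duplicated (ligand, receptor)
    rows are collapsed with a logged warning.
    """
    path = Path(path)
    t = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ligand", "receptor"):
        if col not in t.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    n_before = len(t)
    t = t.drop_duplicates(subset=["ligand", "receptor"]).reset_index(drop=True)
    if len(t) < n_before:
        logger.warning(
            "%s: collapsed %d duplicate ligand-receptor row(s)",
            path, n_before - len(t),
        )
    if "pair_id" not in t.columns:
        t["pair_id"] = t["ligand"] + "_" + t["receptor"]
    else:
        t["pair_id"] = t["pair_id"].fillna(t["ligand"] + "_" + t["receptor"])
    return LRDatabase(pairs=t[["ligand", "receptor", "pair_id"]])


def write_lr_table(db: LRDatabase, path: str | Path) -> None:
    db.pairs.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------

def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival cohort: columns ``sample``, ``time``, ``event``.

    Optional ``score`` and ``group`` columns are preserved.  ``time`` must be
    strictly positive and ``event`` binary.
    """
    path = Path(path)
    t = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "time", "event"):
        if col not in t.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if (t["time"] <= 0).any():
        raise ValidationError(f"{path}: non-positive survival time")
    if not t["event"].isin([0, 1]).all():
        raise ValidationError(f"{path}: event values must be 0 or 1")
    if t["sample"].duplicated().any():
        raise ValidationError(f"{path}: duplicated sample ids")
    return t


def write_survival_table(t: pd.DataFrame, path: str | Path) -> None:
    t.to_csv(path, sep="\t", index=False)
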