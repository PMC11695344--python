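"""Spatial-transcriptomics stage: region labels from deconvolution
fractions, boundary-spot detection on the array lattice, three-criterion
ligand-receptor colocalization calls, and per-spot gene-set scoring.

A spot is labeled ``tumor`` / ``FB`` / ``endothelial`` when that type's
deconvolution fraction strictly exceeds the region threshold (default 0.60;
thresholds <= 0.5 are rejected because two types could then pass at once),
otherwise ``mixed``.  A boundary spot is an FB spot with at least one
lattice-adjacent endothelial spot, or vice versa.  A positive
ligand-receptor call requires all three criteria: the spot is on the
FB/endothelial boundary, the pair is queryable in the database, and the
spot expresses both the ligand and the receptor (counts >= min_count,
default nonzero).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError, ValidationError
from .io import GeneSet, LRDatabase, SpotTable
from .prognosis import ssgsea

logger = logging.getLogger(__name__)

REGION_TYPES = ("tumor", "FB", "endothelial")

ADJACENCY_OFFSETS = {
    "square4": ((1, 0), (-1, 0), (0, 1), (0, -1)),
    "square8": (
        (1, 0), (-1, 0), (0, 1), (0, -1),
        (1, 1), (1, -1), (-1, 1), (-1, -1),
    ),
}


def classify_spots(s: SpotTable, threshold: float = 0.60) -> pd.Series:
    """Label each spot by its dominant deconvolution fraction.

    The label is the type among tumor/FB/endothelial whose fraction strictly
    exceeds ``threshold``; otherwise ``mixed``.  Because fractions sum to at
    most 1 and the threshold exceeds 0.5, at most one type can qualify.
    """
    if threshold <= 0.5:
        raise ConfigError(
            "region threshold must exceed 0.5 to guarantee a unique label"
        )
    if threshold >= 1.0:
        raise ConfigError("region threshold must be < 1")
    missing = [t for t in REGION_TYPES if f"frac_{t}" not in s.spots.columns]
    if missing:
        raise ValidationError(f"missing fraction column(s) for {missing}")
    fr = s.spots[[f"frac_{t}" for t in REGION_TYPES]].to_numpy(dtype=float)
    passing = fr > threshold
    labels = np.full(len(s.spots), "mixed", dtype=object)
    which = passing.argmax(axis=1)
    has = passing.any(axis=1)
    labels[has] = np.array(REGION_TYPES, dtype=object)[which[has]]
    return pd.Series(labels, index=pd.Index(s.spots["spot_id"]), name="region")


def _hex6_offsets(row: int) -> tuple[tuple[int, int], ...]:
    # even-row offset coordinates ("pointy-top" rows shifted on odd rows)
    if row % 2 == 0:
        return ((0, 1), (0, -1), (-1, 0), (-1, -1), (1, 0), (1, -1))
    return ((0, 1), (0, -1), (-1, 0), (-1, 1), (1, 0), (1, 1))


def find_boundary_spots(
    s: SpotTable, regions: pd.Series, adjacency: str = "square4"
) -> set[str]:
    """Spots on the FB/endothelial interface.

    A spot is boundary iff its region is FB and at least one adjacent spot
    is endothelial, or its region is endothelial and at least one adjacent
    spot is FB.  Mixed and tumor spots are never boundary.
    """
    if adjacency not in (*ADJACENCY_OFFSETS, "hex6"):
        raise ConfigError(f"unknown adjacency '{adjacency}'")
    by_coord = {
        (int(r), int(c)): sid
        for sid, r, c in zip(s.spots["spot_id"], s.spots["row"], s.spots["col"])
    }
    region_of = regions.to_dict()
    partner = {"FB": "endothelial", "endothelial": "FB"}
    out: set[str] = set()
    for (r, c), sid in by_coord.items():
        lab = region_of[sid]
        if lab not in partner:
            continue
        offsets = (
            _hex6_offsets(r) if adjacency == "hex6" else ADJACENCY_OFFSETS[adjacency]
        )
        for dr, dc in offsets:
            nid = by_coord.get((r + dr, c + dc))
            if nid is not None and region_of[nid] == partner[lab]:
                out.add(sid)
                break
    return out


def call_lr_spots(
    s: SpotTable,
    boundary: set[str],
    db: LRDatabase,
    pair_id: str,
    min_count: int = 1,
) -> pd.DataFrame:
    """Per-boundary-spot ligand-receptor colocalization calls.

    One row per boundary spot; ``positive`` iff both the ligand and the
    receptor counts reach ``min_count``.  The pair must be queryable in the
    database and both genes present in the expression matrix.
    """
    ligand, receptor = db.get(pair_id)  # raises if not queryable
    for gene in (ligand, receptor):
        if gene not in s.expr.var_names:
            raise ValidationError(
                f"gene '{gene}' absent from the spot expression matrix"
            )
    X = s.expr[:, [ligand, receptor]].X
    counts = X.toarray() if sp.issparse(X) else np.asarray(X)
    frame = pd.DataFrame(
        {
            "spot_id": s.spots["spot_id"].to_numpy(),
            "pair_id": pair_id,
            "boundary": [sid in boundary for sid in s.spots["spot_id"]],
            "ligand_count": counts[:, 0].astype(int),
            "receptor_count": counts[:, 1].astype(int),
        }
    )
    frame = frame[frame["boundary"]].reset_index(drop=True)
    frame["positive"] = (frame["ligand_count"] >= min_count) & (
        frame["receptor_count"] >= min_count
    )
    return frame


def score_spots(s: SpotTable, gs: GeneSet, alpha: float = 0.25) -> pd.Series:
    """Single-sample enrichment score of a gene set for every spot."""
    present = [g for g in gs.members if g in s.expr.var_names]
    missing = sorted(set(gs.members) - set(present))
    if not present:
        raise ValidationError(
            f"no member of gene set '{gs.name}' is present in the matrix"
        )
    if missing:
        logger.info(
            "gene set '%s': %d member(s) absent from the matrix", gs.name,
            len(missing),
        )
    X = s.expr.X
    dense = X.toarray() if sp.issparse(X) else np.asarray(X)
    expr_genes = list(s.expr.var_names)
    scores = [
        ssgsea(pd.Series(dense[i], index=expr_genes), gs, alpha=alpha)
        for i in range(len(s.spots))
    ]
    return pd.Series(
        scores, index=pd.Index(s.spots["spot_id"]), name=f"score_{gs.name}"
    )
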