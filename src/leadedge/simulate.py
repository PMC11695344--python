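"""Synthetic data generators with planted, recoverable structure.

Every downstream stage of the pipeline is tested against data produced here:

* :func:`gen_imc_rois` scatters ~10 cell classes across square regions of
  interest with bimodal log-normal marker intensities, and optionally plants
  a parent-offspring proximity structure in which one fibroblast subtype (S3)
  is placed within a fixed radius of endothelial cells — the spatial signal
  the distance and neighborhood statistics are meant to detect.
* :func:`gen_scrna` draws negative-binomial counts with per-cluster marker
  genes shifted by a known log2 fold change, a mitochondrial gene block, and
  optional pathological cells (high mitochondrial share, low coverage) that
  exercise the QC filters.
* :func:`gen_st` lays out a spot lattice with contiguous fibroblast and
  endothelial regions sharing a boundary, Dirichlet deconvolution fractions
  concentrated on the true region, and ligand/receptor co-expression planted
  at the true boundary.
* :func:`gen_survival` draws exponential event times whose log-hazard is
  linear in a standardized sample score, with independent uniform censoring.

All generators are deterministic in (configuration, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp

from .errors import ConfigError
from .io import SpotTable

# Marker panel used by the synthetic IMC generator: the gating-informative
# channels (lineage markers plus the four fibroblast-subtype markers).
DEFAULT_PANEL = (
    "CD45", "CD20", "CD68", "CD3", "CD4", "CD8",
    "CD31", "PanCK", "aSMA", "CollagenI", "Vimentin", "CD90",
)

#: Which markers each synthetic cell class expresses ("+" channels); all
#: other panel markers are drawn from the negative law.  Fibroblast subtypes
#: S1-S4 share CollagenI+/CD90+ and differ in the aSMA/Vimentin sign pattern.
TYPE_SIGNATURES: dict[str, tuple[str, ...]] = {
    "tumor": ("PanCK",),
    "endothelial": ("CD31",),
    "B": ("CD45", "CD20"),
    "macrophage": ("CD45", "CD68"),
    "CD8 T": ("CD45", "CD3", "CD8"),
    "CD4 T": ("CD45", "CD3", "CD4"),
    "S1": ("CollagenI", "CD90"),
    "S2": ("aSMA", "CollagenI", "CD90"),
    "S3": ("aSMA", "CollagenI", "Vimentin", "CD90"),
    "S4": ("CollagenI", "Vimentin", "CD90"),
}

FB_SUBTYPES = ("S1", "S2", "S3", "S4")

DEFAULT_PROPORTIONS: dict[str, float] = {
    "tumor": 0.35,
    "endothelial": 0.08,
    "B": 0.06,
    "macrophage": 0.08,
    "CD8 T": 0.07,
    "CD4 T": 0.07,
    "S1": 0.08,
    "S2": 0.07,
    "S3": 0.08,
    "S4": 0.06,
}


@dataclass
class MarkerModel:
    """Log-normal intensity law per marker: a positive and a negative mode.

    Ion-count imaging intensities are strictly non-negative and right-skewed;
    a two-mode log-normal gives well-separated positive/negative populations
    so that marker gating has a well-posed ground truth.
    """

    positive_meanlog: float = float(np.log(20.0))
    negative_meanlog: float = float(np.log(0.5))
    sdlog: float = 0.35


@dataclass
class ImcSimConfig:
    """Configuration of the synthetic IMC region-of-interest generator."""

    n_rois: int = 10
    cells_per_roi: int = 1000
    type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    proximity_radius: float = 20.0
    proximity_on: bool = True
    #: subtype planted near endothelial parents when proximity_on
    proximity_subtype: str = "S3"
    roi_side: float = 1000.0
    marker_model: MarkerModel = field(default_factory=MarkerModel)
    panel: tuple[str, ...] = DEFAULT_PANEL

    def validate(self) -> None:
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"type_proportions sum to {total}, expected 1")
        if self.proximity_radius >= self.roi_side:
            raise ConfigError("proximity_radius must be < roi_side")
        if self.proximity_on and "endothelial" not in self.type_proportions:
            raise ConfigError(
                "proximity_on requires an 'endothelial' entry in "
                "type_proportions"
            )
        if self.proximity_on and self.proximity_subtype not in self.type_proportions:
            raise ConfigError(
                f"proximity subtype '{self.proximity_subtype}' missing from "
                "type_proportions"
            )
        unknown = set(self.type_proportions) - set(TYPE_SIGNATURES)
        if unknown:
            raise ConfigError(f"unknown cell types {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted truth aligned one-to-one with a generated object."""

    cells: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    spots: pd.DataFrame | None = None
    hazard_coef: float | None = None


def _counts_from_proportions(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment: counts within 1 of n * proportion."""
    names = list(proportions)
    raw = np.array([proportions[k] * n for k in names])
    base = np.floor(raw).astype(int)
    remainder = raw - base
    short = n - int(base.sum())
    order = np.argsort(-remainder, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(names, (int(b) for b in base)))


def gen_imc_rois(cfg: ImcSimConfig, seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a synthetic multi-ROI single-cell table.

    Cells are placed uniformly in each square ROI.  When
    ``cfg.proximity_on``, cells of ``cfg.proximity_subtype`` are instead
    placed uniformly within ``cfg.proximity_radius`` of a randomly chosen
    endothelial cell of the same ROI (parent-offspring clustering).  Marker
    intensities are log-normal draws from the positive law on the type's
    signature channels and the negative law elsewhere.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    mm = cfg.marker_model
    rows: list[pd.DataFrame] = []
    for r in range(cfg.n_rois):
        roi_id = f"roi{r:03d}"
        counts = _counts_from_proportions(cfg.type_proportions, cfg.cells_per_roi)
        types = np.concatenate(
            [np.repeat(t, c) for t, c in counts.items()]
        )
        n = len(types)
        xy = rng.uniform(0.0, cfg.roi_side, size=(n, 2))
        if cfg.proximity_on:
            endo = np.flatnonzero(types == "endothelial")
            planted = np.flatnonzero(types == cfg.proximity_subtype)
            if len(endo) == 0 and len(planted) > 0:
                raise ConfigError(
                    "proximity_on but the ROI has no endothelial cells"
                )
            for i in planted:
                parent = xy[endo[rng.integers(len(endo))]]
                # uniform draw in the disk of radius proximity_radius
                rad = cfg.proximity_radius * np.sqrt(rng.uniform())
                ang = rng.uniform(0.0, 2.0 * np.pi)
                pt = parent + rad * np.array([np.cos(ang), np.sin(ang)])
                xy[i] = np.clip(pt, 0.0, cfg.roi_side)
        intensities = np.empty((n, len(cfg.panel)))
        for j, marker in enumerate(cfg.panel):
            pos = np.array(
                [marker in TYPE_SIGNATURES[t] for t in types], dtype=bool
            )
            meanlog = np.where(pos, mm.positive_meanlog, mm.negative_meanlog)
            intensities[:, j] = rng.lognormal(meanlog, mm.sdlog)
        df = pd.DataFrame(intensities, columns=list(cfg.panel))
        df.insert(0, "y", xy[:, 1])
        df.insert(0, "x", xy[:, 0])
        df.insert(0, "roi_id", roi_id)
        df.insert(0, "cell_id", [f"{roi_id}_c{i:05d}" for i in range(n)])
        df["true_type"] = types
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    truth_cells = table[["cell_id", "roi_id", "true_type"]].copy()
    truth_cells["true_fb_subtype"] = np.where(
        truth_cells["true_type"].isin(FB_SUBTYPES),
        truth_cells["true_type"],
        "unassigned",
    )
    table = table.drop(columns="true_type")
    return table, GroundTruth(cells=truth_cells)


# ---------------------------------------------------------------------------
# scRNA counts
# ---------------------------------------------------------------------------

def gen_scrna(
    n_cells_per_cluster: dict[str, int],
    n_genes: int = 500,
    n_marker_genes: int = 10,
    planted_lfc: float = 1.0,
    mito_fraction_high: float = 0.0,
    seed: int = 0,
    *,
    n_mito_genes: int = 10,
    n_high_mito_cells: int = 0,
    n_low_coverage_cells: int = 0,
    low_coverage_genes: int = 50,
    nb_dispersion: float = 10.0,
    base_mean_meanlog: float = 0.0,
    base_mean_sdlog: float = 0.5,
) -> tuple[ad.AnnData, GroundTruth]:
    """Generate negative-binomial scRNA counts with planted marker genes.

    Each cluster receives ``n_marker_genes`` genes whose mean is shifted by
    ``planted_lfc`` (log2) in that cluster.  The first ``n_mito_genes`` genes
    are named ``MT-<i>``.  Optionally the first ``n_high_mito_cells`` cells
    of the first cluster have their mitochondrial counts inflated to a
    ``mito_fraction_high`` share of the cell total, and the next
    ``n_low_coverage_cells`` cells are thinned to ``low_coverage_genes``
    detected genes, to exercise the QC filters.
    """
    if n_marker_genes * len(n_cells_per_cluster) + n_mito_genes > n_genes:
        raise ConfigError("n_genes too small for the requested marker blocks")
    if planted_lfc == 0.0 and n_marker_genes > 0:
        raise ConfigError(
            "planted_lfc = 0 with marker genes makes the planted truth "
            "unidentifiable"
        )
    if n_high_mito_cells > 0 and not 0.0 < mito_fraction_high < 1.0:
        raise ConfigError("mito_fraction_high must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    clusters = list(n_cells_per_cluster)
    n_cells = int(sum(n_cells_per_cluster.values()))

    gene_names = [f"MT-{i + 1}" for i in range(n_mito_genes)]
    marker_of: dict[int, str] = {}
    for c in clusters:
        for i in range(n_marker_genes):
            marker_of[len(gene_names)] = c
            gene_names.append(f"MK-{c}-{i + 1}")
    while len(gene_names) < n_genes:
        gene_names.append(f"BG-{len(gene_names) + 1}")

    base_mean = rng.lognormal(base_mean_meanlog, base_mean_sdlog, size=n_genes)
    base_mean[:n_mito_genes] = 1.0  # stable mitochondrial background share
    # marker genes are, by definition, reliably detected: draw their baseline
    # from a moderately expressed law instead of the genome-wide one
    marker_idx = np.array(sorted(marker_of), dtype=int)
    if len(marker_idx):
        base_mean[marker_idx] = rng.lognormal(
            np.log(2.0), 0.3, size=len(marker_idx)
        )

    labels = np.concatenate(
        [np.repeat(c, n_cells_per_cluster[c]) for c in clusters]
    )
    mu = np.tile(base_mean, (n_cells, 1))
    for g, c in marker_of.items():
        mu[labels == c, g] *= 2.0 ** planted_lfc
    # NB(mean mu, size r): p = r / (r + mu)
    r = nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    mito_idx = np.arange(n_mito_genes)
    f = mito_fraction_high
    for i in range(n_high_mito_cells):
        nonmito = counts[i, n_mito_genes:].sum()
        target = int(np.ceil(f / (1.0 - f) * max(nonmito, 1)))
        per_gene = np.full(n_mito_genes, target // n_mito_genes)
        per_gene[: target % n_mito_genes] += 1
        counts[i, mito_idx] = per_gene
    for i in range(n_high_mito_cells, n_high_mito_cells + n_low_coverage_cells):
        keep = rng.choice(n_genes, size=low_coverage_genes, replace=False)
        mask = np.zeros(n_genes, dtype=bool)
        mask[keep] = True
        counts[i, ~mask] = 0

    obs = pd.DataFrame(
        {"cluster": labels},
        index=pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell_id"),
    )
    var = pd.DataFrame(
        {
            "is_mito": [g.startswith("MT-") for g in gene_names],
            "marker_cluster": [marker_of.get(i, "") for i in range(n_genes)],
            "true_lfc": [
                planted_lfc if i in marker_of else 0.0 for i in range(n_genes)
            ],
        },
        index=pd.Index(gene_names, name="gene"),
    )
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    truth_genes = var.reset_index().rename(columns={"index": "gene"})
    truth_cells = obs.reset_index()
    truth_cells["qc_high_mito"] = [
        i < n_high_mito_cells for i in range(n_cells)
    ]
    truth_cells["qc_low_coverage"] = [
        n_high_mito_cells <= i < n_high_mito_cells + n_low_coverage_cells
        for i in range(n_cells)
    ]
    return adata, GroundTruth(cells=truth_cells, genes=truth_genes)


# ---------------------------------------------------------------------------
# spatial transcriptomics
# ---------------------------------------------------------------------------

def _layout_grid(grid_rows: int, grid_cols: int, layout) -> np.ndarray:
    if isinstance(layout, np.ndarray):
        if layout.shape != (grid_rows, grid_cols):
            raise ConfigError("layout array shape does not match the grid")
        return layout.astype(object)
    if layout == "vertical_split":
        grid = np.empty((grid_rows, grid_cols), dtype=object)
        grid[:, : grid_cols // 2] = "FB"
        grid[:, grid_cols // 2:] = "endothelial"
        return grid
    if layout == "three_band":
        grid = np.empty((grid_rows, grid_cols), dtype=object)
        third = max(grid_rows // 3, 1)
        grid[:third, :] = "tumor"
        grid[third: 2 * third, :] = "FB"
        grid[2 * third:, :] = "endothelial"
        return grid
    raise ConfigError(f"unknown layout '{layout}'")


def true_boundary_mask(grid: np.ndarray) -> np.ndarray:
    """FB/endothelial boundary of a true-region grid under 4-adjacency."""
    rows, cols = grid.shape
    out = np.zeros(grid.shape, dtype=bool)
    for i in range(rows):
        for j in range(cols):
            lab = grid[i, j]
            if lab not in ("FB", "endothelial"):
                continue
            partner = "endothelial" if lab == "FB" else "FB"
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < rows and 0 <= nj < cols and grid[ni, nj] == partner:
                    out[i, j] = True
                    break
    return out


def gen_st(
    grid_rows: int,
    grid_cols: int,
    layout="vertical_split",
    lr_pair: tuple[str, str] = ("JAG2", "NOTCH1"),
    boundary_coexpression_rate: float = 0.8,
    background_coexpression_rate: float = 0.05,
    seed: int = 0,
    *,
    concentration: float = 50.0,
    true_weight: float = 0.8,
    n_signature_genes: int = 10,
    n_background_genes: int = 30,
    signature_high_region: str = "FB",
    spot_pitch: float = 100.0,
) -> tuple[SpotTable, GroundTruth]:
    """Generate a spot lattice with planted regions and boundary L-R signal.

    Deconvolution fractions are Dirichlet draws concentrated (weight
    ``true_weight`` at total concentration ``concentration``) on the spot's
    true region, so true-region spots exceed the 60% rule with high
    probability; ``concentration -> inf`` recovers the layout exactly.
    Ligand/receptor counts are co-positive with probability
    ``boundary_coexpression_rate`` at true-boundary spots and
    ``background_coexpression_rate`` elsewhere; a non-co-positive spot
    expresses at most one of the two genes.  Signature genes ``SIG-i`` are
    elevated in ``signature_high_region`` spots.
    """
    if grid_rows < 2 or grid_cols < 2:
        raise ConfigError("grid must be at least 2x2")
    for rate in (boundary_coexpression_rate, background_coexpression_rate):
        if not 0.0 <= rate <= 1.0:
            raise ConfigError("co-expression rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    grid = _layout_grid(grid_rows, grid_cols, layout)
    boundary = true_boundary_mask(grid)

    types = ("tumor", "FB", "endothelial", "other")
    records = []
    fractions = []
    for i in range(grid_rows):
        for j in range(grid_cols):
            lab = grid[i, j]
            if lab in ("tumor", "FB", "endothelial"):
                w = np.full(len(types), (1.0 - true_weight) / (len(types) - 1))
                w[types.index(lab)] = true_weight
            else:
                w = np.full(len(types), 1.0 / len(types))
            fractions.append(rng.dirichlet(w * concentration))
            records.append(
                {
                    "spot_id": f"s{i:03d}_{j:03d}",
                    "row": i,
                    "col": j,
                    "x": j * spot_pitch,
                    "y": i * spot_pitch,
                    "true_region": lab,
                    "true_boundary": bool(boundary[i, j]),
                }
            )
    spots = pd.DataFrame.from_records(records)
    fr = np.asarray(fractions)
    for k, tname in enumerate(types):
        spots[f"frac_{tname}"] = fr[:, k]

    n_spots = len(spots)
    ligand, receptor = lr_pair
    gene_names = [ligand, receptor]
    gene_names += [f"SIG-{i + 1}" for i in range(n_signature_genes)]
    gene_names += [f"BG-{i + 1}" for i in range(n_background_genes)]
    X = np.zeros((n_spots, len(gene_names)), dtype=np.int64)

    is_boundary = spots["true_boundary"].to_numpy()
    rate = np.where(
        is_boundary, boundary_coexpression_rate, background_coexpression_rate
    )
    copositive = rng.uniform(size=n_spots) < rate
    both = 1 + rng.poisson(4.0, size=(n_spots, 2))
    single_gene = rng.integers(2, size=n_spots)
    single_count = rng.poisson(1.0, size=n_spots)
    for s in range(n_spots):
        if copositive[s]:
            X[s, 0], X[s, 1] = both[s]
        else:
            X[s, single_gene[s]] = single_count[s]

    sig_cols = slice(2, 2 + n_signature_genes)
    bg_cols = slice(2 + n_signature_genes, len(gene_names))
    high = (spots["true_region"] == signature_high_region).to_numpy()
    X[:, sig_cols] = rng.poisson(0.3, size=(n_spots, n_signature_genes))
    X[high, sig_cols] = rng.poisson(
        5.0, size=(int(high.sum()), n_signature_genes)
    )
    X[:, bg_cols] = rng.poisson(1.0, size=(n_spots, n_background_genes))

    expr = ad.AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame(index=pd.Index(spots["spot_id"], name="spot_id")),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
    )
    truth = spots[["spot_id", "true_region", "true_boundary"]].copy()
    truth["lr_copositive"] = copositive
    table = SpotTable(
        spots=spots.drop(columns=["true_region", "true_boundary"]), expr=expr
    )
    return table, GroundTruth(spots=truth)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def gen_survival(
    n: int,
    scores: pd.Series | np.ndarray,
    log_hazard_coef: float,
    censor_rate: float = 0.3,
    seed: int = 0,
    *,
    base_rate: float = 0.1,
) -> pd.DataFrame:
    """Exponential survival times with log-hazard linear in the score.

    Event time ``T_i ~ Exp(base_rate * exp(beta * z_i))`` with ``z`` the
    standardized score; censoring times are independent uniform on
    ``(0, m)`` with ``m`` solved so the expected censored share equals
    ``censor_rate``.
    """
    scores = np.asarray(pd.Series(scores).to_numpy(), dtype=float)
    if len(scores) != n:
        raise ConfigError("n must equal the length of scores")
    if not 0.0 <= censor_rate < 1.0:
        raise ConfigError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros(n)
    lam = base_rate * np.exp(log_hazard_coef * z)
    t_event = rng.exponential(1.0 / lam)
    if censor_rate == 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        def censored_share(m: float) -> float:
            # P(C < T) for C ~ U(0, m), T ~ Exp(lam): (1 - exp(-lam m))/(lam m)
            return float(np.mean((1.0 - np.exp(-lam * m)) / (lam * m)))

        m = scipy.optimize.brentq(
            lambda m: censored_share(m) - censor_rate, 1e-9, 1e9
        )
        t_cens = rng.uniform(0.0, m, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    return pd.DataFrame(
        {
            "sample": [f"sample{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "score": scores,
        }
    )
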