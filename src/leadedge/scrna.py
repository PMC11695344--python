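"""Single-cell RNA stage: QC filtering, normalization, differential
expression, and a cluster-label permutation ligand-receptor test.

QC applies the conventional hard thresholds — drop cells with fewer than
200 detected genes or more than 10% mitochondrial counts (both strict), then
drop genes detected in fewer than 3 cells, recomputed after cell removal.
Differential expression is a two-sided Wilcoxon rank-sum per gene (normal
approximation with tie correction; exact enumeration for tiny groups) with
Benjamini-Hochberg adjustment; significance requires |log2FC| >= 0.25 and
adjusted p < 0.05, with the fold change taken on mean linear normalized
expression with a pseudocount of 1.

The ligand-receptor test scores a (pair, cluster A, cluster B) triple as the
average of mean ligand expression in A and mean receptor expression in B,
and builds its null by permuting cluster labels over cells; the add-one
estimator p = (1 + #{null >= observed}) / (1 + n_perm) never returns 0.
"""
from __future__ import annotations

import itertools
import logging
from math import comb

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError
from .io import LRDatabase

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 12


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_mito: float = 0.10,
    min_cells: int = 3,
    mito_prefix: str = "MT-",
) -> ad.AnnData:
    """Drop low-quality cells, then sparsely detected genes.

    A cell is kept iff it has at least ``min_genes`` detected genes AND a
    mitochondrial count share of at most ``max_mito`` (both comparisons
    strict on the removal side).  Genes seen in fewer than ``min_cells``
    of the *remaining* cells are then dropped.
    """
    X = sp.csr_matrix(adata.X)
    n_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    is_mito = adata.var_names.str.startswith(mito_prefix)
    mito_counts = np.asarray(X[:, is_mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        mito_fraction = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep_cells = (n_detected >= min_genes) & (mito_fraction <= max_mito)
    if not keep_cells.any():
        raise ValidationError(
            f"QC removed all {adata.n_obs} cells "
            f"({int((n_detected < min_genes).sum())} low-coverage, "
            f"{int((mito_fraction > max_mito).sum())} high-mito)"
        )
    out = adata[keep_cells].copy()
    n_cells_expr = np.asarray((sp.csr_matrix(out.X) > 0).sum(axis=0)).ravel()
    keep_genes = n_cells_expr >= min_cells
    out = out[:, keep_genes].copy()
    out.obs["n_genes_detected"] = n_detected[keep_cells]
    out.obs["mito_fraction"] = mito_fraction[keep_cells]
    out.var["n_cells_expressing"] = n_cells_expr[keep_genes]
    logger.info(
        "QC kept %d/%d cells and %d/%d genes",
        out.n_obs, adata.n_obs, out.n_vars, adata.n_vars,
    )
    return out


def normalize_log(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Library-size normalize and log-transform.

    Per cell: counts / cell_total * scale, then log2(x + 1) into ``X``; the
    linear normalized values are kept in ``layers['norm']``.  Zero-total
    cells are removed with a warning.
    """
    if scale <= 0:
        raise ConfigError("normalization scale must be positive")
    X = sp.csr_matrix(adata.X).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    keep = totals > 0
    if not keep.all():
        logger.warning("removing %d zero-total cell(s)", int((~keep).sum()))
    out = adata[keep].copy()
    X = sp.csr_matrix(out.X).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    norm = sp.diags(scale / totals) @ X
    out.layers["norm"] = norm.tocsr()
    out.X = norm.copy()
    out.X.data = np.log2(out.X.data + 1.0)
    return out


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n_a = len(x)
    observed = ranks[:n_a].sum()
    mu = ranks.sum() * n_a / len(pooled)
    obs_dev = abs(observed - mu)
    count = 0
    total = comb(len(pooled), n_a)
    for combo in itertools.combinations(range(len(pooled)), n_a):
        if abs(ranks[list(combo)].sum() - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def de_wilcoxon(
    adata: ad.AnnData,
    group_a,
    group_b,
    lfc_threshold: float = 0.25,
    padj_threshold: float = 0.05,
    groupby: str = "cluster",
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum between two cluster sets.

    Expects a normalized matrix (:func:`normalize_log`).  Fold change is
    ``log2((mean_norm_A + 1) / (mean_norm_B + 1))`` on linear normalized
    expression; p-values use the normal approximation with tie correction,
    or exact enumeration when ``n_A + n_B <= 12``; BH adjustment is across
    the tested genes of this one comparison.
    """
    group_a = {group_a} if isinstance(group_a, str) else set(group_a)
    group_b = {group_b} if isinstance(group_b, str) else set(group_b)
    if group_a & group_b:
        raise ValidationError("group_a and group_b overlap")
    labels = adata.obs[groupby]
    mask_a = labels.isin(group_a).to_numpy()
    mask_b = labels.isin(group_b).to_numpy()
    if not mask_a.any() or not mask_b.any():
        raise ValidationError("both groups must be non-empty")
    if "norm" not in adata.layers:
        raise ValidationError("matrix is not normalized; run normalize_log")
    log_vals = _dense(adata.X)
    lin = _dense(adata.layers["norm"])
    a, b = log_vals[mask_a], log_vals[mask_b]
    mean_a = lin[mask_a].mean(axis=0)
    mean_b = lin[mask_b].mean(axis=0)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a + n_b <= EXACT_WILCOXON_MAX_N:
        pvals = np.array(
            [_exact_ranksum_p(a[:, g], b[:, g]) for g in range(adata.n_vars)]
        )
    else:
        res = scipy.stats.mannwhitneyu(
            a, b, axis=0, alternative="two-sided", method="asymptotic"
        )
        pvals = np.asarray(res.pvalue)
    constant = np.array(
        [np.ptp(np.concatenate([a[:, g], b[:, g]])) == 0
         for g in range(adata.n_vars)]
    )
    pvals = np.where(constant, 1.0, pvals)
    padj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": adata.var_names,
            "log2fc": lfc,
            "pvalue": pvals,
            "padj": padj,
        }
    )
    out["significant"] = (np.abs(out["log2fc"]) >= lfc_threshold) & (
        out["padj"] < padj_threshold
    )
    return out


def lr_permutation_test(
    adata: ad.AnnData,
    db: LRDatabase,
    min_expressed_fraction: float = 0.10,
    n_perm: int = 1000,
    seed: int = 0,
    groupby: str = "cluster",
    cluster_pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Cluster-label permutation test of ligand-receptor interactions.

    For every database pair and ordered cluster pair (A, B), the score is
    ``(mean ligand in A + mean receptor in B) / 2`` on the log-normalized
    matrix.  Triples where the ligand's expressed fraction in A or the
    receptor's in B falls below ``min_expressed_fraction`` are not tested.
    The null permutes cluster labels over all cells ``n_perm`` times
    (jointly for all triples); p = (1 + #{null >= obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100 for usable p resolution")
    labels = adata.obs[groupby].to_numpy()
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ValidationError("at least two clusters required")
    if cluster_pairs is None:
        cluster_pairs = [
            (a, b) for a in clusters for b in clusters if a != b
        ]
    rng = np.random.default_rng(seed)

    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    usable = []
    for _, row in db.pairs.iterrows():
        lig, rec, pid = row["ligand"], row["receptor"], row["pair_id"]
        if lig not in gene_index or rec not in gene_index:
            logger.info("pair %s skipped: gene absent from matrix", pid)
            continue
        usable.append((pid, lig, rec))
    if not usable:
        raise ValidationError("no ligand-receptor pair is testable")

    genes = sorted({g for _, l, r in usable for g in (l, r)})
    G = _dense(adata[:, genes].X).T  # genes x cells, log-normalized
    gpos = {g: i for i, g in enumerate(genes)}
    masks = {c: labels == c for c in clusters}

    # observed cluster means / expressed fractions
    obs_mean = {c: G[:, masks[c]].mean(axis=1) for c in clusters}
    obs_frac = {c: (G[:, masks[c]] > 0).mean(axis=1) for c in clusters}

    records = []
    tested: list[tuple[int, int, int]] = []  # (record idx, lig row, rec row)
    for pid, lig, rec in usable:
        for a, b in cluster_pairs:
            frac_l = float(obs_frac[a][gpos[lig]])
            frac_r = float(obs_frac[b][gpos[rec]])
            if frac_l < min_expressed_fraction or frac_r < min_expressed_fraction:
                logger.info(
                    "pair %s (%s->%s) not tested: expressed fraction below "
                    "%.2f", pid, a, b, min_expressed_fraction,
                )
                continue
            score = 0.5 * (obs_mean[a][gpos[lig]] + obs_mean[b][gpos[rec]])
            tested.append((len(records), gpos[lig], gpos[rec]))
            records.append(
                {
                    "pair_id": pid,
                    "ligand": lig,
                    "receptor": rec,
                    "cluster_a": a,
                    "cluster_b": b,
                    "score": float(score),
                    "expressed_fraction_ligand": frac_l,
                    "expressed_fraction_receptor": frac_r,
                }
            )
    if not records:
        return pd.DataFrame(
            columns=[
                "pair_id", "ligand", "receptor", "cluster_a", "cluster_b",
                "score", "expressed_fraction_ligand",
                "expressed_fraction_receptor", "pvalue",
            ]
        )

    exceed = np.zeros(len(records), dtype=int)
    n_cells = adata.n_obs
    obs_scores = np.array([r["score"] for r in records])
    for _ in range(n_perm):
        perm = rng.permutation(n_cells)
        permuted = labels[perm]
        null_mean = {c: G[:, permuted == c].mean(axis=1) for c in clusters}
        for rec_i, (ri, li, gi) in enumerate(tested):
            a = records[ri]["cluster_a"]
            b = records[ri]["cluster_b"]
            null_score = 0.5 * (null_mean[a][li] + null_mean[b][gi])
            if null_score >= obs_scores[ri]:
                exceed[ri] += 1
    out = pd.DataFrame.from_records(records)
    out["pvalue"] = (1.0 + exceed) / (1.0 + n_perm)
    return out
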