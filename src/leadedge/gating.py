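"""Marker transformation, threshold fitting, and rule-based cell typing.

The interactive gating of cytometry practice is replaced here by a
reproducible pipeline: arcsinh variance stabilization, per-marker positivity
thresholds (Otsu on a 256-bin histogram by default, or an empirical
quantile), an ordered rule list for lineage assignment, and the four-marker
sign-pattern table that splits stromal fibroblasts into subtypes S1-S4 over
(aSMA, CollagenI, Vimentin, CD90):

    S1: (-, +, -, +)    S2: (+, +, -, +)
    S3: (+, +, +, +)    S4: (-, +, +, +)

All other 12 sign patterns map to ``unassigned``.  Positivity is strict
(transformed intensity > threshold), which keeps constant-marker columns
well defined (every cell negative).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

TRANSFORM_PREFIX = "asinh_"

FB_MARKERS = ("aSMA", "CollagenI", "Vimentin", "CD90")

#: fibroblast subtype sign patterns over FB_MARKERS (True = positive)
FB_PATTERNS: dict[tuple[bool, bool, bool, bool], str] = {
    (False, True, False, True): "S1",
    (True, True, False, True): "S2",
    (True, True, True, True): "S3",
    (False, True, True, True): "S4",
}


@dataclass(frozen=True)
class GatingRule:
    """One ordered gating rule: positives AND negatives -> label.

    ``any_positive`` rules fire when at least one listed marker is positive
    (used for the stromal CollagenI-or-Vimentin gate).
    """

    label: str
    positives: tuple[str, ...] = ()
    negatives: tuple[str, ...] = ()
    any_positive: bool = False


@dataclass
class GatingRuleSet:
    """Ordered gating rules; the first matching rule wins."""

    rules: list[GatingRule] = field(default_factory=list)
    fb_markers: tuple[str, str, str, str] = FB_MARKERS

    def referenced_markers(self) -> set[str]:
        out: set[str] = set()
        for r in self.rules:
            out.update(r.positives)
            out.update(r.negatives)
        return out


def default_rules(stromal_requires_both: bool = False) -> GatingRuleSet:
    """The default lineage gate order.

    Immune subtypes are resolved before non-immune lineages; within immune,
    B cells, macrophages, then CD8 before CD4 T cells (so CD8 wins for
    CD4/CD8 double positives).  The stromal gate is CollagenI OR Vimentin by
    default (``stromal_requires_both=True`` switches it to AND).
    """
    stromal = GatingRule(
        label="stromal",
        positives=("CollagenI", "Vimentin"),
        negatives=("CD45",),
        any_positive=not stromal_requires_both,
    )
    return GatingRuleSet(
        rules=[
            GatingRule("B", positives=("CD45", "CD20")),
            GatingRule("macrophage", positives=("CD45", "CD68")),
            GatingRule("CD8 T", positives=("CD45", "CD3", "CD8")),
            GatingRule("CD4 T", positives=("CD45", "CD3", "CD4")),
            GatingRule("immune", positives=("CD45",)),
            GatingRule("endothelial", positives=("CD31",), negatives=("CD45",)),
            GatingRule("tumor", positives=("PanCK",), negatives=("CD45",)),
            stromal,
        ]
    )


@dataclass
class ThresholdSet:
    """Per-marker positivity thresholds on the transformed scale."""

    thresholds: dict[str, float]
    method: str

    def __post_init__(self) -> None:
        for marker, th in self.thresholds.items():
            if not np.isfinite(th):
                raise ValidationError(f"non-finite threshold for '{marker}'")


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance-maximizing cut over an nbins histogram.

    When the two modes are separated by an empty valley every cut inside the
    valley ties for the maximum; the midpoint of the tied plateau is
    returned, which places the threshold mid-valley rather than hugging the
    lower mode.
    """
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)[:-1].astype(float)
    w1 = counts.sum() - w0
    csum = np.cumsum(counts * centers)[:-1]
    total_sum = (counts * centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (total_sum - csum) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
    var = np.where((w0 == 0) | (w1 == 0), -np.inf, var)
    best = var.max()
    tied = np.flatnonzero(np.isclose(var, best, rtol=1e-12, atol=0.0))
    cut = tied[len(tied) // 2] + 1  # classes split as [0, cut) / [cut, nbins)
    return float(edges[cut])


def transform_intensities(
    t: pd.DataFrame, markers: list[str], cofactor: float = 1.0
) -> pd.DataFrame:
    """Add arcsinh(raw / cofactor) columns (prefixed) alongside raw values."""
    if cofactor <= 0:
        raise ConfigError("arcsinh cofactor must be positive")
    out = t.copy()
    for m in markers:
        out[TRANSFORM_PREFIX + m] = np.arcsinh(out[m].to_numpy(dtype=float) / cofactor)
    return out


def fit_thresholds(
    t: pd.DataFrame,
    markers: list[str],
    method: str = "otsu",
    q: float | None = None,
) -> ThresholdSet:
    """Fit a positivity threshold per marker on the transformed scale.

    ``otsu`` maximizes between-class variance over a 256-bin histogram of
    the transformed values; ``quantile`` takes the empirical ``q``-quantile
    (midpoint convention).  A constant marker yields its constant value with
    a warning — under strict positivity every cell is then negative.
    """
    if method not in ("otsu", "quantile"):
        raise ConfigError(f"unknown threshold method '{method}'")
    if method == "quantile":
        if q is None or not 0.0 < q < 1.0:
            raise ConfigError("quantile method requires q in (0, 1)")
    thresholds: dict[str, float] = {}
    for m in markers:
        col = TRANSFORM_PREFIX + m
        if col not in t.columns:
            raise ValidationError(
                f"transformed intensities missing for '{m}'; run "
                "transform_intensities first"
            )
        values = t[col].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            logger.warning(
                "marker '%s' is constant; threshold set to the constant "
                "(all cells negative under strict positivity)", m,
            )
            thresholds[m] = float(values[0])
        elif method == "otsu":
            thresholds[m] = otsu_threshold(values, nbins=256)
        else:
            thresholds[m] = float(np.quantile(values, q))
    return ThresholdSet(thresholds=thresholds, method=method)


def _positivity(t: pd.DataFrame, th: ThresholdSet, marker: str) -> np.ndarray:
    if marker not in th.thresholds:
        raise ConfigError(f"no threshold fitted for marker '{marker}'")
    return t[TRANSFORM_PREFIX + marker].to_numpy(dtype=float) > th.thresholds[marker]


def gate_cell_types(
    t: pd.DataFrame, th: ThresholdSet, rules: GatingRuleSet | None = None
) -> pd.DataFrame:
    """Assign exactly one ``cell_type`` per cell by the ordered rule list.

    Cells matched by no rule are labeled ``unassigned``.
    """
    if rules is None:
        rules = default_rules()
    missing = {
        m for m in rules.referenced_markers() if m not in th.thresholds
    }
    if missing:
        raise ConfigError(
            f"gating rules reference markers outside the panel: {sorted(missing)}"
        )
    pos = {m: _positivity(t, th, m) for m in rules.referenced_markers()}
    labels = np.full(len(t), "unassigned", dtype=object)
    unset = np.ones(len(t), dtype=bool)
    for rule in rules.rules:
        if rule.positives:
            if rule.any_positive:
                match = np.logical_or.reduce([pos[m] for m in rule.positives])
            else:
                match = np.logical_and.reduce([pos[m] for m in rule.positives])
        else:
            match = np.ones(len(t), dtype=bool)
        for m in rule.negatives:
            match &= ~pos[m]
        fire = match & unset
        labels[fire] = rule.label
        unset &= ~fire
    out = t.copy()
    out["cell_type"] = labels
    return out


def classify_fb_subtypes(t: pd.DataFrame, th: ThresholdSet) -> pd.DataFrame:
    """Assign fibroblast subtypes S1-S4 to stromal cells by sign pattern.

    Non-stromal cells and stromal cells whose (aSMA, CollagenI, Vimentin,
    CD90) pattern is outside the four defined rows get ``unassigned``.
    """
    if "cell_type" not in t.columns:
        raise ValidationError("cell_type must be assigned before fb subtyping")
    missing = [m for m in FB_MARKERS if m not in th.thresholds]
    if missing:
        raise ConfigError(f"missing thresholds for FB markers {missing}")
    pos = np.column_stack([_positivity(t, th, m) for m in FB_MARKERS])
    # encode the 4-bit sign pattern and map through a 16-entry lookup
    code = pos @ (1 << np.arange(3, -1, -1))
    lookup = np.full(16, "unassigned", dtype=object)
    for pattern, name in FB_PATTERNS.items():
        lookup[int(np.dot(pattern, 1 << np.arange(3, -1, -1)))] = name
    subtype = np.full(len(t), "unassigned", dtype=object)
    stromal = (t["cell_type"] == "stromal").to_numpy()
    subtype[stromal] = lookup[code[stromal]]
    out = t.copy()
    out["fb_subtype"] = subtype
    return out


def threshold_report(t: pd.DataFrame, th: ThresholdSet) -> pd.DataFrame:
    """Tabulate each marker's threshold and percent-positive cells."""
    rows = []
    for m, value in th.thresholds.items():
        frac = float(np.mean(_positivity(t, th, m)))
        rows.append(
            {"marker": m, "method": th.method, "threshold": value,
             "pct_positive": 100.0 * frac}
        )
    return pd.DataFrame(rows)
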