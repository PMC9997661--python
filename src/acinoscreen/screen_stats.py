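"""Phenotype-frequency statistics for the 3D morphogenesis screen.

Classified, tracked objects are aggregated into 12-h time bins and compared
to the control condition (Scr shRNA in the original screen):

* per-cell log2 fold change of class proportions (shared pseudocount),
* Z-scored control proportions per class across bins,
* Cochran-Mantel-Haenszel chi-squared stratified by experimental
  replicate, Bonferroni-adjusted over all heatmap cells,
* Breslow-Day homogeneity of the odds ratio across replicates
  (non-significance = consistent effect magnitude),
* an optional parallel "Area" channel (mean Z-scored area, pooled-variance
  t test vs. control),
* complete-linkage Euclidean clustering of fold-change profiles into
  phenotype groups.

The CMH statistic is the classical no-continuity-correction form

    chi2_CMH = [sum_k (a_k - E_k)]^2 / sum_k V_k,
    E_k = n1k * m1k / Tk,   V_k = n1k n2k m1k m2k / (Tk^2 (Tk - 1)),

and Breslow-Day fits each stratum's expected count under the
Mantel-Haenszel common odds ratio (no Tarone adjustment), matching the R
DescTools defaults.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from . import CLASS_NAMES
from .scoring_stats import bonferroni_adjust, student_t_test

logger = logging.getLogger(__name__)

__all__ = [
    "StratifiedTable",
    "bin_phenotypes",
    "log2_fold_change",
    "zscore_normalize",
    "cmh_test",
    "breslow_day_test",
    "build_heatmap",
    "build_area_channel",
    "cluster_phenotype_groups",
    "GroupAssignment",
]

BIN_WIDTH_H = 12.0


@dataclass
class StratifiedTable:
    """K strata of 2x2 tables ``[[a, b], [c, d]]``.

    Rows are (condition, control); columns are (in class, not in class).
    """

    strata: np.ndarray  # shape (K, 2, 2)

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata, dtype=float)
        if self.strata.ndim != 3 or self.strata.shape[1:] != (2, 2):
            raise ValueError("strata must have shape (K, 2, 2)")
        if (self.strata < 0).any():
            raise ValueError("all entries must be nonnegative")

    @property
    def n_strata(self) -> int:
        return self.strata.shape[0]

    def informative(self) -> np.ndarray:
        """Strata whose four margins are all positive.

        Strata with a zero margin carry no information about association
        and are dropped from the CMH and Breslow-Day statistics.
        """
        t = self.strata
        row1 = t[:, 0].sum(axis=1)
        row2 = t[:, 1].sum(axis=1)
        col1 = t[:, :, 0].sum(axis=1)
        col2 = t[:, :, 1].sum(axis=1)
        keep = (row1 > 0) & (row2 > 0) & (col1 > 0) & (col2 > 0)
        if not keep.all():
            logger.warning(
                "dropping %d/%d strata with a zero margin",
                int((~keep).sum()), keep.size,
            )
        return t[keep]


def cmh_test(table: StratifiedTable) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-squared test (df = 1).

    No continuity correction.  Strata with a zero margin are dropped; if
    every stratum is degenerate the result is flagged undefined and
    ``(nan, 1.0)`` is returned.
    """
    strata = table.informative()
    if strata.shape[0] == 0:
        return float("nan"), 1.0
    a = strata[:, 0, 0]
    n1 = strata[:, 0].sum(axis=1)
    n2 = strata[:, 1].sum(axis=1)
    m1 = strata[:, :, 0].sum(axis=1)
    m2 = strata[:, :, 1].sum(axis=1)
    t = n1 + n2
    expected = n1 * m1 / t
    var = n1 * n2 * m1 * m2 / (t ** 2 * (t - 1))
    denom = var.sum()
    if denom <= 0:
        return float("nan"), 1.0
    statistic = (a - expected).sum() ** 2 / denom
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def mantel_haenszel_or(strata: np.ndarray) -> float:
    """Mantel-Haenszel common odds ratio ``sum(ad/T) / sum(bc/T)``."""
    a, b = strata[:, 0, 0], strata[:, 0, 1]
    c, d = strata[:, 1, 0], strata[:, 1, 1]
    t = strata.sum(axis=(1, 2))
    r = (a * d / t).sum()
    s = (b * c / t).sum()
    if s == 0 or r == 0:
        raise ValueError(
            "Mantel-Haenszel common odds ratio is zero or infinite; "
            "homogeneity test undefined"
        )
    return float(r / s)


def _fitted_cell(n1: float, m1: float, t: float, psi: float) -> float:
    """Expected a-cell under common odds ratio psi with fixed margins.

    Root of ``psi (n1-a)(m1-a) = a (t-n1-m1+a)`` within the admissible
    interval [max(0, n1+m1-t), min(n1, m1)].
    """
    lo, hi = max(0.0, n1 + m1 - t), min(n1, m1)
    if abs(psi - 1.0) < 1e-12:
        return n1 * m1 / t
    # (psi-1) a^2 - [psi(n1+m1) + (t-n1-m1)] a + psi n1 m1 = 0
    qa = psi - 1.0
    qb = -(psi * (n1 + m1) + (t - n1 - m1))
    qc = psi * n1 * m1
    disc = qb * qb - 4 * qa * qc
    disc = max(disc, 0.0)
    sq = np.sqrt(disc)
    for root in ((-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)):
        if lo - 1e-9 <= root <= hi + 1e-9:
            return float(np.clip(root, lo, hi))
    raise ArithmeticError("no admissible root for fitted cell")  # pragma: no cover


def breslow_day_test(table: StratifiedTable) -> tuple[float, float, float]:
    """Breslow-Day test of odds-ratio homogeneity across strata.

    Expected counts are fitted under the Mantel-Haenszel common odds
    ratio; no Tarone adjustment.  Returns ``(statistic, p, common_or)``
    with p from chi-squared on K-1 df.  Raises for fewer than two
    informative strata (homogeneity is undefined).
    """
    strata = table.informative()
    k = strata.shape[0]
    if k < 2:
        raise ValueError("Breslow-Day requires at least two informative strata")
    psi = mantel_haenszel_or(strata)
    statistic = 0.0
    for a, b, c, d in strata.reshape(k, 4):
        n1, m1 = a + b, a + c
        t = a + b + c + d
        a_fit = _fitted_cell(n1, m1, t, psi)
        b_fit, c_fit = n1 - a_fit, m1 - a_fit
        d_fit = t - n1 - m1 + a_fit
        with np.errstate(divide="ignore"):
            inv_var = 1 / a_fit + 1 / b_fit + 1 / c_fit + 1 / d_fit
        if not np.isfinite(inv_var):
            # fitted count on the boundary: stratum contributes no variance
            continue
        statistic += (a - a_fit) ** 2 * inv_var
    p = float(stats.chi2.sf(statistic, df=k - 1))
    return float(statistic), p, psi


def bin_phenotypes(
    labeled: pd.DataFrame,
    bin_width_h: float = BIN_WIDTH_H,
    time_column: str = "time_h",
    class_column: str = "label",
    class_names: tuple[str, ...] = CLASS_NAMES,
) -> pd.DataFrame:
    """Aggregate object-frame classifications into 12-h time bins.

    Each object contributes one count per frame it appears in.  Returns a
    table with columns ``condition, replicate, time_bin, class, count,
    bin_total``.
    """
    required = {"condition", "replicate", time_column, class_column}
    missing = required - set(labeled.columns)
    if missing:
        raise ValueError(f"labeled table is missing columns: {sorted(missing)}")
    if labeled[class_column].isna().any():
        raise ValueError("unlabeled record encountered (NaN class)")
    bad = set(labeled[class_column].unique()) - set(class_names)
    if bad:
        raise ValueError(f"labels outside the class set: {sorted(bad)}")
    if labeled.empty:
        return pd.DataFrame(
            columns=["condition", "replicate", "time_bin", "class",
                     "count", "bin_total"]
        )
    df = labeled[["condition", "replicate", time_column, class_column]].copy()
    df["time_bin"] = (df[time_column] // bin_width_h).astype(int)
    counts = (
        df.groupby(["condition", "replicate", "time_bin", class_column],
                   observed=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={class_column: "class"})
    )
    # complete the class index so absent classes get explicit zeros
    keys = counts[["condition", "replicate", "time_bin"]].drop_duplicates()
    full = keys.merge(pd.DataFrame({"class": list(class_names)}), how="cross")
    counts = full.merge(
        counts, on=["condition", "replicate", "time_bin", "class"], how="left"
    ).fillna({"count": 0})
    counts["count"] = counts["count"].astype(int)
    totals = (
        counts.groupby(["condition", "replicate", "time_bin"], observed=True)
        ["count"].transform("sum")
    )
    counts["bin_total"] = totals
    return counts.sort_values(
        ["condition", "replicate", "time_bin", "class"]
    ).reset_index(drop=True)


def _pooled_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Pool technical/experimental replicates: counts per (condition, bin, class)."""
    pooled = (
        counts.groupby(["condition", "time_bin", "class"], observed=True)
        ["count"].sum().reset_index()
    )
    pooled["total"] = (
        pooled.groupby(["condition", "time_bin"], observed=True)["count"]
        .transform("sum")
    )
    return pooled


def log2_fold_change(
    counts: pd.DataFrame,
    control_condition: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Log2 fold change of class proportions vs. the control condition.

    Proportions are pooled across replicates within each bin.  A shared
    pseudocount-derived offset eps = pseudocount / (N_cond + N_ctrl) is
    added to both proportions, so an empty class in both arms gives
    exactly 0.  A condition with no objects at all in a bin is flagged
    missing (NaN), not 0.

    Returns columns ``condition, time_bin, class, log2fc``.
    """
    pooled = _pooled_proportions(counts)
    ctrl = pooled[pooled["condition"] == control_condition]
    if ctrl.empty:
        raise ValueError(f"control condition {control_condition!r} absent")
    ctrl = ctrl.rename(columns={"count": "ctrl_count", "total": "ctrl_total"})[
        ["time_bin", "class", "ctrl_count", "ctrl_total"]
    ]
    cond = pooled[pooled["condition"] != control_condition]
    merged = cond.merge(ctrl, on=["time_bin", "class"], how="left")
    if merged["ctrl_total"].isna().any() or (merged["ctrl_total"] == 0).any():
        raise ValueError("control has empty bins; cannot form fold changes")
    p_cond = merged["count"] / merged["total"]
    p_ctrl = merged["ctrl_count"] / merged["ctrl_total"]
    eps = pseudocount / (merged["total"] + merged["ctrl_total"])
    lfc = np.log2((p_cond + eps) / (p_ctrl + eps))
    lfc = lfc.where(merged["total"] > 0, np.nan)  # empty condition bin -> missing
    out = merged[["condition", "time_bin", "class"]].copy()
    out["log2fc"] = lfc
    return out.reset_index(drop=True)


def zscore_normalize(values) -> np.ndarray:
    """(x - mean) / SD with the population SD; an all-constant series -> zeros."""
    x = np.asarray(values, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def build_stratified_tables(
    counts: pd.DataFrame, control_condition: str
) -> dict[tuple[str, str, int], StratifiedTable]:
    """Replicate-stratified 2x2xK tables for every (condition, class, bin).

    Each stratum is one experimental replicate:
    ``[[cond in class, cond not], [ctrl in class, ctrl not]]``.
    """
    tables: dict[tuple[str, str, int], StratifiedTable] = {}
    idx = counts.set_index(
        ["condition", "replicate", "time_bin", "class"]
    )["count"]
    tot = counts.drop_duplicates(["condition", "replicate", "time_bin"]).set_index(
        ["condition", "replicate", "time_bin"]
    )["bin_total"]
    conditions = [c for c in counts["condition"].unique()
                  if c != control_condition]
    replicates = sorted(counts["replicate"].unique())
    bins = sorted(counts["time_bin"].unique())
    classes = sorted(counts["class"].unique())
    for condition in conditions:
        for cls in classes:
            for b in bins:
                strata = []
                for rep in replicates:
                    try:
                        a = idx.loc[(condition, rep, b, cls)]
                        n1 = tot.loc[(condition, rep, b)]
                        c = idx.loc[(control_condition, rep, b, cls)]
                        n2 = tot.loc[(control_condition, rep, b)]
                    except KeyError:
                        continue
                    strata.append([[a, n1 - a], [c, n2 - c]])
                if strata:
                    tables[(condition, cls, b)] = StratifiedTable(
                        np.array(strata, dtype=float)
                    )
    return tables


def build_heatmap(
    counts: pd.DataFrame,
    control_condition: str,
    alpha: float = 0.05,
    alpha_bd: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per (condition, class, bin) heatmap cells.

    Columns: ``condition, class, time_bin, log2fc, control_z, cmh_p,
    cmh_p_adj, bd_p, homogeneous``.  CMH p-values are Bonferroni-multiplied
    by the number of cells in the heatmap (conditions x classes x bins),
    capped at 1.  ``homogeneous`` is ``bd_p >= alpha_bd``; with a single
    informative stratum the Breslow-Day test is undefined and the flag is
    reported as True with ``bd_p`` = NaN.
    """
    lfc = log2_fold_change(counts, control_condition, pseudocount)
    tables = build_stratified_tables(counts, control_condition)
    # Z-scored control proportion per class across bins (same for all conditions)
    pooled = _pooled_proportions(counts)
    ctrl = pooled[pooled["condition"] == control_condition].copy()
    if ctrl.empty:
        raise ValueError(f"control condition {control_condition!r} absent")
    ctrl["prop"] = ctrl["count"] / ctrl["total"]
    control_z: dict[tuple[str, int], float] = {}
    for cls, sub in ctrl.groupby("class", observed=True):
        sub = sub.sort_values("time_bin")
        z = zscore_normalize(sub["prop"].to_numpy())
        for b, zv in zip(sub["time_bin"], z):
            control_z[(cls, int(b))] = float(zv)

    records = []
    for _, row in lfc.iterrows():
        key = (row["condition"], row["class"], int(row["time_bin"]))
        table = tables.get(key)
        if table is None:
            cmh_p = np.nan
            bd_p = np.nan
        else:
            _, cmh_p = cmh_test(table)
            try:
                _, bd_p, _ = breslow_day_test(table)
            except ValueError:
                bd_p = np.nan
        records.append(
            {
                "condition": row["condition"],
                "class": row["class"],
                "time_bin": int(row["time_bin"]),
                "log2fc": row["log2fc"],
                "control_z": control_z.get(
                    (row["class"], int(row["time_bin"])), np.nan
                ),
                "cmh_p": cmh_p,
                "bd_p": bd_p,
            }
        )
    grid = pd.DataFrame.from_records(records)
    m = len(grid)  # Bonferroni family: every cell of this heatmap run
    grid["cmh_p_adj"] = np.minimum(1.0, grid["cmh_p"] * m)
    grid["homogeneous"] = grid["bd_p"].isna() | (grid["bd_p"] >= alpha_bd)
    return grid


def build_area_channel(
    labeled: pd.DataFrame,
    control_condition: str,
    bin_width_h: float = BIN_WIDTH_H,
    time_column: str = "time_h",
    area_column: str = "area",
) -> pd.DataFrame:
    """Parallel "Area" heatmap channel.

    Areas are Z-scored across all object-frames of the run, then per
    (condition, bin) the mean Z-scored area and the two-tailed
    pooled-variance t p-value vs. control in the same bin are reported,
    Bonferroni-adjusted over all cells.
    """
    df = labeled[["condition", time_column, area_column]].copy()
    df["time_bin"] = (df[time_column] // bin_width_h).astype(int)
    df["z_area"] = zscore_normalize(df[area_column].to_numpy())
    records = []
    for (condition, b), sub in df.groupby(["condition", "time_bin"],
                                          observed=True):
        if condition == control_condition:
            continue
        ctrl = df[(df["condition"] == control_condition)
                  & (df["time_bin"] == b)]
        if len(ctrl) < 2 or len(sub) < 2:
            p = np.nan
        else:
            _, _, p = student_t_test(sub["z_area"], ctrl["z_area"])
        records.append(
            {"condition": condition, "time_bin": int(b),
             "mean_z_area": float(sub["z_area"].mean()), "t_p": p}
        )
    out = pd.DataFrame.from_records(records)
    if not out.empty:
        out["t_p_adj"] = np.minimum(1.0, out["t_p"] * len(out))
    return out


@dataclass
class GroupAssignment:
    """Phenotype-group clustering result."""

    groups: dict[str, int]                 # condition -> group index (1..k)
    linkage: np.ndarray                    # scipy linkage matrix
    conditions: list[str]                  # leaf order of the linkage
    summaries: pd.DataFrame = field(default_factory=pd.DataFrame)
    overall: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.conditions[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def cluster_phenotype_groups(
    heatmap: pd.DataFrame,
    k: int = 7,
    counts: pd.DataFrame | None = None,
    class_names: tuple[str, ...] = CLASS_NAMES,
) -> GroupAssignment:
    """Complete-linkage Euclidean clustering of log2 fold-change profiles.

    Each condition's profile is its log2fc values concatenated over
    (class, bin); missing values are imputed as 0.  The dendrogram is cut
    into ``k`` groups.  When the phenotype count table is supplied, the
    per-group mean +/- SEM class-fraction time courses and the overall
    mean class proportions are summarised.
    """
    profiles = heatmap.pivot_table(
        index="condition", columns=["class", "time_bin"], values="log2fc",
        sort=True,
    ).sort_index()
    profiles = profiles.fillna(0.0)
    conditions = list(profiles.index)
    if k > len(conditions):
        raise ValueError(f"k={k} exceeds the {len(conditions)} conditions")
    x = profiles.to_numpy()
    if len(conditions) == 1:
        link = np.empty((0, 4))
        groups = {conditions[0]: 1}
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", hierarchy.ClusterWarning)
            link = hierarchy.linkage(x, method="complete", metric="euclidean")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
        groups = dict(zip(conditions, (int(v) for v in labels)))

    summaries = pd.DataFrame()
    overall = pd.DataFrame()
    if counts is not None and not counts.empty:
        pooled = _pooled_proportions(counts)
        pooled = pooled[pooled["condition"].isin(groups)]
        pooled["group"] = pooled["condition"].map(groups)
        pooled["fraction"] = pooled["count"] / pooled["total"]
        summaries = (
            pooled.groupby(["group", "class", "time_bin"], observed=True)
            ["fraction"]
            .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s))
                 if len(s) > 1 else 0.0)
            .reset_index()
        )
        overall = (
            pooled.groupby(["group", "class"], observed=True)["fraction"]
            .mean().rename("mean_fraction").reset_index()
        )
    return GroupAssignment(
        groups=groups, linkage=link, conditions=conditions,
        summaries=summaries, overall=overall,
    )
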