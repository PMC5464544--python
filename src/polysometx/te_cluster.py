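"""Translational-efficiency profiles, correlation k-means, gene-set summaries.

A gene's translational efficiency (TE) in a (cell line, condition) cell is
polysome CPM / total CPM, with CPM first averaged over replicates. The
per-gene profile over the ordered (cell line x {control, knockdown}) cells
— six values for three cell lines — is the clustering substrate.

Clustering uses Pearson-correlation similarity: each profile is z-scored
(mean 0, variance 1) and Euclidean k-means is run on the standardized
profiles. Squared Euclidean distance between z-scored vectors is an
increasing function of (1 - Pearson r), so the objective ordering matches
correlation distance while standard k-means machinery applies. Cluster
labels are renumbered 1..k by ascending mean knockdown-minus-control TE
change so the numbering is stable across seeds for well-separated data.

Gene-set (regulon) summaries report the set's TE quartiles per (cell line,
condition) and a per-cell-line coordination statistic — the median over the
set of (TE_KD - TE_CN) — with a permutation p-value from random same-size
gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import SampleDesign, ValidationError
from .normalize import CPMMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TEProfiles",
    "ClusterAssignment",
    "translational_efficiency",
    "kmeans_correlation",
    "cluster_trends",
    "geneset_te_summary",
]


@dataclass
class TEProfiles:
    """Per-gene TE over (cell line, condition) cells.

    ``values`` has a two-level column MultiIndex (cell_line, condition) in
    design order with conditions ordered (control, knockdown); ``excluded``
    lists genes dropped for a zero total-fraction denominator.
    """

    values: pd.DataFrame
    excluded: list[str]

    @property
    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))


def _first_seen(seq: Iterable[str]) -> list[str]:
    return list(dict.fromkeys(seq))


def translational_efficiency(
    cpm_mat: CPMMatrix,
    designs: Sequence[SampleDesign],
    order: str = "mean-first",
) -> TEProfiles:
    """Compute TE = polysome CPM / total CPM per (gene, cell line, condition).

    ``order="mean-first"`` (default) averages CPM over replicates within
    each (cell line, condition, fraction) and then takes the ratio — more
    stable at low counts. ``order="ratio-first"`` takes per-replicate ratios
    (pairing replicates by label) and averages those. Genes with any zero
    denominator are excluded and listed in the result.
    """
    if cpm_mat.log:
        raise ValidationError("translational_efficiency requires linear-scale CPM")
    if order not in ("mean-first", "ratio-first"):
        raise ValidationError("order must be 'mean-first' or 'ratio-first'")
    by_id = {d.sample_id: d for d in designs}
    missing = [s for s in cpm_mat.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(f"samples missing from design: {missing}")

    cells = _first_seen(d.cell_line for d in designs)
    conditions = ("control", "knockdown")
    cols: dict[tuple[str, str], pd.Series] = {}
    for cell in cells:
        for cond in conditions:
            groups: dict[str, list[str]] = {"total": [], "polysome": []}
            reps: dict[str, dict[str, str]] = {"total": {}, "polysome": {}}
            for s in cpm_mat.sample_ids:
                d = by_id[s]
                if d.cell_line == cell and d.condition == cond:
                    groups[d.fraction].append(s)
                    reps[d.fraction][d.replicate] = s
            if not groups["total"] or not groups["polysome"]:
                raise ValidationError(
                    f"missing fraction pairing for cell line {cell!r}, "
                    f"condition {cond!r}"
                )
            if order == "mean-first":
                num = cpm_mat.values[groups["polysome"]].mean(axis=1)
                den = cpm_mat.values[groups["total"]].mean(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    te = num / den
                te[den == 0] = np.nan
            else:
                shared = sorted(set(reps["total"]) & set(reps["polysome"]))
                if not shared:
                    raise ValidationError(
                        f"no replicate pairing between fractions for {cell!r}/{cond!r}"
                    )
                ratios = []
                for r in shared:
                    num = cpm_mat.values[reps["polysome"][r]]
                    den = cpm_mat.values[reps["total"][r]]
                    with np.errstate(divide="ignore", invalid="ignore"):
                        ratio = num / den
                    ratio[den == 0] = np.nan
                    ratios.append(ratio)
                te = pd.concat(ratios, axis=1).mean(axis=1, skipna=False)
            cols[(cell, cond)] = te

    values = pd.DataFrame(cols)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["cell_line", "condition"])
    bad = values.isna().any(axis=1)
    excluded = values.index[bad].tolist()
    if excluded:
        logger.info(
            "%d gene(s) excluded for zero total-fraction CPM: %s",
            len(excluded), excluded[:10],
        )
    return TEProfiles(values=values.loc[~bad], excluded=excluded)


@dataclass
class ClusterAssignment:
    """k-means result: 1-based labels, centroids (z-score space), objective."""

    labels: pd.Series
    centroids: np.ndarray
    inertia: float
    seed: int
    n_init: int
    excluded: list[str]

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    z = (arr - mean) / np.where(sd == 0, 1.0, sd)
    zdf = pd.DataFrame(z, index=values.index, columns=values.columns)
    return zdf.loc[~flat], values.index[flat].tolist()


def kmeans_correlation(
    profiles: TEProfiles,
    k: int = 4,
    seed: int = 0,
    n_init: int = 50,
) -> ClusterAssignment:
    """Cluster TE profiles with Pearson-correlation k-means.

    Profiles are row z-scored, then Euclidean k-means runs with ``n_init``
    random restarts keeping the lowest within-cluster sum of squares.
    Zero-variance (flat) profiles are excluded and reported. Labels are
    renumbered 1..k by ascending mean knockdown-minus-control TE change.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    z, excluded = _zscore_rows(profiles.values)
    if excluded:
        logger.info("%d flat profile(s) excluded from clustering", len(excluded))
    if len(z) < k:
        raise ValidationError(f"k={k} exceeds the {len(z)} usable profiles")
    km = KMeans(n_clusters=k, n_init=n_init, init="random", random_state=seed)
    raw = km.fit_predict(z.to_numpy())

    te = profiles.values.loc[z.index]
    kd = te.xs("knockdown", axis=1, level="condition")
    cn = te.xs("control", axis=1, level="condition")
    change = (kd.to_numpy() - cn.to_numpy()).mean(axis=1)
    means = np.array([change[raw == c].mean() for c in range(k)])
    order = np.argsort(means, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[raw], index=z.index, name="cluster")
    centroids = km.cluster_centers_[order]
    return ClusterAssignment(
        labels=labels,
        centroids=centroids,
        inertia=float(km.inertia_),
        seed=seed,
        n_init=n_init,
        excluded=excluded,
    )


def cluster_trends(
    profiles: TEProfiles, assignment: ClusterAssignment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster TE trends and the per-gene line-plot table.

    Returns ``(summary, per_gene)``: the summary has one row per
    (cluster, cell line) with mean control TE, mean knockdown TE, the TE
    change and the KD/CN ratio, plus the cluster's gene count; ``per_gene``
    is the long-form table backing per-gene trend lines.
    """
    te = profiles.values.loc[assignment.labels.index]
    long = te.stack(level=["cell_line", "condition"], future_stack=True).rename("te").reset_index()
    long.columns = ["gene_id", "cell_line", "condition", "te"]
    long["cluster"] = assignment.labels.loc[long["gene_id"]].to_numpy()

    rows = []
    for cluster, sub in long.groupby("cluster"):
        n_genes = sub["gene_id"].nunique()
        for cell, cell_sub in sub.groupby("cell_line", sort=False):
            cn = cell_sub.loc[cell_sub["condition"] == "control", "te"].mean()
            kd = cell_sub.loc[cell_sub["condition"] == "knockdown", "te"].mean()
            rows.append(
                {
                    "cluster": cluster,
                    "cell_line": cell,
                    "n_genes": n_genes,
                    "mean_te_control": cn,
                    "mean_te_knockdown": kd,
                    "te_change": kd - cn,
                    "kd_cn_ratio": kd / cn if cn != 0 else np.nan,
                }
            )
    summary = pd.DataFrame(rows)
    return summary, long


@dataclass
class GeneSetSummary:
    """Gene-set TE quartiles and per-cell-line coordination statistics."""

    quartiles: pd.DataFrame  # rows (cell_line, condition); cols q25/median/q75
    coordination: pd.Series  # per cell line: median over set of (TE_KD - TE_CN)
    p_values: pd.Series  # per cell line permutation p (NaN when n_perm = 0)
    n_set: int
    n_perm: int
    seed: int


def geneset_te_summary(
    profiles: TEProfiles,
    gene_set: Iterable[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> GeneSetSummary:
    """Summarize a gene set's TE and test its coordinated knockdown response.

    The coordination statistic per cell line is the median over the set of
    (TE_KD - TE_CN). Its two-sided permutation p-value compares against
    ``n_perm`` random same-size sets drawn from the profiled genes
    (add-one-corrected); ``n_perm=0`` reports the summary with missing p.
    """
    genes = [g for g in gene_set if g in profiles.values.index]
    if not genes:
        raise ValidationError("gene set has no overlap with the profiled genes")
    te = profiles.values
    sub = te.loc[genes]

    rows = []
    for cell, cond in te.columns:
        vals = sub[(cell, cond)].to_numpy()
        rows.append(
            {
                "cell_line": cell,
                "condition": cond,
                "q25": float(np.percentile(vals, 25)),
                "median": float(np.percentile(vals, 50)),
                "q75": float(np.percentile(vals, 75)),
            }
        )
    quartiles = pd.DataFrame(rows).set_index(["cell_line", "condition"])

    cells = profiles.cell_lines
    kd = te.xs("knockdown", axis=1, level="condition")[cells]
    cn = te.xs("control", axis=1, level="condition")[cells]
    diff = kd.to_numpy() - cn.to_numpy()  # genes x cells
    in_set = te.index.isin(genes)
    obs = np.median(diff[in_set], axis=0)
    coordination = pd.Series(obs, index=cells, name="coordination")

    if n_perm > 0:
        rng = np.random.default_rng(seed)
        G, m = len(te), int(in_set.sum())
        perm_stats = np.empty((n_perm, len(cells)))
        for b in range(n_perm):
            idx = rng.choice(G, size=m, replace=False)
            perm_stats[b] = np.median(diff[idx], axis=0)
        ge = (np.abs(perm_stats) >= np.abs(obs)[None, :]).sum(axis=0)
        p = (1.0 + ge) / (n_perm + 1.0)
    else:
        p = np.full(len(cells), np.nan)
    p_values = pd.Series(p, index=cells, name="perm_p")

    return GeneSetSummary(
        quartiles=quartiles,
        coordination=coordination,
        p_values=p_values,
        n_set=int(in_set.sum()),
        n_perm=n_perm,
        seed=seed,
    )
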