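"""Two-group expression analytics.

* moderated two-group statistic d = (mean_A - mean_B) / (s + s0) with
  permutation q-values and linear-scale fold changes
* correlation screening of all genes against a target gene
* gene-set enrichment by weighted running sum with phenotype permutation
* average-linkage hierarchical clustering on 1 - Pearson distance
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression (genes x samples) with a two-group label."""

    values: pd.DataFrame
    labels: pd.Series  # sample -> group, two levels

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = list(self.labels[self.labels.isna()].index)
            raise ValueError(f"samples without phenotype label: {missing}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values; imputation refused")
        groups = self.group_names
        if len(groups) != 2:
            raise ValueError(f"exactly two phenotype groups required, got {groups}")

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.labels:
            seen[g] = None
        return list(seen)

    def group_columns(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])


def _group_arrays(mat: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray, str, str]:
    a, b = mat.group_names
    xa = mat.values[mat.group_columns(a)].to_numpy(float)
    xb = mat.values[mat.group_columns(b)].to_numpy(float)
    return xa, xb, a, b


def _sam_d(xa: np.ndarray, xb: np.ndarray, s0: float | None) -> tuple[np.ndarray, float]:
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    # pooled standard error (gene-specific scatter s_i)
    ss = ((xa - ma[:, None]) ** 2).sum(axis=1) + ((xb - mb[:, None]) ** 2).sum(axis=1)
    pooled_var = ss / (na + nb - 2)
    s = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    if s0 is None:
        s0 = float(np.median(s))
    d = (ma - mb) / (s + s0)
    return d, s0


def sam_differential(
    mat: ExpressionMatrix,
    n_perm: int = 200,
    seed: int | None = None,
    s0: float | None = None,
    q_cut: float = 0.01,
    fc_cut: float = 2.0,
) -> pd.DataFrame:
    """Two-group differential expression with permutation q-values.

    d_i = (mean_A - mean_B) / (s_i + s0); s0 defaults to the median of the
    gene-wise standard errors.  q-values estimate, for each |d| threshold,
    the expected fraction of label-permutation null genes among the called
    set, made monotone non-increasing in |d|.  Fold change is on the linear
    scale: 2^(mean_A - mean_B) (inputs are log2).  A gene is flagged
    significant when q < ``q_cut`` and fold change > ``fc_cut`` or
    < 1/``fc_cut``.
    """
    rng = np.random.default_rng(seed)
    xa, xb, a, b = _group_arrays(mat)
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 samples")
    d, s0_used = _sam_d(xa, xb, s0)
    fc = np.power(2.0, xa.mean(axis=1) - xb.mean(axis=1))

    pooled = np.hstack([xa, xb])
    abs_null = np.empty((n_perm, d.size))
    for p in range(n_perm):
        idx = rng.permutation(na + nb)
        dp, _ = _sam_d(pooled[:, idx[:na]], pooled[:, idx[na:]], s0_used)
        abs_null[p] = np.abs(dp)

    order = np.argsort(-np.abs(d), kind="stable")
    abs_sorted = np.abs(d)[order]
    flat_null = np.sort(abs_null.ravel())
    # mean null exceedances per permutation at each observed |d| threshold
    exceed = (flat_null.size - np.searchsorted(flat_null, abs_sorted, side="left")) / n_perm
    called = np.arange(1, d.size + 1)
    q_sorted = np.minimum(1.0, exceed / called)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    out = pd.DataFrame(
        {
            "gene": mat.values.index,
            "d_statistic": d,
            "fold_change": fc,
            "q_value": q,
        }
    )
    out["significant"] = (out["q_value"] < q_cut) & ((out["fold_change"] > fc_cut) | (out["fold_change"] < 1.0 / fc_cut))
    out.attrs["s0"] = s0_used
    out.attrs["groups"] = (a, b)
    return out


def pcc_to_target(
    mat: ExpressionMatrix,
    target_gene: str,
    cut: float = 0.5,
    samples: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Genes whose Pearson correlation with ``target_gene`` across the
    designated samples is >= cut (positive list) or <= -cut (negative list).
    The target is excluded from its own lists; zero-variance genes are
    skipped with a warning."""
    if target_gene not in mat.values.index:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    cols = samples if samples is not None else list(mat.values.columns)
    if len(cols) < 3:
        raise ValueError("need >= 3 samples for correlation")
    x = mat.values.loc[:, cols].to_numpy(float)
    t = mat.values.loc[target_gene, cols].to_numpy(float)
    t_c = t - t.mean()
    t_ss = float(t_c @ t_c)
    if t_ss == 0.0:
        raise ValueError("target gene has zero variance")
    xc = x - x.mean(axis=1, keepdims=True)
    ss = (xc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ t_c) / np.sqrt(ss * t_ss)
    pos, neg = [], []
    for gene, ri, ssi in zip(mat.values.index, r, ss):
        if gene == target_gene:
            continue
        if ssi == 0.0:
            logger.warning("gene %s has zero variance; correlation undefined, excluded", gene)
            continue
        if ri >= cut:
            pos.append(gene)
        elif ri <= -cut:
            neg.append(gene)
    return pos, neg


def signal_to_noise(mat: ExpressionMatrix) -> pd.Series:
    """Per-gene signal-to-noise ratio (mean_A - mean_B) / (sd_A + sd_B)."""
    xa, xb, _, _ = _group_arrays(mat)
    num = xa.mean(axis=1) - xb.mean(axis=1)
    denom = xa.std(axis=1, ddof=1) + xb.std(axis=1, ddof=1)
    denom = np.maximum(denom, 1e-8)
    return pd.Series(num / denom, index=mat.values.index)


def _enrichment_score(ranked_genes: np.ndarray, stat: np.ndarray, members: set[str], p: float = 1.0) -> float:
    """Maximum-magnitude deviation of the weighted running sum."""
    hits = np.fromiter((g in members for g in ranked_genes), bool, len(ranked_genes))
    n_miss = len(ranked_genes) - int(hits.sum())
    w = np.where(hits, np.abs(stat) ** p, 0.0)
    cw = np.cumsum(w)
    nr = cw[-1]
    if nr == 0.0:
        return 0.0
    hit_term = cw / nr
    miss_term = np.cumsum(~hits) / n_miss if n_miss > 0 else np.zeros(len(ranked_genes))
    running = hit_term - miss_term
    k = int(np.argmax(np.abs(running)))
    return float(running[k])


def gsea_enrichment(
    mat: ExpressionMatrix,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    min_size: int = 50,
    seed: int | None = None,
    weight: float = 1.0,
    fdr_cut: float = 0.20,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Gene-set enrichment with phenotype permutation.

    Genes are ranked by signal-to-noise between the two groups; the
    enrichment score is the maximum deviation of the weighted (exponent
    ``weight``) running sum.  Nominal p compares each set's ES with its own
    sign-matched permutation null; FDR pools permutation ES across sets per
    sign.  Sets with fewer than ``min_size`` members present in the matrix
    are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    present = set(mat.values.index)
    tested = {}
    for name, genes in sets.items():
        members = set(genes) & present
        if len(members) == 0:
            logger.warning("gene set %s has no members in matrix; skipped", name)
            continue
        if len(members) < min_size:
            logger.warning("gene set %s below min_size (%d < %d); skipped", name, len(members), min_size)
            continue
        tested[name] = members
    if not tested:
        return pd.DataFrame(columns=["gene_set", "es", "p", "fdr", "significant"])

    def ranked(m: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
        s = signal_to_noise(m)
        order = np.argsort(-s.to_numpy(), kind="stable")
        return s.index.to_numpy()[order], s.to_numpy()[order]

    genes_obs, stat_obs = ranked(mat)
    es_obs = {name: _enrichment_score(genes_obs, stat_obs, members, weight) for name, members in tested.items()}

    labels = mat.labels.to_numpy()
    null = {name: np.empty(n_perm) for name in tested}
    for b in range(n_perm):
        perm = pd.Series(labels[rng.permutation(len(labels))], index=mat.labels.index)
        pm = ExpressionMatrix(mat.values, perm)
        genes_p, stat_p = ranked(pm)
        for name, members in tested.items():
            null[name][b] = _enrichment_score(genes_p, stat_p, members, weight)

    pooled = np.concatenate([null[name] for name in tested])
    obs_arr = np.array([es_obs[name] for name in tested])
    rows = []
    for name in tested:
        es = es_obs[name]
        nl = null[name]
        same = nl[nl >= 0] if es >= 0 else nl[nl < 0]
        if same.size == 0:
            p = 1.0
        else:
            p = (1 + np.count_nonzero(np.abs(same) >= abs(es))) / (1 + same.size)
        # pooled-null FDR per sign
        if es >= 0:
            num_null = np.mean(pooled[pooled >= 0] >= es) if np.any(pooled >= 0) else 0.0
            num_obs = np.mean(obs_arr[obs_arr >= 0] >= es) if np.any(obs_arr >= 0) else 1.0
        else:
            num_null = np.mean(pooled[pooled < 0] <= es) if np.any(pooled < 0) else 0.0
            num_obs = np.mean(obs_arr[obs_arr < 0] <= es) if np.any(obs_arr < 0) else 1.0
        fdr = min(1.0, num_null / num_obs) if num_obs > 0 else 1.0
        rows.append({"gene_set": name, "es": es, "p": float(p), "fdr": float(fdr)})
    out = pd.DataFrame(rows)
    out["significant"] = (out["fdr"] < fdr_cut) & (out["p"] < p_cut)
    return out


def _pearson_distance(x: np.ndarray, axis_names: list[str]) -> np.ndarray:
    sd = x.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance feature(s): {[axis_names[i] for i in bad]}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize fp noise
    return squareform(d, checks=False)


def hierarchical_cluster(
    mat: ExpressionMatrix,
    genes: list[str] | None = None,
) -> dict[str, object]:
    """Average-linkage clustering of rows (genes) and columns (samples) on
    1 - Pearson correlation distance.  Returns scipy linkage matrices, leaf
    orders and Newick strings."""
    values = mat.values.loc[genes] if genes is not None else mat.values
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    x = values.to_numpy(float)
    row_link = hierarchy.average(_pearson_distance(x, list(values.index)))
    col_link = hierarchy.average(_pearson_distance(x.T, list(values.columns)))
    row_leaves = [values.index[i] for i in hierarchy.leaves_list(row_link)]
    col_leaves = [values.columns[i] for i in hierarchy.leaves_list(col_link)]
    return {
        "row_linkage": row_link,
        "col_linkage": col_link,
        "row_leaves": row_leaves,
        "col_leaves": col_leaves,
        "row_newick": linkage_to_newick(row_link, list(values.index)),
        "col_newick": linkage_to_newick(col_link, list(values.columns)),
    }


def linkage_to_newick(link: np.ndarray, names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
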