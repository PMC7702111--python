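"""OTU tables and classical beta-diversity statistics.

Tables are pandas DataFrames with OTUs as rows and samples as columns
(non-negative integer counts) throughout.  Normalization follows the
with-replacement rarefaction used by phyloseq's ``rarefy_even_depth``:
each sample column is replaced by a multinomial draw at the target depth with
probabilities proportional to the original counts.  Bray-Curtis
dissimilarity, SIMPER decomposition, PERMANOVA and the Mantel test are
implemented with explicit seeds so every permutation p-value is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr, pearsonr
from skbio import DistanceMatrix


@dataclass
class TestResult:
    """Outcome of a permutation test: statistic, effect size, p-value, provenance."""

    method: str
    statistic: float
    p_value: float
    n_perm: int
    seed: int | None
    r_squared: float | None = None


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    if (table.values < 0).any():
        raise ValueError("OTU table contains negative counts")
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise ValueError("OTU table has duplicate ids")
    return table


def build_table(per_sample_counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Assemble an OTUs x samples table from per-sample count mappings."""
    table = pd.DataFrame(per_sample_counts).fillna(0).astype(int)
    table = table.sort_index()
    return validate_table(table)


def pool_replicates(table: pd.DataFrame, replicate_map: dict[str, str]) -> pd.DataFrame:
    """Sum replicate samples into pond-level columns.

    ``replicate_map`` maps each sample id to its pond id; column order follows
    first appearance in the map.
    """
    unknown = [s for s in table.columns if s not in replicate_map]
    if unknown:
        raise ValueError(f"samples missing from replicate map: {unknown}")
    order: list[str] = []
    for s in replicate_map:
        pond = replicate_map[s]
        if pond not in order:
            order.append(pond)
    pooled = table.T.groupby([replicate_map[s] for s in table.columns]).sum().T
    return pooled[[p for p in order if p in pooled.columns]]


def rarefy(
    table: pd.DataFrame,
    depth: int,
    seed: int = 0,
    with_replacement: bool = True,
) -> pd.DataFrame:
    """Normalize every sample to ``depth`` reads by random subsampling.

    Default is with-replacement (multinomial with probabilities proportional
    to counts); without-replacement hypergeometric sampling is available for
    comparison.  Samples totalling zero are dropped with a warning; OTUs left
    with all-zero rows are removed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    validate_table(table)
    rng = np.random.default_rng(seed)
    cols = {}
    for s in table.columns:
        counts = table[s].to_numpy()
        total = counts.sum()
        if total == 0:
            warnings.warn(f"sample {s} has zero reads; dropped from rarefied table")
            continue
        if with_replacement:
            cols[s] = rng.multinomial(depth, counts / total)
        else:
            if depth > total:
                warnings.warn(
                    f"sample {s}: depth {depth} exceeds total {total}; dropped"
                )
                continue
            pool = np.repeat(np.arange(len(counts)), counts)
            take = rng.choice(pool, size=depth, replace=False)
            cols[s] = np.bincount(take, minlength=len(counts))
    out = pd.DataFrame(cols, index=table.index)
    return out.loc[out.sum(axis=1) > 0]


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples (columns)."""
    validate_table(table)
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    data = table.to_numpy(dtype=float).T
    if (data.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    condensed = pdist(data, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(table.columns))


def bray_curtis_similarity(table: pd.DataFrame) -> pd.DataFrame:
    """BC similarity, defined as 1 - BC dissimilarity (unit diagonal)."""
    dm = bray_curtis(table)
    return pd.DataFrame(1.0 - dm.data, index=list(dm.ids), columns=list(dm.ids))


def simper(
    table: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-OTU contribution to the average between-group Bray-Curtis dissimilarity.

    For a sample pair (x, y) the contribution of OTU i is
    |x_i - y_i| / sum_j (x_j + y_j); contributions are averaged over all
    between-group pairs and sum to the mean between-group dissimilarity.
    Significance per OTU is assessed by permuting group labels (upper tail,
    +1 corrected).
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    labels = groups.loc[table.columns]
    levels = labels.unique()
    if len(levels) != 2:
        raise ValueError("simper requires exactly two groups")
    data = table.to_numpy(dtype=float)

    def _contributions(perm_labels: np.ndarray) -> np.ndarray:
        ia = np.flatnonzero(perm_labels == levels[0])
        ib = np.flatnonzero(perm_labels == levels[1])
        if ia.size < 1 or ib.size < 1:
            raise ValueError("each group needs at least one sample")
        contribs = np.zeros(data.shape[0])
        n_pairs = 0
        for i in ia:
            for j in ib:
                x, y = data[:, i], data[:, j]
                denom = (x + y).sum()
                if denom == 0:
                    continue
                contribs += np.abs(x - y) / denom
                n_pairs += 1
        return contribs / max(n_pairs, 1)

    observed = _contributions(labels.to_numpy())
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    lab = labels.to_numpy().copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        exceed += _contributions(lab) >= observed
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    out = pd.DataFrame(
        {
            "average_contribution": observed,
            "contribution_pct": 100.0 * observed / observed.sum(),
            "p_value": pvals,
        },
        index=table.index,
    )
    return out.sort_values("average_contribution", ascending=False)


def _permanova_f(dm: np.ndarray, group_idx: list[np.ndarray]) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances (Anderson's direct formulation)."""
    n = dm.shape[0]
    d2 = dm ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for idx in group_idx:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(group_idx)
    if ss_within == 0 or ss_total == 0:
        return float("nan"), float("nan")
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(
    dm: DistanceMatrix,
    groups: dict[str, str] | pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
) -> TestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    p = (1 + #(permuted F >= observed)) / (1 + n_perm), upper tail.  A
    degenerate matrix (all samples identical) yields a NaN statistic.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    labels = np.asarray([groups[i] for i in dm.ids])
    levels, inv = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 samples")
    mat = dm.data
    idx = [np.flatnonzero(inv == g) for g in range(len(levels))]
    f_obs, r2 = _permanova_f(mat, idx)
    if np.isnan(f_obs):
        warnings.warn("zero total variance; PERMANOVA statistic undefined")
        return TestResult("permanova", float("nan"), float("nan"), n_perm, seed, r2)
    rng = np.random.default_rng(seed)
    count = 0
    perm_inv = inv.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_inv)
        pidx = [np.flatnonzero(perm_inv == g) for g in range(len(levels))]
        f_perm, _ = _permanova_f(mat, pidx)
        if f_perm >= f_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return TestResult("permanova", f_obs, p, n_perm, seed, r2)


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int = 0,
) -> TestResult:
    """Mantel correlation between two distance matrices with matching labels.

    The correlation (Spearman by default) is computed on the vectorized upper
    triangles; the null permutes one matrix's rows and columns jointly.
    Two-sided p with +1 correction.
    """
    if set(dm1.ids) != set(dm2.ids):
        raise ValueError("distance matrices must share labels")
    dm2 = dm2.filter(dm1.ids)
    n = dm1.shape[0]
    iu = np.triu_indices(n, 1)
    corr = spearmanr if method == "spearman" else pearsonr
    x = dm1.data[iu]
    r_obs = float(corr(x, dm2.data[iu])[0])
    rng = np.random.default_rng(seed)
    count = 0
    perm = np.arange(n)
    for _ in range(n_perm):
        rng.shuffle(perm)
        y = dm2.data[np.ix_(perm, perm)][iu]
        if abs(float(corr(x, y)[0])) >= abs(r_obs):
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return TestResult(f"mantel-{method}", r_obs, p, n_perm, seed)
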