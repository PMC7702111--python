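"""Null-model community-assembly statistics.

Three related indices quantify how far observed community turnover departs
from a stochastic expectation:

* the abundance-based (modified) Raup-Crick index compares each pair's
  observed Bray-Curtis dissimilarity with a null distribution and maps it to
  [-1, 1]; pairs outside +-0.95 are more/less similar than chance;
* the normalized stochasticity ratio (NST) converts the gap between observed
  and mean-null dissimilarity into a selection strength per pair and averages
  its complement, in percent: 100% when observations are indistinguishable
  from the null, 0% under maximal divergence; >50% is read as
  stochasticity-dominated assembly.  An occupancy-stratified variant
  recomputes NST on subcommunities of OTUs occurring in at least (or exactly)
  k ponds;
* the beta nearest-taxon index (betaNTI) z-scores the abundance-weighted
  beta mean-nearest-taxon phylogenetic distance (betaMNTD) against tip-label
  shuffles; |betaNTI| < 2 indicates phylogenetically random turnover.

The shared null algorithm preserves each sample's observed richness, draws
species identities with probability proportional to occurrence frequency
across samples, and assigns the observed number of individuals by a
multinomial over the drawn species weighted by regional relative abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community import validate_table


@dataclass
class NullModelConfig:
    """Null-model provenance: replicate count, algorithm, metric and seed."""

    n_reps: int = 1000
    null_algorithm: str = "frequency"  # or "equiprobable"
    seed: int = 0
    metric: str = "bray"  # or "jaccard"

    def __post_init__(self) -> None:
        if self.n_reps < 100:
            raise ValueError("n_reps must be >= 100")
        if self.null_algorithm not in ("frequency", "equiprobable"):
            raise ValueError(f"unknown null algorithm {self.null_algorithm!r}")
        if self.metric not in ("bray", "jaccard"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class AssemblyResult:
    """RC matrix, per-group NST and betaNTI with the config that produced them."""

    rc: pd.DataFrame | None = None
    rc_bins: dict | None = None
    nst: dict | None = None
    bnti: pd.DataFrame | None = None
    config: NullModelConfig | None = None


def _pairwise_d(x: np.ndarray, y: np.ndarray, metric: str) -> np.ndarray:
    """Row-wise dissimilarity between two (reps x S) count matrices."""
    if metric == "bray":
        num = np.abs(x - y).sum(axis=-1)
        den = (x + y).sum(axis=-1)
    else:  # jaccard on incidence
        xb, yb = x > 0, y > 0
        num = (xb ^ yb).sum(axis=-1).astype(float)
        den = (xb | yb).sum(axis=-1).astype(float)
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / den, np.nan)
    return d


def regional_pool(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence frequencies and relative abundances of the analyzed table."""
    counts = table.to_numpy(dtype=float)
    freq = (counts > 0).mean(axis=1)
    abund = counts.sum(axis=1)
    abund = abund / abund.sum()
    return freq, abund


def _null_counts_for_sample(
    richness: int,
    n_individuals: int,
    freq: np.ndarray,
    abund: np.ndarray,
    config: NullModelConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_reps x S) null count matrix for one sample.

    Species identity: weighted sampling without replacement proportional to
    occurrence frequency (Efraimidis-Spirakis Gumbel top-k), or equiprobable.
    Abundance: each drawn species is seeded with one individual (so realized
    richness equals observed richness), and the remaining individuals are a
    multinomial draw with probability proportional to regional relative
    abundance restricted to the drawn species.
    """
    S = freq.size
    eligible = freq > 0
    if richness > eligible.sum():
        raise ValueError(
            f"observed richness {richness} exceeds pool of {int(eligible.sum())} species"
        )
    if richness > n_individuals:
        raise ValueError(
            f"observed richness {richness} exceeds {n_individuals} individuals"
        )
    if config.null_algorithm == "frequency":
        w = np.where(eligible, freq, 0.0)
    else:
        w = eligible.astype(float)
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(w), -np.inf)
    keys = logw[None, :] + rng.gumbel(size=(config.n_reps, S))
    chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    out = np.zeros((config.n_reps, S), dtype=np.int64)
    for r in range(config.n_reps):
        p = abund[chosen[r]]
        total = p.sum()
        p = p / total if total > 0 else np.full(richness, 1.0 / richness)
        out[r, chosen[r]] = 1 + rng.multinomial(n_individuals - richness, p)
    return out


def null_dissimilarity_distribution(
    x: np.ndarray,
    y: np.ndarray,
    freq: np.ndarray,
    abund: np.ndarray,
    config: NullModelConfig | None = None,
) -> np.ndarray:
    """Null dissimilarities for one sample pair with observed counts x, y."""
    config = config or NullModelConfig()
    x = np.asarray(x)
    y = np.asarray(y)
    rng = np.random.default_rng(config.seed)
    nx = _null_counts_for_sample(int((x > 0).sum()), int(x.sum()), freq, abund, config, rng)
    ny = _null_counts_for_sample(int((y > 0).sum()), int(y.sum()), freq, abund, config, rng)
    return _pairwise_d(nx.astype(float), ny.astype(float), config.metric)


def _all_null_samples(
    table: pd.DataFrame, config: NullModelConfig
) -> dict[str, np.ndarray]:
    """Independent null draws for every sample, sharing the regional pool."""
    freq, abund = regional_pool(table)
    counts = table.to_numpy()
    rng = np.random.default_rng(config.seed)
    nulls = {}
    for j, s in enumerate(table.columns):
        col = counts[:, j]
        richness = int((col > 0).sum())
        if richness == 0:
            warnings.warn(f"sample {s} is empty; excluded from null models")
            continue
        nulls[s] = _null_counts_for_sample(
            richness, int(col.sum()), freq, abund, config, rng
        ).astype(float)
    return nulls


def _observed_d(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    data = table.to_numpy(dtype=float).T
    n = data.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_d(data[i], data[j], metric)
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


def raup_crick(
    table: pd.DataFrame, config: NullModelConfig | None = None
) -> pd.DataFrame:
    """Pairwise modified Raup-Crick matrix in [-1, 1].

    RC = 2 [ (#(D_null < D_obs) + 0.5 #(D_null = D_obs)) / n_reps ] - 1, so
    RC = +1 when the pair is less similar than every null draw and 0 when
    observation ties the entire null distribution.
    """
    config = config or NullModelConfig()
    validate_table(table)
    nulls = _all_null_samples(table, config)
    samples = [s for s in table.columns if s in nulls]
    d_obs = _observed_d(table[samples], config.metric)
    rc = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, si in enumerate(samples):
        for sj in samples[i + 1:]:
            dn = _pairwise_d(nulls[si], nulls[sj], config.metric)
            dn = dn[~np.isnan(dn)]
            obs = d_obs.loc[si, sj]
            frac = ((dn < obs).sum() + 0.5 * (dn == obs).sum()) / dn.size
            rc.loc[si, sj] = rc.loc[sj, si] = 2.0 * frac - 1.0
    return rc


def classify_rc(rc: pd.DataFrame) -> dict[str, float]:
    """Percentages of pairwise comparisons below -0.95, between, and above 0.95."""
    n = rc.shape[0]
    iu = np.triu_indices(n, 1)
    vals = rc.to_numpy()[iu]
    total = vals.size
    low = (vals < -0.95).sum()
    high = (vals > 0.95).sum()
    mid = total - low - high
    return {
        "rc_below_-0.95_pct": 100.0 * float(low) / total,
        "rc_middle_pct": 100.0 * float(mid) / total,
        "rc_above_0.95_pct": 100.0 * float(high) / total,
    }


# ---------------------------------------------------------------------------
# NST
# ---------------------------------------------------------------------------

D_MAX = 1.0  # Bray-Curtis and Jaccard are bounded by 1


def _pair_st(d_obs: float, e_null: float) -> float:
    """Stochasticity of one pair: 1 - selection strength."""
    if e_null >= D_MAX:
        warnings.warn("mean null dissimilarity equals the metric maximum")
        return 0.0
    if d_obs < e_null:
        ss = (e_null - d_obs) / e_null if e_null > 0 else 0.0
    else:
        ss = (d_obs - e_null) / (D_MAX - e_null)
    return 1.0 - min(ss, 1.0)


def _nst_from_pairs(
    d_obs: pd.DataFrame,
    e_null: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> float:
    st = [_pair_st(d_obs.loc[i, j], e_null.loc[i, j]) for i, j in pairs]
    return 100.0 * float(np.mean(st))


def _pairs(samples: list[str], labels: pd.Series, scope) -> list[tuple[str, str]]:
    out = []
    for i, si in enumerate(samples):
        for sj in samples[i + 1:]:
            gi, gj = labels[si], labels[sj]
            if scope == "between" and gi != gj:
                out.append((si, sj))
            elif scope not in ("between",) and gi == gj == scope:
                out.append((si, sj))
    return out


def nst(
    table: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    config: NullModelConfig | None = None,
) -> dict[str, float]:
    """Normalized stochasticity ratio (%) within each group and between groups.

    For every sample pair, the null expectation E is the mean null
    dissimilarity; selection strength is (E - D)/E when D < E (more similar
    than chance) and (D - E)/(D_max - E) otherwise; NST averages 1 - SS over
    the pairs in scope, x100.
    """
    config = config or NullModelConfig()
    validate_table(table)
    labels = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    nulls = _all_null_samples(table, config)
    samples = [s for s in table.columns if s in nulls]
    d_obs = _observed_d(table[samples], config.metric)
    e_null = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, si in enumerate(samples):
        for sj in samples[i + 1:]:
            dn = _pairwise_d(nulls[si], nulls[sj], config.metric)
            e_null.loc[si, sj] = e_null.loc[sj, si] = float(np.nanmean(dn))
    result: dict[str, float] = {}
    for g in labels.loc[samples].unique():
        pairs = _pairs(samples, labels, g)
        if pairs:
            result[str(g)] = _nst_from_pairs(d_obs, e_null, pairs)
    between = _pairs(samples, labels, "between")
    if between:
        result["between"] = _nst_from_pairs(d_obs, e_null, between)
    return result


def nst_bootstrap_difference(
    table: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    config: NullModelConfig | None = None,
    n_boot: int = 999,
) -> dict:
    """Two-sided bootstrap test for the within-group NST difference of two groups.

    Samples are resampled with replacement within each group; the p-value is
    the two-sided tail of the bootstrap distribution of NST_A - NST_B around 0.
    """
    config = config or NullModelConfig()
    labels = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    levels = list(pd.unique(labels.loc[table.columns]))
    if len(levels) != 2:
        raise ValueError("bootstrap difference test requires exactly two groups")
    observed = nst(table, labels, config)
    diff_obs = observed[str(levels[0])] - observed[str(levels[1])]
    rng = np.random.default_rng(config.seed)
    diffs = []
    members = {g: [s for s in table.columns if labels[s] == g] for g in levels}
    for b in range(n_boot):
        cols, lab = [], {}
        for g in levels:
            take = rng.choice(members[g], size=len(members[g]), replace=True)
            for k, s in enumerate(take):
                name = f"{s}__b{k}"
                cols.append(table[s].rename(name))
                lab[name] = labels[s]
        bt = pd.concat(cols, axis=1)
        sub_cfg = NullModelConfig(
            n_reps=config.n_reps,
            null_algorithm=config.null_algorithm,
            seed=int(rng.integers(2 ** 31)),
            metric=config.metric,
        )
        try:
            res = nst(bt, lab, sub_cfg)
            diffs.append(res[str(levels[0])] - res[str(levels[1])])
        except ValueError:
            continue
    diffs = np.asarray(diffs)
    # centre the bootstrap distribution on the observed difference and ask how
    # often zero is at least as extreme
    shifted = diffs - diffs.mean()
    p = (1.0 + (np.abs(shifted) >= abs(diff_obs)).sum()) / (1.0 + diffs.size)
    return {"difference": diff_obs, "p_value": float(p), "n_boot": int(diffs.size)}


def occupancy(table: pd.DataFrame) -> pd.Series:
    """Number of samples (ponds) in which each OTU occurs."""
    return (table > 0).sum(axis=1)


def nst_by_occupancy(
    table: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    config: NullModelConfig | None = None,
    mode: str = "at_least",
) -> pd.DataFrame:
    """NST recomputed on subcommunities of OTUs occurring in >= k (or == k) ponds.

    Occupancy is computed on the supplied (pond-level) table.  Levels whose
    subset has fewer than 2 OTUs or empties a sample are skipped with a
    warning.  Returns a DataFrame indexed by k with one column per NST scope.
    """
    if mode not in ("at_least", "exactly"):
        raise ValueError("mode must be 'at_least' or 'exactly'")
    config = config or NullModelConfig()
    occ = occupancy(table)
    rows = {}
    for k in range(1, int(occ.max()) + 1):
        mask = occ >= k if mode == "at_least" else occ == k
        sub = table.loc[mask]
        if sub.shape[0] < 2:
            warnings.warn(f"occupancy level {k}: fewer than 2 OTUs; skipped")
            continue
        if (sub.sum(axis=0) == 0).any():
            warnings.warn(f"occupancy level {k}: empties a sample; skipped")
            continue
        try:
            rows[k] = nst(sub, groups, config)
        except ValueError as exc:
            warnings.warn(f"occupancy level {k}: {exc}; skipped")
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _patristic(tree: TreeNode, otu_ids: list[str]) -> np.ndarray:
    tips = {t.name for t in tree.tips()}
    missing = [o for o in otu_ids if o not in tips]
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing[:10]}")
    dm = tree.tip_tip_distances(endpoints=otu_ids)
    return dm.filter(otu_ids).data


def _bmntd_matrix(
    rel: np.ndarray, pres: np.ndarray, dist: np.ndarray
) -> np.ndarray:
    """betaMNTD over all sample pairs.

    rel: (samples x taxa) relative abundances; pres: boolean presence;
    dist: (taxa x taxa) patristic distances with the self-distance excluded
    via masking per pair.
    """
    n = rel.shape[0]
    big = np.inf
    out = np.zeros((n, n))
    # dmin_to[m] = for each taxon i, min distance to any taxon present in m
    dmin_to = np.empty((n, dist.shape[0]))
    for m in range(n):
        cols = np.flatnonzero(pres[m])
        dmin_to[m] = dist[:, cols].min(axis=1) if cols.size else big
    for k in range(n):
        for m in range(k + 1, n):
            a = rel[k] @ dmin_to[m]
            b = rel[m] @ dmin_to[k]
            out[k, m] = out[m, k] = 0.5 * (a + b)
    return out


def beta_mntd(
    table: pd.DataFrame,
    tree: TreeNode,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Abundance-weighted beta mean-nearest-taxon distance between samples.

    betaMNTD(k, m) = 0.5 [ sum_i f_ik min_{j in m} d_ij +
    sum_j f_jm min_{i in k} d_ij ] with f relative abundances (or 1/richness
    when unweighted) and d patristic distances.  A taxon shared by both
    samples has nearest-taxon distance zero, so identical communities score 0.
    """
    validate_table(table)
    otus = list(table.index)
    dist = _patristic(tree, otus)
    counts = table.to_numpy(dtype=float).T
    pres = counts > 0
    if abundance_weighted:
        rel = counts / counts.sum(axis=1, keepdims=True)
    else:
        rel = pres / pres.sum(axis=1, keepdims=True)
    mat = _bmntd_matrix(rel, pres, dist)
    return pd.DataFrame(mat, index=table.columns, columns=table.columns)


def beta_nti(
    table: pd.DataFrame,
    tree: TreeNode,
    n_reps: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
    shuffle: str = "per_sample",
) -> pd.DataFrame:
    """betaNTI: z-score of observed betaMNTD against tip-label shuffles.

    The null relocates each community to random tips of the whole tree,
    breaking the link between abundance profile and phylogenetic position.
    With ``shuffle="per_sample"`` (default) every sample receives an
    independent tip permutation per replicate, so even two compositionally
    identical samples acquire a non-degenerate null (their observed betaMNTD
    of zero then scores strongly negative); ``shuffle="whole_matrix"``
    applies one permutation to the patristic matrix per replicate, the
    variant that conditions on shared species identity.  Pairs with zero
    null standard deviation are NaN with a warning.
    """
    if shuffle not in ("per_sample", "whole_matrix"):
        raise ValueError("shuffle must be 'per_sample' or 'whole_matrix'")
    validate_table(table)
    otus = list(table.index)
    dist = _patristic(tree, otus)
    counts = table.to_numpy(dtype=float).T
    pres = counts > 0
    if abundance_weighted:
        rel = counts / counts.sum(axis=1, keepdims=True)
    else:
        rel = pres / pres.sum(axis=1, keepdims=True)
    obs = _bmntd_matrix(rel, pres, dist)
    rng = np.random.default_rng(seed)
    n = counts.shape[0]
    null = np.empty((n_reps, n, n))
    S = dist.shape[0]
    for r in range(n_reps):
        if shuffle == "whole_matrix":
            perm = rng.permutation(S)
            null[r] = _bmntd_matrix(rel, pres, dist[np.ix_(perm, perm)])
        else:
            rel_r = np.empty_like(rel)
            for k in range(n):
                perm = rng.permutation(S)
                rel_r[k, perm] = rel[k]
            null[r] = _bmntd_matrix(rel_r, rel_r > 0, dist)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
    if np.any(sd[np.triu_indices(n, 1)] == 0):
        warnings.warn("some pairs have zero null variance; betaNTI undefined there")
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=table.columns, columns=table.columns)


def assembly_summary(
    table: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    tree: TreeNode | None = None,
    config: NullModelConfig | None = None,
    bnti_reps: int = 999,
) -> pd.DataFrame:
    """Table-2-style summary: NST, RC bin percentages and mean betaNTI per contrast."""
    config = config or NullModelConfig()
    labels = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    rc = raup_crick(table, config)
    nst_vals = nst(table, labels, config)
    bnti = (
        beta_nti(table, tree, n_reps=bnti_reps, seed=config.seed)
        if tree is not None
        else None
    )
    levels = list(pd.unique(labels.loc[table.columns]))
    contrasts = {str(g): ("within", g) for g in levels}
    contrasts["between"] = ("between", None)
    rows = {}
    for name, (scope, g) in contrasts.items():
        pairs = _pairs(list(table.columns), labels, "between" if scope == "between" else g)
        if not pairs:
            continue
        vals = np.array([rc.loc[i, j] for i, j in pairs])
        row = {
            "NST_pct": nst_vals.get(name, np.nan),
            "RC_below_-0.95_pct": 100.0 * (vals < -0.95).mean(),
            "RC_middle_pct": 100.0 * ((vals >= -0.95) & (vals <= 0.95)).mean(),
            "RC_above_0.95_pct": 100.0 * (vals > 0.95).mean(),
        }
        if bnti is not None:
            row["mean_bNTI"] = float(
                np.nanmean([bnti.loc[i, j] for i, j in pairs])
            )
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
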