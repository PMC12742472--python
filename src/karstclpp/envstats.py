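"""Statistics over sediment geochemistry and taxon abundances.

* standardized Euclidean complete-linkage clustering of samples, with an
  explicit merge history, deterministic lexicographic tie-breaking, and
  Newick export;
* regulatory limit exceedance reporting (censored values never exceed);
* relative-abundance filtering (taxa above a percentage in >= 1 sample);
* Spearman correlation screens between taxa and environmental parameters
  with two-sided p-values from either the t approximation or exact/Monte
  Carlo permutation.

Values reported only as below a detection limit ("<x") are substituted
before standardization: half the limit by default, or zero, or the limit
itself.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

from .model import EnvTable, ValidationError

#: Default variable set for sample clustering: the bulk mineral matrix
#: (ash and dry-mass content) plus the trace/heavy metals. pH and the
#: nutrient-status elements (C, N, P, S, Ca, K, Mg, Na) reflect organic
#: input rather than the sediment's mineral load and are excluded by
#: default; pass ``parameters=None`` to cluster on every parameter.
DEFAULT_CLUSTER_PARAMETERS = (
    "Ash", "Dry mass", "As", "Be", "Cd", "Co", "Cr", "Cu", "Hg", "Ni",
    "Pb", "V", "Zn",
)


def standardize(
    table: EnvTable,
    censored_policy: str = "half_limit",
    parameters=None,
) -> pd.DataFrame:
    """Z-score each parameter across samples (mean 0, sample SD 1).

    Censored cells are substituted per ``censored_policy`` first. Constant
    parameters carry no distance information and are dropped with a warning.
    Returns samples (rows) by parameters (columns).
    """
    values = table.substituted(censored_policy)
    if parameters is not None:
        missing = [p for p in parameters if p not in values.index]
        if missing:
            raise ValidationError(f"unknown parameters {missing}")
        values = values.loc[list(parameters)]
    mat = values.T  # samples x parameters
    if len(mat) < 2:
        raise ValidationError("standardization needs >= 2 samples")
    sd = mat.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping constant parameters: {constant}", stacklevel=2
        )
        mat = mat.drop(columns=constant)
        sd = sd.drop(constant)
    return (mat - mat.mean()) / sd


def euclidean_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between rows, as a symmetric frame."""
    if np.isnan(matrix.to_numpy()).any():
        r, c = np.argwhere(np.isnan(matrix.to_numpy()))[0]
        raise ValidationError(
            f"missing value at row {matrix.index[r]!r}, "
            f"column {matrix.columns[c]!r}"
        )
    d = squareform(pdist(matrix.to_numpy()))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class Dendrogram:
    """Agglomerative merge history over named leaves.

    ``merges`` lists, in order, ``(members_a, members_b, height)`` with
    members as sorted label tuples. Complete linkage is monotone, so heights
    never decrease.
    """

    leaves: tuple[str, ...]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValidationError("a dendrogram over n leaves has n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def cut(self, k: int) -> list[tuple[str, ...]]:
        """Partition into ``k`` groups by undoing the last k-1 merges."""
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ValidationError(f"k must be in [1, {n}]")
        clusters = {(l,) for l in self.leaves}
        for a, b, _ in self.merges[: n - k]:
            clusters.discard(a)
            clusters.discard(b)
            clusters.add(tuple(sorted(a + b)))
        return sorted(clusters)

    def last_singleton(self) -> str | None:
        """The leaf that stays unmerged the longest (the outlier sample when
        it is the final merge partner)."""
        for a, b, _ in reversed(self.merges):
            if len(a) == 1:
                return a[0]
            if len(b) == 1:
                return b[0]
        return None

    def linkage_matrix(self) -> np.ndarray:
        """SciPy-style (n-1) x 4 linkage matrix for plotting/interop."""
        ids = {(l,): i for i, l in enumerate(self.leaves)}
        out = np.zeros((len(self.merges), 4))
        for step, (a, b, h) in enumerate(self.merges):
            new = tuple(sorted(a + b))
            out[step] = [ids[a], ids[b], h, len(new)]
            ids[new] = len(self.leaves) + step
        return out

    def to_newick(self) -> str:
        """Newick string; branch lengths are the drop from a cluster's merge
        height to its child's (leaves sit at height 0)."""
        node_height = {(l,): 0.0 for l in self.leaves}
        node_str = {(l,): l for l in self.leaves}
        for a, b, h in self.merges:
            new = tuple(sorted(a + b))
            parts = []
            for child in (a, b):
                bl = h - node_height[child]
                parts.append(f"{node_str[child]}:{bl:g}")
            node_str[new] = f"({','.join(parts)})"
            node_height[new] = h
        root = tuple(sorted(self.leaves))
        return node_str[root] + ";"


def complete_linkage(dist: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering with complete (maximum) linkage.

    At each step the pair of clusters with the smallest maximum
    inter-cluster leaf distance is merged; among tied pairs the
    lexicographically smallest pair of member tuples wins, making the merge
    order deterministic.
    """
    labels = list(dist.index)
    if len(labels) < 2:
        raise ValidationError("clustering needs >= 2 items")
    if not dist.index.equals(dist.columns):
        raise ValidationError("distance matrix must be square and labelled")
    D = dist.to_numpy(dtype=float)
    if np.isnan(D).any():
        raise ValidationError("distance matrix contains missing values")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    idx = {l: i for i, l in enumerate(labels)}
    clusters: list[tuple[str, ...]] = [(l,) for l in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(D[idx[x], idx[y]] for x in a for y in b)
            key = (h, a, b)
            if best is None or key < best:
                best = key
        h, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(tuple(sorted(a + b)))
        merges.append((a, b, h))
    return Dendrogram(leaves=tuple(labels), merges=merges)


def cluster_samples(
    table: EnvTable,
    censored_policy: str = "half_limit",
    parameters=DEFAULT_CLUSTER_PARAMETERS,
) -> Dendrogram:
    """Standardize -> Euclidean -> complete linkage over samples.

    ``parameters`` selects which variables enter the profile (default: bulk
    matrix plus metals; None means all).
    """
    present = None
    if parameters is not None:
        present = [p for p in parameters if p in table.parameters]
        if not present:
            raise ValidationError("none of the requested parameters present")
    z = standardize(table, censored_policy, parameters=present)
    return complete_linkage(euclidean_distance(z))


def exceedance_report(table: EnvTable) -> dict[str, list[str]]:
    """Samples whose value strictly exceeds the parameter's regulatory
    limit, for every parameter that has one. Censored values (below a
    detection limit) never exceed."""
    if table.regulatory_limit is None or table.regulatory_limit.isna().all():
        raise ValidationError("no regulatory limits present")
    out: dict[str, list[str]] = {}
    for p, limit in table.regulatory_limit.items():
        if pd.isna(limit):
            continue
        row = table.values.loc[p]
        cens = table.censored.loc[p]
        out[p] = [s for s in table.samples if not cens[s] and row[s] > limit]
    return out


def abundance_filter(
    abundance_percent: pd.DataFrame, min_percent: float = 3.0
) -> list[str]:
    """Taxa (rows) whose maximum relative abundance across samples strictly
    exceeds ``min_percent`` percent."""
    keep = abundance_percent.max(axis=1) > min_percent
    return abundance_percent.index[keep].tolist()


# ---------------------------------------------------------------- Spearman screen

def _pearson_on_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom)


def spearman_exact_p(
    x, y, max_exact_n: int = 8, reps: int = 20000, seed: int = 0
) -> tuple[float, float]:
    """Spearman rho and two-sided permutation p-value.

    For n <= ``max_exact_n`` every one of the n! rank permutations is
    enumerated; larger n falls back to seeded Monte-Carlo with ``reps``
    permutations. The p-value is the fraction of permutations with
    |rho_perm| >= |rho_observed| (within numerical tolerance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 2:
        raise ValidationError("x and y must be equal-length, n >= 2")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValidationError("zero-variance vector: rho undefined")
    obs = _pearson_on_ranks(rx, ry)
    rxc = rx - rx.mean()
    if n <= max_exact_n:
        perms = np.array(list(itertools.permutations(ry)))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(ry) for _ in range(reps)])
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc ** 2).sum() * (pc ** 2).sum(axis=1))
    rho_all = pc @ rxc / denom
    p = float(np.mean(np.abs(rho_all) >= abs(obs) - 1e-12))
    return obs, p


@dataclass
class CorrelationScreen:
    """Taxon-by-parameter Spearman screen results.

    ``table`` has one row per (taxon, parameter) pair with columns ``rho,
    p_value, significant, undefined``; pairs with a zero-variance vector are
    flagged undefined and never significant.
    """

    table: pd.DataFrame
    alpha: float
    p_mode: str

    def rho_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="taxon", columns="parameter", values="rho")

    def significant_pairs(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def spearman_screen(
    taxa: pd.DataFrame,
    env: pd.DataFrame,
    alpha: float = 0.05,
    p_mode: str = "t_approx",
    reps: int = 20000,
    seed: int = 0,
) -> CorrelationScreen:
    """Correlate each taxon's abundance profile with each environmental
    parameter across samples.

    ``taxa`` is taxa (rows) x samples; ``env`` is parameters (rows) x
    samples; columns are aligned on the shared sample set (>= 4 required).
    Rho is Spearman's rank correlation with average ranks for ties; p-values
    are two-sided, from the t approximation (default, t = rho *
    sqrt((n-2)/(1-rho^2)) on n-2 df) or from permutation
    (``p_mode='exact_permutation'``: full enumeration for n <= 8, seeded
    Monte-Carlo beyond).
    """
    if p_mode not in ("t_approx", "exact_permutation"):
        raise ValidationError(f"unknown p_mode {p_mode!r}")
    shared = [s for s in taxa.columns if s in set(env.columns)]
    if len(shared) < 4:
        raise ValidationError("need >= 4 shared samples")
    tx = taxa[shared]
    ev = env[shared]
    rows = []
    for taxon in tx.index:
        xv = tx.loc[taxon].to_numpy(dtype=float)
        for param in ev.index:
            yv = ev.loc[param].to_numpy(dtype=float)
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                rows.append({
                    "taxon": taxon, "parameter": param, "rho": np.nan,
                    "p_value": np.nan, "significant": False, "undefined": True,
                })
                continue
            if p_mode == "t_approx":
                res = spearmanr(xv, yv)
                rho, p = float(res.statistic), float(res.pvalue)
            else:
                rho, p = spearman_exact_p(xv, yv, reps=reps, seed=seed)
            rows.append({
                "taxon": taxon, "parameter": param, "rho": rho,
                "p_value": p, "significant": bool(p < alpha),
                "undefined": False,
            })
    return CorrelationScreen(table=pd.DataFrame(rows), alpha=alpha, p_mode=p_mode)


def cluster_correlation_profiles(screen: CorrelationScreen) -> Dendrogram:
    """Group taxa by the similarity of their correlation profiles
    (complete linkage on Euclidean distances between rho rows)."""
    mat = screen.rho_matrix().dropna(axis=0, how="any")
    return complete_linkage(euclidean_distance(mat))
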