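"""Rarefaction and alpha diversity for OTU count tables.

Libraries are normalized by subsampling without replacement (rarefaction) to
a common depth, by default the minimum library size. Alpha diversity uses
the Shannon index H = -sum p_i ln p_i (natural log) and the Gini-Simpson
index D = 1 - sum p_i^2. Rarefaction curves of expected richness are
available both in closed form (hypergeometric expectation) and by seeded
Monte-Carlo subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import OtuTable, ValidationError


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValidationError("counts must be non-negative")
    if c.sum() <= 0:
        raise ValidationError("counts must not be all zero")
    return c


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p ln p (nats by default; pass ``base`` for
    another logarithm base)."""
    c = _check_counts(counts)
    p = c[c > 0] / c.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def simpson(counts, form: str = "gini") -> float:
    """Simpson diversity.

    ``gini`` (default) returns the Gini-Simpson complement 1 - sum p^2, the
    probability that two random reads are different taxa; ``dominance``
    returns sum p^2; ``inverse`` returns 1 / sum p^2.
    """
    c = _check_counts(counts)
    p = c / c.sum()
    d = float((p ** 2).sum())
    if form == "gini":
        return 1.0 - d
    if form == "dominance":
        return d
    if form == "inverse":
        return 1.0 / d
    raise ValidationError(f"unknown simpson form {form!r}")


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample every library without replacement to ``depth`` reads
    (default: the minimum library size). Deterministic given ``seed``."""
    sizes = table.library_sizes
    if depth is None:
        depth = int(sizes.min())
    depth = int(depth)
    too_small = sizes[sizes < depth]
    if len(too_small):
        raise ValidationError(
            f"depth {depth} exceeds library size of sample "
            f"{too_small.index[0]!r} ({int(too_small.iloc[0])})"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for s in table.samples:
        col = table.counts[s].to_numpy()
        out[s] = rng.multivariate_hypergeometric(col, depth)
    return OtuTable(counts=pd.DataFrame(out, index=table.counts.index))


def _expected_richness(counts: np.ndarray, depth: int) -> float:
    """Hypergeometric expectation of observed richness at ``depth`` draws
    without replacement: E[S] = sum_i (1 - C(N - c_i, n) / C(N, n))."""
    counts = counts[counts > 0]
    total = counts.sum()
    if depth == 0:
        return 0.0
    if depth > total:
        raise ValidationError(f"depth {depth} exceeds library size {total}")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = total - counts
    with np.errstate(invalid="ignore"):
        log_absent = log_comb(rest, depth) - log_comb(total, depth)
    absent = np.where(rest >= depth, np.exp(log_absent), 0.0)
    return float((1.0 - absent).sum())


def rarefaction_curve(
    table: OtuTable,
    depths=None,
    mode: str = "analytic",
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected observed-OTU richness per sample at each subsampling depth.

    ``analytic`` uses the exact hypergeometric expectation; ``montecarlo``
    averages observed richness over ``reps`` seeded subsamples. Returns a
    tidy frame with columns ``sample, depth, expected_otus, mode``.
    """
    if mode not in ("analytic", "montecarlo"):
        raise ValidationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for s in table.samples:
        col = table.counts[s].to_numpy()
        total = int(col.sum())
        sample_depths = (
            depths if depths is not None
            else np.unique(np.linspace(1, total, 20, dtype=int))
        )
        for depth in sample_depths:
            depth = int(depth)
            if depth > total:
                raise ValidationError(
                    f"depth {depth} exceeds library size of sample {s!r}"
                )
            if mode == "analytic":
                val = _expected_richness(col, depth)
            else:
                if depth == 0:
                    val = 0.0
                else:
                    draws = [
                        int((rng.multivariate_hypergeometric(col, depth) > 0).sum())
                        for _ in range(reps)
                    ]
                    val = float(np.mean(draws))
            rows.append({"sample": s, "depth": depth,
                         "expected_otus": val, "mode": mode})
    return pd.DataFrame(rows)


def alpha_diversity_report(
    table: OtuTable,
    depth: int | None = None,
    seed: int = 0,
    rarefy_first: bool = True,
    log_base: float | None = None,
    simpson_form: str = "gini",
) -> pd.DataFrame:
    """Per-sample diversity summary.

    By default indices are computed on the table rarefied to the minimum
    library size (``rarefy_first=False`` computes them on raw counts).
    Columns: ``library_size, observed_otus, shannon, simpson,
    rarefied_depth, seed``.
    """
    sizes = table.library_sizes
    working = rarefy(table, depth=depth, seed=seed) if rarefy_first else table
    used_depth = int(working.library_sizes.iloc[0]) if rarefy_first else None
    rows = []
    for s in table.samples:
        col = working.counts[s].to_numpy()
        rows.append({
            "sample": s,
            "library_size": int(sizes[s]),
            "observed_otus": int((col > 0).sum()),
            "shannon": shannon(col, base=log_base),
            "simpson": simpson(col, form=simpson_form),
            "rarefied_depth": used_depth if rarefy_first else int(sizes[s]),
            "seed": seed,
        })
    return pd.DataFrame(rows).set_index("sample")
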