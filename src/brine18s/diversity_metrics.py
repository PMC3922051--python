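"""Alpha-diversity summaries at 3% dissimilarity.

Per-sample OTU count vectors are rarefied to the smallest library and
summarised as observed OTUs, Shannon index (base 2), bias-corrected Chao1
richness and Good's coverage — the per-sample columns of the study-style
diversity table.

Formulas (N reads, S_obs observed OTUs, n1 singletons, n2 doubletons):

    H      = -sum_i p_i log2 p_i,   p_i = count_i / N
    Chao1  = S_obs + n1 (n1 - 1) / (2 (n2 + 1))     (bias-corrected)
    C      = 1 - n1 / N                              (Good's coverage)

The classic Chao1 form n1^2 / (2 n2) is available via ``bias_corrected=False``
and base-e Shannon via ``base``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from brine18s.otu_clustering import OTUTable


def _as_counts(v) -> np.ndarray:
    counts = np.asarray(list(v.values()) if isinstance(v, dict) else v, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return counts


def rarefy(v, depth: int, seed: int = 0, sample_name: str = "") -> np.ndarray:
    """Subsample exactly ``depth`` reads without replacement.

    The rarefied composition is a multivariate hypergeometric draw from the
    read multiset; deterministic given the seed.
    """
    counts = _as_counts(v)
    total = int(counts.sum())
    if depth > total:
        label = f" {sample_name!r}" if sample_name else ""
        raise ValueError(
            f"rarefaction depth {depth} exceeds library size {total} for sample{label}"
        )
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def shannon(v, base: float = 2.0) -> float:
    """Shannon diversity index in bits (base 2 by default)."""
    counts = _as_counts(v)
    n = counts.sum()
    if n == 0:
        raise ValueError("Shannon index undefined for an empty count vector")
    p = counts[counts > 0] / n
    return float(-(p * (np.log(p) / np.log(base))).sum())


def chao1(v, bias_corrected: bool = True) -> float:
    """Chao1 species-richness estimate from singleton/doubleton counts."""
    counts = _as_counts(v)
    if counts.sum() == 0:
        raise ValueError("Chao1 undefined for an empty count vector")
    s_obs = int((counts > 0).sum())
    n1 = int((counts == 1).sum())
    n2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    if n2 == 0:
        return s_obs + n1 * (n1 - 1) / 2.0
    return s_obs + n1 * n1 / (2.0 * n2)


def goods_coverage(v) -> float:
    """Good's coverage C = 1 - n1/N, the estimated seen-OTU read fraction."""
    counts = _as_counts(v)
    n = counts.sum()
    if n == 0:
        raise ValueError("Good's coverage undefined for an empty count vector")
    n1 = int((counts == 1).sum())
    return 1.0 - n1 / n


def diversity_table(
    table: OTUTable | pd.DataFrame,
    seed: int = 0,
    depth: int | None = None,
    base: float = 2.0,
    n_rarefactions: int = 1,
) -> pd.DataFrame:
    """Per-sample diversity summary after rarefying to the smallest library.

    Accepts an OTU table (typically clustered at 3% dissimilarity) or an
    OTUs x samples count matrix.  Samples with zero reads are excluded with
    a warning.  With ``n_rarefactions > 1`` the metrics are averaged over
    that many seeded rarefaction draws (observed OTU count is then a mean).
    """
    matrix = table.count_matrix() if isinstance(table, OTUTable) else table
    totals = matrix.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        import warnings

        warnings.warn(f"excluding empty samples from diversity table: {empty}")
        matrix = matrix.drop(columns=empty)
        totals = totals.drop(empty)
    if matrix.shape[1] == 0:
        raise ValueError("no non-empty samples")
    depth = int(totals.min()) if depth is None else depth
    rows = []
    rng = np.random.default_rng(seed)
    for sample in matrix.columns:
        counts = matrix[sample].to_numpy()
        reps = []
        for _ in range(max(1, n_rarefactions)):
            r = rarefy(counts, depth, seed=int(rng.integers(0, 2**31)), sample_name=sample)
            reps.append(
                (
                    int((r > 0).sum()),
                    shannon(r, base=base),
                    chao1(r),
                    goods_coverage(r),
                )
            )
        mean = np.mean(reps, axis=0)
        rows.append(
            {
                "sample": sample,
                "reads": int(totals[sample]),
                "otus": float(mean[0]) if n_rarefactions > 1 else int(mean[0]),
                "shannon": float(mean[1]),
                "chao1": float(mean[2]),
                "goods_coverage": float(mean[3]),
                "rarefaction_depth": depth,
            }
        )
    return pd.DataFrame(rows).set_index("sample")
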