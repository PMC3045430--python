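"""Over-representation of gene sets (TF/RBP targets, annotation categories) in clusters.

Two statistics are provided.  The binomial test treats the cluster's
genes as draws with success probability equal to the set's fraction of
the universe and reports the upper tail P(X >= k); it slightly
overstates tails for large sets (sampling with replacement) but is the
conventional quick screen for regulator-target enrichment, reported at
a stringent raw-p cutoff (default 1e-6).  The Monte-Carlo mode computes
raw hypergeometric tails and then a family-wise empirical adjustment:
the adjusted p of a set is the add-one-corrected fraction of random
same-size clusters whose best (minimum) per-set p is at least as
extreme, which accounts for the number and overlap structure of the
sets tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection

DEFAULT_P_CUTOFF = 1e-6


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_id: str
    set_name: str
    n_cluster: int
    n_set: int
    n_universe: int
    k_overlap: int
    expected: float
    p_value: float
    adjusted_p: float | None = None
    significant: bool = False


def binomial_enrichment(
    cluster_genes,
    set_genes,
    universe,
    cluster_id: str = "cluster",
    set_name: str = "set",
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> EnrichmentResult:
    """Binomial upper-tail enrichment of one set in one cluster.

    Draws are the cluster genes; success probability is the set's share
    of the universe; p = P(X >= k) by exact summation.
    """
    cluster = set(cluster_genes)
    target = set(set_genes)
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if not cluster <= uni or not target <= uni:
        raise ValueError("cluster and set must be subsets of the universe")
    n_cluster, n_set, n_uni = len(cluster), len(target), len(uni)
    k = len(cluster & target)
    rate = n_set / n_uni
    expected = n_cluster * rate
    p = 1.0 if k == 0 else float(stats.binom.sf(k - 1, n_cluster, rate))
    p = min(p, 1.0)
    return EnrichmentResult(
        cluster_id, set_name, n_cluster, n_set, n_uni, k, expected, p,
        significant=p < p_cutoff,
    )


def hypergeom_p(k: int, n_cluster: int, n_set: int, n_universe: int) -> float:
    """Hypergeometric upper tail P(overlap >= k)."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_universe, n_set, n_cluster))


def _min_p_for_cluster(
    member_mask: np.ndarray, set_masks: np.ndarray, n_sets_sizes: np.ndarray, n_uni: int
) -> tuple[np.ndarray, float]:
    """Per-set hypergeometric p for one cluster mask and their minimum."""
    n_cluster = int(member_mask.sum())
    ks = set_masks.astype(np.int64) @ member_mask.astype(np.int64)
    ps = stats.hypergeom.sf(ks - 1, n_uni, n_sets_sizes, n_cluster)
    ps = np.where(ks == 0, 1.0, ps)
    return ps, float(ps.min())


def montecarlo_enrichment(
    clusters: dict[str, list[str]],
    annotation: GeneSetCollection,
    n_sims: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment with family-wise empirical adjustment.

    For each cluster, ``n_sims`` random gene draws of the same size give
    the null distribution of the best per-set p; a set's adjusted p is
    (b + 1) / (n_sims + 1) where b counts null draws at least as extreme.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    universe = list(annotation.universe)
    n_uni = len(universe)
    gene_index = {g: i for i, g in enumerate(universe)}
    set_names = list(annotation.sets)
    set_masks = np.zeros((len(set_names), n_uni), dtype=bool)
    for row, name in enumerate(set_names):
        for g in annotation.sets[name]:
            set_masks[row, gene_index[g]] = True
    set_sizes = set_masks.sum(axis=1)

    results: list[EnrichmentResult] = []
    for cluster_id, genes in clusters.items():
        mask = np.zeros(n_uni, dtype=bool)
        for g in genes:
            if g not in gene_index:
                raise ValueError(f"cluster gene {g!r} not in universe")
            mask[gene_index[g]] = True
        n_cluster = int(mask.sum())
        obs_ps, _ = _min_p_for_cluster(mask, set_masks, set_sizes, n_uni)
        null_min = np.empty(n_sims)
        for s in range(n_sims):
            draw = np.zeros(n_uni, dtype=bool)
            draw[rng.choice(n_uni, size=n_cluster, replace=False)] = True
            _, null_min[s] = _min_p_for_cluster(draw, set_masks, set_sizes, n_uni)
        for row, name in enumerate(set_names):
            b = int(np.sum(null_min <= obs_ps[row]))
            adj = (b + 1) / (n_sims + 1)
            k = int(np.sum(set_masks[row] & mask))
            results.append(
                EnrichmentResult(
                    cluster_id, name, n_cluster, int(set_sizes[row]), n_uni, k,
                    n_cluster * set_sizes[row] / n_uni, float(obs_ps[row]),
                    adjusted_p=adj, significant=adj < 0.05,
                )
            )
    return results


def results_table(results: list[EnrichmentResult], bonferroni: bool = True) -> pd.DataFrame:
    """Long-form results table; optional Bonferroni column (informational)."""
    df = pd.DataFrame([r.__dict__ for r in results])
    if bonferroni and len(df):
        df["bonferroni_p"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df
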