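"""Rank-based scoring engines: per-gene z-scoring, single-sample gene-set
enrichment (ssGSEA), and pre-ranked GSEA with permutation p-values.

These are shared by the immune stage (signature scores) and the metabolic
stage (per-pathway enrichment of a per-sample z-score ranking). The enrichment
score (ES) is the maximal deviation of the weighted hit/miss running sum over
the ranked gene list; ties in ranking statistics are broken by stable gene-id
order so every walk is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("imd")


@dataclass
class EnrichmentResult:
    """Pre-ranked GSEA outcome for one gene set against one ranked list."""

    set_name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    n_genes: int
    direction: str

    def __post_init__(self) -> None:
        assert -1.0 <= self.es <= 1.0 + 1e-12
        assert 0.0 <= self.p_value <= 1.0


def zscore_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize every gene across samples to mean 0, sample sd 1.

    Zero-variance genes carry no ranking information and are dropped with a
    warning. Requires at least two samples.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    vals = expr.values
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance genes before z-scoring",
                       int((~keep).sum()))
    vals = vals.loc[keep]
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return ExpressionMatrix(z, scale=expr.scale)


def _ranked_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices ordering genes by decreasing statistic, ties by gene id."""
    return np.lexsort((gene_ids, -values))


def _es_walk(weights: np.ndarray, positions: np.ndarray) -> float:
    """ES of one gene set from its (sorted) positions in the ranked list.

    ``weights`` are the |statistic|^p values in ranked order. The running sum
    gains weight/NR at hits and loses 1/(N-k) at misses; its extrema occur
    immediately after or immediately before hit positions, so only those 2k
    candidates are evaluated.
    """
    n = len(weights)
    k = len(positions)
    if k == 0 or k >= n:
        raise ValueError("gene set must hit a strict non-empty subset of the list")
    hit_w = weights[positions]
    nr = hit_w.sum()
    if nr == 0:
        hit_w = np.ones(k)
        nr = float(k)
    cum = np.cumsum(hit_w) / nr
    miss_before = (positions - np.arange(k)) / (n - k)
    r_after = cum - miss_before
    r_before = (cum - hit_w / nr) - miss_before
    pos = r_after.max()
    neg = min(r_before.min(), 0.0)
    return float(pos if pos >= -neg else neg)


def _es_walk_many(weights: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Vectorized :func:`_es_walk` over rows of a (n_perm, k) position matrix."""
    n = len(weights)
    k = positions.shape[1]
    hit_w = weights[positions]
    nr = hit_w.sum(axis=1, keepdims=True)
    uniform = nr[:, 0] == 0
    if uniform.any():
        hit_w[uniform] = 1.0
        nr[uniform] = k
    cum = np.cumsum(hit_w, axis=1) / nr
    miss_before = (positions - np.arange(k)) / (n - k)
    r_after = cum - miss_before
    r_before = (cum - hit_w / nr) - miss_before
    pos = r_after.max(axis=1)
    neg = np.minimum(r_before.min(axis=1), 0.0)
    return np.where(pos >= -neg, pos, neg)


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Single-sample enrichment scores (sets x samples).

    Per sample, genes are ranked by expression (highest rank = highest
    expression); the score is the integrated difference between the
    rank-weighted in-set ECDF (weight = rank^alpha) and the unweighted
    out-of-set ECDF, accumulated down the ranked list. Depends only on
    within-sample ranks, so it is invariant to monotone transforms of a
    sample's values. Sets intersecting fewer than ``min_genes`` expression
    genes are dropped with a warning; a set covering every gene has an empty
    out-set and is an error.
    """
    vals = expr.values
    genes = np.asarray(vals.index)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    set_members: dict[str, np.ndarray] = {}
    for name, members in sets.sets.items():
        idx = np.array(sorted(gene_pos[g] for g in members if g in gene_pos))
        if len(idx) >= n:
            raise ValueError(f"set {name!r} covers all genes; out-set is empty")
        if len(idx) < min_genes:
            logger.warning("set %r has %d genes after intersection; dropped",
                           name, len(idx))
            continue
        set_members[name] = idx

    scores = pd.DataFrame(
        np.zeros((len(set_members), vals.shape[1])),
        index=list(set_members), columns=vals.columns,
    )
    arr = vals.to_numpy()
    for j, sample in enumerate(vals.columns):
        order = _ranked_order(arr[:, j], genes)
        # absolute ranks: top of the list gets rank n
        rank_weight = (np.arange(n, 0, -1).astype(float)) ** alpha
        in_set = np.zeros(n, dtype=bool)
        pos_of_gene = np.empty(n, dtype=int)
        pos_of_gene[order] = np.arange(n)
        for name, idx in set_members.items():
            in_set[:] = False
            in_set[pos_of_gene[idx]] = True
            k = in_set.sum()
            w_in = np.where(in_set, rank_weight, 0.0)
            denom = w_in.sum()
            p_in = np.cumsum(w_in) / denom
            p_out = np.cumsum(~in_set) / (n - k)
            scores.iloc[scores.index.get_loc(name), j] = np.sum(p_in - p_out)
    if normalize:
        rng = scores.max(axis=1) - scores.min(axis=1)
        rng = rng.replace(0, 1.0)
        scores = scores.div(rng, axis=0)
    return scores


def gsea_preranked(
    ranked_stats: pd.Series,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int | None = 0,
    weight_p: float = 1.0,
    set_name: str = "set",
    rng: np.random.Generator | None = None,
    min_size: int = 3,
) -> EnrichmentResult:
    """Pre-ranked GSEA of one gene set against one per-sample ranking statistic.

    ES is the maximal deviation of the running sum weighted by
    |statistic|^weight_p at hits. The nominal p-value comes from gene-label
    permutations (random sets of the same size, ``n_perm`` draws); NES is ES
    divided by the mean |permuted ES| of the same sign. The FDR field is left
    at the nominal p here; callers adjust across their set family (see
    :func:`gsea_preranked_collection`).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    stats_ = ranked_stats.astype(float)
    if not np.all(np.isfinite(stats_.to_numpy())):
        raise ValueError("ranking statistic contains non-finite values")
    genes = np.asarray(stats_.index)
    values = stats_.to_numpy()
    n = len(genes)
    members = set(gene_set) & set(genes)
    if len(members) < min_size or len(members) >= n:
        raise ValueError(
            f"set {set_name!r}: {len(members)} genes in the list; "
            f"need {min_size} <= k < {n}"
        )
    order = _ranked_order(values, genes)
    weights = np.abs(values[order]) ** weight_p
    in_ranked = np.isin(genes[order], list(members))
    positions = np.flatnonzero(in_ranked)
    es = _es_walk(weights, positions)

    if rng is None:
        rng = np.random.default_rng(seed)
    k = len(positions)
    perm_pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    perm_pos.sort(axis=1)
    perm_es = _es_walk_many(weights, perm_pos)

    if es >= 0:
        same = perm_es[perm_es >= 0]
        p = (1.0 + np.sum(perm_es >= es)) / (1.0 + len(same))
    else:
        same = perm_es[perm_es <= 0]
        p = (1.0 + np.sum(perm_es <= es)) / (1.0 + len(same))
    nes = es / np.mean(np.abs(same)) if len(same) else np.nan
    return EnrichmentResult(
        set_name=set_name, es=es, nes=float(nes), p_value=float(min(p, 1.0)),
        fdr_q=float(min(p, 1.0)), n_genes=k,
        direction="positive" if es >= 0 else "negative",
    )


def gsea_preranked_collection(
    ranked_stats: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Run pre-ranked GSEA for every set and BH-adjust p across the family."""
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sets.sets.items():
        try:
            res = gsea_preranked(
                ranked_stats, members, n_perm=n_perm, weight_p=weight_p,
                set_name=name, rng=rng,
            )
        except ValueError as err:
            logger.warning("skipping set %r: %s", name, err)
            continue
        rows.append({
            "set_name": res.set_name, "es": res.es, "nes": res.nes,
            "p_value": res.p_value, "n_genes": res.n_genes,
            "direction": res.direction,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr_q"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["fdr_q"] = []
    return df.set_index("set_name")
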