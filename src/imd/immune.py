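"""Immune microenvironment state modeling.

The immune feature space joins (a) immune-cell fractions deconvolved from
bulk expression against a cell-type signature matrix and (b) per-sample
immune signature scores. Samples are clustered in a latent-factor reduction
of that space with a Gaussian mixture whose size is selected by BIC; the
three clusters are ordered cold < warm < hot by their mean immune activation
score (highest score = hot). Per-patient immune-state change across
timepoints is classified as negative when the tumor stays cold or moves to a
colder state, positive otherwise (staying warm or hot counts as positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .io import ExpressionMatrix

logger = logging.getLogger("imd")

STATE_RANK = {"cold": 0, "warm": 1, "hot": 2}
RANK_STATE = {v: k for k, v in STATE_RANK.items()}


@dataclass
class ClusteringModel:
    """BIC-selected Gaussian mixture over the latent immune feature space."""

    n_clusters: int
    assignments: pd.Series           # sample -> cluster index
    probabilities: pd.DataFrame      # sample x cluster responsibility
    bic_trace: dict[int, float]
    means: np.ndarray                # cluster means in latent space
    seed: int | None

    def __post_init__(self) -> None:
        best = min(self.bic_trace, key=self.bic_trace.get)
        assert best == self.n_clusters, "selected size must minimize BIC"
        assert (self.assignments == self.probabilities.to_numpy().argmax(1)).all()


@dataclass
class ImmuneProfile:
    """Per-sample immune characterization: fractions, scores, state label."""

    fractions: pd.DataFrame
    signature_scores: pd.DataFrame
    activation_score: pd.Series
    labels: pd.Series
    ranks: pd.Series


def estimate_cell_fractions(
    expr_linear: ExpressionMatrix,
    signature_matrix: pd.DataFrame,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Constrained least-squares immune cell fractions per sample.

    Solves, per sample, min ||b - S f|| with f >= 0 and sum(f) <= 1 over the
    signature genes (linear scale); the unexplained mass 1 - sum(f) is
    reported as ``other``. The inequality is handled by a zero-column slack
    variable inside a sum-to-one nonnegative solve. Requires at least
    ``min_overlap`` of each cell type's signature genes in the expression
    matrix, and a full-rank signature matrix.
    """
    expr = expr_linear.to_linear()
    shared = expr.values.index.intersection(signature_matrix.index)
    frac_found = len(shared) / len(signature_matrix.index)
    if frac_found < min_overlap:
        raise ValueError(
            f"only {frac_found:.0%} of signature genes found; need >= {min_overlap:.0%}"
        )
    S = signature_matrix.loc[shared].to_numpy().astype(float)
    rank = np.linalg.matrix_rank(S)
    if rank < S.shape[1]:
        corr = np.corrcoef(S.T)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        names = signature_matrix.columns
        raise ValueError(
            f"signature matrix is rank-deficient (rank {rank} < {S.shape[1]}); "
            f"most collinear cell types: {names[i]!r} and {names[j]!r}"
        )
    B = expr.values.loc[shared].to_numpy()
    n_types = S.shape[1]
    lam = 1e6 * np.abs(B).mean()
    X = np.hstack([S, np.zeros((S.shape[0], 1))])            # slack column
    X_aug = np.vstack([X, lam * np.ones((1, n_types + 1))])
    out = np.empty((expr.shape[1], n_types))
    for i in range(expr.shape[1]):
        y_aug = np.concatenate([B[:, i], [lam]])
        coef, _ = nnls(X_aug, y_aug)
        out[i] = coef[:n_types]
    frac = pd.DataFrame(out, index=expr.values.columns,
                        columns=signature_matrix.columns)
    frac = frac.clip(lower=0)
    total = frac.sum(axis=1)
    over = total > 1 + 1e-9
    if over.any():  # numerical guard; the slack keeps the sum <= 1
        frac.loc[over] = frac.loc[over].div(total[over], axis=0)
    frac["other"] = (1 - frac.sum(axis=1)).clip(lower=0)
    return frac


def build_immune_feature_matrix(
    fractions: pd.DataFrame, signature_scores: pd.DataFrame
) -> pd.DataFrame:
    """Column-standardized concatenation of fractions and signature scores.

    ``signature_scores`` is sets x samples (as produced by the scoring
    engine) and is transposed to samples x features. Constant features are
    dropped with a warning. Output columns have mean 0, sd 1 (sample sd).
    """
    scores_t = signature_scores.T
    shared = fractions.index.intersection(scores_t.index)
    if len(shared) == 0:
        raise ValueError("fractions and scores share no sample ids")
    feats = pd.concat(
        [fractions.loc[shared].add_prefix("frac_"),
         scores_t.loc[shared].add_prefix("sig_")], axis=1,
    )
    sd = feats.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping constant features: %s",
                       list(feats.columns[constant]))
        feats = feats.loc[:, ~constant]
        sd = sd[~constant]
    return feats.sub(feats.mean(axis=0), axis=1).div(sd, axis=1)


def cluster_immune_states(
    features: pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_latent: int = 5,
    seed: int | None = 0,
    covariance_type: str = "full",
) -> ClusteringModel:
    """Latent-factor reduction + Gaussian mixture, model size by BIC.

    PCA to ``n_latent`` components followed by Gaussian mixtures over every
    k in ``k_range``; the BIC-minimizing k is selected. Full covariances are
    the default because immune clusters are elongated along the overall
    infiltration axis; BIC model-size selection is only reliable with a few
    dozen samples per candidate cluster. Deterministic given the seed.
    """
    if min(k_range) < 1:
        raise ValueError("k_range must contain only k >= 1")
    n = len(features)
    if n <= max(k_range) * 3:
        raise ValueError(f"{n} samples too few for k up to {max(k_range)}")
    X = features.to_numpy()
    n_latent = min(n_latent, X.shape[1], n - 1)
    if np.allclose(X.std(axis=0), 0):
        # all points identical: every k fits equally, pick the smallest
        k = min(k_range)
        assign = pd.Series(0, index=features.index)
        probs = pd.DataFrame(0.0, index=features.index, columns=range(k))
        probs[0] = 1.0
        return ClusteringModel(k, assign, probs, {k: 0.0}, np.zeros((k, n_latent)), seed)
    Z = PCA(n_components=n_latent, random_state=seed).fit_transform(X)
    bic, models = {}, {}
    for k in sorted(k_range):
        gm = GaussianMixture(
            n_components=k, covariance_type=covariance_type, n_init=5,
            random_state=seed, reg_covar=1e-6,
        ).fit(Z)
        bic[k] = float(gm.bic(Z))
        models[k] = gm
    best = min(bic, key=bic.get)
    gm = models[best]
    probs = pd.DataFrame(gm.predict_proba(Z), index=features.index)
    assign = pd.Series(probs.to_numpy().argmax(1), index=features.index)
    return ClusteringModel(best, assign, probs, bic, gm.means_, seed)


def assign_state_labels(
    model: ClusteringModel,
    activation_score: pd.Series,
    tie_tol: float = 1e-9,
) -> pd.DataFrame:
    """Order clusters by mean immune activation score and label them.

    With exactly three clusters the ordered labels are cold < warm < hot
    (highest mean activation = hot); for any other k, ordered generic labels
    ``state_1..state_k`` are used. Ties in cluster means beyond ``tie_tol``
    are broken deterministically by cluster size (larger first) with a
    warning. Labeling depends only on the score ordering, so it is invariant
    to cluster relabeling.
    """
    score = activation_score.reindex(model.assignments.index)
    means = score.groupby(model.assignments).mean()
    sizes = model.assignments.value_counts()
    if means.round(12).duplicated().any() or (
        means.sort_values().diff().dropna().abs() < tie_tol
    ).any():
        logger.warning("tied cluster activation means; breaking ties by size")
    order = sorted(means.index, key=lambda c: (means[c], sizes[c]))
    k = model.n_clusters
    if k == 3:
        names = ["cold", "warm", "hot"]
    else:
        names = [f"state_{i + 1}" for i in range(k)]
    label_of = {cluster: names[rank] for rank, cluster in enumerate(order)}
    rank_of = {cluster: rank for rank, cluster in enumerate(order)}
    return pd.DataFrame({
        "cluster": model.assignments,
        "state": model.assignments.map(label_of),
        "rank": model.assignments.map(rank_of),
    })


def classify_immune_change(state_pre: str, state_later: str) -> str:
    """Immune-state change between two timepoints: negative or positive.

    Negative when the tumor conserved a cold state or moved to a colder
    state; positive otherwise (so conserving warm or hot counts as
    positive).
    """
    for s in (state_pre, state_later):
        if s not in STATE_RANK:
            raise ValueError(f"unknown immune state {s!r}")
    r_pre, r_later = STATE_RANK[state_pre], STATE_RANK[state_later]
    if (state_pre == "cold" and state_later == "cold") or r_later < r_pre:
        return "negative"
    return "positive"


def immune_profile(
    expr: ExpressionMatrix,
    signature_matrix: pd.DataFrame,
    signature_sets,
    activation_set: str,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_latent: int = 5,
    alpha: float = 0.25,
    seed: int | None = 0,
) -> tuple[ImmuneProfile, ClusteringModel]:
    """End-to-end immune characterization of a cohort.

    Scores the immune signatures per sample, deconvolves cell fractions,
    clusters the joint standardized feature space, and labels clusters by
    the mean score of ``activation_set`` (an ESTIMATE-like immune score).
    """
    from .enrichment import ssgsea_score

    scores = ssgsea_score(expr, signature_sets, alpha=alpha)
    if activation_set not in scores.index:
        raise ValueError(f"activation set {activation_set!r} was not scored")
    fractions = estimate_cell_fractions(expr.to_linear(), signature_matrix)
    features = build_immune_feature_matrix(fractions, scores)
    model = cluster_immune_states(features, k_range=k_range,
                                  n_latent=n_latent, seed=seed)
    activation = scores.loc[activation_set]
    labels = assign_state_labels(model, activation)
    profile = ImmuneProfile(
        fractions=fractions,
        signature_scores=scores,
        activation_score=activation,
        labels=labels["state"],
        ranks=labels["rank"],
    )
    return profile, model
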