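"""Association layer: linear mixed-effects models for repeated tumor
samples, two-way ANOVA with interaction, Spearman correlation matrices, and
the correlation-network / k-core analysis.

Two mixed models are used, both with a per-patient random intercept:

* the longitudinal pathway-score model
  ``y_ij ~ b0 + b1*P_ij + b2*S_ij + b3*T_ij + gamma_j + e_ij``
  (score on purity P, subtype S, categorical time T with "pre" as
  reference), where the time effect is judged by a likelihood-ratio test of
  the full against the T-dropped model (ML fits, chi-squared reference with
  df = #levels - 1);
* the immune x metabolic interaction model
  ``I_ij ~ b0 + b1*M_ij + b2*S_ij (+ b3*C_ij) + gamma_j + e_ij``
  with immune state as ordinal 0/1/2 (cold/warm/hot), metabolic state as
  -1/0/+1 (down/neutral/up) and optional cellularity adjustment; a negative
  b1 means upregulated metabolism associates with colder immune states.

Mixed models are fitted with standard REML/ML machinery; the module's
contribution is the model specification, the encodings, and the LRT
protocol. When every patient contributes a single sample the random
intercept is inestimable and the fit falls back to ordinary least squares
with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

logger = logging.getLogger("imd")

IMMUNE_CODE = {"cold": 0, "warm": 1, "hot": 2}
METAB_CODE = {"down": -1, "neutral": 0, "up": 1}


@dataclass
class LMEMResult:
    """Fixed effects, variance components, and the LRT for the tested term."""

    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    random_intercept_var: float
    residual_var: float
    lrt_stat: float | None = None
    lrt_p: float | None = None
    lrt_df: int | None = None
    fallback_ols: bool = False
    converged: bool = True
    encoding: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.random_intercept_var >= -1e-12
        assert self.residual_var >= 0
        if self.lrt_stat is not None:
            assert self.lrt_stat >= -1e-9


def _single_obs_per_patient(groups: pd.Series) -> bool:
    return groups.value_counts().max() == 1


def _fit_mixed(formula: str, data: pd.DataFrame, groups: str, reml: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[groups])
        try:
            return model.fit(reml=reml)
        except np.linalg.LinAlgError:
            # boundary variance estimates can make the default optimizer's
            # score step singular; Powell is derivative-free and robust there
            return model.fit(reml=reml, method="powell")


def fit_state_interaction_lmem(
    data: pd.DataFrame,
    immune_col: str = "immune_state",
    metabolic_col: str = "metabolic_state",
    subtype_col: str | None = "subtype",
    cellularity_col: str | None = None,
    patient_col: str = "patient_id",
) -> LMEMResult:
    """Immune ~ metabolic interaction mixed model (random patient intercept).

    Accepts state labels (cold/warm/hot, down/neutral/up) or pre-coded
    numerics. Reports the metabolic coefficient b1, its p-value, and the
    ML likelihood-ratio test of dropping the metabolic term.
    """
    df = data.copy()
    if df[immune_col].dtype == object:
        df["_I"] = df[immune_col].map(IMMUNE_CODE)
        if df["_I"].isna().any():
            raise ValueError("unknown immune state labels")
    else:
        df["_I"] = df[immune_col].astype(float)
    if df[metabolic_col].dtype == object:
        df["_M"] = df[metabolic_col].map(METAB_CODE)
        if df["_M"].isna().any():
            raise ValueError("unknown metabolic state labels")
    else:
        df["_M"] = df[metabolic_col].astype(float)

    terms = ["_M"]
    if subtype_col and subtype_col in df.columns:
        terms.append(f"C({subtype_col})")
    if cellularity_col and cellularity_col in df.columns:
        terms.append(cellularity_col)
    formula = "_I ~ " + " + ".join(terms)
    reduced = "_I ~ " + " + ".join(terms[1:]) if terms[1:] else "_I ~ 1"
    encoding = {"immune": IMMUNE_CODE, "metabolic": METAB_CODE,
                "formula": formula}
    return _fit_with_lrt(df, formula, reduced, patient_col, "_M", 1, encoding)


def fit_longitudinal_lmem(
    data: pd.DataFrame,
    score_col: str = "score",
    time_col: str = "timepoint",
    purity_col: str | None = "purity",
    subtype_col: str | None = "subtype",
    patient_col: str = "patient_id",
) -> LMEMResult:
    """Longitudinal pathway-score mixed model with a time LRT.

    Time enters as a categorical predictor with ``pre`` as the reference
    level; the likelihood-ratio test compares the ML full fit against the
    time-dropped fit on a chi-squared with (#time levels - 1) df.
    """
    df = data.copy()
    levels = [t for t in ("pre", "on", "post") if t in set(df[time_col])]
    if not levels:
        levels = sorted(set(df[time_col]))
    df["_T"] = pd.Categorical(df[time_col], categories=levels)
    terms = []
    if purity_col and purity_col in df.columns:
        terms.append(purity_col)
    if subtype_col and subtype_col in df.columns:
        terms.append(f"C({subtype_col})")
    full = f"{score_col} ~ " + " + ".join(terms + ["_T"])
    reduced = f"{score_col} ~ " + (" + ".join(terms) if terms else "1")
    encoding = {"time_levels": levels, "formula": full}
    return _fit_with_lrt(df, full, reduced, patient_col, "_T", len(levels) - 1,
                         encoding)


def _fit_with_lrt(
    df: pd.DataFrame, full: str, reduced: str, patient_col: str,
    tested: str, lrt_df: int, encoding: dict,
) -> LMEMResult:
    response = full.split("~")[0].strip()
    if df[response].nunique() <= 1:
        # constant response: every model fits perfectly and identically
        logger.warning("constant response %r: trivial fit, LRT = 0", response)
        coef = pd.Series({"Intercept": float(df[response].iloc[0])})
        zero = pd.Series({"Intercept": 0.0})
        return LMEMResult(
            coefficients=coef, std_errors=zero,
            p_values=pd.Series({"Intercept": np.nan}),
            random_intercept_var=0.0, residual_var=0.0,
            lrt_stat=0.0, lrt_p=1.0, lrt_df=lrt_df, encoding=encoding,
        )
    if _single_obs_per_patient(df[patient_col]):
        logger.warning("single observation per patient everywhere; "
                       "falling back to ordinary least squares")
        fit = smf.ols(full, df).fit()
        fit_red = smf.ols(reduced, df).fit()
        lrt = max(2 * (fit.llf - fit_red.llf), 0.0)
        return LMEMResult(
            coefficients=fit.params, std_errors=fit.bse, p_values=fit.pvalues,
            random_intercept_var=0.0, residual_var=float(fit.scale),
            lrt_stat=float(lrt), lrt_p=float(sps.chi2.sf(lrt, lrt_df)),
            lrt_df=lrt_df, fallback_ols=True, encoding=encoding,
        )
    fit = _fit_mixed(full, df, patient_col, reml=True)
    # ML fits for the likelihood-ratio test
    fit_ml = _fit_mixed(full, df, patient_col, reml=False)
    fit_red = _fit_mixed(reduced, df, patient_col, reml=False)
    lrt = max(2 * (fit_ml.llf - fit_red.llf), 0.0)
    fe = fit.fe_params
    return LMEMResult(
        coefficients=fe,
        std_errors=fit.bse.loc[fe.index],
        p_values=fit.pvalues.loc[fe.index],
        random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
        residual_var=float(fit.scale),
        lrt_stat=float(lrt), lrt_p=float(sps.chi2.sf(lrt, lrt_df)),
        lrt_df=lrt_df, converged=bool(fit.converged), encoding=encoding,
    )


# ---------------------------------------------------------------------------
# ANOVA


def two_way_anova_interaction(
    data: pd.DataFrame,
    score_col: str = "score",
    group_col: str = "group",
    time_col: str = "time",
) -> dict:
    """Interaction term of a two-way ANOVA (group x time) on a score.

    Requires >= 2 levels per factor and >= 2 observations in every crossed
    cell (an empty cell is an error naming it). Constant data yields F = 0
    and p = 1.
    """
    df = data.copy()
    for col in (group_col, time_col):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    cells = df.groupby([group_col, time_col], observed=True).size()
    full_index = pd.MultiIndex.from_product(
        [df[group_col].unique(), df[time_col].unique()]
    )
    missing = full_index.difference(cells.index)
    if len(missing) or (cells < 2).any():
        bad = list(missing) if len(missing) else list(cells[cells < 2].index)
        raise ValueError(f"cell(s) with < 2 observations: {bad}")
    if df[score_col].nunique() == 1:
        return {"F": 0.0, "p": 1.0}
    formula = f"{score_col} ~ C({group_col}) * C({time_col})"
    fit = smf.ols(formula, df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(fit, typ=2)
    inter = f"C({group_col}):C({time_col})"
    F = float(table.loc[inter, "F"])
    p = float(table.loc[inter, "PR(>F)"])
    if np.isnan(F):  # zero residual everywhere
        F, p = 0.0, 1.0
    return {"F": F, "p": p, "anova_table": table}


# ---------------------------------------------------------------------------
# correlation


def spearman_matrix(features: pd.DataFrame, min_obs: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p matrices over the columns of a feature table.

    Pairwise-complete observations; a constant feature has undefined rank
    correlation and is reported as missing (NaN row/column). Diagonal rho
    is 1 for non-constant features.
    """
    cols = list(features.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    constant = {c for c in cols if features[c].dropna().nunique() <= 1}
    for i in range(k):
        for j in range(i, k):
            a, b = cols[i], cols[j]
            if a in constant or b in constant:
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                pmat.loc[a, b] = pmat.loc[b, a] = np.nan
                continue
            if i == j:
                continue
            pair = features[[a, b]].dropna()
            if len(pair) < min_obs:
                raise ValueError(f"pair ({a}, {b}) has < {min_obs} paired observations")
            r, p = sps.spearmanr(pair[a], pair[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pmat.loc[a, b] = pmat.loc[b, a] = p
    return rho, pmat


def correlation_network(
    matrix: pd.DataFrame, threshold: float = 0.3
) -> nx.Graph:
    """Pearson correlation graph over features (rows) across samples
    (columns), keeping edges with |r| >= threshold. Constant features become
    isolated nodes with a warning; no self-loops.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples to correlate")
    arr = matrix.to_numpy()
    sd = arr.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("constant features are isolated nodes: %s",
                       list(matrix.index[constant]))
    G = nx.Graph()
    G.add_nodes_from(matrix.index)
    ok = np.flatnonzero(~constant)
    if len(ok) >= 2:
        r = np.corrcoef(arr[ok])
        ii, jj = np.triu_indices(len(ok), k=1)
        for a, b in zip(ii, jj):
            if abs(r[a, b]) >= threshold:
                G.add_edge(matrix.index[ok[a]], matrix.index[ok[b]],
                           r=float(r[a, b]))
    return G


def k_core_prune(graph: nx.Graph, k: int = 2) -> nx.Graph:
    """Maximal subgraph with every node of degree >= k (iterated removal to
    the fixpoint); the result is independent of removal order."""
    if k < 0:
        raise ValueError("k must be >= 0")
    g = nx.Graph(graph)
    g.remove_edges_from(nx.selfloop_edges(g))
    return nx.k_core(g, k)
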