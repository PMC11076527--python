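"""Somatic-call filtering, cancer cell fractions, clonality, and the
clonal-evolution / immune-change association.

The CCF of a mutation with variant allele frequency VAF in a sample of
purity p at a locus with tumor copy number CN_t (normal CN_n, default 2) is

    CCF = VAF * (1/p) * [p*CN_t + CN_n*(1-p)]     (multiplicity one),

left unclipped so noise can push points above 1. Confidence intervals come
from the exact (Clopper-Pearson) binomial interval on the VAF propagated
through this monotone map; a mutation is clonal when its interval overlaps
1. A patient's clonal evolution is extinction when >90% of baseline
mutations disappear after therapy or fewer than 10 mutations remain in the
post-treatment sample, persistence otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MutationTable

logger = logging.getLogger("imd")


@dataclass
class CCFEstimate:
    """Point estimate and confidence interval for one mutation's CCF."""

    ccf: float
    ci_low: float
    ci_high: float
    clonality: str

    def __post_init__(self) -> None:
        assert self.ci_low - 1e-12 <= self.ccf <= self.ci_high + 1e-12
        expected = "clonal" if self.ci_low <= 1.0 <= self.ci_high else "subclonal"
        assert self.clonality == expected


@dataclass
class ClonalEvolutionCall:
    """Per-patient extinction/persistence call with the counts behind it."""

    n_baseline: int
    n_shared: int
    n_post: int
    status: str

    @property
    def fraction_disappeared(self) -> float:
        return 1.0 - self.n_shared / self.n_baseline


# ---------------------------------------------------------------------------
# somatic filter

_FILTER_REQUIRED = (
    "variant_class", "vaf", "depth", "caller_flags", "normal_vaf",
    "normal_alt_count", "population_freq", "patient_id", "timepoint",
)


def filter_somatic_calls(table: MutationTable) -> tuple[MutationTable, pd.DataFrame]:
    """Apply the tailored somatic filter; returns (kept, per-rule counts).

    SNVs are kept when they satisfy the VAF/caller rule — called by both
    callers with VAF > 2%, called by any caller with VAF > 5%, or VAF > 2%
    and the same variant present at two or more of the patient's timepoints —
    AND depth > 30, normal VAF < 1%, normal alt reads < 5, and population
    frequency not exceeding 1%. Indels additionally require depth > 50.
    The kept set is exactly the intersection of the per-rule kept sets.
    """
    df = table.table
    for col in _FILTER_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"filter requires column {col!r}")

    n_callers = df["caller_flags"].fillna("").map(
        lambda s: len([p for p in str(s).split(",") if p])
    )
    key = (
        df["patient_id"].astype(str) + "|" + df["chrom"].astype(str) + ":"
        + df["pos"].astype(str) + ":" + df["ref"].astype(str) + ":"
        + df["alt"].astype(str)
    )
    n_timepoints = key.map(
        df.assign(_k=key).groupby("_k")["timepoint"].nunique()
    )

    both_callers = (n_callers >= 2) & (df["vaf"] > 0.02)
    any_caller = (n_callers >= 1) & (df["vaf"] > 0.05)
    recurrent = (df["vaf"] > 0.02) & (n_timepoints >= 2)
    rule_vaf = both_callers | any_caller | recurrent
    rule_depth = df["depth"] > 30
    rule_normal_vaf = df["normal_vaf"] < 0.01
    rule_normal_reads = df["normal_alt_count"] < 5
    rule_popfreq = df["population_freq"] <= 0.01
    rule_indel_depth = (df["variant_class"] != "indel") | (df["depth"] > 50)

    rules = {
        "vaf_caller": rule_vaf,
        "depth_gt30": rule_depth,
        "normal_vaf_lt1pct": rule_normal_vaf,
        "normal_reads_lt5": rule_normal_reads,
        "population_freq_le1pct": rule_popfreq,
        "indel_depth_gt50": rule_indel_depth,
    }
    keep = pd.Series(True, index=df.index)
    counts = []
    for name, mask in rules.items():
        counts.append({"rule": name, "rejected": int((~mask).sum())})
        keep &= mask
    counts_df = pd.DataFrame(counts).set_index("rule")
    logger.info("somatic filter kept %d/%d records; per-rule rejections: %s",
                int(keep.sum()), len(df), counts_df["rejected"].to_dict())
    return MutationTable(df[keep].copy()), counts_df


# ---------------------------------------------------------------------------
# CCF


def compute_ccf(vaf: float, purity: float, cn_t: float, cn_n: float = 2.0) -> float:
    """Point CCF from VAF, purity and locus copy numbers (unclipped)."""
    if purity <= 0 or purity > 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if cn_t < 0:
        raise ValueError("cn_t must be >= 0")
    if not 0 <= vaf <= 1:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    return vaf * (1.0 / purity) * (purity * cn_t + cn_n * (1.0 - purity))


def _clopper_pearson(alt: int, depth: int, conf: float) -> tuple[float, float]:
    alpha = 1.0 - conf
    lo = stats.beta.ppf(alpha / 2, alt, depth - alt + 1) if alt > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, alt + 1, depth - alt) if alt < depth else 1.0
    return float(lo), float(hi)


def ccf_interval(
    alt_count: int,
    depth: int,
    purity: float,
    cn_t: float,
    cn_n: float = 2.0,
    conf: float = 0.95,
    method: str = "clopper-pearson",
) -> CCFEstimate:
    """CCF point and confidence interval; clonal iff the interval overlaps 1.

    The exact binomial interval on the VAF is mapped through the (monotone
    in VAF) CCF formula. ``method="normal"`` uses the Wald approximation
    instead. A point above 1 whose interval excludes 1 is flagged as
    inconsistent in the log but still reported as subclonal per the overlap
    rule.
    """
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    if depth < 1 or alt_count > depth:
        raise ValueError("need 1 <= depth and alt_count <= depth")
    vaf = alt_count / depth
    if method == "clopper-pearson":
        v_lo, v_hi = _clopper_pearson(alt_count, depth, conf)
    elif method == "normal":
        se = np.sqrt(max(vaf * (1 - vaf), 1e-12) / depth)
        zcrit = stats.norm.ppf(1 - (1 - conf) / 2)
        v_lo, v_hi = max(vaf - zcrit * se, 0.0), min(vaf + zcrit * se, 1.0)
    else:
        raise ValueError(f"unknown interval method {method!r}")
    ccf = compute_ccf(vaf, purity, cn_t, cn_n)
    lo = compute_ccf(v_lo, purity, cn_t, cn_n)
    hi = compute_ccf(v_hi, purity, cn_t, cn_n)
    clonality = "clonal" if lo <= 1.0 <= hi else "subclonal"
    if ccf > 1.0 and clonality == "subclonal":
        logger.warning("CCF point %.3f > 1 with interval excluding 1; "
                       "inconsistent copy number / purity likely", ccf)
    return CCFEstimate(ccf=ccf, ci_low=lo, ci_high=hi, clonality=clonality)


def ccf_table(mutations: MutationTable, conf: float = 0.95,
              method: str = "clopper-pearson") -> pd.DataFrame:
    """CCF estimates for every record of a mutation table."""
    df = mutations.table
    rows = []
    for _, rec in df.iterrows():
        est = ccf_interval(
            int(rec["alt_count"]), int(rec["depth"]), float(rec["purity"]),
            float(rec["cn_t"]), float(rec["cn_n"]), conf=conf, method=method,
        )
        rows.append({
            "sample_id": rec["sample_id"], "patient_id": rec["patient_id"],
            "timepoint": rec["timepoint"],
            "key": f"{rec['chrom']}:{rec['pos']}:{rec['ref']}:{rec['alt']}",
            "ccf": est.ccf, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "clonality": est.clonality,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clonal evolution


def classify_clonal_evolution(baseline: set, post: set) -> ClonalEvolutionCall:
    """Extinction/persistence from baseline and post-treatment mutation keys.

    Extinction iff the fraction of baseline mutations absent post-treatment
    exceeds 0.9, or fewer than 10 mutations exist post-treatment. Keys are
    de-duplicated sets, so the call is invariant to record order and
    duplicates. An empty baseline leaves the disappeared fraction undefined
    and is an error.
    """
    baseline, post = set(baseline), set(post)
    if not baseline:
        raise ValueError("empty baseline mutation set: disappeared fraction undefined")
    shared = len(baseline & post)
    disappeared = 1.0 - shared / len(baseline)
    status = "extinction" if (disappeared > 0.9 or len(post) < 10) else "persistence"
    return ClonalEvolutionCall(
        n_baseline=len(baseline), n_shared=shared, n_post=len(post), status=status,
    )


def subclone_fraction(estimates: list[CCFEstimate]) -> float:
    """Percentage of subclonal mutations among a sample's estimates."""
    if not estimates:
        raise ValueError("no CCF estimates supplied")
    n_sub = sum(1 for e in estimates if e.clonality == "subclonal")
    return 100.0 * n_sub / len(estimates)


# ---------------------------------------------------------------------------
# co-evolution contingency


def coevolution_contingency(
    immune_changes: pd.Series, statuses: pd.Series
) -> dict:
    """Immune-change x clonal-evolution 2x2 association.

    Rows: immune change (positive, negative); columns: evolution status
    (extinction, persistence). Reports the Yates-corrected chi-squared
    statistic and p, the uncorrected chi-squared p, the two-sided Fisher
    exact p, and the Haldane-Anscombe (+0.5) odds ratio. Zero cells are
    allowed.
    """
    bad = set(immune_changes) - {"negative", "positive"}
    if bad:
        raise ValueError(f"unknown immune change labels {sorted(bad)}")
    bad = set(statuses) - {"extinction", "persistence"}
    if bad:
        raise ValueError(f"unknown evolution labels {sorted(bad)}")
    shared = immune_changes.index.intersection(statuses.index)
    ic, st = immune_changes[shared], statuses[shared]
    table = np.array([
        [int(((ic == "positive") & (st == "extinction")).sum()),
         int(((ic == "positive") & (st == "persistence")).sum())],
        [int(((ic == "negative") & (st == "extinction")).sum()),
         int(((ic == "negative") & (st == "persistence")).sum())],
    ])
    return contingency_tests(table)


def contingency_tests(table: np.ndarray) -> dict:
    """Yates / uncorrected chi-squared, Fisher exact, Haldane odds ratio
    for an explicit 2x2 count table."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    a, b, c, d = table.ravel()
    if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        chi2_yates = chi2_plain = 0.0
        p_yates = p_plain = 1.0
    else:
        chi2_yates, p_yates, _, _ = stats.chi2_contingency(table, correction=True)
        chi2_plain, p_plain, _, _ = stats.chi2_contingency(table, correction=False)
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return {
        "table": table,
        "chi2_yates": float(chi2_yates),
        "p_yates": float(p_yates),
        "chi2": float(chi2_plain),
        "p_chi2": float(p_plain),
        "fisher_p": float(fisher_p),
        "odds_ratio": float(odds),
    }
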