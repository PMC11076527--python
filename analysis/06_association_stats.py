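"""Association layer: the immune x metabolic interaction mixed model, the
longitudinal time-effect model, the group x time ANOVA, and the
correlation network with k-core pruning.

Fits the interaction LMEM (immune rank ~ metabolic state + subtype, random
patient intercept) on the cohort's immune/metabolic calls, the longitudinal
pathway-score LMEM with a likelihood-ratio test for the time effect, a
two-way ANOVA with interaction on signature scores, and builds the
|r| >= 0.3, k-core >= 2 correlation network over the immune feature space.
"""

import argparse
import pathlib

import pandas as pd

from imd.enrichment import ssgsea_score
from imd.io import read_expression_matrix, read_gmt
from imd.stats import (
    correlation_network,
    fit_longitudinal_lmem,
    fit_state_interaction_lmem,
    k_core_prune,
    spearman_matrix,
    two_way_anova_interaction,
)

IMMUNE_RANK = {"cold": 0, "warm": 1, "hot": 2}
METAB_CODE = {"down": -1, "neutral": 0, "up": 1}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=pathlib.Path,
                    default=pathlib.Path("results/cohort"))
    ap.add_argument("--immune", type=pathlib.Path,
                    default=pathlib.Path("results/immune"))
    ap.add_argument("--metabolic", type=pathlib.Path,
                    default=pathlib.Path("results/metabolic"))
    ap.add_argument("--outdir", type=pathlib.Path,
                    default=pathlib.Path("results/associations"))
    ap.add_argument("--pathway", default="tca_cycle")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    annot = pd.read_csv(args.cohort / "sample_annotations.tsv", sep="\t",
                        index_col="sample_id")
    states = pd.read_csv(args.immune / "immune_states.tsv", sep="\t",
                         index_col="sample_id")
    metab = pd.read_csv(args.metabolic / "metabolic_states.tsv", sep="\t",
                        index_col="sample_id")

    shared = states.index.intersection(metab.index)
    df = pd.DataFrame({
        "immune_state": states.loc[shared, "rank"].astype(float),
        "metabolic_state": metab.loc[shared, args.pathway].map(METAB_CODE),
        "subtype": annot.loc[shared, "subtype"],
        "patient_id": annot.loc[shared, "patient_id"],
    })
    res = fit_state_interaction_lmem(df)
    summary = pd.DataFrame({
        "coef": res.coefficients, "se": res.std_errors, "p": res.p_values})
    summary.to_csv(args.outdir / "interaction_lmem.tsv", sep="\t")
    print(f"interaction LMEM ({args.pathway}): beta1 = "
          f"{res.coefficients['_M']:.3f} (p = {res.p_values['_M']:.3g}), "
          f"random-intercept var = {res.random_intercept_var:.3f}")

    # longitudinal pathway-score model on the adaptive-immune ssGSEA score
    expr = read_expression_matrix(args.cohort / "bulk_expression_log2.tsv")
    sigs = read_gmt(args.cohort / "immune_signatures.gmt")
    scores = ssgsea_score(expr, sigs)
    truth = pd.read_csv(args.cohort / "truth_samples.tsv", sep="\t", index_col=0)
    long_df = pd.DataFrame({
        "score": scores.loc["adaptive_immune"],
        "timepoint": annot["timepoint"],
        "purity": truth["purity"],
        "subtype": annot["subtype"],
        "patient_id": annot["patient_id"],
    }).dropna()
    lres = fit_longitudinal_lmem(long_df)
    print(f"longitudinal LMEM: time LRT chi2 = {lres.lrt_stat:.2f} "
          f"(df {lres.lrt_df}), p = {lres.lrt_p:.3g}")

    # two-way ANOVA: immune change group x time on the signature score
    ic = pd.read_csv(args.immune / "immune_change.tsv", sep="\t",
                     index_col="patient_id")["immune_change"]
    adf = long_df.join(ic, on="patient_id").dropna()
    adf = adf.rename(columns={"immune_change": "group",
                              "timepoint": "time"})
    ares = two_way_anova_interaction(adf)
    print(f"two-way ANOVA interaction (change x time): F = {ares['F']:.2f}, "
          f"p = {ares['p']:.3g}")

    # correlation network over immune features, pruned at k-core 2
    feats = pd.concat([
        scores.T,
        pd.read_csv(args.immune / "cell_fractions.tsv", sep="\t",
                    index_col="sample_id"),
    ], axis=1)
    rho, _ = spearman_matrix(feats)
    rho.to_csv(args.outdir / "spearman_rho.tsv", sep="\t")
    g = correlation_network(feats.T, threshold=0.3)
    core = k_core_prune(g, 2)
    edges = pd.DataFrame(
        [{"node_a": a, "node_b": b, "r": d["r"]}
         for a, b, d in core.edges(data=True)])
    edges.to_csv(args.outdir / "network_edges.tsv", sep="\t", index=False)
    print(f"correlation network: {g.number_of_nodes()} nodes, "
          f"{g.number_of_edges()} edges at |r| >= 0.3; "
          f"{core.number_of_nodes()} nodes survive the 2-core")


if __name__ == "__main__":
    main()
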