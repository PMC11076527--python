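"""Per-sample, per-pathway three-state metabolic phenotyping and the
integrated immunometabolic grouping.

Each sample's genes are z-scored across the cohort and the z-scores serve as
the per-sample ranking statistic for pre-ranked GSEA of every metabolic
pathway. P-values are BH-adjusted across the pathways within the sample, the
pathway Z summary is the mean z-score of the pathway's genes in that sample,
and the three-state rule is:

* up      iff FDR < 0.1 and Z > 0
* down    iff FDR < 0.1 and Z < 0
* neutral otherwise (FDR >= 0.1; the boundary FDR = 0.1 is neutral)

Per-patient metabolic change between timepoints is positive exactly when the
later state is downregulated (maintained or newly reached), negative
otherwise. Immune and metabolic changes combine into the 2x2 integrated
groups G1..G4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import gsea_preranked_collection, zscore_genes
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("imd")

GROUP_OF = {
    ("positive", "positive"): "G1",
    ("positive", "negative"): "G2",
    ("negative", "positive"): "G3",
    ("negative", "negative"): "G4",
}


@dataclass
class MetabolicPhenotype:
    """Sample x pathway states with the FDR and Z evidence behind them."""

    states: pd.DataFrame     # sample x pathway, values in {down, neutral, up}
    fdr: pd.DataFrame        # sample x pathway BH-adjusted permutation p
    z: pd.DataFrame          # sample x pathway mean z of pathway genes
    source: str = "tumor_cell"

    def __post_init__(self) -> None:
        assert self.source in ("tumor_cell", "bulk")
        for df in (self.fdr, self.z):
            assert df.shape == self.states.shape


def classify_metabolic_state(q: float, z: float) -> str:
    """Three-state rule on (FDR, Z): up / down / neutral.

    Total on q in [0, 1] and finite z; the boundary q == 0.1 is neutral
    (the significant branches require strict FDR < 0.1). A significant
    pathway with Z exactly 0 carries no direction and is neutral.
    """
    if not 0 <= q <= 1:
        raise ValueError(f"FDR q={q} outside [0, 1]")
    if not np.isfinite(z):
        raise ValueError("Z summary must be finite")
    if q < 0.1 and z > 0:
        return "up"
    if q < 0.1 and z < 0:
        return "down"
    return "neutral"


def profile_sample_metabolism(
    expr: ExpressionMatrix,
    pathways: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = 0,
    weight_p: float = 1.0,
    source: str = "tumor_cell",
    z_summary: str = "mean_z",
) -> MetabolicPhenotype:
    """Classify every sample into down/neutral/up per metabolic pathway.

    Per sample: genes are ranked by their cohort z-score, pre-ranked GSEA is
    run for each pathway (gene-set permutations, seeded), p-values are
    BH-adjusted across the pathways within the sample, and the state follows
    the (FDR, Z) rule. ``z_summary`` selects the Z used by the rule:
    ``"mean_z"`` (mean pathway-gene z-score in the sample, default) or
    ``"nes"`` (sign and magnitude of the normalized enrichment score); the
    two agree in direction on all synthetic fixtures.

    Pathways absent from the expression matrix are skipped with a warning.
    """
    if z_summary not in ("mean_z", "nes"):
        raise ValueError(f"unknown z_summary {z_summary!r}")
    zscored = zscore_genes(expr)
    zvals = zscored.values
    samples = list(zvals.columns)
    names = pathways.names()

    states = pd.DataFrame(index=samples, columns=names, dtype=object)
    fdr = pd.DataFrame(np.nan, index=samples, columns=names)
    zsum = pd.DataFrame(np.nan, index=samples, columns=names)
    rng = np.random.default_rng(seed)
    for sample in samples:
        ranks = zvals[sample]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = gsea_preranked_collection(
            ranks, pathways, n_perm=n_perm, seed=sub_seed, weight_p=weight_p,
        )
        for pw in names:
            if pw not in res.index:
                continue
            genes = [g for g in pathways[pw] if g in ranks.index]
            mean_z = float(ranks.loc[genes].mean())
            z_val = mean_z if z_summary == "mean_z" else float(res.loc[pw, "nes"])
            q = float(res.loc[pw, "fdr_q"])
            states.loc[sample, pw] = classify_metabolic_state(q, z_val)
            fdr.loc[sample, pw] = q
            zsum.loc[sample, pw] = z_val
    skipped = [pw for pw in names if states[pw].isna().all()]
    if skipped:
        logger.warning("pathways absent from expression, skipped: %s", skipped)
        states = states.drop(columns=skipped)
        fdr = fdr.drop(columns=skipped)
        zsum = zsum.drop(columns=skipped)
    return MetabolicPhenotype(states=states, fdr=fdr, z=zsum, source=source)


def classify_metabolic_change(state_pre: str, state_later: str) -> str:
    """Metabolic change between timepoints: positive iff the later state is
    downregulated (maintained down, or moved to down from up/neutral)."""
    for s in (state_pre, state_later):
        if s not in ("down", "neutral", "up"):
            raise ValueError(f"unknown metabolic state {s!r}")
    return "positive" if state_later == "down" else "negative"


def integrate_immunometabolic_group(immune_change: str, metabolic_change: str) -> str:
    """Map the (immune, metabolic) change pair onto integrated groups G1..G4:
    G1 = both positive, G2 = immune-only, G3 = metabolic-only, G4 = neither."""
    key = (immune_change, metabolic_change)
    if key not in GROUP_OF:
        raise ValueError(f"changes must be negative/positive, got {key}")
    return GROUP_OF[key]
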