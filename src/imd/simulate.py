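"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a longitudinal neoadjuvant-chemotherapy expression
cohort with full ground truth, so every downstream stage is testable without
any external download:

* bulk expression as convex linear-space mixtures ``B = p*t + (1-p)*s`` of a
  tumor profile and a combination of tumor-free reference profiles, with
  known purity;
* per-sample, per-pathway metabolic states realized as log2 shifts on
  pathway gene blocks of the tumor compartment;
* cold/warm/hot immune classes realized as the immune-cell content of the
  adjacent compartment, driving both immune-signature gene expression and
  deconvolvable cell fractions;
* paired timepoints realizing configured immune/metabolic state transitions;
* somatic mutation tables with known clonal structure, where read counts are
  binomial draws at the expected VAF implied by the CCF/purity/copy-number
  forward model.

Mixing is applied in linear abundance and logged afterwards (convexity of
mixtures holds on the linear scale); measurement noise is Gaussian on the
log2 scale. Mutation multiplicity is fixed at one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    SampleAnnotationTable,
)

logger = logging.getLogger("imd")

PATHWAY_NAMES = (
    "amino_acid_metabolism",
    "carbohydrate_metabolism",
    "integration_of_energy",
    "lipid_metabolism",
    "nucleotide_metabolism",
    "tca_cycle",
    "vitamin_cofactor_metabolism",
)
IMMUNE_CLASSES = ("cold", "warm", "hot")
CELL_TYPES = (
    "B_cells", "CD8_T_cells", "CD4_T_cells", "Treg_cells", "NK_cells",
    "monocytes", "M1_macrophages", "M2_macrophages", "dendritic_cells",
    "neutrophils",
)
SIGNATURE_NAMES = (
    "adaptive_immune", "innate_immune", "cytokine", "checkpoint",
    "antigen_presentation", "tumor_stroma",
)
# which cell populations express each signature block ("tumor_stroma" is a
# stromal program, expressed by the stroma compartment instead)
SIGNATURE_CELLS: dict[str, tuple[str, ...]] = {
    "adaptive_immune": ("CD8_T_cells", "CD4_T_cells", "B_cells", "NK_cells"),
    "innate_immune": ("monocytes", "M1_macrophages", "dendritic_cells",
                      "neutrophils"),
    "cytokine": ("CD8_T_cells", "NK_cells", "M1_macrophages"),
    "checkpoint": ("Treg_cells", "M2_macrophages", "CD8_T_cells"),
    "antigen_presentation": ("dendritic_cells", "M1_macrophages", "B_cells"),
    "tumor_stroma": (),
}
# immune cell mixes anchoring the reference components: activated (hot-like),
# suppressed (cold-like), mixed, balanced — order matches CELL_TYPES
_ANCHOR_MIXES = {
    "activated": (0.15, 0.25, 0.12, 0.02, 0.10, 0.05, 0.15, 0.02, 0.10, 0.04),
    "suppressed": (0.03, 0.04, 0.08, 0.20, 0.03, 0.15, 0.03, 0.30, 0.04, 0.10),
    "mixed": (0.10, 0.12, 0.12, 0.08, 0.08, 0.10, 0.10, 0.10, 0.10, 0.10),
    "balanced": (0.1,) * 10,
}
# per-class Dirichlet concentrations over the anchor components (cold, warm,
# hot rows; columns activated, suppressed, mixed, balanced). Concentrations
# are high so each class has a crisp compositional identity; between-class
# differences in composition are what the clustering stage must find.
_CLASS_COMPONENT_ALPHA = {
    "cold": (2.0, 60.0, 6.0, 6.0),
    "warm": (6.0, 6.0, 50.0, 12.0),
    "hot": (60.0, 2.0, 6.0, 6.0),
}
METAB_STATES = ("down", "neutral", "up")


@dataclass
class BulkCohortConfig:
    """Study conditions for the expression cohort.

    Defaults mirror a small two-timepoint neoadjuvant cohort: 60 patients
    sampled pre- and on-treatment, ~2,000 genes with seven 40-gene metabolic
    pathway blocks, three balanced immune classes whose between-class
    separation on immune features is 1.5 within-class standard deviations,
    purities broad enough to exercise the deconvolution, and Gaussian log2
    measurement noise of 0.25.
    """

    n_patients: int = 60
    timepoints: tuple[str, ...] = ("pre", "on")
    n_genes: int = 2000
    n_pathways: int = 7
    genes_per_pathway: int = 40
    n_normal_components: int = 5
    purity_range: tuple[float, float] = (0.35, 0.75)
    noise_sd: float = 0.25
    # per-gene biological variability of the tumor compartment (log2 sd drawn
    # uniformly per gene): real cohorts have heterogeneous gene-level
    # variance on top of measurement noise, and without it a gene set whose
    # members are merely *less* variable than the rest of the transcriptome
    # is itself a detectable (artifactual) enrichment signal
    biological_sd_range: tuple[float, float] = (0.2, 0.8)
    pathway_shift: float = 1.0          # log2 shift of an up/down pathway state
    class_separation: float = 1.5       # immune-class gap in within-class sd units
    metab_state_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    # "balanced": stratified so each pathway/timepoint has the exact state
    # proportions above (the three-state call is cohort-relative, so the
    # neutral class is anchored at the cohort centre only when up and down
    # shifts cancel); "markov": independent chains per patient/pathway using
    # metab_transition.
    metab_assignment: str = "balanced"
    # row = state at previous timepoint (down/neutral/up), columns likewise
    metab_transition: tuple[tuple[float, ...], ...] = (
        (0.6, 0.3, 0.1),
        (0.2, 0.6, 0.2),
        (0.1, 0.3, 0.6),
    )
    # row = immune class at previous timepoint (cold/warm/hot)
    immune_transition: tuple[tuple[float, ...], ...] = (
        (0.60, 0.30, 0.10),
        (0.15, 0.55, 0.30),
        (0.05, 0.25, 0.70),
    )

    def __post_init__(self) -> None:
        if self.pathway_shift < 0 or self.noise_sd < 0:
            raise ValueError("effect sizes and noise sd must be >= 0")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purities must lie in (0, 1]")


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort, sufficient to score every stage.

    ``samples`` has one row per sample (purity, immune class, per-pathway
    metabolic state); ``transitions`` one row per patient and pathway with
    the change labels implied by the classification rules. The linear-scale
    mixture components, reference profiles, gene sets and the cell-type
    signature matrix used by the generator are carried along so recovery can
    be checked algebraically.
    """

    samples: pd.DataFrame
    transitions: pd.DataFrame | None = None
    tumor_linear: pd.DataFrame | None = None
    adjacent_linear: pd.DataFrame | None = None
    fractions: pd.DataFrame | None = None
    normal_refs: ExpressionMatrix | None = None
    signature_matrix: pd.DataFrame | None = None
    pathways: GeneSetCollection | None = None
    immune_signatures: GeneSetCollection | None = None
    immune_activation_set: str = "adaptive_immune"
    mutations: pd.DataFrame | None = None
    patient_status: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# gene universe and reference profiles


@dataclass
class _GeneUniverse:
    genes: np.ndarray
    pathway_idx: dict[str, np.ndarray]
    cell_marker_idx: dict[str, np.ndarray]
    immune_program_idx: np.ndarray
    signature_idx: dict[str, np.ndarray]
    tumor_marker_idx: np.ndarray
    stroma_marker_idx: np.ndarray
    baseline: np.ndarray


def _build_universe(cfg: BulkCohortConfig, rng: np.random.Generator) -> _GeneUniverse:
    n = cfg.n_genes
    n_pw = cfg.n_pathways * cfg.genes_per_pathway
    n_cell = len(CELL_TYPES) * 15
    n_prog = len(SIGNATURE_NAMES) * 25
    need = n_pw + n_cell + n_prog + 200
    if n < need:
        raise ValueError(f"n_genes={n} too small; need >= {need}")
    genes = np.array([f"g{i:05d}" for i in range(n)])
    cursor = 0

    pathway_idx = {}
    names = PATHWAY_NAMES[: cfg.n_pathways] if cfg.n_pathways <= 7 else tuple(
        f"pathway_{i}" for i in range(cfg.n_pathways)
    )
    for name in names:
        pathway_idx[name] = np.arange(cursor, cursor + cfg.genes_per_pathway)
        cursor += cfg.genes_per_pathway
    cell_marker_idx = {}
    for ct in CELL_TYPES:
        cell_marker_idx[ct] = np.arange(cursor, cursor + 15)
        cursor += 15
    immune_program_idx = np.arange(cursor, cursor + n_prog)
    signature_idx = {}
    for sig in SIGNATURE_NAMES:
        signature_idx[sig] = np.arange(cursor, cursor + 25)
        cursor += 25
    tumor_marker_idx = np.arange(cursor, cursor + 100)
    cursor += 100
    stroma_marker_idx = np.arange(cursor, cursor + 100)
    cursor += 100
    baseline = rng.uniform(3.0, 9.0, size=n)
    return _GeneUniverse(
        genes, pathway_idx, cell_marker_idx, immune_program_idx,
        signature_idx, tumor_marker_idx, stroma_marker_idx, baseline,
    )


def _compartment_profiles(
    uni: _GeneUniverse, rng: np.random.Generator, separation: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-scale profiles: tumor basis, stroma, one per immune cell type.

    Marker genes of a compartment are exact structural zeros in the other
    compartments (a gene truly not expressed by a cell population has zero
    abundance, not merely low): this is what makes the convex mixture
    identifiable, and at zero measurement noise exactly invertible. At
    ``separation=0`` no contrast exists and mixtures are unidentifiable.
    """
    n = len(uni.baseline)
    hi_t = 2.0 * (separation / 2.0)
    zero = 0.0 if separation > 0 else 1.0

    tumor = np.exp2(uni.baseline + rng.normal(0, 0.3, size=n))
    tumor[uni.tumor_marker_idx] = np.exp2(uni.baseline[uni.tumor_marker_idx] + hi_t)
    for idx in (uni.stroma_marker_idx, uni.immune_program_idx):
        tumor[idx] *= zero
    for ct in CELL_TYPES:
        tumor[uni.cell_marker_idx[ct]] *= zero

    stroma = np.exp2(uni.baseline + rng.normal(0, 0.3, size=n))
    stroma[uni.stroma_marker_idx] = np.exp2(uni.baseline[uni.stroma_marker_idx] + hi_t)
    stroma[uni.tumor_marker_idx] *= zero
    stroma[uni.immune_program_idx] *= zero
    for ct in CELL_TYPES:
        stroma[uni.cell_marker_idx[ct]] *= zero

    # stromal signature program lives in the stroma compartment
    stroma[uni.signature_idx["tumor_stroma"]] = np.exp2(
        uni.baseline[uni.signature_idx["tumor_stroma"]] + 1.5
    )

    cells = np.empty((n, len(CELL_TYPES)))
    for k, ct in enumerate(CELL_TYPES):
        prof = np.exp2(uni.baseline + rng.normal(0, 0.3, size=n))
        prof[uni.tumor_marker_idx] *= zero
        prof[uni.stroma_marker_idx] *= zero
        for sig, expressing in SIGNATURE_CELLS.items():
            idx = uni.signature_idx[sig]
            if ct in expressing:
                prof[idx] = np.exp2(uni.baseline[idx] + 1.5)
            else:
                prof[idx] *= zero
        for ct2 in CELL_TYPES:
            idx = uni.cell_marker_idx[ct2]
            if ct2 == ct:
                prof[idx] = np.exp2(uni.baseline[idx] + 3.0)
            else:
                prof[idx] *= zero
        cells[:, k] = prof
    return tumor, stroma, cells


def simulate_reference_profiles(
    n_genes: int,
    n_normal_components: int = 5,
    seed: int | None = 0,
    separation: float = 2.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Tumor basis profile and tumor-free reference profiles (linear scale).

    The references emulate surgical samples without tumor cells: each
    component is a fixed stroma/immune-cell mixture. ``separation`` scales
    the marker-gene contrast between tumor and references; at zero
    separation the mixture is unidentifiable and a warning is emitted (rank
    check of the tumor profile against the reference span).
    """
    if n_genes < 100:
        raise ValueError("n_genes must be >= 100")
    if n_normal_components < 1:
        raise ValueError("n_normal_components must be >= 1")
    if n_normal_components > n_genes:
        raise ValueError("more normal components than genes")
    if separation == 0:
        logger.warning(
            "separation is 0: no marker contrast, mixture weights are "
            "unidentifiable"
        )
    rng = np.random.default_rng(seed)
    cfg = BulkCohortConfig(n_genes=max(n_genes, 2000),
                           n_normal_components=n_normal_components)
    uni = _build_universe(cfg, rng)
    tumor_lin, stroma_lin, cells_lin = _compartment_profiles(
        uni, rng, separation=separation
    )
    refs = _normal_components(stroma_lin, cells_lin, n_normal_components, rng)
    genes = uni.genes[:n_genes]
    tumor = pd.Series(tumor_lin[:n_genes], index=genes, name="tumor")
    normals = pd.DataFrame(
        refs[:n_genes],
        index=genes,
        columns=[f"ref_{i}" for i in range(n_normal_components)],
    )
    # identifiability: tumor profile must not lie in the reference span
    N_lin = normals.to_numpy()
    t_lin = tumor.to_numpy()
    proj, *_ = np.linalg.lstsq(N_lin, t_lin, rcond=None)
    rel_resid = np.linalg.norm(t_lin - N_lin @ proj) / np.linalg.norm(t_lin)
    if rel_resid < 1e-6:
        logger.warning(
            "tumor profile lies in the reference span; mixture weights are "
            "not identifiable"
        )
    return tumor, normals


def _normal_components(
    stroma_lin: np.ndarray,
    cells_lin: np.ndarray,
    n_components: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reference profiles (linear): stroma plus immune-rich anchor mixtures.

    Component 0 is pure stroma; the others blend 30% stroma with 70% of an
    anchor immune-cell mix (activated, suppressed, mixed, balanced in turn,
    then random mixes if more components are requested). Every sample's
    adjacent compartment is a convex combination of these, so it stays in
    the reference span.
    """
    comps = np.empty((len(stroma_lin), n_components))
    comps[:, 0] = stroma_lin
    anchors = list(_ANCHOR_MIXES.values())
    for j in range(1, n_components):
        if j - 1 < len(anchors):
            mix = np.asarray(anchors[j - 1])
        else:
            mix = rng.dirichlet(np.ones(cells_lin.shape[1]))
        immune_frac = 0.7
        comps[:, j] = (1 - immune_frac) * stroma_lin + immune_frac * (cells_lin @ mix)
    return comps


# ---------------------------------------------------------------------------
# bulk expression cohort


def _balanced_states(
    rng: np.random.Generator, n_patients: int, n_tp: int,
    pathway_names: list[str], probs,
) -> dict[str, np.ndarray]:
    """Stratified state assignment: per pathway and timepoint, exactly
    round(n * p) patients in down and up (equal counts when the down and up
    proportions are equal), the rest neutral, in a random order."""
    out = {}
    n_down = int(round(n_patients * probs[0]))
    n_up = int(round(n_patients * probs[2]))
    for pw in pathway_names:
        grid = np.empty((n_patients, n_tp), dtype=int)
        for t in range(n_tp):
            states = np.concatenate([
                np.zeros(n_down, dtype=int),
                np.full(n_patients - n_down - n_up, 1, dtype=int),
                np.full(n_up, 2, dtype=int),
            ])
            rng.shuffle(states)
            grid[:, t] = states
        out[pw] = grid
    return out


def _markov_states(
    rng: np.random.Generator, init_probs, transition, n_steps: int
) -> list[int]:
    states = [int(rng.choice(len(init_probs), p=np.asarray(init_probs)))]
    for _ in range(n_steps - 1):
        row = np.asarray(transition[states[-1]], dtype=float)
        states.append(int(rng.choice(len(row), p=row / row.sum())))
    return states


def simulate_bulk_cohort(
    config: BulkCohortConfig | None = None, seed: int | None = 0
) -> tuple[ExpressionMatrix, SampleAnnotationTable, CohortTruth]:
    """Generate a paired longitudinal bulk expression cohort with truth.

    Each bulk column equals (in linear space) ``p*t + (1-p)*s`` where the
    tumor compartment ``t`` carries that sample's true per-pathway log2
    shifts and the adjacent compartment ``s`` is a reference-component
    mixture whose immune content follows the sample's true immune class;
    Gaussian noise of ``noise_sd`` is then added on the log2 scale. Identical
    config and seed give bit-identical output.
    """
    cfg = config or BulkCohortConfig()
    rng = np.random.default_rng(seed)
    uni = _build_universe(cfg, rng)
    tumor_lin_base, stroma_lin, cells_lin = _compartment_profiles(uni, rng)
    refs_lin = _normal_components(
        stroma_lin, cells_lin, cfg.n_normal_components, rng
    )
    pathway_names = list(uni.pathway_idx)
    bio_lo, bio_hi = cfg.biological_sd_range
    gene_bio_sd = rng.uniform(bio_lo, bio_hi, size=cfg.n_genes)

    # immune class -> immune weight of the adjacent compartment. The gap
    # between adjacent classes is class_separation within-class sds of the
    # weight jitter, so the configured separation is realized directly.
    jitter_sd = 0.06
    gap = cfg.class_separation * jitter_sd
    base_w = 0.45
    class_immune_w = np.clip(
        base_w + (np.arange(3) - 1) * max(gap, 0.30), 0.02, 0.95
    )
    if cfg.class_separation == 0:
        msg = "class_separation is 0: immune classes are indistinguishable"
        logger.warning(msg)

    n_tp = len(cfg.timepoints)
    rows, ann_rows = [], []
    bulk_cols, tumor_cols, adj_cols, frac_rows = {}, {}, {}, {}
    warnings: list[str] = []
    if cfg.class_separation == 0:
        warnings.append("degenerate config: immune classes identical")

    if cfg.metab_assignment == "balanced":
        metab_by_patient = _balanced_states(
            rng, cfg.n_patients, n_tp, pathway_names, cfg.metab_state_probs
        )
    elif cfg.metab_assignment != "markov":
        raise ValueError(f"unknown metab_assignment {cfg.metab_assignment!r}")

    for pidx in range(cfg.n_patients):
        patient = f"P{pidx:03d}"
        subtype = "TNBC" if pidx % 3 == 0 else "luminal"
        immune_states = _markov_states(
            rng, np.full(3, 1 / 3), cfg.immune_transition, n_tp
        )
        if cfg.metab_assignment == "balanced":
            metab_states = {pw: metab_by_patient[pw][pidx] for pw in pathway_names}
        else:
            metab_states = {
                pw: _markov_states(rng, cfg.metab_state_probs,
                                   cfg.metab_transition, n_tp)
                for pw in pathway_names
            }
        for t_i, tp in enumerate(cfg.timepoints):
            sample = f"{patient}_{tp}"
            purity = rng.uniform(*cfg.purity_range)
            iclass = immune_states[t_i]

            t_lin = tumor_lin_base.copy()
            # per-sample biological variability of tumor cells; the adjacent
            # compartment stays an exact reference combination
            t_lin *= 2.0 ** rng.normal(0, gene_bio_sd)
            for pw in pathway_names:
                shift = (metab_states[pw][t_i] - 1) * cfg.pathway_shift
                t_lin[uni.pathway_idx[pw]] *= 2.0 ** shift

            w_imm = float(np.clip(
                class_immune_w[iclass] + rng.normal(0, jitter_sd), 0.01, 0.98
            ))
            n_ref = cfg.n_normal_components
            if n_ref > 1:
                w = np.empty(n_ref)
                w[0] = 1 - w_imm
                alpha = np.asarray(
                    _CLASS_COMPONENT_ALPHA[IMMUNE_CLASSES[iclass]][: n_ref - 1]
                )
                if cfg.class_separation == 0:
                    alpha = np.ones(n_ref - 1)
                w[1:] = w_imm * rng.dirichlet(alpha)
            else:
                w = np.array([1.0])
            s_lin = refs_lin @ w

            bulk_lin = purity * t_lin + (1 - purity) * s_lin
            noise = rng.normal(0, cfg.noise_sd, size=cfg.n_genes)
            # structural zeros only survive into the bulk in degenerate
            # configs (purity exactly 1); floor them to keep log2 finite
            bulk = np.log2(np.maximum(bulk_lin, 2.0 ** -30)) + noise

            bulk_cols[sample] = bulk
            tumor_cols[sample] = t_lin
            adj_cols[sample] = s_lin
            # true immune cell content of the bulk: components 1.. are 70%
            # immune-cell mixtures over the fixed dirichlet draws
            frac_rows[sample] = (1 - purity) * w_imm

            ann_rows.append({
                "sample_id": sample, "patient_id": patient, "timepoint": tp,
                "subtype": subtype,
                "cellularity": round(float(np.clip(purity + rng.normal(0, 0.05), 0, 1)), 3),
            })
            row = {
                "sample_id": sample, "patient_id": patient, "timepoint": tp,
                "purity": purity, "immune_class": IMMUNE_CLASSES[iclass],
                "immune_weight": w_imm,
            }
            for pw in pathway_names:
                row[f"state_{pw}"] = METAB_STATES[metab_states[pw][t_i]]
            rows.append(row)

    genes = uni.genes
    samples = list(bulk_cols)
    bulk_df = pd.DataFrame(bulk_cols, index=genes)
    truth_samples = pd.DataFrame(rows).set_index("sample_id")

    # change labels across the first two timepoints, per the pipeline's rules
    from .immune import classify_immune_change
    from .metabolic import classify_metabolic_change

    trans_rows = []
    if n_tp >= 2:
        tp0, tp1 = cfg.timepoints[0], cfg.timepoints[1]
        for pidx in range(cfg.n_patients):
            patient = f"P{pidx:03d}"
            pre = truth_samples.loc[f"{patient}_{tp0}"]
            later = truth_samples.loc[f"{patient}_{tp1}"]
            rec = {
                "patient_id": patient,
                "immune_change": classify_immune_change(
                    pre["immune_class"], later["immune_class"]
                ),
            }
            for pw in pathway_names:
                rec[f"metabolic_change_{pw}"] = classify_metabolic_change(
                    pre[f"state_{pw}"], later[f"state_{pw}"]
                )
            trans_rows.append(rec)

    pathways = GeneSetCollection(
        {pw: list(genes[idx]) for pw, idx in uni.pathway_idx.items()}
    )
    immune_sigs = GeneSetCollection(
        {sig: list(genes[idx]) for sig, idx in uni.signature_idx.items()}
    )
    # signature matrix restricted to informative genes (cell-type markers
    # plus the immune programs), the shape real cell-type matrices have
    sig_rows = np.concatenate(
        [uni.cell_marker_idx[ct] for ct in CELL_TYPES]
        + [uni.immune_program_idx]
    )
    sig_matrix = pd.DataFrame(cells_lin[sig_rows], index=genes[sig_rows],
                              columns=list(CELL_TYPES))
    truth = CohortTruth(
        samples=truth_samples,
        transitions=pd.DataFrame(trans_rows).set_index("patient_id")
        if trans_rows else None,
        tumor_linear=pd.DataFrame(tumor_cols, index=genes),
        adjacent_linear=pd.DataFrame(adj_cols, index=genes),
        fractions=pd.Series(frac_rows, name="immune_fraction").to_frame(),
        normal_refs=ExpressionMatrix(
            pd.DataFrame(refs_lin, index=genes,
                         columns=[f"ref_{i}" for i in range(cfg.n_normal_components)]),
            scale="linear",
        ),
        signature_matrix=sig_matrix,
        pathways=pathways,
        immune_signatures=immune_sigs,
        warnings=warnings,
    )
    expr = ExpressionMatrix(bulk_df, scale="log2")
    annot = SampleAnnotationTable(pd.DataFrame(ann_rows))
    return expr, annot, truth


# ---------------------------------------------------------------------------
# association-model cohorts


def simulate_interaction_cohort(
    beta1: float = -0.25,
    n_patients: int = 30,
    n_timepoints: int = 2,
    beta_subtype: float = 0.3,
    random_intercept_sd: float = 0.5,
    noise_sd: float = 0.6,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Repeated-measures cohort for the immune ~ metabolic interaction model.

    Immune response = b0 + beta1*M + b2*subtype + patient intercept + noise,
    with M drawn uniformly from {-1, 0, +1} per sample. Used for the
    calibration and parameter-recovery checks of the interaction fit.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_patients):
        gamma = rng.normal(0, random_intercept_sd)
        subtype = "TNBC" if j % 3 == 0 else "luminal"
        for _ in range(n_timepoints):
            m = int(rng.choice([-1, 0, 1]))
            i = (1.0 + beta1 * m + (beta_subtype if subtype == "TNBC" else 0.0)
                 + gamma + rng.normal(0, noise_sd))
            rows.append({
                "immune_state": i, "metabolic_state": m, "subtype": subtype,
                "patient_id": f"p{j:03d}",
            })
    return pd.DataFrame(rows)


def simulate_longitudinal_scores(
    beta_time: float = 0.5,
    n_patients: int = 60,
    timepoints: tuple[str, ...] = ("pre", "on"),
    beta_purity: float = 0.8,
    beta_subtype: float = 0.3,
    random_intercept_sd: float = 0.5,
    noise_sd: float = 0.6,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Longitudinal pathway-score cohort for the time-effect mixed model:
    score = b0 + b1*purity + b2*subtype + beta_time*1[t != pre] + patient
    intercept + noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_patients):
        gamma = rng.normal(0, random_intercept_sd)
        subtype = "TNBC" if j % 3 == 0 else "luminal"
        for t_i, tp in enumerate(timepoints):
            purity = rng.uniform(0.2, 0.8)
            y = (0.5 + beta_purity * purity
                 + (beta_subtype if subtype == "TNBC" else 0.0)
                 + beta_time * (t_i > 0) + gamma + rng.normal(0, noise_sd))
            rows.append({
                "score": y, "timepoint": tp, "purity": purity,
                "subtype": subtype, "patient_id": f"p{j:03d}",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mutation cohort


@dataclass
class MutationCohortConfig:
    """Study conditions for the longitudinal exome cohort.

    Defaults mirror a 20-patient triple-negative subset with paired
    baseline/post-treatment samples at ~130x depth: per patient one clonal
    population (CCF 1) plus subclones, with the co-evolution structure of the
    study (9 patients with positive immune-state change of whom 7 undergo
    clonal extinction, 11 negative of whom all persist).
    """

    n_patients: int = 20
    timepoints: tuple[str, str] = ("pre", "post")
    mean_depth: float = 130.0
    purity_range: tuple[float, float] = (0.2, 0.6)
    muts_per_clone: int = 15
    subclone_ccf_range: tuple[float, float] = (0.15, 0.6)
    n_subclones: int = 2
    cn_t_choices: tuple[int, ...] = (2,)
    # (immune_change, evolution_status, n_patients)
    design: tuple[tuple[str, str, int], ...] = (
        ("positive", "extinction", 7),
        ("positive", "persistence", 2),
        ("negative", "extinction", 0),
        ("negative", "persistence", 11),
    )


def expected_vaf(ccf: float, purity: float, cn_t: float, cn_n: float = 2.0) -> float:
    """Forward model: expected VAF of a mutation at the given cancer cell
    fraction, purity and locus copy numbers (multiplicity one)."""
    ev = ccf * purity / (purity * cn_t + cn_n * (1 - purity))
    if ev > 1:
        raise ValueError(
            f"inconsistent configuration: expected VAF {ev:.3f} > 1 "
            f"(ccf={ccf}, purity={purity}, cn_t={cn_t}, cn_n={cn_n})"
        )
    return ev


def simulate_mutation_cohort(
    config: MutationCohortConfig | None = None, seed: int | None = 0
) -> tuple[MutationTable, CohortTruth]:
    """Generate a paired-timepoint somatic mutation cohort with clonal truth.

    Each patient carries a clonal population plus subclones; alt read counts
    are Binomial(depth, expected VAF) draws from the CCF/purity/copy-number
    forward model. Post-treatment clone survival encodes the configured
    extinction/persistence status: extinct tumors retain under 10% of
    baseline mutations, persistent tumors retain the clonal population.
    """
    cfg = config or MutationCohortConfig()
    rng = np.random.default_rng(seed)
    n_design = sum(n for *_, n in cfg.design)
    if n_design != cfg.n_patients:
        raise ValueError("design patient counts must sum to n_patients")

    labels: list[tuple[str, str]] = []
    for change, status, n in cfg.design:
        labels += [(change, status)] * n
    rng.shuffle(labels)

    mut_rows, truth_rows, status_rows = [], [], []
    mut_counter = 0
    tp_pre, tp_post = cfg.timepoints
    for pidx, (change, status) in enumerate(labels):
        patient = f"M{pidx:03d}"
        purity = {tp: rng.uniform(*cfg.purity_range) for tp in cfg.timepoints}
        clones = [("clone_0", 1.0)]
        for s in range(cfg.n_subclones):
            clones.append((f"clone_{s + 1}", float(rng.uniform(*cfg.subclone_ccf_range))))

        # which baseline clones survive post-treatment
        if status == "persistence":
            surviving = {c for c, _ in clones}
        else:
            surviving = set()  # extinction: all baseline clones wiped out

        for clone, ccf in clones:
            for _ in range(cfg.muts_per_clone):
                mut_counter += 1
                chrom = f"chr{rng.integers(1, 23)}"
                pos = int(rng.integers(1, 2_000_000))
                ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
                cn_t = int(rng.choice(cfg.cn_t_choices))
                vclass = "SNV" if rng.random() > 0.2 else "indel"
                for tp in cfg.timepoints:
                    present = tp == tp_pre or clone in surviving
                    if not present:
                        continue
                    depth = max(int(rng.poisson(cfg.mean_depth)), 60)
                    ev = expected_vaf(ccf, purity[tp], cn_t)
                    alt_count = int(rng.binomial(depth, ev))
                    mut_rows.append({
                        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                        "variant_class": vclass,
                        "alt_count": alt_count, "depth": depth,
                        "vaf": alt_count / depth,
                        "caller_flags": "callerA,callerB",
                        "normal_vaf": 0.0, "normal_alt_count": 0,
                        "population_freq": 0.0,
                        "cn_t": cn_t, "cn_n": 2, "purity": purity[tp],
                        "sample_id": f"{patient}_{tp}",
                        "patient_id": patient, "timepoint": tp,
                    })
                    truth_rows.append({
                        "patient_id": patient, "timepoint": tp,
                        "key": f"{chrom}:{pos}:{ref}:{alt}",
                        "true_ccf": ccf, "clone_id": clone,
                        "true_clonal": ccf == 1.0,
                        "expected_vaf": ev,
                    })
        # extinct tumors acquire a small new resistant clone (< 10 mutations)
        if status == "extinction":
            ccf_new = 1.0
            for _ in range(int(rng.integers(3, 9))):
                mut_counter += 1
                chrom = f"chr{rng.integers(1, 23)}"
                pos = int(rng.integers(1, 2_000_000))
                ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
                depth = max(int(rng.poisson(cfg.mean_depth)), 60)
                ev = expected_vaf(ccf_new, purity[tp_post], 2)
                alt_count = int(rng.binomial(depth, ev))
                mut_rows.append({
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "variant_class": "SNV",
                    "alt_count": alt_count, "depth": depth,
                    "vaf": alt_count / depth,
                    "caller_flags": "callerA,callerB",
                    "normal_vaf": 0.0, "normal_alt_count": 0,
                    "population_freq": 0.0,
                    "cn_t": 2, "cn_n": 2, "purity": purity[tp_post],
                    "sample_id": f"{patient}_{tp_post}",
                    "patient_id": patient, "timepoint": tp_post,
                })
                truth_rows.append({
                    "patient_id": patient, "timepoint": tp_post,
                    "key": f"{chrom}:{pos}:{ref}:{alt}",
                    "true_ccf": ccf_new, "clone_id": "clone_new",
                    "true_clonal": True, "expected_vaf": ev,
                })
        status_rows.append({
            "patient_id": patient, "immune_change": change, "status": status,
        })

    table = MutationTable(pd.DataFrame(mut_rows))
    truth = CohortTruth(
        samples=pd.DataFrame(status_rows).set_index("patient_id"),
        mutations=pd.DataFrame(truth_rows),
        patient_status=pd.DataFrame(status_rows).set_index("patient_id"),
    )
    return table, truth
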