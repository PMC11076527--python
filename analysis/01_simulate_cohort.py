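"""Generate the synthetic study cohorts and write them to disk.

Produces the default bulk-expression cohort (60 patients, pre/on-treatment,
~2,000 genes with seven 40-gene metabolic pathway blocks and three immune
classes) and the paired-exome mutation cohort (20 patients with the
co-evolution design), together with the ground truth every later stage is
scored against.
"""

import argparse
import pathlib

import numpy as np

from imd.io import write_expression_matrix, write_gmt, write_table
from imd.simulate import simulate_bulk_cohort, simulate_mutation_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", type=pathlib.Path,
                    default=pathlib.Path("results/cohort"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    expr, annot, truth = simulate_bulk_cohort(seed=args.seed)
    write_expression_matrix(expr, args.outdir / "bulk_expression_log2.tsv")
    write_table(annot, args.outdir / "sample_annotations.tsv")
    write_expression_matrix(truth.normal_refs, args.outdir / "normal_references.tsv")
    truth.signature_matrix.to_csv(args.outdir / "cell_signature_matrix.tsv",
                                  sep="\t", index_label="gene_id")
    write_gmt(truth.pathways, args.outdir / "metabolic_pathways.gmt")
    write_gmt(truth.immune_signatures, args.outdir / "immune_signatures.gmt")
    truth.samples.to_csv(args.outdir / "truth_samples.tsv", sep="\t")
    truth.transitions.to_csv(args.outdir / "truth_transitions.tsv", sep="\t")

    muts, mtruth = simulate_mutation_cohort(seed=args.seed)
    write_table(muts, args.outdir / "mutations.tsv")
    mtruth.patient_status.to_csv(args.outdir / "truth_clonal_status.tsv", sep="\t")

    n_samples = expr.shape[1]
    print(f"bulk cohort: {expr.shape[0]} genes x {n_samples} samples "
          f"({truth.samples['immune_class'].value_counts().to_dict()})")
    print(f"mutation cohort: {len(muts)} records, "
          f"{mtruth.patient_status['status'].value_counts().to_dict()}")
    print(f"written to {args.outdir}/")


if __name__ == "__main__":
    main()
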