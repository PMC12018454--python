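#!/usr/bin/env python
"""Build maximum-parsimony trees, assign mutations, run colony QC.

Per patient: greedy perfect-phylogeny + NNI/SPR tree from the genotype
matrix; depth-sensitive hard assignment of every mutation to its best
branch; per-colony sensitivity from germline heterozygous sites; the three
colony filters (sensitivity < 60%, private-branch VAF significantly below
0.4, contamination of non-ancestral colonies); tree rebuilt on retained
colonies; branch lengths corrected for detection sensitivity; driver clade
annotated from the per-colony fusion status.

Writes tree.nwk, assignments.tsv, qc_report.tsv, clade.txt per patient.
"""

from pathlib import Path

import pandas as pd

from clonetime.genotypes import build_genotype_matrix
from clonetime.phylogeny import (
    annotate_driver_clades,
    assign_mutations,
    build_parsimony_tree,
    colony_sensitivities,
    correct_branch_lengths,
    qc_colonies,
)

COHORT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def process(pdir: Path) -> None:
    mtr = pd.read_csv(pdir / "mtr.tsv", sep="\t", index_col=0)
    dep = pd.read_csv(pdir / "dep.tsv", sep="\t", index_col=0)
    sites = pd.read_csv(pdir / "sites.tsv", sep="\t", index_col=0)
    colonies = pd.read_csv(pdir / "colonies.tsv", sep="\t")
    gmtr = pd.read_csv(pdir / "germline_mtr.tsv", sep="\t", index_col=0)
    gdep = pd.read_csv(pdir / "germline_dep.tsv", sep="\t", index_col=0)

    gm = build_genotype_matrix(mtr, dep, sites)
    tree = build_parsimony_tree(gm, seed=1, restarts=2)
    sens = colony_sensitivities(gmtr, gdep)
    assignment = assign_mutations(tree, mtr, dep)
    qc = qc_colonies(tree, mtr, dep, sens, assignment)
    qc.table.to_csv(pdir / "qc_report.tsv", sep="\t", index=False)
    keep = qc.keep

    if len(keep) < tree.n_tips:
        mtr, dep = mtr[keep], dep[keep]
        gm = build_genotype_matrix(mtr, dep, sites)
        tree = build_parsimony_tree(gm, seed=1, restarts=2)
        assignment = assign_mutations(tree, mtr, dep)

    counts = assignment.branch_counts(tree.n_nodes).astype(float)
    corrected = correct_branch_lengths(tree, counts, sens)
    tree.lengths = corrected
    tree.write_newick(pdir / "tree.nwk")
    assignment.branch.rename("branch").to_frame().to_csv(
        pdir / "assignments.tsv", sep="\t")

    status = colonies.set_index("colony_id")["bcr_abl1"]
    calls = {name: bool(status[name]) for name in tree.tip_names}
    if any(calls.values()):
        clade = annotate_driver_clades(tree, calls)
        # membership list, not a node id: node numbering is not stable
        # across newick round trips
        members = [n for n, pos in calls.items() if pos]
        (pdir / "clade.txt").write_text("\n".join(members) + "\n")
    else:
        clade = None
    print(f"{pdir.name}: {qc.n_retained}/{qc.n_total} colonies retained, "
          f"parsimony tree with {tree.n_nodes} nodes, "
          f"driver clade node {clade}")


def main() -> None:
    for pdir in sorted(d for d in COHORT.iterdir() if d.is_dir()):
        process(pdir)


if __name__ == "__main__":
    main()
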