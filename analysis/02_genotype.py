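#!/usr/bin/env python
"""Call per-colony genotypes from the simulated read counts.

Applies the depth-sensitive 20x binomial likelihood-ratio rule per site and
colony, honouring expected VAF by ploidy class and the LOH missing-override,
and writes genotypes.tsv (0/1/NA) plus the A/T/? FASTA dialect used by
external parsimony tools.
"""

from pathlib import Path

import pandas as pd

from clonetime.genotypes import (
    MISSING,
    build_genotype_matrix,
    export_genotype_fasta,
)

COHORT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    for pdir in sorted(d for d in COHORT.iterdir() if d.is_dir()):
        mtr = pd.read_csv(pdir / "mtr.tsv", sep="\t", index_col=0)
        dep = pd.read_csv(pdir / "dep.tsv", sep="\t", index_col=0)
        sites = pd.read_csv(pdir / "sites.tsv", sep="\t", index_col=0)
        gm = build_genotype_matrix(mtr, dep, sites)
        out = gm.states.replace(MISSING, pd.NA)
        out.to_csv(pdir / "genotypes.tsv", sep="\t", na_rep="NA")
        export_genotype_fasta(gm, pdir / "genotypes.fa")
        called = (gm.states.to_numpy() != MISSING).mean()
        print(f"{pdir.name}: {gm.states.shape[0]} sites x "
              f"{gm.states.shape[1]} colonies, {called:.1%} cells called")


if __name__ == "__main__":
    main()
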