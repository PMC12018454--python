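#!/usr/bin/env python
"""Attribute mutational signatures to branch groups of each phylogeny.

Per patient: branches are grouped into the driver expansion (CML), its
shared internal branches (early CML), the trunk (pre-CML lineage),
wild-type branches, and early-in-life mutations (global molecular-time
cutoff at 100 mutations).  Each group's 96-channel spectrum is refit
against the packaged SBS1/SBSblood/SBS18 reference spectra by multinomial
EM; the fitted proportions become priors for exact per-mutation membership
probabilities, which are averaged per branch; C>T-at-CpG proportions
(excluding the trunk) summarize division history.

Writes exposures.tsv, branch_attributions.tsv and ctcpg.tsv per patient.
"""

from pathlib import Path

import pandas as pd

from clonetime.phylogeny import assign_mutations
from clonetime.sigbranch import (
    GROUP_NAMES,
    attribute_branch,
    ctcpg_summary,
    fit_exposures,
    group_branches,
    group_mutation_counts,
    synthetic_spectra,
    write_signatures,
)
from clonetime.trees import Tree

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT = ROOT / "cohort"


def process(pdir: Path, spectra) -> None:
    tree = Tree.read_newick(pdir / "tree.nwk")
    sites = pd.read_csv(pdir / "sites.tsv", sep="\t", index_col=0)
    mtr = pd.read_csv(pdir / "mtr.tsv", sep="\t", index_col=0)
    dep = pd.read_csv(pdir / "dep.tsv", sep="\t", index_col=0)
    keep = pd.read_csv(pdir / "qc_report.tsv", sep="\t")
    keep = list(keep.loc[keep["verdict"] == "keep", "colony_id"])
    asn = assign_mutations(tree, mtr[keep], dep[keep])
    branches = asn.branch
    channels = sites.loc[branches.index, "context96"]

    clade_file = pdir / "clade.txt"
    clade = None
    if clade_file.exists():
        mut = set(clade_file.read_text().split())
        tips = [i for i, n in enumerate(tree.tip_names) if n in mut]
        clade = tree.mrca(tips)

    counts96 = group_mutation_counts(
        tree, branches.to_numpy(), channels.to_numpy(), clade)

    # per-group exposures with credibility intervals
    expo_rows = []
    p0_by_group = {}
    for grp in GROUP_NAMES:
        c = counts96.loc[grp].to_numpy()
        if c.sum() == 0:
            continue
        est = fit_exposures(c, spectra, ci=True, seed=11)
        p0_by_group[grp] = est.proportions.to_numpy()
        for sig in spectra.columns:
            expo_rows.append({
                "group": grp, "signature": sig,
                "proportion": est.proportions[sig],
                "lo95": est.ci95.loc[sig, "lo95"],
                "hi95": est.ci95.loc[sig, "hi95"],
                "n_mutations": est.n_mutations,
            })
    pd.DataFrame(expo_rows).to_csv(pdir / "exposures.tsv", sep="\t",
                                   index=False)

    # per-branch attribution using the branch's structural group prior
    groups = group_branches(tree, clade)
    def branch_group(b):
        for grp in ("pre_cml", "early_cml", "cml", "wt"):
            if b in groups[grp] and grp in p0_by_group:
                return grp
        return "wt"

    att_rows = []
    for b, sub in branches.groupby(branches):
        grp = branch_group(int(b))
        if grp not in p0_by_group:
            continue
        chans = channels.loc[sub.index]
        att = attribute_branch(chans, spectra, p0_by_group[grp])
        if att is None:
            continue
        row = {"branch": int(b), "group": grp, "n_mutations": len(chans),
               "small_branch": len(chans) < 50}
        row.update({f"p_{sig}": att[sig] for sig in spectra.columns})
        att_rows.append(row)
    pd.DataFrame(att_rows).to_csv(pdir / "branch_attributions.tsv", sep="\t",
                                  index=False)

    # C>T at CpG per compartment (trunk excluded on the mutant side)
    wt_mask = branches.isin(list(groups["wt"]))
    cml_mask = branches.isin(list(groups["cml"]))
    rows = []
    for label, mask, excl in [("wt", wt_mask, set()),
                              ("cml", cml_mask, {clade} if clade else set())]:
        if mask.sum() == 0:
            continue
        out = ctcpg_summary(channels[mask].to_numpy(),
                            branches[mask].to_numpy(), excl)
        rows.append({"compartment": label, **{k: v for k, v in out.items()
                                              if k != "ci95"},
                     "lo95": out["ci95"][0], "hi95": out["ci95"][1]})
    ct = pd.DataFrame(rows)
    ct.to_csv(pdir / "ctcpg.tsv", sep="\t", index=False)
    if len(ct) == 2:
        wt_p = ct.loc[ct.compartment == "wt", "proportion"].iloc[0]
        cml_p = ct.loc[ct.compartment == "cml", "proportion"].iloc[0]
        print(f"{pdir.name}: C>T@CpG wt {wt_p:.3f} vs driver clade "
              f"{cml_p:.3f} ({'higher' if cml_p > wt_p else 'lower'} in clade)")


def main() -> None:
    spectra = synthetic_spectra()
    write_signatures(spectra, ROOT / "signatures_synthetic.tsv")
    for pdir in sorted(d for d in COHORT.iterdir() if d.is_dir()):
        process(pdir, spectra)


if __name__ == "__main__":
    main()
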