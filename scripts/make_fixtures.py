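"""Regenerate the packaged synthetic haplogroup fixture trees.

Run from the repository root:

    python scripts/make_fixtures.py

The trees are drawn from the package's own simulator under the regime
models (Europe for R1b, Africa for E1b1a) with replicate seeds chosen by
structural criteria only; see starcoal.synthetic_data.generate_fixture_tree.
"""

from pathlib import Path

from starcoal.coalsim import SimConfig
from starcoal.inference import empirical_tmrca_years
from starcoal.synthetic_data import _FIXTURE_SPECS, generate_fixture_tree
from starcoal.treeio import write_newick

DATA = Path(__file__).resolve().parent.parent / "src" / "starcoal" / "data"

LABELS = {"R1b": "R1b_{}", "E1b1a": "E_{}"}
FILES = {"R1b": "r1b_synthetic.nwk", "E1b1a": "e1b1a_synthetic.nwk"}


def main():
    for hg in ("R1b", "E1b1a"):
        tree, seed = generate_fixture_tree(hg)
        for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
            leaf.taxon.label = LABELS[hg].format(i)
        n = len(tree.leaf_nodes())
        model = _FIXTURE_SPECS[hg][0]().model
        tmrca = empirical_tmrca_years(tree, SimConfig(n_tips=n))
        header = (
            f"# Synthetic stand-in for the observed {hg} haplogroup phylogeny "
            f"({n} Y chromosomes, branch lengths = SNP counts).\n"
            f"# Drawn from starcoal's coalescent simulator under the "
            f"{hg} regime model (start_n={model.start_n:g}, end_n={model.end_n:g}, "
            f"t_end={model.t_end_years:g} y, duration={model.duration_years:g} y; "
            f"seq_len=8.8e6 nt, mu=3e-8, 30 y/generation), replicate seed {seed}, "
            f"selected on tree structure only.\n"
            f"# Empirical TMRCA from mean root-to-tip SNP count: {tmrca:.0f} years.\n"
            f"# Regenerate with: python scripts/make_fixtures.py\n"
        )
        out = DATA / FILES[hg]
        out.write_text(header + write_newick(tree) + "\n")
        print(f"wrote {out} (seed {seed}, TMRCA {tmrca:.0f} y)")


if __name__ == "__main__":
    main()
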