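"""Alpha diversity, taxon-volume scaling, and occupancy-defined subgroups.

Reads the study written by 01_simulate_study.py, computes per-sample richness
and Shannon diversity, fits the taxon-volume relationship (log richness vs log
flow rate), and tabulates the universal colonizers, ubiquitous phylotypes and
Archaea with their occupancy and relative abundance.
"""

import argparse
from pathlib import Path

from distdecay.decay import taxon_volume_fit
from distdecay.io import load_count_table, load_study_design
from distdecay.metrics import alpha_diversity
from distdecay.subgroups import (
    compute_subgroups,
    occupancy_table,
    subgroup_relative_abundance,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    study = args.out / "study"

    table = load_count_table(study / "counts.tsv",
                             taxonomy_path=study / "taxonomy.tsv")
    design = load_study_design(study / "samples.tsv", study / "facilities.tsv")

    alpha = alpha_diversity(table)
    alpha.reset_index(names="sample_id").to_csv(
        args.out / "alpha_diversity.tsv", sep="\t", index=False)
    print(f"alpha diversity: mean richness {alpha['richness'].mean():.0f} "
          f"phylotypes/sample, mean Shannon {alpha['shannon'].mean():.2f} nats")

    tv = taxon_volume_fit(alpha, design)
    print(f"taxon-volume fit: z = {tv.slope:.4f} (rho = {tv.pearson_rho:.2f}, "
          f"P = {tv.p_value:.3g}, n = {tv.n_pairs} bioreactors)")
    if tv.p_value >= 0.001:
        print("  -> no significant taxon-volume scaling at the phylotype level")

    masks = compute_subgroups(table, design)
    occupancy_table(masks).reset_index(names="taxon").to_csv(
        args.out / "occupancy.tsv", sep="\t", index=False)
    for name, mask in (("universal colonizers", masks.universal),
                       ("ubiquitous phylotypes", masks.ubiquitous),
                       ("Archaea", masks.archaea)):
        ra = subgroup_relative_abundance(table, mask)
        print(f"{name}: {len(mask)} phylotypes, "
              f"mean {100 * ra.mean():.1f}% (SD {100 * ra.std():.1f}%) "
              f"of each sample")


if __name__ == "__main__":
    main()
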