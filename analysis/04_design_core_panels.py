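"""Select the 232-SNP core panel from the gated candidates (descending PIC
under per-chromosome quotas with 500 kb minimum spacing) and derive the
nested 192/96/48/24 subsets.

Reads results/dataset/, writes panel tables under results/panels/.
"""

import argparse
from pathlib import Path

import pandas as pd

from pearsnp import (
    filter_loci,
    locus_stats_frame,
    nested_subsets,
    read_vcf,
    select_core_panel,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", default="results/dataset")
    parser.add_argument("--outdir", default="results/panels")
    parser.add_argument("--target", type=int, default=232)
    parser.add_argument("--sizes", default="192,96,48,24")
    args = parser.parse_args()

    matrix = read_vcf(Path(args.data_dir) / "genotypes.vcf")
    filtered, _ = filter_loci(matrix)
    stats = locus_stats_frame(filtered)

    panel = select_core_panel(stats, target_size=args.target)
    sizes = tuple(int(s) for s in args.sizes.split(","))
    subsets = nested_subsets(panel, sizes)

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in [panel, *subsets]:
        p.to_frame().to_csv(out / f"panel_{p.size}.csv", index=False)
        frame = p.to_frame()
        rows.append(
            {
                "panel": p.size,
                "mean_pic": frame["pic"].mean(),
                "chromosomes": len(p.chromosomes_covered()),
                "spacing_relaxations": len(p.relaxations),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "panel_summary.csv", index=False)

    print(f"core panel: {panel.size} markers on {len(panel.chromosomes_covered())} chromosomes")
    counts = panel.per_chromosome_counts()
    print(f"per-chromosome counts: min {min(counts.values())}, max {max(counts.values())}")
    print(summary.round(3).to_string(index=False))
    for parent, child in zip([panel, *subsets], subsets):
        assert set(child.markers) < set(parent.markers)
    print("nesting verified: each subset is contained in its parent")


if __name__ == "__main__":
    main()
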