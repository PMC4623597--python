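"""Lift peaks across species and build the union atlas.

Reads the peak BEDs and chain file written by 01, maps each species'
peaks into the other assembly (whole-locus liftOver, then the
center-outward sub-window scan for loci that fail), and merges
reciprocally overlapping cross-mappings into single conserved loci.
Writes results/atlas.tsv and a genetic-conservation summary.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from common import DATA, RESULTS, ensure_dirs
from epicon.atlas import build_union_atlas
from epicon.chains import invert_chain, parse_chain_file
from epicon.io import read_bed, write_table
from epicon.orthology import ASSAY_PARAMS


def main() -> None:
    ensure_dirs()
    peaks_h = read_bed(DATA / "peaks_human.bed", extra_cols=("locus_id",))
    peaks_m = read_bed(DATA / "peaks_mouse.bed", extra_cols=("locus_id",))
    chains = parse_chain_file(DATA / "human_to_mouse.chain")
    atlas = build_union_atlas(
        peaks_h, peaks_m, chains, [invert_chain(c) for c in chains],
        ASSAY_PARAMS["h3k27ac"],
    )
    df = atlas.to_frame()
    write_table(df, RESULTS / "atlas.tsv")

    counts = df["genetic_status"].value_counts()
    frac = counts / len(df)
    print(f"union atlas: {len(df)} loci from {len(peaks_h)} human + "
          f"{len(peaks_m)} mouse peaks")
    for status in ("conserved", "human-only", "mouse-only"):
        print(f"  {status:12s} {counts.get(status, 0):5d}  "
              f"({100 * frac.get(status, 0.0):.1f}%)")
    paired = int((df["human_peak"] & df["mouse_peak"]).sum())
    print(f"  reciprocally paired peak loci: {paired}")
    print(f"wrote {RESULTS / 'atlas.tsv'}")


if __name__ == "__main__":
    main()
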