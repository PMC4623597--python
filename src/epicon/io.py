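"""Flat-file readers and writers for the pipeline's tabular formats.

Chain files live in :mod:`epicon.chains`, VCF in :mod:`epicon.sim.cohort`.
Everything here is TSV/BED built on pandas, with fixed float formatting
so reruns of the generators are byte-identical.
"""
from __future__ import annotations

from typing import Mapping

import pandas as pd

FLOAT_FORMAT = "%.6g"

BED3 = ["chrom", "start", "end"]


def read_bed(path, extra_cols: tuple = ()) -> pd.DataFrame:
    names = BED3 + list(extra_cols)
    return pd.read_csv(path, sep="\t", header=None, names=names, comment="#")


def write_bed(df: pd.DataFrame, path, cols: tuple = ()) -> None:
    df[BED3 + list(cols)].to_csv(path, sep="\t", header=False, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
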