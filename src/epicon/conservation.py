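"""Genetic vs epigenetic conservation over the union atlas.

A locus is *genetically* conserved when its sequence maps across species,
and *epigenetically* conserved when the activity mark is present in both.
Species-only loci carry zero signal for the missing species and by
definition cannot be epigenetically conserved, so cross-species signal
correlation is computed on genetically conserved loci only.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

LOG_PSEUDOCOUNT = 0.5


def log_rpm(x) -> np.ndarray:
    """log2(RPM + 0.5), the package-wide signal transform."""
    return np.log2(np.asarray(x, dtype=float) + LOG_PSEUDOCOUNT)


def epigenetic_correlation(
    records: pd.DataFrame,
    human_col: str = "rpm_human",
    mouse_col: str = "rpm_mouse",
) -> tuple[float, float]:
    """Pearson r of log-scaled signal across species, conserved loci only.

    ``records`` needs a ``genetic_status`` column plus the two RPM columns.
    Returns (r, p). Fewer than 3 conserved loci is an error.
    """
    conserved = records[records["genetic_status"] == "conserved"]
    if len(conserved) < 3:
        raise ValueError(
            f"need >= 3 genetically conserved loci, got {len(conserved)}"
        )
    r, p = stats.pearsonr(log_rpm(conserved[human_col]), log_rpm(conserved[mouse_col]))
    return float(r), float(p)


def conserved_fraction_by_stratum(
    records: pd.DataFrame, strata: pd.Series
) -> pd.DataFrame:
    """Fraction of genetically conserved loci per stratum.

    ``strata`` is a label per record (RPM bin, TSS-distance bin, intronic
    flag, ...). Empty strata are simply absent from the result rather than
    reported as zero.
    """
    if len(strata) != len(records):
        raise ValueError("strata must align with records")
    conserved = (records["genetic_status"] == "conserved").to_numpy()
    df = pd.DataFrame({"stratum": np.asarray(strata), "conserved": conserved})
    out = (
        df.groupby("stratum", observed=True)["conserved"]
        .agg(n="size", fraction="mean")
        .reset_index()
    )
    return out


def rpm_quantile_strata(rpm: pd.Series, n_bins: int = 5) -> pd.Series:
    """Quantile bins of signal strength (labels are bin ranks, 0 = weakest)."""
    return pd.qcut(rpm.rank(method="first"), n_bins, labels=False)


def tss_distance_strata(
    distance: pd.Series,
    intronic: pd.Series,
    edges: Sequence[int] = (1_000, 10_000, 100_000),
) -> pd.Series:
    """TSS-distance bins with intronic loci as their own stratum."""
    labels = []
    lo = 0
    for e in edges:
        labels.append(f"{lo}-{e}")
        lo = e
    labels.append(f">{edges[-1]}")
    binned = pd.cut(
        distance, bins=[-1, *edges, np.inf], labels=labels
    ).astype(object)
    binned[intronic.to_numpy(bool)] = "intronic"
    return pd.Series(binned, index=distance.index)
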