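"""Synthetic DHS polymorphism summaries with planted constraint.

Generates per-DHS maximum minor-allele frequencies directly at the
summary level used by the constraint permutation test: a fraction of
DHSs carry no common variant (max MAF below 0.05), the rest draw a
folded allele frequency. Planted constraint removes a configurable
fraction of the high-MAF mass from genetically conserved DHSs,
emulating purifying selection at conserved regulatory sequence.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd


def simulate_dhs_summaries(
    n_dhs: int,
    frac_conserved: float = 0.5,
    suppression: float = 0.0,
    frac_no_common: float = 0.45,
    beta_a: float = 0.8,
    beta_b: float = 2.0,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-DHS conserved flag and max MAF with optional planted constraint.

    ``suppression`` is the fraction of high-MAF (>= 0.05) draws at
    conserved DHSs that are knocked down below 0.05 (0.3 plants "30%
    fewer high-MAF variants"). With ``suppression = 0`` the conserved and
    non-conserved distributions are identical, the exchangeable null.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    conserved = rng.uniform(size=n_dhs) < frac_conserved
    maf = np.where(
        rng.uniform(size=n_dhs) < frac_no_common,
        rng.uniform(0, 0.05, size=n_dhs),
        np.minimum(rng.beta(beta_a, beta_b, size=n_dhs), 0.5),
    )
    if suppression > 0:
        knock = conserved & (maf >= 0.05) & (rng.uniform(size=n_dhs) < suppression)
        maf = np.where(knock, rng.uniform(0, 0.05, size=n_dhs), maf)
    return pd.DataFrame({"conserved": conserved, "max_maf": maf})
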