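"""Benjamini–Hochberg adjustment with optional family grouping."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvals, family_labels=None) -> np.ndarray:
    """Step-up BH adjusted p-values, computed within each family separately.

    ``family_labels`` groups tests into independent adjustment families (e.g.
    one family per outcome); ``None`` treats all p-values as one family.
    Original order is preserved.  p-values must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    adj = np.empty_like(p)
    if family_labels is None:
        labels = np.zeros(len(p))
    else:
        labels = np.asarray(family_labels)
        if labels.shape != p.shape:
            raise ValueError("family_labels must match pvals in length")
    for fam in np.unique(labels):
        idx = np.flatnonzero(labels == fam)
        _, p_adj, _, _ = multipletests(p[idx], method="fdr_bh")
        adj[idx] = p_adj
    return adj
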