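"""Relative abundance of each species bin in each sample.

The raw quantity "reads of species k seen in sample j" is
``a_kj * sum_{i in bin k} n_i``.  To compare it across samples and species it
is normalized RPKM-style by the bin's summed contig length ``L_k`` (a proxy
for genome length) and the sample's library size ``T_j``, and scaled by 1e9
to land in a convenient range:

    b_kj = 1e9 * a_kj * (sum_{i: z_i = k} n_i) / (L_k * T_j)

A species is called *significant* in a sample when its relative abundance is
at least 0.1% of the sample's total relative abundance (inclusive bound);
estimates below that share are dominated by estimation error.

GC-content bias correction is out of scope here; counts corrected externally
can be supplied in place of raw counts and flow through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import CountMatrix
from .mixture import MixtureParams

__all__ = ["AbundanceMatrix", "relative_abundance", "significant_species"]

SIGNIFICANCE_SHARE = 0.001  # fraction of a sample's total relative abundance


@dataclass
class AbundanceMatrix:
    """Relative abundances b (K, P) with bin lengths and significance flags."""

    b: np.ndarray
    bin_lengths: np.ndarray  # L_k, summed contig lengths per bin (bp)
    significant: np.ndarray  # (K, P) booleans

    @property
    def n_bins(self) -> int:
        return self.b.shape[0]

    @property
    def n_samples(self) -> int:
        return self.b.shape[1]


def _significance_flags(b: np.ndarray) -> np.ndarray:
    totals = b.sum(axis=0, keepdims=True)
    zero_cols = totals[0] == 0
    if zero_cols.any():
        warnings.warn(
            f"samples {np.flatnonzero(zero_cols).tolist()} have zero total "
            "relative abundance; no significant species there",
            UserWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        flags = b >= SIGNIFICANCE_SHARE * totals
    flags[:, zero_cols] = False
    # a species with b == 0 is never significant, even if the column is empty
    flags &= b > 0
    return flags


def relative_abundance(
    params: MixtureParams, labels: np.ndarray, cm: CountMatrix
) -> AbundanceMatrix:
    """Compute b_kj from fitted profiles, hard labels, and the count matrix.

    ``labels`` are 0-based bin indices aligned with ``params`` rows.  Every
    bin must contain at least one contig — an empty bin has ``L_k = 0`` and
    no meaningful abundance; drop such bins before calling.
    """
    labels = np.asarray(labels)
    K = params.n_components
    if labels.shape[0] != cm.n_contigs:
        raise ValueError("labels length must match number of contigs")
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError(f"labels must lie in [0, {K})")
    lengths = cm.lengths
    n_i = cm.row_totals
    L = np.zeros(K, dtype=np.int64)
    reads = np.zeros(K, dtype=np.int64)
    for k in range(K):
        mask = labels == k
        if not mask.any():
            raise ValueError(
                f"bin {k} is empty (L_k = 0); drop empty bins before "
                "computing abundances"
            )
        L[k] = lengths[mask].sum()
        reads[k] = n_i[mask].sum()
    T = cm.effective_library_sizes().astype(float)
    if (T <= 0).any():
        raise ValueError("library sizes must be positive")
    b = 1e9 * params.A * reads[:, None] / (L[:, None] * T[None, :])
    return AbundanceMatrix(b=b, bin_lengths=L, significant=_significance_flags(b))


def significant_species(abund: AbundanceMatrix) -> np.ndarray:
    """Number of significant species per sample (share >= 0.1%, inclusive)."""
    flags = _significance_flags(abund.b)
    abund.significant = flags
    return flags.sum(axis=0)
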