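"""Population differentiation (pool F_ST), allele-frequency PCA, and
phenotype rescaling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class DivergenceResult:
    per_snp_fst: np.ndarray       # NaN at skipped (monomorphic-in-both) sites
    mean_fst: float
    n_snps: int                   # SNPs entering the mean
    n_truncated: int              # negative per-SNP estimates truncated at 0


@dataclass
class PcaResult:
    coordinates: pd.DataFrame     # one row per sample, columns PC1..PCk
    explained_variance_ratio: np.ndarray
    n_dropped_snps: int


def fst_pairwise(
    freq_matrix: np.ndarray,
    pair: tuple[int, int],
    method: str = "hudson",
) -> DivergenceResult:
    """Per-SNP and mean F_ST between two samples of a SNP x sample frequency
    matrix.

    Hudson-style (default): F_ST = 1 - Hw/Hb with
    Hw = mean over the two pools of 2 p (1 - p) and
    Hb = p1 (1 - p2) + p2 (1 - p1); it has no within-pool sample-size terms.
    method='nei' uses total heterozygosity 2 p̄ (1 - p̄) in the denominator.

    Sites monomorphic in both samples (Hb or Ht = 0) are skipped; negative
    per-SNP estimates are truncated at 0 and counted.
    """
    f = np.asarray(freq_matrix, dtype=float)
    p1, p2 = f[:, pair[0]], f[:, pair[1]]
    ok = ~(np.isnan(p1) | np.isnan(p2))
    fst = np.full(f.shape[0], np.nan)
    hw = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
    if method == "hudson":
        denom = p1 * (1 - p2) + p2 * (1 - p1)
    elif method == "nei":
        pbar = (p1 + p2) / 2
        denom = 2 * pbar * (1 - pbar)
    else:
        raise ValueError("method must be 'hudson' or 'nei'")
    usable = ok & (denom > 0)
    fst[usable] = 1 - hw[usable] / denom[usable]
    n_trunc = int(np.nansum(fst < 0))
    fst = np.where(fst < 0, 0.0, fst)
    values = fst[usable]
    if values.size < 1:
        raise ValueError("no usable SNPs for F_ST")
    return DivergenceResult(fst, float(values.mean()), int(values.size), n_trunc)


def fst_matrix(freq_matrix: np.ndarray, labels: Sequence[str], method: str = "hudson") -> pd.DataFrame:
    """Symmetric matrix of mean pairwise F_ST across all samples."""
    k = len(labels)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = fst_pairwise(freq_matrix, (i, j), method).mean_fst
    return pd.DataFrame(out, index=list(labels), columns=list(labels))


def pca_frequencies(
    freq_matrix: np.ndarray,
    sample_labels: Sequence[str],
    n_components: int = 2,
) -> PcaResult:
    """PCA of samples on SNP frequencies.

    SNPs are centered but not scaled to unit variance (scaling would
    up-weight rare alleles); SNPs with any missing sample are dropped
    listwise.  Component signs are canonicalized so the largest-magnitude
    loading of each component is positive.
    """
    f = np.asarray(freq_matrix, dtype=float)
    n_samples = len(sample_labels)
    if f.shape[1] != n_samples:
        raise ValueError("freq_matrix columns must match sample_labels")
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > n_samples - 1:
        raise ValueError("more components than samples - 1")
    complete = ~np.isnan(f).any(axis=1)
    x = f[complete].T                       # samples x SNPs
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    for k in range(n_components):           # deterministic sign convention
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            coords[:, k] *= -1
    frame = pd.DataFrame(
        coords, index=list(sample_labels),
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return PcaResult(frame, pca.explained_variance_ratio_, int((~complete).sum()))


def minmax_normalize(values) -> np.ndarray:
    """Min-max rescaling to [0, 1]: (x - min) / (max - min)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.nanmax(x) == np.nanmin(x):
        raise ValueError("min-max normalization needs >= 2 distinct values")
    return (x - np.nanmin(x)) / (np.nanmax(x) - np.nanmin(x))
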