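"""Polarizing SNPs by their parental frequency trajectory.

Selection targets in an evolve-and-resequence experiment are unknown, so
every allele that rose in frequency in a parental replicate over the
adaptation phase is treated as potentially beneficial.  Polarization orients
each biallelic SNP so the tracked ("beneficial") allele is the rising one;
conditioning then keeps SNPs that are present but not almost fixed at the end
of adaptation, where the log-odds estimator is informative.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ORIGIN_IMMIGRANT = "immigrant-beneficial"
ORIGIN_RECIPIENT = "recipient-beneficial"
ORIGIN_SHARED_SAME = "shared-same-allele"
ORIGIN_SHARED_OPPOSITE = "shared-opposite"


def polarize_to_rising(
    freqs_gen0: np.ndarray,
    freqs_gen110: np.ndarray,
    allele_pairs: Sequence[tuple],
    chrom: Sequence[str],
    pos: Sequence[int],
    source_replicate: str = "",
) -> pd.DataFrame:
    """Orient each SNP so its beneficial allele rose (q110 - q0 >= 0).

    `freqs_gen0` / `freqs_gen110` give the frequency of the *first* allele of
    each pair in `allele_pairs`.  Exact ties are broken toward the
    lexicographically smaller base and flagged; SNPs with a missing frequency
    at either generation are excluded (and counted in the log).

    Returns a DataFrame with columns chrom, pos, beneficial_allele, q0, q110,
    source_replicate, tie.
    """
    f0 = np.asarray(freqs_gen0, dtype=float)
    f1 = np.asarray(freqs_gen110, dtype=float)
    if not (len(f0) == len(f1) == len(allele_pairs)):
        raise ValueError("inputs must share SNP indexing")
    rows = []
    n_missing = 0
    for i, (a1, a2) in enumerate(allele_pairs):
        if np.isnan(f0[i]) or np.isnan(f1[i]):
            n_missing += 1
            continue
        delta = f1[i] - f0[i]
        tie = delta == 0.0
        if tie:
            benef = min(a1, a2)
            q0, q110 = (f0[i], f1[i]) if benef == a1 else (1 - f0[i], 1 - f1[i])
        elif delta > 0:
            benef, q0, q110 = a1, f0[i], f1[i]
        else:
            benef, q0, q110 = a2, 1 - f0[i], 1 - f1[i]
        rows.append((chrom[i], int(pos[i]), benef, q0, q110, source_replicate, tie))
    if n_missing:
        log.info("polarize_to_rising[%s]: excluded %d SNPs with missing frequencies",
                 source_replicate, n_missing)
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "beneficial_allele", "q0", "q110",
                       "source_replicate", "tie"],
    )


def condition_snps(snps: pd.DataFrame, max_freq: float = 0.9):
    """Keep SNPs present at the end of adaptation (q110 > 0) with
    q110 strictly below max_freq.

    Returns (kept, counts) where counts records each exclusion reason.
    """
    absent = snps["q110"] <= 0.0
    too_high = snps["q110"] >= max_freq
    kept = snps.loc[~(absent | too_high)].copy()
    counts = {"absent": int(absent.sum()),
              "too_high": int((too_high & ~absent).sum()),
              "kept": len(kept)}
    return kept, counts


def assign_origin(snps_immigrant: pd.DataFrame, snps_recipient: pd.DataFrame) -> pd.DataFrame:
    """Classify SNPs by which parental population their beneficial allele
    comes from.

    A SNP polarized in both parents with the same beneficial allele is
    'shared-same-allele' (typically a high-starting-frequency allele selected
    in both replicates); opposite polarization is 'shared-opposite'; SNPs in
    only one set are labeled by their sole source.  The classes partition the
    union of the two inputs.
    """
    imm = snps_immigrant.set_index(["chrom", "pos"])
    rec = snps_recipient.set_index(["chrom", "pos"])
    merged = imm[["beneficial_allele"]].join(
        rec[["beneficial_allele"]], how="outer", lsuffix="_immigrant", rsuffix="_recipient")
    bi = merged["beneficial_allele_immigrant"]
    br = merged["beneficial_allele_recipient"]
    origin = np.where(
        bi.notna() & br.notna(),
        np.where(bi == br, ORIGIN_SHARED_SAME, ORIGIN_SHARED_OPPOSITE),
        np.where(bi.notna(), ORIGIN_IMMIGRANT, ORIGIN_RECIPIENT),
    )
    merged["origin_class"] = origin
    return merged.reset_index()
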