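"""Pause-site calling by TPM-stratified extended isolation forests.

For each expression bin, the codons of every ORF in the bin are stacked into
one 2-D point set (normalized occupancy ``u``, normalized position ``x``);
an EIF is trained on a subsample of size equal to the rounded mean ORF
length of the bin, every codon is scored, and codons whose score reaches the
bin's 0.95 score quantile are labeled pausing peaks.  The positional feature
lets the forest discount the coverage ramps near initiation/termination
instead of calling them pauses.

The conventional position-specific z-score baseline is provided for
comparison: the mean and SD for position i come from the distribution of
normalized counts at position i over all ORFs of the same bin, with each
ORF's last 10 codons excluded.

Site conventions: a called codon is the P-site codon of the paused ribosome;
the A site is the next codon (+1) and the E site the previous one (-1).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    SENSE_CODONS,
    NormalizedProfile,
    TpmPartition,
    codons_of,
)
from .eif import EifModel, anomaly_score, fit_eif

logger = logging.getLogger("ribopause")

SITE_OFFSETS = {"E": -1, "P": 0, "A": 1}

CALL_COLUMNS = ["orf_id", "codon_index", "score", "is_pause", "bin"]


def _bin_point_matrix(
    profiles: Sequence[NormalizedProfile],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (u, x) of all codons; return (X, orf row labels, codon indices)."""
    X = np.concatenate([np.column_stack([p.u, p.x]) for p in profiles])
    orf = np.concatenate([np.repeat(p.orf_id, p.L) for p in profiles])
    idx = np.concatenate([np.arange(p.L) for p in profiles])
    return X, orf, idx


def call_pauses(
    profiles: Iterable[NormalizedProfile],
    partition: TpmPartition,
    n_trees: int = 200,
    threshold_quantile: float = 0.95,
    seed: int = 0,
    psi_scale: float = 1.0,
    return_models: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[int, EifModel]]:
    """Score every codon and flag pausing peaks, one EIF per TPM bin.

    The per-tree subsample size is the rounded mean ORF length of the bin
    (optionally rescaled by ``psi_scale`` for robustness sweeps).  Returns a
    frame with columns ``orf_id, codon_index, score, is_pause, bin``.  Ties
    at the threshold are all flagged.  Bins with fewer than two ORFs are
    skipped with a warning.
    """
    by_orf = {p.orf_id: p for p in profiles}
    frames = []
    models: dict[int, EifModel] = {}
    seeds = np.random.SeedSequence(seed).spawn(partition.n_bins)
    for b in range(partition.n_bins):
        orfs = [o for o in partition.orfs_in_bin(b) if o in by_orf]
        if len(orfs) < 2:
            warnings.warn(f"bin {b}: fewer than 2 ORFs; skipped")
            continue
        bin_profiles = [by_orf[o] for o in orfs]
        X, orf_lab, codon_idx = _bin_point_matrix(bin_profiles)
        psi = int(round(float(np.mean([p.L for p in bin_profiles])) * psi_scale))
        psi = max(2, min(psi, X.shape[0]))
        bin_seed = int(seeds[b].generate_state(1, dtype=np.uint32)[0] % (2**31))
        model = fit_eif(X, n_trees=n_trees, psi=psi, seed=bin_seed)
        scores = anomaly_score(model, X)
        thr = np.quantile(scores, threshold_quantile, method="linear")
        frames.append(
            pd.DataFrame(
                {
                    "orf_id": orf_lab,
                    "codon_index": codon_idx,
                    "score": scores,
                    "is_pause": scores >= thr,
                    "bin": b,
                }
            )
        )
        models[b] = model
    if not frames:
        calls = pd.DataFrame(columns=CALL_COLUMNS)
    else:
        calls = pd.concat(frames, ignore_index=True)
    return (calls, models) if return_models else calls


def zscore_baseline(
    profiles: Iterable[NormalizedProfile],
    partition: TpmPartition,
    exclude_tail: int = 10,
    population_sd: bool = True,
) -> pd.DataFrame:
    """Position-specific z scores within each TPM bin.

    ``z[g, i] = (u[g, i] - mean_i) / sd_i`` where the moments at position i
    pool all bin ORFs long enough to reach i; positions in an ORF's last
    ``exclude_tail`` codons are excluded.  Positions with zero SD, or
    covered by fewer than two ORFs, yield NaN.
    """
    by_orf = {p.orf_id: p for p in profiles}
    ddof = 0 if population_sd else 1
    frames = []
    for b in range(partition.n_bins):
        orfs = [o for o in partition.orfs_in_bin(b) if o in by_orf]
        if not orfs:
            continue
        bin_profiles = [by_orf[o] for o in orfs]
        max_eval = max(p.L - exclude_tail for p in bin_profiles)
        if max_eval <= 0:
            continue
        # matrix of u values, NaN where a position is past an ORF's
        # evaluated span
        mat = np.full((len(bin_profiles), max_eval), np.nan)
        for r, p in enumerate(bin_profiles):
            span = p.L - exclude_tail
            if span > 0:
                mat[r, :span] = p.u[:span]
        n_cov = np.sum(~np.isnan(mat), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(mat, axis=0)
            sd = np.nanstd(mat, axis=0, ddof=ddof)
        sd[(sd == 0) | (n_cov < 2)] = np.nan
        z = (mat - mean) / sd
        for r, p in enumerate(bin_profiles):
            span = p.L - exclude_tail
            if span <= 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "orf_id": p.orf_id,
                        "codon_index": np.arange(span),
                        "z": z[r, :span],
                        "bin": b,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["orf_id", "codon_index", "z", "bin"])
    return pd.concat(frames, ignore_index=True)


def site_codon(
    sequences: Mapping[str, str], orf_id: str, codon_index: int, site: str = "A"
) -> str | None:
    """Codon at the ribosome site relative to a called P-site codon."""
    seq = sequences.get(orf_id)
    if seq is None:
        return None
    j = codon_index + SITE_OFFSETS[site]
    L = len(seq) // 3
    if not (0 <= j < L):
        return None
    return seq[3 * j : 3 * j + 3]


def pause_site_codon_fraction(
    calls: pd.DataFrame, sequences: Mapping[str, str], site: str = "A"
) -> dict[str, float]:
    """Fraction of pause sites carrying each codon at the given site.

    Pause sites whose site codon falls outside the ORF are dropped (logged);
    the returned fractions sum to 1 over the observed codons.
    """
    pauses = calls[calls["is_pause"]]
    counts: dict[str, int] = {}
    dropped = 0
    for orf, idx in zip(pauses["orf_id"], pauses["codon_index"]):
        c = site_codon(sequences, orf, int(idx), site)
        if c is None:
            dropped += 1
            continue
        counts[c] = counts.get(c, 0) + 1
    if dropped:
        logger.info("pause_site_codon_fraction: dropped %d edge sites", dropped)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {c: k / total for c, k in counts.items()}


def replicate_concordance(
    fracs1: Mapping[str, float], fracs2: Mapping[str, float]
) -> float:
    """Pearson correlation of per-codon pause fractions over the 61 sense codons."""
    v1 = np.array([fracs1.get(c, 0.0) for c in SENSE_CODONS])
    v2 = np.array([fracs2.get(c, 0.0) for c in SENSE_CODONS])
    if v1.std() == 0 or v2.std() == 0:
        logger.warning("replicate_concordance: zero variance; undefined")
        return float("nan")
    return float(np.corrcoef(v1, v2)[0, 1])


def overlap_fraction(calls1: pd.DataFrame, calls2: pd.DataFrame) -> float:
    """|pause sites shared| / |pause sites of calls1| on (orf, codon) pairs."""
    s1 = set(
        zip(
            calls1.loc[calls1["is_pause"], "orf_id"],
            calls1.loc[calls1["is_pause"], "codon_index"],
        )
    )
    if not s1:
        logger.warning("overlap_fraction: empty first call set; undefined")
        return float("nan")
    s2 = set(
        zip(
            calls2.loc[calls2["is_pause"], "orf_id"],
            calls2.loc[calls2["is_pause"], "codon_index"],
        )
    )
    return len(s1 & s2) / len(s1)


def write_calls_bed(calls: pd.DataFrame, path) -> None:
    """BED-like TSV: 0-based half-open codon coordinates."""
    out = pd.DataFrame(
        {
            "orf_id": calls["orf_id"],
            "codon_start": calls["codon_index"].astype(int),
            "codon_end": calls["codon_index"].astype(int) + 1,
            "score": calls["score"],
            "is_pause": calls["is_pause"].astype(int),
            "bin": calls["bin"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False)
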