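"""Codon-level annotation of aligned footprint 5' ends.

Ribosome footprints are assigned to codons in three steps: read lengths
without clear 3-nt periodicity are discarded; for each retained length a
P-site offset (distance from the footprint 5' end to the P-site codon) is
estimated from reads whose 5' ends sit upstream of the initiation codon; and
each read then increments the codon ``floor((five_prime_offset + offset)/3)``.

Input coordinates: ``five_prime_offset`` is the position of the read's 5'
end in nt relative to the A of the start AUG (0 = first nt of the CDS,
negative = upstream).
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import TranscriptProfile

logger = logging.getLogger("ribopause")

READ_COLUMNS = ["orf_id", "five_prime_offset", "length"]

#: Footprint sizes considered by default (nt).
DEFAULT_LENGTH_RANGE = (17, 34)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not set(READ_COLUMNS).issubset(df.columns):
        raise ValueError(f"read table must have columns {READ_COLUMNS}")
    return df[READ_COLUMNS].astype(
        {"orf_id": str, "five_prime_offset": int, "length": int}
    )


def periodicity_filter(
    reads: pd.DataFrame,
    min_frame_fraction: float = 0.6,
    min_reads_per_length: int = 100,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> set[int]:
    """Retain read lengths whose modal reading-frame fraction is high.

    A read length shows 3-nt periodicity when most of its 5' ends fall in
    one frame modulo 3; lengths whose modal-frame fraction is below
    ``min_frame_fraction`` (default 0.6) or with too few reads are dropped.
    """
    if reads.empty:
        raise ValueError("empty read table")
    lo, hi = length_range
    kept: set[int] = set()
    for length, grp in reads.groupby("length"):
        if not (lo <= length <= hi) or len(grp) < min_reads_per_length:
            continue
        frames = np.mod(grp["five_prime_offset"].to_numpy(), 3)
        frac = np.bincount(frames, minlength=3).max() / len(frames)
        if frac >= min_frame_fraction:
            kept.add(int(length))
    return kept


def estimate_psite_offset(reads: pd.DataFrame, length: int) -> int:
    """Modal distance from 5' end to the initiation codon for one length.

    Only reads whose 5' end lies upstream of the start AUG contribute (their
    P site sits on the start codon); ties in the mode break toward the
    smaller offset.
    """
    grp = reads[(reads["length"] == length) & (reads["five_prime_offset"] < 0)]
    if grp.empty:
        raise ValueError(f"no initiation-proximal reads for length {length}")
    counts = Counter((-grp["five_prime_offset"]).tolist())
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return int(best[0])


def estimate_psite_offsets(
    reads: pd.DataFrame, retained: Iterable[int]
) -> dict[int, int]:
    offsets = {}
    for length in sorted(retained):
        try:
            offsets[length] = estimate_psite_offset(reads, length)
        except ValueError:
            logger.warning("length %d: no initiation-proximal reads; dropped", length)
    return offsets


def annotate_codon_counts(
    reads: pd.DataFrame,
    offsets: Mapping[int, int],
    orf_lengths: Mapping[str, int] | None = None,
) -> list[TranscriptProfile]:
    """Sum P-site-shifted reads into per-codon counts.

    Reads of lengths without an offset, or whose P site falls outside the
    CDS (requires ``orf_lengths``, in codons), are dropped and logged.
    """
    if reads.empty:
        import warnings

        warnings.warn("empty read table: no profiles produced")
        return []
    usable = reads[reads["length"].isin(list(offsets))].copy()
    n_dropped_length = len(reads) - len(usable)
    if usable.empty:
        import warnings

        warnings.warn("no reads from retained lengths: empty profiles")
        return []
    off = usable["length"].map(offsets).to_numpy()
    codon = np.floor_divide(usable["five_prime_offset"].to_numpy() + off, 3)
    usable["codon_index"] = codon

    profiles: list[TranscriptProfile] = []
    n_dropped_bounds = 0
    for orf, grp in usable.groupby("orf_id", sort=True):
        ci = grp["codon_index"].to_numpy(dtype=int)
        if orf_lengths is not None and orf in orf_lengths:
            L = int(orf_lengths[orf])
        else:
            L = int(ci.max()) + 1 if len(ci) else 0
        ok = (ci >= 0) & (ci < L)
        n_dropped_bounds += int((~ok).sum())
        counts = np.bincount(ci[ok], minlength=L)[:L]
        profiles.append(TranscriptProfile(str(orf), counts.astype(float)))
    logger.info(
        "annotate_codon_counts: %d reads dropped (excluded lengths), "
        "%d dropped (outside CDS)", n_dropped_length, n_dropped_bounds,
    )
    return profiles
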