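"""Pause calling on disome-seq (collided-ribosome) footprints.

Disome footprints cover two stacked ribosomes and come in two read-length
populations separated by about three nucleotides; each population is
processed by its own model to keep ribosome assignment precise.  An
annotated disome pause codon is interpreted as the P site of the 3'
trailing ribosome; the leading (5'-paused) ribosome sits a fixed
displacement downstream (default 10 codons, about one monosome footprint).
Calls from the long-read population are shifted back one codon before
framing, matching the one-codon difference in footprint length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import NormalizedProfile, TpmPartition
from .metagene import MetageneTrace, pause_frequency_trace
from .pauses import call_pauses

logger = logging.getLogger("ribopause")

#: Default leading-ribosome displacement in codons (~30 nt footprint).
DEFAULT_DISPLACEMENT = 10


@dataclass
class DisomeGeometry:
    population: str               # "short" or "long"
    displacement: int = DEFAULT_DISPLACEMENT

    def __post_init__(self) -> None:
        if self.displacement <= 0:
            raise ValueError("displacement must be > 0")
        if self.population not in ("short", "long"):
            raise ValueError("population must be 'short' or 'long'")

    @property
    def trailing_shift(self) -> int:
        # long-population peaks sit one codon downstream of the equivalent
        # short-population peak
        return -1 if self.population == "long" else 0


def split_populations(
    reads: pd.DataFrame, smooth: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a bimodal read-length distribution at its antimode.

    The split point is the minimum of the length histogram between its two
    dominant local maxima, ties broken toward the lower length; ``smooth``
    applies an optional moving average of half-width ``smooth`` first
    (default none — disome length histograms are narrow and a width-3
    average can erase the inter-population gap).  Raises with a diagnostic
    when the histogram is unimodal.
    """
    lengths = reads["length"].to_numpy()
    lo, hi = int(lengths.min()), int(lengths.max())
    support = np.arange(lo, hi + 1)
    hist = np.array([(lengths == l).sum() for l in support], dtype=float)
    if smooth > 0 and len(hist) > 2 * smooth:
        kernel = np.ones(2 * smooth + 1) / (2 * smooth + 1)
        sm = np.convolve(hist, kernel, mode="same")
    else:
        sm = hist
    # local maxima of the smoothed histogram (plateaus collapse to their
    # first position)
    peaks = [
        i for i in range(len(sm))
        if (i == 0 or sm[i] > sm[i - 1]) and (i == len(sm) - 1 or sm[i] >= sm[i + 1])
        and sm[i] > 0
    ]
    if len(peaks) < 2:
        raise ValueError(
            f"unimodal read-length histogram over {lo}..{hi}: "
            "cannot separate disome populations"
        )
    p1, p2 = sorted(sorted(peaks, key=lambda i: -sm[i])[:2])
    between = np.arange(p1 + 1, p2)
    if len(between) == 0:
        split_idx = p1
    else:
        split_idx = int(between[np.argmin(sm[between])])
    split_len = int(support[split_idx])
    short = reads[reads["length"] <= split_len].reset_index(drop=True)
    long = reads[reads["length"] > split_len].reset_index(drop=True)
    logger.info(
        "split_populations: modes at %d and %d nt, split at %d",
        support[p1], support[p2], split_len,
    )
    return short, long


def call_disome_pauses(
    profiles,
    partition: TpmPartition,
    n_trees: int = 200,
    threshold_quantile: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Identical contract to the monosome caller, applied per population."""
    return call_pauses(
        profiles, partition,
        n_trees=n_trees, threshold_quantile=threshold_quantile, seed=seed,
    )


def site_frames(
    calls: pd.DataFrame,
    geometry: DisomeGeometry,
    orf_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """E/P/A codon indices of the trailing and leading ribosomes.

    Trailing P = called codon (shifted one codon for the long population);
    leading P = trailing P + displacement.  Frames extending beyond the ORF
    are dropped and logged.
    """
    pauses = calls[calls["is_pause"]]
    rows = []
    dropped = 0
    for orf, idx in zip(pauses["orf_id"], pauses["codon_index"].astype(int)):
        L = orf_lengths.get(orf)
        if L is None:
            dropped += 1
            continue
        tp = idx + geometry.trailing_shift
        lp = tp + geometry.displacement
        frame = {
            "orf_id": orf,
            "trailing_E": tp - 1, "trailing_P": tp, "trailing_A": tp + 1,
            "leading_E": lp - 1, "leading_P": lp, "leading_A": lp + 1,
        }
        idx_cols = [v for k, v in frame.items() if k != "orf_id"]
        if min(idx_cols) < 0 or max(idx_cols) >= L:
            dropped += 1
            continue
        rows.append(frame)
    if dropped:
        logger.info("site_frames: %d calls dropped at ORF bounds", dropped)
    return pd.DataFrame(
        rows,
        columns=["orf_id", "trailing_E", "trailing_P", "trailing_A",
                 "leading_E", "leading_P", "leading_A"],
    )


def frames_as_calls(frames: pd.DataFrame, which: str = "trailing") -> pd.DataFrame:
    """Re-express disome frames as a call frame anchored at the chosen P site.

    Useful for running the monosome enrichment machinery on trailing or
    leading ribosome positions.
    """
    col = f"{which}_P"
    return pd.DataFrame(
        {
            "orf_id": frames["orf_id"],
            "codon_index": frames[col].astype(int),
            "score": 1.0,
            "is_pause": True,
            "bin": 0,
        }
    )


def monosome_overlap_trace(
    disome_calls: pd.DataFrame,
    monosome_calls: pd.DataFrame,
    window: int,
    geometry: DisomeGeometry | None = None,
    lengths: Mapping[str, int] | None = None,
    background_draws: int = 1000,
    seed: int = 0,
) -> MetageneTrace:
    """Monosome pause frequency around disome trailing-P anchors."""
    shift = geometry.trailing_shift if geometry is not None else 0
    pauses = disome_calls[disome_calls["is_pause"]]
    anchors = [
        (o, int(i) + shift)
        for o, i in zip(pauses["orf_id"], pauses["codon_index"])
    ]
    return pause_frequency_trace(
        monosome_calls, anchors, window,
        background_draws=background_draws, seed=seed, lengths=lengths,
    )
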