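"""Anchor-centered metagene traces with seeded random backgrounds.

A metagene trace averages a per-codon signal across many loci aligned at a
common anchor (pause P sites, factor-binding positions, disome frames).
Offsets are in codons; negative offsets are codons already translated.  The
background is the same statistic over repeatedly drawn random anchor sets
of equal size, giving both a background mean and percentile bootstrap
confidence bounds at every offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GENETIC_CODE, codons_of

logger = logging.getLogger("ribopause")


@dataclass
class MetageneTrace:
    offsets: np.ndarray      # codon offsets, contiguous over the window
    value: np.ndarray        # mean signal at each offset over anchors
    background: np.ndarray   # mean over random anchor sets
    n: np.ndarray            # anchors contributing at each offset
    ci_lo: np.ndarray        # 2.5th percentile of random-set traces
    ci_hi: np.ndarray        # 97.5th percentile

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets.astype(int),
                "value": self.value,
                "background": self.background,
                "n": self.n.astype(int),
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


def _trace_over_anchors(
    anchors: Sequence[tuple[str, int]],
    window: int,
    lengths: Mapping[str, int],
    signal: Callable[[str, int], float],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean signal per offset; NaN signal values are skipped per position."""
    offsets = np.arange(-window, window + 1)
    total = np.zeros(len(offsets))
    n = np.zeros(len(offsets))
    for orf, idx in anchors:
        L = lengths.get(orf)
        if L is None:
            logger.info("metagene: anchor ORF %s unknown; skipped", orf)
            continue
        for k, d in enumerate(offsets):
            j = idx + d
            if 0 <= j < L:
                v = signal(orf, j)
                if not np.isnan(v):
                    total[k] += v
                    n[k] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return mean, n


def anchored_trace(
    anchors: Sequence[tuple[str, int]],
    window: int,
    lengths: Mapping[str, int],
    signal: Callable[[str, int], float],
    background_draws: int = 1000,
    seed: int = 0,
) -> MetageneTrace:
    """Generic metagene engine: observed trace plus random-anchor background.

    Random anchor sets are drawn uniformly over all codon positions of the
    supplied ORFs (same set size as the observed anchors); the background
    mean and 2.5/97.5 percentile bounds summarize their traces.
    """
    if not anchors:
        raise ValueError("empty anchor list")
    value, n = _trace_over_anchors(anchors, window, lengths, signal)

    orf_ids = list(lengths)
    sizes = np.array([lengths[o] for o in orf_ids])
    cum = np.cumsum(sizes)
    total_codons = int(cum[-1])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bg = np.full((background_draws, 2 * window + 1), np.nan)
    for b in range(background_draws):
        flat = rng.integers(0, total_codons, size=len(anchors))
        orf_idx = np.searchsorted(cum, flat, side="right")
        rand_anchors = [
            (orf_ids[oi], int(f - (cum[oi] - sizes[oi])))
            for oi, f in zip(orf_idx, flat)
        ]
        bg[b], _ = _trace_over_anchors(rand_anchors, window, lengths, signal)
    with np.errstate(invalid="ignore"):
        background = np.nanmean(bg, axis=0)
        ci_lo = np.nanpercentile(bg, 2.5, axis=0)
        ci_hi = np.nanpercentile(bg, 97.5, axis=0)
    return MetageneTrace(
        offsets=np.arange(-window, window + 1),
        value=value, background=background, n=n, ci_lo=ci_lo, ci_hi=ci_hi,
    )


def _pause_lookup(calls: pd.DataFrame) -> dict[str, set[int]]:
    d: dict[str, set[int]] = {}
    for orf, idx in zip(
        calls.loc[calls["is_pause"], "orf_id"],
        calls.loc[calls["is_pause"], "codon_index"].astype(int),
    ):
        d.setdefault(orf, set()).add(idx)
    return d


def _call_lengths(calls: pd.DataFrame) -> dict[str, int]:
    g = calls.groupby("orf_id")["codon_index"].max()
    return {o: int(m) + 1 for o, m in g.items()}


def pause_frequency_trace(
    calls: pd.DataFrame,
    anchors: Sequence[tuple[str, int]],
    window: int,
    background_draws: int = 1000,
    seed: int = 0,
    lengths: Mapping[str, int] | None = None,
) -> MetageneTrace:
    """Fraction of anchors with a pause call at each offset."""
    pauses = _pause_lookup(calls)
    if lengths is None:
        lengths = _call_lengths(calls)

    def signal(orf: str, j: int) -> float:
        return 1.0 if j in pauses.get(orf, ()) else 0.0

    return anchored_trace(anchors, window, lengths, signal,
                          background_draws=background_draws, seed=seed)


def property_trace(
    calls: pd.DataFrame,
    sequences: Mapping[str, str],
    scale: Mapping[str, float],
    window: int,
    background_draws: int = 1000,
    seed: int = 0,
) -> MetageneTrace:
    """Mean residue/codon property at offsets around pause P sites.

    ``scale`` may be keyed by codon (e.g., tAI w, optimality indicator) or
    by one-letter residue (e.g., Kyte-Doolittle hydrophobicity, side-chain
    volume); residue keys are applied through each ORF's translation.
    """
    lengths = {o: len(s) // 3 for o, s in sequences.items()}
    anchors = [
        (o, int(i))
        for o, i in zip(calls.loc[calls["is_pause"], "orf_id"],
                        calls.loc[calls["is_pause"], "codon_index"])
        if o in lengths
    ]
    by_codon = any(len(k) == 3 for k in scale)

    def signal(orf: str, j: int) -> float:
        codon = sequences[orf][3 * j : 3 * j + 3]
        key = codon if by_codon else GENETIC_CODE[codon]
        return float(scale.get(key, np.nan))

    return anchored_trace(anchors, window, lengths, signal,
                          background_draws=background_draws, seed=seed)


def secondary_structure_trace(
    calls: pd.DataFrame,
    ss_annotations: Mapping[str, str] | pd.DataFrame,
    window: int,
    classes: Sequence[str] = ("H", "E", "L"),
    background_draws: int = 1000,
    seed: int = 0,
) -> dict[str, MetageneTrace]:
    """Per-class secondary-structure content around pause sites.

    ``ss_annotations`` maps orf_id to a per-residue class string (or a
    frame with columns orf_id/residue_index/class).  ORFs without
    annotation are skipped and logged.  Classes default to helix (H),
    strand (E), loop (L); per-offset fractions over the three traces sum
    to 1 wherever annotations are total.
    """
    if isinstance(ss_annotations, pd.DataFrame):
        ann: dict[str, str] = {}
        for orf, grp in ss_annotations.groupby("orf_id"):
            g = grp.sort_values("residue_index")
            s = [""] * (int(g["residue_index"].max()) + 1)
            for i, c in zip(g["residue_index"].astype(int), g["class"]):
                s[i] = str(c)
            ann[str(orf)] = "".join(ch if ch else "?" for ch in s)
    else:
        ann = dict(ss_annotations)

    lengths = {o: len(s) for o, s in ann.items()}
    skipped = set(calls["orf_id"].unique()) - set(lengths)
    if skipped:
        logger.info("secondary_structure_trace: %d ORFs lack annotation", len(skipped))
    anchors = [
        (o, int(i))
        for o, i in zip(calls.loc[calls["is_pause"], "orf_id"],
                        calls.loc[calls["is_pause"], "codon_index"])
        if o in lengths
    ]
    traces = {}
    for cls in classes:
        def signal(orf: str, j: int, _cls=cls) -> float:
            ch = ann[orf][j]
            return np.nan if ch == "?" else float(ch == _cls)

        traces[cls] = anchored_trace(anchors, window, lengths, signal,
                                     background_draws=background_draws, seed=seed)
    return traces


def read_anchors_tsv(path) -> list[tuple[str, int]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["orf_id"].astype(str), df["codon_index"].astype(int)))
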