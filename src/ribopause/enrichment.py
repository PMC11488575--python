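"""Odds-ratio enrichment of sequence features at pausing-ribosome sites.

Every enrichment in the pipeline is a Fisher's exact test on a 2x2 table
contrasting pause sites against background codon positions:

====================  ==============  =================
                      feature present  feature absent
pause sites                 a                b
background positions        c                d
====================  ==============  =================

The background universe defaults to all codon positions of the analyzed
ORFs excluding the pause sites themselves.  Odds ratios are the sample OR
``(a d)/(b c)`` with a Haldane-Anscombe 0.5 added to every cell when any
cell is zero; p-values come from the exact two-sided hypergeometric test
and are Benjamini-Hochberg adjusted across the features of one analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GENETIC_CODE
from .pauses import SITE_OFFSETS

logger = logging.getLogger("ribopause")


@dataclass
class EnrichmentResult:
    feature: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float = float("nan")


def fisher_or(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Sample odds ratio and exact two-sided Fisher p for a 2x2 table.

    Adds 0.5 to every cell for the OR (only) when any cell is zero; the
    p-value always uses the uncorrected integer table.  Returns (nan, nan)
    when a row margin is empty.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if a + b == 0 or c + d == 0:
        logger.warning("fisher_or: empty margin; undefined")
        return float("nan"), float("nan")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orr), float(p)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(list(pvalues), dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return pd.DataFrame(
        [
            (r.feature, r.a, r.b, r.c, r.d, r.odds_ratio, r.p, r.q)
            for r in results
        ],
        columns=["feature", "a", "b", "c", "d", "odds_ratio", "p", "q"],
    )


def _site_positions(
    calls: pd.DataFrame, sequences: Mapping[str, str], offset: int
) -> tuple[list[str], list[str], int]:
    """Codons at (P-site + offset) for pause sites, and for background.

    Background = every codon position of the analyzed ORFs (those appearing
    in the call frame) that is not a pause site, shifted by the same offset
    and bounds-checked identically.
    """
    pause_keys = set(
        zip(calls.loc[calls["is_pause"], "orf_id"],
            calls.loc[calls["is_pause"], "codon_index"].astype(int))
    )
    fg: list[str] = []
    bg: list[str] = []
    dropped = 0
    for orf in calls["orf_id"].unique():
        seq = sequences.get(orf)
        if seq is None:
            continue
        L = len(seq) // 3
        for i in range(L):
            j = i + offset
            if not (0 <= j < L):
                if (orf, i) in pause_keys:
                    dropped += 1
                continue
            codon = seq[3 * j : 3 * j + 3]
            if (orf, i) in pause_keys:
                fg.append(codon)
            else:
                bg.append(codon)
    if dropped:
        logger.info("site enrichment: %d edge pause sites dropped", dropped)
    return fg, bg, dropped


def site_feature_enrichment(
    calls: pd.DataFrame,
    sequences: Mapping[str, str],
    site: str = "A",
    feature_map: Mapping[str, str] | Callable[[str], str] | None = None,
) -> pd.DataFrame:
    """Per-feature Fisher enrichment at a ribosome site (E, P or A).

    ``feature_map`` maps a codon to a feature label (default: the encoded
    amino acid); one test per feature observed anywhere, BH-corrected.
    """
    if feature_map is None:
        fmap: Callable[[str], str] = lambda c: GENETIC_CODE[c]
    elif callable(feature_map):
        fmap = feature_map
    else:
        fmap = lambda c: feature_map[c]  # noqa: E731

    fg, bg, _ = _site_positions(calls, sequences, SITE_OFFSETS[site])
    fg_feat = pd.Series([fmap(c) for c in fg])
    bg_feat = pd.Series([fmap(c) for c in bg])
    features = sorted(set(fg_feat) | set(bg_feat))
    results = []
    for f in features:
        a = int((fg_feat == f).sum())
        b = len(fg_feat) - a
        c = int((bg_feat == f).sum())
        d = len(bg_feat) - c
        orr, p = fisher_or([[a, b], [c, d]])
        results.append(EnrichmentResult(f, a, b, c, d, orr, p))
    return _results_frame(results)


def optimality_triplet_enrichment(
    calls: pd.DataFrame,
    sequences: Mapping[str, str],
    scale: Mapping[str, str],
    site_offsets: tuple[int, int, int] = (-1, 0, 1),
) -> pd.DataFrame:
    """Enrichment of the 8 O/N codon triplets over the E, P, A sites.

    ``scale`` maps each sense codon to 'O' (optimal) or 'N' (non-optimal).
    Pause sites lacking full E-P-A context are dropped and logged.
    ``site_offsets`` allows anchoring the triplet elsewhere (e.g., on the
    frames of a leading disome ribosome).
    """
    pause_keys = set(
        zip(calls.loc[calls["is_pause"], "orf_id"],
            calls.loc[calls["is_pause"], "codon_index"].astype(int))
    )
    fg: list[str] = []
    bg: list[str] = []
    dropped = 0
    for orf in calls["orf_id"].unique():
        seq = sequences.get(orf)
        if seq is None:
            continue
        L = len(seq) // 3
        for i in range(L):
            js = [i + off for off in site_offsets]
            if not all(0 <= j < L for j in js):
                if (orf, i) in pause_keys:
                    dropped += 1
                continue
            trip = "".join(scale[seq[3 * j : 3 * j + 3]] for j in js)
            (fg if (orf, i) in pause_keys else bg).append(trip)
    if dropped:
        logger.info("triplet enrichment: %d edge pause sites dropped", dropped)
    fg_s, bg_s = pd.Series(fg, dtype=str), pd.Series(bg, dtype=str)
    results = []
    for trip in ["".join(t) for t in itertools.product("ON", repeat=3)]:
        a = int((fg_s == trip).sum())
        c = int((bg_s == trip).sum())
        if a + c == 0:
            continue
        b = len(fg_s) - a
        d = len(bg_s) - c
        orr, p = fisher_or([[a, b], [c, d]])
        results.append(EnrichmentResult(trip, a, b, c, d, orr, p))
    return _results_frame(results)


def bicodon_pair_enrichment(
    calls: pd.DataFrame,
    sequences: Mapping[str, str],
    p_site_codon: str,
    a_site_codons: Sequence[str],
    swap_sites: bool = False,
) -> pd.DataFrame:
    """Enrichment of anchor-codon bicodon pairs at anchor pause sites.

    Among pause sites whose P-site codon equals ``p_site_codon``, tests
    whether each candidate A-site codon is over-represented relative to the
    frequency with which it follows the anchor translatome-wide (non-pause
    anchor occurrences).  ``swap_sites`` tests the inverse order: anchor in
    the A site, candidates in the P site (upstream codon).
    """
    anchor = p_site_codon.upper().replace("U", "T")
    cands = [c.upper().replace("U", "T") for c in a_site_codons]
    pause_keys = set(
        zip(calls.loc[calls["is_pause"], "orf_id"],
            calls.loc[calls["is_pause"], "codon_index"].astype(int))
    )
    partner_off = -1 if swap_sites else 1
    fg: list[str] = []
    bg: list[str] = []
    for orf in calls["orf_id"].unique():
        seq = sequences.get(orf)
        if seq is None:
            continue
        L = len(seq) // 3
        for i in range(L):
            if seq[3 * i : 3 * i + 3] != anchor:
                continue
            j = i + partner_off
            if not (0 <= j < L):
                continue
            partner = seq[3 * j : 3 * j + 3]
            (fg if (orf, i) in pause_keys else bg).append(partner)
    if not fg:
        logger.warning("bicodon enrichment: no anchor pause sites; undefined")
        return pd.DataFrame(
            columns=["feature", "a", "b", "c", "d", "odds_ratio", "p", "q"]
        )
    fg_s, bg_s = pd.Series(fg, dtype=str), pd.Series(bg, dtype=str)
    results = []
    for cand in cands:
        a = int((fg_s == cand).sum())
        c = int((bg_s == cand).sum())
        if a + c == 0:
            logger.info("bicodon %s-%s never observed; skipped", anchor, cand)
            continue
        b = len(fg_s) - a
        d = len(bg_s) - c
        orr, p = fisher_or([[a, b], [c, d]])
        label = f"{cand}-{anchor}" if swap_sites else f"{anchor}-{cand}"
        results.append(EnrichmentResult(label, a, b, c, d, orr, p))
    return _results_frame(results)


def read_scale_tsv(path) -> dict[str, str]:
    """Read an optimality scale (``codon  class`` and/or ``codon  score``).

    When an explicit O/N ``class`` column is present it is used directly;
    otherwise a continuous ``score`` column is binarized at its median
    (above-median codons are optimal).  Covers all 61 sense codons or
    raises.
    """
    from .core import SENSE_CODONS

    df = pd.read_csv(path, sep="\t")
    df["codon"] = df["codon"].str.upper().str.replace("U", "T")
    if "class" in df.columns and df["class"].notna().all():
        scale = dict(zip(df["codon"], df["class"].astype(str).str.upper()))
        if not set(scale.values()) <= {"O", "N"}:
            raise ValueError("scale classes must be O or N")
    elif "score" in df.columns:
        med = df["score"].median()
        scale = {
            c: ("O" if s > med else "N")
            for c, s in zip(df["codon"], df["score"])
        }
    else:
        raise ValueError("scale TSV needs a 'class' or 'score' column")
    missing = set(SENSE_CODONS) - set(scale)
    if missing:
        raise ValueError(f"scale missing {len(missing)} sense codons")
    return {c: scale[c] for c in SENSE_CODONS}


def theil_sen_outliers(
    x: Mapping[str, float] | np.ndarray,
    y: Mapping[str, float] | np.ndarray,
    k: float = 3.0,
) -> tuple[float, float, list[str]]:
    """Robust Theil-Sen fit of condition-2 vs condition-1 codon fractions.

    Slope is the median of pairwise slopes, intercept the median of
    ``y - slope * x``; outliers are the labels whose absolute residual
    exceeds ``k`` times the median absolute deviation of the residuals.
    """
    if isinstance(x, Mapping):
        labels = sorted(set(x) & set(y))
        xv = np.array([x[c] for c in labels], dtype=float)
        yv = np.array([y[c] for c in labels], dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        labels = [str(i) for i in range(len(xv))]
    if len(xv) < 3:
        raise ValueError("need at least 3 points")
    if np.all(xv == xv[0]):
        raise ValueError("all x identical: slope undefined")
    slope = float(stats.theilslopes(yv, xv).slope)
    intercept = float(np.median(yv - slope * xv))
    resid = yv - (slope * xv + intercept)
    mad = float(np.median(np.abs(resid - np.median(resid))))
    if mad == 0:
        outliers = [labels[i] for i in np.nonzero(np.abs(resid) > 0)[0]]
    else:
        outliers = [labels[i] for i in np.nonzero(np.abs(resid) > k * mad)[0]]
    return slope, intercept, outliers
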