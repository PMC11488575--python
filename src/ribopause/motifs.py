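"""Sequence-logo information content and tripeptide-motif clustering.

Logo matrices use the relative-entropy decomposition

    H(l, i) = q(l, i) * log2(q(l, i) / p_i)

where q are the observed column frequencies of an ungapped alignment and p
the background proteome residue frequencies.  A positive H(l, i) marks
enrichment of residue i at column l relative to background, a negative
value depletion; the column total H_l is the signed sum over residues (and
can be negative — it is a per-term signed decomposition, not the
non-negative Kullback-Leibler divergence of the whole column).

Enriched E-P-A tripeptide motifs at pause sites are grouped by hierarchical
clustering on the restricted Damerau-Levenshtein (optimal string alignment)
distance, which extends Levenshtein edits with adjacent transpositions but
never edits a substring twice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import AMINO_ACIDS, GENETIC_CODE
from .enrichment import EnrichmentResult, _results_frame, fisher_or


@dataclass
class LogoMatrix:
    H: pd.DataFrame  # rows = amino acids, columns = alignment positions
    q: pd.DataFrame  # observed column frequencies
    p: pd.Series     # background frequencies

    @property
    def column_totals(self) -> np.ndarray:
        return self.H.sum(axis=0).to_numpy()


def information_content(
    alignment: Sequence[str], p: Mapping[str, float]
) -> LogoMatrix:
    """Per-residue information contributions of an ungapped alignment."""
    if not alignment:
        raise ValueError("empty alignment")
    L = len(alignment[0])
    if any(len(s) != L for s in alignment):
        raise ValueError("alignment sequences must have equal length")
    pv = pd.Series({aa: float(p[aa]) for aa in AMINO_ACIDS})
    if (pv <= 0).any() or abs(pv.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must be positive and sum to 1")
    q = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=range(L))
    for l in range(L):
        counts = Counter(s[l] for s in alignment)
        for aa, k in counts.items():
            if aa not in q.index:
                raise ValueError(f"unknown residue {aa!r}")
            q.loc[aa, l] = k / len(alignment)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = q.to_numpy() / pv.to_numpy()[:, None]
        H = np.where(q.to_numpy() > 0, q.to_numpy() * np.log2(ratio), 0.0)
    return LogoMatrix(
        H=pd.DataFrame(H, index=q.index, columns=q.columns), q=q, p=pv
    )


def proteome_frequencies(sequences: Mapping[str, str]) -> dict[str, float]:
    """Residue background frequencies of the analyzed proteome."""
    counts = Counter()
    for seq in sequences.values():
        for i in range(0, len(seq), 3):
            counts[GENETIC_CODE[seq[i : i + 3]]] += 1
    # floor at one pseudocount so log ratios stay finite for residues absent
    # from degenerate (synthetic) proteomes, then renormalize
    floored = {aa: max(counts.get(aa, 0), 1) for aa in AMINO_ACIDS}
    total = sum(floored.values())
    return {aa: v / total for aa, v in floored.items()}


def pause_tripeptides(
    calls: pd.DataFrame, sequences: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    """E-P-A residue triplets at pause sites and at background positions."""
    pause_keys = set(
        zip(calls.loc[calls["is_pause"], "orf_id"],
            calls.loc[calls["is_pause"], "codon_index"].astype(int))
    )
    fg, bg = [], []
    for orf in calls["orf_id"].unique():
        seq = sequences.get(orf)
        if seq is None:
            continue
        res = "".join(GENETIC_CODE[seq[i : i + 3]] for i in range(0, len(seq), 3))
        for i in range(1, len(res) - 1):
            trip = res[i - 1 : i + 2]
            (fg if (orf, i) in pause_keys else bg).append(trip)
    return fg, bg


def enriched_tripeptides(
    calls: pd.DataFrame,
    sequences: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tripeptides over-represented at pause P sites (BH q < alpha, OR > 1)."""
    fg, bg = pause_tripeptides(calls, sequences)
    fg_counts = Counter(fg)
    bg_counts = Counter(bg)
    results = []
    for trip in sorted(fg_counts):
        a = fg_counts[trip]
        b = len(fg) - a
        c = bg_counts.get(trip, 0)
        d = len(bg) - c
        orr, p = fisher_or([[a, b], [c, d]])
        results.append(EnrichmentResult(trip, a, b, c, d, orr, p))
    df = _results_frame(results)
    return df[(df["q"] < alpha) & (df["odds_ratio"] > 1)].reset_index(drop=True)


def osa_distance(s1: str, s2: str) -> int:
    """Optimal string alignment (restricted Damerau-Levenshtein) distance.

    Substitutions, insertions, deletions, and adjacent transpositions, with
    no substring edited more than once.
    """
    n, m = len(s1), len(s2)
    d = np.zeros((n + 1, m + 1), dtype=int)
    d[:, 0] = np.arange(n + 1)
    d[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if s1[i - 1] == s2[j - 1] else 1
            best = min(d[i - 1, j] + 1, d[i, j - 1] + 1, d[i - 1, j - 1] + cost)
            if (
                i > 1 and j > 1
                and s1[i - 1] == s2[j - 2] and s1[i - 2] == s2[j - 1]
            ):
                best = min(best, d[i - 2, j - 2] + 1)
            d[i, j] = best
    return int(d[n, m])


@dataclass
class TripeptideClusters:
    members: dict[int, list[str]]       # cluster id -> tripeptides
    assignment: dict[str, int]          # tripeptide -> cluster id
    linkage: np.ndarray

    def consensus_logo(
        self, cluster_id: int, p: Mapping[str, float]
    ) -> LogoMatrix:
        return information_content(self.members[cluster_id], p)


def cluster_tripeptides(
    tripeptides: Sequence[str],
    n_clusters: int = 5,
    height: float | None = None,
    linkage_method: str = "average",
) -> TripeptideClusters:
    """Agglomerative clustering of tripeptides on pairwise OSA distance.

    Cut either into ``n_clusters`` groups (default 5) or at a dendrogram
    ``height``.  Input order does not affect the result: tripeptides are
    sorted before the distance matrix is built.
    """
    trips = sorted(set(tripeptides))
    if not trips:
        raise ValueError("no tripeptides to cluster")
    if len(trips) == 1:
        return TripeptideClusters({1: trips}, {trips[0]: 1}, np.empty((0, 4)))
    n = len(trips)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = osa_distance(trips[i], trips[j])
    Z = hierarchy.linkage(squareform(dm, checks=False), method=linkage_method)
    if height is not None:
        labels = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        labels = hierarchy.fcluster(Z, t=min(n_clusters, n), criterion="maxclust")
    members: dict[int, list[str]] = {}
    for t, lab in zip(trips, labels):
        members.setdefault(int(lab), []).append(t)
    return TripeptideClusters(
        members=members,
        assignment={t: int(lab) for t, lab in zip(trips, labels)},
        linkage=Z,
    )
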