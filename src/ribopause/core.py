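"""Core domain types for codon-level ribosome-profiling profiles.

A translatome is represented as a collection of :class:`TranscriptProfile`
objects, one per ORF, holding raw footprint counts per codon (the stop codon
is excluded from the length ``L`` and from every downstream site analysis).
Downstream pause detection works on two derived quantities:

* ``u`` — counts normalized by the ORF's mean count, so every ORF has mean
  occupancy 1 regardless of expression level;
* ``x`` — normalized codon position in ``(0, 1]``, which lets the anomaly
  model account for the elevated coverage ramps near initiation and
  termination shared by ORFs of very different lengths.

ORFs are stratified into five expression bins by TPM quantiles so that
outliers are judged against similarly expressed genes only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ribopause")

#: Number of expression strata used throughout the pipeline.
DEFAULT_N_BINS = 5

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: The 61 sense codons (DNA alphabet), in lexicographic order.
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

AMINO_ACIDS = tuple(sorted(set(GENETIC_CODE.values())))


def _as_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass
class TranscriptProfile:
    """Raw per-codon footprint counts for one ORF (stop codon excluded)."""

    orf_id: str
    counts: np.ndarray
    codons: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError(f"{self.orf_id}: counts must be 1-D")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError(f"{self.orf_id}: counts must be finite and >= 0")
        if self.codons is not None:
            self.codons = [_as_dna(c) for c in self.codons]
            if len(self.codons) != len(self.counts):
                raise ValueError(f"{self.orf_id}: codons/counts length mismatch")
            bad = [c for c in self.codons if c in STOP_CODONS]
            if bad:
                raise ValueError(f"{self.orf_id}: internal stop codon {bad[0]}")

    @property
    def L(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class NormalizedProfile:
    """Mean-normalized occupancy ``u`` and normalized position ``x``."""

    orf_id: str
    u: np.ndarray
    x: np.ndarray

    @property
    def L(self) -> int:
        return len(self.u)


@dataclass
class TpmPartition:
    """Quantile assignment of ORFs into expression bins.

    ``bin_edges`` holds the ``n_bins + 1`` TPM quantile boundaries
    (0/20/40/60/80/100th percentiles for the default five bins); ties at an
    interior edge are assigned to the lower bin.
    """

    tpm: dict[str, float]
    bin_edges: np.ndarray
    bin_of: dict[str, int]
    n_bins: int = DEFAULT_N_BINS

    def orfs_in_bin(self, b: int) -> list[str]:
        return [o for o, k in self.bin_of.items() if k == b]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "orf_id": list(self.tpm),
                "tpm": [self.tpm[o] for o in self.tpm],
                "bin": [self.bin_of[o] for o in self.tpm],
            }
        )


def compute_tpm(profiles: Iterable[TranscriptProfile]) -> dict[str, float]:
    """Transcripts-per-million from codon-level counts.

    The per-ORF rate is total counts per kilobase of coding sequence
    (``L * 3 / 1000`` nt); rates are rescaled to sum to 1e6.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles supplied")
    ids = [p.orf_id for p in profiles]
    rate = np.array([p.total / (p.L * 3.0 / 1000.0) for p in profiles])
    total = rate.sum()
    if total <= 0:
        raise ValueError("no reads: all profiles have zero counts")
    tpm = rate / total * 1e6
    return dict(zip(ids, tpm.tolist()))


def normalize_profile(p: TranscriptProfile) -> NormalizedProfile:
    """Divide counts by the ORF mean; attach normalized positions (i+1)/L."""
    if p.L == 0:
        raise ValueError(f"{p.orf_id}: empty profile")
    mean = p.counts.mean()
    if mean <= 0:
        raise ValueError(f"{p.orf_id}: zero total counts")
    u = p.counts / mean
    x = np.arange(1, p.L + 1, dtype=float) / p.L
    return NormalizedProfile(p.orf_id, u, x)


def normalize_profiles(
    profiles: Iterable[TranscriptProfile], min_mean_coverage: float = 0.0
) -> list[NormalizedProfile]:
    """Normalize all ORFs with nonzero coverage.

    ORFs with zero total counts, or mean coverage below
    ``min_mean_coverage``, are dropped (the default keeps every nonzero ORF).
    """
    out = []
    dropped = 0
    for p in profiles:
        if p.L == 0 or p.total <= 0 or p.counts.mean() < min_mean_coverage:
            dropped += 1
            continue
        out.append(normalize_profile(p))
    if dropped:
        logger.info("normalize_profiles: dropped %d low/zero-coverage ORFs", dropped)
    return out


def partition_by_tpm(
    tpm_map: Mapping[str, float], n_bins: int = DEFAULT_N_BINS
) -> TpmPartition:
    """Assign each ORF to the quantile bin containing its TPM.

    Quantiles use linear interpolation; an ORF whose TPM falls exactly on an
    interior edge goes to the lower bin, which makes the partition
    deterministic and independent of input order.
    """
    ids = list(tpm_map)
    if len(ids) < n_bins:
        raise ValueError(f"need at least {n_bins} ORFs, got {len(ids)}")
    values = np.array([tpm_map[o] for o in ids], dtype=float)
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.quantile(values, qs, method="linear")
    if edges[0] == edges[-1]:
        warnings.warn("degenerate TPM distribution: all ORFs in one bin")
        bins = np.zeros(len(ids), dtype=int)
    else:
        # side="left": v == inner edge -> index of that edge -> lower bin
        bins = np.searchsorted(edges[1:-1], values, side="left")
    return TpmPartition(
        tpm=dict(zip(ids, values.tolist())),
        bin_edges=edges,
        bin_of=dict(zip(ids, bins.tolist())),
        n_bins=n_bins,
    )


# ---------------------------------------------------------------------------
# IO: counts TSV, CDS FASTA, partition TSV
# ---------------------------------------------------------------------------

def read_counts_tsv(path) -> list[TranscriptProfile]:
    """Read a ``orf_id  codon_index  count`` table (0-based codon_index)."""
    df = pd.read_csv(path, sep="\t")
    required = {"orf_id", "codon_index", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts TSV must have columns {sorted(required)}")
    profiles = []
    for orf, grp in df.groupby("orf_id", sort=True):
        L = int(grp["codon_index"].max()) + 1
        counts = np.zeros(L)
        counts[grp["codon_index"].to_numpy(dtype=int)] = grp["count"].to_numpy()
        profiles.append(TranscriptProfile(str(orf), counts))
    return profiles


def write_counts_tsv(profiles: Iterable[TranscriptProfile], path) -> None:
    rows = []
    for p in profiles:
        for i, c in enumerate(p.counts):
            rows.append((p.orf_id, i, int(c)))
    pd.DataFrame(rows, columns=["orf_id", "codon_index", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_cds_fasta(path) -> dict[str, str]:
    """Read coding sequences; a trailing stop codon is trimmed.

    Returns a map orf_id -> sense-codon DNA string (length divisible by 3).
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = _as_dna(str(rec.seq))
        if len(s) % 3 != 0:
            raise ValueError(f"{rec.id}: CDS length {len(s)} not divisible by 3")
        if s[-3:] in STOP_CODONS:
            s = s[:-3]
        seqs[rec.id] = s
    return seqs


def write_cds_fasta(sequences: Mapping[str, str], path, add_stop: bool = True) -> None:
    with open(path, "w") as fh:
        for orf, seq in sequences.items():
            s = _as_dna(seq) + ("TAA" if add_stop else "")
            fh.write(f">{orf}\n")
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")


def codons_of(sequence: str) -> list[str]:
    s = _as_dna(sequence)
    return [s[i : i + 3] for i in range(0, len(s), 3)]


def residues_of(sequence: str) -> str:
    return "".join(GENETIC_CODE[c] for c in codons_of(sequence))
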