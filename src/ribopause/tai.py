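"""tRNA adaptation index from tRNA gene copy numbers.

The tAI scores each codon by the decoding capacity of the cellular tRNA
pool.  The absolute adaptiveness of codon c is

    W_c = sum over recognizing anticodons a of (1 - s_pair(a, c)) * tGCN_a

where tGCN is the genomic copy number of the tRNA carrying anticodon a and
``s`` is the selective penalty of the codon:anticodon pairing at the third
(wobble) position — 0 for Watson-Crick pairs, larger for wobble pairs.
Relative adaptiveness is w = W / max(W); codons with W = 0 receive the
geometric mean of the nonzero w values.  The tAI of a gene is the geometric
mean of w over its (sense) codons.

Standard eukaryotic wobble recognition: a codon ending in U is read by the
Watson-Crick anticodon (A34, usually edited to inosine; s = 0) and by
G34 (G:U wobble); NNC by G34 (WC) and inosine (I:C); NNA by U34 (WC) and
inosine (I:A, heavily penalized); NNG by C34 (WC) and U34 (U:G wobble).
The default ``s`` constraints are the classical optimized values shipped as
an editable TSV so organism-specific sets can be substituted.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .core import SENSE_CODONS, codons_of

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Pairing classes at the wobble position (anticodon base 34 : codon base 3).
#: Default selective constraints follow the classical optimized set.
DEFAULT_S = {
    "WC": 0.0,        # Watson-Crick third-position pair
    "G:U": 0.41,      # G34 reading NNU
    "I:C": 0.28,      # inosine (from A34) reading NNC
    "I:A": 0.9999,    # inosine reading NNA
    "U:G": 0.68,      # U34 reading NNG
}

# codon third base -> list of (anticodon wobble base, pairing class)
_WOBBLE_RULES = {
    "T": [("A", "WC"), ("G", "G:U")],
    "C": [("G", "WC"), ("A", "I:C")],
    "A": [("T", "WC"), ("A", "I:A")],
    "G": [("C", "WC"), ("T", "U:G")],
}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def recognizing_anticodons(codon: str) -> list[tuple[str, str]]:
    """(anticodon, pairing class) pairs able to read a codon.

    Anticodons are written 5'->3' in DNA alphabet; the wobble base (position
    34) pairs with the codon's third base.
    """
    codon = codon.upper().replace("U", "T")
    stem = _revcomp(codon[:2])  # anticodon positions 35-36, reversed
    return [
        (wobble + stem, cls) for wobble, cls in _WOBBLE_RULES[codon[2]]
    ]


def load_s_table(path=None) -> dict[str, float]:
    """Wobble-constraint table (``pairing_type  s``); default = shipped TSV."""
    if path is None:
        ref = resources.files("ribopause.data").joinpath("wobble_s.tsv")
        with resources.as_file(ref) as fp:
            df = pd.read_csv(fp, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["pairing_type"], df["s"].astype(float)))


def read_tgcn_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(a).upper().replace("U", "T"): float(c)
        for a, c in zip(df["anticodon"], df["copies"])
    }


def codon_w(
    tgcn: Mapping[str, float],
    s_params: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Relative adaptiveness w per sense codon from tRNA gene copy numbers."""
    s = dict(DEFAULT_S)
    if s_params:
        s.update(s_params)
    if any(v < 0 for v in tgcn.values()):
        raise ValueError("tGCN values must be non-negative")
    if not any(v > 0 for v in tgcn.values()):
        raise ValueError("all-zero tGCN")
    gcn = {k.upper().replace("U", "T"): float(v) for k, v in tgcn.items()}
    W = {}
    for codon in SENSE_CODONS:
        W[codon] = sum(
            (1.0 - s[cls]) * gcn.get(anti, 0.0)
            for anti, cls in recognizing_anticodons(codon)
        )
    w_max = max(W.values())
    if w_max <= 0:
        raise ValueError("no codon is decodable with the supplied tGCN")
    w = {c: W[c] / w_max for c in W}
    nonzero = [v for v in w.values() if v > 0]
    gm = float(np.exp(np.mean(np.log(nonzero))))
    return {c: (v if v > 0 else gm) for c, v in w.items()}


def gene_tai(sequence: str, w: Mapping[str, float]) -> float:
    """Geometric mean of codon w over a coding sequence (stop excluded)."""
    cods = codons_of(sequence)
    if not cods:
        raise ValueError("empty sequence")
    vals = []
    for c in cods:
        if c not in w:
            raise ValueError(f"unknown codon {c}")
        vals.append(w[c])
    return float(np.exp(np.mean(np.log(vals))))


def write_w_tsv(w: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"codon": list(w), "w": [w[c] for c in w]}
    ).to_csv(path, sep="\t", index=False)
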