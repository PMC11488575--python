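"""Anchored metagene traces: coordinates, backgrounds, linearity."""

import numpy as np
import pandas as pd
import pytest

from ribopause import (
    pause_frequency_trace,
    property_trace,
    secondary_structure_trace,
)
from ribopause.metagene import anchored_trace


def _calls(pause_pairs, universe):
    rows = []
    flagged = set(pause_pairs)
    for orf, L in universe.items():
        for i in range(L):
            rows.append((orf, i, 1.0, (orf, i) in flagged, 0))
    return pd.DataFrame(
        rows, columns=["orf_id", "codon_index", "score", "is_pause", "bin"]
    )


class TestPauseFrequencyTrace:
    def test_anchors_on_pauses_give_one_at_zero(self):
        universe = {f"g{i}": 50 for i in range(5)}
        pairs = [(f"g{i}", 20) for i in range(5)]
        trace = pause_frequency_trace(
            _calls(pairs, universe), pairs, window=5,
            background_draws=20, seed=1,
        )
        mid = np.where(trace.offsets == 0)[0][0]
        assert trace.value[mid] == 1.0

    def test_shifted_anchors_peak_at_minus_two(self):
        universe = {f"g{i}": 50 for i in range(5)}
        pauses = [(f"g{i}", 20) for i in range(5)]
        anchors = [(o, c + 2) for o, c in pauses]
        trace = pause_frequency_trace(
            _calls(pauses, universe), anchors, window=5,
            background_draws=20, seed=1,
        )
        assert trace.value[np.where(trace.offsets == -2)[0][0]] == 1.0
        assert trace.value[np.where(trace.offsets == 0)[0][0]] == 0.0

    def test_random_anchors_match_flag_rate(self, rng):
        universe = {f"g{i}": 200 for i in range(30)}
        pairs = [
            (f"g{i}", int(j))
            for i in range(30)
            for j in rng.choice(200, size=10, replace=False)
        ]
        anchors = [
            (f"g{rng.integers(30)}", int(rng.integers(20, 180)))
            for _ in range(400)
        ]
        trace = pause_frequency_trace(
            _calls(pairs, universe), anchors, window=3,
            background_draws=50, seed=2,
        )
        assert np.allclose(trace.value, 0.05, atol=0.03)
        assert np.allclose(trace.background, 0.05, atol=0.02)

    def test_empty_anchors_rejected(self):
        with pytest.raises(ValueError):
            pause_frequency_trace(_calls([], {"g": 10}), [], window=2)


class TestPropertyTrace:
    def test_constant_scale_flat_trace(self):
        seqs = {f"g{i}": "GCT" * 40 for i in range(4)}
        calls = _calls([(f"g{i}", 20) for i in range(4)], {o: 40 for o in seqs})
        scale = {aa: 2.5 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        trace = property_trace(calls, seqs, scale, window=4,
                               background_draws=10, seed=0)
        np.testing.assert_allclose(trace.value, 2.5)
        np.testing.assert_allclose(trace.background, 2.5)

    def test_codon_keyed_scale_dips_at_anchor(self, rng):
        # low-value codon planted exactly at pause P sites
        seqs, pairs = {}, []
        for g in range(6):
            codons = ["GAA"] * 60
            codons[30] = "CCG"
            seqs[f"g{g}"] = "".join(codons)
            pairs.append((f"g{g}", 30))
        scale = {"GAA": 1.0, "CCG": 0.1}
        trace = property_trace(_calls(pairs, {o: 60 for o in seqs}), seqs,
                               scale, window=3, background_draws=10, seed=1)
        mid = np.where(trace.offsets == 0)[0][0]
        assert trace.value[mid] == pytest.approx(0.1)
        assert trace.value[mid - 1] == pytest.approx(1.0)

    def test_linearity_against_brute_force(self, rng):
        """Trace equals the mean of per-anchor property values."""
        seqs = {
            f"g{i}": "".join(
                rng.choice(["GCT", "AAA", "CCG", "TGG"], size=50)
            )
            for i in range(8)
        }
        from ribopause.core import GENETIC_CODE

        kd = {"A": 1.8, "K": -3.9, "P": -1.6, "W": -0.9}
        anchors = [(f"g{i}", int(rng.integers(10, 40))) for i in range(8)]
        calls = _calls(anchors, {o: 50 for o in seqs})
        trace = property_trace(calls, seqs, kd, window=2,
                               background_draws=5, seed=3)
        for k, d in enumerate(trace.offsets):
            vals = []
            for orf, i in anchors:
                j = i + d
                codon = seqs[orf][3 * j : 3 * j + 3]
                vals.append(kd[GENETIC_CODE[codon]])
            assert trace.value[k] == pytest.approx(np.mean(vals))


class TestSecondaryStructure:
    def test_all_loop_annotation(self):
        ann = {f"g{i}": "L" * 40 for i in range(3)}
        calls = _calls([(f"g{i}", 20) for i in range(3)], {o: 40 for o in ann})
        traces = secondary_structure_trace(calls, ann, window=3,
                                           background_draws=5, seed=0)
        np.testing.assert_allclose(traces["L"].value, 1.0)
        np.testing.assert_allclose(traces["H"].value, 0.0)
        np.testing.assert_allclose(traces["E"].value, 0.0)

    def test_loop_at_anchor_helix_distal(self):
        ann = {}
        pairs = []
        for g in range(4):
            # helix everywhere except a loop patch around residue 20
            s = ["H"] * 40
            for j in range(18, 23):
                s[j] = "L"
            ann[f"g{g}"] = "".join(s)
            pairs.append((f"g{g}", 20))
        calls = _calls(pairs, {o: 40 for o in ann})
        traces = secondary_structure_trace(calls, ann, window=6,
                                           background_draws=5, seed=0)
        mid = np.where(traces["L"].offsets == 0)[0][0]
        assert traces["L"].value[mid] == 1.0
        assert traces["H"].value[mid] == 0.0
        assert traces["H"].value[0] == 1.0  # offset -6: helix

    def test_class_fractions_sum_to_one(self, rng):
        ann = {
            f"g{i}": "".join(rng.choice(list("HEL"), size=60))
            for i in range(5)
        }
        pairs = [(f"g{i}", int(rng.integers(10, 50))) for i in range(5)]
        calls = _calls(pairs, {o: 60 for o in ann})
        traces = secondary_structure_trace(calls, ann, window=4,
                                           background_draws=5, seed=1)
        total = traces["H"].value + traces["E"].value + traces["L"].value
        np.testing.assert_allclose(total, 1.0)


class TestBackgroundBehaviour:
    def test_background_reproducible_given_seed(self):
        universe = {f"g{i}": 80 for i in range(6)}
        pairs = [(f"g{i}", 40) for i in range(6)]
        kwargs = dict(window=3, background_draws=30, seed=7)
        t1 = pause_frequency_trace(_calls(pairs, universe), pairs, **kwargs)
        t2 = pause_frequency_trace(_calls(pairs, universe), pairs, **kwargs)
        np.testing.assert_array_equal(t1.background, t2.background)
        np.testing.assert_array_equal(t1.ci_lo, t2.ci_lo)

    def test_ci_width_shrinks_with_more_anchors(self, rng):
        universe = {f"g{i}": 300 for i in range(20)}
        pairs = [
            (f"g{i}", int(j))
            for i in range(20)
            for j in rng.choice(300, size=15, replace=False)
        ]
        calls = _calls(pairs, universe)

        def width(n_anchors):
            anchors = [
                (f"g{rng.integers(20)}", int(rng.integers(280)))
                for _ in range(n_anchors)
            ]
            t = pause_frequency_trace(calls, anchors, window=1,
                                      background_draws=60, seed=4)
            return float(np.mean(t.ci_hi - t.ci_lo))

        w_small, w_big = width(25), width(400)
        # sqrt(16)-fold anchor increase shrinks the CI by roughly 4x
        assert w_big < w_small / 2.5
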