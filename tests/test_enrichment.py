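"""Fisher enrichment, BH correction and Theil-Sen outlier detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribopause import (
    SimConfig,
    bh_adjust,
    bicodon_pair_enrichment,
    call_pauses,
    compute_tpm,
    fisher_or,
    generate_translatome,
    normalize_profiles,
    optimality_triplet_enrichment,
    partition_by_tpm,
    site_feature_enrichment,
    theil_sen_outliers,
)


class TestFisherOr:
    def test_sample_odds_ratio(self):
        orr, p = fisher_or([[20, 80], [100, 900]])
        assert orr == pytest.approx(2.25)
        assert 0 < p < 1

    def test_no_association(self):
        orr, p = fisher_or([[5, 5], [5, 5]])
        assert orr == 1.0
        assert p == pytest.approx(1.0)

    def test_zero_cells_haldane_anscombe(self):
        orr, p = fisher_or([[3, 0], [0, 3]])
        assert orr == pytest.approx(49.0)
        assert 0 < p <= 1

    def test_empty_margin_undefined(self):
        orr, p = fisher_or([[0, 0], [5, 5]])
        assert np.isnan(orr) and np.isnan(p)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_or([[1, -1], [1, 1]])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_applied_step_up(self):
        # ranks 1..4: p*4/k = [.04, .04, .04, .04] after step-up monotone min
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_mixed_vector_hand_computed(self):
        q = bh_adjust([0.005, 0.04, 0.8])
        np.testing.assert_allclose(q, [0.015, 0.06, 0.8])

    @given(
        ps=st.lists(
            st.floats(1e-9, 1.0, allow_nan=False), min_size=1, max_size=30
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_q_dominates_p_and_preserves_order(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        # q is monotone in p: sorting by p sorts q
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _calls_at(pairs, universe):
    """A call frame flagging the given (orf, codon) pairs over a universe."""
    rows = []
    flagged = set(pairs)
    for orf, L in universe.items():
        for i in range(L):
            rows.append((orf, i, 1.0, (orf, i) in flagged, 0))
    return pd.DataFrame(
        rows, columns=["orf_id", "codon_index", "score", "is_pause", "bin"]
    )


class TestSiteEnrichment:
    def test_planted_proline_recovered(self, rng):
        """Pauses placed only where the A site holds a Pro codon."""
        seqs = {}
        pairs = []
        for g in range(40):
            orf = f"g{g}"
            codons = rng.choice(
                ["AAA", "GAA", "CTG", "TTC", "GGT", "CCA"], size=60
            ).tolist()
            seqs[orf] = "".join(codons)
            for i in range(1, 59):
                if codons[i + 1] == "CCA" and rng.random() < 0.6:
                    pairs.append((orf, i))
        calls = _calls_at(pairs, {o: 60 for o in seqs})
        df = site_feature_enrichment(calls, seqs, site="A")
        pro = df[df["feature"] == "P"].iloc[0]
        assert pro["odds_ratio"] > 1 and pro["q"] < 0.05
        others = df[df["feature"] != "P"]
        assert (others["odds_ratio"] <= 1).all()

    def test_null_calls_show_no_enrichment(self, rng):
        seqs = {}
        pairs = []
        for g in range(40):
            orf = f"g{g}"
            codons = rng.choice(["AAA", "GAA", "CTG", "TTC"], size=80).tolist()
            seqs[orf] = "".join(codons)
            for i in rng.choice(np.arange(1, 79), size=4, replace=False):
                pairs.append((orf, int(i)))
        df = site_feature_enrichment(
            _calls_at(pairs, {o: 80 for o in seqs}), seqs, site="A"
        )
        assert (df["q"] >= 0.05).all()


class TestTripletEnrichment:
    def test_planted_nonoptimal_a_site(self, rng):
        scale = {}
        opt = ["GAA", "AAA", "CTG"]
        non = ["CCA", "CGG", "ATA"]
        for c in opt:
            scale[c] = "O"
        for c in non:
            scale[c] = "N"
        seqs, pairs = {}, []
        for g in range(40):
            orf = f"g{g}"
            codons = rng.choice(opt + non, p=[0.3, 0.3, 0.3, 0.04, 0.03, 0.03],
                                size=60).tolist()
            seqs[orf] = "".join(codons)
            for i in range(1, 58):
                if codons[i + 1] in non and rng.random() < 0.7:
                    pairs.append((orf, i))
        df = optimality_triplet_enrichment(
            _calls_at(pairs, {o: 60 for o in seqs}), seqs, scale
        ).set_index("feature")
        assert df.loc["OON", "odds_ratio"] > 1  # N planted in the A site
        assert df.loc["OOO", "odds_ratio"] < 1

    def test_triplet_counts_conserve_pause_sites(self, rng):
        seqs, pairs = {}, []
        scale = {"AAA": "O", "CCA": "N"}
        for g in range(10):
            orf = f"g{g}"
            codons = rng.choice(["AAA", "CCA"], size=30).tolist()
            seqs[orf] = "".join(codons)
            pairs += [(orf, i) for i in range(5, 10)]
        calls = _calls_at(pairs, {o: 30 for o in seqs})
        df = optimality_triplet_enrichment(calls, seqs, scale)
        assert df["a"].sum() == len(pairs)  # none at edges -> all retained


class TestBicodon:
    def test_planted_agg_ccg_pairs(self, rng):
        seqs, pairs = {}, []
        fillers = ["GAA", "TTC", "GGT"]
        for g in range(60):
            codons = rng.choice(fillers, size=50).tolist()
            # plant AGG-CCG at a fixed spot, paused; and AGG-GAA unpaused
            codons[10], codons[11] = "AGG", "CCG"
            codons[30], codons[31] = "AGG", "GAA"
            orf = f"g{g}"
            seqs[orf] = "".join(codons)
            if rng.random() < 0.8:
                pairs.append((orf, 10))
        df = bicodon_pair_enrichment(
            _calls_at(pairs, {o: 50 for o in seqs}), seqs,
            p_site_codon="AGG", a_site_codons=["CCG", "CCA", "GAA"],
        ).set_index("feature")
        assert df.loc["AGG-CCG", "odds_ratio"] > 1
        assert "AGG-CCA" not in df.index  # never observed downstream of AGG
        assert df.loc["AGG-GAA", "odds_ratio"] < 1

    def test_swap_sites_inverse_order(self, rng):
        seqs = {"g": "GAACCGAGGGAA"}  # codons GAA CCG AGG GAA
        calls = _calls_at([("g", 2)], {"g": 4})
        df = bicodon_pair_enrichment(
            calls, seqs, p_site_codon="AGG", a_site_codons=["CCG"],
            swap_sites=True,
        )
        assert df.iloc[0]["feature"] == "CCG-AGG"
        assert df.iloc[0]["a"] == 1


class TestScaleTsv:
    def test_class_column_used_directly(self, tmp_path):
        from ribopause.core import SENSE_CODONS
        from ribopause.enrichment import read_scale_tsv

        path = tmp_path / "scale.tsv"
        rows = ["codon\tclass"] + [
            f"{c}\t{'O' if i % 2 else 'N'}" for i, c in enumerate(SENSE_CODONS)
        ]
        path.write_text("\n".join(rows) + "\n")
        scale = read_scale_tsv(path)
        assert len(scale) == 61 and set(scale.values()) == {"O", "N"}

    def test_continuous_score_binarized_at_median(self, tmp_path):
        from ribopause.core import SENSE_CODONS
        from ribopause.enrichment import read_scale_tsv

        path = tmp_path / "scale.tsv"
        rows = ["codon\tscore"] + [
            f"{c}\t{float(i)}" for i, c in enumerate(SENSE_CODONS)
        ]
        path.write_text("\n".join(rows) + "\n")
        scale = read_scale_tsv(path)
        assert scale[SENSE_CODONS[0]] == "N"
        assert scale[SENSE_CODONS[-1]] == "O"

    def test_incomplete_scale_rejected(self, tmp_path):
        from ribopause.enrichment import read_scale_tsv

        path = tmp_path / "scale.tsv"
        path.write_text("codon\tclass\nGCT\tO\n")
        with pytest.raises(ValueError, match="missing"):
            read_scale_tsv(path)


class TestTheilSen:
    def test_identity_line_no_outliers(self):
        x = {f"c{i}": float(i) for i in range(10)}
        slope, intercept, out = theil_sen_outliers(x, x)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0)
        assert out == []

    def test_exact_affine_line(self):
        xs = np.arange(10.0)
        ys = 2 * xs + 1
        slope, intercept, out = theil_sen_outliers(xs, ys)
        assert (slope, intercept) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_single_displaced_codon_flagged(self, rng):
        x = {f"c{i}": v for i, v in enumerate(rng.uniform(0, 1, 60))}
        y = dict(x)
        y["c7"] = x["c7"] + 10.0
        _, _, out = theil_sen_outliers(x, y)
        assert out == ["c7"]

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="slope undefined"):
            theil_sen_outliers(np.ones(5), np.arange(5.0))


class TestPlantedCodonRecovery:
    def test_slow_codon_ranks_first_across_seeds(self):
        """A 5x-dwell codon tops the A-site odds ratios in >=95% of seeds."""
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = SimConfig(
                n_orfs=150, length_median=120, seed=100 + seed,
                dwell={"CCG": 5.0},
            )
            profiles, sequences, _ = generate_translatome(cfg)
            part = partition_by_tpm(compute_tpm(profiles))
            calls = call_pauses(
                normalize_profiles(profiles), part, n_trees=100, seed=seed
            )
            df = site_feature_enrichment(
                calls, sequences, site="A", feature_map=lambda c: c
            )
            top = df.loc[df["odds_ratio"].idxmax(), "feature"]
            wins += top == "CCG"
        assert wins >= int(np.ceil(0.95 * n_seeds))
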