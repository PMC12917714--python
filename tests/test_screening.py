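"""Funnel-stage behaviour: substructure filter, percentile selection,
prioritization, informative bits and bit–selectivity correlation."""

import numpy as np
import pytest
from scipy import stats

from gpcrscreen.affinity_scoring import OffTargetProfile
from gpcrscreen.chem_features import Fingerprint, LigandRecord
from gpcrscreen.classifier import PredictionRecord, confidence_percentiles
from gpcrscreen.screening import (
    BitCorrelation,
    ScreeningCandidate,
    bit_offtarget_correlation,
    informative_bits,
    percentile_select,
    prioritize,
    substructure_filter,
)

NBITS = 64


def _ligand(lig_id, on_bits):
    bits = np.zeros(NBITS, dtype=np.uint8)
    bits[list(on_bits)] = 1
    return LigandRecord(
        ligand_id=lig_id, mw=300.0, logp=2.0, hbd=1, hba=2, tpsa=60.0,
        fingerprint=Fingerprint(bits=bits, radius=2, nbits=NBITS),
    )


def _prediction(lig_id, score):
    return PredictionRecord(
        ligand_id=lig_id, predicted_class=1, predicted_label="antagonist",
        probability=score, prob_antagonist=score, confidence_score=score,
    )


class TestSubstructureFilter:
    TOP = [1, 2, 3, 4, 5]

    def test_no_hit_dropped(self):
        lib = [_ligand("a", [10, 20]), _ligand("b", [1, 10])]
        kept = substructure_filter(lib, self.TOP, mode="any")
        assert [l.ligand_id for l in kept] == ["b"]

    def test_all_mode_subset_of_any_mode(self):
        rng = np.random.default_rng(0)
        lib = [_ligand(f"l{i}", rng.choice(NBITS, 6, replace=False))
               for i in range(50)]
        any_ids = {l.ligand_id for l in substructure_filter(lib, self.TOP, "any")}
        all_ids = {l.ligand_id for l in substructure_filter(lib, self.TOP, "all")}
        assert all_ids <= any_ids

    def test_retained_fraction_matches_independence_closed_form(self):
        rng = np.random.default_rng(1)
        p = 0.25
        n = 4000
        lib = []
        for i in range(n):
            on = [b for b in self.TOP if rng.random() < p]
            lib.append(_ligand(f"l{i}", on or [40]))
        kept = substructure_filter(lib, self.TOP, "any")
        expected = 1 - (1 - p) ** 5
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(len(kept) / n - expected) < 3 * se

    def test_empty_top_bits_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            substructure_filter([_ligand("a", [1])], [])


class TestPercentileSelect:
    def test_87_distinct_scores_select_9(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(np.linspace(0.4, 0.99, 87))
        preds = [_prediction(f"c{i}", s) for i, s in enumerate(scores)]
        pct = confidence_percentiles([p.confidence_score for p in preds])
        for p, q in zip(preds, pct):
            p.confidence_percentile = q
        assert len(percentile_select(preds, pct=90)) == 9

    def test_ten_distinct_scores_select_max(self):
        preds = [_prediction(f"c{i}", s) for i, s in enumerate(np.linspace(0, 1, 10))]
        out = percentile_select(preds, pct=90)
        assert [p.ligand_id for p in out] == ["c9"]

    def test_all_tied_selects_everything(self, caplog):
        preds = [_prediction(f"c{i}", 0.6) for i in range(8)]
        with caplog.at_level("WARNING"):
            out = percentile_select(preds, pct=90)
        assert len(out) == 8
        assert "tied" in caplog.text

    def test_empty_input(self):
        assert percentile_select([], pct=90) == []


def _candidate(lig_id, target_delta, off_score):
    return ScreeningCandidate(
        ligand=_ligand(lig_id, [1]),
        target_delta_affinity=target_delta,
        off_target=OffTargetProfile(
            ligand_id=lig_id, target_receptor="HCAR1",
            per_receptor={}, off_target_score=off_score,
        ),
    )


class TestPrioritize:
    def test_published_ordering_by_off_target_score(self):
        cands = [
            _candidate("Cefuroxime", 3.222, 14.597),
            _candidate("Ketanserin", 2.526, 12.807),
            _candidate("CryptopyranmoscatoneA1", 2.767, 13.658),
        ]
        ranked = prioritize(cands)
        assert [c.ligand_id for c in ranked] == [
            "Ketanserin", "CryptopyranmoscatoneA1", "Cefuroxime",
        ]

    def test_single_candidate(self):
        c = _candidate("only", 1.0, 5.0)
        assert prioritize([c]) == [c]

    def test_order_independent_of_input_permutation(self):
        rng = np.random.default_rng(3)
        cands = [_candidate(f"l{i}", 1 + rng.random(), 10 * rng.random())
                 for i in range(12)]
        ranked_ids = [c.ligand_id for c in prioritize(cands)]
        rng.shuffle(cands)
        assert [c.ligand_id for c in prioritize(cands)] == ranked_ids

    def test_tie_broken_by_descending_target_affinity(self):
        ranked = prioritize([_candidate("low", 1.0, 5.0), _candidate("high", 3.0, 5.0)])
        assert [c.ligand_id for c in ranked] == ["high", "low"]

    def test_nonpositive_target_affinity_rejected(self):
        with pytest.raises(ValueError, match="bad"):
            prioritize([_candidate("bad", -0.5, 2.0)])


class TestInformativeBits:
    def test_universal_bit_excluded(self):
        ligs = [_ligand(f"l{i}", [7, i + 10]) for i in range(9)]
        bits = informative_bits(ligs)
        assert 7 not in bits
        assert 10 in bits

    def test_identical_fingerprints_give_none(self):
        ligs = [_ligand("a", [1, 2]), _ligand("b", [1, 2])]
        assert informative_bits(ligs) == []

    def test_nine_ligand_set_yields_order_of_magnitude_many(self):
        # a realistic small prioritized set keeps tens of informative bits
        rng = np.random.default_rng(5)
        ligs = [_ligand(f"l{i}", rng.choice(NBITS, 12, replace=False))
                for i in range(9)]
        assert 10 <= len(informative_bits(ligs)) <= NBITS

    def test_single_ligand_rejected(self):
        with pytest.raises(ValueError):
            informative_bits([_ligand("a", [1])])


def spearman_oracle(x, y):
    """Brute-force rank-based formula with average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestBitCorrelation:
    def test_perfectly_coranked_bit(self):
        # bit present exactly in the high-scoring half
        ligs = [_ligand(f"l{i}", [5] if i >= 4 else [9]) for i in range(8)]
        scores = np.arange(8, dtype=float)
        out = bit_offtarget_correlation(ligs, scores, top_n=2)
        top = {bc.bit: bc for bc in out}
        assert top[5].spearman_r == pytest.approx(
            spearman_oracle([0, 0, 0, 0, 1, 1, 1, 1], scores)
        )
        assert top[5].direction == "off-target-associated"
        assert top[9].spearman_r < 0

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(6)
        ligs = [_ligand(f"l{i}", rng.choice(NBITS, 10, replace=False))
                for i in range(9)]
        scores = rng.random(9) * 20
        out = bit_offtarget_correlation(ligs, scores, top_n=50)
        presence = np.stack([l.fingerprint.bits for l in ligs])
        for bc in out:
            assert bc.spearman_r == pytest.approx(
                spearman_oracle(presence[:, bc.bit], scores), abs=1e-12
            )

    def test_selectivity_flag_below_threshold(self):
        assert BitCorrelation(bit=1, spearman_r=-0.5).selective
        assert not BitCorrelation(bit=1, spearman_r=-0.3).selective

    def test_unmappable_bits_dropped_with_log(self, caplog):
        ligs = [_ligand(f"l{i}", [5] if i >= 4 else [9]) for i in range(8)]
        scores = np.arange(8, dtype=float)
        with caplog.at_level("WARNING"):
            out = bit_offtarget_correlation(
                ligs, scores, top_n=5,
                bit_mapper=lambda b: ["frag"] if b == 5 else [],
            )
        assert [bc.bit for bc in out] == [5]
        assert "could not be mapped" in caplog.text

    def test_constant_scores_rejected(self):
        ligs = [_ligand(f"l{i}", [i % 4]) for i in range(6)]
        with pytest.raises(ValueError, match="constant"):
            bit_offtarget_correlation(ligs, np.ones(6))
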