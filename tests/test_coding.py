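"""Coding-potential features: ORF, Fickett, hexamers, logistic scorer."""

import io
import math

import numpy as np
import pytest

from p53lnc.coding import (
    CodingModel,
    HexamerTable,
    coding_probability,
    compute_features,
    fickett_score,
    hexamer_llr,
    longest_orf,
    train_coding_model,
    train_hexamer_table,
    _CONTENT_THRESHOLDS,
    _FICKETT_CONTENT_PROB,
    _FICKETT_CONTENT_WEIGHT,
    _FICKETT_POSITION_PROB,
    _FICKETT_POSITION_WEIGHT,
    _POSITION_THRESHOLDS,
)

STOPS = ("TAA", "TAG", "TGA")


def orf_oracle(seq):
    """Exhaustive three-frame scan: every ATG to its first in-frame stop."""
    seq = seq.upper().replace("U", "T")
    best = (0, -1)  # (length, -start) ordering helper
    results = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i, len(seq) - 2, 3):
            if seq[j : j + 3] in STOPS:
                results.append((j + 3 - i, i))
                break
    if not results:
        return 0, -1
    length = max(r[0] for r in results)
    start = min(r[1] for r in results if r[0] == length)
    return length, start


class TestLongestOrf:
    def test_minimal_orf(self):
        r = longest_orf("ATGAAATAA")
        assert (r.start, r.length) == (0, 9) and r.coverage == 1.0

    def test_no_start_codon(self):
        r = longest_orf("CCCCCC")
        assert r.length == 0 and r.coverage == 0.0

    def test_empty_sequence(self):
        assert longest_orf("").length == 0

    def test_n_never_matches_codons(self):
        assert longest_orf("ATGNNNTAA").length == 9  # internal codon may be N
        assert longest_orf("ATNAAATAA").length == 0  # N breaks the start codon

    def test_matches_exhaustive_scan_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
            r = longest_orf(seq)
            length, start = orf_oracle(seq)
            assert (r.length, r.start) == (length, start)

    def test_appending_three_prime_sequence_keeps_orf(self):
        seq = "CCATGAAACCCTAA"
        base = longest_orf(seq)
        extended = longest_orf(seq + "GGGTTT")
        assert extended.length >= base.length


def fickett_oracle(seq):
    """Independent table-lookup implementation (digitize-based)."""
    seq = seq.upper().replace("U", "T")
    total = 0.0
    for base in "ACGT":
        counts = [seq[k::3].count(base) for k in range(3)]
        pos_val = max(counts) / (min(counts) + 1)
        content = seq.count(base) / max(sum(seq.count(b) for b in "ACGT"), 1)
        pos_bin = int(np.digitize(-pos_val, -np.array(_POSITION_THRESHOLDS), right=True))
        con_bin = int(np.digitize(-content, -np.array(_CONTENT_THRESHOLDS), right=True))
        total += _FICKETT_POSITION_PROB[base][min(pos_bin, 9)] * _FICKETT_POSITION_WEIGHT[base]
        total += _FICKETT_CONTENT_PROB[base][min(con_bin, 9)] * _FICKETT_CONTENT_WEIGHT[base]
    return total


class TestFickett:
    def test_score_within_attainable_bounds(self):
        lo = sum(min(_FICKETT_POSITION_PROB[b]) * _FICKETT_POSITION_WEIGHT[b] for b in "ACGT")
        lo += sum(min(_FICKETT_CONTENT_PROB[b]) * _FICKETT_CONTENT_WEIGHT[b] for b in "ACGT")
        hi = sum(max(_FICKETT_POSITION_PROB[b]) * _FICKETT_POSITION_WEIGHT[b] for b in "ACGT")
        hi += sum(max(_FICKETT_CONTENT_PROB[b]) * _FICKETT_CONTENT_WEIGHT[b] for b in "ACGT")
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=240))
            assert lo <= fickett_score(seq) <= hi

    def test_homopolymer_matches_independent_lookup(self):
        assert fickett_score("A" * 300) == pytest.approx(fickett_oracle("A" * 300))

    def test_random_sequences_match_independent_lookup(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(200, 400))))
            assert fickett_score(seq) == pytest.approx(fickett_oracle(seq))

    def test_random_sequence_mean_in_noncoding_range(self):
        rng = np.random.default_rng(3)
        scores = [
            fickett_score("".join("ACGT"[i] for i in rng.integers(0, 4, size=300)))
            for _ in range(300)
        ]
        assert np.mean(scores) < 0.74  # below the coding-indicative range


def hexamer_count_oracle(seqs, step, pseudocount):
    counts = {}
    for seq in seqs:
        for i in range(0, len(seq) - 5, step):
            h = seq[i : i + 6]
            if set(h) <= set("ACGT"):
                counts[h] = counts.get(h, 0) + 1
    total = sum(counts.values()) + 4096 * pseudocount
    alphabet = [a + b + c + d + e + f
                for a in "ACGT" for b in "ACGT" for c in "ACGT"
                for d in "ACGT" for e in "ACGT" for f in "ACGT"]
    return np.array([(counts.get(h, 0) + pseudocount) / total for h in alphabet])


class TestHexamer:
    def test_identical_training_sets_give_equal_tables(self):
        seqs = ["ATGAAACCCGGGTTT", "ATGCGTACGTAGCTA"]
        # same sets AND same counting step: train twice with swapped roles
        t1 = train_hexamer_table(seqs, seqs)
        t2 = train_hexamer_table(seqs, seqs)
        assert np.array_equal(t1.coding, t2.coding)
        assert np.array_equal(t1.noncoding, t2.noncoding)

    def test_tables_sum_to_one(self):
        rng = np.random.default_rng(4)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 100)) for _ in range(5)]
        t = train_hexamer_table(seqs[:3], seqs[3:])
        assert t.coding.sum() == pytest.approx(1.0, abs=1e-12)
        assert t.noncoding.sum() == pytest.approx(1.0, abs=1e-12)

    def test_frequencies_match_brute_force_counting(self):
        rng = np.random.default_rng(5)
        coding = ["".join("ACGTN"[i] for i in rng.integers(0, 5, 90)) for _ in range(10)]
        noncoding = ["".join("ACGT"[i] for i in rng.integers(0, 4, 90)) for _ in range(10)]
        t = train_hexamer_table(coding, noncoding, pseudocount=1 / 4096)
        up = lambda s: s.upper()
        assert np.allclose(t.coding, hexamer_count_oracle(coding, 3, 1 / 4096))
        assert np.allclose(t.noncoding, hexamer_count_oracle(noncoding, 1, 1 / 4096))

    def test_empty_training_set_is_error(self):
        with pytest.raises(ValueError):
            train_hexamer_table([], ["ACGTACGTAC"])

    def test_equal_tables_give_zero_llr(self):
        table = HexamerTable(np.full(4096, 1 / 4096), np.full(4096, 1 / 4096))
        rng = np.random.default_rng(6)
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
            assert hexamer_llr(seq, table) == 0.0

    def test_sequences_from_coding_table_have_positive_mean_llr(self):
        # coding table = product measure of a skewed base composition, so
        # every window of a sequence drawn from it has positive expected LLR
        rng = np.random.default_rng(7)
        q = np.array([0.1, 0.4, 0.4, 0.1])  # A C G T
        p = np.ones(4096)
        for h in range(4096):
            for k in range(6):
                p[h] *= q[(h >> (2 * k)) & 3]
        table = HexamerTable(p / p.sum(), np.full(4096, 1 / 4096))
        llrs = []
        for _ in range(300):
            seq = "".join("ACGT"[i] for i in rng.choice(4, size=120, p=q))
            llrs.append(hexamer_llr(seq, table))
        assert np.mean(llrs) > 0

    def test_short_sequence_scores_zero(self):
        table = HexamerTable(np.full(4096, 1 / 4096), np.full(4096, 1 / 4096))
        assert hexamer_llr("ACGT", table) == 0.0


class TestCodingModel:
    def zero_model(self):
        return CodingModel({k: 0.0 for k in ("orf_length", "orf_coverage", "fickett", "hexamer_llr")}, 0.0)

    def test_all_zero_weights_give_half(self):
        feats = {"orf_length": 5.0, "orf_coverage": 0.5, "fickett": 1.0, "hexamer_llr": 0.1}
        assert coding_probability(feats, self.zero_model()) == 0.5

    def test_missing_feature_raises_naming_it(self):
        with pytest.raises(KeyError, match="fickett"):
            coding_probability({"orf_length": 1.0, "orf_coverage": 0.1, "hexamer_llr": 0}, self.zero_model())

    def test_probability_monotone_in_positively_weighted_feature(self):
        m = self.zero_model()
        m.weights["orf_length"] = 0.01
        probs = [
            coding_probability(
                {"orf_length": L, "orf_coverage": 0, "fickett": 0, "hexamer_llr": 0}, m
            )
            for L in (0, 100, 500, 1000)
        ]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_cutoff_must_be_in_open_unit_interval(self):
        with pytest.raises(ValueError):
            CodingModel({k: 0.0 for k in ("orf_length", "orf_coverage", "fickett", "hexamer_llr")}, 0.0, cutoff=1.0)

    def test_model_text_round_trip(self):
        m = CodingModel(
            {"orf_length": 0.004, "orf_coverage": 2.1, "fickett": 1.5, "hexamer_llr": 3.0},
            intercept=-4.2,
            cutoff=0.364,
        )
        buf = io.StringIO()
        m.to_text(buf)
        m2 = CodingModel.from_text(io.StringIO(buf.getvalue()))
        assert m2.weights == m.weights and m2.intercept == m.intercept

    def test_trained_model_separates_planted_classes(self):
        rng = np.random.default_rng(8)
        nonstop = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in STOPS]

        def coding_seq(n=600):
            n_codons = int(0.7 * n) // 3
            orf = "ATG" + "".join(
                nonstop[i] for i in rng.integers(0, len(nonstop), n_codons - 2)
            ) + "TAA"
            pad = "".join("ACGT"[i] for i in rng.integers(0, 4, n - len(orf)))
            cut = int(rng.integers(0, len(pad) + 1))
            return pad[:cut] + orf + pad[cut:]

        def noncoding_seq(n=600):
            return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

        train_c = [coding_seq() for _ in range(60)]
        train_n = [noncoding_seq() for _ in range(60)]
        model, table = train_coding_model(train_c, train_n)
        held = [(coding_seq(), 1) for _ in range(40)] + [(noncoding_seq(), 0) for _ in range(40)]
        correct = 0
        for seq, label in held:
            p = coding_probability(compute_features(seq, table), model)
            correct += int((p >= model.cutoff) == bool(label))
        assert correct / len(held) >= 0.95
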