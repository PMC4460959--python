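"""PWM scoring, exact match p-values, window scanning, enrichment formulas."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from enhancerlink.motifs import (
    DEFAULT_BACKGROUND,
    enrichment_stats,
    log_odds_matrix,
    motif_enrichment,
    scan_windows,
    score_pvalue_table,
)
from enhancerlink.simulate import PLANTED_MOTIF_CONSENSUS, _consensus_pwm
from enhancerlink.types import PWM, Probe

UNIFORM = np.array([0.25, 0.25, 0.25, 0.25])


def random_pwm(rng, width):
    probs = rng.dirichlet(np.ones(4), size=width)
    return PWM(motif_id=f"rand{width}", probs=probs, nsites=30)


class TestLogOdds:
    def test_background_row_is_zero(self):
        pwm = PWM("bg", np.tile(UNIFORM, (4, 1)), nsites=50)
        lom = log_odds_matrix(pwm, UNIFORM)
        np.testing.assert_allclose(lom, 0.0, atol=1e-12)

    def test_consensus_sign_pattern(self):
        pwm = PWM("cons", np.array([[1.0, 0.0, 0.0, 0.0]]), nsites=20)
        lom = log_odds_matrix(pwm, UNIFORM)
        assert lom[0, 0] > 0
        assert (lom[0, 1:] < 0).all()
        assert lom[0, 0] == pytest.approx(
            math.log2(((1.0 * 20 + 0.1 * 0.25) / 20.1) / 0.25))

    def test_random_matches_elementwise_formula(self, rng):
        pwm = random_pwm(rng, 7)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        lom = log_odds_matrix(pwm, bg, pseudocount=0.1)
        expected = np.log2(((pwm.probs * 30 + 0.1 * bg) / 30.1) / bg)
        np.testing.assert_allclose(lom, expected, atol=1e-12)

    def test_zero_background_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            log_odds_matrix(random_pwm(rng, 3), np.array([0.5, 0.5, 0.0, 0.0]))


class TestScorePvalueTable:
    def test_single_position(self):
        bg = np.array([0.1, 0.2, 0.3, 0.4])
        pwm = PWM("one", np.array([[0.7, 0.1, 0.1, 0.1]]), nsites=1000)
        lom = log_odds_matrix(pwm, bg)
        dist = score_pvalue_table(lom, bg)
        best = lom.max()
        # p of the best base's score = background probability of that base (A)
        assert dist.pvalue(best) == pytest.approx(0.1, abs=1e-9)

    def test_min_score_has_p_one(self, rng):
        lom = log_odds_matrix(random_pwm(rng, 4), UNIFORM)
        dist = score_pvalue_table(lom, UNIFORM)
        assert dist.pvalue(lom.min(axis=1).sum()) == pytest.approx(1.0)
        assert dist.tail[0] == pytest.approx(1.0)

    def test_tail_monotone_nonincreasing(self, rng):
        lom = log_odds_matrix(random_pwm(rng, 6), UNIFORM)
        dist = score_pvalue_table(lom, UNIFORM)
        assert (np.diff(dist.tail) <= 1e-15).all()

    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5])
    def test_matches_exhaustive_kmer_enumeration(self, width, rng):
        bg = np.array([0.2, 0.3, 0.3, 0.2])
        pwm = random_pwm(rng, width)
        lom = log_odds_matrix(pwm, bg)
        dist = score_pvalue_table(lom, bg)
        # oracle: enumerate all 4^width sequences with quantized scores
        q = dist.qmatrix
        for _ in range(10):
            kmer = rng.integers(0, 4, size=width)
            qscore = int(q[np.arange(width), kmer].sum())
            p_oracle = 0.0
            for word in itertools.product(range(4), repeat=width):
                ws = int(q[np.arange(width), word].sum())
                if ws >= qscore:
                    p_oracle += np.prod(bg[list(word)])
            assert dist.quantized_pvalue(qscore) == pytest.approx(p_oracle, rel=1e-9)


def _probe_genome(window_seq, window=100):
    """A single-contig genome whose probe window is exactly ``window_seq``."""
    assert len(window_seq) == 2 * window + 1
    pad = "A" * 50
    probe = Probe("p0", "chrS", 50 + window + 1)  # window starts at offset 50
    return {"chrS": pad + window_seq + pad}, probe


_RC = str.maketrans("ACGT", "TGCA")


@pytest.fixture(scope="module")
def planted_pwm():
    return _consensus_pwm("PLANT", PLANTED_MOTIF_CONSENSUS)


class TestScanWindows:

    def test_planted_consensus_recovered_at_offset(self, planted_pwm, rng):
        bases = "ACGT"
        seq = "".join(rng.choice(list(bases), size=201))
        offset = 77
        seq = seq[:offset] + PLANTED_MOTIF_CONSENSUS + seq[offset + 10:]
        genome, probe = _probe_genome(seq)
        hits = scan_windows([probe], genome, [planted_pwm])
        fwd = hits[(hits["strand"] == "+") & (hits["offset"] == offset)]
        assert len(fwd) == 1
        assert fwd["p_match"].iloc[0] < 1e-4

    def test_all_n_window_has_no_hits(self, planted_pwm):
        genome, probe = _probe_genome("N" * 201)
        assert len(scan_windows([probe], genome, [planted_pwm])) == 0

    def test_reverse_complement_symmetry(self, planted_pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), size=201))
        seq = seq[:30] + PLANTED_MOTIF_CONSENSUS + seq[40:]
        genome, probe = _probe_genome(seq)
        hits = scan_windows([probe], genome, [planted_pwm])
        rc_genome = {"chrS": genome["chrS"].translate(_RC)[::-1]}
        L = len(genome["chrS"])
        rc_probe = Probe("p0", "chrS", L - probe.pos + 1)
        rc_hits = scan_windows([rc_probe], rc_genome, [planted_pwm])
        got = sorted(zip(rc_hits["offset"], rc_hits["strand"]))
        width = planted_pwm.width
        expected = sorted(
            (201 - width - off, "+" if strand == "-" else "-")
            for off, strand in zip(hits["offset"], hits["strand"]))
        assert got == expected
        np.testing.assert_allclose(np.sort(rc_hits["p_match"]),
                                   np.sort(hits["p_match"]), rtol=1e-12)

    def test_missing_contig_skipped(self, planted_pwm):
        probe = Probe("ghost", "chrNope", 500)
        hits = scan_windows([probe], {"chrS": "ACGT" * 100}, [planted_pwm])
        assert len(hits) == 0


class TestEnrichment:
    def test_printed_formula_example(self):
        st = enrichment_stats(20, 80, 100, 900)
        assert st["p_sel"] == pytest.approx(0.2)
        assert st["p_bg"] == pytest.approx(0.1)
        assert st["odds_ratio"] == pytest.approx(2.25)
        assert st["sd"] == pytest.approx(
            math.sqrt(1 / 20 + 1 / 80 + 1 / 100 + 1 / 900))
        assert st["lower_ci"] == pytest.approx(
            math.exp(math.log(2.25) - 1.96 * st["sd"]))

    def test_z_one_reproduces_one_sd_bound(self):
        st = enrichment_stats(20, 80, 100, 900, z=1.0)
        assert st["lower_ci"] == pytest.approx(math.exp(math.log(2.25) - st["sd"]))

    def _hits_for(self, probes_with_hit, motif="M"):
        return pd.DataFrame({
            "probe_id": list(probes_with_hit),
            "motif_id": motif,
            "offset": 0, "strand": "+", "score": 10.0, "p_match": 1e-6,
        })

    def test_self_comparison_is_null(self):
        bg = [f"p{i}" for i in range(100)]
        hits = self._hits_for(bg[:30])
        res = motif_enrichment(bg, bg, hits)
        assert res["odds_ratio"].iloc[0] == pytest.approx(1.0)
        assert not res["enriched"].iloc[0]

    def test_occurrence_floor_excludes_small_a(self):
        bg = [f"p{i}" for i in range(1000)]
        sel = bg[:20]
        hits = self._hits_for(sel[:9] + bg[900:905])  # a=9, huge OR
        res = motif_enrichment(sel, bg, hits)
        assert res["a"].iloc[0] == 9
        assert res["lower_ci"].iloc[0] > 1.1
        assert not res["enriched"].iloc[0]

    def test_per_probe_binarization(self):
        bg = [f"p{i}" for i in range(50)]
        sel = bg[:10]
        hits = pd.concat([self._hits_for(["p0"] * 5), self._hits_for(["p1"])],
                         ignore_index=True)
        res = motif_enrichment(sel, bg, hits)
        assert res["a"].iloc[0] == 2  # five occurrences in p0 count once

    def test_zero_cell_unevaluable(self):
        bg = [f"p{i}" for i in range(40)]
        sel = bg[:10]
        res = motif_enrichment(sel, bg, self._hits_for(sel))  # d=30? c=10,d=30,b=0
        assert not res["evaluable"].iloc[0]
        assert not res["enriched"].iloc[0]

    def test_doubling_counts_keeps_or_shrinks_sd(self):
        a = enrichment_stats(20, 80, 100, 900)
        b = enrichment_stats(40, 160, 200, 1800)
        assert b["odds_ratio"] == pytest.approx(a["odds_ratio"])
        assert b["sd"] < a["sd"]

    def test_requires_subset(self):
        with pytest.raises(ValueError, match="subset"):
            motif_enrichment(["a", "zzz"], ["a", "b"], self._hits_for(["a"]))

    def test_planted_motif_tops_ranking(self, cohort, hits, pairs):
        enh = sorted(cohort.universe.distal_enhancer)
        paired = sorted(set(pairs["probe_id"]))
        res = motif_enrichment(paired, enh, hits)
        assert res["motif_id"].iloc[0] == cohort.truth.motif_id
        assert bool(res["enriched"].iloc[0])
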