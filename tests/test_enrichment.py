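"""Peak-overlap enrichment and PWM delta scoring."""

import numpy as np
import pandas as pd
import pytest

from starr_regvar import delta_enrichment, overlap_enrichment, pwm_delta_scores
from starr_regvar.enrichment import score_sequence, snps_in_peaks, _log_odds


def naive_membership(positions, peaks):
    """O(n*m) oracle for point-in-interval membership."""
    out = np.zeros(len(positions), dtype=bool)
    for i, row in positions.reset_index(drop=True).iterrows():
        p0 = row["pos"] - 1
        for _, pk in peaks.iterrows():
            if pk["chrom"] == row["chrom"] and pk["start"] <= p0 < pk["end"]:
                out[i] = True
                break
    return out


class TestOverlap:
    def test_sweep_matches_naive_oracle(self):
        rng = np.random.default_rng(8)
        positions = pd.DataFrame({
            "chrom": rng.choice(["c1", "c2"], 200),
            "pos": rng.integers(1, 5000, 200),
        })
        starts = rng.integers(0, 4900, 60)
        peaks = pd.DataFrame({
            "chrom": rng.choice(["c1", "c2"], 60),
            "start": starts,
            "end": starts + rng.integers(1, 300, 60),
        })
        assert (snps_in_peaks(positions, peaks) == naive_membership(positions, peaks)).all()

    def test_zero_overlap_zero_margin(self):
        by_class = {
            "active": pd.DataFrame({"chrom": ["c1"], "pos": [100]}),
            "inactive": pd.DataFrame({"chrom": ["c1"], "pos": [200]}),
        }
        peaks = pd.DataFrame({"chrom": ["c1"], "start": [5000], "end": [5100]})
        res = overlap_enrichment(by_class, peaks, "active", "inactive")
        assert res["pvalue"] == 1.0 and np.isnan(res["odds_ratio"])

    def test_empty_class_rejected(self):
        by_class = {"active": pd.DataFrame({"chrom": [], "pos": []}),
                    "inactive": pd.DataFrame({"chrom": ["c1"], "pos": [1]})}
        peaks = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [10]})
        with pytest.raises(ValueError):
            overlap_enrichment(by_class, peaks, "active", "inactive")

    def test_invalid_peak_rejected(self):
        pos = pd.DataFrame({"chrom": ["c1"], "pos": [5]})
        with pytest.raises(ValueError):
            snps_in_peaks(pos, pd.DataFrame({"chrom": ["c1"], "start": [10], "end": [10]}))

    def test_planted_or_recovered_within_ci(self):
        """simulate_annotations at OR=3 -> recovered OR inside the 95% CI."""
        from starr_regvar import SimulationConfig, simulate_annotations, simulate_dataset

        cfg = SimulationConfig(n_tag_snps=300, linked_per_tag=9, pre_fraction=0.08,
                               nre_fraction=0.0, seed=23, materialize_fragments=False)
        screen = simulate_dataset(cfg)
        peaks = simulate_annotations(screen.panel, screen.truth, target_or=3.0,
                                     baseline_rate=0.04, seed=2)
        pos = screen.panel.set_index("snp_id")[["chrom", "pos"]]
        active_ids = screen.truth.index[screen.truth["class"] == "PRE"]
        inactive_ids = screen.truth.index[screen.truth["class"] == "inactive"]
        by_class = {"active": pos.loc[active_ids].reset_index(),
                    "inactive": pos.loc[inactive_ids].reset_index()}
        res = overlap_enrichment(by_class, peaks, "active", "inactive")
        assert res["ci_low"] < 3.0 < res["ci_high"]


class TestPwm:
    def test_flat_motif_zero_delta(self, tiny_panel):
        seqs = {"chrS": "A" * 6000}
        pwms = {"flat": np.full((4, 4), 0.25)}
        out = pwm_delta_scores(tiny_panel, seqs, pwms, pseudocount=0.0)
        assert len(out) == 3
        assert np.allclose(out["delta"], 0.0)
        assert np.allclose(out["ref_score"], 0.0)

    def test_width1_hand_example_forward_strand(self):
        """A-favoring width-1 motif, T->A, uniform background, no pseudocount:
        delta = log2(0.7/0.25) - log2(0.1/0.25) = log2(7) ~ 2.807."""
        panel = pd.DataFrame({"chrom": ["c"], "pos": [11], "snp_id": ["s"],
                              "ref": ["T"], "alt": ["A"], "maf": [0.1]})
        seqs = {"c": "C" * 30}
        pwms = {"m": np.array([[0.7, 0.1, 0.1, 0.1]])}
        out = pwm_delta_scores(panel, seqs, pwms, pseudocount=0.0, both_strands=False)
        assert out["delta"].iloc[0] == pytest.approx(np.log2(7), abs=1e-9)

    def test_delta_antisymmetric_under_allele_swap(self, tiny_panel):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 6000))
        pwm = rng.dirichlet(np.ones(4), size=6)
        swapped = tiny_panel.rename(columns={"ref": "alt", "alt": "ref"})
        a = pwm_delta_scores(tiny_panel, {"chrS": seq}, {"m": pwm})
        b = pwm_delta_scores(swapped, {"chrS": seq}, {"m": pwm})
        assert np.allclose(a["delta"].to_numpy(), -b["delta"].to_numpy())

    def test_consensus_and_reverse_complement_scoring(self):
        """A sharp motif scores its consensus and the consensus's reverse
        complement identically when both strands are scanned."""
        pwm = np.array([[0.97, 0.01, 0.01, 0.01],
                        [0.01, 0.97, 0.01, 0.01],
                        [0.01, 0.01, 0.97, 0.01]])  # consensus ACG
        lo = _log_odds(pwm, 0.0, np.full(4, 0.25))
        fwd = score_sequence("ACG", lo)
        rc = score_sequence("CGT", lo)  # revcomp of ACG
        assert fwd == pytest.approx(3 * np.log2(0.97 / 0.25))
        assert rc < fwd
        # scanning both strands over the revcomp context recovers fwd
        panel = pd.DataFrame({"chrom": ["c"], "pos": [11], "snp_id": ["s"],
                              "ref": ["G"], "alt": ["T"], "maf": [0.1]})
        seq = "T" * 9 + "CGT" + "T" * 9  # pos 11 is the 'G' of CGT
        out = pwm_delta_scores(panel, {"c": seq}, {"m": pwm}, pseudocount=0.0)
        assert out["ref_score"].iloc[0] == pytest.approx(fwd, abs=1e-9)

    def test_score_sum_decomposition(self):
        rng = np.random.default_rng(9)
        pwm = rng.dirichlet(np.ones(4), size=5)
        lo = _log_odds(pwm, 0.01, np.full(4, 0.25))
        seq = "GATCA"
        total = score_sequence(seq, lo)
        parts = sum(lo[i, "ACGT".index(b)] for i, b in enumerate(seq))
        assert total == pytest.approx(parts, abs=1e-12)

    def test_out_of_bounds_snp_skipped(self):
        panel = pd.DataFrame({"chrom": ["c"], "pos": [2], "snp_id": ["s"],
                              "ref": ["A"], "alt": ["C"], "maf": [0.1]})
        pwms = {"m": np.full((6, 4), 0.25)}
        out = pwm_delta_scores(panel, {"c": "ACGTACGT"}, pwms)
        assert len(out) == 0


class TestDeltaEnrichment:
    def _deltas(self, vals):
        return pd.DataFrame({"snp_id": [f"s{i}" for i in range(len(vals))],
                             "motif_id": "m", "ref_score": 0.0,
                             "alt_score": vals, "delta": vals})

    def test_threshold_rule_at_three(self):
        deltas = self._deltas([3.2, 2.9, -3.5, 0.0])
        classes = pd.Series({"s0": "regulatory", "s1": "regulatory",
                             "s2": "inactive", "s3": "inactive"})
        out = delta_enrichment(deltas, classes, threshold=3.0)
        row = out.iloc[0]
        assert row["n_disrupting_test"] == 1  # |3.2| >= 3 yes, |2.9| no
        assert row["n_disrupting_ref"] == 1   # |-3.5| >= 3

    def test_all_zero_deltas_zero_margin(self):
        deltas = self._deltas([0.0, 0.0, 0.0, 0.0])
        classes = pd.Series({"s0": "regulatory", "s1": "regulatory",
                             "s2": "inactive", "s3": "inactive"})
        out = delta_enrichment(deltas, classes)
        assert out["pvalue"].iloc[0] == 1.0 and np.isnan(out["odds_ratio"].iloc[0])

    def test_planted_disruption_enrichment_recovered(self):
        """Disrupting alleles planted 5x more often among regulatory SNPs."""
        rng = np.random.default_rng(12)
        n_reg, n_in = 300, 3000
        p_base = 0.05
        odds = p_base / (1 - p_base) * 5
        p_reg = odds / (1 + odds)
        ids = [f"s{i}" for i in range(n_reg + n_in)]
        classes = pd.Series(["regulatory"] * n_reg + ["inactive"] * n_in, index=ids)
        dis = np.concatenate([rng.random(n_reg) < p_reg, rng.random(n_in) < p_base])
        deltas = pd.DataFrame({"snp_id": ids, "motif_id": "m", "ref_score": 0.0,
                               "alt_score": np.where(dis, 4.0, 1.0),
                               "delta": np.where(dis, 4.0, 1.0)})
        out = delta_enrichment(deltas, classes)
        row = out.iloc[0]
        assert row["ci_low"] < 5.0 < row["ci_high"]
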