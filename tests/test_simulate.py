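"""Synthetic dataset generator and the greedy identity filter."""

import numpy as np
import pytest

from raacfam import SimulationConfig, SVMConfig, generate, generate_dataset
from raacfam.alphabet import CANONICAL
from raacfam.errors import ConfigError, DatasetError
from raacfam.simulate import (
    count_motif_matches,
    identity_filter,
    motif_match_probability,
    motif_regex,
    pairwise_identity,
)


class TestGenerate:
    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        config = SimulationConfig(n_pos=15, n_neg=15, seed=42)
        p1, n1, t1 = generate_dataset(config, tmp_path / "a")
        p2, n2, t2 = generate_dataset(config, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()
        assert n1.read_bytes() == n2.read_bytes()
        assert t1.read_bytes() == t2.read_bytes()

    def test_default_config_mirrors_training_set_scale(self):
        pos, neg, manifest = generate(SimulationConfig(seed=1))
        assert len(pos) == 240 and len(neg) == 240
        assert len(manifest) == 480

    def test_every_noise_free_positive_contains_exact_motif(self):
        config = SimulationConfig(
            n_pos=50, n_neg=1, motif_noise=0.0, seed=3
        )
        pos, _, manifest = generate(config)
        pattern = motif_regex(config.motif, config.spacer_range)
        starts = dict(zip(manifest[manifest.label == 1].id, manifest.motif_start))
        for sid, seq in pos:
            m = pattern.match(seq, starts[sid])
            assert m is not None and m.start() == starts[sid]

    def test_negative_match_rate_matches_closed_form(self):
        """Exact-motif rate in background sequences agrees with the analytic
        per-window probability within 3 SE (scaled-down count)."""
        config = SimulationConfig(
            n_pos=1, n_neg=2000, length_range=(60, 60),
            motif="HxD-H", spacer_range=(3, 3), seed=7,
        )
        _, neg, _ = generate(config)
        # window = H,x,D + 3-spacer + H spans 7; literal positions H,D,H
        p_window = motif_match_probability(config.motif)  # (1/20)^3
        windows = 60 - 7 + 1
        p_seq = 1 - (1 - p_window) ** windows
        hits = sum(
            count_motif_matches(seq, config.motif, config.spacer_range) > 0
            for _, seq in neg
        )
        se = np.sqrt(2000 * p_seq * (1 - p_seq))
        assert abs(hits - 2000 * p_seq) <= 3 * se

    def test_positive_bias_tilts_polar_composition(self):
        from raacfam.simulate import POLAR_GROUP

        biased = SimulationConfig(n_pos=40, n_neg=40, positive_bias=0.5, seed=9)
        pos, neg, _ = generate(biased)
        frac = lambda recs: np.mean(
            [sum(c in POLAR_GROUP for c in s) / len(s) for _, s in recs]
        )
        assert frac(pos) > frac(neg) + 0.1

    def test_infeasible_motif_length_combination_rejected(self):
        with pytest.raises(ConfigError, match="motif span"):
            SimulationConfig(length_range=(5, 10), spacer_range=(10, 20))

    def test_invalid_motif_symbol_rejected(self):
        with pytest.raises(ConfigError, match="motif symbol"):
            SimulationConfig(motif="HZ9")

    def test_separability_rises_with_bias_and_vanishes_without_signal(self):
        """CV accuracy is non-decreasing in the polar bias (paired over
        seeds) and at zero bias with the motif destroyed it is chance."""
        from raacfam import ProteinFamilyModel, cross_validate, encode_sequences
        from raacfam.features import FeatureSpec
        from raacfam import get_type33

        spec = FeatureSpec(get_type33(5), 1)
        svm = SVMConfig(cv_folds=5, seed=0)

        def cv_acc(bias, noise, seed):
            cfg = SimulationConfig(
                n_pos=40, n_neg=40, length_range=(80, 160),
                positive_bias=bias, motif_noise=noise, seed=seed,
            )
            pos, neg, _ = generate(cfg)
            X, _, _ = encode_sequences(pos + neg, spec)
            y = np.array([1] * 40 + [0] * 40)
            pooled, _ = cross_validate(X, y, 32.0, 1 / spec.n_features, svm)
            return pooled.acc

        seeds = [101, 102, 103]
        levels = [0.0, 0.2, 0.5]
        means = [np.mean([cv_acc(b, 0.0, s) for s in seeds]) for b in levels]
        assert means[0] <= means[1] + 0.05 and means[1] <= means[2] + 0.05
        null = np.mean([cv_acc(0.0, 1.0, s) for s in seeds])
        se = np.sqrt(0.25 / 80) / np.sqrt(len(seeds))
        assert abs(null - 0.5) <= 3 * np.sqrt(0.25 / 80)  # per-run binomial SE


class TestIdentityFilter:
    def test_exact_duplicates_collapse(self):
        kept = identity_filter([("a", "ACDEF"), ("b", "ACDEF")], 0.5)
        assert [sid for sid, _ in kept] == ["a"]

    def test_threshold_one_removes_only_exact_duplicates(self):
        records = [("a", "ACDEFGHIK"), ("prefix", "ACDEF"), ("dup", "ACDEFGHIK")]
        kept = identity_filter(records, 1.0)
        assert [sid for sid, _ in kept] == ["a", "prefix"]

    def test_random_distinct_sequences_all_retained(self, rng):
        # uniform background: expected pairwise identity ~ 1/20 << 0.5
        records = [
            (f"s{i}", "".join(rng.choice(list(CANONICAL), size=50)))
            for i in range(50)
        ]
        assert len(identity_filter(records, 0.5)) == 50

    def test_near_identical_pair_collapses(self):
        a = "ACDEFGHIKL" * 3
        b = a[:-1] + "W"  # 29/30 identity
        kept = identity_filter([("a", a), ("b", b)], 0.5)
        assert [sid for sid, _ in kept] == ["a"]

    def test_empty_input_rejected(self):
        with pytest.raises(DatasetError):
            identity_filter([], 0.5)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ConfigError):
            identity_filter([("a", "ACD")], 0.0)

    def test_pairwise_identity_uses_shorter_length(self):
        assert pairwise_identity("ACDEF", "ACD") == 1.0
        assert pairwise_identity("ACDEF", "ACW") == pytest.approx(2 / 3)
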