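"""Fixed pattern set, bias fitting, and the ppv/pnv feature doubling."""

import numpy as np
import pytest

from neurofp import (
    FittedMiniRocket,
    MiniRocketConfig,
    TrialSet,
    enumerate_patterns,
    fit,
    minirocket_features,
)

from conftest import random_trialset
from naive import naive_minirocket_features


def zero_trialset(n_trials=3, n_regions=2, n_samples=40):
    return TrialSet(
        data=np.zeros((n_trials, n_regions, n_samples)),
        labels=np.array([f"s{i}" for i in range(n_trials)], dtype=object),
        duration=n_samples / 100.0,
        sampling_rate=100.0,
    )


class TestPatterns:
    def test_enumeration_is_the_84_three_high_tap_vectors(self):
        pats = enumerate_patterns()
        assert len(pats) == 84  # C(9, 3) by brute-force enumeration
        seen = set()
        for p in pats:
            w = p.weights
            assert len(w) == 9
            assert sorted(set(w.tolist())) == [-1.0, 2.0]
            assert np.sum(w == 2.0) == 3
            assert w.sum() == 0.0
            seen.add(tuple(w.tolist()))
        assert len(seen) == 84  # each exactly once
        assert pats[0].positions == (0, 1, 2)  # lexicographic ordering


class TestFit:
    def test_budget_accounting_and_every_pattern_used(self, rng):
        trials = random_trialset(rng, n_trials=4, n_regions=3, n_samples=120)
        fitted = fit(trials, MiniRocketConfig(num_features=840, seed=3))
        assert fitted.num_features == 840
        expected_biases = sum((int(n) + 1) // 2 for n in fitted.features_per_combo)
        assert sum(len(b) for b in fitted.biases) == expected_biases
        used_patterns = {c.pattern_id for c, n in zip(fitted.combos, fitted.features_per_combo) if n > 0}
        assert used_patterns == set(range(84))
        assert all(np.isfinite(b).all() for b in fitted.biases)

    def test_dilation_cap_respected(self, rng):
        trials = random_trialset(rng, n_trials=2, n_regions=2, n_samples=500)
        fitted = fit(trials, MiniRocketConfig(num_features=8400, seed=1))
        per_pattern = {}
        for c in fitted.combos:
            per_pattern.setdefault(c.pattern_id, set()).add(c.dilation)
        assert max(len(v) for v in per_pattern.values()) <= 32
        for c in fitted.combos:
            assert (9 - 1) * c.dilation < trials.samples_per_trial

    def test_fit_is_deterministic(self, rng):
        trials = random_trialset(rng, n_trials=3, n_regions=2, n_samples=60)
        f1 = fit(trials, MiniRocketConfig(num_features=168, seed=11))
        f2 = fit(trials, MiniRocketConfig(num_features=168, seed=11))
        assert f1.combos == f2.combos
        for b1, b2 in zip(f1.biases, f2.biases):
            assert np.array_equal(b1, b2)

    def test_all_zero_training_gives_zero_biases_and_features(self):
        trials = zero_trialset()
        fitted = fit(trials, MiniRocketConfig(num_features=168, seed=0))
        assert all(np.all(b == 0.0) for b in fitted.biases)
        feats = minirocket_features(trials, fitted)
        assert np.all(feats.values == 0.0)  # strict positivity: 0 - 0 is not > 0

    def test_invalid_inputs_rejected(self, rng):
        trials = random_trialset(rng, n_trials=3, n_regions=2, n_samples=60)
        with pytest.raises(ValueError):
            MiniRocketConfig(num_features=50)
        with pytest.raises(ValueError):
            MiniRocketConfig(num_features=168, max_dilations_per_kernel=40)
        empty = TrialSet(data=np.zeros((0, 2, 60)), labels=np.array([], dtype=object),
                         duration=0.6, sampling_rate=100.0)
        with pytest.raises(ValueError):
            fit(empty, MiniRocketConfig(num_features=168))


class TestTransform:
    def test_shape_contract(self, rng):
        trials = random_trialset(rng, n_trials=30, n_regions=3, n_samples=100)
        fitted = fit(trials, MiniRocketConfig(num_features=840, seed=5))
        feats = minirocket_features(trials, fitted)
        assert feats.values.shape == (30, 840)
        assert feats.values.min() >= 0.0 and feats.values.max() <= 1.0

    def test_pnv_doubling_identity_on_tie_free_inputs(self, rng):
        trials = random_trialset(rng, n_trials=6, n_regions=2, n_samples=80)
        # 2 features per combo -> every feature has a (ppv, pnv) partner
        fitted = fit(trials, MiniRocketConfig(num_features=336, max_dilations_per_kernel=2, seed=7))
        feats = minirocket_features(trials, fitted)
        names = feats.feature_names
        assert sum(n.endswith("_pnv") for n in names) == 168
        # continuous Gaussian data: ties with the bias have probability 0
        for j in range(0, feats.values.shape[1], 2):
            assert names[j].endswith("_ppv") and names[j + 1].endswith("_pnv")
            assert np.allclose(feats.values[:, j + 1], 1.0 - feats.values[:, j], atol=1e-12)

    def test_matches_explicit_two_pass_oracle(self, rng):
        trials = random_trialset(rng, n_trials=4, n_regions=3, n_samples=64)
        fitted = fit(trials, MiniRocketConfig(num_features=168, max_dilations_per_kernel=2, seed=13))
        fast = minirocket_features(trials, fitted).values
        slow, ties = naive_minirocket_features(trials.data, fitted)
        assert np.max(np.abs((fast - slow)[~ties])) < 1e-9
        assert ties.mean() < 0.05  # exact bias ties are rare on continuous data

    def test_transform_deterministic_and_serializable(self, rng, tmp_path):
        trials = random_trialset(rng, n_trials=5, n_regions=2, n_samples=60)
        fitted = fit(trials, MiniRocketConfig(num_features=168, seed=21))
        f1 = minirocket_features(trials, fitted).values
        fitted.to_json(tmp_path / "mr.json")
        reloaded = FittedMiniRocket.from_json(tmp_path / "mr.json")
        f2 = minirocket_features(trials, reloaded).values
        assert np.array_equal(f1, f2)

    def test_shape_mismatch_rejected(self, rng):
        trials = random_trialset(rng, n_trials=3, n_regions=2, n_samples=60)
        other = random_trialset(rng, n_trials=3, n_regions=2, n_samples=59)
        fitted = fit(trials, MiniRocketConfig(num_features=168, seed=0))
        with pytest.raises(ValueError):
            minirocket_features(other, fitted)
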