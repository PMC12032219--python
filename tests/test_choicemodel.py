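import math

import numpy as np
import pytest

from forageworld import choicemodel
from forageworld.choicemodel import MODEL_SPECS, WeightVector
from forageworld.features import ChoiceRecord, standardize_columns


def _weights(spec, w=0.0, alpha=0.0):
    return WeightVector(
        w={f: w for f in spec.feature_set}, alpha={f: alpha for f in spec.dynamic_map}
    )


def test_dynamic_weight_arithmetic():
    assert choicemodel.dynamic_weight(1.0, -0.5, 1.0) == pytest.approx(0.5)
    for dt in (-2.0, 0.0, 3.5):
        assert choicemodel.dynamic_weight(0.7, 0.0, dt) == pytest.approx(0.7)
    vals = [choicemodel.dynamic_weight(1.0, -0.4, dt) for dt in (0.0, 0.5, 1.0, 2.0)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_registry_covers_eight_models():
    assert set(MODEL_SPECS) == {
        "Asocial", "Unbiased", "SuccessBiased", "PlayerSpecific",
        "ARS", "Critical", "Conditional", "ARSCond",
    }
    assert MODEL_SPECS["ARS"].dynamic_map == {"locality": choicemodel.CLOCK_INDIVIDUAL}
    assert MODEL_SPECS["Critical"].dynamic_map == {"reward_prediction": choicemodel.CLOCK_SOCIAL}
    assert set(MODEL_SPECS["ARSCond"].dynamic_map) == {
        "locality", "successful_proximity", "unsuccessful_proximity",
    }
    for name in ("Asocial", "Unbiased", "SuccessBiased", "PlayerSpecific"):
        assert not MODEL_SPECS[name].is_dynamic


def test_zero_weights_uniform():
    recs = choicemodel.synthesize_records(20, 7, seed=0)
    spec = MODEL_SPECS["SuccessBiased"]
    ll = choicemodel.choice_loglikelihood(recs, spec, _weights(spec))
    assert ll == pytest.approx(20 * math.log(1 / 7))


def test_probabilities_sum_to_one():
    recs = choicemodel.synthesize_records(10, 12, seed=1)
    spec = MODEL_SPECS["ARSCond"]
    wv = _weights(spec, w=0.8, alpha=-0.3)
    for r in recs:
        p = np.exp(choicemodel.choice_logprobs(spec, wv, r))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_softmax_shift_invariance():
    recs = choicemodel.synthesize_records(15, 8, seed=2)
    spec = MODEL_SPECS["Asocial"]
    wv = _weights(spec, w=1.3)
    base = choicemodel.choice_loglikelihood(recs, spec, wv)
    for r in recs:
        r.features = dict(r.features)
        r.features["locality"] = r.features["locality"] + 5.0
    shifted = choicemodel.choice_loglikelihood(recs, spec, wv)
    assert shifted == pytest.approx(base)


def test_loglikelihood_matches_enumeration_oracle():
    """Direct per-choice enumeration of exp(f.w)/sum exp(f.w) on a 5-block toy."""
    rng = np.random.default_rng(3)
    spec = MODEL_SPECS["ARS"]
    recs = []
    for k in range(6):
        cols = standardize_columns(
            {
                "locality": rng.uniform(0, 1, 5),
                "visibility": (rng.random(5) < 0.5).astype(float),
                "reward_prediction": rng.uniform(0, 1, 5),
            }
        )
        recs.append(
            ChoiceRecord(
                k=k, time=k * 3.0, block_ids=np.arange(5), features=cols,
                chosen=int(rng.integers(5)),
                delta_t={choicemodel.CLOCK_INDIVIDUAL: float(rng.exponential(5))},
            )
        )
    choicemodel.normalize_delta_t(recs)
    wv = WeightVector(w={"locality": 0.9, "visibility": -0.2, "reward_prediction": 1.4},
                      alpha={"locality": -0.6})
    got = choicemodel.choice_loglikelihood(recs, spec, wv)
    want = 0.0
    for r in recs:
        dt = r.delta_t_norm[choicemodel.CLOCK_INDIVIDUAL]
        w_loc = 0.9 + (-0.6) * dt
        utilities = []
        for b in range(5):
            utilities.append(
                w_loc * r.features["locality"][b]
                + (-0.2) * r.features["visibility"][b]
                + 1.4 * r.features["reward_prediction"][b]
            )
        exps = [math.exp(u) for u in utilities]
        want += math.log(exps[r.chosen] / sum(exps))
    assert got == pytest.approx(want, rel=1e-12)


def test_arscond_alpha_zero_nests_successbiased():
    recs = choicemodel.synthesize_records(40, 10, seed=4)
    w = {f: 0.7 for f in MODEL_SPECS["SuccessBiased"].feature_set}
    ll_static = choicemodel.choice_loglikelihood(
        recs, MODEL_SPECS["SuccessBiased"], WeightVector(w=w)
    )
    ll_dyn = choicemodel.choice_loglikelihood(
        recs,
        MODEL_SPECS["ARSCond"],
        WeightVector(w=w, alpha={f: 0.0 for f in MODEL_SPECS["ARSCond"].dynamic_map}),
    )
    assert ll_dyn == pytest.approx(ll_static)


def test_simulate_deterministic_and_saturating():
    recs = choicemodel.synthesize_records(30, 10, seed=5)
    spec = MODEL_SPECS["Asocial"]
    strong = WeightVector(w={"locality": 10.0, "visibility": 0.0, "reward_prediction": 0.0})
    a = choicemodel.simulate_choices(recs, spec, strong, seed=9)
    b = choicemodel.simulate_choices(recs, spec, strong, seed=9)
    assert [r.chosen for r in a] == [r.chosen for r in b]
    nearest = sum(r.chosen == int(np.argmax(r.features["locality"])) for r in a)
    assert nearest >= 29  # softmax saturation picks the most local block


def test_simulate_uniform_frequencies_under_zero_weights():
    """Empirical choice frequencies of zero-weight simulation are uniform
    within 3 SE (multinomial oracle)."""
    n_draws, B = 10_000, 5
    rec = choicemodel.synthesize_records(1, B, seed=6)[0]
    spec = MODEL_SPECS["Asocial"]
    counts = np.zeros(B)
    rng_records = [rec] * n_draws
    sims = choicemodel.simulate_choices(rng_records, spec, _weights(spec), seed=11)
    for r in sims:
        counts[r.chosen] += 1
    p = 1 / B
    se = np.sqrt(p * (1 - p) * n_draws)
    assert np.all(np.abs(counts - n_draws * p) < 3 * se)


def test_chosen_outside_candidates_rejected():
    rec = choicemodel.synthesize_records(1, 4, seed=7)[0]
    rec.chosen = 10
    with pytest.raises(ValueError):
        choicemodel.choice_loglikelihood([rec], MODEL_SPECS["Asocial"], _weights(MODEL_SPECS["Asocial"]))
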