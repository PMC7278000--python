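"""Synthetic-generator fidelity, determinism, and learnability tests."""

import numpy as np
import pytest

from pgms import synthetic as syn
from pgms.data import PairedDataset
from pgms.metrics import mard


def test_dataset1_marginals_exact(dataset1):
    data, _ = dataset1
    spec = syn.dataset1_spec()
    report = syn.validate_against_spec(data, spec)
    assert report.passed, report.to_dict()
    e = (data.invasive - data.noninvasive) / data.invasive * 100
    assert len(data) == 918
    assert e.min() == pytest.approx(-221.0, abs=1e-9)
    assert e.max() == pytest.approx(61.0, abs=1e-9)
    assert abs(mard(data.invasive, data.noninvasive) - 23.9) <= 1.0


def test_dataset2_marginals_exact(dataset2):
    data, _ = dataset2
    report = syn.validate_against_spec(data, syn.dataset2_spec())
    assert report.passed, report.to_dict()
    assert len(data) == 470
    assert abs(mard(data.invasive, data.noninvasive) - 17.4) <= 1.0


def test_determinism_byte_identical():
    a = syn.generate_dataset(syn.dataset1_spec(), syn.dataset1_config(seed=9))
    b = syn.generate_dataset(syn.dataset1_spec(), syn.dataset1_config(seed=9))
    assert np.array_equal(a.invasive, b.invasive)
    assert np.array_equal(a.noninvasive, b.noninvasive)
    c = syn.generate_dataset(syn.dataset1_spec(), syn.dataset1_config(seed=10))
    assert not np.array_equal(a.noninvasive, c.noninvasive)


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_reported_mard_matches_independent_loop(seed):
    """Provenance MARD equals a brute-force per-record recomputation."""
    data = syn.generate_dataset(syn.dataset2_spec(), syn.dataset2_config(seed=seed))
    total = 0.0
    for y, x in zip(data.invasive, data.noninvasive):
        total += abs(y - x) / y * 100.0
    assert data.provenance["realized_mard"] == pytest.approx(
        total / len(data), abs=1e-9
    )


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_marginal_fidelity_across_seeds(seed):
    for spec, conf in (
        (syn.dataset1_spec(), syn.dataset1_config(seed=seed)),
        (syn.dataset2_spec(), syn.dataset2_config(seed=seed)),
    ):
        data = syn.generate_dataset(spec, conf)
        assert abs(data.provenance["realized_mard"] - spec.target_mard) <= 1.0


def test_zero_noise_zero_bias_identity():
    # the noninvasive range covers the invasive one, so nothing clips
    spec = syn.DatasetSpec(
        n_pairs=200, invasive_min=65, invasive_max=300,
        noninvasive_min=40, noninvasive_max=400,
        target_mard=23.9, signed_error_min=-221, signed_error_max=61,
    )
    config = syn.GeneratorConfig(
        bias_knots=[(spec.invasive_min, 0.0), (spec.invasive_max, 0.0)],
        noise_sigma=0.0,
        seed=4,
        anchor_pairs=[],
    )
    data = syn.generate_dataset(spec, config)
    assert np.allclose(data.invasive, data.noninvasive)
    assert mard(data.invasive, data.noninvasive) == 0.0


def test_learnable_systematic_component():
    """With sigma = 0.09 (mean absolute noise about 7 %), removing the
    true systematic component leaves a residual MARD in [5 %, 10 %]."""
    for spec, conf_fn in (
        (syn.dataset1_spec(), syn.dataset1_config),
        (syn.dataset2_spec(), syn.dataset2_config),
    ):
        config = conf_fn(seed=1)
        config.noise_sigma = 0.09
        data, truth = syn.generate_with_truth(spec, config)
        corrected = np.clip(truth.corrected(data), 1.0, None)
        residual = mard(data.invasive, corrected)
        assert 5.0 <= residual <= 10.0


def test_validation_reports_mard_failure():
    data = PairedDataset([100.0, 100.0, 100.0, 100.0, 100.0,
                          100.0, 100.0, 100.0, 100.0, 100.0],
                         [100.0] * 10)
    spec = syn.DatasetSpec(
        n_pairs=10, invasive_min=100, invasive_max=100.0001,
        noninvasive_min=100, noninvasive_max=100.0001,
        target_mard=23.9, signed_error_min=-221, signed_error_max=61,
    )
    report = syn.validate_against_spec(data, spec)
    assert not report.passed
    assert not report.checks["mard"]["passed"]
    assert report.checks["mard"]["realized"] == pytest.approx(0.0)


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda s: setattr(s, "n_pairs", 5), "n_pairs"),
        (lambda s: setattr(s, "invasive_max", 10.0), "invasive range"),
        (lambda s: setattr(s, "signed_error_min", 5.0), "straddle"),
        (lambda s: setattr(s, "target_mard", 500.0), "target MARD"),
    ],
)
def test_invalid_specs_name_the_constraint(mutate, message):
    spec = syn.dataset1_spec()
    mutate(spec)
    with pytest.raises(syn.InfeasibleSpecError, match=message):
        spec.validate()


def test_unreachable_extreme_is_infeasible():
    spec = syn.dataset1_spec()
    # an error this negative cannot fit inside both value ranges
    spec.signed_error_min = -5000.0
    with pytest.raises(syn.InfeasibleSpecError, match="unreachable"):
        syn.default_anchor_pairs(spec)


def test_anchor_outside_ranges_rejected():
    spec = syn.dataset1_spec()
    config = syn.dataset1_config(seed=1)
    config.anchor_pairs = [(500.0, 100.0)]  # reference outside 65..492
    with pytest.raises(syn.InfeasibleSpecError, match="anchor"):
        syn.generate_dataset(spec, config)


def test_clipped_records_flagged(dataset1):
    data, _ = dataset1
    rows = data.provenance["clipped_rows"]
    assert data.provenance["n_clipped"] == len(rows)
    spec = syn.dataset1_spec()
    for r in rows:
        assert data.noninvasive[r] in (spec.noninvasive_min, spec.noninvasive_max)


def test_spec_roundtrip_dict():
    spec = syn.dataset2_spec()
    assert syn.DatasetSpec.from_dict(spec.to_dict()) == spec
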