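"""Evaluation machinery: rank correlation, FDP bounds, entrapment
construction, entropy similarity and NCE calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dia_librarian.errors import ValidationError
from dia_librarian.evaluation import (
    EntrapmentCounts,
    build_entrapment_db,
    calibrate_nce,
    counts_from_paired_scores,
    estimate_fdp,
    spearman_unmasked,
    spectral_entropy_similarity,
)
from dia_librarian.fragmentation import MASK_OUT_OF_RANGE, MASK_SHARED, MASK_USE


# -- spearman ---------------------------------------------------------------


def test_spearman_perfect_and_reversed():
    obs = np.array([[0.1, 0.4, 0.2, 0.9]])
    mask = np.full_like(obs, MASK_USE, dtype=np.int8)
    assert spearman_unmasked(obs, obs, mask) == pytest.approx(1.0)
    rev = np.array([[0.9, 0.2, 0.4, 0.1]])
    assert spearman_unmasked(rev, obs, mask) == pytest.approx(-1.0)


def test_spearman_ignores_masked_cells():
    obs = np.array([[0.1, 0.4, 0.2, 0.9, 0.5]])
    pred = obs.copy()
    mask = np.full_like(obs, MASK_USE, dtype=np.int8)
    mask[0, 4] = MASK_SHARED
    pred_perturbed = pred.copy()
    pred_perturbed[0, 4] = -123.0
    assert spearman_unmasked(pred, obs, mask) == spearman_unmasked(
        pred_perturbed, obs, mask
    )


def test_spearman_undefined_below_three_cells():
    obs = np.array([[0.1, 0.4]])
    mask = np.full_like(obs, MASK_USE, dtype=np.int8)
    assert spearman_unmasked(obs, obs, mask) is None


# -- FDP bounds -------------------------------------------------------------


def test_fdp_closed_form_example():
    est = estimate_fdp(EntrapmentCounts(90, 10, 4, 3))
    assert est.upper == pytest.approx(0.20)
    assert est.lower == pytest.approx(0.10)


def test_fdp_no_entrapment_discoveries():
    est = estimate_fdp(EntrapmentCounts(50, 0, 0, 0))
    assert est.upper == 0.0 and est.lower == 0.0


def test_fdp_all_entrapments_outscore_discovered_targets():
    n_t, n_e = 70, 30
    est = estimate_fdp(EntrapmentCounts(n_t, n_e, 0, n_e))
    assert est.upper == pytest.approx(3 * n_e / (n_t + n_e))


def test_fdp_no_discoveries_undefined():
    assert estimate_fdp(EntrapmentCounts(0, 0, 0, 0)) is None


def test_invalid_counts_rejected():
    with pytest.raises(ValidationError):
        EntrapmentCounts(10, 2, 2, 1)  # partitions exceed N_E


def test_fdp_matches_brute_force_recount():
    """1,000 random paired score lists: counts and bounds agree with a
    direct per-pair recount."""
    rng = np.random.default_rng(33)
    for _ in range(1000):
        n = int(rng.integers(1, 40))
        t = rng.normal(size=n)
        e = rng.normal(size=n)
        s = float(rng.normal())
        counts = counts_from_paired_scores(t, e, s)
        # independent recount
        n_t = sum(1 for x in t if x >= s)
        n_e = sum(1 for x in e if x >= s)
        a = sum(1 for ti, ei in zip(t, e) if ei >= s and ti < s)
        b = sum(1 for ti, ei in zip(t, e) if ei >= s and ti >= s and ei > ti)
        assert (counts.n_t, counts.n_e, counts.n_e_ge_s_gt_t,
                counts.n_e_gt_t_ge_s) == (n_t, n_e, a, b)
        est = estimate_fdp(counts)
        if n_t + n_e == 0:
            assert est is None
        else:
            assert est.upper == pytest.approx((n_e + a + 2 * b) / (n_t + n_e))
            assert est.lower == pytest.approx(n_e / (n_t + n_e))
            assert est.lower <= est.upper


# -- entrapment database ----------------------------------------------------


def test_entrapment_fixed_cterm_and_permutation():
    pairs = build_entrapment_db(["PEPTIDEK"], seed=0)
    assert len(pairs) == 1
    target, entrapment = pairs[0]
    assert entrapment[-1] == "K"
    assert sorted(entrapment) == sorted(target)
    assert entrapment != target


def test_entrapment_i_to_l_and_degenerate_drop():
    pairs = build_entrapment_db(["IK"], seed=0)
    assert pairs == []  # "LK" has no distinct prefix permutation
    pairs = build_entrapment_db(["AIK"], seed=0)
    assert pairs[0][0] == "ALK"
    assert "I" not in pairs[0][1]


def test_entrapment_deterministic():
    peps = ["PEPTIDEK", "AGSTWYNR", "LVMHQFDEK"]
    assert build_entrapment_db(peps, seed=5) == build_entrapment_db(peps, seed=5)


# -- spectral entropy similarity --------------------------------------------


def test_entropy_similarity_identical_is_one():
    mz = np.array([100.0, 200.0, 300.0])
    inten = np.array([1.0, 2.0, 3.0])
    assert spectral_entropy_similarity((mz, inten), (mz, inten)) == pytest.approx(1.0)


def test_entropy_similarity_disjoint_is_zero():
    a = (np.array([100.0, 200.0]), np.array([1.0, 1.0]))
    b = (np.array([500.0, 600.0]), np.array([2.0, 1.0]))
    assert spectral_entropy_similarity(a, b) == pytest.approx(0.0, abs=1e-12)


def test_entropy_similarity_symmetric():
    rng = np.random.default_rng(2)
    a = (np.sort(rng.uniform(100, 1000, 5)), rng.uniform(0.1, 1, 5))
    b = (np.sort(rng.uniform(100, 1000, 7)), rng.uniform(0.1, 1, 7))
    assert spectral_entropy_similarity(a, b) == pytest.approx(
        spectral_entropy_similarity(b, a)
    )


def test_entropy_similarity_empty_undefined():
    a = (np.array([]), np.array([]))
    b = (np.array([100.0]), np.array([1.0]))
    assert spectral_entropy_similarity(a, b) is None


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    mz_a=st.lists(st.floats(100, 2000), min_size=1, max_size=10, unique=True),
    mz_b=st.lists(st.floats(100, 2000), min_size=1, max_size=10, unique=True),
    data=st.data(),
)
def test_entropy_similarity_bounded(mz_a, mz_b, data):
    """Similarity lies in [0, 1] for all non-negative spectra pairs."""
    int_a = data.draw(st.lists(st.floats(1e-6, 1e6), min_size=len(mz_a),
                               max_size=len(mz_a)))
    int_b = data.draw(st.lists(st.floats(1e-6, 1e6), min_size=len(mz_b),
                               max_size=len(mz_b)))
    sim = spectral_entropy_similarity(
        (np.sort(mz_a), np.array(int_a)), (np.sort(mz_b), np.array(int_b))
    )
    assert sim is not None and 0.0 <= sim <= 1.0


# -- NCE calibration --------------------------------------------------------


def _constant_model_examples():
    """A stub model whose predictions do not depend on NCE, plus a couple
    of observed examples — medians tie across the grid."""
    from dia_librarian.models import TrainedModel, IntensityModelConfig, _Mlp
    from dia_librarian.models import encode_intensity_rows
    from dia_librarian.fragmentation import layout_for_mode
    from dia_librarian.io_formats import Peptidoform
    from dia_librarian.training_data import IntensityExample

    layout = layout_for_mode("global")
    pf = Peptidoform("PEPTIDEK")
    d = encode_intensity_rows(pf, 2, 27.0, "Lumos", ("Lumos",)).shape[1]
    net = _Mlp([d, len(layout)], np.random.default_rng(0))
    net.params[0][0][:] = 0.0
    net.params[0][1][:] = [1.0, 0.5, 0.8, 0.3]
    model = TrainedModel("intensity", net, IntensityModelConfig(), [0.1],
                         layout, ("Lumos",))
    target = np.tile([1.0, 0.5, 0.8, 0.3], (len(pf) - 1, 1))
    mask = np.full_like(target, MASK_USE, dtype=np.int8)
    ex = IntensityExample(pf, 2, 27.0, "Lumos", layout, target, mask)
    return model, [ex]


def test_calibrate_single_point_grid():
    model, examples = _constant_model_examples()
    res = calibrate_nce(model, examples, grid=[28])
    assert res.optimal_nce == 28.0


def test_calibrate_tie_goes_to_lowest_nce():
    model, examples = _constant_model_examples()
    res = calibrate_nce(model, examples, grid=range(20, 41))
    assert len(set(np.round(res.median_similarity, 12))) == 1
    assert res.optimal_nce == 20.0
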