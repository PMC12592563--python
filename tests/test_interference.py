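"""Shared-peak detection: smoothing, apex selection, shape scoring and
the two labeling routes."""

import numpy as np
import pytest

from dia_librarian.errors import DataError
from dia_librarian.fragmentation import match_peaks
from dia_librarian.interference import (
    InterferenceConfig,
    Xic,
    combine_labels,
    extract_xic,
    peak_shape_score,
    peptide_centric_labels,
    select_apex_spectrum,
    smooth_xic,
    spectrum_centric_labels,
)
from dia_librarian.io_formats import DetectionRecord, Peptidoform


def _xic(values, t0=0.0, dt=0.05):
    v = np.asarray(values, float)
    return Xic(t0 + dt * np.arange(len(v)), v)


# -- smoothing --------------------------------------------------------------


def test_savgol_preserves_constant_and_linear():
    const = _xic(np.full(9, 3.5))
    assert np.allclose(smooth_xic(const).values, 3.5)
    ramp = _xic(np.arange(9, dtype=float))
    assert np.allclose(smooth_xic(ramp).values, ramp.values, atol=1e-9)


def test_wma_spike_spread():
    spike = _xic([0, 0, 4, 0, 0])
    out = smooth_xic(spike, method="weighted_moving_average")
    assert np.allclose(out.values, [0, 1, 2, 1, 0])


def test_savgol_window_clipped_to_series_length():
    short = _xic([1.0, 2.0, 1.0])
    out = smooth_xic(short, window=7)
    assert out.values.shape == (3,)


# -- apex selection and XIC extraction --------------------------------------


def _record_at(mz, apex, start, stop):
    return DetectionRecord(
        peptidoform=Peptidoform("PEPTIDEK"), charge=2, q_value=0.001,
        apex_rt=apex, rt_start=start, rt_stop=stop, precursor_mz=mz,
    )


def test_select_apex_nearest_and_tie_earlier(tiny_sim):
    run = tiny_sim.run
    (low, high), idx = next(iter(run.window_index.items()))
    mz = (low + high) / 2
    rts = [run.spectra[i].rt for i in idx]
    # exactly on a cycle
    rec = _record_at(mz, rts[3], rts[2], rts[4])
    assert select_apex_spectrum(run, rec) == idx[3]
    # midway between two cycles -> earlier one
    mid = (rts[3] + rts[4]) / 2
    rec = _record_at(mz, mid, rts[2], rts[5])
    assert select_apex_spectrum(run, rec) == idx[3]


def test_select_apex_outside_all_windows(tiny_sim):
    rec = _record_at(5000.0, 1.0, 0.5, 1.5)
    with pytest.raises(DataError):
        select_apex_spectrum(tiny_sim.run, rec)


def test_extract_xic_matches_generated_profile(noisefree_sim):
    """On a noise-free run the XIC reproduces the Gaussian elution
    profile samples exactly."""
    cfg, truth, sim, pairs = noisefree_sim
    pid = 0
    rec = sim.report[pid]
    ann, _ = pairs[pid]
    cells = np.argwhere(ann.matched_peak >= 0)
    row, col = cells[np.argmax([ann.intensity[r, c] for r, c in cells])]
    xic = extract_xic(sim.run, float(ann.fragment_mz[row, col]), rec)
    assert xic.times.size >= 3
    sigma = (cfg.elution_fwhm / 2.354820045) / 60.0
    apex_val = xic.values.max()
    expected = apex_val * np.exp(
        -((xic.times - rec.apex_rt) ** 2) / (2 * sigma**2)
    ) / np.exp(-((xic.times[np.argmax(xic.values)] - rec.apex_rt) ** 2) / (2 * sigma**2))
    assert np.allclose(xic.values, expected, rtol=1e-6)


def test_extract_xic_nothing_matches(tiny_sim):
    rec = tiny_sim.report[0]
    xic = extract_xic(tiny_sim.run, 1234.56789, rec)
    assert (xic.values == 0).all()


# -- peak shape score -------------------------------------------------------


def _gaussian(n=13, sigma=2.0, center=None, amp=1.0):
    x = np.arange(n, dtype=float)
    c = (n - 1) / 2 if center is None else center
    return amp * np.exp(-((x - c) ** 2) / (2 * sigma**2))


def test_shape_score_contained_gaussian_is_zero():
    """A peak fully contained in its boundaries returns to ~5% of apex at
    both ends: neither boundary criterion can fire."""
    g = _xic(_gaussian(13, sigma=2.2))
    others = [_xic(_gaussian(13, sigma=2.2, amp=a)) for a in (1.0, 0.8, 0.6)]
    assert peak_shape_score(g, others) == 0


def test_shape_score_plateau_is_two():
    plateau = _xic(np.full(9, 5.0))
    others = [_xic(_gaussian(9, sigma=1.5, amp=a)) for a in (1.0, 0.9, 0.8)]
    assert peak_shape_score(plateau, others + [plateau]) == 2


def test_shape_score_one_sided_shoulder_is_one():
    v = _gaussian(11, sigma=1.8)
    v[-3:] = [0.6, 0.7, 0.8]  # fails to come down on the right only
    shoulder = _xic(v)
    others = [_xic(_gaussian(11, sigma=1.8, amp=a)) for a in (1.0, 0.9, 0.8)]
    assert peak_shape_score(shoulder, others + [shoulder]) == 1


# -- peptide-centric labels -------------------------------------------------


def _cells_xics(profiles):
    return {(i, 0): _xic(p) for i, p in enumerate(profiles)}


def test_scaled_profiles_not_shared():
    """Correlation is scale-invariant: pure rescalings of one profile are
    never flagged by the correlation clause."""
    base = _gaussian(13, sigma=2.2)
    xics = _cells_xics([base, 0.5 * base, 0.1 * base, 2.0 * base])
    labels = peptide_centric_labels(xics, InterferenceConfig(), (4, 1))
    assert not labels.any()


def test_shifted_contaminant_flagged():
    base = _gaussian(15, sigma=2.0)
    contaminated = base + 1.5 * _gaussian(15, sigma=2.0, center=11.5)
    xics = _cells_xics([base, base * 0.7, base * 0.4, contaminated])
    labels = peptide_centric_labels(xics, InterferenceConfig(), (4, 1))
    assert labels[3, 0]
    assert not labels[0, 0] and not labels[1, 0]


def test_top_fragment_never_shared_by_correlation():
    base = _gaussian(15, sigma=2.0)
    noisy = [base + 0.02 * np.sin(np.arange(15) + k) for k in range(4)]
    xics = _cells_xics(noisy)
    labels = peptide_centric_labels(xics, InterferenceConfig(), (4, 1))
    # identify top-scoring fragment as the implementation does
    from dia_librarian.interference import smooth_xic as _s

    sm = [_s(x).values for x in xics.values()]
    corr = np.corrcoef(np.vstack(sm))
    top = int(np.argmax(corr.sum(axis=1) - 1))
    assert corr[top, top] == pytest.approx(1.0)
    # the top fragment can only be flagged via the shape clause
    if labels[top, 0]:
        assert peak_shape_score(_s(list(xics.values())[top]), [_s(x) for x in xics.values()]) == 2


def test_constant_trace_conservatively_shared():
    base = _gaussian(13, sigma=2.0)
    xics = _cells_xics([base, 0.8 * base, np.full(13, 2.0)])
    labels = peptide_centric_labels(xics, InterferenceConfig(), (3, 1))
    assert labels[2, 0]


# -- spectrum-centric labels ------------------------------------------------


def _annotate_pair(spec_peptides, spectrum):
    """Annotate several peptides against one spectrum."""
    anns = []
    for pf, z in spec_peptides:
        rec = DetectionRecord(
            peptidoform=pf, charge=z, q_value=0.001, apex_rt=spectrum.rt,
            rt_start=spectrum.rt - 0.3, rt_stop=spectrum.rt + 0.3,
            precursor_mz=(spectrum.iso_low + spectrum.iso_high) / 2,
        )
        anns.append(match_peaks(spectrum, rec, tol_ppm=10.0))
    return anns


def test_two_peptides_sharing_a_peak(tiny_sim):
    from dia_librarian.fragmentation import fragment_mz
    from dia_librarian.io_formats import CentroidSpectrum

    pf_a = Peptidoform("PEPTIDEK")
    pf_b = Peptidoform("EPPTIDEK")  # y6..y1 identical suffix, shared peaks
    mz_shared = fragment_mz(pf_a, "y", 4, 1)
    spec = CentroidSpectrum(
        mz=np.array([mz_shared]), intensity=np.array([10.0]), rt=10.0,
        iso_low=400.0, iso_high=424.0, scan_low=100.0, scan_high=2000.0,
    )
    anns = _annotate_pair([(pf_a, 2), (pf_b, 2)], spec)
    labels = spectrum_centric_labels({0: anns})
    a, b = labels[(0, 0)], labels[(0, 1)]
    assert a.any() and b.any()


def test_sole_peptide_has_no_spectrum_centric_labels(tiny_sim):
    cfg, truth, sim, pairs = (None, None, tiny_sim, None)
    from dia_librarian.io_formats import CentroidSpectrum
    from dia_librarian.fragmentation import fragment_mz

    pf = Peptidoform("PEPTIDEK")
    spec = CentroidSpectrum(
        mz=np.array([fragment_mz(pf, "y", 3, 1)]), intensity=np.array([5.0]),
        rt=10.0, iso_low=400.0, iso_high=424.0, scan_low=100.0, scan_high=2000.0,
    )
    anns = _annotate_pair([(pf, 2)], spec)
    labels = spectrum_centric_labels({0: anns})
    assert not labels[(0, 0)].any()


def test_same_mz_in_different_spectra_not_shared():
    """The spectrum-centric route is scoped per spectrum."""
    from dia_librarian.io_formats import CentroidSpectrum
    from dia_librarian.fragmentation import fragment_mz

    pf_a, pf_b = Peptidoform("PEPTIDEK"), Peptidoform("EPPTIDEK")
    mz = fragment_mz(pf_a, "y", 4, 1)
    spec1 = CentroidSpectrum(np.array([mz]), np.array([5.0]), 10.0,
                             400.0, 424.0, 100.0, 2000.0)
    spec2 = CentroidSpectrum(np.array([mz]), np.array([6.0]), 10.1,
                             400.0, 424.0, 100.0, 2000.0)
    anns1 = _annotate_pair([(pf_a, 2)], spec1)
    anns2 = _annotate_pair([(pf_b, 2)], spec2)
    labels = spectrum_centric_labels({0: anns1, 1: anns2})
    assert not labels[(0, 0)].any()
    assert not labels[(1, 0)].any()


# -- label combination ------------------------------------------------------


@pytest.mark.parametrize(
    "sc,pc,amb,expected",
    [(True, False, False, True), (False, False, False, False),
     (False, False, True, True), (False, True, False, True)],
)
def test_combine_labels_union(sc, pc, amb, expected):
    shape = (2, 4)
    mk = lambda flag: np.full(shape, flag)
    labels = combine_labels(mk(sc), mk(pc), mk(amb))
    assert labels.shared.all() == expected
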