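"""Shared (interfered) fragment-peak detection in chimeric DIA spectra.

Two complementary routes label a matched fragment peak as shared:

* **spectrum-centric** — within one MS2 spectrum, a peak matched by
  fragments of two or more different detected peptides is shared;
* **peptide-centric** — for one peptide's fragments, extracted ion
  chromatograms (XICs) over the precursor's peak boundaries are smoothed
  and correlated; a fragment whose Pearson correlation to the top-scoring
  fragment falls below a threshold (default 0.8) is shared, and a
  well-correlated fragment whose peak shape fails to return to baseline at
  both boundaries (peak-shape score 2) is shared too.

The final label is the union of the two routes plus within-peptide
ambiguous matches (one peak claimed by two fragment ions of the same
peptide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigurationError, DataError, InternalError
from .fragmentation import AnnotatedSpectrum, match_peaks
from .io_formats import DetectionRecord, DiaRun

logger = logging.getLogger(__name__)


@dataclass
class Xic:
    """One fragment's intensity trace across the spectra covering the
    precursor's isolation window within its peak boundaries."""

    times: np.ndarray  # minutes, strictly increasing
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InternalError("XIC times not strictly increasing")

    @property
    def scorable(self) -> bool:
        return self.times.size >= 3 and float(np.ptp(self.values)) > 0.0


@dataclass
class SharedPeakLabels:
    """Per-cell boolean matrices for each detection route and their union."""

    spectrum_centric: np.ndarray
    peptide_centric: np.ndarray
    ambiguous: np.ndarray
    shared: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (
            self.spectrum_centric.shape
            == self.peptide_centric.shape
            == self.ambiguous.shape
        ):
            raise InternalError("label matrices have mismatched shapes")
        self.shared = self.spectrum_centric | self.peptide_centric | self.ambiguous


@dataclass
class InterferenceConfig:
    """Knobs for annotation and shared-peak detection."""

    tol_ppm: float = 10.0
    corr_threshold: float = 0.8
    smoothing: str = "savitzky_golay"  # or "weighted_moving_average"
    sg_window: int = 5
    sg_order: int = 2
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.smoothing not in ("savitzky_golay", "weighted_moving_average"):
            raise ConfigurationError(f"unknown smoothing method {self.smoothing!r}")
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ConfigurationError("Savitzky-Golay window must be odd and >= 3")
        if self.sg_order >= self.sg_window:
            raise ConfigurationError("Savitzky-Golay order must be below the window")


# ---------------------------------------------------------------------------
# apex spectrum and XIC extraction
# ---------------------------------------------------------------------------


def select_apex_spectrum(run: DiaRun, record: DetectionRecord) -> int:
    """Index of the covering spectrum whose RT is nearest the apex.

    Ties are broken toward the earlier spectrum.
    """
    idx = run.covering(record.precursor_mz)
    if not idx:
        raise DataError(
            f"precursor m/z {record.precursor_mz:.4f} outside every isolation window"
        )
    rts = np.array([run.spectra[i].rt for i in idx])
    return idx[int(np.argmin(np.abs(rts - record.apex_rt)))]


def extract_xic(
    run: DiaRun, fragment_mz: float, record: DetectionRecord, tol_ppm: float = 10.0
) -> Xic:
    """XIC of ``fragment_mz`` over the precursor's boundaries.

    Per covering spectrum inside ``[rt_start, rt_stop]``, the value is the
    intensity of the nearest peak within the ppm tolerance, else 0.
    """
    times, values = [], []
    for i in run.covering(record.precursor_mz):
        s = run.spectra[i]
        if not record.rt_start <= s.rt <= record.rt_stop:
            continue
        v = 0.0
        if s.mz.size:
            j = int(np.searchsorted(s.mz, fragment_mz))
            best, best_err = -1, np.inf
            for cand in (j - 1, j):
                if 0 <= cand < s.mz.size:
                    err = abs(s.mz[cand] - fragment_mz)
                    if err < best_err:
                        best, best_err = cand, err
            if best >= 0 and best_err <= fragment_mz * tol_ppm * 1e-6:
                v = float(s.intensity[best])
        times.append(s.rt)
        values.append(v)
    return Xic(np.array(times), np.array(values))


def smooth_xic(xic: Xic, method: str = "savitzky_golay", window: int = 5, order: int = 2) -> Xic:
    """Smooth an XIC; the series length is preserved.

    Savitzky-Golay uses an odd window (clipped to the series length) with
    polynomial order 2 by default; the weighted moving average uses
    triangular weights (0.25, 0.5, 0.25) over a window of 3.
    """
    v = xic.values
    if method == "savitzky_golay":
        if window < 3 or window % 2 == 0:
            raise ConfigurationError("Savitzky-Golay window must be odd and >= 3")
        w = min(window, v.size if v.size % 2 == 1 else v.size - 1)
        if w <= order:
            return Xic(xic.times.copy(), v.copy())
        return Xic(xic.times.copy(), savgol_filter(v, w, order))
    if method == "weighted_moving_average":
        if v.size < 3:
            return Xic(xic.times.copy(), v.copy())
        padded = np.concatenate([v[:1], v, v[-1:]])
        out = 0.25 * padded[:-2] + 0.5 * padded[1:-1] + 0.25 * padded[2:]
        return Xic(xic.times.copy(), out)
    raise ConfigurationError(f"unknown smoothing method {method!r}")


# ---------------------------------------------------------------------------
# spectrum-centric route
# ---------------------------------------------------------------------------


def spectrum_centric_labels(
    annotations_by_spectrum: dict[int, list[AnnotatedSpectrum]],
) -> dict[tuple[int, int], np.ndarray]:
    """Label cells whose matched peak is also matched by another peptide.

    ``annotations_by_spectrum`` maps spectrum index -> annotations of all
    detected peptides matched against that spectrum. Returns a map from
    ``(spectrum index, annotation position)`` to a boolean cell matrix.
    """
    labels: dict[tuple[int, int], np.ndarray] = {}
    for spec_idx, anns in annotations_by_spectrum.items():
        claims: dict[int, set[int]] = {}
        for a_pos, ann in enumerate(anns):
            for peak in np.unique(ann.matched_peak[ann.matched_peak >= 0]):
                claims.setdefault(int(peak), set()).add(a_pos)
        for a_pos, ann in enumerate(anns):
            shared = np.zeros(ann.matched_peak.shape, dtype=bool)
            it = np.nditer(ann.matched_peak, flags=["multi_index"])
            for peak in it:
                p = int(peak)
                if p >= 0 and len(claims.get(p, ())) > 1:
                    shared[it.multi_index] = True
            labels[(spec_idx, a_pos)] = shared
    return labels


# ---------------------------------------------------------------------------
# peptide-centric route
# ---------------------------------------------------------------------------


def peak_shape_score(xic: Xic, all_xics: list[Xic]) -> int:
    """0, 1 or 2: how many peak boundaries fail to return to baseline.

    A boundary meets the criterion when the trace's intensity there
    exceeds (a) the median intensity of all detected fragment traces at
    that boundary time point and (b) a fraction of this trace's own apex
    within the boundaries — 10% normally, raised to 25% when this trace's
    apex is below half the highest apex among all detected fragments.
    """
    if xic.values.size == 0:
        return 0
    apex = float(np.max(xic.values))
    if apex <= 0:
        return 0
    max_apex = max(float(np.max(x.values)) for x in all_xics if x.values.size)
    frac = 0.10 if apex >= 0.5 * max_apex else 0.25
    score = 0
    for b in (0, -1):
        boundary_val = float(xic.values[b])
        others = [float(x.values[b]) for x in all_xics if x.values.size == xic.values.size]
        med = float(np.median(others)) if others else 0.0
        if boundary_val > med and boundary_val > frac * apex:
            score += 1
    return score


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def peptide_centric_labels(
    xics: dict[tuple[int, int], Xic],
    config: InterferenceConfig,
    shape: tuple[int, int],
) -> np.ndarray:
    """Label one precursor's cells as shared by XIC correlation.

    ``xics`` maps matrix cells to raw XICs of the matched fragments. All
    XICs are smoothed; each fragment's aggregate score is the sum of its
    Pearson correlations to all other scorable fragments; a fragment is
    shared when its correlation to the top-scoring fragment falls below
    the threshold, or when the correlation passes but the peak-shape score
    is 2. Fragments with a constant (zero-variance) trace carry no usable
    shape evidence and are conservatively labeled shared; traces shorter
    than 3 points are non-scorable and left unlabeled.
    """
    labels = np.zeros(shape, dtype=bool)
    if not xics:
        return labels
    smoothed: dict[tuple[int, int], Xic] = {
        cell: smooth_xic(x, config.smoothing, config.sg_window, config.sg_order)
        for cell, x in xics.items()
    }
    scorable = [cell for cell, x in xics.items() if x.scorable]
    for cell, x in xics.items():
        if x.times.size >= 3 and not x.scorable:
            labels[cell] = True  # constant trace: no shape evidence
    if len(scorable) < 2:
        if len(scorable) == 1:
            logger.warning("fewer than 2 scorable fragment XICs; no correlation labels")
        return labels

    vals = {c: smoothed[c].values for c in scorable}
    n = len(scorable)
    corr = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            corr[i, j] = corr[j, i] = _pearson(vals[scorable[i]], vals[scorable[j]])
    agg = corr.sum(axis=1) - 1.0  # sum over the *other* fragments
    top = int(np.argmax(agg))
    all_smoothed = [smoothed[c] for c in scorable]
    for i, cell in enumerate(scorable):
        if corr[i, top] < config.corr_threshold:
            labels[cell] = True
        elif peak_shape_score(smoothed[cell], all_smoothed) == 2:
            labels[cell] = True
    return labels


def combine_labels(
    spectrum_centric: np.ndarray, peptide_centric: np.ndarray, ambiguous: np.ndarray
) -> SharedPeakLabels:
    """Union of the routes per cell."""
    return SharedPeakLabels(spectrum_centric, peptide_centric, ambiguous)


# ---------------------------------------------------------------------------
# orchestration over a whole run
# ---------------------------------------------------------------------------


def annotate_run(
    run: DiaRun,
    report: list[DetectionRecord],
    config: InterferenceConfig | None = None,
) -> list[tuple[AnnotatedSpectrum, SharedPeakLabels]]:
    """Annotate every detected precursor at its apex spectrum and attach
    combined shared-peak labels.

    For the spectrum-centric route, each apex spectrum is annotated with
    every detected peptide whose isolation window covers it and whose peak
    boundaries span the spectrum's RT (co-eluting peptides need not have
    their own apex on that spectrum).
    """
    config = config or InterferenceConfig()

    apex_of: list[int] = [select_apex_spectrum(run, r) for r in report]

    # annotate all co-eluting detected peptides on each apex spectrum
    annotations_by_spectrum: dict[int, list[AnnotatedSpectrum]] = {}
    primary_pos: dict[tuple[int, int], int] = {}  # (record idx, spec idx) -> position
    for spec_idx in sorted(set(apex_of)):
        spec = run.spectra[spec_idx]
        anns: list[AnnotatedSpectrum] = []
        for r_idx, rec in enumerate(report):
            if not spec.iso_low <= rec.precursor_mz < spec.iso_high:
                continue
            if not rec.rt_start <= spec.rt <= rec.rt_stop:
                continue
            ann = match_peaks(spec, rec, config.tol_ppm, config.mode, spec_idx)
            if apex_of[r_idx] == spec_idx:
                primary_pos[(r_idx, spec_idx)] = len(anns)
            anns.append(ann)
        annotations_by_spectrum[spec_idx] = anns

    sc_labels = spectrum_centric_labels(annotations_by_spectrum)

    out: list[tuple[AnnotatedSpectrum, SharedPeakLabels]] = []
    for r_idx, rec in enumerate(report):
        spec_idx = apex_of[r_idx]
        a_pos = primary_pos[(r_idx, spec_idx)]
        ann = annotations_by_spectrum[spec_idx][a_pos]
        sc = sc_labels[(spec_idx, a_pos)]

        xics: dict[tuple[int, int], Xic] = {}
        for row, col in zip(*np.nonzero(ann.matched_peak >= 0)):
            xic = extract_xic(run, float(ann.fragment_mz[row, col]), rec, config.tol_ppm)
            if xic.times.size >= 3:
                xics[(int(row), int(col))] = xic
        pc = peptide_centric_labels(xics, config, ann.intensity.shape)

        out.append((ann, combine_labels(sc, pc, ann.ambiguous)))
    return out


def labels_to_table(pairs: list[tuple[AnnotatedSpectrum, SharedPeakLabels]]):
    """Diagnostic per-cell table of labels (for TSV dumps)."""
    import pandas as pd

    rows = []
    for ann, lab in pairs:
        pep = ann.record.peptidoform.to_unimod_string()
        for row in range(ann.intensity.shape[0]):
            for col, name in enumerate(ann.layout):
                if ann.matched_peak[row, col] < 0:
                    continue
                rows.append(
                    {
                        "peptidoform": pep,
                        "charge": ann.record.charge,
                        "site": row + 1,
                        "column": name,
                        "intensity": ann.intensity[row, col],
                        "spectrum_centric": bool(lab.spectrum_centric[row, col]),
                        "peptide_centric": bool(lab.peptide_centric[row, col]),
                        "ambiguous": bool(lab.ambiguous[row, col]),
                        "shared": bool(lab.shared[row, col]),
                    }
                )
    return pd.DataFrame(rows)
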