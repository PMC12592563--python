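"""Theoretical peptide/fragment masses and spectrum annotation.

The fragment-intensity matrix uses a fixed tabular layout: rows are the
L-1 backbone cleavage sites of a length-L peptide, columns are fragment
ion species with a specific charge (``b1+``, ``b2+``, ``y1+``, ``y2+``; in
phospho mode four additional columns for the -98 Da phosphoric-acid
neutral-loss variants). Row ``k`` (0-based) corresponds to cleavage after
residue ``k+1``, so it holds b_(k+1) in the b columns and y_(L-k-1) in the
y columns. Matrices are always full-shape; inapplicable cells are masked
rather than dropped.

Mask codes: 0 = use, 1 = shared (interfered), 2 = out of range /
inapplicable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import PHOSPHO_NEUTRAL_LOSS, PROTON, RESIDUE_MASS, WATER
from .errors import InternalError, ValidationError
from .io_formats import CentroidSpectrum, DetectionRecord, Peptidoform

MASK_USE = 0
MASK_SHARED = 1
MASK_OUT_OF_RANGE = 2

GLOBAL_LAYOUT = ("b1", "b2", "y1", "y2")
PHOSPHO_LAYOUT = GLOBAL_LAYOUT + ("b1-98", "b2-98", "y1-98", "y2-98")

PHOSPHO_LOSS_TAG = "-98"


def layout_for_mode(mode: str) -> tuple[str, ...]:
    if mode == "global":
        return GLOBAL_LAYOUT
    if mode == "phospho":
        return PHOSPHO_LAYOUT
    raise ValidationError(f"unknown annotation mode {mode!r}")


def parse_column(label: str) -> tuple[str, int, str]:
    """Split a layout label into (series, fragment charge, loss tag)."""
    series = label[0]
    charge = int(label[1])
    loss = PHOSPHO_LOSS_TAG if label.endswith(PHOSPHO_LOSS_TAG) else ""
    return series, charge, loss


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' | 'y'
    ordinal: int  # 1 .. L-1
    charge: int  # 1 | 2
    loss: str  # '' | '-98'
    mz: float

    @property
    def column(self) -> str:
        return f"{self.series}{self.charge}{self.loss}"


@dataclass
class AnnotatedSpectrum:
    """Per-precursor fragment matrix annotated against one MS2 spectrum."""

    record: DetectionRecord
    layout: tuple[str, ...]
    intensity: np.ndarray  # (L-1, len(layout)) observed intensity
    matched_peak: np.ndarray  # int peak index into the spectrum, -1 = unmatched
    mask: np.ndarray  # MASK_* codes
    ambiguous: np.ndarray  # bool: peak claimed by >1 fragment of this peptide
    fragment_mz: np.ndarray  # theoretical m/z per cell (nan where inapplicable)
    spectrum_index: int = -1


def _prefix_masses(pf: Peptidoform) -> np.ndarray:
    """Cumulative neutral masses of prefixes of length 1..L, mods included.

    N-terminal mods (position 0) belong to every prefix.
    """
    masses = np.array([RESIDUE_MASS[a] for a in pf.sequence], dtype=float)
    for pos, delta, _ in pf.mods:
        masses[max(pos - 1, 0)] += delta
    return np.cumsum(masses)


def peptide_mono_mass(pf: Peptidoform) -> float:
    """Monoisotopic neutral mass: residues + water + modification deltas."""
    return float(_prefix_masses(pf)[-1] + WATER)


def precursor_mz(pf: Peptidoform, charge: int) -> float:
    return (peptide_mono_mass(pf) + charge * PROTON) / charge


def fragment_mz(
    pf: Peptidoform, series: str, ordinal: int, charge: int, loss: str = ""
) -> float:
    """m/z of a b/y fragment, optionally with the -98 Da neutral loss."""
    L = len(pf)
    if not 1 <= ordinal <= L - 1:
        raise ValidationError(f"fragment ordinal {ordinal} out of range for length {L}")
    prefixes = _prefix_masses(pf)
    if series == "b":
        neutral = prefixes[ordinal - 1]
    elif series == "y":
        neutral = prefixes[-1] - prefixes[L - ordinal - 1] + WATER
    else:
        raise ValidationError(f"unknown ion series {series!r}")
    if loss == PHOSPHO_LOSS_TAG:
        neutral -= PHOSPHO_NEUTRAL_LOSS
    elif loss:
        raise ValidationError(f"unknown neutral loss {loss!r}")
    return (neutral + charge * PROTON) / charge


def _phosphosites(pf: Peptidoform) -> list[int]:
    return [pos for pos, _, name in pf.mods if name == "Phospho" and pos >= 1]


def _spans_phosphosite(series: str, ordinal: int, L: int, sites: list[int]) -> bool:
    if series == "b":
        return any(p <= ordinal for p in sites)
    return any(p > L - ordinal for p in sites)


def enumerate_fragments(
    pf: Peptidoform, precursor_charge: int, mode: str = "global"
) -> list[FragmentIon]:
    """All b/y fragments for a precursor.

    Fragment charges are {1} for singly charged precursors and {1, 2}
    otherwise. Phospho mode adds -98 Da loss variants for fragments that
    span at least one phosphosite.
    """
    L = len(pf)
    charges = (1,) if precursor_charge == 1 else (1, 2)
    sites = _phosphosites(pf) if mode == "phospho" else []
    out: list[FragmentIon] = []
    for series in ("b", "y"):
        for ordinal in range(1, L):
            for z in charges:
                out.append(
                    FragmentIon(series, ordinal, z, "", fragment_mz(pf, series, ordinal, z))
                )
                if mode == "phospho" and _spans_phosphosite(series, ordinal, L, sites):
                    out.append(
                        FragmentIon(
                            series,
                            ordinal,
                            z,
                            PHOSPHO_LOSS_TAG,
                            fragment_mz(pf, series, ordinal, z, PHOSPHO_LOSS_TAG),
                        )
                    )
    return out


def cell_of(frag: FragmentIon, L: int, layout: tuple[str, ...]) -> tuple[int, int]:
    """(row, column) of a fragment in the intensity matrix."""
    row = frag.ordinal - 1 if frag.series == "b" else L - frag.ordinal - 1
    return row, layout.index(frag.column)


def match_peaks(
    spectrum: CentroidSpectrum,
    record: DetectionRecord,
    tol_ppm: float = 10.0,
    mode: str = "global",
    spectrum_index: int = -1,
) -> AnnotatedSpectrum:
    """Match theoretical fragments to the nearest peak within ``tol_ppm``.

    Unmatched in-range cells keep intensity 0. Cells whose theoretical m/z
    falls outside the spectrum's acquired scan range, charge-2 columns for
    singly charged precursors, and loss columns for fragments that do not
    span a phosphosite are masked ``MASK_OUT_OF_RANGE``. A spectrum peak
    claimed by more than one fragment of this peptide marks all its cells
    ambiguous.
    """
    if spectrum.mz.size > 1 and not np.all(np.diff(spectrum.mz) > 0):
        raise InternalError("spectrum passed to match_peaks is unsorted")
    pf = record.peptidoform
    L = len(pf)
    layout = layout_for_mode(mode)
    shape = (L - 1, len(layout))
    intensity = np.zeros(shape)
    matched = np.full(shape, -1, dtype=int)
    mask = np.full(shape, MASK_OUT_OF_RANGE, dtype=np.int8)
    ambiguous = np.zeros(shape, dtype=bool)
    frag_mz = np.full(shape, np.nan)

    fragments = enumerate_fragments(pf, record.charge, mode)
    peak_claims: dict[int, list[tuple[int, int]]] = {}
    for frag in fragments:
        row, col = cell_of(frag, L, layout)
        frag_mz[row, col] = frag.mz
        if not spectrum.scan_low <= frag.mz <= spectrum.scan_high:
            continue  # stays out_of_range
        mask[row, col] = MASK_USE
        if spectrum.mz.size == 0:
            continue
        j = int(np.searchsorted(spectrum.mz, frag.mz))
        best, best_err = -1, np.inf
        for cand in (j - 1, j):
            if 0 <= cand < spectrum.mz.size:
                err = abs(spectrum.mz[cand] - frag.mz)
                if err < best_err:
                    best, best_err = cand, err
        if best >= 0 and best_err <= frag.mz * tol_ppm * 1e-6:
            intensity[row, col] = spectrum.intensity[best]
            matched[row, col] = best
            peak_claims.setdefault(best, []).append((row, col))

    for cells in peak_claims.values():
        if len(cells) > 1:
            for row, col in cells:
                ambiguous[row, col] = True

    return AnnotatedSpectrum(
        record=record,
        layout=layout,
        intensity=intensity,
        matched_peak=matched,
        mask=mask,
        ambiguous=ambiguous,
        fragment_mz=frag_mz,
        spectrum_index=spectrum_index,
    )
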