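"""Deterministic simulator for DIA runs with known fragment interference.

The simulator provides the full chain the pipeline consumes — a FASTA
proteome, a ground-truth fragmentation/elution process, a DIA run of
wide-window centroided MS2 spectra, and a matching detection report — so
every downstream stage is testable without external data.

The ground truth is a smooth deterministic surrogate for the unknown true
fragmentation and elution processes: fragment intensities are a function
of the residues flanking each cleavage site, the relative cleavage
position, precursor charge, and NCE; retention time is a logistic
function of mean residue hydrophobicity and length. Both are therefore
learnable by the context/composition networks in :mod:`.models`.

Peptides elute as Gaussian profiles over consecutive DIA cycles. With
probability ``interference_rate`` a fragment peak additionally receives a
co-eluting contaminant trace at the same m/z with a shifted apex — the
kind of interference the shared-peak detectors must find. Chance m/z
collisions between co-isolated detected peptides are also genuine
interference; they are labeled and counted separately, and give the
spectrum-centric route its true positives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import CANONICAL_AA, PROTON
from .errors import ConfigurationError, DataError
from .fragmentation import (
    cell_of,
    enumerate_fragments,
    layout_for_mode,
    peptide_mono_mass,
)
from .io_formats import CentroidSpectrum, DetectionRecord, DiaRun, Peptidoform

# Kyte-Doolittle hydropathy scaled to [-1, 1]: the per-residue coefficient
# behind both ground-truth rules.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
RESIDUE_COEF = {a: v / 4.5 for a, v in _KD.items()}

_MERGE_PPM = 10.0  # centroiding merge width for coinciding sticks
_NEAR_COLLISION_PPM = 25.0  # bookkeeping window for near-collisions
_TRACE_TRUNCATION_SIGMA = 4.0
_BOUNDARY_FRACTION = 0.05  # peak boundaries reported at 5% of apex height


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimConfig:
    """Study conditions of a simulated DIA experiment."""

    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (80, 160)
    isolation_window_width: float = 24.0  # m/z
    precursor_mz_range: tuple[float, float] = (400.0, 1000.0)
    fragment_scan_range: tuple[float, float] = (200.0, 1700.0)
    gradient_minutes: float = 30.0
    cycle_time: float = 3.0  # seconds
    elution_fwhm: float = 18.0  # seconds
    interference_rate: float = 0.0
    noise_sd: float = 0.02  # relative (multiplicative) intensity noise
    nce: float = 27.0
    instrument: str = "Lumos"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.interference_rate <= 1.0:
            raise ConfigurationError("interference_rate must lie in [0, 1]")
        for name, (lo, hi) in (
            ("protein_length_range", self.protein_length_range),
            ("precursor_mz_range", self.precursor_mz_range),
            ("fragment_scan_range", self.fragment_scan_range),
        ):
            if not lo < hi:
                raise ConfigurationError(f"degenerate {name}: ({lo}, {hi})")
        if min(self.isolation_window_width, self.gradient_minutes,
               self.cycle_time, self.elution_fwhm) <= 0:
            raise ConfigurationError("widths and times must be positive")


@dataclass
class GroundTruthModel:
    """Deterministic fragmentation + elution surrogate."""

    gradient_minutes: float = 30.0
    residue_params: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_COEF))

    def _coefs(self, pf: Peptidoform) -> np.ndarray:
        c = np.array([self.residue_params[a] for a in pf.sequence])
        for pos, delta, _ in pf.mods:
            c[max(pos - 1, 0)] += delta / 200.0
        return c

    def intensity_matrix(self, pf: Peptidoform, charge: int, nce: float,
                         mode: str = "global") -> np.ndarray:
        """Fragment intensities in [0, 1] with max exactly 1."""
        if len(pf) < 2:
            raise ConfigurationError("need peptide length >= 2 for fragments")
        layout = layout_for_mode(mode)
        L = len(pf)
        c = self._coefs(pf)
        M = np.zeros((L - 1, len(layout)))
        for r in range(L - 1):
            c1, c2 = c[r], c[r + 1]
            relpos = (r + 1) / L
            f_b = math.exp(-((nce - (27.0 + 4.0 * c1)) ** 2) / (2 * 8.0**2))
            f_y = math.exp(-((nce - (29.0 - 3.0 * c2)) ** 2) / (2 * 9.0**2))
            b1 = _sigmoid(1.4 * c1 - 0.7 * c2 + 2.0 * relpos - 1.0 + 0.2 * charge) * f_b
            y1 = _sigmoid(1.1 * c2 - 0.5 * c1 + 2.2 * (1 - relpos) - 0.6 + 0.1 * charge) * f_y
            M[r, layout.index("b1")] = b1
            M[r, layout.index("y1")] = y1
            if charge >= 2:
                M[r, layout.index("b2")] = 0.45 * b1 * _sigmoid(1.5 * (charge - 1.5) + c2)
                M[r, layout.index("y2")] = 0.50 * y1 * _sigmoid(1.5 * (charge - 1.5) + c1)
        if mode == "phospho":
            from .fragmentation import _phosphosites, _spans_phosphosite

            sites = _phosphosites(pf)
            for r in range(L - 1):
                for series, parent_col, loss_col in (
                    ("b", "b1", "b1-98"), ("b", "b2", "b2-98"),
                    ("y", "y1", "y1-98"), ("y", "y2", "y2-98"),
                ):
                    ordinal = r + 1 if series == "b" else L - r - 1
                    if sites and _spans_phosphosite(series, ordinal, L, sites):
                        M[r, layout.index(loss_col)] = (
                            0.6 * M[r, layout.index(parent_col)]
                        )
        peak = M.max()
        if peak > 0:
            M /= peak
        return M

    def rt_minutes(self, pf: Peptidoform) -> float:
        """Elution time: logistic in mean hydropathy and length, always
        inside (0.06, 0.94) of the gradient."""
        c = self._coefs(pf)
        frac = 0.06 + 0.88 * _sigmoid(4.0 * float(c.mean()) + 0.02 * (len(pf) - 15))
        return self.gradient_minutes * frac


def ground_truth_intensities(pf: Peptidoform, charge: int, nce: float,
                             mode: str = "global",
                             gradient_minutes: float = 30.0) -> np.ndarray:
    """Module-level convenience over a default :class:`GroundTruthModel`."""
    return GroundTruthModel(gradient_minutes).intensity_matrix(pf, charge, nce, mode)


def generate_proteome(n_proteins: int, length_range: tuple[int, int], seed: int) -> str:
    """Random protein FASTA over the 20 canonical residues."""
    if n_proteins < 1:
        raise ConfigurationError("n_proteins must be >= 1")
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise ConfigurationError(f"invalid protein length range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    aas = np.array(list(CANONICAL_AA))
    lines = []
    for i in range(n_proteins):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aas, size=L))
        lines.append(f">SYN{i:04d} synthetic protein {i}")
        lines.extend(seq[j : j + 60] for j in range(0, L, 60))
    return "\n".join(lines) + "\n"


@dataclass
class SimulatedRun:
    """A DIA run plus everything the simulator knows about it."""

    run: DiaRun
    report: list[DetectionRecord]
    precursors: list[tuple[Peptidoform, int]]
    truth_intensities: dict[int, np.ndarray]  # precursor index -> matrix
    truth_shared: dict[tuple[int, int, int], bool]  # (precursor, row, col) -> True
    collision_cells: set[tuple[int, int, int]]
    stats: dict[str, int] = field(default_factory=dict)

    def is_shared(self, precursor: int, row: int, col: int) -> bool:
        return self.truth_shared.get((precursor, row, col), False)


@dataclass
class _Trace:
    window: int
    mz: float
    apex: float  # minutes
    sigma: float  # minutes
    amplitude: float
    precursor: int
    cell: tuple[int, int]
    is_contaminant: bool


def simulate_dia_run(
    precursors: list[tuple[Peptidoform, int]],
    ground_truth: GroundTruthModel,
    config: SimConfig,
) -> SimulatedRun:
    """Simulate DIA cycles of MS2 spectra for the given precursors.

    Each precursor elutes as a Gaussian (FWHM from the config) centred at
    its ground-truth RT; its fragments appear in the isolation window
    covering the precursor m/z across consecutive cycles. Interference is
    bursty, as in real chimeric data where crowded isolation windows and
    retention-time regions are hit much harder than quiet ones: each
    precursor draws an interference level from a Beta distribution with
    mean ``interference_rate`` (concentration 2), and each of its
    fragments then receives a contaminant trace with that probability
    (apex offset 1.2-2.5 elution sigmas, amplitude 0.8-2.0x the fragment
    apex, same width). ``truth_shared`` marks those cells.
    The report carries the apex RT, 5%-of-apex peak boundaries and
    synthetic q-values drawn uniform(0, 0.01), emulating a 1% FDR-filtered
    report.
    """
    if not precursors:
        raise ConfigurationError("simulate_dia_run requires at least one precursor")
    rng = np.random.default_rng(config.seed)

    mz_lo, mz_hi = config.precursor_mz_range
    width = config.isolation_window_width
    n_windows = int(math.ceil((mz_hi - mz_lo) / width))
    sigma_min = (config.elution_fwhm / 2.354820045) / 60.0
    half_width = math.sqrt(-2.0 * math.log(_BOUNDARY_FRACTION)) * sigma_min
    cycle_min = config.cycle_time / 60.0
    n_cycles = int(config.gradient_minutes / cycle_min)

    def spectrum_rt(cycle: int, window: int) -> float:
        return (cycle + window / n_windows) * cycle_min

    traces: list[_Trace] = []
    report: list[DetectionRecord] = []
    truth_intensities: dict[int, np.ndarray] = {}
    truth_shared: dict[tuple[int, int, int], bool] = {}
    n_contaminants = 0

    for pid, (pf, charge) in enumerate(precursors):
        prec_mz = (peptide_mono_mass(pf) + charge * PROTON) / charge
        if not mz_lo <= prec_mz < mz_hi:
            raise DataError(
                f"precursor {pf.to_unimod_string()}/{charge} m/z {prec_mz:.3f} "
                "outside the configured precursor m/z range"
            )
        window = min(int((prec_mz - mz_lo) / width), n_windows - 1)
        apex = ground_truth.rt_minutes(pf) + 0.02 * rng.standard_normal()
        apex = float(np.clip(apex, half_width, config.gradient_minutes - half_width))
        amplitude = float(rng.lognormal(math.log(2e5), 0.6))
        rate = config.interference_rate
        if 0.0 < rate < 1.0:
            rate = float(rng.beta(2.0 * rate, 2.0 * (1.0 - rate)))
        M = ground_truth.intensity_matrix(pf, charge, config.nce)
        truth_intensities[pid] = M
        L = len(pf)
        layout = layout_for_mode("global")
        for frag in enumerate_fragments(pf, charge, "global"):
            row, col = cell_of(frag, L, layout)
            rel = M[row, col]
            if rel <= 0.0:
                continue
            if not config.fragment_scan_range[0] <= frag.mz <= config.fragment_scan_range[1]:
                continue
            frag_amp = amplitude * rel
            traces.append(_Trace(window, frag.mz, apex, sigma_min, frag_amp,
                                 pid, (row, col), False))
            if rng.random() < rate:
                offset = rng.choice([-1.0, 1.0]) * rng.uniform(1.2, 2.5) * sigma_min
                contam_amp = rng.uniform(0.8, 2.0) * frag_amp
                traces.append(_Trace(window, frag.mz, apex + offset, sigma_min,
                                     contam_amp, pid, (row, col), True))
                truth_shared[(pid, row, col)] = True
                n_contaminants += 1
        report.append(
            DetectionRecord(
                peptidoform=pf,
                charge=charge,
                q_value=float(rng.uniform(0.0, 0.01)),
                apex_rt=apex,
                rt_start=max(apex - half_width, 0.0),
                rt_stop=min(apex + half_width, config.gradient_minutes),
                precursor_mz=prec_mz,
            )
        )

    # chance m/z collisions between co-eluting fragment traces in one
    # window: across detected peptides, and between two fragment ions of
    # the same peptide (e.g. a b and a y ion at nearly equal m/z) — both
    # put two ions into one centroided peak
    collision_cells: set[tuple[int, int, int]] = set()
    by_window: dict[int, list[_Trace]] = {}
    for t in traces:
        if not t.is_contaminant:
            by_window.setdefault(t.window, []).append(t)
    for wtraces in by_window.values():
        wtraces.sort(key=lambda t: t.mz)
        for i, a in enumerate(wtraces):
            for b in wtraces[i + 1 :]:
                ppm = (b.mz - a.mz) / a.mz * 1e6
                if ppm > _NEAR_COLLISION_PPM:
                    break
                overlap = abs(a.apex - b.apex) <= _TRACE_TRUNCATION_SIGMA * (
                    a.sigma + b.sigma
                )
                cells = (
                    (a.precursor, a.cell[0], a.cell[1]),
                    (b.precursor, b.cell[0], b.cell[1]),
                )
                if overlap:
                    collision_cells.update(cells)
                    if ppm <= _MERGE_PPM:
                        for cell in cells:
                            truth_shared[cell] = True

    # assemble spectra: sticks per (cycle, window), then centroid-merge
    buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}
    for t in traces:
        lo_t = t.apex - _TRACE_TRUNCATION_SIGMA * t.sigma
        hi_t = t.apex + _TRACE_TRUNCATION_SIGMA * t.sigma
        c_lo = max(0, int(math.floor((lo_t / cycle_min) - t.window / n_windows)))
        c_hi = min(n_cycles - 1, int(math.ceil((hi_t / cycle_min))))
        for c in range(c_lo, c_hi + 1):
            rt = spectrum_rt(c, t.window)
            dt = rt - t.apex
            if abs(dt) > _TRACE_TRUNCATION_SIGMA * t.sigma:
                continue
            value = t.amplitude * math.exp(-(dt * dt) / (2 * t.sigma * t.sigma))
            value *= max(0.0, 1.0 + config.noise_sd * rng.standard_normal())
            if value > 0.0:
                buckets.setdefault((c, t.window), []).append((t.mz, value))

    spectra: list[CentroidSpectrum] = []
    scan_lo, scan_hi = config.fragment_scan_range
    for c in range(n_cycles):
        for w in range(n_windows):
            sticks = buckets.get((c, w), [])
            if sticks:
                sticks.sort()
                mzs, vals = [], []
                for mz, v in sticks:
                    if mzs and (mz - mzs[-1]) / mzs[-1] * 1e6 <= _MERGE_PPM:
                        # centroid merge: intensity-weighted position
                        mzs[-1] = (mzs[-1] * vals[-1] + mz * v) / (vals[-1] + v)
                        vals[-1] += v
                    else:
                        mzs.append(mz)
                        vals.append(v)
                mz_arr, int_arr = np.array(mzs), np.array(vals)
            else:
                mz_arr = np.empty(0)
                int_arr = np.empty(0)
            spectra.append(
                CentroidSpectrum(
                    mz=mz_arr,
                    intensity=int_arr,
                    rt=spectrum_rt(c, w),
                    iso_low=mz_lo + w * width,
                    iso_high=mz_lo + (w + 1) * width,
                    scan_low=scan_lo,
                    scan_high=scan_hi,
                )
            )

    stats = {
        "n_precursors": len(precursors),
        "n_contaminant_traces": n_contaminants,
        "n_collision_cells": len(collision_cells),
        "n_spectra": len(spectra),
    }
    return SimulatedRun(
        run=DiaRun(spectra),
        report=report,
        precursors=list(precursors),
        truth_intensities=truth_intensities,
        truth_shared=truth_shared,
        collision_cells=collision_cells,
        stats=stats,
    )


def precursors_from_fasta(
    fasta_text: str,
    config: SimConfig,
    charges: tuple[int, ...] = (2, 3),
    limit: int | None = None,
) -> list[tuple[Peptidoform, int]]:
    """Tryptic precursors of a proteome whose m/z falls inside the
    configured precursor range (carbamidomethyl C applied), in a
    deterministic order."""
    from .library_builder import DigestParams, digest_fasta, expand_precursors

    params = DigestParams(charge_range=(min(charges), max(charges)))
    peptides = digest_fasta(fasta_text, params)
    out = []
    mz_lo, mz_hi = config.precursor_mz_range
    for pf, charge, _proteins in expand_precursors(peptides, params):
        if charge not in charges:
            continue
        mz = (peptide_mono_mass(pf) + charge * PROTON) / charge
        if mz_lo <= mz < mz_hi:
            out.append((pf, charge))
    out.sort(key=lambda pc: (pc[0].sequence, pc[0].mods, pc[1]))
    if limit is not None:
        out = out[:limit]
    return out


def write_truth_tables(sim: SimulatedRun, path) -> None:
    """Dump the interference ground truth as tab-separated text."""
    import pandas as pd

    layout = layout_for_mode("global")
    rows = []
    for pid, (pf, charge) in enumerate(sim.precursors):
        M = sim.truth_intensities[pid]
        for r in range(M.shape[0]):
            for col, name in enumerate(layout):
                rows.append(
                    {
                        "precursor_index": pid,
                        "peptidoform": pf.to_unimod_string(),
                        "charge": charge,
                        "site": r + 1,
                        "column": name,
                        "truth_intensity": M[r, col],
                        "truth_shared": sim.is_shared(pid, r, col),
                        "collision": (pid, r, col) in sim.collision_cells,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
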