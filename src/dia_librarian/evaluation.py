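"""Quantitative evaluation procedures.

* rank correlation between predicted and observed intensities restricted
  to non-interfered (unmasked) cells;
* entrapment-based false discovery proportion bounds from paired
  target/entrapment discovery counts:

  .. math::

     \\widehat{FDP}_{upper} = \\frac{N_E + N_{E \\ge s > T} + 2 N_{E > T \\ge s}}{N_T + N_E},
     \\qquad
     \\widehat{FDP}_{lower} = \\frac{N_E}{N_T + N_E};

* entrapment database construction (shuffled prefix, fixed C-terminal
  residue, I converted to L);
* unweighted spectral-entropy similarity and the NCE grid calibration
  that maximizes its median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .errors import ConfigurationError, InternalError, ValidationError
from .fragmentation import MASK_USE

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# unmasked rank correlation
# ---------------------------------------------------------------------------


def spearman_unmasked(pred: np.ndarray, obs: np.ndarray, mask: np.ndarray) -> float | None:
    """Spearman rho over cells with ``mask == MASK_USE`` (average ranks
    for ties); ``None`` when fewer than 3 usable cells."""
    pred, obs, mask = np.asarray(pred), np.asarray(obs), np.asarray(mask)
    if not pred.shape == obs.shape == mask.shape:
        raise ValidationError("pred/obs/mask shapes differ")
    use = mask == MASK_USE
    if use.sum() < 3:
        logger.warning("fewer than 3 unmasked cells; correlation undefined")
        return None
    rho = spearmanr(pred[use], obs[use]).statistic
    return None if np.isnan(rho) else float(rho)


# ---------------------------------------------------------------------------
# entrapment FDP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntrapmentCounts:
    """Discovery counts at a score cutoff s.

    ``n_e_ge_s_gt_t``: discovered entrapments whose paired target scored
    below s; ``n_e_gt_t_ge_s``: discovered entrapments that outscored
    their paired target while both were discovered.
    """

    n_t: int
    n_e: int
    n_e_ge_s_gt_t: int
    n_e_gt_t_ge_s: int

    def __post_init__(self) -> None:
        if min(self.n_t, self.n_e, self.n_e_ge_s_gt_t, self.n_e_gt_t_ge_s) < 0:
            raise ValidationError("entrapment counts must be non-negative")
        if self.n_e_ge_s_gt_t + self.n_e_gt_t_ge_s > self.n_e:
            raise ValidationError("partitioned entrapment counts exceed N_E")


@dataclass(frozen=True)
class FdpEstimate:
    upper: float
    lower: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper:
            raise InternalError("FDP bounds out of order")


def estimate_fdp(counts: EntrapmentCounts) -> FdpEstimate | None:
    """Paired upper bound and lower bound; ``None`` with no discoveries."""
    denom = counts.n_t + counts.n_e
    if denom == 0:
        return None
    upper = (counts.n_e + counts.n_e_ge_s_gt_t + 2 * counts.n_e_gt_t_ge_s) / denom
    lower = counts.n_e / denom
    return FdpEstimate(upper=upper, lower=lower)


def counts_from_paired_scores(
    target_scores: np.ndarray, entrapment_scores: np.ndarray, cutoff: float
) -> EntrapmentCounts:
    """Derive discovery counts from paired score lists (discovery means
    score >= cutoff; pair i is target i vs entrapment i)."""
    t = np.asarray(target_scores, dtype=float)
    e = np.asarray(entrapment_scores, dtype=float)
    if t.shape != e.shape:
        raise ValidationError("paired score lists differ in length")
    t_disc = t >= cutoff
    e_disc = e >= cutoff
    return EntrapmentCounts(
        n_t=int(t_disc.sum()),
        n_e=int(e_disc.sum()),
        n_e_ge_s_gt_t=int((e_disc & ~t_disc).sum()),
        n_e_gt_t_ge_s=int((e_disc & t_disc & (e > t)).sum()),
    )


def fdp_curve(target_scores, entrapment_scores, cutoffs):
    """FDP bounds over a threshold sweep, as rows of
    ``(cutoff, n_t, n_e, upper, lower)``."""
    rows = []
    for s in cutoffs:
        counts = counts_from_paired_scores(target_scores, entrapment_scores, s)
        est = estimate_fdp(counts)
        if est is not None:
            rows.append((float(s), counts.n_t, counts.n_e, est.upper, est.lower))
    return rows


def build_entrapment_db(
    target_peptides: list[str], seed: int, max_attempts: int = 20
) -> list[tuple[str, str]]:
    """Paired (target, entrapment) peptides.

    I is converted to L in both before pairing; the entrapment is a
    shuffle of the target's prefix with the C-terminal residue fixed.
    Targets for which no distinct permutation is found within
    ``max_attempts`` are dropped and logged.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    for pep in target_peptides:
        if len(pep) < 2:
            raise ConfigurationError(f"peptide {pep!r} too short to entrap")
        target = pep.replace("I", "L")
        prefix = list(target[:-1])
        entrapment = None
        for _ in range(max_attempts):
            perm = list(rng.permutation(prefix))
            cand = "".join(perm) + target[-1]
            if cand != target:
                entrapment = cand
                break
        if entrapment is None:
            logger.info("dropping %r: no distinct prefix permutation", target)
            continue
        pairs.append((target, entrapment))
    return pairs


# ---------------------------------------------------------------------------
# spectral-entropy similarity and NCE calibration
# ---------------------------------------------------------------------------


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _align_peaks(
    mz_a: np.ndarray, int_a: np.ndarray, mz_b: np.ndarray, int_b: np.ndarray,
    merge_tol_ppm: float,
):
    """Merge both peak lists onto a common dimension set: peaks within the
    ppm tolerance share a dimension, unmatched peaks stay distinct."""
    mz_all = np.concatenate([mz_a, mz_b])
    src = np.concatenate([np.zeros(len(mz_a), dtype=int), np.ones(len(mz_b), dtype=int)])
    vals = np.concatenate([int_a, int_b])
    order = np.argsort(mz_all)
    dims_a, dims_b = [], []
    cur_mz = None
    for k in order:
        if cur_mz is None or (mz_all[k] - cur_mz) / cur_mz * 1e6 > merge_tol_ppm:
            dims_a.append(0.0)
            dims_b.append(0.0)
            cur_mz = mz_all[k]
        if src[k] == 0:
            dims_a[-1] += vals[k]
        else:
            dims_b[-1] += vals[k]
    return np.array(dims_a), np.array(dims_b)


def spectral_entropy_similarity(
    spec_a: tuple[np.ndarray, np.ndarray],
    spec_b: tuple[np.ndarray, np.ndarray],
    merge_tol_ppm: float = 10.0,
) -> float | None:
    """Unweighted spectral-entropy similarity in [0, 1].

    Both spectra are normalized to sum 1; the similarity is
    ``1 - (2 H(A/2 + B/2) - H(A) - H(B)) / ln 4``. Identical spectra give
    1, spectra with disjoint peak sets give 0. ``None`` for an empty
    spectrum.
    """
    mz_a, int_a = np.asarray(spec_a[0], float), np.asarray(spec_a[1], float)
    mz_b, int_b = np.asarray(spec_b[0], float), np.asarray(spec_b[1], float)
    if mz_a.size == 0 or mz_b.size == 0 or int_a.sum() <= 0 or int_b.sum() <= 0:
        return None
    a, b = _align_peaks(mz_a, int_a, mz_b, int_b, merge_tol_ppm)
    a = a / a.sum()
    b = b / b.sum()
    mixed = 0.5 * a + 0.5 * b
    sim = 1.0 - (2.0 * _entropy(mixed) - _entropy(a) - _entropy(b)) / np.log(4.0)
    return float(np.clip(sim, 0.0, 1.0))


@dataclass
class NceCalibrationResult:
    grid: list[float]
    median_similarity: list[float]
    optimal_nce: float


def calibrate_nce(
    intensity_model,
    examples,
    grid=tuple(range(20, 41)),
) -> NceCalibrationResult:
    """Grid-search the NCE maximizing the median entropy similarity.

    For each NCE on the grid, every example's fragment intensities are
    predicted and compared with its observed unshared peaks; the NCE with
    the highest median similarity wins (ties go to the lowest NCE).
    """
    from .fragmentation import MASK_USE as _USE
    from .models import predict_intensity

    if not grid:
        raise ConfigurationError("empty NCE grid")
    grid = [float(g) for g in grid]
    medians = []
    for nce in grid:
        sims = []
        for ex in examples:
            pred = predict_intensity(
                intensity_model, ex.peptidoform, ex.charge, nce, ex.instrument
            )
            use = (ex.mask == _USE) & (ex.target > 0)
            if use.sum() < 2:
                continue
            # pseudo-spectra over the usable cells; positions are synthetic
            # dimensions, so alignment is the identity
            dims = np.arange(use.sum(), dtype=float) * 1000.0 + 100.0
            sim = spectral_entropy_similarity(
                (dims, pred[use]), (dims, ex.target[use]), merge_tol_ppm=1.0
            )
            if sim is not None:
                sims.append(sim)
        medians.append(float(np.median(sims)) if sims else float("-inf"))
    best = int(np.argmax(medians))  # argmax takes the first = lowest NCE on ties
    return NceCalibrationResult(grid, medians, grid[best])
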