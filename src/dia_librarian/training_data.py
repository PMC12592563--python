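"""Masked intensity training examples and normalized RT pairs.

An annotated, labeled apex spectrum becomes an :class:`IntensityExample`
unless it is rejected: matched intensities are normalized so the highest
matched peak is 1, shared cells are masked, unmatched in-range cells are
zero targets, and the whole spectrum is dropped when the highest matched
peak is shared or the shared fraction among matched peaks exceeds a
threshold (default 50%).

RT examples are deduplicated at the peptidoform level — the precursor
with the lowest q-value supplies the apex RT — and normalized to [0, 1]
by the run's maximum RT (or a user-supplied factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .fragmentation import MASK_OUT_OF_RANGE, MASK_SHARED, MASK_USE, AnnotatedSpectrum
from .interference import InterferenceConfig, SharedPeakLabels, annotate_run
from .io_formats import DetectionRecord, DiaRun, Peptidoform


@dataclass
class IntensityExample:
    peptidoform: Peptidoform
    charge: int
    nce: float
    instrument: str
    layout: tuple[str, ...]
    target: np.ndarray  # (L-1, len(layout)) in [0, 1]
    mask: np.ndarray  # MASK_* codes


@dataclass(frozen=True)
class RtExample:
    peptidoform: Peptidoform
    rt_normalized: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rt_normalized <= 1.0:
            raise ValidationError(
                f"normalized RT {self.rt_normalized} outside [0, 1]"
            )


@dataclass(frozen=True)
class NormalizationFactor:
    """RT normalization factor in minutes (max observed RT or user value)."""

    value: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ConfigurationError("RT normalization factor must be positive")

    @classmethod
    def from_records(cls, records: list[DetectionRecord]) -> "NormalizationFactor":
        if not records:
            raise ConfigurationError("cannot derive RT factor from an empty report")
        return cls(max(r.apex_rt for r in records))


def build_intensity_example(
    annotated: AnnotatedSpectrum,
    labels: SharedPeakLabels,
    nce: float,
    instrument: str,
    reject_shared_fraction: float = 0.5,
    apply_masks: bool = True,
) -> IntensityExample | None:
    """Turn one labeled annotation into a training example, or reject it.

    Returns ``None`` (rejection) when there are no matched peaks, when the
    highest matched peak is shared, or when the shared fraction among
    matched peaks exceeds ``reject_shared_fraction``. With
    ``apply_masks=False`` the shared labels are ignored entirely (the
    "no masking" ablation): no shared masks and no shared-based rejection.
    """
    matched = annotated.matched_peak >= 0
    n_matched = int(matched.sum())
    if n_matched == 0:
        return None
    normalizer = float(annotated.intensity[matched].max())
    if normalizer <= 0:
        return None

    mask = annotated.mask.copy()
    if apply_masks:
        shared_matched = labels.shared & matched
        n_shared = int(shared_matched.sum())
        top_cell = np.unravel_index(
            int(np.argmax(np.where(matched, annotated.intensity, -np.inf))),
            annotated.intensity.shape,
        )
        if labels.shared[top_cell]:
            return None
        if n_shared / n_matched > reject_shared_fraction:
            return None
        mask[shared_matched & (mask != MASK_OUT_OF_RANGE)] = MASK_SHARED

    target = np.clip(annotated.intensity / normalizer, 0.0, 1.0)
    target[annotated.mask == MASK_OUT_OF_RANGE] = 0.0
    return IntensityExample(
        peptidoform=annotated.record.peptidoform,
        charge=annotated.record.charge,
        nce=nce,
        instrument=instrument,
        layout=annotated.layout,
        target=target,
        mask=mask,
    )


def strip_shared_masks(examples: list[IntensityExample]) -> list[IntensityExample]:
    """The "no masking" ablation: the same training examples with shared
    cells unmasked, so interfered peaks re-enter the loss. Rejection (part
    of training-data generation) is unchanged — only the loss-level
    masking differs."""
    out = []
    for ex in examples:
        mask = ex.mask.copy()
        mask[mask == MASK_SHARED] = MASK_USE
        out.append(
            IntensityExample(ex.peptidoform, ex.charge, ex.nce, ex.instrument,
                             ex.layout, ex.target.copy(), mask)
        )
    return out


def build_rt_examples(
    records: list[DetectionRecord], factor: NormalizationFactor
) -> list[RtExample]:
    """One RT example per peptidoform, from its most confident precursor."""
    best: dict[Peptidoform, DetectionRecord] = {}
    for r in records:
        cur = best.get(r.peptidoform)
        if cur is None or r.q_value < cur.q_value:
            best[r.peptidoform] = r
    out = []
    for pf, r in best.items():
        if r.apex_rt > factor.value:
            raise ValidationError(
                f"apex RT {r.apex_rt} min exceeds normalization factor {factor.value}"
            )
        out.append(RtExample(pf, r.apex_rt / factor.value))
    return out


def train_test_split(examples, test_fraction: float, seed: int):
    """Split at the peptidoform level: no peptidoform appears in both
    partitions. Works for both intensity and RT examples."""
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError("test_fraction must lie in (0, 1)")
    groups: dict[Peptidoform, list] = {}
    for ex in examples:
        groups.setdefault(ex.peptidoform, []).append(ex)
    keys = sorted(groups, key=lambda pf: (pf.sequence, pf.mods))
    if len(keys) < 10:
        raise ConfigurationError(
            f"need at least 10 peptidoforms to split, got {len(keys)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    n_test = max(1, round(test_fraction * len(keys)))
    test_keys = {keys[i] for i in order[:n_test]}
    train, test = [], []
    for pf, exs in groups.items():
        (test if pf in test_keys else train).extend(exs)
    return train, test


@dataclass
class ExtractionStats:
    n_records: int = 0
    n_examples: int = 0
    n_rejected: int = 0
    n_cells_matched: int = 0
    n_cells_shared: int = 0


def extract_training_data(
    run: DiaRun,
    report: list[DetectionRecord],
    nce: float,
    instrument: str,
    config: InterferenceConfig | None = None,
    reject_shared_fraction: float = 0.5,
    apply_masks: bool = True,
    rt_factor: NormalizationFactor | None = None,
):
    """Full extraction: annotate, label, build intensity + RT examples.

    Returns ``(intensity_examples, rt_examples, rt_factor, stats)``.
    """
    pairs = annotate_run(run, report, config)
    stats = ExtractionStats(n_records=len(report))
    intensity_examples: list[IntensityExample] = []
    for ann, labels in pairs:
        matched = ann.matched_peak >= 0
        stats.n_cells_matched += int(matched.sum())
        stats.n_cells_shared += int((labels.shared & matched).sum())
        ex = build_intensity_example(
            ann, labels, nce, instrument, reject_shared_fraction, apply_masks
        )
        if ex is None:
            stats.n_rejected += 1
        else:
            intensity_examples.append(ex)
    stats.n_examples = len(intensity_examples)
    factor = rt_factor or NormalizationFactor.from_records(report)
    rt_examples = build_rt_examples(report, factor)
    return intensity_examples, rt_examples, factor, stats


def examples_to_table(examples: list[IntensityExample]):
    """One row per cell, for TSV serialization and inspection."""
    import pandas as pd

    rows = []
    for ex in examples:
        pep = ex.peptidoform.to_unimod_string()
        for row in range(ex.target.shape[0]):
            for col, name in enumerate(ex.layout):
                rows.append(
                    {
                        "peptidoform": pep,
                        "charge": ex.charge,
                        "nce": ex.nce,
                        "instrument": ex.instrument,
                        "site": row + 1,
                        "column": name,
                        "target": ex.target[row, col],
                        "mask": int(ex.mask[row, col]),
                    }
                )
    return pd.DataFrame(rows)
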