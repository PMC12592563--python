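"""Self-contained benchmark experiments on simulated data.

These are the package's own end-to-end quality checks: shared-peak
detector precision/recall against the simulator's ground truth, model
learnability and the masking-benefit ablation, RT hold-out accuracy, and
a full simulate -> extract -> train -> build-library integrity run. Both
the test suite and ``scripts/acceptance.py`` drive them.

Problem sizes are desk-scale by design: a few hundred precursors and
compact networks, enough to exercise every pipeline stage end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import spearman_unmasked
from .fragmentation import MASK_OUT_OF_RANGE, MASK_USE, layout_for_mode
from .interference import InterferenceConfig, annotate_run
from .library_builder import DigestParams, build_library, digest_fasta, expand_precursors
from .models import (
    IntensityModelConfig,
    RtModelConfig,
    predict_intensity,
    predict_rt,
    train_intensity_model,
    train_rt_model,
)
from .synthetic_data import (
    GroundTruthModel,
    SimConfig,
    generate_proteome,
    precursors_from_fasta,
    simulate_dia_run,
)
from .training_data import (
    NormalizationFactor,
    build_rt_examples,
    extract_training_data,
    strip_shared_masks,
    train_test_split,
)


def _simulated(seed: int, interference_rate: float, n_precursors: int,
               n_proteins: int = 20, noise_sd: float = 0.02):
    cfg = SimConfig(interference_rate=interference_rate, seed=seed, noise_sd=noise_sd)
    fasta = generate_proteome(n_proteins, cfg.protein_length_range, seed)
    prec = precursors_from_fasta(fasta, cfg, limit=n_precursors)
    truth = GroundTruthModel(cfg.gradient_minutes)
    sim = simulate_dia_run(prec, truth, cfg)
    return cfg, truth, sim


@dataclass
class DetectorScore:
    precision: float
    recall: float
    n_true_shared: int
    n_labeled: int


def shared_peak_recovery(seed: int = 11, interference_rate: float = 0.3,
                         n_precursors: int = 300, sim=None, pairs=None) -> DetectorScore:
    """Precision/recall of the combined detector against truth labels."""
    if sim is None:
        _, _, sim = _simulated(seed, interference_rate, n_precursors)
    if pairs is None:
        pairs = annotate_run(sim.run, sim.report, InterferenceConfig())
    tp = fp = fn = 0
    for pid, (ann, lab) in enumerate(pairs):
        matched = ann.matched_peak >= 0
        for r, c in zip(*np.nonzero(matched)):
            t = sim.is_shared(pid, int(r), int(c))
            p = bool(lab.shared[r, c])
            tp += t and p
            fp += (not t) and p
            fn += t and (not p)
    return DetectorScore(
        precision=tp / (tp + fp) if tp + fp else float("nan"),
        recall=tp / (tp + fn) if tp + fn else float("nan"),
        n_true_shared=tp + fn,
        n_labeled=tp + fp,
    )


def clean_run_false_labels(seed: int = 5, n_precursors: int = 200,
                           sim=None, pairs=None) -> int:
    """Shared labels on an interference-free run, excluding the counted
    m/z-collision cells (which are genuine two-ion peaks)."""
    if sim is None:
        _, _, sim = _simulated(seed, 0.0, n_precursors)
    if pairs is None:
        pairs = annotate_run(sim.run, sim.report, InterferenceConfig())
    fp = 0
    for pid, (ann, lab) in enumerate(pairs):
        matched = ann.matched_peak >= 0
        for r, c in zip(*np.nonzero(lab.shared & matched)):
            if (pid, int(r), int(c)) not in sim.collision_cells:
                fp += 1
    return fp


def intensity_learnability(seed: int = 5, n_precursors: int = 200,
                           sim_bundle=None) -> float:
    """Median training Spearman of the from-scratch intensity model on a
    clean simulated run."""
    if sim_bundle is None:
        cfg, truth, sim = _simulated(seed, 0.0, n_precursors)
    else:
        cfg, truth, sim = sim_bundle
    examples, _, _, _ = extract_training_data(sim.run, sim.report, cfg.nce, cfg.instrument)
    model = train_intensity_model(examples, IntensityModelConfig.desk_scale(seed))
    rhos = []
    for ex in examples:
        pred = predict_intensity(model, ex.peptidoform, ex.charge, ex.nce, ex.instrument)
        rho = spearman_unmasked(pred, ex.target, ex.mask)
        if rho is not None:
            rhos.append(rho)
    return float(np.median(rhos))


@dataclass
class MaskingBenefit:
    masked_median: float
    unmasked_median: float

    @property
    def masked_wins(self) -> bool:
        return self.masked_median > self.unmasked_median


def masking_benefit(seed: int, interference_rate: float = 0.4,
                    n_precursors: int = 700) -> MaskingBenefit:
    """The masking ablation: train on the same extracted spectra with and
    without loss-level shared masks; evaluate median Spearman against the
    noise-free ground truth on all precursors outside the training set."""
    cfg = SimConfig(interference_rate=interference_rate, seed=seed)
    fasta = generate_proteome(40, cfg.protein_length_range, seed)
    prec = precursors_from_fasta(fasta, cfg, limit=n_precursors)
    truth = GroundTruthModel(cfg.gradient_minutes)
    sim = simulate_dia_run(prec, truth, cfg)
    examples, _, _, _ = extract_training_data(sim.run, sim.report, cfg.nce, cfg.instrument)
    train, _ = train_test_split(examples, 0.2, seed)
    train_pfs = {ex.peptidoform for ex in train}
    medians = {}
    for name, training_set in (("masked", train), ("unmasked", strip_shared_masks(train))):
        model = train_intensity_model(training_set, IntensityModelConfig.desk_scale(seed))
        rhos = []
        for pf, z in prec:
            if pf in train_pfs:
                continue
            M = truth.intensity_matrix(pf, z, cfg.nce)
            pred = predict_intensity(model, pf, z, cfg.nce, cfg.instrument)
            mask = np.where(M > 0, MASK_USE, MASK_OUT_OF_RANGE)
            rho = spearman_unmasked(pred, M, mask)
            if rho is not None:
                rhos.append(rho)
        medians[name] = float(np.median(rhos))
    return MaskingBenefit(medians["masked"], medians["unmasked"])


def rt_holdout_r2(seed: int = 7, n_peptides: int = 500) -> float:
    """Held-out R^2 of the RT model against the synthetic elution rule."""
    cfg = SimConfig(seed=seed)
    fasta = generate_proteome(25, cfg.protein_length_range, seed)
    prec = precursors_from_fasta(fasta, cfg, limit=n_peptides)
    sim = simulate_dia_run(prec, GroundTruthModel(cfg.gradient_minutes), cfg)
    factor = NormalizationFactor.from_records(sim.report)
    examples = build_rt_examples(sim.report, factor)
    train, test = train_test_split(examples, 0.1, seed)
    model = train_rt_model(train, RtModelConfig.desk_scale(seed))
    pred = predict_rt(model, [e.peptidoform for e in test])
    y = np.array([e.rt_normalized for e in test])
    ss_res = float(np.sum((pred - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class PipelineResult:
    entries: list
    scan_range: tuple[float, float]
    rt_factor: float
    max_fragments: int
    fraction_fragments_in_range: float
    max_relative_intensity_per_precursor: float
    min_relative_intensity_max: float
    rt_roundtrip_max_error: float


def pipeline_integrity(seed: int = 13, n_precursors: int = 150) -> PipelineResult:
    """Full chain: simulate -> extract -> train -> build-library, with the
    integrity quantities the library contract demands."""
    cfg, truth, sim = _simulated(seed, 0.1, n_precursors)
    examples, rt_examples, factor, _ = extract_training_data(
        sim.run, sim.report, cfg.nce, cfg.instrument
    )
    icfg = IntensityModelConfig.desk_scale(seed)
    rcfg = RtModelConfig.desk_scale(seed)
    imodel = train_intensity_model(examples, icfg)
    rmodel = train_rt_model(rt_examples, rcfg)

    fasta = generate_proteome(4, (80, 140), seed + 1)
    params = DigestParams()
    peptides = digest_fasta(fasta, params)
    precursors = expand_precursors(peptides, params)
    scan_range = cfg.fragment_scan_range
    entries = build_library(imodel, rmodel, precursors, scan_range,
                            rt_factor=factor.value, top_n=20,
                            nce=cfg.nce, instrument=cfg.instrument)
    n_in_range = sum(
        1 for e in entries for f, _ in e.fragments
        if scan_range[0] <= f.mz <= scan_range[1]
    )
    n_total = sum(len(e.fragments) for e in entries)
    # RT round trip: normalize by the factor, denormalize, compare
    rt_err = max(abs((e.rt / factor.value) * factor.value - e.rt) for e in entries)
    return PipelineResult(
        entries=entries,
        scan_range=scan_range,
        rt_factor=factor.value,
        max_fragments=max(len(e.fragments) for e in entries),
        fraction_fragments_in_range=n_in_range / n_total,
        max_relative_intensity_per_precursor=max(
            max(rel for _, rel in e.fragments) for e in entries
        ),
        min_relative_intensity_max=min(
            max(rel for _, rel in e.fragments) for e in entries
        ),
        rt_roundtrip_max_error=rt_err,
    )


def nce_recovery(seed: int = 9, n_precursors: int = 200,
                 true_nce: float = 30.0) -> float:
    """Parameter recovery: train across NCEs on ground-truth matrices,
    then calibrate against observations generated at ``true_nce``."""
    from .evaluation import calibrate_nce
    from .training_data import IntensityExample

    truth = GroundTruthModel()
    cfg = SimConfig(seed=seed)
    fasta = generate_proteome(12, cfg.protein_length_range, seed)
    prec = precursors_from_fasta(fasta, cfg, limit=n_precursors)
    layout = layout_for_mode("global")
    nce_grid = list(range(20, 41, 2))
    train_ex, obs_ex = [], []
    for i, (pf, z) in enumerate(prec):
        nce = float(nce_grid[i % len(nce_grid)])
        M = truth.intensity_matrix(pf, z, nce)
        mask = np.where(M > 0, MASK_USE, MASK_OUT_OF_RANGE)
        train_ex.append(IntensityExample(pf, z, nce, "Lumos", layout, M, mask))
        if i % 3 == 0:
            M_obs = truth.intensity_matrix(pf, z, true_nce)
            obs_ex.append(IntensityExample(
                pf, z, true_nce, "Lumos", layout, M_obs,
                np.where(M_obs > 0, MASK_USE, MASK_OUT_OF_RANGE)))
    model = train_intensity_model(train_ex, IntensityModelConfig.desk_scale(seed % (2**31)))
    result = calibrate_nce(model, obs_ex, grid=range(20, 41))
    return result.optimal_nce
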