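"""Shared fixtures: simulated runs at the study conditions.

Session-scoped because simulation + annotation of a run is the expensive
step; tests treat the fixtures as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from dia_librarian.interference import InterferenceConfig, annotate_run
from dia_librarian.synthetic_data import (
    GroundTruthModel,
    SimConfig,
    generate_proteome,
    precursors_from_fasta,
    simulate_dia_run,
)


@pytest.fixture(scope="session")
def tiny_sim():
    """A small clean run (10 precursors, 4-minute gradient) for IO tests."""
    cfg = SimConfig(gradient_minutes=4.0, n_proteins=3, seed=3)
    fasta = generate_proteome(3, (60, 100), 3)
    prec = precursors_from_fasta(fasta, cfg, limit=10)
    return simulate_dia_run(prec, GroundTruthModel(cfg.gradient_minutes), cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Interference-free run of 200 precursors with its annotations."""
    cfg = SimConfig(interference_rate=0.0, seed=5)
    fasta = generate_proteome(cfg.n_proteins, cfg.protein_length_range, 5)
    prec = precursors_from_fasta(fasta, cfg, limit=200)
    truth = GroundTruthModel(cfg.gradient_minutes)
    sim = simulate_dia_run(prec, truth, cfg)
    pairs = annotate_run(sim.run, sim.report, InterferenceConfig())
    return cfg, truth, sim, pairs


@pytest.fixture(scope="session")
def noisefree_sim():
    """Noise-free, interference-free run for exact-recovery checks."""
    cfg = SimConfig(interference_rate=0.0, noise_sd=0.0, seed=6)
    fasta = generate_proteome(cfg.n_proteins, cfg.protein_length_range, 5)
    prec = precursors_from_fasta(fasta, cfg, limit=30)
    truth = GroundTruthModel(cfg.gradient_minutes)
    sim = simulate_dia_run(prec, truth, cfg)
    pairs = annotate_run(sim.run, sim.report, InterferenceConfig())
    return cfg, truth, sim, pairs


@pytest.fixture(scope="session")
def interfered_sim():
    """300 precursors at interference rate 0.3 with annotations — the
    shared-peak recovery condition."""
    cfg = SimConfig(interference_rate=0.3, seed=11)
    fasta = generate_proteome(cfg.n_proteins, cfg.protein_length_range, 11)
    prec = precursors_from_fasta(fasta, cfg, limit=300)
    truth = GroundTruthModel(cfg.gradient_minutes)
    sim = simulate_dia_run(prec, truth, cfg)
    pairs = annotate_run(sim.run, sim.report, InterferenceConfig())
    return cfg, truth, sim, pairs


def random_peptidoform(rng: np.random.Generator, min_len=6, max_len=20):
    """Random peptidoform with occasional mods, for property tests."""
    from dia_librarian.chem import CANONICAL_AA
    from dia_librarian.io_formats import Peptidoform

    L = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list(CANONICAL_AA), size=L))
    mods = []
    for i, aa in enumerate(seq, start=1):
        if aa == "C":
            mods.append((i, 57.021464, "Carbamidomethyl"))
        elif aa in "STY" and rng.random() < 0.15:
            mods.append((i, 79.966331, "Phospho"))
        elif aa == "M" and rng.random() < 0.2:
            mods.append((i, 15.994915, "Oxidation"))
    return Peptidoform(seq, tuple(mods))
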