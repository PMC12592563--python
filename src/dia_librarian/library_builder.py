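"""In silico digestion, precursor expansion, and library assembly.

Digestion is tryptic without proline suppression (Trypsin/P), one missed
cleavage by default, peptide length 7-35. Fixed carbamidomethyl on C;
phospho mode adds up to one variable phospho on S/T/Y. Precursor charges
default to 2+-4+. N-terminal methionine excision is deliberately not
applied.

Library assembly predicts a full fragment matrix and RT per precursor,
drops precursors and fragments outside the training run's m/z scan
range, then keeps the top-N fragments by predicted intensity (filtering
happens before the top-N selection) and renormalizes the kept set to a
maximum of 1.
"""

from __future__ import annotations

import io
import itertools
import logging
from dataclasses import dataclass

from pyteomics import fasta as _pyteomics_fasta
from pyteomics import parser as _pyteomics_parser

from .chem import MOD_BY_NAME, PROTON
from .errors import ConfigurationError, DataError
from .fragmentation import (
    FragmentIon,
    cell_of,
    enumerate_fragments,
    layout_for_mode,
    peptide_mono_mass,
)
from .io_formats import Peptidoform
from .models import TrainedModel, predict_intensity, predict_rt

logger = logging.getLogger(__name__)


@dataclass
class DigestParams:
    enzyme: str = "trypsin_p"
    max_missed_cleavages: int = 1
    length_range: tuple[int, int] = (7, 35)
    fixed_mods: tuple[tuple[str, str], ...] = (("Carbamidomethyl", "C"),)
    variable_mods: tuple[tuple[str, str], ...] = ()  # e.g. (("Phospho", "STY"),)
    max_variable_mods: int = 1
    charge_range: tuple[int, int] = (2, 4)

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin_p":
            raise ConfigurationError(f"unsupported enzyme {self.enzyme!r}")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(f"invalid peptide length range ({lo}, {hi})")
        zlo, zhi = self.charge_range
        if zlo < 1 or zhi < zlo:
            raise ConfigurationError(f"invalid charge range ({zlo}, {zhi})")

    @classmethod
    def phospho(cls, **kwargs) -> "DigestParams":
        return cls(variable_mods=(("Phospho", "STY"),), **kwargs)


@dataclass
class LibraryEntry:
    """One precursor's library rows: predicted RT and top fragments."""

    peptidoform: Peptidoform
    charge: int
    precursor_mz: float
    rt: float  # minutes, already denormalized
    fragments: list[tuple[FragmentIon, float]]
    protein_ids: str = ""


def digest_fasta(fasta: str, params: DigestParams) -> dict[str, list[str]]:
    """Digest a FASTA text (or path) into a peptide -> protein-ids map.

    Cleaves after K/R without proline suppression, keeps peptides with at
    most ``max_missed_cleavages`` internal sites and a length inside the
    configured range. A peptide found in several proteins maps to all of
    them.
    """
    if fasta and "\n" not in fasta and not fasta.startswith(">"):
        with open(fasta, encoding="utf-8") as fh:
            fasta = fh.read()
    lo, hi = params.length_range
    peptides: dict[str, set[str]] = {}
    n_proteins = 0
    for header, seq in _pyteomics_fasta.read(io.StringIO(fasta), use_index=False):
        n_proteins += 1
        pid = header.split()[0]
        for pep in _pyteomics_parser.cleave(
            seq, "[KR]", missed_cleavages=params.max_missed_cleavages
        ):
            if lo <= len(pep) <= hi:
                peptides.setdefault(pep, set()).add(pid)
    if n_proteins == 0:
        raise DataError("empty FASTA: no protein records")
    return {pep: sorted(pids) for pep, pids in peptides.items()}


def expand_precursors(
    peptides: dict[str, list[str]], params: DigestParams
) -> list[tuple[Peptidoform, int, str]]:
    """Apply fixed and variable modifications and the charge range.

    Returns ``(peptidoform, charge, protein_ids)`` triples: fixed mods on
    every matching residue; every combination of up to
    ``max_variable_mods`` variable modifications; cross product with the
    charge range.
    """
    out: list[tuple[Peptidoform, int, str]] = []
    zlo, zhi = params.charge_range
    for pep in sorted(peptides):
        proteins = ";".join(peptides[pep])
        fixed = []
        for name, residues in params.fixed_mods:
            _, delta = MOD_BY_NAME[name]
            fixed.extend(
                (i + 1, delta, name) for i, a in enumerate(pep) if a in residues
            )
        var_sites = []
        for name, residues in params.variable_mods:
            _, delta = MOD_BY_NAME[name]
            var_sites.extend(
                (i + 1, delta, name) for i, a in enumerate(pep) if a in residues
            )
        combos = [()]
        for k in range(1, params.max_variable_mods + 1):
            combos.extend(itertools.combinations(var_sites, k))
        for combo in combos:
            mods = tuple(sorted(fixed + list(combo)))
            pf = Peptidoform(pep, mods)
            for z in range(zlo, zhi + 1):
                out.append((pf, z, proteins))
    return out


def build_library(
    intensity_model: TrainedModel,
    rt_model: TrainedModel,
    precursors: list[tuple[Peptidoform, int, str]],
    scan_range: tuple[float, float],
    rt_factor: float,
    top_n: int = 20,
    nce: float = 27.0,
    instrument: str = "Lumos",
    mode: str = "global",
) -> list[LibraryEntry]:
    """Predict and filter library entries for the given precursors.

    Precursors with m/z outside ``scan_range`` are dropped; fragment
    cells outside the range are dropped before the top-``top_n``
    selection; kept intensities are renormalized to max 1; RTs are
    denormalized by ``rt_factor`` (minutes). Entries whose fragments all
    fall away are dropped and logged.
    """
    scan_lo, scan_hi = scan_range
    layout = layout_for_mode(mode)
    entries: list[LibraryEntry] = []
    n_dropped_precursor, n_dropped_empty = 0, 0

    peptidoforms = [pf for pf, _, _ in precursors]
    rts = predict_rt(rt_model, peptidoforms) * rt_factor if precursors else []

    for (pf, charge, proteins), rt in zip(precursors, rts):
        prec_mz = (peptide_mono_mass(pf) + charge * PROTON) / charge
        if not scan_lo <= prec_mz <= scan_hi:
            n_dropped_precursor += 1
            continue
        matrix = predict_intensity(intensity_model, pf, charge, nce, instrument)
        candidates = []
        for frag in enumerate_fragments(pf, charge, mode):
            if not scan_lo <= frag.mz <= scan_hi:
                continue
            row, col = cell_of(frag, len(pf), layout)
            rel = float(matrix[row, col])
            if rel > 0.0:
                candidates.append((frag, rel))
        candidates.sort(key=lambda fr: -fr[1])
        kept = candidates[:top_n]
        if not kept:
            n_dropped_empty += 1
            logger.info(
                "dropping precursor %s/%d: no fragments survive the scan-range filter",
                pf.to_unimod_string(), charge,
            )
            continue
        peak = max(rel for _, rel in kept)
        kept = [(frag, rel / peak) for frag, rel in kept]
        entries.append(
            LibraryEntry(
                peptidoform=pf,
                charge=charge,
                precursor_mz=prec_mz,
                rt=float(rt),
                fragments=kept,
                protein_ids=proteins,
            )
        )
    logger.info(
        "library build: %d entries, %d precursors outside scan range, %d without fragments",
        len(entries), n_dropped_precursor, n_dropped_empty,
    )
    return entries
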