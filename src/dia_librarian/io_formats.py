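"""Readers and writers for the formats the pipeline touches.

Supported formats: mzML DIA runs (read; the simulator writes its own
minimal mzML), tab-separated peptide detection reports in the DIA-NN main
report dialect (a Skyline-style column mapping is also accepted),
UniMod-tagged modified-sequence notation, and the output spectral library
as a row-oriented TSV.

Conventions: retention times are minutes everywhere, m/z is double
precision, isolation windows are half-open ``[low, high)``.
"""

from __future__ import annotations

import base64
import re
import struct
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lxml import etree

from .chem import CANONICAL_AA, PROTON, UNIMOD_TABLE
from .errors import ConfigurationError, FormatError

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence plus its modifications.

    ``mods`` holds ``(position, mass_delta, name)`` with 1-based residue
    positions; position 0 denotes the N-terminus.
    """

    sequence: str
    mods: tuple[tuple[int, float, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence or any(c not in CANONICAL_AA for c in self.sequence):
            raise FormatError(f"non-canonical residues in sequence {self.sequence!r}")
        for pos, _, name in self.mods:
            if not 0 <= pos <= len(self.sequence):
                raise FormatError(
                    f"mod {name} position {pos} outside peptide {self.sequence!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def mod_delta_at(self, pos: int) -> float:
        return sum(d for p, d, _ in self.mods if p == pos)

    def to_unimod_string(self) -> str:
        """Serialize as e.g. ``PEPTC(UniMod:4)K``."""
        name_to_uid = {name: uid for uid, (name, _) in UNIMOD_TABLE.items()}
        parts = []
        nterm = "".join(
            f"(UniMod:{name_to_uid[name]})" for p, _, name in self.mods if p == 0
        )
        parts.append(nterm)
        for i, aa in enumerate(self.sequence, start=1):
            parts.append(aa)
            for p, _, name in self.mods:
                if p == i:
                    parts.append(f"(UniMod:{name_to_uid[name]})")
        return "".join(parts)


@dataclass
class CentroidSpectrum:
    """One centroided MS2 spectrum with acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    rt: float  # minutes
    iso_low: float
    iso_high: float
    scan_low: float
    scan_high: float
    ms_level: int = 2

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise FormatError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise FormatError("spectrum m/z array is not strictly increasing")
        if not self.iso_low < self.iso_high:
            raise FormatError("degenerate isolation window")


class DiaRun:
    """A time-ordered DIA run with an isolation-window index.

    ``covering(mz)`` returns the indices of spectra whose isolation window
    contains ``mz`` (half-open ``[low, high)``), in time order.
    """

    def __init__(self, spectra: list[CentroidSpectrum]):
        self.spectra = spectra
        self.window_index: dict[tuple[float, float], list[int]] = {}
        for i, s in enumerate(spectra):
            self.window_index.setdefault((s.iso_low, s.iso_high), []).append(i)

    def covering(self, mz: float) -> list[int]:
        for (low, high), idx in self.window_index.items():
            if low <= mz < high:
                return idx
        return []

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass(frozen=True)
class DetectionRecord:
    """A detected precursor from an upstream DIA search report."""

    peptidoform: Peptidoform
    charge: int
    q_value: float
    apex_rt: float
    rt_start: float
    rt_stop: float
    precursor_mz: float
    site_confidence: float | None = None
    protein_ids: str = ""

    def __post_init__(self) -> None:
        if not self.rt_start <= self.apex_rt <= self.rt_stop:
            raise FormatError(
                f"apex RT {self.apex_rt} outside peak boundaries "
                f"[{self.rt_start}, {self.rt_stop}]"
            )
        if not 0.0 <= self.q_value <= 1.0:
            raise FormatError(f"q-value {self.q_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# modified-sequence notation
# ---------------------------------------------------------------------------

_UNIMOD_TAG = re.compile(r"\(UniMod:(\d+)\)")


def parse_modified_sequence(text: str, notation: str = "unimod_parenthetical") -> Peptidoform:
    """Parse a UniMod-tagged sequence like ``PES(UniMod:21)K``."""
    if notation != "unimod_parenthetical":
        raise ConfigurationError(f"unknown sequence notation {notation!r}")
    mods: list[tuple[int, float, str]] = []
    seq_chars: list[str] = []
    i = 0
    while i < len(text):
        if text[i] == "(":
            m = _UNIMOD_TAG.match(text, i)
            if not m:
                end = text.find(")", i)
                raise FormatError(f"unknown modification tag {text[i:end + 1]!r}")
            uid = int(m.group(1))
            if uid not in UNIMOD_TABLE:
                raise FormatError(f"unknown modification tag {m.group(0)!r}")
            name, delta = UNIMOD_TABLE[uid]
            mods.append((len(seq_chars), delta, name))
            i = m.end()
        else:
            seq_chars.append(text[i])
            i += 1
    return Peptidoform("".join(seq_chars), tuple(mods))


# ---------------------------------------------------------------------------
# detection reports
# ---------------------------------------------------------------------------

_DIANN_COLUMNS = {
    "modified_sequence": "Modified.Sequence",
    "charge": "Precursor.Charge",
    "rt": "RT",
    "rt_start": "RT.Start",
    "rt_stop": "RT.Stop",
    "q_value": "Q.Value",
    "site_confidence": "PTM.Site.Confidence",  # optional
    "precursor_mz": "Precursor.Mz",  # optional
    "protein_ids": "Protein.Ids",  # optional
}

_SKYLINE_COLUMNS = {
    "modified_sequence": "ModifiedSequence",
    "charge": "PrecursorCharge",
    "rt": "BestRetentionTime",
    "rt_start": "MinStartTime",
    "rt_stop": "MaxEndTime",
    "q_value": "DetectionQValue",
    "site_confidence": "SiteConfidence",
    "precursor_mz": "PrecursorMz",
    "protein_ids": "ProteinName",
}

_OPTIONAL_FIELDS = {"site_confidence", "precursor_mz", "protein_ids"}


def _precursor_mz(pf: Peptidoform, charge: int) -> float:
    # local import: fragmentation imports chem only, no cycle
    from .fragmentation import peptide_mono_mass

    return (peptide_mono_mass(pf) + charge * PROTON) / charge


def read_detection_report(
    path,
    dialect: str = "diann",
    q_threshold: float = 0.01,
    phospho_mode: bool = False,
    site_confidence_threshold: float = 0.75,
) -> list[DetectionRecord]:
    """Read a detection report and apply the confidence filters.

    Records are kept when ``q_value <= q_threshold``; in phospho mode a
    site-localization confidence of at least ``site_confidence_threshold``
    is additionally required.
    """
    if dialect == "diann":
        cols = _DIANN_COLUMNS
    elif dialect == "skyline":
        cols = _SKYLINE_COLUMNS
    else:
        raise ConfigurationError(f"unknown report dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    missing = [
        c for k, c in cols.items() if k not in _OPTIONAL_FIELDS and c not in df.columns
    ]
    if missing:
        raise FormatError(f"report missing required column(s): {', '.join(missing)}")
    if phospho_mode and cols["site_confidence"] not in df.columns:
        raise FormatError(
            f"phospho mode requires column {cols['site_confidence']!r}"
        )

    records: list[DetectionRecord] = []
    for _, row in df.iterrows():
        q = float(row[cols["q_value"]])
        if q > q_threshold:
            continue
        conf = None
        if cols["site_confidence"] in df.columns:
            conf = float(row[cols["site_confidence"]])
        if phospho_mode and (conf is None or conf < site_confidence_threshold):
            continue
        pf = parse_modified_sequence(str(row[cols["modified_sequence"]]))
        charge = int(row[cols["charge"]])
        mz = (
            float(row[cols["precursor_mz"]])
            if cols["precursor_mz"] in df.columns
            else _precursor_mz(pf, charge)
        )
        records.append(
            DetectionRecord(
                peptidoform=pf,
                charge=charge,
                q_value=q,
                apex_rt=float(row[cols["rt"]]),
                rt_start=float(row[cols["rt_start"]]),
                rt_stop=float(row[cols["rt_stop"]]),
                precursor_mz=mz,
                site_confidence=conf,
                protein_ids=str(row[cols["protein_ids"]])
                if cols["protein_ids"] in df.columns
                else "",
            )
        )
    return records


def write_detection_report(records: list[DetectionRecord], path, dialect: str = "diann") -> None:
    """Write records in the given report dialect (used by the simulator)."""
    if dialect == "diann":
        cols = _DIANN_COLUMNS
    elif dialect == "skyline":
        cols = _SKYLINE_COLUMNS
    else:
        raise ConfigurationError(f"unknown report dialect {dialect!r}")
    rows = []
    for r in records:
        row = {
            cols["modified_sequence"]: r.peptidoform.to_unimod_string(),
            cols["charge"]: r.charge,
            cols["rt"]: r.apex_rt,
            cols["rt_start"]: r.rt_start,
            cols["rt_stop"]: r.rt_stop,
            cols["q_value"]: r.q_value,
            cols["precursor_mz"]: r.precursor_mz,
            cols["protein_ids"]: r.protein_ids,
        }
        if r.site_confidence is not None:
            row[cols["site_confidence"]] = r.site_confidence
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------


# cvParam accessions used by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_SCAN_LOW = "MS:1000501"
_ACC_SCAN_HIGH = "MS:1000500"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LO_OFF = "MS:1000828"
_ACC_ISO_HI_OFF = "MS:1000829"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _cv_params(element) -> dict[str, dict]:
    """accession -> {'value':…, 'unit':…} over all descendant cvParams."""
    out = {}
    for cv in element.iter("{*}cvParam"):
        out[cv.get("accession")] = {
            "value": cv.get("value"),
            "unit": cv.get("unitName"),
        }
    return out


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    binary = bda.find("{*}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem) -> CentroidSpectrum | None:
    sid = elem.get("id", "?")
    params = _cv_params(elem)
    if params.get(_ACC_MS_LEVEL, {}).get("value") != "2":
        return None
    if _ACC_PROFILE in params:
        raise FormatError(f"profile-mode spectrum {sid!r}: centroided data required")
    scan = elem.find("{*}scanList/{*}scan")
    if scan is None or _ACC_SCAN_START not in _cv_params(scan):
        raise FormatError(f"spectrum {sid!r} lacks a scan start time")
    scan_params = _cv_params(scan)
    rt_entry = scan_params[_ACC_SCAN_START]
    rt = float(rt_entry["value"])
    if rt_entry["unit"] == "second":
        rt /= 60.0
    iso = elem.find("{*}precursorList/{*}precursor/{*}isolationWindow")
    iso_params = _cv_params(iso) if iso is not None else {}
    if not {_ACC_ISO_TARGET, _ACC_ISO_LO_OFF, _ACC_ISO_HI_OFF} <= iso_params.keys():
        raise FormatError(f"spectrum {sid!r} lacks isolation-window metadata")
    target = float(iso_params[_ACC_ISO_TARGET]["value"])
    lo_off = float(iso_params[_ACC_ISO_LO_OFF]["value"])
    hi_off = float(iso_params[_ACC_ISO_HI_OFF]["value"])
    if not {_ACC_SCAN_LOW, _ACC_SCAN_HIGH} <= scan_params.keys():
        raise FormatError(f"spectrum {sid!r} lacks scan-window metadata")
    mz_arr = int_arr = None
    for bda in elem.findall("{*}binaryDataArrayList/{*}binaryDataArray"):
        p = _cv_params(bda)
        if _ACC_MZ_ARRAY in p:
            mz_arr = _decode_binary_array(bda)
        elif _ACC_INT_ARRAY in p:
            int_arr = _decode_binary_array(bda)
    if mz_arr is None or int_arr is None:
        raise FormatError(f"spectrum {sid!r} lacks m/z or intensity arrays")
    return CentroidSpectrum(
        mz=mz_arr,
        intensity=int_arr,
        rt=rt,
        iso_low=target - lo_off,
        iso_high=target + hi_off,
        scan_low=float(scan_params[_ACC_SCAN_LOW]["value"]),
        scan_high=float(scan_params[_ACC_SCAN_HIGH]["value"]),
    )


def read_mzml(path) -> DiaRun:
    """Read a centroided DIA mzML file into a :class:`DiaRun`.

    Rejects files without MS2 spectra, profile-mode spectra, and MS2
    spectra lacking isolation-window metadata, naming the offending
    spectrum. MS1 spectra are skipped.
    """
    spectra: list[CentroidSpectrum] = []
    for _, elem in etree.iterparse(str(path), tag="{*}spectrum"):
        spec = _parse_spectrum(elem)
        if spec is not None:
            spectra.append(spec)
        elem.clear(keep_tail=True)
        while elem.getprevious() is not None:
            del elem.getparent()[0]
    if not spectra:
        raise FormatError(f"no centroided MS2 spectra found in {path}")
    spectra.sort(key=lambda s: s.rt)
    return DiaRun(spectra)


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="dia_librarian" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="dp1">
      <processingMethod order="1" softwareRef="dia_librarian"/>
    </dataProcessing>
  </dataProcessingList>
  <run id="run1" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="dp1">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.8f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
            <scanWindowList count="1">
              <scanWindow>
                <cvParam cvRef="MS" accession="MS:1000501" name="scan window lower limit" value="{scan_low:.4f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
                <cvParam cvRef="MS" accession="MS:1000500" name="scan window upper limit" value="{scan_high:.4f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
              </scanWindow>
            </scanWindowList>
          </scan>
        </scanList>
        <precursorList count="1">
          <precursor>
            <isolationWindow>
              <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{target:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
              <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{lo_off:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
              <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{hi_off:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            </isolationWindow>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{target:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
              </selectedIon>
            </selectedIonList>
            <activation>
              <cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/>
            </activation>
          </precursor>
        </precursorList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(run: DiaRun, path) -> None:
    """Write a minimal centroided mzML file readable by standard parsers.

    Only covers what the simulator needs: MS2 spectra with scan start
    time, isolation-window and scan-window metadata, uncompressed 64-bit
    float arrays.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.replace("{count}", str(len(run.spectra))))
        for i, s in enumerate(run.spectra):
            mz_b64 = _b64_doubles(s.mz)
            int_b64 = _b64_doubles(s.intensity)
            fh.write(
                _MZML_SPECTRUM.format(
                    index=i,
                    scan=i + 1,
                    n=len(s.mz),
                    rt=s.rt,
                    scan_low=s.scan_low,
                    scan_high=s.scan_high,
                    target=(s.iso_low + s.iso_high) / 2.0,
                    lo_off=(s.iso_high - s.iso_low) / 2.0,
                    hi_off=(s.iso_high - s.iso_low) / 2.0,
                    mz_len=len(mz_b64),
                    mz_b64=mz_b64,
                    int_len=len(int_b64),
                    int_b64=int_b64,
                )
            )
        fh.write(_MZML_FOOTER)


# ---------------------------------------------------------------------------
# library TSV
# ---------------------------------------------------------------------------

LIBRARY_COLUMNS = [
    "ModifiedPeptide",
    "PrecursorCharge",
    "PrecursorMz",
    "NormalizedRetentionTime",
    "FragmentType",
    "FragmentSeriesNumber",
    "FragmentCharge",
    "FragmentLossType",
    "FragmentMz",
    "RelativeIntensity",
    "ProteinId",
]


def write_library_tsv(entries, path) -> None:
    """Write library entries as one row per (precursor, fragment)."""
    from .errors import ValidationError

    if not entries:
        raise ValidationError("refusing to write an empty library")
    rows = []
    for e in entries:
        if not e.fragments:
            raise ValidationError(
                f"library entry {e.peptidoform.to_unimod_string()}/{e.charge} "
                "has no fragments"
            )
        for frag, rel in e.fragments:
            rows.append(
                {
                    "ModifiedPeptide": e.peptidoform.to_unimod_string(),
                    "PrecursorCharge": e.charge,
                    "PrecursorMz": e.precursor_mz,
                    "NormalizedRetentionTime": e.rt,
                    "FragmentType": frag.series,
                    "FragmentSeriesNumber": frag.ordinal,
                    "FragmentCharge": frag.charge,
                    "FragmentLossType": frag.loss or "noloss",
                    "FragmentMz": frag.mz,
                    "RelativeIntensity": rel,
                    "ProteinId": e.protein_ids,
                }
            )
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_library_tsv(path):
    """Read a library TSV back into :class:`~.library_builder.LibraryEntry`
    objects (round-trip counterpart of :func:`write_library_tsv`)."""
    from .fragmentation import FragmentIon
    from .library_builder import LibraryEntry

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"library missing column(s): {', '.join(missing)}")
    entries = []
    for (pep, charge), grp in df.groupby(["ModifiedPeptide", "PrecursorCharge"], sort=False):
        pf = parse_modified_sequence(str(pep))
        fragments = []
        for _, row in grp.iterrows():
            loss = "" if row["FragmentLossType"] == "noloss" else str(row["FragmentLossType"])
            frag = FragmentIon(
                series=str(row["FragmentType"]),
                ordinal=int(row["FragmentSeriesNumber"]),
                charge=int(row["FragmentCharge"]),
                loss=loss,
                mz=float(row["FragmentMz"]),
            )
            fragments.append((frag, float(row["RelativeIntensity"])))
        entries.append(
            LibraryEntry(
                peptidoform=pf,
                charge=int(charge),
                precursor_mz=float(grp["PrecursorMz"].iloc[0]),
                rt=float(grp["NormalizedRetentionTime"].iloc[0]),
                fragments=fragments,
                protein_ids=str(grp["ProteinId"].iloc[0]),
            )
        )
    return entries
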