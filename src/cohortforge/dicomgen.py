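"""Rendering of synthetic DICOM Part 10 study fixtures.

Studies are written as one directory per accession containing one file per
instance.  Pixel content is a synthetic gradient (clinical realism is a
non-goal); what matters is the metadata and the injected integrity fault:

``none``
    readable axial CT instances (plus one leading localizer, as real CT
    studies have);
``topogram_only``
    every instance is flagged as a localizer — no cross-sectional content;
``corrupted``
    the first instance's pixel payload is truncated, so metadata parses
    but pixel decoding fails;
``encoding_error``
    the first instance's Part 10 magic bytes are mangled, so it cannot be
    parsed as DICOM at all;
``test_patient``
    the patient name carries a sentinel test/phantom pattern.

Files are Explicit VR Little Endian throughout.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

__all__ = ["StudySpec", "RENDER_MODES", "render_dicom_fixture"]

RENDER_MODES = ("none", "topogram_only", "corrupted", "encoding_error", "test_patient")

_ROOT_UID = "1.2.826.0.1.3680043.10.1551"  # fixture UID namespace


@dataclass(frozen=True)
class StudySpec:
    """What to render for one study."""

    mrn: str
    accession: str
    study_date: dt.date
    n_instances: int = 24
    patient_name: str = "Synthetic^Patient"
    rows: int = 32
    columns: int = 32


def _instance_dataset(spec: StudySpec, idx: int, localizer: bool, study_uid: str) -> Dataset:
    sop_uid = f"{_ROOT_UID}.{spec.accession}.1.{idx + 1}"
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = f"{study_uid}.{1 if localizer else 2}"
    ds.StudyDate = spec.study_date.strftime("%Y%m%d")
    ds.SeriesDate = ds.StudyDate
    ds.AccessionNumber = spec.accession
    ds.PatientID = spec.mrn
    ds.PatientName = spec.patient_name
    ds.Modality = "CT"
    ds.BodyPartExamined = "ABDOMEN"
    ds.ImageType = ["ORIGINAL", "PRIMARY", "LOCALIZER" if localizer else "AXIAL"]
    ds.InstanceNumber = idx + 1
    ds.Rows = spec.rows
    ds.Columns = spec.columns
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.SamplesPerPixel = 1
    ds.PixelRepresentation = 0
    ds.PhotometricInterpretation = "MONOCHROME2"
    gradient = (np.arange(spec.rows * spec.columns, dtype=np.uint32) * (idx + 1)) % 4096
    ds.PixelData = gradient.astype(np.uint16).tobytes()
    return ds


def render_dicom_fixture(spec: StudySpec, mode: str, out_dir: Path) -> Path:
    """Write one synthetic study under ``out_dir / accession``.

    Returns the study directory.  Unknown modes raise ``ValueError``.
    """
    if mode not in RENDER_MODES:
        raise ValueError(f"unknown render mode {mode!r}; expected one of {RENDER_MODES}")
    study_dir = Path(out_dir) / spec.accession
    study_dir.mkdir(parents=True, exist_ok=True)
    study_uid = f"{_ROOT_UID}.{spec.accession}"

    patient_name = spec.patient_name
    if mode == "test_patient":
        patient_name = "TEST^PHANTOM^ZZZ"

    for idx in range(spec.n_instances):
        localizer = (mode == "topogram_only") or (mode != "topogram_only" and idx == 0)
        inst_spec = StudySpec(
            mrn=spec.mrn,
            accession=spec.accession,
            study_date=spec.study_date,
            n_instances=spec.n_instances,
            patient_name=patient_name,
            rows=spec.rows,
            columns=spec.columns,
        )
        ds = _instance_dataset(inst_spec, idx, localizer, study_uid)
        path = study_dir / f"IM{idx + 1:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)

    if mode == "corrupted":
        _truncate_pixels(study_dir / "IM0002.dcm")
    elif mode == "encoding_error":
        _mangle_magic(study_dir / "IM0002.dcm")
    return study_dir


def _truncate_pixels(path: Path) -> None:
    """Drop the tail of the pixel payload: metadata stays readable,
    pixel decoding fails."""
    raw = path.read_bytes()
    path.write_bytes(raw[:-500])


def _mangle_magic(path: Path) -> None:
    """Break the Part 10 'DICM' magic so the file is undecodable as DICOM."""
    raw = bytearray(path.read_bytes())
    raw[128:132] = b"DCIM"
    path.write_bytes(bytes(raw))
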