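"""Read/write treatment-plan geometry: fixture dialect and DICOM-RT.

Two on-disk representations of the same :class:`~brachyrobust.case.CaseModel`:

* a line-oriented plain-text *fixture dialect* (normative for the test
  suite; floats written with ``repr`` so round-trips are exact), and
* DICOM-RT Plan (brachytherapy application setup: channels → needles,
  brachy control points → dwells, cumulative time weights → seconds)
  plus RT Structure Set (closed planar contours), via pydicom.

Structure names are matched case-insensitively through a configurable
alias table, since clinical naming varies (``Prostate``, ``CTV``, …).

Fixture dialect schema (``# brachyrobust-case 1`` header)::

    prescription_gy = 16.0
    [needle 1]
    tip = x y z
    dwell = x y z t          # one line per dwell, tip-ward first
    [structure prostate]
    slice_width = 2.5
    slice z = x y x y ...    # one line per slice, inferior first
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .case import CaseModel, CaseValidationError, ContourSet, DwellSet, Structure

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"

#: default structure-name aliases, matched against lower-cased ROI names
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "prostate": ("prostate", "ctv", "target", "ptv"),
    "urethra": ("urethra", "urethra_or", "uretra"),
    "rectum": ("rectum", "rectal wall", "rectum_or"),
}


class CaseIOError(IOError):
    """Raised on malformed case files."""


def _match_structure(roi_name: str, aliases: dict[str, tuple[str, ...]]) -> str | None:
    low = roi_name.strip().lower()
    for canon, names in aliases.items():
        if low == canon or low in names:
            return canon
    for canon, names in aliases.items():
        if any(a in low for a in (canon, *names)):
            return canon
    return None


# ---------------------------------------------------------------------------
# fixture dialect
# ---------------------------------------------------------------------------

_HEADER = "# brachyrobust-case 1"


def _write_fixture(case: CaseModel, path: Path) -> None:
    lines = [_HEADER, f"prescription_gy = {case.prescription!r}"]
    for i in range(case.dwells.n_needles):
        tip = case.dwells.tips[i]
        lines.append(f"[needle {i + 1}]")
        lines.append("tip = " + " ".join(repr(float(v)) for v in tip))
        for p, t in zip(case.dwells.positions[i], case.dwells.times[i]):
            lines.append("dwell = " + " ".join(repr(float(v)) for v in (*p, t)))
    for name, s in case.contours.structures.items():
        lines.append(f"[structure {name}]")
        lines.append(f"slice_width = {s.slice_width!r}")
        for sl in s.slices:
            xy = " ".join(repr(float(v)) for v in sl[:, :2].ravel())
            lines.append(f"slice {float(sl[0, 2])!r} = {xy}")
    path.write_text("\n".join(lines) + "\n")


def _read_fixture(path: Path) -> CaseModel:
    text = path.read_text().splitlines()
    if not text or not text[0].startswith("# brachyrobust-case"):
        raise CaseIOError(f"{path}: missing fixture header {_HEADER!r}")
    prescription = None
    needles: list[dict] = []
    structures: dict[str, dict] = {}
    section: dict | None = None
    for ln, raw in enumerate(text[1:], start=2):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[needle"):
            section = {"tip": None, "dwells": [], "times": []}
            needles.append(section)
            continue
        if line.startswith("[structure"):
            name = line[len("[structure"):].strip(" ]")
            section = {"slice_width": None, "slices": []}
            structures[name] = section
            continue
        if "=" not in line:
            raise CaseIOError(f"{path}:{ln}: cannot parse {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key == "prescription_gy":
            prescription = float(val)
        elif key == "tip":
            section["tip"] = [float(v) for v in val.split()]
        elif key == "dwell":
            nums = [float(v) for v in val.split()]
            section["dwells"].append(nums[:3])
            section["times"].append(nums[3])
        elif key == "slice_width":
            section["slice_width"] = float(val)
        elif key.startswith("slice"):
            z = float(key.split(None, 1)[1])
            xy = np.array([float(v) for v in val.split()], dtype=float).reshape(-1, 2)
            section["slices"].append(np.column_stack([xy, np.full(len(xy), z)]))
        else:
            raise CaseIOError(f"{path}:{ln}: unknown key {key!r}")
    if prescription is None:
        raise CaseIOError(f"{path}: missing prescription_gy")
    dwells = DwellSet(
        [np.array(n["dwells"]) for n in needles],
        [np.array(n["times"]) for n in needles],
        [np.array(n["tip"]) for n in needles],
    )
    contours = ContourSet(
        {
            name: Structure(d["slices"], d["slice_width"])
            for name, d in structures.items()
        }
    )
    return CaseModel(dwells, contours, prescription)


# ---------------------------------------------------------------------------
# DICOM-RT adapters
# ---------------------------------------------------------------------------


def _file_meta(sop_class: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _ds(v: float) -> str:
    """Format a float within the 16-character DICOM DS limit."""
    s = f"{v:.8g}"
    return s if len(s) <= 16 else f"{v:.6g}"


def _write_dicom_plan(case: CaseModel, path: Path) -> None:
    ds = Dataset()
    ds.SOPClassUID = RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = "brachyrobust"
    ds.BrachyTreatmentType = "HDR"
    setup = Dataset()
    setup.ApplicationSetupNumber = 1
    channels = []
    for i in range(case.dwells.n_needles):
        ch = Dataset()
        ch.ChannelNumber = i + 1
        ch.SourceMovementType = "STEPWISE"
        total = float(case.dwells.times[i].sum())
        ch.ChannelTotalTime = _ds(total)
        ch.FinalCumulativeTimeWeight = _ds(total)
        cps = []
        w = 0.0

        def cp(pos, weight, idx):
            c = Dataset()
            c.ControlPointIndex = idx
            c.ControlPoint3DPosition = [_ds(v) for v in pos]
            c.CumulativeTimeWeight = _ds(weight)
            return c

        cps.append(cp(case.dwells.tips[i], 0.0, 0))
        idx = 1
        for p, t in zip(case.dwells.positions[i], case.dwells.times[i]):
            cps.append(cp(p, w, idx))
            w += float(t)
            cps.append(cp(p, w, idx + 1))
            idx += 2
        ch.NumberOfControlPoints = len(cps)
        ch.BrachyControlPointSequence = cps
        channels.append(ch)
    setup.ChannelSequence = channels
    ds.ApplicationSetupSequence = [setup]
    # prescription carried as the target dose of the single fraction group
    ref = Dataset()
    ref.TargetPrescriptionDose = _ds(case.prescription)
    ds.DoseReferenceSequence = [ref]
    ds.file_meta = _file_meta(RTPLAN_SOP_CLASS)
    pydicom.dcmwrite(path, ds, enforce_file_format=True)


def _write_dicom_struct(case: CaseModel, path: Path) -> None:
    ds = Dataset()
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "brachyrobust"
    rois, roi_contours = [], []
    for num, (name, s) in enumerate(case.contours.structures.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        rois.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        contour_seq = []
        for sl in s.slices:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(sl)
            c.ContourData = [_ds(v) for v in sl.ravel()]
            contour_seq.append(c)
        rc.ContourSequence = contour_seq
        roi_contours.append(rc)
    ds.StructureSetROISequence = rois
    ds.ROIContourSequence = roi_contours
    ds.file_meta = _file_meta(RTSTRUCT_SOP_CLASS)
    pydicom.dcmwrite(path, ds, enforce_file_format=True)


def _read_dicom_plan(path: Path) -> tuple[DwellSet, float]:
    ds = pydicom.dcmread(path)
    positions, times, tips = [], [], []
    setups = getattr(ds, "ApplicationSetupSequence", None)
    if not setups:
        raise CaseIOError(f"{path}: no brachytherapy application setup")
    for setup in setups:
        for ch in setup.ChannelSequence:
            cps = ch.BrachyControlPointSequence
            total = float(ch.ChannelTotalTime)
            final_w = float(ch.FinalCumulativeTimeWeight)
            scale = total / final_w if final_w > 0 else 0.0
            tips.append(np.array([float(v) for v in cps[0].ControlPoint3DPosition]))
            pos, t = [], []
            # dwells are written as (arrival, departure) control-point pairs
            for a, b in zip(cps[1::2], cps[2::2]):
                pos.append([float(v) for v in a.ControlPoint3DPosition])
                t.append((float(b.CumulativeTimeWeight) - float(a.CumulativeTimeWeight)) * scale)
            positions.append(np.array(pos).reshape(-1, 3))
            times.append(np.array(t))
    prescription = 16.0
    if getattr(ds, "DoseReferenceSequence", None):
        prescription = float(ds.DoseReferenceSequence[0].TargetPrescriptionDose)
    if sum(len(p) for p in positions) == 0:
        raise CaseIOError(f"{path}: plan contains zero dwells")
    return DwellSet(positions, times, tips), prescription


def _read_dicom_struct(path: Path, aliases: dict[str, tuple[str, ...]]) -> ContourSet:
    ds = pydicom.dcmread(path)
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    structures: dict[str, Structure] = {}
    for rc in ds.ROIContourSequence:
        name = names.get(int(rc.ReferencedROINumber), "")
        canon = _match_structure(name, aliases)
        if canon is None:
            continue
        slices = []
        for c in rc.ContourSequence:
            pts = np.array([float(v) for v in c.ContourData], dtype=float).reshape(-1, 3)
            slices.append(pts)
        slices.sort(key=lambda s: s[0, 2])
        z = np.array([s[0, 2] for s in slices])
        width = float(np.median(np.diff(z))) if len(z) > 1 else 1.0
        structures[canon] = Structure(slices, width)
    missing = [n for n in ("prostate", "urethra", "rectum") if n not in structures]
    if missing:
        raise CaseIOError(
            f"{path}: missing structures {missing}; available ROI names: {sorted(names.values())}"
        )
    return ContourSet(structures)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _is_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def load_case(
    plan_path: str | os.PathLike,
    struct_path: str | os.PathLike,
    aliases: dict[str, tuple[str, ...]] | None = None,
) -> CaseModel:
    """Load a case from a plan/structure file pair.

    Both files may be DICOM-RT or the fixture dialect; for the fixture
    dialect the two paths may be the same file (it holds both halves).
    The returned model is validated (times in seconds, coordinates mm).
    """
    plan_path, struct_path = Path(plan_path), Path(struct_path)
    aliases = aliases or DEFAULT_ALIASES
    for p in (plan_path, struct_path):
        if not p.exists():
            raise CaseIOError(f"no such file: {p}")
    if _is_dicom(plan_path):
        dwells, prescription = _read_dicom_plan(plan_path)
        contours = _read_dicom_struct(struct_path, aliases)
        case = CaseModel(dwells, contours, prescription)
    else:
        case = _read_fixture(plan_path)
        if struct_path != plan_path:
            other = _read_fixture(struct_path)
            case.contours = other.contours
        canon = {}
        for name, s in case.contours.structures.items():
            m = _match_structure(name, aliases)
            if m is not None:
                canon[m] = s
        missing = [n for n in ("prostate", "urethra", "rectum") if n not in canon]
        if missing:
            raise CaseIOError(
                f"{struct_path}: missing structures {missing}; "
                f"available: {sorted(case.contours.structures)}"
            )
        case.contours = ContourSet(canon)
    case.validate()
    return case


def write_case(
    case: CaseModel, out_path: str | os.PathLike, dialect: str = "fixture"
) -> tuple[Path, ...]:
    """Write a case to disk; returns the path(s) written.

    ``dialect="fixture"`` writes one plain-text file.  ``dialect="dicom"``
    writes ``<out_path>`` as the RT Plan and ``<stem>_struct.dcm`` as the
    RT Structure Set, returning both paths.
    """
    case.validate()
    out_path = Path(out_path)
    if dialect == "fixture":
        _write_fixture(case, out_path)
        return (out_path,)
    if dialect == "dicom":
        struct_path = out_path.with_name(out_path.stem + "_struct.dcm")
        _write_dicom_plan(case, out_path)
        _write_dicom_struct(case, struct_path)
        return (out_path, struct_path)
    raise ValueError(f"unknown dialect {dialect!r}")
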