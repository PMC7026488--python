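"""Synthetic ParaVision study generator with fully known ground truth.

Stands in for a real multi-species scanner archive: it writes study
directories in exactly the layout the loaders expect (``subject``,
``ScanProgram.scanProgram``, numbered scans with ``acqp``/``method``/
``pdata/1/{visu_pars,2dseq}``), with compliant, non-compliant and
corrupted variants.  The generator is the format-dialect authority for
this package: whatever it writes, the parsers must read.  Generation is
fully deterministic in (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import jcampdx
from .convert import BYTE_ORDERS, WORD_TYPES

__all__ = [
    "ScanSpec",
    "StudySpec",
    "FixtureSpecError",
    "encode_2dseq",
    "scan_array",
    "generate_study",
    "generate_collection",
    "species_collection_specs",
]


class FixtureSpecError(ValueError):
    pass


@dataclass
class ScanSpec:
    """Ground truth for one synthetic scan."""

    scan_number: int
    instruction_name: str
    sequence_name: str = "EPI"
    matrix: tuple[int, int, int] = (8, 8, 4)
    frames: int = 1
    word_type: str = "_16BIT_SGN_INT"
    byte_order: str = "littleEndian"
    slope: float = 1.0
    offset: float = 0.0
    repetition_time: float = 1.0  # seconds (volume TR)
    echo_time: float = 0.02  # seconds
    extent: tuple[float, float, float] | None = None  # mm; defaults to matrix
    orientation: tuple[float, ...] = (1, 0, 0, 0, 1, 0, 0, 0, 1)
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    truncate_2dseq: bool = False

    def validate(self) -> None:
        if self.scan_number < 1:
            raise FixtureSpecError("scan_number must be >= 1")
        if self.word_type not in WORD_TYPES:
            raise FixtureSpecError(f"unknown word type {self.word_type!r}")
        if self.byte_order not in BYTE_ORDERS:
            raise FixtureSpecError(f"unknown byte order {self.byte_order!r}")
        if len(self.matrix) != 3 or any(d < 1 for d in self.matrix):
            raise FixtureSpecError(f"bad matrix {self.matrix!r}")
        if self.frames < 1:
            raise FixtureSpecError("frames must be >= 1")
        if self.repetition_time <= 0:
            raise FixtureSpecError("repetition_time must be positive")


@dataclass
class StudySpec:
    """Ground truth for one synthetic study directory."""

    timestamp: str  # "YYYYMMDD_HHMMSS"
    subject: str
    session: str
    scans: list[ScanSpec] = field(default_factory=list)
    directory_suffix: str = "1_1"
    write_scan_program: bool = True

    @property
    def directory_name(self) -> str:
        return f"{self.timestamp}_{self.subject}_{self.directory_suffix}"

    def validate(self) -> None:
        if not self.subject or not self.session:
            raise FixtureSpecError("subject and session must be nonempty")
        numbers = [s.scan_number for s in self.scans]
        if len(numbers) != len(set(numbers)):
            raise FixtureSpecError("duplicate scan numbers in study spec")
        for scan in self.scans:
            scan.validate()


def encode_2dseq(array: np.ndarray, spec: ScanSpec) -> bytes:
    """Encode a raw (x, y, z, t) integer/float array as 2dseq bytes.

    Frames (volumes) are written consecutively, each x-fastest — the
    inverse of the decoder's layout.  The stored words are the *raw*
    values; scaled ground truth is ``raw * slope + offset``.
    """
    dtype = WORD_TYPES[spec.word_type].newbyteorder(BYTE_ORDERS[spec.byte_order])
    if array.ndim == 3:
        array = array[..., np.newaxis]
    # (x, y, z, t) -> (t, z, y, x) so x varies fastest in the stream
    return np.ascontiguousarray(array.transpose(3, 2, 1, 0)).astype(dtype).tobytes()


def scan_array(spec: ScanSpec, seed: int) -> np.ndarray:
    """The deterministic raw array a given (spec, seed) scan contains."""
    rng = np.random.default_rng([seed, spec.scan_number])
    shape = (*spec.matrix, spec.frames)
    dtype = WORD_TYPES[spec.word_type]
    if dtype.kind == "f":
        return rng.integers(0, 1024, size=shape).astype(dtype.newbyteorder("="))
    info = np.iinfo(dtype)
    low, high = max(info.min, -1024), min(info.max, 1024)
    return rng.integers(low, high, size=shape, dtype=dtype.newbyteorder("="))


def _visu_params(spec: ScanSpec) -> dict:
    extent = spec.extent or tuple(float(d) for d in spec.matrix)
    params = {
        "VisuCoreDim": 3,
        "VisuCoreSize": list(spec.matrix),
        "VisuCoreExtent": [float(e) for e in extent],
        "VisuCoreFrameCount": spec.frames,
        "VisuCoreWordType": spec.word_type,
        "VisuCoreByteOrder": spec.byte_order,
        "VisuCoreOrientation": [float(v) for v in spec.orientation],
        "VisuCorePosition": [float(v) for v in spec.position],
        "VisuAcqRepetitionTime": spec.repetition_time * 1000.0,
        "VisuAcqEchoTime": spec.echo_time * 1000.0,
    }
    if spec.frames > 1:
        params["VisuCoreDataSlope"] = [float(spec.slope)] * spec.frames
        params["VisuCoreDataOffs"] = [float(spec.offset)] * spec.frames
    else:
        params["VisuCoreDataSlope"] = float(spec.slope)
        params["VisuCoreDataOffs"] = float(spec.offset)
    return params


def corner_world_coordinates(spec: ScanSpec) -> np.ndarray:
    """Ground-truth world (mm) coordinates of the 8 corner voxels.

    Computed from the spec alone (voxel size = extent/matrix, rotated by
    the orientation matrix, shifted by position) — independent of the
    affine builder under test.
    """
    extent = spec.extent or tuple(float(d) for d in spec.matrix)
    vox = np.array(extent) / np.array(spec.matrix)
    rot = np.array(spec.orientation, dtype=float).reshape(3, 3).T
    corners = []
    for i in (0, spec.matrix[0] - 1):
        for j in (0, spec.matrix[1] - 1):
            for k in (0, spec.matrix[2] - 1):
                index = np.array([i, j, k], dtype=float)
                corners.append(rot @ (vox * index) + np.array(spec.position))
    return np.array(corners)


def generate_study(study: StudySpec, root: str | Path, seed: int = 0) -> Path:
    """Write one synthetic study directory under ``root``; returns its path."""
    study.validate()
    root = Path(root)
    study_dir = root / study.directory_name
    study_dir.mkdir(parents=True, exist_ok=True)

    (study_dir / "subject").write_text(
        jcampdx.dumps(
            {
                "SUBJECT_version": 7,
                "SUBJECT_id": study.subject,
                "SUBJECT_study_name": study.session,
                "SUBJECT_study_nr": 1,
            },
            title="Parameter List, ParaVision 6.0.1",
        ),
        encoding="utf-8",
    )

    if study.write_scan_program:
        lines = ["<?xml version=\"1.0\"?>", "<ScanProgram>"]
        for scan in study.scans:
            lines.append(
                f"  <displayName>{scan.instruction_name} "
                f"(E{scan.scan_number})</displayName>"
            )
        lines.append("</ScanProgram>")
        (study_dir / "ScanProgram.scanProgram").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )

    for scan in study.scans:
        scan_dir = study_dir / str(scan.scan_number)
        pdata = scan_dir / "pdata" / "1"
        pdata.mkdir(parents=True, exist_ok=True)
        (scan_dir / "acqp").write_text(
            jcampdx.dumps(
                {
                    "ACQ_scan_name": f"{scan.instruction_name} (E{scan.scan_number})",
                    "ACQ_method": f"Bruker:{scan.sequence_name}",
                    "ACQ_repetition_time": scan.repetition_time * 1000.0,
                    "ACQ_echo_time": scan.echo_time * 1000.0,
                }
            ),
            encoding="utf-8",
        )
        (scan_dir / "method").write_text(
            jcampdx.dumps({"Method": f"Bruker:{scan.sequence_name}"}),
            encoding="utf-8",
        )
        (pdata / "visu_pars").write_text(
            jcampdx.dumps(_visu_params(scan)), encoding="utf-8"
        )
        payload = encode_2dseq(scan_array(scan, seed), scan)
        if scan.truncate_2dseq:
            payload = payload[: max(0, len(payload) // 2)]
        (pdata / "2dseq").write_bytes(payload)
    return study_dir


# ---------------------------------------------------------------------------
# Multi-species collection emulation: species are separable by disjoint
# acquisition-string vocabularies and subject-id pools, so selector-scoped
# pipeline runs split the collection into dedicated per-species datasets.

_SPECIES = [
    {
        "name": "mouse",
        "subjects": ["M4007", "MSN9879"],
        "func_acq": "seEPIMus",
        "anat_acq": "RAREMus",
        "timestamps": ["20180730_110000", "20180731_093000"],
    },
    {
        "name": "rat",
        "subjects": ["R21", "R22"],
        "func_acq": "seEPIRat",
        "anat_acq": "RARERat",
        "timestamps": ["20171106_184345", "20171107_101500"],
    },
    {
        "name": "lemur",
        "subjects": ["Mc365A", "Mc285AB"],
        "func_acq": "seEPILem",
        "anat_acq": "RARELem",
        "timestamps": ["20171024_165248", "20171025_120000"],
    },
]


def species_selectors(species_index: int) -> dict[str, dict[str, list[str]]]:
    """Per-category selector dictionaries isolating one species."""
    info = _SPECIES[species_index % len(_SPECIES)]
    return {
        "func": {"acquisition": [info["func_acq"]]},
        "anat": {"acquisition": [info["anat_acq"]]},
    }


def species_collection_specs(
    n_species: int, studies_per_species: int = 1
) -> list[StudySpec]:
    """Build study specs for a synthetic multi-species collection."""
    if n_species > len(_SPECIES):
        raise FixtureSpecError(f"at most {len(_SPECIES)} species supported")
    specs = []
    for s in range(n_species):
        info = _SPECIES[s]
        for i in range(studies_per_species):
            subject = info["subjects"][i % len(info["subjects"])]
            specs.append(
                StudySpec(
                    timestamp=info["timestamps"][i % len(info["timestamps"])],
                    subject=subject,
                    session=f"ses{i + 1}",
                    scans=[
                        ScanSpec(
                            scan_number=5,
                            instruction_name=f"acq-{info['anat_acq']}_T2w",
                            sequence_name="TurboRARE",
                            matrix=(8, 8, 4),
                            frames=1,
                            repetition_time=2.0,
                        ),
                        ScanSpec(
                            scan_number=7,
                            instruction_name=(
                                f"acq-{info['func_acq']}_task-rest_bold"
                            ),
                            sequence_name="EPI",
                            matrix=(8, 8, 4),
                            frames=5,
                            slope=2.0,
                            offset=1.0,
                            repetition_time=1.5,
                        ),
                    ],
                )
            )
    return specs


def noncompliant_study_spec(timestamp: str = "20160101_120000") -> StudySpec:
    """A study with free-field operator input that defeats extraction."""
    return StudySpec(
        timestamp=timestamp,
        subject="MD1704_Mc285AB",  # underscore: non-compliant
        session="P-02",  # hyphen: non-compliant
        scans=[
            ScanSpec(
                scan_number=5,
                instruction_name="T2 TurboRARE",  # bare tokens, space
                sequence_name="TurboRARE",
            ),
            ScanSpec(
                scan_number=7,
                instruction_name="rsfMRI EPI",
                sequence_name="EPI",
                frames=5,
                repetition_time=1.5,
            ),
        ],
    )


def generate_collection(
    n_species: int,
    studies_per_species: int,
    root: str | Path,
    seed: int = 0,
    include_noncompliant: bool = False,
) -> list[StudySpec]:
    """Write a multi-species collection; returns the ground-truth specs."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    specs = species_collection_specs(n_species, studies_per_species)
    if include_noncompliant:
        specs = specs + [noncompliant_study_spec()]
    for spec in specs:
        generate_study(spec, root, seed=seed)
    return specs


def load_spec_file(path: str | Path) -> list[StudySpec]:
    """Read study specs from a simple declarative JSON config.

    Top level is a list of study objects mirroring :class:`StudySpec` /
    :class:`ScanSpec` field names.
    """
    import json

    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    specs = []
    for study in raw:
        scans = [
            ScanSpec(
                **{
                    **scan,
                    "matrix": tuple(scan.get("matrix", (8, 8, 4))),
                }
            )
            for scan in study.pop("scans", [])
        ]
        specs.append(StudySpec(scans=scans, **study))
    return specs


def with_missing_scan_program(spec: StudySpec) -> StudySpec:
    """Corruption variant: the scan-program file is absent (acqp fallback)."""
    return replace(spec, write_scan_program=False)
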