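"""Sequential conversion pipeline: collection directory → BIDS tree.

Categories are processed in a fixed order (structural, functional,
diffusion-weighted) for reproducibility; per-scan conversion decodes the
2dseq reconstruction, writes the BIDS-named NIfTI plus sidecar (and an
empty events stub for functional scans), then session tables and dataset
boilerplate, and finally the work-directory metadata record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bids, metadata
from .convert import CorruptDataError, UnsupportedFormatError, decode_2dseq
from .convert import write_nifti
from .study import find_studies, load_study, parse_directory_timestamp

__all__ = ["RunConfig", "PipelineResult", "ExitStatus", "run_pipeline"]

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("anat", "func", "dwi")

VALIDATOR_HINT = (
    "Conversion finished. For an authoritative compliance check, run the "
    "BIDS validator on the output (https://bids-standard.github.io/bids-validator/)."
)


class ExitStatus:
    OK = 0
    VALIDATION_FAILED = 1
    NO_SCANS_MATCHED = 3


@dataclass
class RunConfig:
    """Parameters of one pipeline invocation (CLI and library share it)."""

    input_path: Path
    output_path: Path
    functional_match: dict[str, list[str]] = field(default_factory=dict)
    structural_match: dict[str, list[str]] = field(default_factory=dict)
    diffusion_match: dict[str, list[str]] = field(default_factory=dict)
    work_directory: Path | None = None
    run_base: int = 0
    keep_int: bool = False
    canonical: bool = False

    def __post_init__(self):
        self.input_path = Path(self.input_path)
        self.output_path = Path(self.output_path)
        if self.work_directory is None:
            # hidden so the emitted tree stays validator-clean
            self.work_directory = self.output_path / ".work"
        self.work_directory = Path(self.work_directory)
        if not (
            self.functional_match or self.structural_match or self.diffusion_match
        ):
            raise ValueError("at least one category selector must be provided")
        if not self.input_path.is_dir():
            raise ValueError(f"input collection {self.input_path} is not a directory")
        if self.run_base not in (0, 1):
            raise ValueError("run_base must be 0 or 1")


@dataclass
class PipelineResult:
    status: int
    bids_root: Path
    table: pd.DataFrame
    converted: list[Path]
    violations: list[str]


def _selector_for(config: RunConfig, category: str) -> dict[str, list[str]]:
    return {
        "anat": config.structural_match,
        "func": config.functional_match,
        "dwi": config.diffusion_match,
    }[category]


def _convert_row(row, studies_by_path, config: RunConfig) -> list[Path]:
    study = studies_by_path[row["study_path"]]
    scan = next(s for s in study.scans if s.scan_number == row["scan_number"])
    entities = metadata.BidsEntities(
        subject=row["subject"],
        session=row["session"],
        task=row["task"] if isinstance(row["task"], str) else None,
        acq=row["acq"] if isinstance(row["acq"], str) else None,
        run=int(row["run"]),
        suffix=row["suffix"],
        category=row["category"],
    )
    if scan.data_path is None or scan.visu is None:
        logger.warning(
            "skipping %s scan %s: no readable reconstruction",
            study.directory_name,
            scan.scan_number,
        )
        return []
    try:
        image = decode_2dseq(scan.data_path.read_bytes(), scan.visu)
    except (CorruptDataError, UnsupportedFormatError) as exc:
        logger.warning(
            "skipping %s scan %s: %s", study.directory_name, scan.scan_number, exc
        )
        return []
    rel = bids.compose_bids_path(entities, ".nii.gz")
    nifti_path = config.output_path / rel
    nifti_path.parent.mkdir(parents=True, exist_ok=True)
    written = [
        write_nifti(
            image, nifti_path, keep_int=config.keep_int, canonical=config.canonical
        )
    ]
    sidecar_rel = bids.compose_bids_path(entities, ".json")
    written.append(
        bids.write_sidecar(scan, entities, config.output_path / sidecar_rel)
    )
    if entities.category == "func":
        events_entities = entities.merged(suffix="events")
        events_rel = bids.compose_bids_path(events_entities, ".tsv")
        written.append(bids.write_events_stub(config.output_path / events_rel))
        # dwi placeholders are the only other non-image siblings
    if entities.category == "dwi":
        for ext in (".bval", ".bvec"):
            placeholder = config.output_path / bids.compose_bids_path(entities, ext)
            placeholder.write_text("", encoding="utf-8")
            written.append(placeholder)
    return written


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full repositing pipeline for one collection.

    Returns a result whose ``status`` is 0 on success with a clean
    internal validation, 1 when the internal tree check finds violations,
    and 3 when no scan matched any selector (nothing is written then).
    """
    studies = [load_study(p) for p in find_studies(config.input_path)]
    table = metadata.build_metadata_table(studies)
    studies_by_path = {str(s.path): s for s in studies}

    selected_frames = []
    for category in CATEGORY_ORDER:
        selector = _selector_for(config, category)
        if not selector:
            continue
        picked = metadata.select_scans(table, selector, category)
        picked = metadata.assign_run_numbers(picked, base=config.run_base)
        selected_frames.append(picked)
    selected = (
        pd.concat(selected_frames, ignore_index=True)
        if selected_frames
        else table.iloc[0:0]
    )

    config.output_path.mkdir(parents=True, exist_ok=True)
    if selected.empty:
        logger.warning("no scans matched the selection criteria; nothing to convert")
        return PipelineResult(
            status=ExitStatus.NO_SCANS_MATCHED,
            bids_root=config.output_path,
            table=selected,
            converted=[],
            violations=[],
        )

    converted: list[Path] = []
    sessions: dict[str, set] = {}
    for _, row in selected.sort_values(
        ["category", "subject", "session", "scan_number"]
    ).iterrows():
        written = _convert_row(row, studies_by_path, config)
        if written:
            converted.extend(written)
            acq_time = (
                parse_directory_timestamp(row["study_name"])
                if isinstance(row["study_name"], str)
                else None
            )
            sessions.setdefault(row["subject"], set()).add(
                (row["session"], acq_time)
            )

    for subject, subject_sessions in sorted(sessions.items()):
        bids.write_sessions_tsv(
            config.output_path,
            subject,
            sorted(
                subject_sessions,
                key=lambda s: (s[0], s[1].isoformat() if s[1] else ""),
            ),
        )
    bids.write_dataset_description(config.output_path, config.input_path.name)
    bids.write_participants(config.output_path, sorted(sessions))

    metadata.write_metadata_table(
        selected, config.work_directory / "metadata.tsv"
    )

    violations = bids.validate_tree(config.output_path)
    status = ExitStatus.OK if not violations else ExitStatus.VALIDATION_FAILED
    if not violations:
        logger.info(VALIDATOR_HINT)
    else:
        for violation in violations:
            logger.error("BIDS check: %s", violation)
    return PipelineResult(
        status=status,
        bids_root=config.output_path,
        table=selected,
        converted=converted,
        violations=violations,
    )
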