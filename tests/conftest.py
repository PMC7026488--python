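from pathlib import Path

import pytest

from bru2bids import fixtures


@pytest.fixture
def compliant_study_spec():
    return fixtures.StudySpec(
        timestamp="20171106_184345",
        subject="21",
        session="ses1",
        scans=[
            fixtures.ScanSpec(
                scan_number=5,
                instruction_name="acq-TurboRARE_T2w",
                sequence_name="TurboRARE",
            ),
            fixtures.ScanSpec(
                scan_number=6,
                instruction_name="acq-FLASH_T1w",
                sequence_name="FLASH",
            ),
            fixtures.ScanSpec(
                scan_number=7,
                instruction_name="acq-seEPI_task-rest_bold",
                sequence_name="EPI",
                frames=5,
                slope=2.0,
                offset=1.0,
                repetition_time=1.5,
            ),
        ],
    )


@pytest.fixture
def compliant_study(tmp_path, compliant_study_spec) -> Path:
    return fixtures.generate_study(compliant_study_spec, tmp_path / "coll", seed=0)


@pytest.fixture
def noncompliant_study(tmp_path) -> Path:
    spec = fixtures.noncompliant_study_spec()
    return fixtures.generate_study(spec, tmp_path / "nc", seed=0)


def tree_bytes(root: Path) -> dict[str, bytes]:
    """Relative path -> content map, for byte-level tree comparison."""
    return {
        str(p.relative_to(root)): p.read_bytes()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }
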