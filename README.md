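# bru2bids

Convert small-animal MRI studies from the Bruker ParaVision on-disk layout
(plain-text JCAMP-DX-style parameter files + binary `2dseq` reconstructions)
into [BIDS](https://bids-specification.readthedocs.io/) 1.x datasets:
NIfTI images, sidecar JSON, events/sessions tables and the standard
directory hierarchy.

Features:

- **Conversion pipeline** — discovers studies in a collection directory,
  parses operator metadata (`subject`, `ScanProgram.scanProgram`, falling
  back to each scan's `acqp`), categorizes scans with selector dictionaries
  (substring matching, e.g. `acquisition=EPI`), decodes `2dseq` via
  `visu_pars` geometry, and emits a deterministic, internally validated
  BIDS tree. A tab-separated record of every candidate scan is kept in a
  work directory for debugging.
- **Redress** — retroactive compliance editing for preexisting studies
  with free-field operator input: surgical line-level edits of the
  `subject` and `ScanProgram.scanProgram` files (at most 2 + 1-per-scan
  lines), with unified-diff preview, `.orig` backups, and refusal of
  non-BIDS-legal values.
- **Fixtures** — a synthetic multi-species ParaVision collection generator
  with fully known ground truth (compliant, non-compliant and corrupted
  variants), used by the test suite so everything runs offline.

## CLI

```sh
# convert a collection; selectors are field=comma-separated-substrings
bru2bids /data/collection /data/bids \
    --func acquisition=EPI --anat acquisition=TurboRARE

# options: --dwi k=v  --run-base 0|1  --keep-int  --canonical  --workdir PATH

# retroactively fix a non-compliant study (preview with --dry-run)
bru2bids redress /data/collection/20171024_165248_X_1_1 \
    --subject Mc285AB --session P02 \
    --rename 5=acq-TurboRARE_T2w --rename 7=acq-seEPI_task-rest_bold

# generate a synthetic 3-species test collection
bru2bids fixtures /tmp/collection --seed 1 --species 3
```

Exit status: `0` success (clean internal validation), `1` internal BIDS
check violations, `3` no scans matched the selectors.

The same functionality is available as a library:

```python
from bru2bids import RunConfig, run_pipeline

result = run_pipeline(RunConfig(
    input_path="/data/collection",
    output_path="/data/bids",
    functional_match={"acquisition": ["EPI"]},
    structural_match={"acquisition": ["TurboRARE"]},
))
```

## Operator conventions

- Subject/session come from the `SUBJECT_id` / `SUBJECT_study_name` fields
  of the `subject` file (never from the directory name) and must be purely
  alphanumeric.
- Scan instruction names encode entities as `key-value` pairs separated by
  underscores with a trailing modality suffix, e.g.
  `acq-seEPI_task-rest_bold`. FLASH/RARE-family scans without an explicit
  suffix are auto-assigned `T1w`/`T2w`.
- Run ordinals are assigned automatically (zero-based by default, matching
  the native output; `--run-base 1` for common BIDS practice).

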