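"""Shared fixtures: tiny hand-built SAM/FASTA inputs and simulated bundles."""

from __future__ import annotations

import pytest

from generra.io_align import AlignedReadRecord, AmpliconRef
from generra.roi_profile import ROI

# the printed worked example: read aligned with one 5-nt internal deletion
WORKED_REF = "AGTAGTCGATCGATC"
WORKED_READ = "AGTAGCAATC"
WORKED_CODE = "000001111100000"


def make_read(
    cigar: list[tuple[int, str]],
    query: str,
    pos: int = 0,
    ref_name: str = "amp1",
    library: str = "gDNA",
    name: str = "r",
) -> AlignedReadRecord:
    return AlignedReadRecord(
        ref_name=ref_name, pos=pos, cigar=cigar, query=query,
        library=library, mapped=True, name=name,
    )


def sam_text(ref_name: str, ref_len: int, records: list[str]) -> str:
    header = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{ref_name}\tLN:{ref_len}",
    ]
    return "\n".join(header + records) + "\n"


@pytest.fixture
def worked_ref() -> AmpliconRef:
    return AmpliconRef(name="amp1", sequence=WORKED_REF)


@pytest.fixture
def worked_roi() -> ROI:
    return ROI(ref_name="amp1", start=0, end=15)
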