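"""Shared fixtures: a bundled-style marker ReferenceDB and simulated samples."""

from __future__ import annotations

import pytest

from uscgam.families import DEFAULT_FAMILY_LENGTHS_AA, uscg_families
from uscgam.reference_db import ReferenceDB


def make_uscg_db(lengths_aa: dict[str, int] | None = None) -> ReferenceDB:
    """ReferenceDB with one reference per bundled family, named USCG_<family>
    (the subject-id convention of the community simulator)."""
    lengths_aa = lengths_aa or DEFAULT_FAMILY_LENGTHS_AA
    fams = uscg_families()
    seq_lengths: dict[str, int] = {}
    seq_to_family: dict[str, str] = {}
    for fam in fams:
        sid = f"USCG_{fam.family_name}"
        fam.member_seq_ids.append(sid)
        seq_lengths[sid] = lengths_aa[fam.family_name]
        seq_to_family[sid] = fam.family_name
    return ReferenceDB(
        families=fams, seq_lengths_aa=seq_lengths, seq_to_family=seq_to_family
    )


@pytest.fixture
def uscg_db() -> ReferenceDB:
    return make_uscg_db()
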