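"""Reference protein database: loading, validation and dereplication.

A reference database is a protein FASTA plus a two-column TSV mapping each
sequence id to a marker-family name. Sequence lengths are kept in amino-acid
residues; the abundance layer converts to nucleotide bp (x3) when applying
the RPKM formula to translated-search hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .families import FAMILY_NAMES, USCGFamily, uscg_families

# 20 canonical residues plus the usual ambiguity/placeholder codes emitted by
# gene callers.
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBJZXUO*")


class ReferenceDBError(ValueError):
    """Raised when a reference FASTA / family map fails validation."""


@dataclass
class ReferenceDB:
    """Validated marker (or gene) reference set.

    Attributes
    ----------
    families
        One entry per family; the bundled USCG set has exactly 14.
    seq_lengths_aa
        Protein length in residues for every member sequence.
    seq_to_family
        Family membership of every member sequence; a sequence belongs to
        exactly one family.
    """

    families: list[USCGFamily]
    seq_lengths_aa: dict[str, int] = field(default_factory=dict)
    seq_to_family: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [f.family_name for f in self.families]
        if len(names) != len(set(names)):
            raise ReferenceDBError("duplicate family names in ReferenceDB")
        for fam in self.families:
            for sid in fam.member_seq_ids:
                if sid not in self.seq_lengths_aa:
                    raise ReferenceDBError(
                        f"member sequence {sid!r} of family {fam.family_name!r} "
                        "has no recorded length"
                    )
                if self.seq_to_family.get(sid) != fam.family_name:
                    raise ReferenceDBError(
                        f"sequence {sid!r} not mapped to family {fam.family_name!r}"
                    )
        for sid, length in self.seq_lengths_aa.items():
            if length <= 0:
                raise ReferenceDBError(f"non-positive length for sequence {sid!r}")

    @property
    def family_names(self) -> list[str]:
        return [f.family_name for f in self.families]

    @property
    def n_families(self) -> int:
        return len(self.families)

    def subject_length_aa(self, seq_id: str) -> int:
        try:
            return self.seq_lengths_aa[seq_id]
        except KeyError:
            raise ReferenceDBError(f"unknown reference sequence {seq_id!r}") from None

    def family_of(self, seq_id: str) -> str:
        try:
            return self.seq_to_family[seq_id]
        except KeyError:
            raise ReferenceDBError(f"unknown reference sequence {seq_id!r}") from None


def _read_family_map(path: Path) -> dict[str, str]:
    """Parse the two-column (seq_id, family_name) TSV; header row optional.

    A first row whose second column is not a known family name AND whose
    first column looks like a label ("seq", "id", ...) is treated as a header.
    """
    mapping: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ReferenceDBError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            rows.append((parts[0].strip(), parts[1].strip()))
    if not rows:
        raise ReferenceDBError(f"{path}: empty family map")
    first_id, first_fam = rows[0]
    if first_fam not in FAMILY_NAMES and first_id.lower() in {
        "seq_id",
        "seqid",
        "sequence",
        "id",
    }:
        rows = rows[1:]
    for seq_id, fam in rows:
        if seq_id in mapping:
            raise ReferenceDBError(f"duplicate sequence id {seq_id!r} in family map")
        mapping[seq_id] = fam
    return mapping


def load_reference_db(fasta_path: str | Path, family_map_path: str | Path) -> ReferenceDB:
    """Load and validate a reference database.

    Lengths are computed from the FASTA records; every mapped sequence must be
    present in the FASTA and vice versa. Family names outside the bundled
    14-name set are accepted with a warning (user gene databases may extend
    the set).
    """
    fasta_path = Path(fasta_path)
    family_map_path = Path(family_map_path)

    lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in lengths:
            raise ReferenceDBError(f"duplicate sequence id {rec.id!r} in {fasta_path}")
        if len(rec.seq) == 0:
            raise ReferenceDBError(f"empty sequence {rec.id!r} in {fasta_path}")
        lengths[rec.id] = len(rec.seq)
    if not lengths:
        raise ReferenceDBError(f"{fasta_path}: no FASTA records")

    mapping = _read_family_map(family_map_path)
    for seq_id in mapping:
        if seq_id not in lengths:
            raise ReferenceDBError(
                f"family map references sequence {seq_id!r} absent from {fasta_path}"
            )
    unmapped = set(lengths) - set(mapping)
    if unmapped:
        raise ReferenceDBError(
            "sequences present in FASTA but missing from family map: "
            + ", ".join(sorted(unmapped)[:5])
        )

    known = {f.family_name: f for f in uscg_families()}
    families: dict[str, USCGFamily] = {}
    for seq_id, fam_name in mapping.items():
        if fam_name not in families:
            if fam_name in known:
                families[fam_name] = known[fam_name]
            else:
                warnings.warn(
                    f"family {fam_name!r} is not one of the 14 bundled USCG "
                    "families; treating it as a user-defined family",
                    stacklevel=2,
                )
                families[fam_name] = USCGFamily(
                    family_name=fam_name, ko_ids=["user"], cog_id="user"
                )
        families[fam_name].member_seq_ids.append(seq_id)

    return ReferenceDB(
        families=list(families.values()),
        seq_lengths_aa=lengths,
        seq_to_family=dict(mapping),
    )


def _global_identity(aligner: PairwiseAligner, a: str, b: str) -> float:
    """Fraction of identical columns in one optimal global alignment of a, b."""
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def dereplicate_references(
    seqs: list[tuple[str, str]],
    identity_threshold: float = 0.60,
) -> list[tuple[str, str]]:
    """Greedy length-first clustering; returns one representative per cluster.

    Sequences are sorted by length descending (ties broken by id ascending);
    each sequence joins the first existing cluster whose representative shares
    at least ``identity_threshold`` global identity (identical columns divided
    by alignment length), otherwise it founds a new cluster. The default 0.60
    mirrors the 60 % identity customarily used to dereplicate marker
    references before translated search. Deterministic; no word-filter
    heuristics, so results need not be bit-identical to external clustering
    tools — a precomputed representative FASTA can be supplied instead.
    """
    if not seqs:
        raise ReferenceDBError("dereplicate_references: empty input")
    if not (0.0 < identity_threshold <= 1.0):
        raise ReferenceDBError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    bad = [sid for sid, s in seqs if not s or set(s.upper()) - _AA_ALPHABET]
    if bad:
        raise ReferenceDBError(
            "non-amino-acid characters (or empty sequence) in: " + ", ".join(sorted(bad))
        )

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5

    ordered = sorted(seqs, key=lambda kv: (-len(kv[1]), kv[0]))
    representatives: list[tuple[str, str]] = []
    for sid, seq in ordered:
        placed = False
        for rid, rseq in representatives:
            if _global_identity(aligner, rseq.upper(), seq.upper()) >= identity_threshold:
                placed = True
                break
        if not placed:
            representatives.append((sid, seq))
    return representatives


def assign_to_representatives(
    seqs: list[tuple[str, str]],
    identity_threshold: float = 0.60,
) -> dict[str, str]:
    """Cluster membership map (seq id -> representative id) for the same greedy
    procedure as :func:`dereplicate_references`."""
    if not seqs:
        raise ReferenceDBError("assign_to_representatives: empty input")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5

    ordered = sorted(seqs, key=lambda kv: (-len(kv[1]), kv[0]))
    membership: dict[str, str] = {}
    representatives: list[tuple[str, str]] = []
    for sid, seq in ordered:
        placed = False
        for rid, rseq in representatives:
            if _global_identity(aligner, rseq.upper(), seq.upper()) >= identity_threshold:
                membership[sid] = rid
                placed = True
                break
        if not placed:
            representatives.append((sid, seq))
            membership[sid] = sid
    return membership
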