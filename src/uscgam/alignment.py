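"""Tabular ("m6" / outfmt-6) alignment parsing, best-hit selection, filters.

The pipeline consumes DIAMOND/BLAST tabular output. The native dialect is an
8-field layout carrying everything the abundance math needs:

    qseqid  sseqid  pident  length  evalue  bitscore  slen  qcovhsp

The standard 12-field BLAST outfmt-6 is also accepted when subject lengths
can be resolved through a reference database; query coverage is then
computed from qstart/qend only if a read-length table is available, so the
8-field dialect is preferred.

Best-hit selection emulates aligner-side truncation (one hit per query,
highest bitscore) and is applied BEFORE threshold filtering: if a query's
best hit fails the filters the query is lost, exactly as when the aligner
itself reports a single alignment per read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

DEFAULT_M6_COLUMNS: tuple[str, ...] = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "evalue",
    "bitscore",
    "slen",
    "qcovhsp",
)

#: USCG-side hit filter defaults: bitscore >= 40 and query coverage >= 80 %.
USCG_MIN_BITSCORE: float = 40.0
USCG_MIN_QCOV: float = 80.0
#: Gene-side hit filter defaults: identity >= 50 % and query coverage >= 80 %.
GENE_MIN_IDENTITY: float = 50.0
GENE_MIN_QCOV: float = 80.0


class M6ParseError(ValueError):
    """Raised for a malformed m6 file; the message names the line."""


@dataclass(frozen=True)
class AlignmentHit:
    """One parsed alignment row (one HSP)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_coverage: float
    subject_length_aa: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(
                f"percent_identity out of [0, 100]: {self.percent_identity}"
            )
        if not (0.0 <= self.query_coverage <= 100.0):
            raise ValueError(f"query_coverage out of [0, 100]: {self.query_coverage}")
        if self.subject_length_aa < 1:
            raise ValueError(f"subject_length_aa must be >= 1: {self.subject_length_aa}")
        if self.alignment_length < 1:
            raise ValueError(f"alignment_length must be >= 1: {self.alignment_length}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")


_NUMERIC_FIELDS = {
    "pident": float,
    "length": int,
    "mismatch": int,
    "gapopen": int,
    "qstart": int,
    "qend": int,
    "sstart": int,
    "send": int,
    "evalue": float,
    "bitscore": float,
    "slen": int,
    "qcovhsp": float,
    "qlen": int,
}


def parse_m6(
    m6_path: str | Path,
    column_spec: Sequence[str] = DEFAULT_M6_COLUMNS,
    subject_lengths_aa: dict[str, int] | None = None,
) -> list[AlignmentHit]:
    """Parse a tab-separated alignment file into :class:`AlignmentHit` rows.

    Rows are preserved in file order. ``column_spec`` names the fields in
    order; it must include qseqid, sseqid, pident, length, evalue, bitscore
    and qcovhsp, plus either slen or ``subject_lengths_aa`` to resolve
    subject lengths (as with the 12-field standard outfmt-6).

    Raises
    ------
    M6ParseError
        On a wrong column count or an unparseable numeric field, naming the
        1-based line number.
    """
    path = Path(m6_path)
    columns = list(column_spec)
    required = {"qseqid", "sseqid", "pident", "length", "evalue", "bitscore", "qcovhsp"}
    missing = required - set(columns)
    if missing:
        raise M6ParseError(f"column_spec missing required fields: {sorted(missing)}")
    if "slen" not in columns and subject_lengths_aa is None:
        raise M6ParseError(
            "column_spec has no 'slen' and no subject_lengths_aa mapping was given"
        )

    idx = {name: i for i, name in enumerate(columns)}
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(columns):
                raise M6ParseError(
                    f"{path}: line {lineno}: expected {len(columns)} columns, "
                    f"got {len(parts)}"
                )
            row: dict[str, object] = {}
            for name, value in zip(columns, parts):
                caster = _NUMERIC_FIELDS.get(name)
                if caster is None:
                    row[name] = value
                    continue
                try:
                    row[name] = caster(value)
                except ValueError:
                    raise M6ParseError(
                        f"{path}: line {lineno}: field {name!r} is not numeric: "
                        f"{value!r}"
                    ) from None
            if "slen" in row:
                slen = int(row["slen"])  # type: ignore[arg-type]
            else:
                assert subject_lengths_aa is not None
                try:
                    slen = subject_lengths_aa[str(row["sseqid"])]
                except KeyError:
                    raise M6ParseError(
                        f"{path}: line {lineno}: subject {row['sseqid']!r} has no "
                        "known length"
                    ) from None
            try:
                hits.append(
                    AlignmentHit(
                        query_id=str(row["qseqid"]),
                        subject_id=str(row["sseqid"]),
                        percent_identity=float(row["pident"]),  # type: ignore[arg-type]
                        alignment_length=int(row["length"]),  # type: ignore[arg-type]
                        evalue=float(row["evalue"]),  # type: ignore[arg-type]
                        bitscore=float(row["bitscore"]),  # type: ignore[arg-type]
                        query_coverage=float(row["qcovhsp"]),  # type: ignore[arg-type]
                        subject_length_aa=slen,
                    )
                )
            except ValueError as exc:
                raise M6ParseError(f"{path}: line {lineno}: {exc}") from None
    return hits


def write_m6(hits: Iterable[AlignmentHit], out_path: str | Path) -> None:
    """Write hits in the native 8-field dialect (inverse of :func:`parse_m6`)."""
    with open(out_path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:g}\t"
                f"{h.alignment_length}\t{h.evalue:g}\t{h.bitscore:g}\t"
                f"{h.subject_length_aa}\t{h.query_coverage:g}\n"
            )


def best_hit_per_query(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Keep exactly one hit per query.

    Selection key: highest bitscore, then lowest e-value, then
    lexicographically smallest subject id — a deterministic emulation of
    single-best-hit aligner output (``--max-target-seqs 1 --max-hsps 1``).
    Output order follows each query's first appearance in the input.
    """
    best: dict[str, AlignmentHit] = {}
    order: list[str] = []
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
            order.append(hit.query_id)
            continue
        if (-hit.bitscore, hit.evalue, hit.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[hit.query_id] = hit
    return [best[q] for q in order]


def filter_uscg_hits(
    hits: Sequence[AlignmentHit],
    min_bitscore: float = USCG_MIN_BITSCORE,
    min_query_coverage: float = USCG_MIN_QCOV,
) -> list[AlignmentHit]:
    """Marker-side filter: bitscore and query coverage, both inclusive.

    Identity is deliberately not tested here; the marker references are
    conserved enough that bitscore + coverage carry the specificity.
    """
    return [
        h
        for h in hits
        if h.bitscore >= min_bitscore and h.query_coverage >= min_query_coverage
    ]


def filter_gene_hits(
    hits: Sequence[AlignmentHit],
    min_identity: float = GENE_MIN_IDENTITY,
    min_query_coverage: float = GENE_MIN_QCOV,
) -> list[AlignmentHit]:
    """Gene-side filter: percent identity and query coverage, both inclusive."""
    return [
        h
        for h in hits
        if h.percent_identity >= min_identity and h.query_coverage >= min_query_coverage
    ]
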