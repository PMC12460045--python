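"""Read counting with the minimum-length filter.

The per-sample total read count (TRC) is the RPKM denominator: the number of
reads surviving the minimum-length filter. Reads *shorter than* the threshold
are discarded; a read of exactly the threshold length is retained. TRC is
stored as a raw count — the 10^9 factor of the RPKM formula supplies the
per-million and per-kilobase scalings.

For paired-end data only the forward (R1) file should be counted; the CLI
enforces this by accepting a single reads file per sample.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO

from Bio import SeqIO


class ReadStatsError(ValueError):
    """Raised for unreadable, empty or truncated read files."""


@dataclass(frozen=True)
class SampleReadStats:
    """Per-sample read tally after length filtering."""

    sample_id: str
    trc: int
    n_discarded_short: int
    min_length_bp: int = 50

    def __post_init__(self) -> None:
        if self.min_length_bp < 1:
            raise ReadStatsError(f"min_length_bp must be >= 1, got {self.min_length_bp}")
        if self.trc < 0 or self.n_discarded_short < 0:
            raise ReadStatsError("negative read counts")

    @property
    def total_records(self) -> int:
        return self.trc + self.n_discarded_short


def _open_maybe_gzip(path: Path) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _detect_format(handle: IO[str], path: Path) -> str:
    first = handle.read(1)
    handle.seek(0)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    if first == "":
        raise ReadStatsError(f"{path}: empty file")
    raise ReadStatsError(
        f"{path}: cannot detect format (first byte {first!r}; expected '>' or '@')"
    )


def count_reads(
    reads_path: str | Path,
    min_length_bp: int = 50,
    sample_id: str | None = None,
) -> SampleReadStats:
    """Count reads in a FASTA/FASTQ file (plain or gzip), applying the
    minimum-length filter.

    Parameters
    ----------
    reads_path
        Reads file; format auto-detected from the first byte ('>' FASTA,
        '@' FASTQ); gzip detected from the magic bytes.
    min_length_bp
        Reads with sequence length >= this are retained (default 50 bp).
    sample_id
        Defaults to the file stem (with .fastq/.fasta/.gz suffixes stripped).

    Raises
    ------
    ReadStatsError
        On an empty or unreadable file, a file with zero records, or a
        truncated FASTQ record (reported with its record index).
    """
    path = Path(reads_path)
    if min_length_bp < 1:
        raise ReadStatsError(f"min_length_bp must be >= 1, got {min_length_bp}")
    if not path.exists():
        raise ReadStatsError(f"{path}: no such file")

    if sample_id is None:
        sample_id = path.name
        for suffix in (".gz", ".fastq", ".fq", ".fasta", ".fa", ".fna"):
            if sample_id.endswith(suffix):
                sample_id = sample_id[: -len(suffix)]

    kept = 0
    short = 0
    with _open_maybe_gzip(path) as handle:
        fmt = _detect_format(handle, path)
        record_index = 0
        try:
            for rec in SeqIO.parse(handle, fmt):
                record_index += 1
                if len(rec.seq) >= min_length_bp:
                    kept += 1
                else:
                    short += 1
        except ValueError as exc:  # Bio.SeqIO signals malformed records this way
            raise ReadStatsError(
                f"{path}: malformed {fmt.upper()} near record {record_index + 1}: {exc}"
            ) from exc

    if kept + short == 0:
        raise ReadStatsError(f"{path}: no sequence records (empty sample)")
    return SampleReadStats(
        sample_id=sample_id, trc=kept, n_discarded_short=short, min_length_bp=min_length_bp
    )


def write_stats_tsv(stats: list[SampleReadStats], out_path: str | Path) -> None:
    """Write the per-sample stats table (sample_id, trc, n_discarded_short)."""
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write("sample_id\ttrc\tn_discarded_short\tmin_length_bp\n")
        for s in stats:
            fh.write(f"{s.sample_id}\t{s.trc}\t{s.n_discarded_short}\t{s.min_length_bp}\n")
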