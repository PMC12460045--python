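"""End-to-end wiring: m6 / RG-table inputs to profile and GAM tables.

Two entry points produce GAM: the full alignment path (gene m6 file through
best-hit selection, filtering and RPKM) and a precomputed per-gene RPKM
table. On matched inputs they yield identical output.

Table formats (all TSV, NA as the literal ``NA``, numbers at 6 significant
digits; re-running on identical inputs is byte-identical):

* profile table — one row per sample: sample_id, one column per marker
  family (RUSCG, RPKM), mruscg, cv_ruscg.
* RG table      — long form: sample_id, gene_id, rg.
* GAM matrix    — samples x genes, percent.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .abundance import (
    AbundanceProfile,
    family_ruscg,
    gam,
    gene_rg,
)
from .alignment import (
    best_hit_per_query,
    filter_gene_hits,
    filter_uscg_hits,
    parse_m6,
)
from .config import RunConfig
from .reference_db import ReferenceDB
from .sequence_stats import SampleReadStats


class PipelineError(ValueError):
    """A stage failure, annotated with the stage name."""


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.6g}"


def uscg_profile_from_m6(
    m6_path: str | Path,
    db: ReferenceDB,
    stats: SampleReadStats,
    config: RunConfig | None = None,
) -> AbundanceProfile:
    """Marker m6 file -> finalized per-sample abundance profile."""
    config = config or RunConfig()
    try:
        hits = parse_m6(m6_path)
    except ValueError as exc:
        raise PipelineError(f"uscg/parse: {exc}") from exc
    hits = best_hit_per_query(hits)
    hits = filter_uscg_hits(
        hits,
        min_bitscore=config.uscg_min_bitscore,
        min_query_coverage=config.uscg_min_coverage,
    )
    try:
        profile = family_ruscg(hits, db, stats, aa_to_bp=config.aa_to_bp)
    except ValueError as exc:
        raise PipelineError(f"uscg/abundance: {exc}") from exc
    return profile.finalize(zero_policy=config.zero_policy)


def rg_from_m6(
    m6_path: str | Path,
    gene_db_lengths_aa: Mapping[str, int] | None,
    stats: SampleReadStats,
    config: RunConfig | None = None,
) -> dict[str, float]:
    """Gene m6 file -> per-gene RPKM (RG) table for one sample.

    Subject lengths come from the m6 ``slen`` column; a
    ``gene_db_lengths_aa`` mapping backs the 12-column dialect.
    """
    config = config or RunConfig()
    try:
        hits = parse_m6(m6_path, subject_lengths_aa=dict(gene_db_lengths_aa or {}) or None)
    except ValueError as exc:
        raise PipelineError(f"gene/parse: {exc}") from exc
    hits = best_hit_per_query(hits)
    hits = filter_gene_hits(
        hits,
        min_identity=config.filter_identity,
        min_query_coverage=config.filter_coverage,
    )
    lengths = dict(gene_db_lengths_aa or {})
    for h in hits:
        lengths.setdefault(h.subject_id, h.subject_length_aa)
    try:
        return gene_rg(hits, lengths, stats, aa_to_bp=config.aa_to_bp)
    except ValueError as exc:
        raise PipelineError(f"gene/abundance: {exc}") from exc


# ---------------------------------------------------------------------------
# tables


def write_profile_tsv(
    profiles: Sequence[AbundanceProfile],
    out_path: str | Path,
) -> None:
    if not profiles:
        raise PipelineError("profile/write: no profiles")
    family_names = list(profiles[0].ruscg.keys())
    with open(out_path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(family_names) + "\tmruscg\tcv_ruscg\n")
        for p in profiles:
            if list(p.ruscg.keys()) != family_names:
                raise PipelineError(
                    f"profile/write: sample {p.sample_id!r} has a different family set"
                )
            cells = [_fmt(p.ruscg[f]) for f in family_names]
            fh.write(
                f"{p.sample_id}\t" + "\t".join(cells)
                + f"\t{_fmt(p.mruscg)}\t{_fmt(p.cv_ruscg)}\n"
            )


def read_profile_tsv(path: str | Path) -> list[AbundanceProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    needed = {"sample_id", "mruscg", "cv_ruscg"}
    if not needed.issubset(df.columns):
        raise PipelineError(f"profile/read: {path} missing columns {sorted(needed - set(df.columns))}")
    family_cols = [c for c in df.columns if c not in needed]
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            AbundanceProfile(
                sample_id=row["sample_id"],
                ruscg={f: float(row[f]) for f in family_cols},
                mruscg=float(row["mruscg"]) if pd.notna(row["mruscg"]) else float("nan"),
                cv_ruscg=float(row["cv_ruscg"]) if pd.notna(row["cv_ruscg"]) else float("nan"),
            )
        )
    return profiles


def write_rg_table(
    rg_by_sample: Mapping[str, Mapping[str, float]],
    out_path: str | Path,
) -> None:
    with open(out_path, "w") as fh:
        fh.write("sample_id\tgene_id\trg\n")
        for sample in rg_by_sample:
            for gene in sorted(rg_by_sample[sample]):
                fh.write(f"{sample}\t{gene}\t{_fmt(rg_by_sample[sample][gene])}\n")


def read_rg_table(path: str | Path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    needed = {"sample_id", "gene_id", "rg"}
    if not needed.issubset(df.columns):
        raise PipelineError(f"rg/read: {path} missing columns {sorted(needed - set(df.columns))}")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["sample_id"], {})[row["gene_id"]] = float(row["rg"])
    return out


def gam_matrix(
    rg_by_sample: Mapping[str, Mapping[str, float]],
    profiles: Sequence[AbundanceProfile],
) -> pd.DataFrame:
    """Samples x genes GAM matrix (percent), NA-safe.

    Sample ids of the RG input and the profiles must match exactly; a gene
    absent from a sample gets RG 0 and hence GAM 0 (or NA when that sample's
    MRUSCG is NA).
    """
    prof_ids = [p.sample_id for p in profiles]
    rg_ids = list(rg_by_sample.keys())
    unmatched = sorted(set(prof_ids) ^ set(rg_ids))
    if unmatched:
        raise PipelineError(
            "gam: sample ids of the RG input and profiles do not match; "
            f"unmatched: {unmatched}"
        )
    genes = sorted({g for table in rg_by_sample.values() for g in table})
    by_id = {p.sample_id: p for p in profiles}
    data = {
        gene: [
            gam(rg_by_sample[s].get(gene, 0.0), by_id[s].mruscg) for s in prof_ids
        ]
        for gene in genes
    }
    return pd.DataFrame(data, index=pd.Index(prof_ids, name="sample_id"))


def write_gam_tsv(matrix: pd.DataFrame, out_path: str | Path) -> None:
    with open(out_path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
        for sample, row in matrix.iterrows():
            fh.write(str(sample) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_gam_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
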