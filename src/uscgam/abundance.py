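"""Abundance math: RPKM, per-family marker abundance, geometric-mean
community size, GAM, CV, and the CPM/TPM utilities.

The chain is::

    RPKM        = MRC x 10^9 / (TRC x gene_length_bp)          (per subject)
    RUSCG_f     = sum of member-subject RPKMs of family f      (per sample)
    MRUSCG      = geometric mean of the 14 RUSCG values        (per sample)
    GAM         = RG / MRUSCG x 100 %                          (per gene)

MRC is the retained (best-hit, filtered) alignment count for a subject; TRC
the sample's length-filtered read total. Subject lengths from translated
search are amino acids and are converted to bp (x3) before the RPKM formula;
pass ``aa_to_bp=1`` for nucleotide reference databases.

A marker family with zero retained hits makes the geometric mean collapse;
the default policy reports MRUSCG (and every downstream GAM) as NA rather
than 0, which would otherwise send every GAM to infinity. A pseudocount
policy is available for exploratory use.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .alignment import AlignmentHit
from .reference_db import ReferenceDB
from .sequence_stats import SampleReadStats

logger = logging.getLogger(__name__)

#: Default pseudocount (RPKM) substituted for zero marker abundances under
#: the "pseudocount" zero policy.
DEFAULT_PSEUDOCOUNT: float = 1e-6

ZERO_POLICIES = ("na", "error", "pseudocount")


class AbundanceError(ValueError):
    """Raised for invalid abundance-math inputs."""


def rpkm(mrc: int, trc: int, gene_length_bp: int) -> float:
    """Reads per kilobase per million mapped reads.

    ``mrc x 10^9 / (trc x gene_length_bp)`` with TRC as a raw read count;
    the 10^9 combines the per-million read scaling with per-kilobase length
    scaling.
    """
    if trc < 1:
        raise AbundanceError(f"trc must be >= 1, got {trc}")
    if gene_length_bp < 1:
        raise AbundanceError(f"gene_length_bp must be >= 1, got {gene_length_bp}")
    if mrc < 0:
        raise AbundanceError(f"mrc must be >= 0, got {mrc}")
    return mrc * 1e9 / (trc * gene_length_bp)


def geometric_mean(
    values: Sequence[float],
    zero_policy: str = "na",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Geometric mean, computed in log space.

    Parameters
    ----------
    values
        Non-negative reals, non-empty.
    zero_policy
        "na"          -> return NaN if any value is zero (default; the zero
                         entries are logged);
        "error"       -> raise;
        "pseudocount" -> substitute ``pseudocount`` for zeros.
    """
    if len(values) == 0:
        raise AbundanceError("geometric_mean: empty input")
    if zero_policy not in ZERO_POLICIES:
        raise AbundanceError(f"unknown zero_policy {zero_policy!r}")
    vals = list(values)
    for v in vals:
        if v < 0:
            raise AbundanceError(f"geometric_mean: negative value {v}")
    zeros = [i for i, v in enumerate(vals) if v == 0.0]
    if zeros:
        if zero_policy == "error":
            raise AbundanceError(f"geometric_mean: zero values at positions {zeros}")
        if zero_policy == "na":
            logger.warning(
                "geometric mean undefined: %d zero value(s) at positions %s",
                len(zeros),
                zeros,
            )
            return float("nan")
        vals = [pseudocount if v == 0.0 else v for v in vals]
    return math.exp(sum(math.log(v) for v in vals) / len(vals))


def gam(rg: float, mruscg: float) -> float:
    """Gene abundance in the microbial community, in percent.

    ``rg / mruscg x 100`` — interpretable as gene copies per genome
    equivalent, in percent. NA (NaN) MRUSCG propagates; a zero or negative
    MRUSCG also yields NA.
    """
    if rg < 0:
        raise AbundanceError(f"rg must be >= 0, got {rg}")
    if mruscg is None or math.isnan(mruscg) or mruscg <= 0:
        return float("nan")
    return rg / mruscg * 100.0


def cv(values: Sequence[float], use_sample_sd: bool = True) -> float:
    """Coefficient of variation: standard deviation / mean.

    Sample (n-1) standard deviation by default — the 14 marker families are
    treated as a sample of the genome's single-copy content. Returns NA when
    the mean is non-positive.
    """
    n = len(values)
    if n < 2:
        raise AbundanceError(f"cv requires n >= 2, got n = {n}")
    mean = sum(values) / n
    if mean <= 0:
        return float("nan")
    ddof = 1 if use_sample_sd else 0
    var = sum((v - mean) ** 2 for v in values) / (n - ddof)
    return math.sqrt(var) / mean


@dataclass
class AbundanceProfile:
    """Per-sample marker-family abundances and the derived community size.

    ``ruscg`` maps every family of the reference database to its RPKM;
    ``mruscg`` is their geometric mean (NA under the default policy when any
    family is absent) and ``cv_ruscg`` the coefficient of variation of the
    family values, a per-sample quality diagnostic.
    """

    sample_id: str
    ruscg: dict[str, float] = field(default_factory=dict)
    mruscg: float = float("nan")
    cv_ruscg: float = float("nan")

    def finalize(
        self,
        zero_policy: str = "na",
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "AbundanceProfile":
        """Compute ``mruscg`` and ``cv_ruscg`` from the filled ``ruscg``."""
        vals = list(self.ruscg.values())
        self.mruscg = geometric_mean(vals, zero_policy=zero_policy, pseudocount=pseudocount)
        self.cv_ruscg = cv(vals) if len(vals) >= 2 else float("nan")
        return self


@dataclass(frozen=True)
class GeneAbundance:
    """One gene's RPKM (``rg``) and community-normalised abundance (``gam``)."""

    sample_id: str
    gene_id: str
    rg: float
    gam: float


def _per_subject_rpkm(
    hits: Iterable[AlignmentHit],
    subject_length_aa: Callable[[str], int],
    trc: int,
    aa_to_bp: int,
) -> dict[str, float]:
    mrc: dict[str, int] = {}
    for h in hits:
        mrc[h.subject_id] = mrc.get(h.subject_id, 0) + 1
    return {
        sid: rpkm(count, trc, subject_length_aa(sid) * aa_to_bp)
        for sid, count in mrc.items()
    }


def family_ruscg(
    filtered_hits: Sequence[AlignmentHit],
    db: ReferenceDB,
    stats: SampleReadStats,
    aa_to_bp: int = 3,
) -> AbundanceProfile:
    """Per-family marker abundance (RUSCG, in RPKM) for one sample.

    ``filtered_hits`` must already be best-hit-per-query and marker-filtered.
    Each subject's mapped-read count is turned into an RPKM with its own
    length; a family's RUSCG is the sum over its member subjects, so families
    whose references differ in length remain well defined. Families with no
    hits get RUSCG = 0. ``mruscg``/``cv_ruscg`` are left for
    :meth:`AbundanceProfile.finalize`.
    """
    per_subject = _per_subject_rpkm(
        filtered_hits, db.subject_length_aa, stats.trc, aa_to_bp
    )
    ruscg = {name: 0.0 for name in db.family_names}
    for sid, value in per_subject.items():
        ruscg[db.family_of(sid)] += value
    return AbundanceProfile(sample_id=stats.sample_id, ruscg=ruscg)


def default_gene_name_rule(subject_id: str) -> str:
    """Gene id = substring before the first '|', else the whole subject id."""
    return subject_id.split("|", 1)[0]


def gene_rg(
    filtered_hits: Sequence[AlignmentHit],
    gene_db_lengths_aa: Mapping[str, int],
    stats: SampleReadStats,
    gene_name_rule: Callable[[str], str] = default_gene_name_rule,
    aa_to_bp: int = 3,
) -> dict[str, float]:
    """Per-gene RPKM (RG) for one sample.

    ``filtered_hits`` must already be best-hit-per-query and gene-filtered.
    Subjects are tallied individually (own length in the RPKM), then grouped
    into genes by ``gene_name_rule`` and summed.
    """
    def lookup(sid: str) -> int:
        try:
            return gene_db_lengths_aa[sid]
        except KeyError:
            raise AbundanceError(f"subject {sid!r} has no known length") from None

    per_subject = _per_subject_rpkm(filtered_hits, lookup, stats.trc, aa_to_bp)
    out: dict[str, float] = {}
    for sid, value in per_subject.items():
        gid = gene_name_rule(sid)
        out[gid] = out.get(gid, 0.0) + value
    return out


def gene_abundances(
    rg_table: Mapping[str, float],
    profile: AbundanceProfile,
) -> list[GeneAbundance]:
    """Combine a per-gene RG table with a finalized profile into GAM records."""
    return [
        GeneAbundance(
            sample_id=profile.sample_id,
            gene_id=gid,
            rg=value,
            gam=gam(value, profile.mruscg),
        )
        for gid, value in rg_table.items()
    ]


def tpm(
    counts: Mapping[str, int],
    lengths_bp: Mapping[str, int],
) -> dict[str, float]:
    """Transcripts per million: length-normalised rates rescaled to sum 10^6.

    Unlike RPKM, the TPM of all genes in a sample always sums to 10^6, which
    makes values directly comparable across samples.
    """
    if set(counts) != set(lengths_bp):
        raise AbundanceError("tpm: counts and lengths must share one key set")
    if not counts:
        raise AbundanceError("tpm: empty input")
    for g, length in lengths_bp.items():
        if length < 1:
            raise AbundanceError(f"tpm: non-positive length for {g!r}")
    rates = {g: counts[g] / lengths_bp[g] for g in counts}
    total = sum(rates.values())
    if total <= 0:
        raise AbundanceError("tpm: all counts are zero")
    return {g: rate / total * 1e6 for g, rate in rates.items()}


def cpm(counts: Mapping[str, int]) -> dict[str, float]:
    """Counts per million: counts rescaled to sum 10^6 (no length term)."""
    if not counts:
        raise AbundanceError("cpm: empty input")
    total = sum(counts.values())
    if total <= 0:
        raise AbundanceError("cpm: all counts are zero")
    return {g: c / total * 1e6 for g, c in counts.items()}
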