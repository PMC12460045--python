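"""Synthetic communities with known gene carriage, for parameter recovery.

The simulator emulates a shotgun-sequenced community of ``n_genomes``
genomes. Every genome carries exactly one copy of each of the 14 marker
families (the single-copy assumption); a known fraction of genomes also
carries one copy of a target gene. Each genome is modelled as a fixed-size
stretch of ``genome_length_bp`` of which the marker and gene loci occupy
length-proportional slices; the remainder is unaligned background. Reads are
thrown multinomially across (genome x locus-or-background) cells with
probability ``abundance_g x locus_bp / genome_length_bp``, so the expected
mapped-read count of every locus is depth-proportional and the pipeline's
GAM estimate is unbiased for the abundance-weighted carriage:

    GAM_true = 100 x sum of carrier-genome abundances.

Reads are error-free; hit attributes (identity, coverage, bitscore) are
jittered above the default filter thresholds. The simulator exercises the
normalisation math, not an aligner.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import AlignmentHit, write_m6
from .families import DEFAULT_FAMILY_LENGTHS_AA, FAMILY_NAMES
from .sequence_stats import SampleReadStats


class SimulationError(ValueError):
    """Raised for an invalid community specification."""


@dataclass
class CommunitySpec:
    """Ground-truth description of one simulated community.

    Parameters
    ----------
    n_genomes
        Number of genomes in the community.
    carriage_fraction
        Fraction of genomes bearing the target gene, in [0, 1]. The first
        ``round(carriage_fraction * n_genomes)`` genomes are the carriers.
    genome_abundances
        Relative depths, one per genome; normalised to sum 1. Default
        uniform.
    n_reads
        Total reads drawn (the sample's TRC in the tabular-alignment
        scenario).
    read_length_bp
        Read length; >= 50 so simulated reads survive the length filter.
    uscg_length_aa
        Per-family marker protein lengths (aa). Defaults to typical
        ribosomal-protein lengths.
    gene_length_aa
        Target gene protein length (aa); default 1245, a nitrate-reductase
        catalytic subunit scale.
    genome_length_bp
        Common genome size; loci occupy length-proportional slices of it.
        Default 500 kb — a scaled-down genome that keeps simulations
        desk-sized while giving each marker tens-to-hundreds of reads at the
        default depth.
    decoy_fraction
        Fraction of reads emitted as sub-50-bp decoys (read simulation only),
        to exercise the length filter.
    seed
        Mandatory RNG seed; all sampling derives from it in a fixed order.
    """

    n_genomes: int
    carriage_fraction: float
    seed: int
    genome_abundances: np.ndarray | None = None
    n_reads: int = 200_000
    read_length_bp: int = 150
    uscg_length_aa: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_LENGTHS_AA)
    )
    gene_length_aa: int = 1245
    gene_name: str = "narG"
    genome_length_bp: int = 500_000
    decoy_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise SimulationError(f"n_genomes must be >= 1, got {self.n_genomes}")
        if not (0.0 <= self.carriage_fraction <= 1.0):
            raise SimulationError(
                f"carriage_fraction must be in [0, 1], got {self.carriage_fraction}"
            )
        if self.n_reads < 1:
            raise SimulationError(f"n_reads must be >= 1, got {self.n_reads}")
        if self.read_length_bp < 50:
            raise SimulationError(
                f"read_length_bp must be >= 50, got {self.read_length_bp}"
            )
        if not (0.0 <= self.decoy_fraction < 1.0):
            raise SimulationError(
                f"decoy_fraction must be in [0, 1), got {self.decoy_fraction}"
            )
        if set(self.uscg_length_aa) != set(FAMILY_NAMES):
            raise SimulationError(
                "uscg_length_aa must provide a length for each of the 14 families"
            )
        if self.gene_length_aa < 1:
            raise SimulationError("gene_length_aa must be >= 1")
        if self.genome_abundances is None:
            self.genome_abundances = np.full(self.n_genomes, 1.0 / self.n_genomes)
        else:
            ab = np.asarray(self.genome_abundances, dtype=float)
            if ab.shape != (self.n_genomes,):
                raise SimulationError(
                    f"genome_abundances must have length {self.n_genomes}"
                )
            if np.any(ab <= 0):
                raise SimulationError("genome_abundances must be positive")
            self.genome_abundances = ab / ab.sum()
        locus_bp = sum(v * 3 for v in self.uscg_length_aa.values()) + self.gene_length_aa * 3
        if locus_bp > self.genome_length_bp:
            raise SimulationError(
                f"genome_length_bp ({self.genome_length_bp}) smaller than the "
                f"combined locus length ({locus_bp})"
            )

    @property
    def n_carriers(self) -> int:
        return round(self.carriage_fraction * self.n_genomes)

    @property
    def carrier_abundance(self) -> float:
        assert self.genome_abundances is not None
        return float(self.genome_abundances[: self.n_carriers].sum())

    @property
    def gam_true(self) -> float:
        """Expected GAM (%): abundance-weighted gene carriage."""
        return 100.0 * self.carrier_abundance


@dataclass(frozen=True)
class CommunityTruth:
    """What the pipeline should recover from a simulated sample."""

    gam_true: float
    carrier_abundance: float
    expected_ruscg: dict[str, float]
    expected_rg: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "gam_true": self.gam_true,
                    "carrier_abundance": self.carrier_abundance,
                    "expected_ruscg": self.expected_ruscg,
                    "expected_rg": self.expected_rg,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _truth(spec: CommunitySpec) -> CommunityTruth:
    # E[MRC_f] = n_reads * locus_bp / G summed over genomes (abundances sum
    # to 1), so E[RUSCG_f] = 1e9 / G for every family; the gene scales by the
    # carrier abundance.
    expected = {name: 1e9 / spec.genome_length_bp for name in FAMILY_NAMES}
    return CommunityTruth(
        gam_true=spec.gam_true,
        carrier_abundance=spec.carrier_abundance,
        expected_ruscg=expected,
        expected_rg=spec.carrier_abundance * 1e9 / spec.genome_length_bp,
    )


def _cells(spec: CommunitySpec) -> tuple[list[tuple[int, str]], np.ndarray]:
    """Multinomial cells (genome, locus) incl. per-genome background, with
    probabilities. Locus label is a family name, "__gene__", or "__bg__"."""
    assert spec.genome_abundances is not None
    labels: list[tuple[int, str]] = []
    probs: list[float] = []
    fam_bp = {name: spec.uscg_length_aa[name] * 3 for name in FAMILY_NAMES}
    gene_bp = spec.gene_length_aa * 3
    n_carriers = spec.n_carriers
    for g in range(spec.n_genomes):
        a = float(spec.genome_abundances[g])
        used = 0
        for name in FAMILY_NAMES:
            labels.append((g, name))
            probs.append(a * fam_bp[name] / spec.genome_length_bp)
            used += fam_bp[name]
        if g < n_carriers:
            labels.append((g, "__gene__"))
            probs.append(a * gene_bp / spec.genome_length_bp)
            used += gene_bp
        labels.append((g, "__bg__"))
        probs.append(a * (spec.genome_length_bp - used) / spec.genome_length_bp)
    p = np.array(probs)
    return labels, p / p.sum()


def _uscg_subject(name: str) -> str:
    return f"USCG_{name}"


def _gene_subject(spec: CommunitySpec) -> str:
    return f"{spec.gene_name}|ref1"


def _jittered_hit(
    rng: np.random.Generator,
    query_id: str,
    subject_id: str,
    subject_length_aa: int,
    read_length_bp: int,
) -> AlignmentHit:
    # All attributes drawn above the default filter thresholds: the planted
    # hits must survive filtering so that MRC equals the multinomial draw.
    identity = float(np.round(rng.uniform(80.0, 100.0), 1))
    qcov = float(np.round(rng.uniform(85.0, 100.0), 1))
    bitscore = float(np.round(rng.uniform(55.0, 160.0), 1))
    evalue = float(10.0 ** (-rng.uniform(8.0, 30.0)))
    aln_len = max(1, int(read_length_bp // 3 * qcov / 100.0))
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=identity,
        alignment_length=aln_len,
        evalue=evalue,
        bitscore=bitscore,
        query_coverage=qcov,
        subject_length_aa=subject_length_aa,
    )


@dataclass(frozen=True)
class M6Simulation:
    uscg_m6: Path
    gene_m6: Path
    stats: SampleReadStats
    truth: CommunityTruth
    truth_json: Path


def simulate_m6(
    spec: CommunitySpec,
    out_dir: str | Path,
    sample_id: str = "sim",
) -> M6Simulation:
    """Simulate the tabular-alignment scenario directly.

    Draws ``n_reads`` multinomially over (genome, locus/background) cells;
    every read landing on a locus emits one m6 row against that locus's
    shared per-family (or gene) reference. Writes ``<sample>.uscg.m6``,
    ``<sample>.gene.m6`` and ``<sample>.truth.json``; TRC = ``n_reads``.
    Fully reproducible from ``spec.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    labels, probs = _cells(spec)
    draws = rng.multinomial(spec.n_reads, probs)

    uscg_hits: list[AlignmentHit] = []
    gene_hits: list[AlignmentHit] = []
    read_no = 0
    for (g, locus), count in zip(labels, draws):
        if locus == "__bg__":
            read_no += count
            continue
        for _ in range(count):
            qid = f"r{read_no}"
            read_no += 1
            if locus == "__gene__":
                gene_hits.append(
                    _jittered_hit(
                        rng, qid, _gene_subject(spec), spec.gene_length_aa,
                        spec.read_length_bp,
                    )
                )
            else:
                uscg_hits.append(
                    _jittered_hit(
                        rng, qid, _uscg_subject(locus), spec.uscg_length_aa[locus],
                        spec.read_length_bp,
                    )
                )

    uscg_path = out / f"{sample_id}.uscg.m6"
    gene_path = out / f"{sample_id}.gene.m6"
    write_m6(uscg_hits, uscg_path)
    write_m6(gene_hits, gene_path)

    truth = _truth(spec)
    truth_path = out / f"{sample_id}.truth.json"
    truth.to_json(truth_path)

    stats = SampleReadStats(
        sample_id=sample_id, trc=spec.n_reads, n_discarded_short=0, min_length_bp=50
    )
    return M6Simulation(
        uscg_m6=uscg_path, gene_m6=gene_path, stats=stats, truth=truth,
        truth_json=truth_path,
    )


_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass(frozen=True)
class ReadSimulation:
    reads_fasta: Path
    references: dict[str, str]
    truth: CommunityTruth
    truth_json: Path


def simulate_reads(
    spec: CommunitySpec,
    out_dir: str | Path,
    sample_id: str = "sim",
) -> ReadSimulation:
    """Simulate error-free reads as exact substrings of synthetic references.

    One nucleotide reference is generated per marker family (shared across
    genomes) plus one for the target gene; reads from a locus are exact
    substrings of its reference, background reads are random DNA, and a
    ``decoy_fraction`` of reads are sub-50-bp decoys for the length filter.
    Byte-identical output for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    references: dict[str, str] = {}
    for name in FAMILY_NAMES:
        length = spec.uscg_length_aa[name] * 3
        if spec.read_length_bp > length:
            raise SimulationError(
                f"read_length_bp ({spec.read_length_bp}) exceeds locus length of "
                f"family {name} ({length} bp)"
            )
        references[_uscg_subject(name)] = _random_dna(rng, length)
    gene_len = spec.gene_length_aa * 3
    if spec.read_length_bp > gene_len:
        raise SimulationError(
            f"read_length_bp ({spec.read_length_bp}) exceeds the gene locus length "
            f"({gene_len} bp)"
        )
    references[_gene_subject(spec)] = _random_dna(rng, gene_len)

    n_decoys = round(spec.decoy_fraction * spec.n_reads)
    n_real = spec.n_reads - n_decoys

    labels, probs = _cells(spec)
    draws = rng.multinomial(n_real, probs)

    records: list[tuple[str, str]] = []
    read_no = 0
    for (g, locus), count in zip(labels, draws):
        for _ in range(count):
            qid = f"r{read_no}"
            read_no += 1
            if locus == "__bg__":
                seq = _random_dna(rng, spec.read_length_bp)
            else:
                subject = (
                    _gene_subject(spec) if locus == "__gene__" else _uscg_subject(locus)
                )
                ref = references[subject]
                start = int(rng.integers(0, len(ref) - spec.read_length_bp + 1))
                seq = ref[start : start + spec.read_length_bp]
            records.append((qid, seq))
    for d in range(n_decoys):
        length = int(rng.integers(20, 50))
        records.append((f"decoy{d}", _random_dna(rng, length)))

    reads_path = out / f"{sample_id}.reads.fasta"
    with open(reads_path, "w") as fh:
        for qid, seq in records:
            fh.write(f">{qid}\n{seq}\n")

    refs_path = out / f"{sample_id}.refs.fasta"
    with open(refs_path, "w") as fh:
        for rid, seq in references.items():
            fh.write(f">{rid}\n{seq}\n")

    truth = _truth(spec)
    truth_path = out / f"{sample_id}.truth.json"
    truth.to_json(truth_path)
    return ReadSimulation(
        reads_fasta=reads_path, references=references, truth=truth,
        truth_json=truth_path,
    )


def exact_match_m6(
    reads_fasta: str | Path,
    references: dict[str, str],
) -> list[AlignmentHit]:
    """Map reads to references by exact substring search, emitting m6 hits.

    A deliberately naive stand-in for a translated aligner, usable only on
    the error-free simulated reads: a read matching a reference exactly gets
    identity 100, coverage 100 and a length-scaled bitscore. Reads matching
    nothing produce no hit; ties go to the lexicographically smallest
    reference id, mirroring the best-hit tie-break.
    """
    from Bio import SeqIO

    hits: list[AlignmentHit] = []
    ordered_refs = sorted(references.items())
    for rec in SeqIO.parse(str(reads_fasta), "fasta"):
        seq = str(rec.seq)
        for rid, ref in ordered_refs:
            if seq in ref:
                aa_len = max(1, len(seq) // 3)
                hits.append(
                    AlignmentHit(
                        query_id=rec.id,
                        subject_id=rid,
                        percent_identity=100.0,
                        alignment_length=aa_len,
                        evalue=1e-20,
                        bitscore=2.0 * aa_len,
                        query_coverage=100.0,
                        subject_length_aa=len(ref) // 3,
                    )
                )
                break
    return hits
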