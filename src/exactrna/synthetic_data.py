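"""Synthetic two-condition RNA-seq and qPCR data with recorded ground truth.

The generator emulates a desk-scale version of a two-condition morpholino
knockdown experiment: a toy multi-gene reference chromosome, single-end
reads (100 nt by default) drawn from expression-weighted genes in a
control group and a case group with planted per-gene log2 fold changes, a
cohort of genes at a shared low-expression noise floor (the mode the
noise estimator must find), optional i.i.d. substitution errors, and
triplicate qPCR plates quantified against a reference gene.

Every simulator is a pure function of (config, seed): the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .mapper import ReadRecord, reverse_complement
from .qpcr import CtTable
from .quant import Annotation
from .refindex import ReferenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults describe the standard scenario the test-bed exercises:
    200 genes of 400-800 bp, 20 of them differentially expressed at
    |log2 FC| = 2 planted on well-expressed genes, 30% of genes at a
    shared low noise floor, 100-nt reads at ~30x mean depth, three
    replicates per condition, and triplicate qPCR with 0.2-cycle
    replicate noise.
    """

    seed: int
    n_genes: int = 200
    gene_length: tuple[int, int] = (400, 800)
    spacer: int = 100
    read_length: int = 100
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.0
    n_de_genes: int = 20
    de_log2_fc: float = 2.0
    de_genes: dict[str, float] | None = None  # explicit plan overrides auto-pick
    noise_floor_fraction: float = 0.5
    noise_floor_level: float = 1.0  # relative expression weight of floor genes
    substitution_error_rate: float = 0.001
    mean_depth: float = 30.0
    reads_per_sample: int | None = None  # overrides mean_depth when set
    n_replicates: int = 3
    repeat_free: bool = True
    repeat_kmer: int = 32
    qpcr_n_per_group: int = 6
    qpcr_replicates: int = 3
    qpcr_ct_sd: float = 0.2
    qpcr_ct_offset: float = 30.0
    qpcr_reference_gene: str = "rpp0"
    qpcr_reference_level: float = 256.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        lo, hi = self.gene_length
        if lo > hi or lo < self.read_length:
            raise ConfigError(
                f"gene_length range {self.gene_length} must be ascending and "
                f">= read_length {self.read_length}"
            )
        if (self.read_length - 4) % 3 != 0 or (self.read_length - 4) // 3 < 1:
            raise ConfigError(
                f"read_length {self.read_length} violates the (L-4) % 3 == 0 geometry"
            )
        for name, rate in (
            ("substitution_error_rate", self.substitution_error_rate),
            ("noise_floor_fraction", self.noise_floor_fraction),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")
        if self.qpcr_ct_sd < 0:
            raise ConfigError("qpcr_ct_sd must be >= 0")


@dataclass
class GroundTruth:
    """Per-gene truth (baseline weight, planted log2 FC) and per-read truth
    (source gene, position, strand), appended as reads are simulated."""

    genes: pd.DataFrame  # index gene_id; columns baseline, log2_fc, is_floor
    reads: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["read_id", "sample_id", "gene_id", "start", "strand"]
        )
    )

    def expression(self, condition: str) -> pd.Series:
        base = self.genes["baseline"]
        if condition == "ctrl":
            return base
        if condition == "case":
            return base * 2.0 ** self.genes["log2_fc"]
        raise ConfigError(f"unknown condition {condition!r}")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _has_repeat(seq: str, k: int) -> bool:
    """True when any k-mer occurs twice, counting reverse complements (and
    self-reverse-complementary k-mers, which would map on both strands)."""
    seen: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in seen or reverse_complement(km) in seen or km == reverse_complement(km):
            return True
        seen.add(km)
    return False


def simulate_reference(
    config: SimulationConfig,
) -> tuple[ReferenceSet, Annotation, GroundTruth]:
    """Toy reference chromosome with non-overlapping spacer-separated genes.

    Base composition is i.i.d. uniform.  In ``repeat_free`` mode the
    chromosome is resampled until every ``repeat_kmer``-mer is unique on
    both strands, which makes exact split-read placement unambiguous for
    error-free reads.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    n_floor = int(round(config.noise_floor_fraction * config.n_genes))
    floor_idx = set(rng.choice(config.n_genes, size=n_floor, replace=False).tolist())
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]

    baselines = np.empty(config.n_genes)
    regular = [i for i in range(config.n_genes) if i not in floor_idx]
    baselines[regular] = 2.0 ** rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=len(regular)
    )
    baselines[list(floor_idx)] = config.noise_floor_level

    log2_fc = np.zeros(config.n_genes)
    if config.de_genes is not None:
        for g, fc in config.de_genes.items():
            if g not in gene_ids:
                raise ConfigError(f"de_genes names unknown gene {g!r}")
            log2_fc[gene_ids.index(g)] = fc
    elif config.n_de_genes > 0:
        if config.n_de_genes > len(regular):
            raise ConfigError("more DE genes requested than non-floor genes available")
        # plant DE on well-expressed genes in the upper-middle of the
        # baseline distribution (not the extreme top, where rank-based
        # normalization has no headroom), alternating up/down
        by_baseline = sorted(regular, key=lambda i: baselines[i])
        start = min(int(0.55 * len(regular)), len(regular) - config.n_de_genes)
        for rank, i in enumerate(by_baseline[start : start + config.n_de_genes]):
            log2_fc[i] = config.de_log2_fc if rank % 2 == 0 else -config.de_log2_fc

    total = config.spacer + int(np.sum(lengths + config.spacer))
    for attempt in range(50):
        chrom = _random_seq(rng, total)
        if not (config.repeat_free and _has_repeat(chrom, config.repeat_kmer)):
            break
    else:
        raise ConfigError(
            f"could not sample a repeat-free chromosome of {total} bp in 50 tries"
        )

    intervals = []
    pos = config.spacer
    for gid, ln in zip(gene_ids, lengths):
        intervals.append(("chr1", pos, pos + int(ln), gid))
        pos += int(ln) + config.spacer

    refs = ReferenceSet({"chr1": chrom})
    annotation = Annotation(intervals)
    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "baseline": baselines,
                "log2_fc": log2_fc,
                "is_floor": [i in floor_idx for i in range(config.n_genes)],
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    return refs, annotation, truth


def simulate_reads(
    refs: ReferenceSet,
    annotation: Annotation,
    truth: GroundTruth,
    condition: str,
    sample_id: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ReadRecord]:
    """Draw one sample's reads and append their truth rows in place.

    Read counts per gene are multinomial over expression-weighted gene
    lengths; start positions are uniform within the gene, strands uniform,
    substitution errors i.i.d. per base at the configured rate.
    """
    L = config.read_length
    gene_iv = {g: ivs[0] for g, ivs in annotation.by_gene().items()}
    genes = list(truth.genes.index)
    lengths = np.array([gene_iv[g][2] - gene_iv[g][1] for g in genes], dtype=float)
    if (lengths < L).any():
        raise ConfigError(f"gene shorter than read_length {L}")
    expr = truth.expression(condition).loc[genes].to_numpy()
    weights = expr * lengths
    p = weights / weights.sum()
    total_gene_bp = lengths.sum()
    n_reads = (
        config.reads_per_sample
        if config.reads_per_sample is not None
        else int(round(config.mean_depth * total_gene_bp / (L - 4)))
    )
    counts = rng.multinomial(n_reads, p)
    chrom = refs.records["chr1"]
    reads: list[ReadRecord] = []
    rows = []
    qual = "I" * L
    serial = 0
    for g, c in zip(genes, counts):
        if c == 0:
            continue
        _, gstart, gend = gene_iv[g]
        starts = rng.integers(gstart, gend - L + 1, size=c)
        strands = rng.integers(0, 2, size=c)
        n_err = rng.binomial(L, config.substitution_error_rate, size=c)
        for s, neg, ne in zip(starts, strands, n_err):
            seq = chrom[s : s + L]
            if neg:
                seq = reverse_complement(seq)
            if ne:
                seq_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                pos = rng.choice(L, size=int(ne), replace=False)
                for pp in pos:
                    choices = _BASES[_BASES != seq_arr[pp]]
                    seq_arr[pp] = rng.choice(choices)
                seq = seq_arr.tobytes().decode("ascii")
            rid = f"{sample_id}.{serial:07d}"
            serial += 1
            reads.append(ReadRecord(rid, seq, qual))
            rows.append(
                {
                    "read_id": rid,
                    "sample_id": sample_id,
                    "gene_id": g,
                    "start": int(s),
                    "strand": "-" if neg else "+",
                }
            )
    new = pd.DataFrame(rows, columns=truth.reads.columns)
    truth.reads = (
        new if truth.reads.empty else pd.concat([truth.reads, new], ignore_index=True)
    )
    return reads


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality or 'I' * len(r.sequence)}\n")


def simulate_qpcr(
    truth: GroundTruth,
    config: SimulationConfig,
    genes: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> CtTable:
    """Triplicate qPCR plates for selected genes plus the reference gene.

    Ct = offset - log2(true expression) + Normal(0, replicate sd); the
    reference gene has fold change 1 by construction.  Samples are paired
    across conditions via pair_id (clutch-style pairing).
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 97))
    if genes is None:
        genes = list(truth.genes.index)
    unknown = set(genes) - set(truth.genes.index)
    if unknown:
        raise ConfigError(f"qPCR genes not in truth: {sorted(unknown)}")
    rows = []
    for cond in ("ctrl", "case"):
        expr = truth.expression(cond)
        for i in range(config.qpcr_n_per_group):
            sid = f"{cond}{i + 1}"
            pair = f"clutch{i + 1}"
            for g in list(genes) + [config.qpcr_reference_gene]:
                level = (
                    config.qpcr_reference_level
                    if g == config.qpcr_reference_gene
                    else float(expr.loc[g])
                )
                ct = config.qpcr_ct_offset - np.log2(level)
                row = {
                    "sample_id": sid,
                    "condition": cond,
                    "pair_id": pair,
                    "gene_id": g,
                }
                for r in range(config.qpcr_replicates):
                    row[f"ct_{r + 1}"] = ct + rng.normal(0.0, config.qpcr_ct_sd)
                rows.append(row)
    return CtTable(data=pd.DataFrame(rows), reference_gene=config.qpcr_reference_gene)


@dataclass
class SimulatedExperiment:
    refs: ReferenceSet
    annotation: Annotation
    truth: GroundTruth
    samples: dict[str, list[ReadRecord]]  # sample_id -> reads
    groups: dict[str, str]  # sample_id -> ctrl | case


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Reference plus n_replicates read sets per condition, ground truth
    attached.  Deterministic in config.seed."""
    refs, annotation, truth = simulate_reference(config)
    samples: dict[str, list[ReadRecord]] = {}
    groups: dict[str, str] = {}
    for ci, cond in enumerate(("ctrl", "case")):
        for rep in range(config.n_replicates):
            sid = f"{cond}{rep + 1}"
            rng = np.random.default_rng((config.seed, ci + 1, rep + 1))
            samples[sid] = simulate_reads(
                refs, annotation, truth, cond, sid, config, rng
            )
            groups[sid] = cond
    return SimulatedExperiment(refs, annotation, truth, samples, groups)
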