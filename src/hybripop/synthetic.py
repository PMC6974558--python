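"""Synthetic data generation for hybrid-genome and population analyses.

Everything the downstream modules consume can be generated here with known
ground truth: a pair of diverged parental genomes, hybrid genomes built from
per-segment copy-number plans with planted heterozygosity and LOH tracts,
paired short reads with substitution errors, co-dominant MLST genotype panels
under partial selfing, and flow-cytometry G1/G2 intensity mixtures.

All randomness flows from one explicit integer seed per call through
``numpy.random.default_rng`` (PCG64), so outputs are reproducible across runs
and releases.  Substitutions are drawn uniformly over the three alternative
bases; indels are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ParentalPair",
    "Segment",
    "HybridPlan",
    "CopyFragment",
    "HybridSimTruth",
    "ReadPair",
    "SelfingSimConfig",
    "FlowSimConfig",
    "simulate_parental_pair",
    "simulate_hybrid_genome",
    "simulate_reads",
    "simulate_mlst_population",
    "simulate_flow_events",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Parental genomes
# ---------------------------------------------------------------------------

@dataclass
class ParentalPair:
    """Two collinear parental genome sequences of equal length.

    ``divergence_map`` lists the positions (0-based) where ``seq_b`` differs
    from ``seq_a``; ``divergence_rate`` is the per-site substitution
    probability used to generate them.
    """

    seq_a: str
    seq_b: str
    divergence_map: list
    divergence_rate: float

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("parental sequences must have equal length")

    @property
    def length(self) -> int:
        return len(self.seq_a)


def simulate_parental_pair(length: int, divergence_rate: float, seed: int) -> ParentalPair:
    """Simulate two parental genomes separated by uniform substitutions.

    Parameters
    ----------
    length : genome length in bp (>= 1000).
    divergence_rate : per-site probability that parent B differs from A
        (0 <= rate <= 0.2).
    seed : RNG seed; the call is deterministic given the seed.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000 bp")
    if not 0.0 <= divergence_rate <= 0.2:
        raise ValueError("divergence_rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    a = _BASES[rng.integers(0, 4, size=length)]
    b = a.copy()
    div = np.flatnonzero(rng.random(length) < divergence_rate)
    if div.size:
        # shift by 1..3 in base space: guaranteed different base, uniform over
        # the three alternatives
        idx = np.searchsorted(_BASES, a[div])
        b[div] = _BASES[(idx + rng.integers(1, 4, size=div.size)) % 4]
    return ParentalPair(_array_to_seq(a), _array_to_seq(b), div.tolist(), divergence_rate)


# ---------------------------------------------------------------------------
# Hybrid genome plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One genome segment of a hybrid plan, 0-based half-open."""

    start: int
    end: int
    copies_a: int
    copies_b: int
    loh: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.copies_a <= 4 and 0 <= self.copies_b <= 4):
            raise ValueError("copy numbers must be integers in 0..4")
        if self.copies_a + self.copies_b <= 0:
            raise ValueError("every segment needs at least one copy")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HybridPlan:
    """Per-segment subgenome copy-number plan for one hybrid genome.

    Segments must tile ``[0, genome_length)`` without overlap.  Heterozygosity
    rates are expressed in sites per kb planted on one copy of the carrying
    subgenome; segments flagged ``loh`` receive no planted heterozygosity.
    """

    segments: Sequence[Segment]
    het_rate_a: float = 0.0
    het_rate_b: float = 0.0
    total_ploidy: Optional[int] = None

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        if not segs:
            raise ValueError("plan needs at least one segment")
        if segs[0].start != 0:
            raise ValueError("plan must start at position 0")
        for prev, cur in zip(segs, segs[1:]):
            if cur.start != prev.end:
                raise ValueError("segments must tile the genome without gaps or overlaps")
        self.segments = segs
        if self.total_ploidy is None:
            self.total_ploidy = int(round(self.mean_copy_number))

    @property
    def length(self) -> int:
        return self.segments[-1].end

    @property
    def mean_copy_number(self) -> float:
        """Length-weighted mean total copy number across the genome."""
        tot = sum((s.copies_a + s.copies_b) * s.length for s in self.segments)
        return tot / self.length

    def max_copies(self, subgenome: str) -> int:
        attr = "copies_a" if subgenome == "A" else "copies_b"
        return max(getattr(s, attr) for s in self.segments)


@dataclass
class CopyFragment:
    """One contiguous chromosome-copy fragment carried by the hybrid.

    ``label`` identifies the source copy (e.g. ``A0``, ``B1``); ``start`` is
    the fragment's offset on the parental reference coordinate system.
    """

    label: str
    subgenome: str
    slot: int
    start: int
    seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass
class HybridSimTruth:
    """Ground truth of one simulated hybrid genome."""

    pair: ParentalPair
    plan: HybridPlan
    copies: list  # list[CopyFragment]
    planted_het_positions: dict = field(default_factory=dict)  # {"A": [...], "B": [...]}

    def copies_overlapping(self, pos: int) -> list:
        return [c for c in self.copies if c.start <= pos < c.end]


def simulate_hybrid_genome(pair: ParentalPair, plan: HybridPlan, seed: int) -> HybridSimTruth:
    """Build the chromosome copies of a hybrid following a copy-number plan.

    Each subgenome contributes ``copies_a`` / ``copies_b`` copies per segment;
    copy "slots" that persist across adjacent segments form contiguous
    fragments.  Heterozygous sites are planted as Poisson events at the plan's
    per-kb rates, each assigning the alternative base to exactly one uniformly
    chosen copy of the carrying subgenome, outside LOH segments.
    """
    if plan.length > pair.length:
        raise ValueError("plan extends beyond the parental genome")
    rng = np.random.default_rng(seed)
    ref = {"A": _seq_to_array(pair.seq_a), "B": _seq_to_array(pair.seq_b)}
    planted: dict = {"A": [], "B": []}
    fragments: list = []

    for sub in ("A", "B"):
        attr = "copies_a" if sub == "A" else "copies_b"
        het_rate = plan.het_rate_a if sub == "A" else plan.het_rate_b
        n_slots = plan.max_copies(sub)
        # per-slot presence mask along segments -> contiguous runs
        for slot in range(n_slots):
            run_start = None
            runs = []
            for seg in plan.segments:
                present = getattr(seg, attr) > slot
                if present and run_start is None:
                    run_start = seg.start
                elif not present and run_start is not None:
                    runs.append((run_start, seg.start))
                    run_start = None
            if run_start is not None:
                runs.append((run_start, plan.length))
            for rs, re in runs:
                fragments.append(CopyFragment(
                    label=f"{sub}{slot}", subgenome=sub, slot=slot,
                    start=rs, seq=_array_to_seq(ref[sub][rs:re])))
        # plant heterozygosity per non-LOH segment
        if het_rate > 0:
            for seg in plan.segments:
                n_copies = getattr(seg, attr)
                if seg.loh or n_copies == 0:
                    continue
                n_sites = rng.poisson(het_rate * seg.length / 1000.0)
                if n_sites == 0:
                    continue
                pos = np.unique(rng.integers(seg.start, seg.end, size=n_sites))
                for p in pos.tolist():
                    slot = int(rng.integers(0, n_copies))
                    planted[sub].append((p, slot))

    # apply planted alternative alleles to the chosen copy
    frag_by_label: dict = {}
    frag_arrays = {}
    for fr in fragments:
        frag_by_label.setdefault(fr.label, []).append(fr)
        frag_arrays[id(fr)] = _seq_to_array(fr.seq)
    for sub in ("A", "B"):
        for p, slot in planted[sub]:
            for fr in frag_by_label.get(f"{sub}{slot}", []):
                if fr.start <= p < fr.end:
                    arr = frag_arrays[id(fr)]
                    old = arr[p - fr.start]
                    idx = int(np.searchsorted(_BASES, old))
                    arr[p - fr.start] = _BASES[(idx + int(rng.integers(1, 4))) % 4]
    for fr in fragments:
        fr.seq = _array_to_seq(frag_arrays[id(fr)])

    het_positions = {sub: sorted(p for p, _ in planted[sub]) for sub in ("A", "B")}
    return HybridSimTruth(pair=pair, plan=plan, copies=fragments,
                          planted_het_positions=het_positions)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadPair:
    """One simulated paired-end read with its ground-truth origin."""

    name: str
    seq1: str
    seq2: str
    origin: str      # source copy label, e.g. "A0"
    start: int       # 0-based leftmost position of the insert on the reference
    insert: int


def _inject_errors(arr: np.ndarray, error_rate: float, rng) -> np.ndarray:
    if error_rate <= 0:
        return arr
    err = np.flatnonzero(rng.random(arr.size) < error_rate)
    if err.size:
        idx = np.searchsorted(_BASES, arr[err])
        arr[err] = _BASES[(idx + rng.integers(1, 4, size=err.size)) % 4]
    return arr


def simulate_reads(truth: HybridSimTruth, coverage: float, read_len: int = 150,
                   insert_mean: int = 400, error_rate: float = 0.001,
                   seed: int = 0) -> list:
    """Simulate paired-end shotgun reads from every chromosome copy.

    ``coverage`` is the expected per-base depth over each individual copy;
    read pair counts per fragment are Poisson.  Inserts have fixed length
    ``insert_mean`` (clipped to the fragment); substitution errors are uniform
    at ``error_rate`` per base.  Returns a list of :class:`ReadPair`.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_len >= insert_mean:
        raise ValueError("read_len must be smaller than insert_mean")
    rng = np.random.default_rng(seed)
    pairs: list = []
    serial = 0
    for fr in truth.copies:
        L = len(fr.seq)
        if L < read_len:
            continue
        insert = min(insert_mean, L)
        n_pairs = rng.poisson(coverage * L / (2.0 * read_len))
        if n_pairs == 0:
            continue
        starts = rng.integers(0, L - insert + 1, size=n_pairs)
        arr = _seq_to_array(fr.seq)
        for s in starts.tolist():
            r1 = _inject_errors(arr[s:s + read_len].copy(), error_rate, rng)
            r2src = revcomp(_array_to_seq(arr[s + insert - read_len:s + insert]))
            seq2 = _array_to_seq(_inject_errors(_seq_to_array(r2src), error_rate, rng))
            pairs.append(ReadPair(
                name=f"sim_{fr.label}_{serial}", seq1=_array_to_seq(r1), seq2=seq2,
                origin=fr.label, start=fr.start + s, insert=insert))
            serial += 1
    return pairs


def write_fastq_pair(pairs: Sequence[ReadPair], path1: str, path2: str) -> None:
    """Write paired reads to two FASTQ files with /1 and /2 suffixes."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rp in pairs:
            q1 = "I" * len(rp.seq1)
            q2 = "I" * len(rp.seq2)
            f1.write(f"@{rp.name}/1\n{rp.seq1}\n+\n{q1}\n")
            f2.write(f"@{rp.name}/2\n{rp.seq2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# MLST genotype panels under partial selfing
# ---------------------------------------------------------------------------

@dataclass
class SelfingSimConfig:
    """Configuration of the partial-selfing MLST panel generator.

    Each individual carries a latent number of consecutive selfing
    generations ``t`` with P(t) proportional to (1-s)*s^t, truncated at
    ``t_max``; locus k is heterozygous with probability ``h0[k] * 2^-t``.
    The shared ``t`` induces identity disequilibrium across loci.
    """

    n_individuals: int
    n_loci: int
    h0: float | Sequence[float] = 0.5
    s: float = 0.0
    t_max: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("selfing rate s must be in [0, 1]")
        h = np.broadcast_to(np.asarray(self.h0, dtype=float), (self.n_loci,))
        if np.any((h <= 0) | (h >= 1)):
            raise ValueError("h0 must be in (0, 1)")
        if self.s == 1.0 and self.t_max == 0:
            raise ValueError("s=1 with t_max=0 leaves no valid selfing-generation state")

    @property
    def h0_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.h0, dtype=float), (self.n_loci,)).copy()


def selfing_generation_weights(s: float, t_max: int) -> np.ndarray:
    """Truncated, renormalized distribution of selfing-generation counts."""
    t = np.arange(t_max + 1)
    if s >= 1.0:
        w = np.zeros(t_max + 1)
        w[-1] = 1.0  # limiting case: all mass at the truncation point
        return w
    w = (1.0 - s) * s ** t
    return w / w.sum()


def simulate_mlst_population(cfg: SelfingSimConfig):
    """Draw a co-dominant genotype panel under the partial-selfing model.

    Returns a :class:`hybripop.mlst.GenotypePanel`.  Each locus has two
    nucleotide alleles at frequency 1/2; heterozygotes carry both, homozygotes
    one chosen uniformly (allele frequencies stay at 1/2, so the expected
    inbreeding coefficient is s/(2-s)).
    """
    from .mlst import GenotypePanel  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    h0 = cfg.h0_vector
    w = selfing_generation_weights(cfg.s, cfg.t_max)
    t = rng.choice(cfg.t_max + 1, size=cfg.n_individuals, p=w)
    p_het = h0[None, :] * np.power(2.0, -t)[:, None]
    is_het = rng.random((cfg.n_individuals, cfg.n_loci)) < p_het

    locus_names = [f"L{k + 1}" for k in range(cfg.n_loci)]
    # two distinct nucleotide alleles per locus
    alleles = []
    for _ in range(cfg.n_loci):
        i, j = rng.choice(4, size=2, replace=False)
        alleles.append(("ACGT"[i], "ACGT"[j]))
    genotypes = []
    homo_pick = rng.integers(0, 2, size=(cfg.n_individuals, cfg.n_loci))
    for i in range(cfg.n_individuals):
        row = []
        for k in range(cfg.n_loci):
            a1, a2 = alleles[k]
            if is_het[i, k]:
                row.append((a1, a2))
            else:
                a = (a1, a2)[homo_pick[i, k]]
                row.append((a, a))
        genotypes.append(row)
    individuals = [f"ind{i + 1}" for i in range(cfg.n_individuals)]
    return GenotypePanel(individuals=individuals, loci=locus_names, genotypes=genotypes)


# ---------------------------------------------------------------------------
# Flow cytometry events
# ---------------------------------------------------------------------------

@dataclass
class FlowSimConfig:
    """Two-component G1/G2 fluorescence mixture configuration.

    The G2 component mean is fixed at twice the G1 mean (DNA content doubles
    after replication); both components share the coefficient of variation.
    """

    g1_mean: float
    cv: float = 0.05
    g2_fraction: float = 0.3
    n_events: int = 30000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if not 0.0 <= self.g2_fraction <= 1.0:
            raise ValueError("g2_fraction must be in [0, 1]")
        if self.g1_mean <= 0:
            raise ValueError("g1_mean must be positive")


def simulate_flow_events(cfg: FlowSimConfig) -> np.ndarray:
    """Draw fluorescence intensities from the G1/G2 normal mixture.

    Negative draws are resampled so all intensities are positive.
    """
    rng = np.random.default_rng(cfg.seed)
    comp = rng.random(cfg.n_events) < cfg.g2_fraction
    means = np.where(comp, 2.0 * cfg.g1_mean, cfg.g1_mean)
    sds = cfg.cv * means
    x = rng.normal(means, sds)
    bad = x <= 0
    while bad.any():
        x[bad] = rng.normal(means[bad], sds[bad])
        bad = x <= 0
    return x


# ---------------------------------------------------------------------------
# Truth export helpers
# ---------------------------------------------------------------------------

def write_truth_bed(plan: HybridPlan, path: str, chrom: str = "chr1") -> None:
    """Write the plan's segments as BED (0-based half-open) with copy counts."""
    with open(path, "w") as f:
        for seg in plan.segments:
            name = f"A{seg.copies_a}B{seg.copies_b}" + ("_LOH" if seg.loh else "")
            f.write(f"{chrom}\t{seg.start}\t{seg.end}\t{name}\n")


def read_plan_bed(path: str, het_rate_a: float = 0.0, het_rate_b: float = 0.0) -> HybridPlan:
    """Read a BED-like plan file written by :func:`write_truth_bed`."""
    segs = []
    with open(path) as f:
        for line in f:
            if not line.strip() or line.startswith("#"):
                continue
            _, start, end, name = line.split()[:4]
            loh = name.endswith("_LOH")
            core = name[:-4] if loh else name
            ca, cb = core[1:].split("B")
            segs.append(Segment(int(start), int(end), int(ca), int(cb), loh))
    return HybridPlan(segments=segs, het_rate_a=het_rate_a, het_rate_b=het_rate_b)


def parental_proportion(plan: HybridPlan) -> str:
    """Reduced A:B ratio of length-weighted mean copy numbers of a plan."""
    wa = sum(s.copies_a * s.length for s in plan.segments)
    wb = sum(s.copies_b * s.length for s in plan.segments)
    ca = int(round(wa / plan.length))
    cb = int(round(wb / plan.length))
    g = gcd(ca, cb) or 1
    return f"{ca // g}:{cb // g}"
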