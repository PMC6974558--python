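"""MLST alignment handling, diversity statistics and mating-system inference.

Marker alignments carry Sanger-consensus sequences in which heterozygous
positions are encoded with two-fold IUPAC ambiguity codes (R, Y, S, W, K, M).
The module converts between consensus and pseudo-haplotype ("bi-allelic")
representations, counts heterozygous/polymorphic sites per locus, computes
nucleotide diversity (mean pairwise differences per locus and per kb),
estimates the Weir & Cockerham (1984) inbreeding coefficient, and infers the
selfing rate both from Fis (s = 2*Fis/(1+Fis), the inbreeding-equilibrium
transform) and by maximum likelihood from the multilocus heterozygosity
profile (heterozygosity decays as 2^-t over t generations of selfing).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerAlignment",
    "DiversityStats",
    "GenotypePanel",
    "SelfingEstimate",
    "encode_heterozygous_consensus",
    "expand_biallelic",
    "site_counts",
    "percent_polymorphic",
    "nucleotide_diversity",
    "fis_estimate",
    "selfing_from_fis",
    "selfing_from_profile",
    "export_structure",
    "import_structure",
    "concatenate_markers",
    "read_marker_fasta",
    "round_half_up",
]

# two-fold IUPAC ambiguity codes and their constituent base pairs
IUPAC_HET = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
HET_TO_BASES = {code: tuple(sorted(bases)) for bases, code in IUPAC_HET.items()}
UNSUPPORTED_CODES = set("BDHV")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ndigits (printed-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Alignment containers
# ---------------------------------------------------------------------------

@dataclass
class MarkerAlignment:
    """Aligned IUPAC-coded sequences of one MLST locus across strains."""

    locus: str
    ids: list
    seqs: list
    species: dict = field(default_factory=dict)  # strain id -> species label

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        if self.length == 0:
            raise ValueError("locus length must be positive")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.seqs)

    def subset(self, ids: Sequence[str]) -> "MarkerAlignment":
        keep = [self.ids.index(i) for i in ids]
        return MarkerAlignment(self.locus, [self.ids[i] for i in keep],
                               [self.seqs[i] for i in keep],
                               {i: self.species[i] for i in ids if i in self.species})


def read_marker_fasta(path: str, locus: Optional[str] = None,
                      species: Optional[dict] = None) -> MarkerAlignment:
    """Read one locus alignment from FASTA (strain ids taken from headers)."""
    ids, seqs = [], []
    for rec in SeqIO.parse(path, "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if locus is None:
        locus = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return MarkerAlignment(locus, ids, seqs, species or {})


@dataclass
class DiversityStats:
    """Per-locus site counts and nucleotide diversity (Table-style report)."""

    locus: str
    n_sequences: int
    n_total_sites: int
    n_heterozygous_sites: int
    n_polymorphic_sites: int
    pct_polymorphic: float
    Pi: float
    pi_per_kb: float


# ---------------------------------------------------------------------------
# IUPAC consensus <-> pseudo-haplotypes
# ---------------------------------------------------------------------------

def encode_heterozygous_consensus(hap1: str, hap2: str) -> str:
    """Collapse two haplotypes into an IUPAC consensus string.

    Identical bases pass through; differing base pairs map to the unique
    two-fold ambiguity code; any position with N in either haplotype yields N.
    A gap paired with a base is reported as N (undetermined in consensus).
    """
    if len(hap1) != len(hap2):
        raise ValueError("haplotypes must have equal length")
    out = []
    for a, b in zip(hap1.upper(), hap2.upper()):
        if a == "N" or b == "N":
            out.append("N")
        elif a == b:
            out.append(a)
        elif a == "-" or b == "-":
            out.append("N")
        else:
            try:
                out.append(IUPAC_HET[frozenset((a, b))])
            except KeyError:
                raise ValueError(f"cannot encode base pair {a}/{b}") from None
    return "".join(out)


def _split_base(c: str) -> tuple:
    """Constituent bases of one alignment symbol (alphabetical order)."""
    if c in HET_TO_BASES:
        return HET_TO_BASES[c]
    if c in UNSUPPORTED_CODES:
        raise ValueError(f"3/4-fold ambiguity code {c!r} not supported")
    return (c, c)


def expand_biallelic(aln: MarkerAlignment) -> MarkerAlignment:
    """Expand each strain into two pseudo-haplotypes.

    At ambiguous positions the two constituent bases are split one per
    pseudo-haplotype, alphabetically-first base to haplotype 1 (phase is not
    identifiable from Sanger consensus; downstream statistics are
    phase-invariant).  Round-trips with :func:`encode_heterozygous_consensus`.
    """
    ids, seqs = [], []
    for sid, seq in zip(aln.ids, aln.seqs):
        pairs = [_split_base(c) for c in seq]
        ids.append(f"{sid}_1")
        seqs.append("".join(p[0] for p in pairs))
        ids.append(f"{sid}_2")
        seqs.append("".join(p[1] for p in pairs))
    species = {}
    for sid, sp in aln.species.items():
        species[f"{sid}_1"] = sp
        species[f"{sid}_2"] = sp
    return MarkerAlignment(aln.locus, ids, seqs, species)


# ---------------------------------------------------------------------------
# Site counts and nucleotide diversity
# ---------------------------------------------------------------------------

def percent_polymorphic(n_poly: int, n_total: int) -> float:
    """Percent polymorphic sites, rounded half-up to two decimals."""
    return round_half_up(100.0 * n_poly / n_total, 2)


def _clean_columns(aln: MarkerAlignment) -> list:
    """Column indices free of gaps and missing data in every strain."""
    keep = []
    for j in range(aln.length):
        col = [s[j] for s in aln.seqs]
        if any(c in "-N" for c in col):
            continue
        keep.append(j)
    return keep


def site_counts(aln: MarkerAlignment):
    """Count total, heterozygous and polymorphic sites of one locus.

    Columns containing a gap or N in any strain are excluded from all counts.
    A column is heterozygous if at least one strain carries an IUPAC ambiguity
    code; polymorphic if the union of constituent alleles across strains holds
    two or more distinct bases.
    """
    if aln.n < 2:
        raise ValueError("site counts need at least 2 sequences")
    keep = _clean_columns(aln)
    n_total = len(keep)
    n_het = 0
    n_poly = 0
    for j in keep:
        col = [s[j] for s in aln.seqs]
        if any(c in HET_TO_BASES for c in col):
            n_het += 1
        alleles = set()
        for c in col:
            alleles.update(_split_base(c))
        if len(alleles) >= 2:
            n_poly += 1
    pct = percent_polymorphic(n_poly, n_total) if n_total else 0.0
    return n_total, n_het, n_poly, pct


def nucleotide_diversity(aln: MarkerAlignment):
    """Mean pairwise differences Pi per locus, and per kb of clean sites.

    The alignment is expanded to 2N pseudo-haplotypes and Pi is the mean
    Hamming distance over all C(2N, 2) haplotype pairs, restricted to columns
    surviving the gap/missing filter.
    """
    if aln.n < 2:
        raise ValueError("nucleotide diversity is undefined for a single strain")
    keep = _clean_columns(aln)
    hap = expand_biallelic(aln)
    m = len(hap.seqs)
    n_pairs = m * (m - 1) // 2
    # column-wise allele counting: pairs differing = (m^2 - sum n_i^2) / 2
    total_diff = 0.0
    for j in keep:
        counts: dict = {}
        for s in hap.seqs:
            counts[s[j]] = counts.get(s[j], 0) + 1
        total_diff += (m * m - sum(v * v for v in counts.values())) / 2.0
    Pi = total_diff / n_pairs
    pi_per_kb = 1000.0 * Pi / len(keep) if keep else 0.0
    return Pi, pi_per_kb


def diversity_stats(aln: MarkerAlignment) -> DiversityStats:
    n_total, n_het, n_poly, pct = site_counts(aln)
    Pi, pi_kb = nucleotide_diversity(aln)
    return DiversityStats(aln.locus, aln.n, n_total, n_het, n_poly, pct, Pi, pi_kb)


# ---------------------------------------------------------------------------
# Genotype panels, Fis and selfing
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Individuals x loci co-dominant genotypes (two alleles per cell).

    Cells are ordered pairs of allele codes (strings) or None for missing.
    """

    individuals: list
    loci: list
    genotypes: list  # genotypes[i][k] = (a1, a2) or None

    def __post_init__(self) -> None:
        for row in self.genotypes:
            if len(row) != len(self.loci):
                raise ValueError("genotype row length mismatch")

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def het_matrix(self) -> np.ndarray:
        """Binary heterozygosity matrix, NaN where missing."""
        H = np.full((self.n, self.n_loci), np.nan)
        for i, row in enumerate(self.genotypes):
            for k, g in enumerate(row):
                if g is not None:
                    H[i, k] = float(g[0] != g[1])
        return H

    def locus_alleles(self, k: int) -> list:
        alleles = set()
        for row in self.genotypes:
            g = row[k]
            if g is not None:
                alleles.update(g)
        return sorted(alleles)


@dataclass
class SelfingEstimate:
    """Mating-system summary: Fis, selfing from Fis and from the profile."""

    fis: float
    s_from_fis: float
    s_from_profile: float
    s_profile_se: float
    h0_hat: np.ndarray
    g2_hat: float
    negative_fis_clamped: bool = False
    boundary: bool = False


def fis_estimate(panel: GenotypePanel, method: str = "weir-cockerham") -> float:
    """Multilocus inbreeding coefficient.

    The default is the Weir & Cockerham (1984) small-f estimator for a single
    population: per-locus, per-allele within-individual (c) and
    between-individual (b) variance components are summed across alleles and
    loci before forming f = 1 - sum(c) / sum(b + c).  Individuals missing a
    locus are excluded locus-wise.  ``method='ho-he'`` gives the simpler
    1 - Ho/He estimator for sensitivity checks.
    """
    sum_c = 0.0
    sum_bc = 0.0
    sum_ho = 0.0
    sum_he = 0.0
    informative = False
    for k in range(panel.n_loci):
        genos = [row[k] for row in panel.genotypes if row[k] is not None]
        n = len(genos)
        if n < 2:
            continue
        alleles = sorted({a for g in genos for a in g})
        if len(alleles) < 2:
            continue
        informative = True
        for a in alleles:
            p = sum((g[0] == a) + (g[1] == a) for g in genos) / (2.0 * n)
            ho = sum(1 for g in genos if (a in g) and g[0] != g[1]) / n
            c = ho / 2.0
            b = n / (n - 1.0) * (p * (1.0 - p) - (2.0 * n - 1.0) / (4.0 * n) * ho)
            sum_c += c
            sum_bc += b + c
            sum_ho += ho
            sum_he += 2.0 * p * (1.0 - p) * n / (n - 1.0)
    if not informative:
        raise ValueError("Fis undefined: all loci monomorphic")
    if method == "weir-cockerham":
        return 1.0 - sum_c / sum_bc
    if method == "ho-he":
        return 1.0 - sum_ho / sum_he
    raise ValueError(f"unknown Fis method {method!r}")


def selfing_from_fis(fis: float, ndigits: Optional[int] = None):
    """Selfing rate under inbreeding equilibrium, s = 2*Fis/(1+Fis).

    Negative Fis is clamped to s = 0 (with a warning); the result is clamped
    to [0, 1].  ``ndigits`` applies half-up rounding for table-style reports.
    """
    if not -1.0 <= fis <= 1.0:
        raise ValueError("Fis must lie in [-1, 1]")
    if fis == -1.0:
        raise ValueError("selfing rate undefined at Fis = -1")
    if fis < 0:
        logger.warning("negative Fis %.4f: selfing rate clamped to 0", fis)
        s = 0.0
    else:
        s = min(1.0, 2.0 * fis / (1.0 + fis))
    return round_half_up(s, ndigits) if ndigits is not None else s


def _profile_loglik(s: float, h0: np.ndarray, H: np.ndarray, t_max: int) -> float:
    """Log-likelihood of the heterozygosity profile under partial selfing.

    H is the binary het matrix (NaN = missing); the latent per-individual
    selfing-generation count t is marginalized over 0..t_max.
    """
    from .synthetic import selfing_generation_weights

    w = selfing_generation_weights(s, t_max)          # (T,)
    decay = np.power(2.0, -np.arange(t_max + 1.0))    # (T,)
    p = h0[None, :] * decay[:, None]                  # (T, K)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    logp = np.log(p)
    log1mp = np.log1p(-p)
    obs = ~np.isnan(H)
    Hf = np.nan_to_num(H)
    # per-individual, per-t log-likelihood: sum over observed loci
    ll_it = Hf @ logp.T + ((1.0 - Hf) * obs) @ log1mp.T  # (N, T)
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    m = ll_it + logw[None, :]
    mmax = m.max(axis=1, keepdims=True)
    ll = mmax[:, 0] + np.log(np.exp(m - mmax).sum(axis=1))
    return float(ll.sum())


def _g2_identity_disequilibrium(H: np.ndarray) -> float:
    """Mean over locus pairs of <Hk Hl>/(<Hk><Hl>) - 1 (diagnostic)."""
    K = H.shape[1]
    vals = []
    for k, l in itertools.combinations(range(K), 2):
        ok = ~np.isnan(H[:, k]) & ~np.isnan(H[:, l])
        if ok.sum() < 2:
            continue
        mk = H[ok, k].mean()
        ml = H[ok, l].mean()
        if mk == 0 or ml == 0:
            continue
        vals.append((H[ok, k] * H[ok, l]).mean() / (mk * ml) - 1.0)
    return float(np.mean(vals)) if vals else float("nan")


def selfing_from_profile(panel: GenotypePanel, t_max: int = 20):
    """Maximum-likelihood selfing rate from the multilocus het profile.

    Maximizes the marginal likelihood over s and the per-locus outcrossed
    heterozygosities h0_k, with multi-start over s in {0.1,...,0.9} to avoid
    boundary traps.  The standard error comes from the numerical curvature of
    the profile log-likelihood in s.  Returns (s_hat, se, h0_hat, g2_hat).
    """
    if panel.n_loci < 2:
        raise ValueError("profile-based selfing needs at least 2 loci")
    H = panel.het_matrix()
    g2 = _g2_identity_disequilibrium(H)
    het_freq = np.nanmean(H, axis=0)
    if np.nansum(H) == 0:
        # no heterozygote anywhere: boundary solution s = 1
        return 1.0, float("nan"), np.full(panel.n_loci, np.nan), g2

    K = panel.n_loci
    eps = 1e-4
    bounds = [(0.0, 1.0 - 1e-9)] + [(eps, 1.0 - eps)] * K

    def neg(theta):
        return -_profile_loglik(theta[0], np.asarray(theta[1:]), H, t_max)

    best = None
    h0_init = np.clip(het_freq, 0.02, 0.98)
    for s0 in np.arange(0.1, 1.0, 0.1):
        # initialize h0 consistent with the candidate s (E[2^-t] correction)
        from .synthetic import selfing_generation_weights
        w = selfing_generation_weights(s0, t_max)
        e_decay = float(w @ np.power(2.0, -np.arange(t_max + 1.0)))
        x0 = np.concatenate([[s0], np.clip(h0_init / e_decay, eps, 1 - eps)])
        res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    s_hat = float(best.x[0])
    h0_hat = np.asarray(best.x[1:])

    # profile-likelihood curvature in s (re-optimizing h0 at s +/- delta)
    def profile_ll(s):
        r = minimize(lambda h: -_profile_loglik(s, np.asarray(h), H, t_max),
                     h0_hat, method="L-BFGS-B", bounds=bounds[1:])
        return -r.fun

    delta = 0.02
    lo = max(0.0, s_hat - delta)
    hi = min(1.0 - 1e-9, s_hat + delta)
    if hi - lo > 1e-6:
        l0 = profile_ll(s_hat)
        lm = profile_ll(lo)
        lp = profile_ll(hi)
        h = (hi - lo) / 2.0
        curv = (lp - 2.0 * l0 + lm) / (h * h)
        se = 1.0 / np.sqrt(-curv) if curv < 0 else float("nan")
    else:
        se = float("nan")
    return s_hat, float(se), h0_hat, g2


def selfing_estimate(panel: GenotypePanel, t_max: int = 20) -> SelfingEstimate:
    """Full Table-3-style mating-system summary for one species panel."""
    fis = fis_estimate(panel)
    clamped = fis < 0
    s_fis = selfing_from_fis(fis)
    s_prof, se, h0_hat, g2 = selfing_from_profile(panel, t_max=t_max)
    return SelfingEstimate(fis=fis, s_from_fis=s_fis, s_from_profile=s_prof,
                           s_profile_se=se, h0_hat=h0_hat, g2_hat=g2,
                           negative_fis_clamped=clamped,
                           boundary=(s_prof >= 1.0))


# ---------------------------------------------------------------------------
# STRUCTURE export / import
# ---------------------------------------------------------------------------

DIGIT_OF_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}
BASE_OF_DIGIT = {v: k for k, v in DIGIT_OF_BASE.items()}
MISSING_DIGIT = -9


def export_structure(panel: GenotypePanel, path: str) -> None:
    """Write the panel in STRUCTURE two-row-per-individual format.

    Nucleotide alleles are encoded A->0, C->1, G->2, T->3 (alphabetical
    order); missing genotypes become -9.  The header row lists locus names.
    """
    with open(path, "w") as f:
        f.write("\t".join(panel.loci) + "\n")
        for ind, row in zip(panel.individuals, panel.genotypes):
            for hap in (0, 1):
                digits = []
                for g in row:
                    if g is None:
                        digits.append(MISSING_DIGIT)
                    else:
                        a = g[hap]
                        if a not in DIGIT_OF_BASE:
                            raise ValueError(f"non-nucleotide allele {a!r}")
                        digits.append(DIGIT_OF_BASE[a])
                f.write(ind + "\t" + "\t".join(str(d) for d in digits) + "\n")


def import_structure(path: str) -> GenotypePanel:
    """Re-read a STRUCTURE file written by :func:`export_structure`."""
    with open(path) as f:
        loci = f.readline().split()
        rows = [line.split() for line in f if line.strip()]
    if len(rows) % 2:
        raise ValueError("STRUCTURE file must have two rows per individual")
    individuals, genotypes = [], []
    for r1, r2 in zip(rows[::2], rows[1::2]):
        if r1[0] != r2[0]:
            raise ValueError("individual row pairing broken")
        individuals.append(r1[0])
        geno = []
        for d1, d2 in zip(r1[1:], r2[1:]):
            if int(d1) == MISSING_DIGIT or int(d2) == MISSING_DIGIT:
                geno.append(None)
            else:
                geno.append((BASE_OF_DIGIT[int(d1)], BASE_OF_DIGIT[int(d2)]))
        genotypes.append(geno)
    return GenotypePanel(individuals=individuals, loci=loci, genotypes=genotypes)


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

def concatenate_markers(alignments: Sequence[MarkerAlignment],
                        strains: Optional[Sequence[str]] = None,
                        drop_gap_columns: bool = False,
                        max_minor_fraction: Optional[float] = None) -> MarkerAlignment:
    """Concatenate per-locus alignments end to end for shared strains.

    Optional per-locus column cleaning removes columns containing gaps
    (``drop_gap_columns``) or exceeding a minor-allele-fraction threshold
    (``max_minor_fraction``, high-variability filter).  Strains absent from
    any locus are excluded with a logged warning.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    shared = set(alignments[0].ids)
    union = set(alignments[0].ids)
    for aln in alignments[1:]:
        shared &= set(aln.ids)
        union |= set(aln.ids)
    if strains is not None:
        union = set(strains)
        shared &= union
    for missing in sorted(union - shared):
        logger.warning("strain %s missing from at least one locus: excluded "
                       "from concatenation", missing)
    if not shared:
        raise ValueError("no strain is present in every locus")
    order = [s for s in alignments[0].ids if s in shared]

    parts = {s: [] for s in order}
    for aln in alignments:
        idx = {sid: i for i, sid in enumerate(aln.ids)}
        keep_cols = range(aln.length)
        if drop_gap_columns or max_minor_fraction is not None:
            keep = []
            for j in range(aln.length):
                col = [aln.seqs[idx[s]][j] for s in order]
                if drop_gap_columns and any(c == "-" for c in col):
                    continue
                if max_minor_fraction is not None:
                    counts: dict = {}
                    for c in col:
                        for b in _split_base(c) if c not in "-N" else ():
                            counts[b] = counts.get(b, 0) + 1
                    if counts:
                        tot = sum(counts.values())
                        minor = tot - max(counts.values())
                        if minor / tot > max_minor_fraction:
                            continue
                keep.append(j)
            keep_cols = keep
        for s in order:
            seq = aln.seqs[idx[s]]
            parts[s].append("".join(seq[j] for j in keep_cols))

    species = {}
    for aln in alignments:
        species.update(aln.species)
    return MarkerAlignment("concat", order, ["".join(parts[s]) for s in order],
                           {s: sp for s, sp in species.items() if s in shared})
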