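"""Synthetic cohorts, sequences and truth sets for the sex-chromosome pipeline.

Every generator is deterministic given its arguments: the same config and seed
yield byte-identical outputs.  The cohort generator emulates a resequenced
diploid population of n males and n females carrying a recombination-suppressed
sex-determination region (SDR), a hemizygous Y-specific (or W-specific)
segment, and occasional recombinant individuals of the homogametic sex; the
sequence generators plant gametolog pairs at a target synonymous divergence and
LTR retrotransposons whose paired arms diverged at a known age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import DepthTable, GenotypeMatrix, SequenceRecord

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
# transition partner of each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# Codon families whose third position is fully synonymous and whose first and
# second positions are fully nonsynonymous under the standard code.  Using
# only these (plus the ATG start) makes the NG86 synonymous site count of a
# generated CDS exactly one per non-start codon, which lets the gametolog
# generator calibrate the planted Ks analytically.
_FOURFOLD_PREFIXES = ("GT", "GC", "AC", "CC", "TC", "GG")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults follow the resequencing design the pipeline targets: 30 males and
    30 females at ~32x coverage, an XY system with the SDR on a non-terminal
    stretch of one chromosome (6.39-8.73 Mb), a hemizygous Y-specific segment
    inside it, and a 10% chance that a female carries a recombined (Y-like)
    SDR haplotype (3 of 30 in the motivating data).  The LTR substitution rate
    mu is 2.5e-9 per site per year.
    """

    seed: int = 0
    n_males: int = 30
    n_females: int = 30
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr7": 12_000_000, "chr1": 6_000_000}
    )
    sdr_chrom: str = "chr7"
    sdr_interval: tuple = (6_390_000, 8_730_000)
    system: str = "XY"
    y_specific_interval: tuple = (7_400_000, 7_900_000)
    snp_rate: float = 5e-5
    mean_depth: float = 32.0
    depth_dispersion: float = 0.1
    recombinant_fraction: float = 0.1
    gametolog_ks_target: float = 0.033
    ltr_ages: tuple = (1e6, 5e6, 10e6, 20e6)
    mu: float = 2.5e-9
    kappa: float = 2.0
    read_length: int = 10_000
    depth_window_bp: int = 100_000
    genotype_error: float = 0.02
    autosomal_missing_rate: float = 0.02
    # hemizygous-segment call model (see docs/methods.md): the homogametic sex
    # is mostly uncalled there, with spillover hom-ref calls; carriers are
    # called hom-alt at a high rate.
    hemizygous_missing_rate: float = 0.75
    carrier_call_rate: float = 0.9

    def __post_init__(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_males + self.n_females == 0:
            raise ValueError("zero-length cohort")
        if self.system not in {"XY", "ZW"}:
            raise ValueError(f"system must be XY or ZW, got {self.system!r}")
        if self.sdr_chrom not in self.chrom_lengths:
            raise ValueError(f"sdr_chrom {self.sdr_chrom!r} not in chrom_lengths")
        s, e = self.sdr_interval
        if not (0 <= s < e <= self.chrom_lengths[self.sdr_chrom]):
            raise ValueError("sdr_interval empty or outside chromosome")
        ys, ye = self.y_specific_interval
        if not (s <= ys < ye <= e):
            raise ValueError("y_specific_interval must lie inside sdr_interval")
        if not 0.0 <= self.recombinant_fraction <= 1.0:
            raise ValueError("recombinant_fraction must be in [0, 1]")
        if self.mu <= 0:
            raise ValueError("mu must be positive")

    @property
    def heterogametic_sex(self) -> str:
        return "M" if self.system == "XY" else "F"

    @property
    def homogametic_sex(self) -> str:
        return "F" if self.system == "XY" else "M"


@dataclass
class TruthSet:
    """Planted ground truth accompanying each generated dataset."""

    sdr_interval: tuple = (0, 0)
    y_specific_interval: tuple = (0, 0)
    system: str = "XY"
    recombinant_ids: list = field(default_factory=list)
    gametolog_true_ks: list = field(default_factory=list)
    ltr_true_ages: list = field(default_factory=list)
    planted_effect_classes: list = field(default_factory=list)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"system\t{self.system}\n")
            fh.write(f"sdr_interval\t{self.sdr_interval[0]}-{self.sdr_interval[1]}\n")
            fh.write(
                "y_specific_interval\t"
                f"{self.y_specific_interval[0]}-{self.y_specific_interval[1]}\n"
            )
            fh.write(f"recombinant_ids\t{','.join(self.recombinant_ids)}\n")
            for i, ks in enumerate(self.gametolog_true_ks):
                fh.write(f"gametolog_ks_{i}\t{ks:g}\n")
            for i, age in enumerate(self.ltr_true_ages):
                fh.write(f"ltr_age_{i}\t{age:g}\n")


def _zone(cfg: SimulationConfig, chrom: str, pos0: int) -> str:
    if chrom != cfg.sdr_chrom:
        return "AUT"
    ys, ye = cfg.y_specific_interval
    if ys <= pos0 < ye:
        return "HEMI"
    s, e = cfg.sdr_interval
    if s <= pos0 < e:
        return "SDR"
    return "AUT"


def simulate_cohort(cfg: SimulationConfig):
    """Generate genotypes, per-window depths and the truth set for a cohort.

    Autosomal sites segregate independently of sex under Hardy-Weinberg
    proportions.  Inside the SDR, heterogametic-sex individuals are
    heterozygous at diagnostic sites and homogametic-sex individuals
    homozygous (mirrored for ZW); recombinant homogametic individuals carry
    the full opposite-pattern haplotype.  Inside the hemizygous segment the
    homogametic sex is mostly uncalled and carriers are called homozygous,
    with carrier depth at half the genome-wide expectation.

    Returns ``(GenotypeMatrix, DepthTable, TruthSet)``.
    """
    rng = np.random.default_rng(cfg.seed)
    het_sex, hom_sex = cfg.heterogametic_sex, cfg.homogametic_sex

    ids = [f"M{i + 1:03d}" for i in range(cfg.n_males)] + [
        f"F{i + 1:03d}" for i in range(cfg.n_females)
    ]
    sexes = ["M"] * cfg.n_males + ["F"] * cfg.n_females
    samples = pd.DataFrame({"id": ids, "sex": sexes})
    n_ind = len(ids)
    hom_mask = np.array([s == hom_sex for s in sexes])
    het_mask = ~hom_mask

    # whole-haplotype recombinants among the homogametic sex
    recomb = hom_mask & (rng.random(n_ind) < cfg.recombinant_fraction)
    carrier = het_mask | recomb  # individuals carrying the Y (or W) haplotype

    site_rows, code_rows = [], []
    for chrom in cfg.chrom_lengths:
        length = cfg.chrom_lengths[chrom]
        n_sites = rng.poisson(cfg.snp_rate * length)
        if n_sites == 0:
            continue
        positions = np.sort(
            rng.choice(length, size=min(n_sites, length), replace=False)
        )
        for pos0 in positions:
            zone = _zone(cfg, chrom, int(pos0))
            ref, alt = rng.choice(list(BASES), size=2, replace=False)
            if zone == "AUT":
                qual = rng.uniform(20, 90)
                p_alt = rng.uniform(0.05, 0.5)
                codes = rng.binomial(2, p_alt, size=n_ind).astype(np.int8)
                codes[rng.random(n_ind) < cfg.autosomal_missing_rate] = -1
            elif zone == "SDR":
                qual = rng.uniform(40, 90)
                codes = np.where(carrier, 1, 0).astype(np.int8)
                err = rng.random(n_ind) < cfg.genotype_error
                codes[err] = rng.choice([0, 1, 2, -1], size=int(err.sum()))
            else:  # HEMI
                qual = rng.uniform(40, 90)
                codes = np.full(n_ind, -1, dtype=np.int8)
                called_carrier = carrier & (rng.random(n_ind) < cfg.carrier_call_rate)
                codes[called_carrier] = 2
                spill = (~carrier) & (
                    rng.random(n_ind) >= cfg.hemizygous_missing_rate
                )
                codes[spill] = 0
            site_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos0) + 1,
                    "ref": ref,
                    "alt": alt,
                    "qual": round(float(qual), 2),
                }
            )
            code_rows.append(codes)

    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    codes = np.vstack(code_rows) if code_rows else np.empty((0, n_ind), np.int8)
    gm = GenotypeMatrix(sites=sites, samples=samples, codes=codes)

    # depth: negative-binomial window means, variance m + dispersion * m^2
    win_rows, means = [], []
    ys, ye = cfg.y_specific_interval
    for chrom, length in cfg.chrom_lengths.items():
        for start in range(0, length, cfg.depth_window_bp):
            end = min(start + cfg.depth_window_bp, length)
            win_rows.append({"chrom": chrom, "start": start, "end": end})
            if chrom == cfg.sdr_chrom:
                ovl = max(0, min(end, ye) - max(start, ys)) / (end - start)
            else:
                ovl = 0.0
            m = cfg.mean_depth
            mean_i = np.where(
                carrier,
                m * (1 - ovl) + (m / 2) * ovl,
                m * (1 - ovl),
            )
            means.append(mean_i)
    mean_arr = np.vstack(means)
    if cfg.depth_dispersion > 0:
        r = 1.0 / cfg.depth_dispersion
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(mean_arr > 0, r / (r + mean_arr), 1.0)
        values = rng.negative_binomial(r, p).astype(float)
        values[mean_arr == 0] = 0.0
    else:
        values = rng.poisson(mean_arr).astype(float)
    depth = DepthTable(
        windows=pd.DataFrame(win_rows), values=values, sample_ids=ids
    )

    truth = TruthSet(
        sdr_interval=cfg.sdr_interval,
        y_specific_interval=cfg.y_specific_interval,
        system=cfg.system,
        recombinant_ids=[i for i, r in zip(ids, recomb) if r],
    )
    return gm, depth, truth


# ---------------------------------------------------------------------------
# Gametolog pairs
# ---------------------------------------------------------------------------

def _jc_expected_p(d: float) -> float:
    """Expected proportion of differing sites after Jukes-Cantor divergence d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def simulate_gametolog_pairs(n_pairs: int, cds_length: int, ks_target: float,
                             seed: int):
    """Generate X/Y coding-sequence pairs with a planted synonymous divergence.

    Each pair starts ATG, contains no internal stops, and diverges only at
    synonymous (fourfold-degenerate third) positions under a Jukes-Cantor
    process calibrated so the expected NG86 Ks equals ``ks_target``.

    Returns a list of ``(SequenceRecord x, SequenceRecord y)`` tuples.
    """
    if cds_length % 3 != 0:
        raise ValueError(f"cds_length {cds_length} not divisible by 3")
    if ks_target < 0:
        raise ValueError("ks_target must be non-negative")
    if ks_target > 3.0:
        raise ValueError(
            f"ks_target {ks_target} too large: divergence correction is "
            "numerically undefined at this saturation level"
        )
    rng = np.random.default_rng(seed)
    n_codons = cds_length // 3
    p_sub = _jc_expected_p(ks_target)
    pairs = []
    for k in range(n_pairs):
        prefixes = rng.choice(list(_FOURFOLD_PREFIXES), size=n_codons - 1)
        thirds = rng.choice(list(BASES), size=n_codons - 1)
        codons = ["ATG"] + [p + t for p, t in zip(prefixes, thirds)]
        x_seq = "".join(codons)
        y_codons = list(codons)
        hit = rng.random(n_codons - 1) < p_sub
        for i in np.flatnonzero(hit):
            c = y_codons[i + 1]
            others = [b for b in BASES if b != c[2]]
            y_codons[i + 1] = c[:2] + rng.choice(others)
        y_seq = "".join(y_codons)
        pairs.append(
            (
                SequenceRecord(id=f"gamX_{k}", residues=x_seq),
                SequenceRecord(id=f"gamY_{k}", residues=y_seq),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# LTR elements
# ---------------------------------------------------------------------------

def _k2p_probs(d: float, kappa: float):
    """Kimura two-parameter substitution probabilities after divergence ``d``
    (expected substitutions per site) with transition/transversion rate ratio
    ``kappa``: returns (p_transition, p_each_transversion)."""
    alpha = d * kappa / (kappa + 2.0)
    beta = d / (kappa + 2.0)
    # closed-form K2P transition probabilities
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * beta) - 0.5 * math.exp(-2.0 * (alpha + beta))
    p_tv = 0.25 - 0.25 * math.exp(-4.0 * beta)  # per transversion target
    return p_ts, p_tv


def _evolve_k2p(seq: np.ndarray, d: float, kappa: float, rng) -> np.ndarray:
    """Evolve an integer-coded sequence under K2P for divergence ``d``."""
    p_ts, p_tv = _k2p_probs(d, kappa)
    u = rng.random(len(seq))
    out = seq.copy()
    ts_target = np.array([_BASE_IDX[_TRANSITION[b]] for b in BASES])
    # transversion targets per base, deterministic order
    tv_targets = np.array(
        [[j for j in range(4) if j != i and j != ts_target[i]] for i in range(4)]
    )
    ts_hit = u < p_ts
    tv1_hit = (u >= p_ts) & (u < p_ts + p_tv)
    tv2_hit = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts_hit] = ts_target[seq[ts_hit]]
    out[tv1_hit] = tv_targets[seq[tv1_hit], 0]
    out[tv2_hit] = tv_targets[seq[tv2_hit], 1]
    return out


def simulate_ltr_elements(ages, mu: float, arm_length: int, kappa: float,
                          seed: int):
    """Generate paired LTR arms that diverged from one ancestral arm.

    Each element's two arms accumulate substitutions independently for ``age``
    years at rate ``mu`` per site per year (total divergence expectation
    ``2 * mu * age``), with transitions favoured by ``kappa``.

    Returns a list of ``(element_id, SequenceRecord arm5, SequenceRecord arm3,
    age_years)`` tuples.
    """
    if arm_length <= 0:
        raise ValueError("arm_length must be positive")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if any(a < 0 for a in ages):
        raise ValueError("ages must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for k, age in enumerate(ages):
        anc = rng.integers(0, 4, size=arm_length)
        d = mu * age
        arm5 = _evolve_k2p(anc, d, kappa, rng)
        arm3 = _evolve_k2p(anc, d, kappa, rng)
        s5 = "".join(BASES[i] for i in arm5)
        s3 = "".join(BASES[i] for i in arm3)
        out.append(
            (
                f"ltr_{k}",
                SequenceRecord(id=f"ltr_{k}_5p", residues=s5),
                SequenceRecord(id=f"ltr_{k}_3p", residues=s3),
                float(age),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(genome, read_length: int, depth: float, seed: int):
    """Draw error-free reads with uniform start positions from each sequence.

    ``genome`` is a list of :class:`SequenceRecord`.  The expected per-base
    coverage equals ``depth``.  Read ids encode their source sequence and
    start (``<source>|<start>|<serial>``) for truth tracking.
    """
    if not genome:
        raise ValueError("empty genome")
    if any(len(rec) < read_length for rec in genome):
        raise ValueError("read_length exceeds the shortest sequence")
    rng = np.random.default_rng(seed)
    reads = []
    serial = 0
    for rec in genome:
        n_reads = int(round(depth * len(rec) / read_length))
        starts = rng.integers(0, len(rec) - read_length + 1, size=n_reads)
        for start in np.sort(starts):
            reads.append(
                SequenceRecord(
                    id=f"{rec.id}|{start}|{serial}",
                    residues=rec.residues[start: start + read_length],
                )
            )
            serial += 1
    return reads


def simulate_sex_sequences(n_males: int, n_females: int, background_length: int,
                           y_insert_length: int, seed: int):
    """Per-individual sequence sets with a Y-limited insert planted in males.

    All individuals share a common background sequence (with rare private
    SNVs); males additionally carry a unique Y-specific insert.  Returns
    ``(per_individual, sex_map, y_insert)`` where ``per_individual`` maps
    individual id -> list of SequenceRecord.
    """
    rng = np.random.default_rng(seed)
    background = "".join(rng.choice(list(BASES), size=background_length))
    y_insert = "".join(rng.choice(list(BASES), size=y_insert_length))
    per_individual, sex_map = {}, {}
    for i in range(n_males + n_females):
        sex = "M" if i < n_males else "F"
        ind = f"{sex}{i + 1:03d}" if sex == "M" else f"F{i - n_males + 1:03d}"
        seq = list(background)
        for j in rng.choice(background_length, size=3, replace=False):
            seq[j] = rng.choice([b for b in BASES if b != seq[j]])
        recs = [SequenceRecord(id=f"{ind}_bg", residues="".join(seq))]
        if sex == "M":
            recs.append(SequenceRecord(id=f"{ind}_y", residues=y_insert))
        per_individual[ind] = recs
        sex_map[ind] = sex
    return per_individual, sex_map, SequenceRecord(id="y_insert", residues=y_insert)


def simulate_phased_observations(n_sites: int, n_reads: int, span: int,
                                 seed: int, chimera_rate: float = 0.0,
                                 chrom: str = "chr7"):
    """Read-to-site allele observations from two complementary haplotypes.

    Haplotype 0 (X-like) carries the reference allele at every heterozygous
    site; haplotype 1 (Y-like) carries the alternate.  Each read covers
    ``span`` consecutive sites; chimeric reads switch haplotype mid-read.

    Returns ``(observations DataFrame(read_id, chrom, pos, allele),
    read_truth dict read_id -> 0/1, male_allele dict pos -> Y allele)``.
    """
    rng = np.random.default_rng(seed)
    positions = [1000 * (i + 1) for i in range(n_sites)]
    alleles = []
    for _ in range(n_sites):
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        alleles.append((ref, alt))
    rows, truth = [], {}
    for r in range(n_reads):
        hap = int(rng.integers(0, 2))
        start = int(rng.integers(0, max(1, n_sites - span + 1)))
        chimeric = rng.random() < chimera_rate
        switch_at = int(rng.integers(1, span)) if chimeric and span > 1 else span
        rid = f"read{r}"
        truth[rid] = hap
        for k in range(span):
            i = start + k
            if i >= n_sites:
                break
            h = hap if k < switch_at else 1 - hap
            rows.append(
                {
                    "read_id": rid,
                    "chrom": chrom,
                    "pos": positions[i],
                    "allele": alleles[i][h],
                }
            )
    obs = pd.DataFrame(rows, columns=["read_id", "chrom", "pos", "allele"])
    male_allele = {p: a[1] for p, a in zip(positions, alleles)}
    return obs, truth, male_allele


def simulate_gene_load(n_genes: int, syn_mean: float, del_per_syn: float,
                       tol_per_syn: float, seed: int) -> pd.DataFrame:
    """Per-gene SYN/DEL/TOL variant counts for load-comparison calibration.

    SYN counts are Poisson(``syn_mean``) + 1 (every gene keeps a defined
    neutral denominator); DEL and TOL counts are Poisson with means
    proportional to the gene's SYN count.
    """
    rng = np.random.default_rng(seed)
    syn = rng.poisson(syn_mean, size=n_genes) + 1
    dele = rng.poisson(del_per_syn * syn)
    tol = rng.poisson(tol_per_syn * syn)
    return pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(n_genes)],
            "n_del": dele,
            "n_tol": tol,
            "n_syn": syn,
        }
    )


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``cfg`` with a different seed (convenience for replicate runs)."""
    return replace(cfg, seed=seed)
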