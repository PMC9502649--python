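"""Coding-variant effect annotation and deleterious-load comparison.

Variants are classified straight from the standard genetic code as SYN
(synonymous), MISSENSE, or LOF (stop gained, start lost, stop lost).
Missense variants are then split into deleterious (DEL) and tolerated (TOL)
by a conservation-based consensus of two scorers over per-gene ortholog
alignment columns; a variant is DEL only when both scorers agree.  Load is
compared between regions on per-gene DEL/SYN and TOL/SYN ratios, with SYN
variants as the selectively neutral reference, using a two-sided
Mann-Whitney U test plus a label-permutation p-value, Holm-corrected across
region pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import CODON_AA
from .io import GeneModel

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class VariantEffect:
    chrom: str
    pos: int  # 1-based
    gene_id: str
    codon_index: int
    ref_codon: str
    alt_codon: str
    effect: str  # SYN / MISSENSE / LOF
    detail: str = ""  # stop_gained / start_lost / stop_lost for LOF


@dataclass
class DeleteriousnessCall:
    variant: VariantEffect
    klass: str  # DEL / TOL
    conservation: float
    votes: tuple  # (scorer A vote, scorer B vote)

    def __post_init__(self) -> None:
        if self.klass == "DEL" and not all(self.votes):
            raise ValueError("DEL requires consensus of both scorers")


@dataclass
class LoadSummary:
    per_gene: pd.DataFrame  # region, gene, n_del, n_tol, n_syn, del_syn, tol_syn
    tests: pd.DataFrame  # region_a, region_b, metric, u, p_ranksum, p_perm, p_holm
    flagged_regions: list = field(default_factory=list)


def classify_codon_change(ref_codon: str, alt_codon: str,
                          codon_index: int) -> tuple:
    """Effect of one codon substitution under the standard code.

    Returns ``(effect, detail)``.  LOF covers stop gained, stop lost, and
    loss of the initiator ATG at codon 0.
    """
    ref_aa = CODON_AA[ref_codon]
    alt_aa = CODON_AA[alt_codon]
    if codon_index == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "LOF", "start_lost"
    if ref_aa == "*" and alt_aa != "*":
        return "LOF", "stop_lost"
    if alt_aa == "*" and ref_aa != "*":
        return "LOF", "stop_gained"
    if ref_aa == alt_aa:
        return "SYN", ""
    return "MISSENSE", ""


def annotate_effects(variants, gene_models, genome: dict) -> tuple:
    """Annotate SNVs against gene models and the genome sequence.

    ``variants`` is an iterable of (chrom, pos, ref, alt) with 1-based
    positions; ``genome`` maps chrom -> sequence.  Minus-strand genes are
    handled by reverse complement.  Returns ``(effects, non_coding)`` where
    ``non_coding`` lists variants outside every CDS (excluded from load).
    """
    models_by_chrom: dict[str, list] = {}
    for m in gene_models:
        models_by_chrom.setdefault(m.chrom, []).append(m)
    effects, non_coding = [], []
    for chrom, pos, ref, alt in variants:
        hit = False
        for m in models_by_chrom.get(chrom, ()):
            off = m.cds_offset(pos)
            if off is None:
                continue
            hit = True
            cds = m.cds_sequence(genome)
            if m.strand == "-":
                ref_c = ref.translate(_COMPLEMENT)
                alt_c = alt.translate(_COMPLEMENT)
            else:
                ref_c, alt_c = ref, alt
            if cds[off] != ref_c:
                raise ValueError(
                    f"{chrom}:{pos}: reference allele {ref} does not match "
                    f"the genome through gene {m.gene_id}"
                )
            ci = off // 3
            within = off % 3
            ref_codon = cds[3 * ci: 3 * ci + 3]
            alt_codon = (
                ref_codon[:within] + alt_c + ref_codon[within + 1:]
            )
            effect, detail = classify_codon_change(ref_codon, alt_codon, ci)
            effects.append(
                VariantEffect(
                    chrom=chrom, pos=pos, gene_id=m.gene_id, codon_index=ci,
                    ref_codon=ref_codon, alt_codon=alt_codon,
                    effect=effect, detail=detail,
                )
            )
        if not hit:
            non_coding.append((chrom, pos, ref, alt))
    return effects, non_coding


def conservation_scores(variant_effects, ortholog_alignments: dict,
                        conservation_min: float = 0.8,
                        variant_freq_max: float = 0.05) -> tuple:
    """Consensus conservation-based DEL/TOL calls for missense variants.

    ``ortholog_alignments`` maps gene id -> list of ortholog protein
    sequences aligned to the reference protein (one residue per codon).
    Scorer A votes deleterious when the reference residue's column
    conservation is >= ``conservation_min`` and the variant residue is absent
    from the column; scorer B votes deleterious when the variant residue's
    column frequency is below ``variant_freq_max``.  DEL requires both votes;
    SYN variants are never scored.  Variants whose gene or column is missing
    are excluded and reported.

    Returns ``(calls, excluded_variants)``.
    """
    calls, excluded = [], []
    for ve in variant_effects:
        if ve.effect != "MISSENSE":
            continue
        aln = ortholog_alignments.get(ve.gene_id)
        if aln is None or not aln or any(ve.codon_index >= len(s) for s in aln):
            excluded.append(ve)
            continue
        ref_aa = CODON_AA[ve.ref_codon]
        alt_aa = CODON_AA[ve.alt_codon]
        column = [s[ve.codon_index] for s in aln]
        conservation = column.count(ref_aa) / len(column)
        alt_freq = column.count(alt_aa) / len(column)
        vote_a = conservation >= conservation_min and alt_aa not in column
        vote_b = alt_freq < variant_freq_max
        klass = "DEL" if (vote_a and vote_b) else "TOL"
        calls.append(
            DeleteriousnessCall(
                variant=ve, klass=klass, conservation=conservation,
                votes=(vote_a, vote_b),
            )
        )
    return calls, excluded


def gene_counts_from_calls(effects, calls, pool_lof_with_del: bool = True
                           ) -> pd.DataFrame:
    """Tabulate per-gene DEL/TOL/SYN counts from effects and DEL/TOL calls.

    LOF variants are pooled with DEL by default (configurable), keeping SYN
    as the neutral denominator.
    """
    klass_by_variant = {
        (c.variant.chrom, c.variant.pos, c.variant.gene_id): c.klass
        for c in calls
    }
    rows: dict[str, dict] = {}
    for ve in effects:
        g = rows.setdefault(
            ve.gene_id, {"gene": ve.gene_id, "n_del": 0, "n_tol": 0, "n_syn": 0}
        )
        if ve.effect == "SYN":
            g["n_syn"] += 1
        elif ve.effect == "LOF":
            if pool_lof_with_del:
                g["n_del"] += 1
        elif ve.effect == "MISSENSE":
            k = klass_by_variant.get((ve.chrom, ve.pos, ve.gene_id))
            if k == "DEL":
                g["n_del"] += 1
            elif k == "TOL":
                g["n_tol"] += 1
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["gene"]),
                        columns=["gene", "n_del", "n_tol", "n_syn"])


def _perm_pvalue(x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> float:
    """Two-sided label-permutation p-value for a difference in means."""
    obs = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    nx = len(x)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:nx].mean() - pooled[nx:].mean()) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _holm(pvals: list) -> list:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def load_compare(counts_by_region: dict, n_perm: int = 2000,
                 seed: int = 0, min_genes: int = 5) -> LoadSummary:
    """Compare deleterious load between regions with SYN as neutral reference.

    ``counts_by_region`` maps region label -> DataFrame with columns gene,
    n_del, n_tol, n_syn.  Per-gene DEL/SYN and TOL/SYN ratios are compared
    between every region pair with a two-sided Mann-Whitney U test and a
    label-permutation test (``n_perm`` draws); Holm correction is applied
    across region pairs per metric.  Regions with fewer than ``min_genes``
    genes having a defined ratio (SYN > 0) are flagged; with fewer than two
    usable regions the comparison is an error.
    """
    if len(counts_by_region) < 2:
        raise ValueError("load comparison requires at least two regions")
    rng = np.random.default_rng(seed)
    frames = []
    flagged = []
    for region in sorted(counts_by_region):
        df = counts_by_region[region].copy()
        df["region"] = region
        with np.errstate(divide="ignore", invalid="ignore"):
            df["del_syn"] = np.where(df["n_syn"] > 0,
                                     df["n_del"] / df["n_syn"], np.nan)
            df["tol_syn"] = np.where(df["n_syn"] > 0,
                                     df["n_tol"] / df["n_syn"], np.nan)
        if int((df["n_syn"] > 0).sum()) < min_genes:
            flagged.append(region)
        frames.append(df)
    per_gene = pd.concat(frames, ignore_index=True)

    usable = [r for r in sorted(counts_by_region) if r not in flagged]
    if len(usable) < 2:
        raise ValueError(
            f"fewer than two regions with >= {min_genes} genes having "
            f"defined ratios (flagged: {flagged})"
        )
    rows = []
    for metric in ("del_syn", "tol_syn"):
        pvals_rank, pvals_perm, pairs = [], [], []
        for ra, rb in itertools.combinations(usable, 2):
            x = per_gene.loc[per_gene["region"] == ra, metric].dropna().to_numpy()
            y = per_gene.loc[per_gene["region"] == rb, metric].dropna().to_numpy()
            u, p_rank = stats.mannwhitneyu(x, y, alternative="two-sided")
            p_perm = _perm_pvalue(x, y, n_perm, rng)
            pairs.append((ra, rb, float(u)))
            pvals_rank.append(float(p_rank))
            pvals_perm.append(float(p_perm))
        holm = _holm(pvals_rank) if pvals_rank else []
        for (ra, rb, u), pr, pp, ph in zip(pairs, pvals_rank, pvals_perm, holm):
            rows.append(
                {
                    "region_a": ra, "region_b": rb, "metric": metric,
                    "u": u, "p_ranksum": pr, "p_perm": pp, "p_holm": ph,
                }
            )
    tests = pd.DataFrame(
        rows,
        columns=["region_a", "region_b", "metric", "u",
                 "p_ranksum", "p_perm", "p_holm"],
    )
    return LoadSummary(per_gene=per_gene, tests=tests, flagged_regions=flagged)
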