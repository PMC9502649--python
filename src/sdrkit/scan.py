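"""Sex-association scan: variant filtering, per-site Fisher exact tests with
Bonferroni control, heterogamety classification, recombinant detection and
SDR interval delineation.

The association test is a two-sided Fisher exact test on the 2x2 table of
allele counts by sex (the allelic test); significance is controlled at a
family-wise alpha by Bonferroni over the number of sites tested.  Intervals
are delineated by gap-joining significant sites, and each interval is
labelled from three lines of evidence: sex-specific heterozygosity,
sex-specific missingness, and sex-normalized read depth (hemizygous sequence
shows ~0.5 normalized depth in carriers and ~0 plus high missingness in the
other sex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DepthTable, GenotypeMatrix


@dataclass
class ScanConfig:
    """Thresholds for the sex-association scan (defaults in docstrings of the
    operations that consume them)."""

    alpha: float = 0.05
    min_quality: float = 30.0
    indel_exclusion_bp: int = 5
    depth_low_frac: float = 1.0 / 3.0
    depth_high_frac: float = 3.0
    het_high: float = 0.6
    het_low: float = 0.2
    missing_high: float = 0.5
    depth_ratio_target: float = 0.5
    depth_ratio_tol: float = 0.15
    depth_zero_max: float = 0.1
    cluster_gap_bp: int = 1_000_000
    min_cluster_sites: int = 5
    recombinant_het_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.het_low < self.het_high:
            raise ValueError("het_low must be below het_high")
        for name in ("het_high", "het_low", "missing_high",
                     "recombinant_het_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SiteAssociation:
    site_index: int
    chrom: str
    pos: int
    table: np.ndarray  # rows: (heterogametic-candidate M, F); cols: (ref, alt)
    p_value: float
    significant: bool = False

    def __post_init__(self) -> None:
        if (self.table < 0).any():
            raise ValueError("allele counts must be non-negative")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class SexGenotypeProfile:
    """Per-site and pooled genotype-state fractions by sex.

    Fractions of het/hom are computed over called genotypes only; missingness
    is reported over all genotypes.  Cells with no called genotypes carry NaN
    rather than zero.
    """

    per_site: pd.DataFrame  # chrom,pos + {M,F}_{het,hom,missing,called}
    pooled: dict  # sex -> {het, hom, missing, called_total, n_total}


@dataclass
class RegionCall:
    chrom: str
    start: int
    end: int
    region_class: str  # X_SDR / Y_SPECIFIC / Z_SDR / W_SPECIFIC / NOT_SEX_LINKED
    n_sites: int = 0
    best_p: float = 1.0
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")


@dataclass
class HeterogametyCall:
    system: str  # XY / ZW / UNDETERMINED
    evidence: dict


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_variants(gm: GenotypeMatrix, depth: DepthTable, indel_positions,
                    cfg: ScanConfig) -> GenotypeMatrix:
    """Apply the four variant-quality filters and return a new matrix.

    Removes sites with (i) quality below ``min_quality`` (default 30);
    (ii) more than two alleles; (iii) positions within ``indel_exclusion_bp``
    (default 5) of any indel; (iv) cohort mean depth below 1/3 or above 3x
    the genome-wide mean.  The input matrix is not modified.
    """
    gw_mean = float(depth.genome_wide_mean().mean())
    indels_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in indel_positions:
        indels_by_chrom.setdefault(chrom, []).append(pos)
    indels_by_chrom = {c: np.sort(np.asarray(p)) for c, p in indels_by_chrom.items()}

    keep = []
    for i, site in enumerate(gm.sites.itertuples(index=False)):
        if not np.isnan(site.qual) and site.qual < cfg.min_quality:
            continue
        if len([a for a in str(site.alt).split(",") if a and a != "."]) > 1:
            continue
        near = indels_by_chrom.get(site.chrom)
        if near is not None and len(near):
            j = np.searchsorted(near, site.pos)
            dists = []
            if j < len(near):
                dists.append(abs(int(near[j]) - site.pos))
            if j > 0:
                dists.append(abs(int(near[j - 1]) - site.pos))
            if dists and min(dists) <= cfg.indel_exclusion_bp:
                continue
        try:
            w = depth.window_of(site.chrom, site.pos)
        except KeyError as exc:
            raise ValueError(
                f"site {site.chrom}:{site.pos} lacks a depth window"
            ) from exc
        # mean over individuals with coverage: hemizygous sequence is absent
        # (not low-quality) in the non-carrying sex, so zero-coverage
        # individuals carry no depth information for the site
        covered = depth.values[w][depth.values[w] > 0]
        site_mean = float(covered.mean()) if len(covered) else 0.0
        if site_mean < cfg.depth_low_frac * gw_mean:
            continue
        if site_mean > cfg.depth_high_frac * gw_mean:
            continue
        keep.append(i)
    return gm.take_sites(keep)


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

def _allele_table(codes_site: np.ndarray, male_mask: np.ndarray,
                  female_mask: np.ndarray) -> np.ndarray:
    """2x2 allele-count table (rows M, F; cols ref, alt) from genotype codes.

    Codes contribute 0 -> 2 ref, 1 -> 1+1, 2 -> 2 alt; missing is excluded.
    """
    table = np.zeros((2, 2), dtype=np.int64)
    for row, mask in enumerate((male_mask, female_mask)):
        c = codes_site[mask]
        c = c[c >= 0]
        n_het = int((c == 1).sum())
        table[row, 0] = 2 * int((c == 0).sum()) + n_het
        table[row, 1] = 2 * int((c == 2).sum()) + n_het
    return table


def associate_sex(gm: GenotypeMatrix) -> list:
    """Per-site two-sided Fisher exact tests of allele counts against sex."""
    male = gm.sex_mask("M")
    female = gm.sex_mask("F")
    if male.sum() == 0 or female.sum() == 0:
        raise ValueError("association requires at least one individual of each sex")
    out = []
    for i, site in enumerate(gm.sites.itertuples(index=False)):
        table = _allele_table(gm.codes[i], male, female)
        if table.sum() == 0 or table.sum(axis=0).min() == 0 or \
                table.sum(axis=1).min() == 0:
            p = 1.0  # degenerate margin: no information
        else:
            _, p = stats.fisher_exact(table, alternative="two-sided")
        out.append(
            SiteAssociation(
                site_index=i, chrom=site.chrom, pos=int(site.pos),
                table=table, p_value=float(min(p, 1.0)),
            )
        )
    return out


def bonferroni_significant(assocs, alpha: float) -> list:
    """Mark associations significant at family-wise ``alpha`` (Bonferroni).

    The correction divides by the number of sites tested (``len(assocs)``),
    not by the number surviving.  Returns the significant subset; the
    ``significant`` flags on the inputs are updated in place.
    """
    m = len(assocs)
    if m == 0:
        raise ValueError("no sites tested")
    cut = alpha / m
    sig = []
    for a in assocs:
        a.significant = a.p_value < cut
        if a.significant:
            sig.append(a)
    return sig


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def genotype_profile(gm: GenotypeMatrix, site_indices) -> SexGenotypeProfile:
    """Sex-specific het/hom/missing fractions per site and pooled."""
    site_indices = list(site_indices)
    if not site_indices:
        raise ValueError("sites subset is empty")
    rows = []
    totals = {s: {"het": 0, "hom": 0, "missing": 0, "n": 0} for s in "MF"}
    masks = {s: gm.sex_mask(s) for s in "MF"}
    for i in site_indices:
        site = gm.sites.iloc[i]
        row = {"chrom": site["chrom"], "pos": int(site["pos"])}
        for s in "MF":
            c = gm.codes[i][masks[s]]
            n = len(c)
            n_missing = int((c == -1).sum())
            n_called = n - n_missing
            n_het = int((c == 1).sum())
            n_hom = int(((c == 0) | (c == 2)).sum())
            row[f"{s}_het"] = n_het / n_called if n_called else np.nan
            row[f"{s}_hom"] = n_hom / n_called if n_called else np.nan
            row[f"{s}_missing"] = n_missing / n if n else np.nan
            row[f"{s}_called"] = n_called
            totals[s]["het"] += n_het
            totals[s]["hom"] += n_hom
            totals[s]["missing"] += n_missing
            totals[s]["n"] += n
    # pooled fractions over all genotype calls at the selected sites
        rows.append(row)
    pooled = {}
    for s in "MF":
        t = totals[s]
        called = t["het"] + t["hom"]
        pooled[s] = {
            "het": t["het"] / called if called else np.nan,
            "hom": t["hom"] / called if called else np.nan,
            "missing": t["missing"] / t["n"] if t["n"] else np.nan,
            "called_total": called,
            "n_total": t["n"],
        }
    return SexGenotypeProfile(per_site=pd.DataFrame(rows), pooled=pooled)


def detect_recombinants(gm: GenotypeMatrix, significant_sites, system_guess: str,
                        cfg: ScanConfig):
    """Flag homogametic-sex individuals with an excess of heterozygous calls
    across the significant sites (evidence of an X-Y recombined haplotype).

    Returns ``(flagged_ids, reprofiled SexGenotypeProfile)`` where the profile
    excludes the flagged individuals.
    """
    if not list(significant_sites):
        raise ValueError("significant_sites is empty")
    hom_sex = "F" if system_guess == "XY" else "M"
    mask = gm.sex_mask(hom_sex)
    idx = np.asarray(list(significant_sites))
    codes = gm.codes[idx][:, mask]
    called = (codes >= 0).sum(axis=0)
    het = (codes == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(called > 0, het / np.maximum(called, 1), 0.0)
    ids = gm.samples["id"].to_numpy()[mask]
    flagged = [str(i) for i, f in zip(ids, frac)
               if f > cfg.recombinant_het_threshold]
    reduced = gm.drop_samples(flagged)
    return flagged, genotype_profile(reduced, idx)


def classify_heterogamety(profile: SexGenotypeProfile,
                          cfg: ScanConfig) -> HeterogametyCall:
    """Call the sex system from pooled heterozygosity at significant sites.

    XY iff male het >= ``het_high`` and female het <= ``het_low``; ZW iff the
    mirror holds; otherwise UNDETERMINED.
    """
    m_het = profile.pooled["M"]["het"]
    f_het = profile.pooled["F"]["het"]
    evidence = {"male_het": m_het, "female_het": f_het,
                "het_high": cfg.het_high, "het_low": cfg.het_low}
    if np.isnan(m_het) or np.isnan(f_het):
        return HeterogametyCall("UNDETERMINED", evidence)
    if m_het >= cfg.het_high and f_het <= cfg.het_low:
        return HeterogametyCall("XY", evidence)
    if f_het >= cfg.het_high and m_het <= cfg.het_low:
        return HeterogametyCall("ZW", evidence)
    return HeterogametyCall("UNDETERMINED", evidence)


def depth_ratio_profile(depth: DepthTable, sexes: dict) -> pd.DataFrame:
    """Per-window sex-normalized depth ratios.

    For each window and sex, the mean over individuals of (window depth /
    that individual's genome-wide mean depth).  A diploid window sits near
    1.0; hemizygous sequence sits near 0.5 in carriers and near 0 otherwise.
    """
    gw = depth.genome_wide_mean()
    if (gw <= 0).any():
        bad = [s for s, g in zip(depth.sample_ids, gw) if g <= 0]
        raise ValueError(f"zero genome-wide depth for individuals: {bad}")
    norm = depth.values / gw[None, :]
    out = depth.windows.copy()
    for s in "MF":
        cols = np.array([sexes.get(i) == s for i in depth.sample_ids])
        out[f"{s}_ratio"] = norm[:, cols].mean(axis=1) if cols.any() else np.nan
    return out


# ---------------------------------------------------------------------------
# Delineation
# ---------------------------------------------------------------------------

def _cluster_positions(positions, gap: int, min_sites: int):
    """Group sorted positions into runs with inter-site gaps <= ``gap``."""
    clusters, current = [], []
    for p in positions:
        if current and p - current[-1] > gap:
            if len(current) >= min_sites:
                clusters.append(current)
            current = []
        current.append(p)
    if len(current) >= min_sites:
        clusters.append(current)
    return clusters


def delineate_regions(assocs, profile: SexGenotypeProfile, ratios: pd.DataFrame,
                      cfg: ScanConfig, system: str | None = None) -> list:
    """Cluster significant sites into intervals and label each one.

    Within a chromosome, significant sites are first split by site-level
    pattern — hemizygous-type (homogametic-sex missingness above
    ``missing_high``) versus SDR-type — and each class is gap-joined
    separately, so that a hemizygous Y-limited segment embedded in the SDR is
    delineated as its own interval.  Labels: X_SDR when the heterogametic sex
    is heterozygous and the homogametic sex diploid; Y_SPECIFIC when the
    homogametic sex is mostly uncalled, carriers sit at ~0.5 normalized depth
    and the homogametic sex at ~0 (mirror classes under ZW); anything else
    NOT_SEX_LINKED.
    """
    sig = [a for a in assocs if a.significant]
    if not sig:
        return []
    if system is None:
        system = classify_heterogamety(profile, cfg).system
    het_sex, hom_sex = ("M", "F") if system != "ZW" else ("F", "M")
    per_site = profile.per_site.set_index(["chrom", "pos"])

    def site_missing(a):
        try:
            return float(per_site.loc[(a.chrom, a.pos), f"{hom_sex}_missing"])
        except KeyError:
            return 0.0

    calls = []
    by_chrom: dict[str, list] = {}
    for a in sig:
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom in by_chrom:
        sites = sorted(by_chrom[chrom], key=lambda a: a.pos)
        hemi = [a for a in sites if site_missing(a) > cfg.missing_high]
        sdr = [a for a in sites if site_missing(a) <= cfg.missing_high]
        for group in (sdr, hemi):
            pos = [a.pos for a in group]
            lookup = {a.pos: a for a in group}
            for cluster in _cluster_positions(pos, cfg.cluster_gap_bp,
                                              cfg.min_cluster_sites):
                members = [lookup[p] for p in cluster]
                calls.append(
                    _label_interval(chrom, members, per_site, ratios, cfg,
                                    het_sex, hom_sex, system)
                )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def _label_interval(chrom, members, per_site, ratios, cfg, het_sex, hom_sex,
                    system) -> RegionCall:
    start = members[0].pos - 1
    end = members[-1].pos
    stats_rows = per_site.loc[[(chrom, a.pos) for a in members]]
    het_het = float(np.nanmean(stats_rows[f"{het_sex}_het"]))
    hom_het = float(np.nanmean(stats_rows[f"{hom_sex}_het"]))
    hom_missing = float(np.nanmean(stats_rows[f"{hom_sex}_missing"]))
    w = ratios[
        (ratios["chrom"] == chrom)
        & (ratios["end"] > start)
        & (ratios["start"] < end)
    ]
    het_ratio = float(np.nanmean(w[f"{het_sex}_ratio"])) if len(w) else np.nan
    hom_ratio = float(np.nanmean(w[f"{hom_sex}_ratio"])) if len(w) else np.nan
    evidence = {
        "het_sex_het": het_het, "hom_sex_het": hom_het,
        "hom_sex_missing": hom_missing,
        "het_sex_depth_ratio": het_ratio, "hom_sex_depth_ratio": hom_ratio,
    }
    lo = cfg.depth_ratio_target - cfg.depth_ratio_tol
    hi = cfg.depth_ratio_target + cfg.depth_ratio_tol
    label = "NOT_SEX_LINKED"
    if (
        hom_missing > cfg.missing_high
        and not np.isnan(het_ratio) and lo <= het_ratio <= hi
        and not np.isnan(hom_ratio) and hom_ratio <= cfg.depth_zero_max
    ):
        label = "Y_SPECIFIC" if system != "ZW" else "W_SPECIFIC"
    elif (
        het_het >= cfg.het_high
        and hom_het <= cfg.het_low
        and not np.isnan(hom_ratio)
        and abs(hom_ratio - 1.0) <= 2 * cfg.depth_ratio_tol
    ):
        label = "X_SDR" if system != "ZW" else "Z_SDR"
    return RegionCall(
        chrom=chrom, start=start, end=end, region_class=label,
        n_sites=len(members), best_p=min(a.p_value for a in members),
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def summarize_scan(assocs, calls) -> dict:
    """Report significant-site totals and the share falling in each interval.

    Percentages are rounded to two decimals (e.g. 92 of 113 -> 81.42).
    """
    sig = [a for a in assocs if a.significant]
    total = len(sig)
    report = {"n_tested": len(assocs), "n_significant": total, "intervals": []}
    if total == 0:
        return report
    for c in calls:
        inside = [
            a for a in sig
            if a.chrom == c.chrom and c.start < a.pos <= c.end
        ]
        report["intervals"].append(
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "region_class": c.region_class,
                "n_sites": len(inside),
                "pct_of_significant": round(100.0 * len(inside) / total, 2),
            }
        )
    return report


# ---------------------------------------------------------------------------
# Model-style front end
# ---------------------------------------------------------------------------

class SexLinkageScan:
    """Sex-linkage association scan over a genotyped, sexed cohort.

    Statsmodels-style front end: construct from data, call :meth:`fit`, read
    the :class:`ScanResults`.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    depth : DepthTable
    indel_positions : iterable of (chrom, pos), optional
    config : ScanConfig, optional
    """

    def __init__(self, genotypes: GenotypeMatrix, depth: DepthTable,
                 indel_positions=(), config: ScanConfig | None = None):
        self.genotypes = genotypes
        self.depth = depth
        self.indel_positions = list(indel_positions)
        self.config = config or ScanConfig()

    @classmethod
    def from_files(cls, vcf_path, sex_map_path, depth_path,
                   config: ScanConfig | None = None) -> "SexLinkageScan":
        from . import io
        sex_map = io.read_sex_map(sex_map_path)
        return cls(
            genotypes=io.read_vcf(vcf_path, sex_map),
            depth=io.read_depth_table(depth_path),
            config=config,
        )

    def fit(self) -> "ScanResults":
        cfg = self.config
        gm = filter_variants(self.genotypes, self.depth, self.indel_positions, cfg)
        assocs = associate_sex(gm)
        sig = bonferroni_significant(assocs, cfg.alpha)
        sexes = dict(zip(gm.samples["id"], gm.samples["sex"]))
        ratios = depth_ratio_profile(self.depth, sexes)
        if sig:
            sig_idx = [a.site_index for a in sig]
            prelim = genotype_profile(gm, sig_idx)
            guess = classify_heterogamety(prelim, cfg).system
            if guess == "UNDETERMINED":
                guess = "XY" if prelim.pooled["M"]["het"] >= (
                    prelim.pooled["F"]["het"] or 0) else "ZW"
            recombinants, profile = detect_recombinants(gm, sig_idx, guess, cfg)
            heterogamety = classify_heterogamety(profile, cfg)
            regions = delineate_regions(assocs, profile, ratios, cfg,
                                        system=heterogamety.system)
        else:
            recombinants, profile, heterogamety, regions = (
                [], None, HeterogametyCall("UNDETERMINED", {}), []
            )
        return ScanResults(
            model=self, filtered=gm, associations=assocs,
            heterogamety=heterogamety, recombinant_ids=recombinants,
            profile=profile, depth_ratios=ratios, regions=regions,
            report=summarize_scan(assocs, regions),
        )


@dataclass
class ScanResults:
    """Fitted results of a :class:`SexLinkageScan`."""

    model: SexLinkageScan
    filtered: GenotypeMatrix
    associations: list
    heterogamety: HeterogametyCall
    recombinant_ids: list
    profile: SexGenotypeProfile | None
    depth_ratios: pd.DataFrame
    regions: list
    report: dict

    @property
    def significant(self) -> list:
        return [a for a in self.associations if a.significant]

    def association_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [a.chrom for a in self.associations],
                "pos": [a.pos for a in self.associations],
                "p": [a.p_value for a in self.associations],
                "significant": [a.significant for a in self.associations],
            }
        )

    def summary(self) -> str:
        lines = [
            "Sex-linkage scan summary",
            "========================",
            f"sites tested:        {self.report['n_tested']}",
            f"significant (Bonf.): {self.report['n_significant']}",
            f"heterogamety:        {self.heterogamety.system}",
            f"recombinants:        {len(self.recombinant_ids)}"
            + (f" ({', '.join(self.recombinant_ids)})"
               if self.recombinant_ids else ""),
        ]
        if self.profile is not None:
            m = self.profile.pooled["M"]["het"]
            f = self.profile.pooled["F"]["het"]
            lines.append(
                f"pooled het at significant sites (recombinants excluded): "
                f"M={m:.3f} F={f:.3f}"
            )
        lines.append("regions:")
        for r in self.regions:
            lines.append(
                f"  {r.chrom}:{r.start}-{r.end}  {r.region_class}  "
                f"sites={r.n_sites}  best_p={r.best_p:.3g}"
            )
        for iv in self.report["intervals"]:
            lines.append(
                f"  {iv['chrom']}:{iv['start']}-{iv['end']} holds "
                f"{iv['n_sites']} significant sites "
                f"({iv['pct_of_significant']:.2f}% of all significant)"
            )
        return "\n".join(lines)
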