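"""Heterogametic-chromosome read identification.

Two complementary routes mirror how Y-limited sequence is recovered from a
sexed cohort: (1) canonical k-mers present in many males and absent from all
females select reads carrying male-specific sequence; (2) read-backed greedy
phasing of heterozygous sites splits reads into two haplotypes, and blocks
whose haplotype carries the male-associated allele at sex-associated sites
contribute their supporting reads.  The two bins are merged with provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        km = seq[i: i + k]
        if "N" not in km:
            yield canonical(km)


@dataclass
class KmerCatalog:
    """Canonical k-mer -> (male individual count, female individual count)."""

    k: int
    entries: dict = field(default_factory=dict)
    n_males: int = 0
    n_females: int = 0


@dataclass
class PhaseBlock:
    chrom: str
    positions: list  # ordered heterozygous site positions
    haplotypes: tuple  # two allele strings, one char per position
    reads: tuple  # (read ids supporting hap 0, read ids supporting hap 1)

    def __post_init__(self) -> None:
        if len(self.haplotypes[0]) != len(self.positions) or \
                len(self.haplotypes[1]) != len(self.positions):
            raise ValueError("haplotype strings must match the site count")


@dataclass
class YReadBin:
    """Selected read ids with per-read provenance (kmer / phase / both)."""

    provenance: dict = field(default_factory=dict)  # read_id -> label

    @property
    def read_ids(self) -> set:
        return set(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)


# ---------------------------------------------------------------------------
# k-mer route
# ---------------------------------------------------------------------------

def build_kmer_catalog(per_individual, sexes: dict, k: int = 30) -> KmerCatalog:
    """Count, per sex, how many individuals contain each canonical k-mer.

    ``per_individual`` maps individual id -> iterable of SequenceRecord (or
    plain strings).  An individual "contains" a k-mer when it occurs at least
    once in any of that individual's sequences; sequences shorter than k
    simply contribute nothing.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    entries: dict[str, list] = {}
    n = {"M": 0, "F": 0}
    for ind, seqs in per_individual.items():
        sex = sexes[ind]
        if sex not in n:
            continue
        n[sex] += 1
        seen = set()
        for rec in seqs:
            seq = getattr(rec, "residues", rec).upper()
            seen.update(_kmers(seq, k))
        col = 0 if sex == "M" else 1
        for km in seen:
            entry = entries.setdefault(km, [0, 0])
            entry[col] += 1
    return KmerCatalog(k=k, entries=entries, n_males=n["M"], n_females=n["F"])


def male_specific_kmers(cat: KmerCatalog, min_males: int = 20,
                        max_females: int = 0) -> set:
    """Select k-mers present in >= ``min_males`` males and in <=
    ``max_females`` females (default: strict absence from females)."""
    if min_males > cat.n_males:
        raise ValueError(
            f"min_males={min_males} exceeds the {cat.n_males} males in the catalog"
        )
    return {
        km for km, (m, f) in cat.entries.items()
        if m >= min_males and f <= max_females
    }


def bin_reads_by_kmers(reads, kmer_set: set, k: int,
                       provenance: str = "kmer") -> YReadBin:
    """Select every read sharing at least one canonical k-mer with the set."""
    bin_ = YReadBin()
    for rec in reads:
        seq = getattr(rec, "residues", rec).upper()
        rid = getattr(rec, "id", None) or seq
        for km in _kmers(seq, k):
            if km in kmer_set:
                bin_.provenance[rid] = provenance
                break
    return bin_


# ---------------------------------------------------------------------------
# phasing route
# ---------------------------------------------------------------------------

def greedy_phase(observations: pd.DataFrame, het_sites=None,
                 mismatch_tolerance: int = 1) -> tuple:
    """Greedy read-backed phasing of heterozygous sites into blocks.

    ``observations`` is a table with columns read_id, chrom, pos, allele —
    one allele per covered heterozygous site per read.  Sites connected by at
    least one read form a block (connected component).  Within a block, reads
    are two-coloured greedily in order of leftmost covered site: a read joins
    the haplotype it agrees with best; reads disagreeing with both colourings
    in more than ``mismatch_tolerance`` sites are dropped and reported.

    Returns ``(blocks, conflicting_read_ids)``.
    """
    if het_sites is not None:
        het = {(c, p) for c, p in het_sites}
        observations = observations[
            [(c, p) in het for c, p in
             zip(observations["chrom"], observations["pos"])]
        ]
    blocks, conflicts = [], []
    for chrom, chrom_obs in observations.groupby("chrom", sort=True):
        per_read: dict[str, dict] = {}
        for row in chrom_obs.itertuples(index=False):
            per_read.setdefault(row.read_id, {})[int(row.pos)] = str(row.allele)

        # union-find over sites
        parent: dict[int, int] = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for obs in per_read.values():
            for p in obs:
                parent.setdefault(p, p)
        for obs in per_read.values():
            ps = sorted(obs)
            for a, b in zip(ps, ps[1:]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
        components: dict[int, list] = {}
        for p in parent:
            components.setdefault(find(p), []).append(p)

        for root in sorted(components):
            sites = sorted(components[root])
            site_idx = {p: i for i, p in enumerate(sites)}
            # stable sort by leftmost covered site, preserving input order
            # among ties so early (well-supported) reads seed the colouring
            members = sorted(
                (rid for rid, obs in per_read.items()
                 if find(next(iter(obs))) == root),
                key=lambda rid: min(per_read[rid]),
            )
            # votes[i][hap] = {allele: weight}
            votes = [({}, {}) for _ in sites]
            assigned = ([], [])
            alleles_at: dict[int, set] = {p: set() for p in sites}
            for obs in per_read.values():
                for p, a in obs.items():
                    if p in alleles_at:
                        alleles_at[p].add(a)

            def consensus(hap):
                out = []
                for i in range(len(sites)):
                    v = votes[i][hap]
                    if v:
                        out.append(max(sorted(v), key=lambda a: v[a]))
                    else:
                        out.append(None)
                return out

            for rid in members:
                obs = per_read[rid]
                scores = []
                for hap in (0, 1):
                    cons = consensus(hap)
                    agree = disagree = 0
                    for p, a in obs.items():
                        c = cons[site_idx[p]]
                        if c is None:
                            continue
                        if c == a:
                            agree += 1
                        else:
                            disagree += 1
                    scores.append((agree, disagree))
                defined = [s for s in scores if s[0] + s[1] > 0]
                if not defined:
                    hap = 0  # first read seeds haplotype 0
                else:
                    # pick the haplotype with more agreements, ties to 0
                    hap = 0 if scores[0][0] - scores[0][1] >= \
                        scores[1][0] - scores[1][1] else 1
                    if scores[hap][1] > mismatch_tolerance:
                        conflicts.append(rid)
                        continue
                assigned[hap].append(rid)
                for p, a in obs.items():
                    i = site_idx[p]
                    votes[i][hap][a] = votes[i][hap].get(a, 0) + 1
                    # the complementary haplotype carries the other allele
                    other = alleles_at[p] - {a}
                    if len(other) == 1:
                        oa = next(iter(other))
                        votes[i][1 - hap].setdefault(oa, 0)

            hap_strings = []
            for hap in (0, 1):
                cons = consensus(hap)
                chars = []
                for i, c in enumerate(cons):
                    if c is None:
                        other = consensus(1 - hap)[i]
                        alt = alleles_at[sites[i]] - {other}
                        if alt:
                            c = sorted(alt)[0]
                        elif other is not None:
                            c = other  # single observed allele at the site
                        else:
                            c = "N"
                    chars.append(c)
                hap_strings.append("".join(chars))
            blocks.append(
                PhaseBlock(
                    chrom=chrom, positions=sites,
                    haplotypes=(hap_strings[0], hap_strings[1]),
                    reads=(tuple(assigned[0]), tuple(assigned[1])),
                )
            )
    return blocks, conflicts


def assign_y_blocks(blocks, male_allele: dict, significant_positions=None,
                    provenance: str = "phase") -> tuple:
    """Label each block's Y haplotype by majority male-associated allele.

    ``male_allele`` maps (chrom, pos) or pos -> the allele associated with the
    heterogametic sex at that significant site.  Within each block overlapping
    at least one such site, the haplotype carrying the male-associated allele
    at the majority of those sites is labelled Y and its supporting reads are
    returned.  Ties are ambiguous: the block is excluded and reported.

    Returns ``(YReadBin, ambiguous_blocks)``.
    """

    def lookup(chrom, pos):
        if (chrom, pos) in male_allele:
            return male_allele[(chrom, pos)]
        return male_allele.get(pos)

    bin_ = YReadBin()
    ambiguous = []
    for block in blocks:
        scores = [0, 0]
        n_overlap = 0
        for i, pos in enumerate(block.positions):
            if significant_positions is not None and \
                    (block.chrom, pos) not in significant_positions and \
                    pos not in significant_positions:
                continue
            ma = lookup(block.chrom, pos)
            if ma is None:
                continue
            n_overlap += 1
            for hap in (0, 1):
                if block.haplotypes[hap][i] == ma:
                    scores[hap] += 1
        if n_overlap == 0:
            continue
        if scores[0] == scores[1]:
            ambiguous.append(block)
            continue
        y_hap = 0 if scores[0] > scores[1] else 1
        for rid in block.reads[y_hap]:
            bin_.provenance[rid] = provenance
    return bin_, ambiguous


def merge_read_bins(bins) -> YReadBin:
    """Deduplicating union; reads found by several routes are marked both."""
    merged = YReadBin()
    for b in bins:
        for rid, label in b.provenance.items():
            if rid in merged.provenance and merged.provenance[rid] != label:
                merged.provenance[rid] = "both"
            else:
                merged.provenance[rid] = label
    return merged


def write_kmer_set(kmer_set: set, path) -> None:
    with open(path, "w") as fh:
        for km in sorted(kmer_set):
            fh.write(km + "\n")


def read_observation_table(path) -> pd.DataFrame:
    """Read the TSV of read-to-site allele observations
    (read_id, chrom, pos, allele)."""
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"read_id": str, "chrom": str, "allele": str})
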