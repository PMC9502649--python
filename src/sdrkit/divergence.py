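"""Gametolog divergence, LTR dating and SDR gene classification.

Ka/Ks follows Nei & Gojobori's pathway-counting method: fractional synonymous
site counts per codon under the standard genetic code, differences averaged
over all orderings of single-nucleotide steps (paths through stop codons
excluded), and a Jukes-Cantor correction ``d = -3/4 ln(1 - 4p/3)``.  Stop
codons are excluded from both mutational pathways and site counts.  LTR arm
divergence is corrected for saturation with Kimura's two-parameter distance
and converted to an insertion age as ``K / (2 mu)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Data import CodonTable

BASES = "ACGT"
_table = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, with '*' for stops
CODON_AA = dict(_table.forward_table)
CODON_AA.update({c: "*" for c in _table.stop_codons})
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _residues(x) -> str:
    return getattr(x, "residues", x).upper()


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedPair:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")


def _make_aligner(match=1.0, mismatch=-1.0, gap=-1.0,
                  substitution_matrix=None, end_gap_free_target=False):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if substitution_matrix is not None:
        aligner.substitution_matrix = substitution_matrix
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    if end_gap_free_target:
        aligner.target_end_gap_score = 0.0
    return aligner


def global_align(a, b, match: float = 1.0, mismatch: float = -1.0,
                 gap: float = -1.0, substitution_matrix=None,
                 end_gap_free_target: bool = False) -> AlignedPair:
    """Optimal global alignment under linear gap scoring.

    ``a`` is the target, ``b`` the query; identity is matches over aligned
    non-gap columns and coverage is the fraction of the query aligned to a
    non-gap target position.
    """
    sa, sb = _residues(a), _residues(b)
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(match, mismatch, gap, substitution_matrix,
                            end_gap_free_target)
    aln = aligner.align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    aligned_cols = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-")
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return AlignedPair(
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
        identity=matches / aligned_cols if aligned_cols else 0.0,
        coverage=aligned_cols / len(sb),
    )


def reciprocal_best_hits(set_a, set_b, min_score: float = 0.0,
                         **align_kwargs) -> dict:
    """Reciprocal best hits between two sequence sets by alignment score.

    A pair (a, b) is reported iff b is a's best-scoring hit and a is b's,
    with both scores >= ``min_score``.  Score ties are broken by
    lexicographic id.  Returns ``{a_id: b_id}``.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    scores = {}
    for ra in set_a:
        for rb in set_b:
            scores[(ra.id, rb.id)] = global_align(ra, rb, **align_kwargs).score

    def best(ids_from, ids_to, forward: bool):
        out = {}
        for i in ids_from:
            candidates = sorted(
                ids_to,
                key=lambda j: (-(scores[(i, j)] if forward else scores[(j, i)]), j),
            )
            top = candidates[0]
            sc = scores[(i, top)] if forward else scores[(top, i)]
            if sc >= min_score:
                out[i] = top
        return out

    a_ids = sorted(r.id for r in set_a)
    b_ids = sorted(r.id for r in set_b)
    best_a = best(a_ids, b_ids, True)
    best_b = best(b_ids, a_ids, False)
    return {
        a: b for a, b in best_a.items() if best_b.get(b) == a
    }


def codon_align(cds_a, cds_b, gap: float = -11.0) -> tuple:
    """Codon-aware alignment: align translated proteins, thread codons back.

    Gap-containing codon columns are dropped.  Returns the two codon-aligned
    (gap-free, equal-length, length % 3 == 0) nucleotide strings.
    """
    from Bio.Align import substitution_matrices

    sa, sb = _residues(cds_a), _residues(cds_b)
    if len(sa) % 3 or len(sb) % 3:
        raise ValueError("CDS lengths must be divisible by 3")
    pa = "".join(CODON_AA.get(sa[i: i + 3], "X") for i in range(0, len(sa), 3))
    pb = "".join(CODON_AA.get(sb[i: i + 3], "X") for i in range(0, len(sb), 3))
    pa = pa.replace("*", "X")
    pb = pb.replace("*", "X")
    blosum = substitution_matrices.load("BLOSUM62")
    pair = global_align(pa, pb, substitution_matrix=blosum, gap=gap)
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(pair.aligned_a, pair.aligned_b):
        if ca != "-" and cb != "-":
            out_a.append(sa[3 * ia: 3 * ia + 3])
            out_b.append(sb[3 * ib: 3 * ib + 3])
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class GametologPair:
    x_id: str
    y_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    Ks: float | None
    Ka: float | None
    saturated: bool = False
    n_codons: int = 0

    @property
    def ka_ks(self) -> float | None:
        if self.Ka is None or self.Ks is None or self.Ks == 0:
            return None
        return self.Ka / self.Ks


def _codon_sites(codon: str) -> tuple:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each position contributes syn/3 and nonsyn/3 over its three possible
    substitutions; substitutions creating stop codons count as neither.
    """
    aa = CODON_AA[codon]
    s = n = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            mut_aa = CODON_AA[mut]
            if mut_aa == "*":
                continue
            if mut_aa == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


def _pathway_differences(c1: str, c2: str) -> tuple:
    """Pathway-averaged (synonymous, nonsynonymous) differences of a codon
    pair, averaging over all orderings of single-base steps and skipping
    paths that pass through a stop codon."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        syn = non = 0.0
        cur = c1
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if CODON_AA[nxt] == "*":
                return None
            if CODON_AA[nxt] == CODON_AA[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non

    results = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    if not valid:
        # all paths pass through stops; fall back to counting stop steps as
        # nonsynonymous so the codon still contributes its differences
        valid = []
        for order in itertools.permutations(diff_pos):
            syn = non = 0.0
            cur = c1
            for i in order:
                nxt = cur[:i] + c2[i] + cur[i + 1:]
                if CODON_AA[nxt] == CODON_AA[cur]:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            valid.append((syn, non))
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance ``-(3/4) ln(1 - 4p/3)``; None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_ka_ks(cds_x, cds_y, x_id: str | None = None,
               y_id: str | None = None) -> GametologPair:
    """NG86 Ka/Ks for a codon-aligned CDS pair.

    Input strings must have equal length divisible by three; codons with
    gaps, ambiguous bases or stops are excluded.
    """
    sx, sy = _residues(cds_x), _residues(cds_y)
    if len(sx) != len(sy):
        raise ValueError("aligned CDS lengths differ")
    if len(sx) % 3:
        raise ValueError("aligned length must be divisible by 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(sx), 3):
        cx, cy = sx[i: i + 3], sy[i: i + 3]
        if any(b not in BASES for b in cx + cy):
            continue
        if CODON_AA[cx] == "*" or CODON_AA[cy] == "*":
            continue
        sx_sites, nx_sites = _codon_sites(cx)
        sy_sites, ny_sites = _codon_sites(cy)
        S += (sx_sites + sy_sites) / 2.0
        N += (nx_sites + ny_sites) / 2.0
        sd, nd = _pathway_differences(cx, cy)
        Sd += sd
        Nd += nd
        n_codons += 1
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS) if S > 0 else None
    Ka = jukes_cantor(pN) if N > 0 else None
    return GametologPair(
        x_id=x_id or getattr(cds_x, "id", "x"),
        y_id=y_id or getattr(cds_y, "id", "y"),
        S=S, N=N, Sd=Sd, Nd=Nd, Ks=Ks, Ka=Ka,
        saturated=(S > 0 and Ks is None) or (N > 0 and Ka is None),
        n_codons=n_codons,
    )


# ---------------------------------------------------------------------------
# Strata
# ---------------------------------------------------------------------------

@dataclass
class StrataResult:
    pairs: list  # ordered (x_position, Ks)
    statistic: float
    p_value: float
    breakpoints: list


def strata_test(pairs, n_perm: int = 10_000, seed: int = 0,
                min_segment: int = 4) -> StrataResult:
    """Permutation test for evolutionary strata along the X.

    Statistic: the maximum, over candidate breakpoints leaving at least
    ``min_segment`` points on each side, of the absolute difference in mean
    Ks between the left and right segments.  The null permutes Ks values over
    positions.  Breakpoints are reported only when p < 0.05.
    """
    pairs = sorted(pairs)
    if len(pairs) < 2 * min_segment:
        raise ValueError(
            f"need at least {2 * min_segment} pairs, got {len(pairs)}"
        )
    ks = np.array([k for _, k in pairs], dtype=float)
    positions = [p for p, _ in pairs]

    def stat_and_break(values):
        best, best_i = -1.0, None
        csum = np.cumsum(values)
        total = csum[-1]
        n = len(values)
        for i in range(min_segment, n - min_segment + 1):
            left = csum[i - 1] / i
            right = (total - csum[i - 1]) / (n - i)
            d = abs(left - right)
            if d > best:
                best, best_i = d, i
        return best, best_i

    obs, obs_i = stat_and_break(ks)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm, _ = stat_and_break(rng.permutation(ks))
        if perm >= obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    breakpoints = []
    if p < 0.05 and obs_i is not None:
        breakpoints = [positions[obs_i]]
    return StrataResult(pairs=pairs, statistic=float(obs), p_value=float(p),
                        breakpoints=breakpoints)


# ---------------------------------------------------------------------------
# Kimura two-parameter distance and LTR dating
# ---------------------------------------------------------------------------

@dataclass
class LTRElement:
    element_id: str
    P: float
    Q: float
    K: float | None
    age_years: float | None
    saturated: bool = False


def kimura2p(arm_a, arm_b) -> tuple:
    """Kimura two-parameter distance of two equal-length aligned arms.

    Returns ``(P, Q, K)`` with P and Q the transition and transversion
    difference proportions and
    ``K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)``; K is None when saturated.
    Sites with non-ACGT characters are excluded; gap columns must have been
    stripped beforehand.
    """
    sa, sb = _residues(arm_a), _residues(arm_b)
    if len(sa) != len(sb):
        raise ValueError("arms must be equal length (pre-aligned)")
    n = ts = tv = 0
    for x, y in zip(sa, sb):
        if x not in BASES or y not in BASES:
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return P, Q, None
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return P, Q, K


def ltr_insertion_age(K: float, mu: float) -> float:
    """Insertion age in years from arm divergence: ``age = K / (2 mu)``."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if K < 0:
        raise ValueError("K must be non-negative")
    return K / (2.0 * mu)


def date_ltr_elements(elements, mu: float) -> list:
    """Date a list of ``(element_id, arm5, arm3[, ...])`` tuples."""
    out = []
    for elem in elements:
        eid, arm5, arm3 = elem[0], elem[1], elem[2]
        P, Q, K = kimura2p(arm5, arm3)
        out.append(
            LTRElement(
                element_id=eid, P=P, Q=Q, K=K,
                age_years=None if K is None else ltr_insertion_age(K, mu),
                saturated=K is None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tandems, pseudogenes and gene classification
# ---------------------------------------------------------------------------

def tandem_duplicates(genes, min_score: float, window: int = 500_000,
                      **align_kwargs) -> list:
    """Pairs of genes on one coordinate system that align above
    ``min_score`` and start within ``window`` bp of each other.

    ``genes`` is a list of (SequenceRecord, start_position).  Self-pairs are
    excluded; each unordered pair is reported once.
    """
    out = []
    for (ra, pa), (rb, pb) in itertools.combinations(genes, 2):
        if abs(pa - pb) > window:
            continue
        if global_align(ra, rb, **align_kwargs).score >= min_score:
            out.append((ra.id, rb.id))
    return out


@dataclass
class PseudogeneCall:
    candidate_id: str
    parent_id: str
    identity: float
    coverage: float
    disruptions: list  # e.g. ["premature_stop", "frameshift"]


def call_pseudogene(candidate, parent_cds, min_identity: float = 0.70,
                    min_coverage: float = 0.50) -> PseudogeneCall | None:
    """Call a degraded gene copy: homology above the identity and coverage
    thresholds plus at least one reading-frame disruption (premature stop or
    frameshift-inducing indel) in the threaded frame.

    Returns None for candidates below threshold or for intact copies.
    """
    cand = _residues(candidate)
    parent = _residues(parent_cds)
    # gaps strictly worse than mismatches: stops the aligner from gapping
    # around substitutions and inflating per-column identity
    pair = global_align(parent, cand, match=1.0, mismatch=-1.0, gap=-2.0)
    if pair.identity <= min_identity or pair.coverage < min_coverage:
        return None

    disruptions = []
    ga, gb = pair.aligned_a, pair.aligned_b  # parent, candidate
    first = next((i for i, (x, y) in enumerate(zip(ga, gb))
                  if x != "-" and y != "-"), None)
    last = max(i for i, (x, y) in enumerate(zip(ga, gb))
               if x != "-" and y != "-")
    # frameshift: any internal indel run whose length is not a multiple of 3
    run_char, run_len = None, 0
    for i in range(first, last + 1):
        gap_in = "a" if ga[i] == "-" else ("b" if gb[i] == "-" else None)
        if gap_in == run_char:
            run_len += 1
            continue
        if run_char is not None and run_len % 3 != 0:
            disruptions.append("frameshift")
        run_char, run_len = gap_in, (1 if gap_in else 0)
    if run_char is not None and run_len % 3 != 0:
        disruptions.append("frameshift")

    # premature stop: thread candidate bases over parent coordinates and
    # translate in the parent frame (head-padded with parent bases)
    parent_pos = 0
    threaded = []
    head_pad = None
    for i in range(len(ga)):
        if ga[i] != "-":
            if first <= i <= last:
                if head_pad is None:
                    off = parent_pos % 3
                    head_pad = parent[parent_pos - off: parent_pos]
                    threaded.append(head_pad)
                threaded.append(gb[i] if gb[i] != "-" else "")
            parent_pos += 1
    cds = "".join(threaded)
    cds = cds[: len(cds) - len(cds) % 3]
    n_codons = len(cds) // 3
    for ci in range(n_codons - 1):
        codon = cds[3 * ci: 3 * ci + 3]
        if CODON_AA.get(codon) == "*":
            disruptions.append("premature_stop")
            break
    if not disruptions:
        return None
    return PseudogeneCall(
        candidate_id=getattr(candidate, "id", "candidate"),
        parent_id=getattr(parent_cds, "id", "parent"),
        identity=pair.identity, coverage=pair.coverage,
        disruptions=sorted(set(disruptions)),
    )


@dataclass
class GeneClassification:
    gene_id: str
    haplotype: str  # X or Y
    labels: set
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "LOST" in self.labels and "SPECIFIC" in self.labels:
            raise ValueError("LOST and SPECIFIC are mutually exclusive")
        if not self.labels:
            raise ValueError("classification produced an empty label set")


def classify_sdr_genes(x_genes, y_genes, autosomal_genes=(), outgroup_genes=(),
                       pseudogene_calls: dict | None = None,
                       tandem_pairs=(), min_score: float = 0.0,
                       **align_kwargs) -> list:
    """Classify SDR genes as shared / ancestral / transposed / lost /
    specific (plus tandem), following reciprocal-best-hit logic.

    Labels per gene (they may combine): X_Y_SHARED when an RBH partner exists
    on the other haplotype; ANCESTRAL when the gene hits the corresponding
    outgroup region above ``min_score``; AUTOSOMAL_TRANSPOSITION when there
    is no outgroup-region hit but a mutual best hit to an autosomal gene;
    LOST when a gene has no X-Y homolog but a pseudogene relic and/or an
    ANCESTRAL homolog exists; SPECIFIC otherwise.  ``pseudogene_calls`` maps
    gene id -> PseudogeneCall (relic on the opposite haplotype).
    """
    pseudogene_calls = pseudogene_calls or {}
    ids_seen: dict[str, str] = {}
    for name, group in (("x", x_genes), ("y", y_genes),
                        ("autosomal", autosomal_genes),
                        ("outgroup", outgroup_genes)):
        for rec in group:
            if rec.id in ids_seen:
                raise ValueError(
                    f"gene {rec.id} present in both {ids_seen[rec.id]} "
                    f"and {name} sets"
                )
            ids_seen[rec.id] = name

    shared = {}
    if x_genes and y_genes:
        rbh = reciprocal_best_hits(x_genes, y_genes, min_score=min_score,
                                   **align_kwargs)
        shared.update(rbh)
        shared.update({b: a for a, b in rbh.items()})

    def best_score(rec, pool):
        if not pool:
            return -math.inf
        return max(global_align(rec, other, **align_kwargs).score
                   for other in pool)

    aut_rbh = {}
    for hap_genes in (x_genes, y_genes):
        if hap_genes and autosomal_genes:
            rbh = reciprocal_best_hits(hap_genes, autosomal_genes,
                                       min_score=min_score, **align_kwargs)
            aut_rbh.update(rbh)

    out = []
    for hap, genes in (("X", x_genes), ("Y", y_genes)):
        for rec in sorted(genes, key=lambda r: r.id):
            labels, evidence = set(), {}
            if rec.id in shared:
                labels.add("X_Y_SHARED")
                evidence["partner"] = shared[rec.id]
            ancestral = best_score(rec, outgroup_genes) >= min_score \
                if outgroup_genes else False
            if ancestral:
                labels.add("ANCESTRAL")
            elif rec.id in aut_rbh:
                labels.add("AUTOSOMAL_TRANSPOSITION")
                evidence["autosomal_hit"] = aut_rbh[rec.id]
            if "X_Y_SHARED" not in labels:
                pseudo = pseudogene_calls.get(rec.id)
                if pseudo is not None or ancestral:
                    # loss is recorded on the haplotype that carries only a
                    # relic (or nothing) of this gene
                    labels.add("LOST")
                    evidence["lost_haplotype"] = "Y" if hap == "X" else "X"
                    if pseudo is not None:
                        evidence["pseudogene"] = pseudo.candidate_id
                else:
                    labels.add("SPECIFIC")
            if any(rec.id in pair for pair in tandem_pairs):
                labels.add("TANDEM")
            out.append(
                GeneClassification(gene_id=rec.id, haplotype=hap,
                                   labels=labels, evidence=evidence)
            )
    return out
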