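"""Readers, writers and containers for the standard formats the pipeline touches.

Coordinate conventions: VCF and GFF3 positions are 1-based inclusive on disk
(per their standards); everything held in memory and everything written to BED
or the depth table is 0-based half-open.  A VCF position ``pos`` maps to the
internal interval ``[pos - 1, pos)``.
"""

from __future__ import annotations

import gzip
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1  # genotype code for uncalled / half-called sites

VALID_SEXES = {"M", "F", "U"}


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    residues: str
    alphabet: str = "nucleotide"  # or "protein"

    def __post_init__(self) -> None:
        allowed = set("ACGTN-") if self.alphabet == "nucleotide" else set(
            "ACDEFGHIKLMNPQRSTVWYX*-"
        )
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: residues {sorted(bad)} outside "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GenotypeMatrix:
    """Sites x individuals genotype codes with site metadata and sex labels.

    ``sites`` has columns chrom, pos (1-based), ref, alt (comma-joined string
    for multi-allelic sites), qual.  ``samples`` has columns id, sex with sex
    in {M, F, U}.  ``codes`` holds 0 hom-ref, 1 het, 2 hom-alt, -1 missing.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        bad_sex = set(self.samples["sex"]) - VALID_SEXES
        if bad_sex:
            raise ValueError(f"invalid sex labels: {sorted(bad_sex)}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sex_mask(self, sex: str) -> np.ndarray:
        return (self.samples["sex"] == sex).to_numpy()

    def take_sites(self, idx) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given site indices."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=self.samples.copy(),
            codes=self.codes[idx].copy(),
        )

    def drop_samples(self, ids) -> "GenotypeMatrix":
        keep = ~self.samples["id"].isin(set(ids)).to_numpy()
        return GenotypeMatrix(
            sites=self.sites.copy(),
            samples=self.samples[keep].reset_index(drop=True),
            codes=self.codes[:, keep].copy(),
        )


@dataclass
class DepthTable:
    """Per-window mean read depth for every individual.

    Windows are 0-based half-open and must not overlap within a chromosome.
    """

    windows: pd.DataFrame  # columns: chrom, start, end
    values: np.ndarray  # windows x individuals, reads per bp
    sample_ids: list

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.windows), len(self.sample_ids)):
            raise ValueError("values shape does not match windows x samples")
        if (self.values < 0).any():
            raise ValueError("negative depth values")
        for chrom, grp in self.windows.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["end"].to_numpy()[:-1] > g["start"].to_numpy()[1:]).any():
                raise ValueError(f"overlapping windows on {chrom}")

    def genome_wide_mean(self) -> np.ndarray:
        """Length-weighted genome-wide mean depth per individual."""
        w = (self.windows["end"] - self.windows["start"]).to_numpy(float)
        return (self.values * w[:, None]).sum(axis=0) / w.sum()

    def window_of(self, chrom: str, pos1: int) -> int:
        """Index of the window containing 1-based position ``pos1``.

        Raises ``KeyError`` when no window covers the site.
        """
        p0 = pos1 - 1
        hit = (
            (self.windows["chrom"] == chrom)
            & (self.windows["start"] <= p0)
            & (self.windows["end"] > p0)
        )
        idx = np.flatnonzero(hit.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"no depth window covers {chrom}:{pos1}")
        return int(idx[0])


@dataclass
class GeneModel:
    """A protein-coding gene model: ordered CDS segments on one strand.

    Segments are 0-based half-open genome intervals listed in transcription
    (5'->3') order, i.e. reverse genome order for minus-strand genes.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list  # [(start, end), ...] transcription order
    frames: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        total = sum(e - s for s, e in self.cds_segments)
        if total % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {total} not divisible by 3")
        genome_order = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(genome_order, genome_order[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
        if not self.frames:
            self.frames = [0] * len(self.cds_segments)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def cds_sequence(self, genome: dict) -> str:
        """Spliced CDS in reading orientation given ``{chrom: sequence}``."""
        chrom_seq = genome[self.chrom]
        parts = [chrom_seq[s:e] for s, e in self.cds_segments]
        if self.strand == "-":
            parts = [str(Seq(p).reverse_complement()) for p in parts]
        return "".join(parts)

    def cds_offset(self, pos1: int) -> int | None:
        """Map a 1-based genomic position to its 0-based offset in the CDS.

        Returns ``None`` when the position is not inside any CDS segment.
        """
        p0 = pos1 - 1
        off = 0
        segments = self.cds_segments
        if self.strand == "+":
            for s, e in sorted(segments):
                if s <= p0 < e:
                    return off + (p0 - s)
                off += e - s
        else:
            for s, e in sorted(segments, reverse=True):
                if s <= p0 < e:
                    return off + (e - 1 - p0)
                off += e - s
        return None


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_sex_map(path) -> dict:
    """Read a two-column TSV of individual id -> sex (M/F/U)."""
    out = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            ind, sex = line.split()[:2]
            sex = sex.upper()
            if sex not in VALID_SEXES:
                raise ValueError(f"sex map: invalid sex {sex!r} for {ind}")
            out[ind] = sex
    return out


def read_vcf(path, sex_map: dict) -> GenotypeMatrix:
    """Load diploid genotypes from a VCF 4.x file into a GenotypeMatrix.

    Half calls and ``./.`` map to the missing code; phased separators are
    accepted and treated as unphased.  Samples absent from ``sex_map`` are
    labelled ``U`` (unknown).  Multi-allelic sites are preserved with all alt
    alleles so the downstream filter can drop them.
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vf.header.samples)
    samples = pd.DataFrame(
        {"id": sample_ids, "sex": [sex_map.get(s, "U") for s in sample_ids]}
    )
    rows, code_rows = [], []
    for lineno, rec in enumerate(vf, start=1):
        alts = rec.alts or ()
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": ",".join(alts),
                "qual": float("nan") if rec.qual is None else float(rec.qual),
            }
        )
        codes = np.empty(len(sample_ids), dtype=np.int8)
        for j, sid in enumerate(sample_ids):
            gt = rec.samples[sid].get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                codes[j] = MISSING
            elif gt[0] == gt[1]:
                codes[j] = 0 if gt[0] == 0 else 2
            else:
                codes[j] = 1
        code_rows.append(codes)
    vf.close()
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    codes = (
        np.vstack(code_rows) if code_rows else np.empty((0, len(sample_ids)), np.int8)
    )
    return GenotypeMatrix(sites=sites, samples=samples, codes=codes)


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict | None = None,
              header_extra: list | None = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 file."""
    chroms = list(dict.fromkeys(gm.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sdrkit\n")
        for extra in header_extra or []:
            fh.write(f"##{extra}\n")
        for c in chroms:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples["id"])
            + "\n"
        )
        for i, site in enumerate(gm.sites.itertuples(index=False)):
            qual = "." if math.isnan(site.qual) else f"{site.qual:g}"
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in gm.codes[i])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt or '.'}\t"
                f"{qual}\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Depth tables
# ---------------------------------------------------------------------------

def write_depth_table(dt: DepthTable, path, header_extra: list | None = None) -> None:
    """Write the long-format depth TSV (chrom, window_start, window_end,
    individual, mean_depth)."""
    with open(path, "w") as fh:
        for extra in header_extra or []:
            fh.write(f"# {extra}\n")
        fh.write("chrom\twindow_start\twindow_end\tindividual\tmean_depth\n")
        for i, w in enumerate(dt.windows.itertuples(index=False)):
            for j, sid in enumerate(dt.sample_ids):
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{sid}\t{dt.values[i, j]:g}\n")


def read_depth_table(path) -> DepthTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    wide = df.pivot_table(
        index=["chrom", "window_start", "window_end"],
        columns="individual",
        values="mean_depth",
        sort=False,
    )
    windows = wide.index.to_frame(index=False)
    windows.columns = ["chrom", "start", "end"]
    return DepthTable(
        windows=windows,
        values=wide.to_numpy(float),
        sample_ids=list(wide.columns),
    )


# ---------------------------------------------------------------------------
# Region calls (BED6)
# ---------------------------------------------------------------------------

def write_region_calls(calls, path, header_extra: list | None = None) -> None:
    """Write region calls as BED6: name = region class, score = capped
    -log10 of the best supporting site p-value.

    Calls must be sorted by (chrom, start); unsorted input is an error.
    """
    keys = [(c.chrom, c.start) for c in calls]
    if keys != sorted(keys):
        raise ValueError("region calls must be sorted by (chrom, start)")
    with open(path, "w") as fh:
        fh.write("# sdrkit region calls (BED6: class in name, score=-log10 best p)\n")
        for extra in header_extra or []:
            fh.write(f"# {extra}\n")
        for c in calls:
            best_p = getattr(c, "best_p", None)
            if best_p is None or best_p <= 0:
                score = 1000
            else:
                score = min(1000, int(round(-math.log10(best_p))))
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.region_class}\t{score}\t.\n"
            )


def read_region_calls(path) -> list:
    """Round-trip reader for :func:`write_region_calls` output.

    Returns a list of (chrom, start, end, region_class, score) tuples.
    """
    out = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, score, _strand = line.split("\t")
            out.append((chrom, int(start), int(end), name, int(score)))
    return out


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: str = "nucleotide") -> list:
    with _open_text(path) as fh:
        return [
            SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), alphabet=alphabet)
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_fasta(records, path) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_gff3(path) -> list:
    """Parse GFF3 gene models (CDS features grouped by Parent/ID) into
    :class:`GeneModel` objects."""
    import gffutils

    with _open_text(path) as fh:
        text = fh.read()
    db = gffutils.create_db(
        text, ":memory:", from_string=True, force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    models = []
    by_gene: dict[str, list] = {}
    strands: dict[str, tuple] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [cds.id])[0]
        by_gene.setdefault(parent, []).append(
            (cds.start - 1, cds.end, int(cds.frame) if cds.frame != "." else 0)
        )
        strands[parent] = (cds.seqid, cds.strand)
    for gid in sorted(by_gene):
        chrom, strand = strands[gid]
        segs = sorted(by_gene[gid])
        if strand == "-":
            segs = segs[::-1]
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                cds_segments=[(s, e) for s, e, _ in segs],
                frames=[f for _, _, f in segs],
            )
        )
    return models


def write_gff3(models, path, header_extra: list | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for extra in header_extra or []:
            fh.write(f"# {extra}\n")
        for m in models:
            genome_order = sorted(m.cds_segments)
            gstart = genome_order[0][0] + 1
            gend = genome_order[-1][1]
            fh.write(
                f"{m.chrom}\tsdrkit\tgene\t{gstart}\t{gend}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tsdrkit\tmRNA\t{gstart}\t{gend}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            frames = m.frames or [0] * len(m.cds_segments)
            for (s, e), frame in zip(m.cds_segments, frames):
                fh.write(
                    f"{m.chrom}\tsdrkit\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{frame}\t"
                    f"ID={m.gene_id}.t1;Parent={m.gene_id}.t1\n"
                )


# ---------------------------------------------------------------------------
# Assembly QC
# ---------------------------------------------------------------------------

def qv_to_accuracy(qv: float) -> float:
    """Convert a Phred-scaled consensus quality value to percent accuracy.

    ``accuracy = 100 * (1 - 10**(-qv/10))``; rounding is left to presentation.
    """
    if qv < 0:
        raise ValueError(f"QV must be non-negative, got {qv}")
    return 100.0 * (1.0 - 10.0 ** (-qv / 10.0))
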