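"""Readers, writers, and in-memory containers for the standard formats.

Conventions are strict and localized here: variant positions are 1-based
(VCF convention); intervals are 0-based half-open (BED convention); the
single conversion between the two lives in :func:`position_in_interval`.
JASPAR-style count matrices list rows in A, C, G, T order. Expression
tables are features x samples TSV with ``#key=value`` metadata comments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


TRANSFORMS = ("raw", "log2", "rank")


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant; ``pos`` is 1-based."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    risk_is_alt: bool = True

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id}: ref == alt")

    @property
    def risk_allele(self) -> str:
        return self.alt if self.risk_is_alt else self.ref


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes: rows are haplotypes, columns variants.

    Entry 1 means the haplotype carries the ALT allele. Haplotypes ``2i``
    and ``2i + 1`` belong to sample ``i``.
    """

    variants: list[VariantRecord]
    haplotypes: np.ndarray  # (2n, m) int8

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-dimensional")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("haplotype columns must match variant count")
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype rows must pair into diploid samples")

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0] // 2

    def variant_index(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.id == variant_id:
                return i
        raise KeyError(variant_id)

    def dosage(self) -> pd.DataFrame:
        """Risk-allele dosage per sample, derived from the phased alleles."""
        alt_dosage = (self.haplotypes[0::2] + self.haplotypes[1::2]).T.astype(float)
        for i, v in enumerate(self.variants):
            if not v.risk_is_alt:
                alt_dosage[i] = 2 - alt_dosage[i]
        samples = [f"S{i:04d}" for i in range(self.n_samples)]
        return pd.DataFrame(alt_dosage, index=[v.id for v in self.variants],
                            columns=samples)


@dataclass
class GenotypeData:
    """Dosage matrix (variants x samples, risk-allele count, NaN = missing)
    plus the phased panel when the source carried phase marks."""

    variants: list[VariantRecord]
    dosage: pd.DataFrame
    panel: HaplotypePanel | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.dosage.columns)

    def variant(self, variant_id: str) -> VariantRecord:
        for v in self.variants:
            if v.id == variant_id:
                return v
        raise KeyError(variant_id)

    def dosage_vector(self, variant_id: str) -> pd.Series:
        return self.dosage.loc[variant_id]


def position_in_interval(pos: int, start: int, end: int) -> bool:
    """Is 1-based position ``pos`` inside 0-based half-open [start, end)?

    Equivalent to ``start < pos <= end``: BED line "chr5 10 20" contains the
    1-based positions 11..20.
    """
    return start < pos <= end


@dataclass
class IntervalTrack:
    """A named, unstranded set of genomic intervals (0-based half-open)."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"track {self.name}: interval {chrom}:{start}-{end} "
                    "violates start < end")
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in self.intervals:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def contains_position(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based variant position."""
        tree = self._trees.get(chrom)
        return bool(tree.overlaps_point(pos - 1)) if tree else False


@dataclass
class ExpressionMatrix:
    """Features x samples expression values on a nonnegative FPKM scale.

    ``transform`` tags the space the values currently live in. ``metadata``
    records generator provenance (e.g. the latent-to-FPKM map) so transforms
    can invert it exactly.
    """

    values: pd.DataFrame
    transform: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if self.transform == "raw" and (self.values.values < 0).any():
            raise ValueError("raw expression values must be nonnegative")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def transformed(self, transform: str) -> pd.DataFrame:
        """Return values in the requested space (from raw).

        ``log2`` is log2(x + 1); ``rank`` ranks each feature across samples
        (average ranks for ties).
        """
        if transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {transform!r}")
        if self.transform != "raw" and transform != self.transform:
            raise ValueError(
                f"matrix already in {self.transform!r} space; cannot reach "
                f"{transform!r}")
        if transform == self.transform:
            return self.values
        if transform == "log2":
            return np.log2(self.values + 1.0)
        return self.values.rank(axis=1)


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)


@dataclass
class ReadCollection:
    """Plain sequence reads; quality is carried but never interpreted."""

    ids: list[str]
    sequences: list[str]

    def __len__(self):
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


# ---------------------------------------------------------------------------
# genotypes

_EXON_ID_RE = re.compile(
    r"^(?P<gene>[^|]+)\|exon(?P<exon>\d+)\|(?P<chrom>[^|]+)\|(?P<start>\d+)\|(?P<end>\d+)$"
)


def exon_feature_id(gene: str, exon: int, chrom: str, start: int, end: int) -> str:
    """Canonical exon feature id carrying gene, exon index, and coordinates."""
    return f"{gene}|exon{exon}|{chrom}|{start}|{end}"


def parse_exon_feature_id(feature_id: str) -> dict:
    m = _EXON_ID_RE.match(feature_id)
    if not m:
        raise ParseError(f"not an exon feature id: {feature_id!r}")
    d = m.groupdict()
    return {"gene": d["gene"], "exon": int(d["exon"]), "chrom": d["chrom"],
            "start": int(d["start"]), "end": int(d["end"])}


def read_genotypes(path: str | Path, dialect: str = "vcf_gt",
                   require_phased: bool = False) -> GenotypeData:
    """Read genotypes from a GT-only VCF subset or a dosage TSV.

    With ``dialect="vcf_gt"`` the risk allele is ALT. A phased panel is
    returned whenever every genotype carries phase marks; ``require_phased``
    turns an unphased genotype into an error (LD needs phase).
    """
    if dialect == "vcf_gt":
        return _read_vcf_gt(Path(path), require_phased)
    if dialect == "tsv":
        if require_phased:
            raise ParseError("TSV dosage files carry no phase information")
        return _read_dosage_tsv(Path(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf_gt(path: Path, require_phased: bool) -> GenotypeData:
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    variants: list[VariantRecord] = []
    rows: list[list[float]] = []
    hap_rows: list[np.ndarray] = []
    all_phased = True
    for line_no, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
        if rec.alts is None or len(rec.alts) != 1:
            raise ParseError(
                f"{path}: record {rec.id or rec.pos}: exactly one ALT required")
        variants.append(VariantRecord(
            id=rec.id or f"{rec.chrom}:{rec.pos}",
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0]))
        dos: list[float] = []
        haps = np.zeros(2 * len(samples), dtype=np.int8)
        rec_phased = True
        for si, s in enumerate(samples):
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or len(gt) != 2:
                raise ParseError(
                    f"{path}: variant {variants[-1].id}, sample {s}: "
                    f"malformed or non-diploid GT {gt!r}")
            if gt[0] is None or gt[1] is None:
                dos.append(float("nan"))
                rec_phased = False
                continue
            if not call.phased:
                rec_phased = False
                if require_phased:
                    raise ParseError(
                        f"{path}: variant {variants[-1].id}, sample {s}: "
                        "unphased genotype but a phased panel was requested")
            dos.append(float(gt[0] + gt[1]))
            haps[2 * si] = gt[0]
            haps[2 * si + 1] = gt[1]
        all_phased &= rec_phased
        rows.append(dos)
        hap_rows.append(haps)
    dosage = pd.DataFrame(rows, index=[v.id for v in variants], columns=samples)
    panel = None
    if all_phased and variants:
        panel = HaplotypePanel(variants, np.array(hap_rows, dtype=np.int8).T)
    if require_phased and panel is None:
        raise ParseError(f"{path}: phased panel requested but file is empty "
                         "or contains missing genotypes")
    return GenotypeData(variants, dosage, panel)


def write_genotypes_vcf(data: GenotypeData, path: str | Path) -> None:
    """Write the GT-only VCF subset (phased ``a|b`` when a panel is present)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    chroms = []
    for v in data.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(data.samples))
    sep = "|" if data.panel is not None else "/"
    for i, v in enumerate(data.variants):
        gts = []
        for si in range(len(data.samples)):
            if data.panel is not None:
                a = data.panel.haplotypes[2 * si, i]
                b = data.panel.haplotypes[2 * si + 1, i]
                gts.append(f"{a}{sep}{b}")
            else:
                d = data.dosage.iloc[i, si]
                if np.isnan(d):
                    gts.append("./.")
                else:
                    d = int(d)
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
        lines.append(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")


_TSV_META_COLS = ["chrom", "pos", "ref", "alt", "risk_is_alt"]


def write_genotypes_tsv(data: GenotypeData, path: str | Path) -> None:
    df = pd.DataFrame(
        {"chrom": [v.chrom for v in data.variants],
         "pos": [v.pos for v in data.variants],
         "ref": [v.ref for v in data.variants],
         "alt": [v.alt for v in data.variants],
         "risk_is_alt": [int(v.risk_is_alt) for v in data.variants]},
        index=[v.id for v in data.variants])
    out = pd.concat([df, data.dosage], axis=1)
    out.to_csv(path, sep="\t", index_label="variant_id", na_rep="NA")


def _read_dosage_tsv(path: Path) -> GenotypeData:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in _TSV_META_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata columns {missing}")
    variants = [VariantRecord(str(vid), str(r["chrom"]), int(r["pos"]),
                              str(r["ref"]), str(r["alt"]),
                              bool(int(r["risk_is_alt"])))
                for vid, r in df[_TSV_META_COLS].iterrows()]
    dosage = df.drop(columns=_TSV_META_COLS).astype(float)
    bad = dosage.stack().dropna()
    if not bad.isin([0.0, 1.0, 2.0]).all():
        raise ParseError(f"{path}: dosage values must be 0, 1, 2, or NA")
    return GenotypeData(variants, dosage)


def write_haplotypes_tsv(panel: HaplotypePanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.haplotypes,
                      index=[f"H{i:04d}" for i in range(panel.haplotypes.shape[0])],
                      columns=[v.id for v in panel.variants])
    df.to_csv(path, sep="\t", index_label="haplotype")


# ---------------------------------------------------------------------------
# intervals, gene sets, motifs, expression, reads


def read_intervals(path: str | Path, name: str | None = None) -> IntervalTrack:
    """Read a BED track (0-based half-open; extra columns ignored)."""
    path = Path(path)
    intervals = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ParseError(f"{path}:{line_no}: BED needs >= 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as e:
            raise ParseError(f"{path}:{line_no}: non-integer coordinate") from e
        if start < 0 or start >= end:
            raise ParseError(
                f"{path}:{line_no}: invalid interval {parts[0]}:{start}-{end}")
        intervals.append((parts[0], start, end))
    return IntervalTrack(name or path.stem, intervals)


def write_bed(track: IntervalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{track.name}\n")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read GMT: one set per line — name, description, member genes."""
    path = Path(path)
    coll = GeneSetCollection()
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{line_no}: GMT needs name, description, "
                             "and at least one member")
        name = parts[0]
        if name in coll.sets:
            raise ParseError(f"{path}:{line_no}: duplicate set name {name!r}")
        coll.sets[name] = [g for g in parts[2:] if g]
        coll.descriptions[name] = parts[1]
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_pcm(path: str | Path):
    """Read a JASPAR-style position count matrix (rows ordered A, C, G, T)."""
    from allelreg.motif import PositionCountMatrix

    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ParseError(f"{path}: expected '>' header line")
    name = lines[0][1:].strip().split()[0]
    if len(lines) < 5:
        raise ParseError(f"{path}: expected four base rows after the header")
    rows = []
    for expected, line in zip("ACGT", lines[1:5]):
        m = re.match(r"^\s*([A-Za-z])\s*\[?\s*([-\d.\s]+?)\s*\]?\s*$", line)
        if not m:
            raise ParseError(f"{path}: malformed matrix row {line!r}")
        base = m.group(1).upper()
        if base != expected:
            raise ParseError(
                f"{path}: rows must be ordered A,C,G,T; got {base!r} where "
                f"{expected!r} expected")
        rows.append([float(x) for x in m.group(2).split()])
    if len({len(r) for r in rows}) != 1:
        raise ParseError(f"{path}: ragged matrix rows")
    counts = np.array(rows, dtype=float).T  # (L, 4)
    return PositionCountMatrix(name=name, counts=counts)


def write_pcm(pcm, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pcm.name}\n")
        for bi, base in enumerate("ACGT"):
            vals = " ".join(f"{v:g}" for v in pcm.counts[:, bi])
            fh.write(f"{base} [ {vals} ]\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a features x samples TSV with ``#key=value`` metadata comments."""
    path = Path(path)
    metadata: dict = {}
    transform = "raw"
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key == "transform":
                    transform = val
                else:
                    try:
                        metadata[key] = float(val)
                    except ValueError:
                        metadata[key] = val
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate feature ids {dupes[:5]}")
    return ExpressionMatrix(df, transform=transform, metadata=metadata)


def write_expression(mat: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#transform={mat.transform}\n")
        for key, val in sorted(mat.metadata.items()):
            fh.write(f"#{key}={val}\n")
        mat.values.to_csv(fh, sep="\t", index_label="feature_id")


def read_reads(path: str | Path) -> ReadCollection:
    """Read FASTQ (or FASTA) into a plain read collection."""
    path = Path(path)
    fmt = "fasta" if path.suffix in {".fa", ".fasta"} else "fastq"
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), fmt):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return ReadCollection(ids, seqs)


def write_fastq(reads: ReadCollection, path: str | Path) -> None:
    """Write reads as FASTQ with constant quality 'I' (quality is unused)."""
    records = []
    for rid, seq in zip(reads.ids, reads.sequences):
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
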