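"""Domain types, file I/O and functional-effect annotation of adenosine sites.

Coordinate conventions
----------------------
All on-disk formats (count tables, GFF3, VCF) are 1-based, following the
VCF/GFF convention.  Internally every position is a 0-based genomic offset;
conversion happens only at the I/O boundary.

A candidate "adenosine" always means A on the transcript strand: the genomic
base is ``A`` under a + gene and ``T`` under a − gene.  Editing converts it
to a base read as G, so the functional consequence is that of an A→G change
in the spliced transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: standard genetic code, stops as "*"
CODON_AA = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
}

#: column order of the on-disk count table (positions 1-based in files)
COUNT_TABLE_COLUMNS = ["chrom", "pos", "library_id", "coverage", "edited_count"]

#: stable column order of the annotated site table written by the CLI
SITE_TABLE_COLUMNS = [
    "chrom", "pos", "site_class", "joint_P_E1", "q_value", "C_max",
    "C_total", "n_libraries_detected", "effect", "is_novel",
]


class ParseError(ValueError):
    """Malformed input row; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryMeta:
    """One sequencing library: species, sex, age and temperature condition."""

    library_id: str
    species: str = "mel"
    sex: str = "mixed"           # {"F", "M", "mixed"}
    age_days: str = ""
    temperature_condition: str = "25C"
    strain: str = ""


@dataclass(frozen=True)
class SiteObservation:
    """Coverage and edited-allele count of one site in one library."""

    chrom: str
    pos: int                     # 0-based genomic position
    library_id: str
    coverage: int                # C_k
    edited_count: int            # L_k

    def __post_init__(self):
        if not (0 <= self.edited_count <= self.coverage):
            raise ValueError(
                f"edited count {self.edited_count} outside [0, coverage="
                f"{self.coverage}] at {self.chrom}:{self.pos + 1}"
            )

    @property
    def level(self) -> float:
        """Editing level l_k = L_k / C_k (NaN when uncovered)."""
        return self.edited_count / self.coverage if self.coverage else float("nan")


@dataclass(frozen=True)
class SiteEffect:
    """Functional consequence of editing one adenosine (canonical transcript)."""

    category: str                # N, S, UTR5, UTR3, intron, intergenic,
                                 # ncRNA, stop_retained, stop_lost
    gene_id: str | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


@dataclass
class GeneModel:
    """Canonical-transcript gene model with exon and CDS intervals.

    Intervals are 0-based half-open, sorted by genomic coordinate and
    non-overlapping.  The CDS must translate cleanly: length divisible by 3.
    """

    gene_id: str
    chromosome: str
    strand: str                          # "+" or "-"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(tuple(iv) for iv in self.exons)
        self.cds = sorted(tuple(iv) for iv in self.cds)
        for ivs, label in ((self.exons, "exon"), (self.cds, "CDS")):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"{self.gene_id}: overlapping {label} intervals")
        if self.cds and self.cds_length % 3:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    # -- geometry -----------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos < e

    def region_of(self, pos: int) -> str | None:
        """One of CDS/UTR5/UTR3/intron/ncRNA for a contained position."""
        if not self.contains(pos):
            return None
        in_exon = any(s <= pos < e for s, e in self.exons)
        if not in_exon:
            return "intron"
        if not self.is_coding:
            return "ncRNA"
        if any(s <= pos < e for s, e in self.cds):
            return "CDS"
        cds_start, cds_end = self.cds[0][0], self.cds[-1][1]
        if pos < cds_start:
            return "UTR5" if self.strand == "+" else "UTR3"
        if pos >= cds_end:
            return "UTR3" if self.strand == "+" else "UTR5"
        # exonic, between CDS chunks (does not occur in well-formed models)
        return "intron"

    # -- sequence -----------------------------------------------------------

    def coding_sequence(self, genome: dict[str, str]) -> str:
        chrom_seq = genome[self.chromosome]
        s = "".join(chrom_seq[a:b] for a, b in self.cds)
        return reverse_complement(s) if self.strand == "-" else s

    def cds_offset(self, pos: int) -> int | None:
        """Transcript-strand offset of a genomic position inside the CDS."""
        off = 0
        for s, e in self.cds:
            if s <= pos < e:
                plus_off = off + (pos - s)
                if self.strand == "+":
                    return plus_off
                return self.cds_length - 1 - plus_off
            off += e - s
        return None


class SNPMask:
    """Set of (chromosome, 0-based position) excluded as genomic polymorphisms."""

    def __init__(self, positions=()):
        self._positions = {(str(c), int(p)) for c, p in positions}

    def __contains__(self, key) -> bool:
        c, p = key
        return (str(c), int(p)) in self._positions

    def __len__(self) -> int:
        return len(self._positions)

    def __iter__(self):
        return iter(sorted(self._positions))

    @classmethod
    def from_vcf(cls, path) -> "SNPMask":
        return cls(read_vcf_positions(path))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

#: overlap precedence: canonical transcript, CDS wins over UTR wins over intron
_REGION_PRECEDENCE = {"CDS": 0, "UTR5": 1, "UTR3": 1, "ncRNA": 2, "intron": 3}


class AnnotationError(ValueError):
    pass


def annotate_site(
    chrom: str,
    pos: int,
    genes: list[GeneModel],
    genome: dict[str, str],
) -> SiteEffect:
    """Functional effect of an A→G edit at a genomic position.

    The site must be an adenosine on the transcript strand of a containing
    gene (genomic A under + genes, genomic T under − genes); intergenic sites
    must be A or T on the genome.  When genes overlap, CDS beats UTR beats
    intron (canonical transcripts only).
    """
    base = genome[chrom][pos].upper()
    hits: list[tuple[int, str, GeneModel]] = []
    for gene in genes:
        if gene.chromosome != chrom or not gene.contains(pos):
            continue
        expected = "A" if gene.strand == "+" else "T"
        if base != expected:
            continue
        region = gene.region_of(pos)
        if region is not None:
            hits.append((_REGION_PRECEDENCE[region], region, gene))

    if not hits:
        overlapping = any(
            g.chromosome == chrom and g.contains(pos) for g in genes
        )
        if overlapping:
            raise AnnotationError(
                f"{chrom}:{pos + 1} is not an adenosine on any containing "
                f"transcript strand (genomic base {base})"
            )
        if base not in "AT":
            raise AnnotationError(
                f"{chrom}:{pos + 1} genomic base {base} is not an adenosine "
                "on either strand"
            )
        return SiteEffect(category="intergenic")

    hits.sort(key=lambda h: h[0])
    _, region, gene = hits[0]
    if region != "CDS":
        return SiteEffect(category=region, gene_id=gene.gene_id)
    return _cds_effect(gene, pos, genome)


def _cds_effect(
    gene: GeneModel, pos: int, genome: dict[str, str], cds_seq: str | None = None
) -> SiteEffect:
    if cds_seq is None:
        cds_seq = gene.coding_sequence(genome).upper()
    off = gene.cds_offset(pos)
    codon_idx, within = divmod(off, 3)
    ref_codon = cds_seq[codon_idx * 3: codon_idx * 3 + 3]
    if ref_codon[within] != "A":
        raise AnnotationError(
            f"{gene.gene_id} {gene.chromosome}:{pos + 1}: transcript base "
            f"{ref_codon[within]} is not A"
        )
    alt_codon = ref_codon[:within] + "G" + ref_codon[within + 1:]
    ref_aa = CODON_AA[ref_codon]
    alt_aa = CODON_AA[alt_codon]
    if ref_codon in STOP_CODONS:
        category = "stop_retained" if alt_codon in STOP_CODONS else "stop_lost"
    else:
        category = "S" if ref_aa == alt_aa else "N"
    return SiteEffect(
        category=category, gene_id=gene.gene_id,
        ref_codon=ref_codon, alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa,
    )


def iter_cds_adenosines(gene: GeneModel, genome: dict[str, str]):
    """Yield (pos, SiteEffect) for every transcript-strand A in a gene's CDS."""
    target = "A" if gene.strand == "+" else "T"
    chrom_seq = genome[gene.chromosome]
    cds_seq = gene.coding_sequence(genome).upper()
    for s, e in gene.cds:
        for pos in range(s, e):
            if chrom_seq[pos].upper() == target:
                yield pos, _cds_effect(gene, pos, genome, cds_seq)


# ---------------------------------------------------------------------------
# I/O: count tables
# ---------------------------------------------------------------------------

def load_site_observations(
    path,
    meta: list[LibraryMeta] | None = None,
    mask: SNPMask | None = None,
) -> pd.DataFrame:
    """Read a tab-separated count table into an observation frame.

    File columns: chrom, pos (1-based), library_id, coverage, edited_count.
    Returns a DataFrame with 0-based ``pos``, an ``level`` column and a
    (chrom, pos, library_id) row per observation; SNP-masked positions are
    dropped (count logged).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "library_id": str})
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in COUNT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df[COUNT_TABLE_COLUMNS].copy()
    for col in ("pos", "coverage", "edited_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise ParseError(
                f"non-numeric {col} value {df[col][bad].iloc[0]!r}",
                line=int(bad.idxmax()) + 2,
            )
        df[col] = vals.astype(int)

    over = df["edited_count"] > df["coverage"]
    if over.any():
        i = int(over.idxmax())
        raise ParseError(
            f"edited_count {df['edited_count'][i]} exceeds coverage "
            f"{df['coverage'][i]}", line=i + 2,
        )
    if (df[["pos", "coverage", "edited_count"]] < 0).any().any():
        raise ParseError(f"{path}: negative count or position")

    if meta is not None:
        known = {m.library_id for m in meta}
        unknown = set(df["library_id"]) - known
        if unknown:
            raise ParseError(f"{path}: unknown library ids {sorted(unknown)}")

    df["pos"] = df["pos"] - 1  # 1-based on disk -> 0-based in memory
    if mask is not None and len(mask):
        keep = [(c, p) not in mask for c, p in zip(df["chrom"], df["pos"])]
        n_dropped = len(df) - sum(keep)
        if n_dropped:
            logger.info("dropped %d observations at SNP-masked positions", n_dropped)
        df = df[keep].reset_index(drop=True)

    df["level"] = df["edited_count"] / df["coverage"].where(df["coverage"] > 0)
    return df


def write_site_observations(df: pd.DataFrame, path) -> None:
    """Inverse of :func:`load_site_observations` (positions back to 1-based)."""
    out = df[COUNT_TABLE_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def load_library_meta(path) -> list[LibraryMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [LibraryMeta(**row) for row in df.to_dict("records")]


def write_library_meta(meta: list[LibraryMeta], path) -> None:
    pd.DataFrame([vars(m) for m in meta]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O: FASTA / GFF3 / VCF
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def load_gene_models(gff_path) -> list[GeneModel]:
    """Parse canonical-transcript gene models from a GFF3 file."""
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons, cds = [], []
        for child in db.children(g, level=None):
            iv = (child.start - 1, child.end)  # GFF3 1-based closed -> half-open
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
        if not exons:
            exons = [(g.start - 1, g.end)]
        genes.append(GeneModel(g.id, g.seqid, g.strand, exons, cds))
    return genes


def write_gene_models(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chromosome}\teditome\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chromosome}\teditome\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for a, b in g.exons:
                fh.write(
                    f"{g.chromosome}\teditome\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                    f"Parent={mrna}\n"
                )
            # CDS phase on the transcript strand
            intervals = g.cds if g.strand == "+" else g.cds[::-1]
            consumed = 0
            for a, b in intervals:
                phase = (3 - consumed % 3) % 3
                fh.write(
                    f"{g.chromosome}\teditome\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t"
                    f"{phase}\tParent={mrna}\n"
                )
                consumed += b - a


def read_vcf_positions(path) -> list[tuple[str, int]]:
    """(chrom, 0-based pos) pairs from a plain-text VCF body."""
    positions = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ParseError("VCF row with fewer than 5 columns", line=i)
            positions.append((parts[0], int(parts[1]) - 1))
    return positions


def write_snp_vcf(positions, genome: dict[str, str], path) -> None:
    """Emit a minimal VCF 4.2 with the masked SNP positions (ALT fixed to G/C)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in genome.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos in sorted(positions):
            ref = genome[chrom][pos].upper()
            alt = {"A": "G", "T": "C", "C": "T", "G": "A"}[ref]
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
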