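"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversion to and from
the 1-based conventions of VCF and GFF3 happens only here, at the format
boundary. ``VariantTable.positions`` keeps the source VCF's 1-based
coordinates for exact round-trips; ``pos0`` is the internal view.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import intervals as iv
from .popgen_core import HaplotypeMatrix

__all__ = [
    "LoadReport",
    "VariantTable",
    "GeneModel",
    "MaskSet",
    "read_vcf",
    "write_vcf",
    "read_gff",
    "read_masks",
    "write_tables",
    "write_network_graphml",
]


@dataclass
class LoadReport:
    n_records: int = 0
    n_kept: int = 0
    n_non_snp: int = 0
    n_multiallelic: int = 0
    n_missing_gt: int = 0

    def summary(self) -> str:
        return (
            f"kept: {self.n_kept}; dropped: {self.n_non_snp} non-SNP, "
            f"{self.n_multiallelic} multiallelic, {self.n_missing_gt} missing-GT"
        )


@dataclass
class VariantTable:
    """Biallelic phased SNPs on one contig.

    genotypes is a haplotype-by-site {0,1} matrix with ``2 * n_diploids``
    rows; sample_ids are haplotype labels, two per diploid with ``_1``/``_2``
    suffixes.
    """

    contig: str
    positions: np.ndarray  # 1-based, as in the source VCF
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    sample_ids: list[str]
    load_report: Optional[LoadReport] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.uint8)
        if self.genotypes.shape[1] != len(self.positions):
            raise ValueError("genotype matrix must have one column per site")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be unique and increasing per contig")
        if self.genotypes.shape[0] % 2:
            raise ValueError("expected 2 haplotype rows per diploid")

    @property
    def pos0(self) -> np.ndarray:
        """0-based site coordinates (internal convention)."""
        return self.positions - 1

    @property
    def n_hap(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def haplotypes(self) -> HaplotypeMatrix:
        return HaplotypeMatrix(self.genotypes, self.pos0)

    def slice_region(self, start0: int, end0: int) -> "VariantTable":
        lo, hi = np.searchsorted(self.pos0, [start0, end0])
        return VariantTable(
            self.contig,
            self.positions[lo:hi],
            self.ref[lo:hi],
            self.alt[lo:hi],
            self.genotypes[:, lo:hi],
            self.sample_ids,
        )


def read_vcf(path, region=None) -> VariantTable:
    """Load phased biallelic SNPs from a VCF 4.x file.

    ``region`` is an optional ``(contig, start0, end0)`` half-open interval.
    Multiallelic records, non-SNPs and records with missing genotypes are
    dropped and counted in the attached :class:`LoadReport`. Any unphased
    genotype is a hard error naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = []
    for s in vcf.samples:
        sample_ids.extend([f"{s}_1", f"{s}_2"])
    rep = LoadReport()
    positions, refs, alts, rows = [], [], [], []
    contigs_seen = set()
    for v in vcf:
        if region is not None:
            # streamed filter: plain VCFs carry no tabix index
            contig, start0, end0 = region
            if v.CHROM != contig or not (start0 < v.POS <= end0):
                continue
        rep.n_records += 1
        if len(v.ALT) != 1:
            rep.n_multiallelic += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.ALT[0] not in "ACGT":
            rep.n_non_snp += 1
            continue
        gts = v.genotypes  # per sample: [allele_a, allele_b, phased]
        alleles = np.array([g[:2] for g in gts], dtype=np.int16).reshape(-1)
        if np.any(alleles < 0):
            rep.n_missing_gt += 1
            continue
        if any(not g[2] for g in gts):
            raise ValueError(
                f"unphased genotype at {v.CHROM}:{v.POS}; this pipeline "
                "requires fully phased input"
            )
        contigs_seen.add(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(alleles.astype(np.uint8))
        rep.n_kept += 1
    if len(contigs_seen) > 1:
        raise ValueError(
            "VCF spans multiple contigs; pass a region to read one contig "
            f"at a time (found: {sorted(contigs_seen)})"
        )
    if region is not None:
        contig = region[0]
    elif contigs_seen:
        contig = next(iter(contigs_seen))
    else:
        contig = "NA"
    geno = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.uint8)
    )
    return VariantTable(
        contig,
        np.asarray(positions, dtype=np.int64),
        np.asarray(refs, dtype=object),
        np.asarray(alts, dtype=object),
        geno,
        sample_ids,
        load_report=rep,
    )


def write_vcf(table: VariantTable, path, contig_length: Optional[int] = None) -> None:
    """Write a minimal phased VCF 4.2 file."""
    diploids = [s[:-2] for s in table.sample_ids[::2]]
    length = contig_length or (int(table.positions.max()) + 1000 if table.n_sites else 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={table.contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(diploids) + "\n")
        G = table.genotypes
        for j in range(table.n_sites):
            gt = "\t".join(
                f"{G[2 * i, j]}|{G[2 * i + 1, j]}" for i in range(len(diploids))
            )
            fh.write(
                f"{table.contig}\t{table.positions[j]}\t.\t{table.ref[j]}\t"
                f"{table.alt[j]}\t.\tPASS\t.\tGT\t{gt}\n"
            )


@dataclass
class GeneModel:
    """One gene: span plus exon/CDS structure, all 0-based half-open."""

    gene_id: str
    contig: str
    strand: str
    gene_span: tuple[int, int]
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for s, e in ivs:
                if not (self.gene_span[0] <= s < e <= self.gene_span[1]):
                    raise ValueError(
                        f"{name} interval [{s},{e}) outside gene span of {self.gene_id}"
                    )

    @property
    def length(self) -> int:
        return self.gene_span[1] - self.gene_span[0]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def read_gff(path) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon/CDS features).

    1-based inclusive GFF coordinates become 0-based half-open. When a gene
    carries several mRNAs the one with the longest summed CDS (falling back
    to exon length) is used. A gene without exons is an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("ID", [g.id])[0]
        mrnas = list(db.children(g, featuretype="mRNA"))
        parents = mrnas if mrnas else [g]
        best, best_len = None, -1
        for p in parents:
            cds = [(c.start - 1, c.end) for c in db.children(p, featuretype="CDS")]
            exons = [(c.start - 1, c.end) for c in db.children(p, featuretype="exon")]
            score = sum(e - s for s, e in (cds or exons))
            if score > best_len:
                best, best_len = (exons, cds), score
        exons, cds = best
        if not exons:
            raise ValueError(f"gene {gid} has no exon features")
        span = (g.start - 1, g.end)
        for s, e in cds:
            if not (span[0] <= s < e <= span[1]):
                raise ValueError(f"CDS outside gene span for gene {gid}")
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                gene_span=span,
                exons=sorted(exons),
                cds=sorted(cds),
            )
        )
    return genes


def write_gff(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.gene_span
            fh.write(
                f"{g.contig}\t.\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.m1"
            fh.write(
                f"{g.contig}\t.\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.contig}\t.\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.e{i};Parent={mid}\n"
                )
            for i, (cs, ce) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.contig}\t.\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                    f"ID={mid}.c{i};Parent={mid}\n"
                )


@dataclass
class MaskSet:
    """Repeat, gap and indel intervals per contig (0-based half-open).

    Indels are stored as the intervals given in the source BED (points as
    1-bp intervals); expansion by a radius is the beta scan's job.
    """

    repeats: dict = field(default_factory=dict)
    gaps: dict = field(default_factory=dict)
    indels: dict = field(default_factory=dict)


def _read_bed(path) -> dict:
    out: dict[str, list] = {}
    if path is None:
        return {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            contig, s, e = parts[0], int(parts[1]), int(parts[2])
            if s >= e:
                raise ValueError(
                    f"{path}: line {lineno}: start >= end ({s} >= {e})"
                )
            out.setdefault(contig, []).append((s, e))
    return {c: iv.merge(lst) for c, lst in out.items()}


def read_masks(repeat_bed=None, gap_bed=None, indel_bed=None) -> MaskSet:
    """Load repeat/gap/indel BEDs; overlapping intervals are unioned."""
    return MaskSet(
        repeats=_read_bed(repeat_bed),
        gaps=_read_bed(gap_bed),
        indels=_read_bed(indel_bed),
    )


def write_bed(per_contig: dict, path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(per_contig):
            for s, e in np.asarray(per_contig[contig]):
                fh.write(f"{contig}\t{s}\t{e}\n")


GENE_TABLE_COLUMNS = [
    "gene",
    "cds_length",
    "S",
    "pi",
    "k",
    "p_mlhka",
    "beta_std_max",
    "percentile_rank",
]


def write_network_graphml(network, path) -> None:
    """Serialise a haplotype network (HapNetwork) as GraphML."""
    import networkx as nx

    G = nx.Graph()
    for i, (seq, freq) in enumerate(network.nodes):
        G.add_node(i, sequence=seq, frequency=int(freq), inferred=int(freq == 0))
    for a, b, w in network.edges:
        G.add_edge(a, b, weight=int(w))
    nx.write_graphml(G, path)


def write_tables(report, out_dir) -> list[str]:
    """Write pipeline results as TSV/GraphML files; returns paths written.

    ``report`` may provide any of: gene_table (DataFrame in the Table-1
    schema), diagnostics (DataFrame), beta_track (DataFrame), hka_table,
    tracks (dict gene -> DiversityTrack), ld_pairs/ld_blocks (dicts of
    DataFrames), networks (dict gene -> HapNetwork).
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []

    def _tsv(df: pd.DataFrame, name: str) -> None:
        p = os.path.join(out_dir, name)
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)

    gene_table = getattr(report, "gene_table", None)
    if gene_table is not None:
        _tsv(gene_table[GENE_TABLE_COLUMNS], "gene_summary.tsv")
    for attr, name in [
        ("diagnostics", "gene_diagnostics.tsv"),
        ("beta_track", "beta_track.tsv"),
        ("hka_table", "hka_results.tsv"),
    ]:
        df = getattr(report, attr, None)
        if df is not None:
            _tsv(df, name)
    for gene, track in (getattr(report, "tracks", None) or {}).items():
        _tsv(track.to_dataframe(), f"track_{gene}.tsv")
    for gene, df in (getattr(report, "ld_pairs", None) or {}).items():
        _tsv(df, f"ld_pairs_{gene}.tsv")
    for gene, df in (getattr(report, "ld_blocks", None) or {}).items():
        _tsv(df, f"ld_blocks_{gene}.bed")
    for gene, net in (getattr(report, "networks", None) or {}).items():
        p = os.path.join(out_dir, f"network_{gene}.graphml")
        write_network_graphml(net, p)
        written.append(p)
    return written
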