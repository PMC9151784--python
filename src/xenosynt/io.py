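"""Readers and writers for every external format the pipeline touches.

Coordinates are 1-based closed (GFF3 native) throughout. Writers emit a
record-count pragma so that a truncated copy of their own output is always
detected on re-read; readers enforce the count only when the pragma is
present, so files from other tools still parse.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "FormatError",
    "GeneModel",
    "GenomeAnnotation",
    "HomologyHit",
    "OrthogroupMap",
    "read_annotation",
    "write_annotation",
    "read_hits",
    "write_hits",
    "read_orthogroups",
    "write_orthogroups",
    "read_expression",
    "write_expression",
]

#: E-values of exactly zero are clamped to this floor on read so the
#: downstream log transform (alien index) stays defined; it matches the
#: pseudocount of the alien-index convention.
EVALUE_FLOOR = 1e-200

TAXON_GROUPS = ("metazoan", "non_metazoan")


class FormatError(ValueError):
    """Malformed input file."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GeneModel:
    """One gene model: 1-based closed interval on a scaffold, with exon count.

    The intron count of the gene is ``exon_count - 1``.
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    exon_count: int

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.exon_count < 1:
            raise FormatError(f"gene {self.gene_id}: exon_count must be >= 1")


@dataclass
class GenomeAnnotation:
    """Ordered gene models on named scaffolds for one species."""

    species_id: str
    scaffolds: dict[str, int]
    genes: list[GeneModel]
    _by_id: dict[str, GeneModel] = field(default_factory=dict, repr=False)
    _by_scaffold: dict[str, list[GeneModel]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_id = {}
        self._by_scaffold = {s: [] for s in self.scaffolds}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise FormatError(f"duplicate gene id {g.gene_id}")
            if g.scaffold_id not in self.scaffolds:
                raise FormatError(f"gene {g.gene_id}: unknown scaffold {g.scaffold_id}")
            if g.end > self.scaffolds[g.scaffold_id]:
                raise FormatError(f"gene {g.gene_id}: extends past scaffold end")
            self._by_id[g.gene_id] = g
            self._by_scaffold.setdefault(g.scaffold_id, []).append(g)
        for s, gs in self._by_scaffold.items():
            gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
        # keep self.genes in scaffold order too
        self.genes = [g for s in self.scaffolds for g in self._by_scaffold.get(s, [])]

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r} in {self.species_id}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def scaffold_genes(self, scaffold_id: str) -> list[GeneModel]:
        return self._by_scaffold.get(scaffold_id, [])


@dataclass(frozen=True)
class HomologyHit:
    """One row of an outfmt-6 style hit table, with the two appended
    taxonomy columns (taxon_group, taxon_name)."""

    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    taxon_group: str
    taxon_name: str


class OrthogroupMap:
    """Gene -> orthogroup assignments; genes absent are species-specific."""

    def __init__(self, assignments: dict[str, str], species: list[str] | None = None,
                 members: dict[str, dict[str, list[str]]] | None = None):
        self.assignments = assignments
        self.species = species or []
        #: orthogroup -> species -> member gene ids (kept for writing)
        self.members = members or {}

    def get(self, gene_id: str) -> str | None:
        """Orthogroup of a gene, or None if species-specific."""
        return self.assignments.get(gene_id)

    def __len__(self) -> int:
        return len(self.assignments)


# ---------------------------------------------------------------------------
# GFF3

def read_annotation(path, species_id: str | None = None) -> GenomeAnnotation:
    """Read a GFF3 file with gene and exon features.

    Scaffold lengths come from ``##sequence-region`` pragmas. Exon counts are
    derived from exon features (``Parent=`` back-references); a gene without
    exons, or an exon outside its gene span, is a format error.
    """
    path = Path(path)
    scaffolds: dict[str, int] = {}
    gene_rows: dict[str, tuple[str, int, int, str]] = {}
    gene_order: list[str] = []
    exon_counts: dict[str, int] = {}
    declared: int | None = None
    saw_end = False
    sp = species_id or path.stem.split(".")[0]
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line == "###":
                saw_end = True
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise FormatError(f"{path}:{lineno}: bad sequence-region pragma")
                scaffolds[parts[1]] = int(parts[3])
                continue
            if line.startswith("##records"):
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: bad records pragma")
                declared = int(parts[1])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr.get("ID")
                if not gid:
                    raise FormatError(f"{path}:{lineno}: gene without ID attribute")
                if gid in gene_rows:
                    raise FormatError(f"{path}:{lineno}: duplicate gene {gid}")
                gene_rows[gid] = (seqid, start_i, end_i, strand)
                gene_order.append(gid)
            elif ftype == "exon":
                parent = attr.get("Parent")
                if not parent or parent not in gene_rows:
                    raise FormatError(f"{path}:{lineno}: exon without known gene parent")
                gsc, gs, ge, _ = gene_rows[parent]
                if seqid != gsc or start_i < gs or end_i > ge:
                    raise FormatError(f"{path}:{lineno}: exon outside gene span of {parent}")
                exon_counts[parent] = exon_counts.get(parent, 0) + 1
            # other feature types ignored
    genes = []
    for gid in gene_order:
        seqid, s, e, strand = gene_rows[gid]
        if gid not in exon_counts:
            raise FormatError(f"{path}: gene {gid} has no exon features")
        genes.append(GeneModel(gid, seqid, s, e, strand, exon_counts[gid]))
    if declared is not None:
        if declared != len(genes):
            raise FormatError(f"{path}: declares {declared} genes, found {len(genes)} (truncated?)")
        if not saw_end:
            raise FormatError(f"{path}: missing ### end-of-data marker (truncated?)")
    if not genes:
        raise FormatError(f"{path}: annotation contains no gene features")
    return GenomeAnnotation(sp, scaffolds, genes)


def write_annotation(ann: GenomeAnnotation, path) -> None:
    """Write GFF3 in the canonical form ``read_annotation`` round-trips."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for sc in ann.scaffolds:
            fh.write(f"##sequence-region {sc} 1 {ann.scaffolds[sc]}\n")
        fh.write(f"##records {len(ann.genes)}\n")
        for g in ann.genes:
            fh.write(f"{g.scaffold_id}\txenosynt\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            # exons are written as an even partition of the gene span; only
            # their count is meaningful downstream
            span = g.end - g.start + 1
            n = g.exon_count
            bounds = [(g.start - 1) + (span * i) // n for i in range(n + 1)]
            for i in range(n):
                s, e = bounds[i] + 1, bounds[i + 1]
                if s > e:  # very short gene with many exons
                    s = e
                fh.write(f"{g.scaffold_id}\txenosynt\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}.e{i+1};Parent={g.gene_id}\n")
        fh.write("###\n")


# ---------------------------------------------------------------------------
# Homology hit tables (outfmt 6 + taxon_group + taxon_name)

_HIT_COLS = 14


def read_hits(path) -> list[HomologyHit]:
    """Read a 12-column BLAST/DIAMOND tabular file with two appended columns.

    E-values are parsed as floats (scientific notation included); a zero
    E-value is clamped to ``EVALUE_FLOOR``. ``taxon_group`` must be
    ``metazoan`` or ``non_metazoan``.
    """
    hits: list[HomologyHit] = []
    declared: int | None = None
    saw_end = False
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# records="):
                    declared = int(line.split("=", 1)[1])
                elif line == "# end":
                    saw_end = True
                else:
                    raise FormatError(f"{path}:{lineno}: unrecognised comment line")
                continue
            cols = line.split("\t")
            if len(cols) != _HIT_COLS:
                raise FormatError(f"{path}:{lineno}: expected {_HIT_COLS} columns, got {len(cols)}")
            try:
                evalue = float(cols[10])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: unparsable evalue {cols[10]!r}") from None
            if evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative evalue")
            if evalue == 0.0:
                evalue = EVALUE_FLOOR
            group = cols[12]
            if group not in TAXON_GROUPS:
                raise FormatError(f"{path}:{lineno}: taxon_group must be one of {TAXON_GROUPS}, got {group!r}")
            try:
                hits.append(HomologyHit(
                    cols[0], cols[1], float(cols[2]), int(cols[3]), int(cols[4]),
                    int(cols[5]), int(cols[6]), int(cols[7]), int(cols[8]), int(cols[9]),
                    evalue, float(cols[11]), group, cols[13]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    if declared is not None:
        if declared != len(hits):
            raise FormatError(f"{path}: declares {declared} rows, found {len(hits)} (truncated?)")
        if not saw_end:
            raise FormatError(f"{path}: missing end-of-data marker (truncated?)")
    return hits


def write_hits(hits: list[HomologyHit], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"# records={len(hits)}\n")
        for h in hits:
            fh.write("\t".join(str(v) for v in (
                h.query_id, h.subject_id, f"{h.pident:.1f}", h.length, h.mismatch,
                h.gapopen, h.qstart, h.qend, h.sstart, h.send,
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}", h.taxon_group, h.taxon_name)) + "\n")
        fh.write("# end\n")


# ---------------------------------------------------------------------------
# Orthogroups (OrthoFinder Orthogroups.tsv dialect)

def read_orthogroups(path) -> OrthogroupMap:
    """Read an OrthoFinder-style table: first column orthogroup id, one column
    per species, comma-separated gene ids. A gene in two orthogroups is a
    format error; genes absent from the table are species-specific."""
    declared: int | None = None
    assignments: dict[str, str] = {}
    members: dict[str, dict[str, list[str]]] = {}
    with _open_text(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise FormatError(f"{path}: empty orthogroup table")
    body = []
    saw_end = False
    for l in lines:
        if l.startswith("# records="):
            declared = int(l.split("=", 1)[1])
        elif l == "# end":
            saw_end = True
        elif l.startswith("#"):
            raise FormatError(f"{path}: unrecognised comment line {l!r}")
        else:
            body.append(l)
    if not body:
        raise FormatError(f"{path}: orthogroup table has no header")
    header = body[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: orthogroup table needs at least one species column")
    species = header[1:]
    for lineno, line in enumerate(body[1:], 2):
        cols = line.split("\t")
        if len(cols) != len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} columns, got {len(cols)}")
        og = cols[0]
        if og in members:
            raise FormatError(f"{path}:{lineno}: duplicate orthogroup {og}")
        members[og] = {}
        for sp, cell in zip(species, cols[1:]):
            genes = [g.strip() for g in cell.split(",") if g.strip()]
            members[og][sp] = genes
            for g in genes:
                if g in assignments:
                    raise FormatError(f"{path}:{lineno}: gene {g} listed in {assignments[g]} and {og}")
                assignments[g] = og
    if declared is not None:
        if declared != len(members):
            raise FormatError(f"{path}: declares {declared} orthogroups, found {len(members)} (truncated?)")
        if not saw_end:
            raise FormatError(f"{path}: missing end-of-data marker (truncated?)")
    return OrthogroupMap(assignments, species, members)


def write_orthogroups(omap: OrthogroupMap, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"# records={len(omap.members)}\n")
        fh.write("Orthogroup\t" + "\t".join(omap.species) + "\n")
        for og in omap.members:
            cells = [", ".join(omap.members[og].get(sp, [])) for sp in omap.species]
            fh.write(og + "\t" + "\t".join(cells) + "\n")
        fh.write("# end\n")


# ---------------------------------------------------------------------------
# Expression matrices (TPM, genes x samples)

def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expression table has no sample columns")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"# records={df.shape[0]}\n")
        df.to_csv(fh, sep="\t", index_label="gene_id")
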