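"""Annotated-genome I/O and descriptive genome statistics.

Genomes are circular (or linear) dsDNA molecules carrying an ordered list of
protein-coding features.  Coordinates are 1-based inclusive throughout, the
GenBank convention; a CDS that spans the origin of a circular genome is kept
as a single feature with ``wraps_origin`` set and ``end < start``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord
from Bio.Data.CodonTable import standard_dna_table

STOP_CODONS = set(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)


class GenomeIOError(ValueError):
    """Raised on malformed genome input."""


@dataclass
class CdsFeature:
    """One protein-coding feature.

    ``start``/``end`` are 1-based inclusive on the forward strand.  For an
    origin-spanning CDS on a circular genome ``wraps_origin`` is True and the
    feature runs start..L then 1..end.
    """

    cds_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    protein: str
    wraps_origin: bool = False
    product: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeIOError(f"bad strand {self.strand!r} for {self.cds_id}")
        if len(self.protein) < 1:
            raise GenomeIOError(f"empty protein for {self.cds_id}")

    def nt_span(self, genome_length: int) -> int:
        if self.wraps_origin:
            return (genome_length - self.start + 1) + self.end
        return self.end - self.start + 1

    def spans(self, genome_length: int) -> list[tuple[int, int]]:
        """Forward-strand intervals covered (1-based inclusive)."""
        if self.wraps_origin:
            return [(self.start, genome_length), (1, self.end)]
        return [(self.start, self.end)]


@dataclass
class AnnotatedGenome:
    genome_id: str
    sequence: str
    topology: str = "circular"  # or "linear"
    features: list[CdsFeature] = field(default_factory=list)
    source_accession: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeIOError(f"{self.genome_id}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise GenomeIOError(f"{self.genome_id}: bad topology {self.topology}")
        seen = set()
        L = len(self.sequence)
        for f in self.features:
            if f.cds_id in seen:
                raise GenomeIOError(f"duplicate cds_id {f.cds_id}")
            seen.add(f.cds_id)
            if not (1 <= f.start <= L and 1 <= f.end <= L):
                raise GenomeIOError(f"{f.cds_id}: coordinates outside genome")
            if f.wraps_origin and self.topology != "circular":
                raise GenomeIOError(f"{f.cds_id}: wrapped CDS on linear genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def cds_nucleotides(self, f: CdsFeature) -> str:
        """Spliced, strand-corrected coding sequence of a feature."""
        if f.wraps_origin:
            nt = self.sequence[f.start - 1 :] + self.sequence[: f.end]
        else:
            nt = self.sequence[f.start - 1 : f.end]
        if f.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        return nt

    def proteins(self) -> dict[str, str]:
        return {f.cds_id: f.protein for f in self.features}


@dataclass
class GenomeStats:
    genome_id: str
    length_bp: int
    gc_overall: float
    gc_coding: float
    gc_noncoding: float
    n_cds: int
    n_plus: int
    n_minus: int
    gene_density: float  # genes per kbp
    coding_density: float  # percent of bases under >=1 CDS
    orf_len_min: int  # amino acids
    orf_len_max: int
    orf_len_mean: float


@dataclass
class UsageTable:
    genome_id: str
    codon_counts: dict[str, int]
    codon_freq: dict[str, dict[str, float]]  # aa -> codon -> rel freq
    aa_freq: dict[str, float]
    n_ambiguous: int = 0  # codons containing N, excluded from counts


# ---------------------------------------------------------------------------
# reading


def _translate_cds(nt: str) -> str:
    prot = str(Seq(nt).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read one annotated genome from a GenBank flat file.

    Translations are taken from the record's ``/translation`` qualifier when
    present, otherwise derived with the standard genetic code.  Compound
    (join) locations whose parts bracket the origin of a circular genome are
    normalized into a single wrapped feature.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # malformed file
        raise GenomeIOError(f"cannot parse GenBank file {path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise GenomeIOError(f"{path}: record has no usable sequence")
    topology = record.annotations.get("topology", "linear")
    genome = AnnotatedGenome(
        genome_id=record.id or record.name,
        sequence=seq,
        topology="circular" if topology == "circular" else "linear",
        features=[],
        source_accession=record.id,
    )
    L = len(seq)
    n = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        n += 1
        cds_id = (
            feat.qualifiers.get("locus_tag", [None])[0]
            or feat.qualifiers.get("protein_id", [None])[0]
            or feat.qualifiers.get("gene", [None])[0]
            or f"CDS_{n:04d}"
        )
        strand = "-" if feat.location.strand == -1 else "+"
        wraps = False
        if isinstance(feat.location, CompoundLocation):
            parts = sorted(feat.location.parts, key=lambda p: int(p.start))
            # wrapped iff one part ends at L and another starts at 1
            if len(parts) == 2 and int(parts[1].end) == L and int(parts[0].start) == 0:
                wraps = True
                start = int(parts[1].start) + 1
                end = int(parts[0].end)
            else:
                start = int(feat.location.start) + 1
                end = int(feat.location.end)
        else:
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
        nt = str(feat.extract(record.seq)).upper()
        given = feat.qualifiers.get("translation", [None])[0]
        if given:
            protein = given
            if "*" in protein.rstrip("*"):
                warnings.warn(
                    f"{cds_id}: provided translation contains internal stop; kept",
                    stacklevel=2,
                )
        else:
            protein = _translate_cds(nt)
        product = feat.qualifiers.get("product", [None])[0]
        genome.features.append(
            CdsFeature(
                cds_id=cds_id,
                start=start,
                end=end,
                strand=strand,
                protein=protein,
                wraps_origin=wraps,
                product=product,
            )
        )
    if not genome.features:
        raise GenomeIOError(f"{path}: no CDS features")
    return AnnotatedGenome(
        genome_id=genome.genome_id,
        sequence=genome.sequence,
        topology=genome.topology,
        features=genome.features,
        source_accession=genome.source_accession,
    )


def read_fasta_gff(
    fasta: str | Path, gff: str | Path, protein_fasta: str | Path | None = None
) -> AnnotatedGenome:
    """Read a genome from FASTA + GFF3 CDS features.

    An optional protein FASTA (ids matching the GFF3 ``ID`` attributes)
    overrides the standard-code translation.
    """
    recs = list(SeqIO.parse(str(fasta), "fasta"))
    if len(recs) != 1:
        raise GenomeIOError(f"{fasta}: expected exactly one sequence")
    seq = str(recs[0].seq).upper()
    overrides: dict[str, str] = {}
    if protein_fasta is not None:
        overrides = {r.id: str(r.seq) for r in SeqIO.parse(str(protein_fasta), "fasta")}
    genome = AnnotatedGenome(
        genome_id=recs[0].id, sequence=seq, topology="linear", features=[]
    )
    feats = []
    n = 0
    for line in Path(gff).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9 or cols[2] != "CDS":
            continue
        n += 1
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
        )
        cds_id = attrs.get("ID", f"CDS_{n:04d}")
        start, end, strand = int(cols[3]), int(cols[4]), cols[6]
        f = CdsFeature(cds_id, start, end, strand, protein="M", product=attrs.get("product"))
        nt = genome.cds_nucleotides(
            CdsFeature(cds_id, start, end, strand, protein="M")
        )
        f.protein = overrides.get(cds_id) or _translate_cds(nt)
        feats.append(f)
    if not feats:
        raise GenomeIOError(f"{gff}: no CDS features")
    return AnnotatedGenome(
        genome_id=genome.genome_id, sequence=seq, topology="linear", features=feats
    )


# ---------------------------------------------------------------------------
# writing


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write a genome as a GenBank flat file (round-trips with read_genbank)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.genome_id,
        name=genome.genome_id[:16].replace("|", "_"),
        description=f"{genome.genome_id} annotated genome",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = genome.topology
    record.annotations["date"] = "01-JAN-2016"  # fixed for determinism
    L = len(genome.sequence)
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps_origin:
            parts = [
                SimpleLocation(f.start - 1, L, strand),
                SimpleLocation(0, f.end, strand),
            ]
            if strand == -1:
                parts = parts[::-1]
            loc = CompoundLocation(parts)
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals = {"locus_tag": [f.cds_id], "translation": [f.protein]}
        if f.product:
            quals["product"] = [f.product]
        record.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
    handle = path if hasattr(path, "write") else str(path)
    SeqIO.write([record], handle, "genbank")


def write_protein_fasta(
    genomes: Iterable[AnnotatedGenome], path: str | Path
) -> None:
    """Write all proteins, headers ``genomeID|cdsID``."""
    with open(path, "w") as fh:
        for g in genomes:
            for f in g.features:
                fh.write(f">{g.genome_id}|{f.cds_id}\n{f.protein}\n")


def write_stats_tsv(stats: Iterable[GenomeStats], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([vars(s) for s in stats]).to_csv(path, sep="\t", index=False)


def write_usage_tsv(tables: Iterable[UsageTable], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for t in tables:
        for codon, n in sorted(t.codon_counts.items()):
            aa = CODON_TO_AA.get(codon, "*")
            rows.append(
                {
                    "genome_id": t.genome_id,
                    "codon": codon,
                    "aa": aa,
                    "count": n,
                    "codon_freq": t.codon_freq.get(aa, {}).get(codon, float("nan")),
                    "aa_freq": t.aa_freq.get(aa, float("nan")),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# statistics


def _gc(seq: str) -> float:
    if not seq:
        return float("nan")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def _coding_union(genome: AnnotatedGenome) -> list[tuple[int, int]]:
    """Merged forward-strand intervals covered by >=1 CDS (1-based incl.)."""
    ivs: list[tuple[int, int]] = []
    for f in genome.features:
        ivs.extend(f.spans(len(genome)))
    ivs.sort()
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def compute_stats(genome: AnnotatedGenome) -> GenomeStats:
    """Descriptive statistics: G+C (overall and coding vs non-coding),
    strand distribution, gene and coding density, ORF length summary.

    Overlapping CDS count each genomic base once; G+C is computed on the
    forward strand.
    """
    if not genome.features:
        raise GenomeIOError("genome has no CDS")
    L = len(genome)
    union = _coding_union(genome)
    coding_bases = sum(b - a + 1 for a, b in union)
    coding_seq = "".join(genome.sequence[a - 1 : b] for a, b in union)
    mask = bytearray(L)
    for a, b in union:
        for i in range(a - 1, b):
            mask[i] = 1
    noncoding_seq = "".join(
        ch for ch, m in zip(genome.sequence, mask) if not m
    )
    lens = [len(f.protein) for f in genome.features]
    n_plus = sum(1 for f in genome.features if f.strand == "+")
    return GenomeStats(
        genome_id=genome.genome_id,
        length_bp=L,
        gc_overall=_gc(genome.sequence),
        gc_coding=_gc(coding_seq),
        gc_noncoding=_gc(noncoding_seq),
        n_cds=len(genome.features),
        n_plus=n_plus,
        n_minus=len(genome.features) - n_plus,
        gene_density=len(genome.features) / (L / 1000.0),
        coding_density=100.0 * coding_bases / L,
        orf_len_min=min(lens),
        orf_len_max=max(lens),
        orf_len_mean=sum(lens) / len(lens),
    )


def usage_profile(genome: AnnotatedGenome) -> UsageTable:
    """Codon and amino-acid usage over all CDS.

    Stop codons are excluded from the amino-acid frequencies; codons
    containing N are excluded from all counts and tallied separately.
    """
    codon_counts: dict[str, int] = {}
    n_ambiguous = 0
    for f in genome.features:
        nt = genome.cds_nucleotides(f)
        for i in range(0, len(nt) - len(nt) % 3, 3):
            codon = nt[i : i + 3]
            if "N" in codon:
                n_ambiguous += 1
                continue
            codon_counts[codon] = codon_counts.get(codon, 0) + 1
    aa_counts: dict[str, int] = {}
    for codon, n in codon_counts.items():
        aa = CODON_TO_AA.get(codon)
        if aa is None:  # stop
            continue
        aa_counts[aa] = aa_counts.get(aa, 0) + n
    total_aa = sum(aa_counts.values())
    aa_freq = {aa: n / total_aa for aa, n in aa_counts.items()}
    codon_freq: dict[str, dict[str, float]] = {}
    for aa, codons in AA_TO_CODONS.items():
        counts = {c: codon_counts.get(c, 0) for c in codons}
        tot = sum(counts.values())
        if tot:
            codon_freq[aa] = {c: n / tot for c, n in counts.items()}
    return UsageTable(
        genome_id=genome.genome_id,
        codon_counts=codon_counts,
        codon_freq=codon_freq,
        aa_freq=aa_freq,
        n_ambiguous=n_ambiguous,
    )
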