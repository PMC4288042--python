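"""File formats: FASTA, GFF3, headered TSV, hit tables, reactions.

Every tabular output starts with ``#``-prefixed metadata lines (tool
version, seed, parameter digest) so a run is traceable from its files
alone; readers skip those lines transparently.
"""

from __future__ import annotations

import hashlib
import json
from fractions import Fraction
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .abundance import HitRecord
from .curation import GeneCall
from .energetics import Reaction, Species, ThermoTable
from .synthetic import Contig

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_tsv",
    "read_tsv",
    "write_truth",
    "read_truth",
    "write_hit_table",
    "read_hit_table",
    "write_reactions",
    "read_reactions",
    "write_thermo_table",
    "read_thermo_table",
    "metadata_header",
    "params_digest",
]


def params_digest(params: dict) -> str:
    """Short stable digest of a parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def metadata_header(seed=None, params: dict | None = None) -> list[str]:
    lines = [f"# sulfomics {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if params is not None:
        lines.append(f"# params={params_digest(params)}")
    return lines


# ---------------------------------------------------------------- FASTA

def write_fasta(contigs, path) -> None:
    """Contigs to FASTA; depth and truth ride along in the description."""
    records = []
    for c in contigs:
        desc = f"depth={c.depth:.4f} genome={c.genome_id}" if isinstance(c, Contig) else ""
        records.append(SeqRecord(Seq(c.sequence), id=c.contig_id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[Contig]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        depth = 1.0
        genome = ""
        for tok in rec.description.split():
            if tok.startswith("depth="):
                depth = float(tok[6:])
            elif tok.startswith("genome="):
                genome = tok[7:]
        out.append(Contig(contig_id=rec.id, sequence=str(rec.seq).upper(), depth=depth, genome_id=genome))
    return out


# ----------------------------------------------------------------- GFF3

_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def write_gff3(gene_calls, path, seed=None, params=None) -> None:
    """Gene calls as GFF3 (1-based inclusive, strand in column 7); taxon
    labels, scores and marker flags go in column-9 attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in metadata_header(seed, params):
            fh.write(line + "\n")
        for g in gene_calls:
            attrs = [
                f"ID={g.gene_id}",
                f"function={g.function_label}",
                f"taxon_class={g.best_hit_taxon_class}",
                f"taxon_genus={g.best_hit_taxon_genus}",
                f"evalue={g.evalue:g}",
                f"bit_score={g.bit_score:g}",
                f"query_coverage={g.query_coverage:g}",
            ]
            if g.is_marker is not None:
                attrs.append(f"marker={g.is_marker}")
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "sulfomics",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[GeneCall]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            out.append(
                GeneCall(
                    gene_id=attrs.get("ID", f"{cols[0]}:{cols[3]}-{cols[4]}"),
                    contig_id=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    function_label=attrs.get("function", "hyp"),
                    best_hit_taxon_class=attrs.get("taxon_class", ""),
                    best_hit_taxon_genus=attrs.get("taxon_genus", ""),
                    evalue=float(attrs.get("evalue", 1e-30)),
                    bit_score=float(attrs.get("bit_score", 200.0)),
                    query_coverage=float(attrs.get("query_coverage", 1.0)),
                    is_marker=attrs.get("marker"),
                )
            )
    return out


# ------------------------------------------------------------------ TSV

def write_tsv(df: pd.DataFrame, path, seed=None, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in metadata_header(seed, params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_truth(truth: dict, path, seed=None) -> None:
    df = pd.DataFrame(sorted(truth.items()), columns=["contig_id", "genome_id"])
    write_tsv(df, path, seed=seed)


def read_truth(path) -> dict:
    df = read_tsv(path)
    return dict(zip(df["contig_id"], df["genome_id"]))


# ------------------------------------------------------------ hit table

_OUTFMT6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
_HIT_COLS = _OUTFMT6_COLS + ["taxon_class", "taxon_genus"]


def write_hit_table(records, path, seed=None) -> None:
    """12-column BLAST-tabular-like layout plus two appended taxon columns.

    The ``length`` column holds the query gene length and ``qstart..qend``
    the aligned span, so query coverage is recoverable as
    (qend-qstart+1)/length (up to 1 bp of rounding).
    """
    rows = []
    for r in records:
        qend = max(1, round(r.query_coverage * r.gene_length))
        rows.append(
            [
                r.query_id, r.gene_family, 90.0, r.gene_length, 0, 0,
                1, qend, 1, qend, r.evalue, r.bit_score,
                r.subject_taxon_class, r.subject_taxon_genus,
            ]
        )
    write_tsv(pd.DataFrame(rows, columns=_HIT_COLS), path, seed=seed)


def read_hit_table(path) -> list[HitRecord]:
    df = read_tsv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            HitRecord(
                query_id=str(row.qseqid),
                gene_family=str(row.sseqid),
                subject_taxon_class=str(row.taxon_class),
                subject_taxon_genus=str(row.taxon_genus),
                evalue=float(row.evalue),
                bit_score=float(row.bitscore),
                query_coverage=min(1.0, (row.qend - row.qstart + 1) / row.length),
                gene_length=int(row.length),
            )
        )
    return out


# ---------------------------------------------- reactions / thermo table

def write_reactions(reactions, path) -> None:
    """One reaction per record: ``label<TAB>species:coeff,...<TAB>notes``;
    coefficients are signed rationals (reactants negative)."""
    with open(path, "w") as fh:
        fh.write("# sulfomics reaction set; coefficients are signed rationals\n")
        fh.write("label\tstoichiometry\tnotes\n")
        for r in reactions:
            st = ",".join(f"{s}:{Fraction(c).limit_denominator(10**6)}" for s, c in r.stoichiometry.items())
            fh.write(f"{r.label}\t{st}\t{r.notes}\n")


def read_reactions(path) -> list[Reaction]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip() or line.startswith("label\t"):
                continue
            label, st, *rest = line.rstrip("\n").split("\t")
            stoich = {}
            for tok in st.split(","):
                name, coeff = tok.rsplit(":", 1)
                stoich[name] = Fraction(coeff)
            out.append(Reaction(label, stoich, rest[0] if rest else ""))
    return out


def write_thermo_table(table: ThermoTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sulfomics thermo table; provenance: {table.provenance}\n")
        fh.write("name\telements\tcharge\tdgf0_kj_mol\n")
        for sp in table.species.values():
            el = ",".join(f"{e}:{n}" for e, n in sp.elements.items())
            fh.write(f"{sp.name}\t{el}\t{sp.charge}\t{sp.dgf0}\n")


def read_thermo_table(path) -> ThermoTable:
    provenance = ""
    species = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "provenance:" in line:
                    provenance = line.split("provenance:", 1)[1].strip()
                continue
            if not line.strip() or line.startswith("name\t"):
                continue
            name, el, charge, dgf0 = line.rstrip("\n").split("\t")
            elements = {}
            if el:
                for tok in el.split(","):
                    e, n = tok.split(":")
                    elements[e] = int(n)
            species[name] = Species(name, elements, int(charge), float(dgf0))
    return ThermoTable(species=species, provenance=provenance)
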