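"""Shared readers/writers and packaged reference tables.

Conventions: genomic intervals are 1-based inclusive in memory; BED output is
0-based half-open; FASTA goes through Biopython. Tab-separated outputs carry a
``# config_sha256=`` comment so any file can be traced to the configuration
that produced it.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------------------
# Packaged tables (published printed values used as inputs)
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("ervrip.data").joinpath(name)


def load_cd36_primers() -> dict:
    """Published primer triplet for the CD36-intronic ERV presence/absence assay."""
    df = pd.read_csv(_data_path("cd36_primers.tsv"), sep="\t")
    return dict(zip(df["name"], df["sequence"]))


def load_erv_intervals() -> pd.DataFrame:
    """Published 1-based inclusive coordinates of carrier elements and the host gene."""
    return pd.read_csv(_data_path("erv_intervals.tsv"), sep="\t")


def load_breed_genotype_counts() -> pd.DataFrame:
    """Genotype counts (n=24 per breed) back-calculated from the published
    six-breed survey percentages at the CD36-intronic ERV locus."""
    return pd.read_csv(_data_path("breed_genotype_counts.tsv"), sep="\t")


# ---------------------------------------------------------------------------
# Config hashing
# ---------------------------------------------------------------------------


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _comment_header(config: Mapping | None) -> str:
    if config is None:
        return ""
    return f"# config_sha256={config_hash(config)}\n"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(path, genome: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genomes(outdir, genomes: Mapping[str, Mapping[str, str]]) -> None:
    """One multi-FASTA per genome, named ``<genome_id>.fa``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gid, seqs in genomes.items():
        write_fasta(outdir / f"{gid}.fa", seqs)


# ---------------------------------------------------------------------------
# Truth tables, populations, loci
# ---------------------------------------------------------------------------


def write_truth(prefix, truth: pd.DataFrame, specs=None, config=None) -> None:
    """Planted-insertion ground truth as BED (0-based half-open, name =
    genome_id) plus a JSON sidecar with full plant provenance."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bed"), "w") as fh:
        fh.write(_comment_header(config))
        for _, row in truth.iterrows():
            fh.write(
                f"{row.chrom}\t{row.position - 1}\t{row.position}\t"
                f"{row.genome_id}\t{row.element_length}\t{row.strand}\n"
            )
    sidecar = {
        "records": truth.to_dict(orient="records"),
        "specs": [s.__dict__ if hasattr(s, "__dict__") else dict(s._asdict()) for s in specs]
        if specs
        else None,
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, default=str)


def read_truth_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            rows.append(
                {
                    "genome_id": name,
                    "chrom": chrom,
                    "position": int(start) + 1,
                    "strand": strand.strip(),
                    "element_length": int(score),
                }
            )
    return pd.DataFrame(rows)


def write_tsv(path, df: pd.DataFrame, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(config))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_population_tsv(path, population: pd.DataFrame, config=None) -> None:
    write_tsv(path, population, config=config)


# ---------------------------------------------------------------------------
# RIP loci as BED / VCF
# ---------------------------------------------------------------------------


def loci_to_bed(path, loci, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(config))
        for i, locus in enumerate(loci):
            fh.write(
                f"{locus.ref_chrom}\t{locus.ref_start - 1}\t{locus.ref_end}\t"
                f"RIP{i + 1}\t{len(locus.members)}\t{locus.strand}\n"
            )


def loci_to_vcf(path, loci, contig_lengths: Mapping[str, int], family="ERV") -> None:
    """Symbolic mobile-element insertion records (VCF 4.2, ALT=<INS:ME:ERV>)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=INS:ME:ERV,Description="ERV insertion">\n')
        fh.write('##INFO=<ID=FAMILY,Number=1,Type=String,Description="ERV family">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Insertion length">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Carrier genomes">\n')
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, locus in enumerate(loci):
            info = (
                f"FAMILY={family};SVLEN={getattr(locus, 'element_length', 0)};"
                f"SUPPORT={len(locus.members)}"
            )
            fh.write(
                f"{locus.ref_chrom}\t{locus.ref_start}\tRIP{i + 1}\tN\t<INS:ME:ERV>\t"
                f".\tPASS\t{info}\n"
            )


def presence_matrix_tsv(path, loci, config=None) -> None:
    """Rows = loci, columns = genomes, values 1 (present) / 0 (absent) / . (unknown)."""
    genome_ids = sorted({g for locus in loci for g in locus.presence})
    code = {"present": "1", "absent": "0", "unknown": "."}
    with open(path, "w") as fh:
        fh.write(_comment_header(config))
        fh.write("locus\t" + "\t".join(genome_ids) + "\n")
        for i, locus in enumerate(loci):
            vals = [code[locus.presence.get(g, "unknown")] for g in genome_ids]
            fh.write(f"RIP{i + 1}\t" + "\t".join(vals) + "\n")
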