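"""Reading and writing the on-disk formats: FASTA, TSV tables, Newick.

Marker multi-FASTA records are identified as ``<strain>|<marker>``; genome
and proteome FASTA files are one file per strain.  All tables are
tab-separated.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mlsa import MARKER_ORDER, MarkerProfile
from .pocp import Proteome

__all__ = [
    "read_fasta",
    "write_fasta",
    "profiles_from_fasta",
    "profiles_to_fasta",
    "read_genome_fasta",
    "read_proteome_fasta",
    "read_meta_tsv",
    "write_clade",
    "read_measures_tsv",
]


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def profiles_from_fasta(path) -> list[MarkerProfile]:
    """Parse a marker multi-FASTA with ``<strain>|<marker>`` record ids."""
    seqs: dict[str, dict[str, str]] = {}
    for rid, seq in read_fasta(path):
        if "|" not in rid:
            raise ValueError(f"marker record id {rid!r} lacks '<strain>|<marker>'")
        strain, marker = rid.rsplit("|", 1)
        if marker not in MARKER_ORDER:
            raise ValueError(f"unknown marker {marker!r} in record {rid!r}")
        seqs.setdefault(strain, {})[marker] = seq
    return [MarkerProfile(s, m) for s, m in sorted(seqs.items())]


def profiles_to_fasta(profiles: list[MarkerProfile], path) -> None:
    records = []
    for p in profiles:
        for m in MARKER_ORDER:
            if m in p.sequences:
                records.append((f"{p.strain_id}|{m}", p.sequences[m]))
    write_fasta(records, path)


def read_genome_fasta(path) -> list[tuple[str, str]]:
    """Genome records; callers fragment per record, never across."""
    records = read_fasta(path)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_proteome_fasta(path, strain_id: str | None = None) -> Proteome:
    records = read_fasta(path)
    sid = strain_id or Path(path).stem
    return Proteome(sid, records)


def read_meta_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"strain_id", "species_name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table lacks columns {sorted(missing)}")
    return df


def read_measures_tsv(path) -> pd.DataFrame:
    """Long-format pair measures: strain_a, strain_b, metric, value[, provenance]."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain_a", "strain_b", "metric", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measures table lacks columns {sorted(missing)}")
    return df


def write_clade(clade, outdir) -> None:
    """Serialize a simulated clade: FASTA per leaf, markers, tree, truth."""
    out = Path(outdir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "proteomes").mkdir(parents=True, exist_ok=True)
    for leaf in clade.leaves():
        write_fasta([(leaf, clade.genomes[leaf])], out / "genomes" / f"{leaf}.fasta")
        write_fasta(clade.proteomes[leaf], out / "proteomes" / f"{leaf}.faa")
    profiles_to_fasta([clade.markers[l] for l in clade.leaves()], out / "markers.fasta")
    (out / "tree.nwk").write_text(clade.tree_newick + "\n")
    rows = [
        {"strain_a": a, "strain_b": b, "expected_distance": d}
        for (a, b), d in sorted(clade.truth_distances.items())
    ]
    pd.DataFrame(rows).to_csv(out / "truth_distances.tsv", sep="\t", index=False)
    if clade.truth_partition:
        rows = [
            {"strain_id": leaf, "rank": rank, "cluster": label}
            for rank, assign in clade.truth_partition.items()
            for leaf, label in sorted(assign.items())
        ]
        pd.DataFrame(rows).to_csv(out / "truth_partition.tsv", sep="\t", index=False)
    cfg = clade.config
    (out / "config.json").write_text(
        json.dumps(
            {
                "seed": cfg.seed,
                "n_genes": cfg.n_genes,
                "gene_length_codons": list(cfg.gene_length_codons),
                "marker_lengths": cfg.marker_lengths,
                "marker_rate_multipliers": cfg.marker_rate_multipliers,
                "gene_loss_prob_per_unit_branch": cfg.gene_loss_prob_per_unit_branch,
                "gene_gain_rate_per_unit_branch": cfg.gene_gain_rate_per_unit_branch,
                "spacer_length": cfg.spacer_length,
                "tree": cfg.tree,
            },
            indent=2,
        )
    )
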