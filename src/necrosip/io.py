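"""Readers and writers for the pipeline's tabular and sequence formats.

All tables are plain TSV/CSV with explicit headers; missing values are
written as empty fields.  Sequence data go through Biopython FASTA.  A
minimal reader for the BIOM 1.0 JSON dialect (dense and sparse) covers OTU
tables exported by other tools.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .decompose import AbundanceTables, TAXONOMY_RANKS
from .gradient import FractionRecord, GradientProfile
from .traits import BLAST_TABULAR_COLUMNS, GenomeRecord

__all__ = [
    "read_otu_table", "write_otu_table",
    "read_taxonomy", "write_taxonomy",
    "read_qpcr", "write_qpcr",
    "read_sample_meta", "write_sample_meta",
    "read_fasta", "write_fasta",
    "read_fraction_table", "write_fraction_table",
    "read_decomposition_table", "write_decomposition_table",
    "read_blast_tabular",
    "read_biom_json",
    "read_genome_db", "write_genome_db",
    "load_abundance_tables",
]


def write_otu_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="otu_id")


def read_otu_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "otu_id"
    return df


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index_label="otu_id")


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [r for r in TAXONOMY_RANKS if r not in df.columns]
    if missing:
        raise ValueError(f"taxonomy file {path}: missing rank columns {missing}")
    return df


def write_qpcr(qpcr: pd.Series, sample_meta: pd.DataFrame, path) -> None:
    out = sample_meta[["timepoint_day", "replicate", "fraction_class"]].copy()
    out["copies_per_g"] = qpcr
    out.to_csv(path, index_label="sample_id")


def read_qpcr(path) -> pd.Series:
    df = pd.read_csv(path, index_col="sample_id")
    if "copies_per_g" not in df.columns:
        raise ValueError(f"qPCR file {path}: missing column 'copies_per_g'")
    return df["copies_per_g"].astype(float)


def write_sample_meta(sample_meta: pd.DataFrame, path) -> None:
    sample_meta.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    for col in ("timepoint_day", "replicate", "fraction_class", "treatment"):
        if col not in df.columns:
            raise ValueError(f"sample metadata file {path}: missing column {col!r}")
    return df


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fraction_table(profiles: list[GradientProfile], path) -> None:
    rows = [
        {"tube_id": p.tube_id, "fraction_id": f.fraction_id,
         "density_g_ml": f.density, "dna_ng": f.dna_amount}
        for p in profiles for f in p.fractions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fraction_table(path) -> list[GradientProfile]:
    df = pd.read_csv(path, sep="\t")
    for col in ("tube_id", "fraction_id", "density_g_ml", "dna_ng"):
        if col not in df.columns:
            raise ValueError(f"fraction table {path}: missing column {col!r}")
    profiles = []
    for tube, grp in df.groupby("tube_id", sort=False):
        fractions = [
            FractionRecord(str(r.fraction_id), float(r.density_g_ml), float(r.dna_ng))
            for r in grp.itertuples()
        ]
        profiles.append(GradientProfile(fractions, tube_id=str(tube)))
    return profiles


def write_decomposition_table(dtable: pd.DataFrame, path) -> None:
    out = dtable.copy()
    out["d_reps"] = out["d_reps"].map(lambda v: ",".join(f"{x:.10g}" for x in v))
    out.to_csv(path, sep="\t", index=False)


def read_decomposition_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["d_reps"] = df["d_reps"].map(
        lambda s: [float(x) for x in str(s).split(",")] if isinstance(s, str) and s else []
    )
    df["significant"] = df["significant"].astype("boolean")
    return df


def read_blast_tabular(path) -> pd.DataFrame:
    """12-column blast-tabular (outfmt-6 dialect) hit table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != len(BLAST_TABULAR_COLUMNS):
        raise ValueError(
            f"blast tabular file {path}: expected {len(BLAST_TABULAR_COLUMNS)} columns, "
            f"got {df.shape[1]}"
        )
    df.columns = BLAST_TABULAR_COLUMNS
    return df


def read_biom_json(path) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """OTU counts (and taxonomy, when present) from a BIOM 1.0 JSON file.

    Supports dense and sparse matrix types; observation metadata with a
    ``taxonomy`` list is converted to the 7-rank taxonomy table (shorter
    lineages are padded with empty strings).
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("rows", "columns", "data", "shape", "matrix_type"):
        if key not in doc:
            raise ValueError(f"BIOM file {path}: missing key {key!r}")
    n_obs, n_samp = doc["shape"]
    obs_ids = [r["id"] for r in doc["rows"]]
    samp_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((n_obs, n_samp))
    if doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise ValueError(f"BIOM file {path}: unsupported matrix_type {doc['matrix_type']!r}")
    counts = pd.DataFrame(mat, index=pd.Index(obs_ids, name="otu_id"), columns=samp_ids)

    taxonomy = None
    if all(isinstance(r.get("metadata"), dict) and "taxonomy" in r["metadata"] for r in doc["rows"]):
        rows = []
        for r in doc["rows"]:
            lineage = list(r["metadata"]["taxonomy"])[: len(TAXONOMY_RANKS)]
            lineage += [""] * (len(TAXONOMY_RANKS) - len(lineage))
            rows.append(dict(zip(TAXONOMY_RANKS, lineage)))
        taxonomy = pd.DataFrame(rows, index=counts.index)
    return counts, taxonomy


def write_genome_db(db: list[GenomeRecord], meta_path, fasta_path) -> None:
    pd.DataFrame(
        [
            {"genome_id": r.genome_id, "gc": r.gc_content,
             "size_bp": r.genome_size, "db_weight": r.db_weight}
            for r in db
        ]
    ).to_csv(meta_path, sep="\t", index=False)
    write_fasta({r.genome_id: r.marker_seq for r in db}, fasta_path)


def read_genome_db(meta_path, fasta_path) -> list[GenomeRecord]:
    meta = pd.read_csv(meta_path, sep="\t")
    for col in ("genome_id", "gc", "size_bp", "db_weight"):
        if col not in meta.columns:
            raise ValueError(f"genome metadata {meta_path}: missing column {col!r}")
    markers = read_fasta(fasta_path)
    records = []
    for r in meta.itertuples():
        if r.genome_id not in markers:
            raise ValueError(f"genome {r.genome_id}: no marker sequence in {fasta_path}")
        records.append(
            GenomeRecord(
                genome_id=str(r.genome_id), gc_content=float(r.gc),
                genome_size=int(r.size_bp), marker_seq=markers[r.genome_id],
                db_weight=float(r.db_weight),
            )
        )
    return records


def load_abundance_tables(otu_path, taxonomy_path, qpcr_path, meta_path) -> AbundanceTables:
    """Assemble an :class:`AbundanceTables` from the four on-disk tables."""
    counts = read_otu_table(otu_path)
    taxonomy = read_taxonomy(taxonomy_path)
    qpcr = read_qpcr(qpcr_path)
    meta = read_sample_meta(meta_path)
    missing = [s for s in counts.columns if s not in meta.index or s not in qpcr.index]
    if missing:
        raise ValueError(f"samples missing metadata or qPCR entries: {missing}")
    return AbundanceTables(counts=counts, sample_meta=meta.loc[counts.columns],
                           qpcr=qpcr.loc[counts.columns], taxonomy=taxonomy)
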