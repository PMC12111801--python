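"""Readers and writers for the pipeline's plain-text dialects.

Formats: .smi (SMILES + optional id per line), metabolite CSV/TSV,
prediction tables (SwissTargetPrediction-style CSV or TSV), GMT gene sets,
long-form docking score tables, contact tables, and aligned FASTA.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .docking import DockingMatrix
from .enrichment import PathwayAnnotation
from .fingerprint import ResidueContact
from .targets import TargetPrediction


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a .smi file: one 'SMILES [id]' per line; id defaults to the SMILES."""
    entries: list[tuple[str, str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        mid = parts[1] if len(parts) > 1 else smiles
        entries.append((mid, smiles))
    return entries


def read_metabolite_table(path) -> list[tuple[str, str, str]]:
    """CSV/TSV with columns [id, smiles, source] (source optional)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if "source" not in df.columns:
        df["source"] = "reference"
    return [
        (str(r["id"]), str(r["smiles"]), str(r["source"])) for _, r in df.iterrows()
    ]


def read_predictions(path) -> list[TargetPrediction]:
    """Prediction table: TSV with header [metabolite_id, gene_symbol, uniprot,
    probability], or the comma-separated export dialect with quoted names."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, quoting=csv.QUOTE_MINIMAL)
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]
    preds = []
    for _, r in df.iterrows():
        preds.append(
            TargetPrediction(
                metabolite_id=str(r["metabolite_id"]),
                gene_symbol=str(r["gene_symbol"]),
                uniprot=str(r["uniprot"]) if "uniprot" in df.columns and pd.notna(r.get("uniprot")) else None,
                probability=float(r["probability"]) if "probability" in df.columns and pd.notna(r.get("probability")) else None,
            )
        )
    return preds


def write_predictions(preds: Sequence[TargetPrediction], path) -> None:
    pd.DataFrame(
        [
            {
                "metabolite_id": p.metabolite_id,
                "gene_symbol": p.gene_symbol,
                "uniprot": p.uniprot,
                "probability": p.probability,
            }
            for p in preds
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[PathwayAnnotation]:
    annotations = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        pid, name, genes = parts[0], parts[1], parts[2:]
        if pid in seen:
            raise ValueError(f"duplicate pathway id: {pid}")
        seen.add(pid)
        annotations.append(
            PathwayAnnotation(pathway_id=pid, pathway_name=name,
                              genes=frozenset(g for g in genes if g))
        )
    return annotations


def write_gmt(annotations: Sequence[PathwayAnnotation], path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            fh.write("\t".join([ann.pathway_id, ann.pathway_name, *sorted(ann.genes)]) + "\n")


def read_scores(path) -> DockingMatrix:
    """Long-form score table: [ligand_id, receptor_id, score, class, bbb_flag]."""
    df = pd.read_csv(path, sep="\t")
    wide = df.pivot_table(index="ligand_id", columns="receptor_id", values="score",
                          aggfunc="first")
    wide.columns.name = None
    classes = {}
    if "class" in df.columns:
        classes = df.drop_duplicates("ligand_id").set_index("ligand_id")["class"].dropna().to_dict()
    matrix = DockingMatrix(scores=wide, ligand_class={str(k): str(v) for k, v in classes.items()})
    return matrix


def read_bbb_flags(path) -> set[str]:
    df = pd.read_csv(path, sep="\t")
    if "bbb_flag" in df.columns:
        return set(df.loc[df["bbb_flag"].astype(bool), "ligand_id"].astype(str))
    return set()


def write_scores(matrix: DockingMatrix, bbb: Iterable[str], path) -> None:
    long = matrix.long()
    bbb = set(bbb)
    long["class"] = long.pop("ligand_class")
    long["bbb_flag"] = long["ligand_id"].isin(bbb)
    long.to_csv(path, sep="\t", index=False)


def read_contacts(path) -> list[ResidueContact]:
    """Contact table: [ligand_id, receptor_id, author_resnum, residue_name,
    categories] with categories comma-joined."""
    df = pd.read_csv(path, sep="\t")
    contacts = []
    for _, r in df.iterrows():
        raw = r.get("categories")
        cats = frozenset(str(raw).split(",")) if pd.notna(raw) and str(raw) else frozenset({"any"})
        contacts.append(
            ResidueContact(
                ligand_id=str(r["ligand_id"]),
                receptor_id=str(r["receptor_id"]),
                author_resnum=int(r["author_resnum"]),
                residue_name=str(r["residue_name"]),
                categories=cats,
            )
        )
    return contacts


def write_contacts(contacts: Sequence[ResidueContact], path) -> None:
    pd.DataFrame(
        [
            {
                "ligand_id": c.ligand_id,
                "receptor_id": c.receptor_id,
                "author_resnum": c.author_resnum,
                "residue_name": c.residue_name,
                "categories": ",".join(sorted(c.categories)),
            }
            for c in contacts
        ]
    ).to_csv(path, sep="\t", index=False)


def read_aligned_fasta(path) -> dict[str, str]:
    """Aligned FASTA into {id: gapped sequence}, preserving order."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                out[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
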