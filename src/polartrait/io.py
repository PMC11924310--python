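"""Readers and writers for the pipeline's standard formats.

FASTA headers follow the ``taxon|source|habitat[|focal]`` convention so a
sequence carries its habitat label with it; trees are plain newick; all
tables are TSV (tab-separated, UTF-8, '.' decimal) with a header row.
Internal coordinates are 0-based; human-facing reports are 1-based.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caas import HabitatLabel, HomologCluster
from .errors import InvalidDataError, LabelingError


def parse_label_header(header: str) -> HabitatLabel:
    """``taxon|source|habitat[|focal]`` -> HabitatLabel."""
    parts = header.strip().split("|")
    if len(parts) < 3:
        raise LabelingError(
            f"header {header!r} does not follow taxon|source|habitat[|focal]"
        )
    taxon, source, habitat = parts[0], parts[1], parts[2]
    is_focal = len(parts) > 3 and parts[3].lower() == "focal"
    return HabitatLabel(taxon=taxon, habitat=habitat.lower(), source=source.lower(),
                        is_focal=is_focal)


def format_label_header(label: HabitatLabel) -> str:
    base = f"{label.taxon}|{label.source}|{label.habitat}"
    return base + "|focal" if label.is_focal else base


def read_fasta(path) -> tuple[dict[str, str], dict[str, HabitatLabel]]:
    """Labelled sequences from FASTA; wrapped lines and gaps are preserved.

    Returns (taxon -> sequence, taxon -> label).  Duplicate taxa are an
    error; an empty file yields empty mappings.
    """
    sequences: dict[str, str] = {}
    labels: dict[str, HabitatLabel] = {}
    duplicates = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = parse_label_header(rec.id)
        if label.taxon in sequences:
            duplicates.append(label.taxon)
            continue
        sequences[label.taxon] = str(rec.seq).upper()
        labels[label.taxon] = label
    if duplicates:
        raise InvalidDataError(f"duplicate sequence IDs: {sorted(set(duplicates))}")
    return sequences, labels


def write_fasta(path, sequences: dict[str, str], labels: dict[str, HabitatLabel],
                width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=format_label_header(labels[taxon]), description="")
        for taxon, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_cluster(path, cluster_id: str | None = None,
                 tree: dendropy.Tree | None = None) -> HomologCluster:
    """One aligned FASTA file -> HomologCluster (ID defaults to the stem)."""
    path = Path(path)
    sequences, labels = read_fasta(path)
    return HomologCluster(
        cluster_id=cluster_id or path.stem,
        members=sequences,
        labels=labels,
        tree=tree,
    )


def write_cluster(path, cluster: HomologCluster) -> None:
    write_fasta(path, cluster.members, cluster.labels)


def read_newick(path_or_string) -> dendropy.Tree:
    """Newick tree from a file path or a literal newick string."""
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    return dendropy.Tree.get(path=s, schema="newick", preserve_underscores=True)


def write_newick(path, tree: dendropy.Tree) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Reroot at the midpoint of the longest tip-to-tip path (in place)."""
    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(path, table: pd.DataFrame, comment: str | None = None) -> None:
    """TSV with a header row; optional leading '#' comment line."""
    buf = _io.StringIO()
    if comment:
        buf.write(f"# {comment}\n")
    table.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_growth_table(path) -> pd.DataFrame:
    """Growth time-series TSV: strain_id, condition columns, replicate,
    time_d, abundance."""
    df = read_tsv(path)
    required = {"strain_id", "replicate", "time_d", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidDataError(f"growth table missing columns: {sorted(missing)}")
    return df


def load_reference_candidates():
    """The packaged reference candidate table from the comparative
    Arctic-temperate diatom screen.

    Returns (records, annotations): per-position CAAS records rebuilt from
    the printed residue sets, and the annotation table for summary tallies.
    """
    from importlib.resources import files

    from .caas import CAASRecord, classify_origin_specificity

    path = files("polartrait.data") / "reference_candidates.tsv"
    df = pd.read_csv(_io.StringIO(path.read_text()), sep="\t")
    records = []
    for _, row in df.iterrows():
        arctic = frozenset(x.strip() for x in str(row["arctic_aa"]).split(","))
        temperate = frozenset(x.strip() for x in str(row["temperate_aa"]).split(","))
        carriers = {res: [] for res in arctic | temperate}
        records.append(
            CAASRecord(
                cluster_id=str(row["cluster_id"]),
                column=int(row["position"]) - 1,
                arctic_residues=arctic,
                temperate_residues=temperate,
                specificity=classify_origin_specificity(arctic, temperate),
                carriers=carriers,
            )
        )
    annotations = df[["cluster_id", "functional_annotation", "functional_group"]].copy()
    annotations["cluster_id"] = annotations["cluster_id"].astype(str)
    return records, annotations
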