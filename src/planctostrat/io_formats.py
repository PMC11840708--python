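"""Reading and writing of every on-disk artifact used by the pipeline.

Formats: FASTA (via biopython), TSV count/taxonomy/metadata tables,
primer-pair TSV, distance-matrix TSV and ultrametric Newick dendrograms.
All text I/O is UTF-8 and tab-separated; validation is strict and errors
name the offending record.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: IUPAC DNA alphabet accepted everywhere (degenerate codes included).
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: The four depth layers of the study design, shallow to deep.
LAYERS = ("surface", "dcm", "below_dcm", "mesopelagic")

#: Canonical rank order for 7-rank taxonomy strings.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_LAYER_ALIASES = {
    "surface": "surface",
    "dcm": "dcm",
    "below_dcm": "below_dcm",
    "below dcm": "below_dcm",
    "belowdcm": "below_dcm",
    "mesopelagic": "mesopelagic",
}

_SILVA_PREFIX = re.compile(r"^[dpcofgs]__")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the IUPAC alphabet (stored upper-case)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id must be a non-empty token, got {self.id!r}")
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if len(seq) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(seq, start=1):
            if ch not in IUPAC_ALPHABET:
                raise FormatError(
                    f"sequence {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records, preserving file order."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, sequence lines folded at 80 columns."""
    recs = list(records)
    seen: set[str] = set()
    for r in recs:
        if r.id in seen:
            raise FormatError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in recs
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedTaxonomy:
    """Seven ordered rank labels (domain..species); empty string = unknown.

    Once a rank is unknown every deeper rank must be unknown too, so a
    taxonomy is fully described by its known prefix.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(RANKS):
            raise FormatError(
                f"taxonomy needs exactly {len(RANKS)} ranks, got {len(self.labels)}"
            )
        unknown_seen = False
        for rank, label in zip(RANKS, self.labels):
            if label == "Unknown":
                raise FormatError(
                    "'Unknown' is a reserved label and cannot name a real taxon "
                    f"(rank {rank})"
                )
            if label == "":
                unknown_seen = True
            elif unknown_seen:
                raise FormatError(
                    f"rank {rank} is labelled {label!r} below an unknown rank"
                )

    def label_at(self, rank: str) -> str:
        return self.labels[RANKS.index(rank)]

    def is_known_at(self, rank: str) -> bool:
        return self.label_at(rank) != ""

    def to_string(self) -> str:
        return ";".join(self.labels)


def parse_taxonomy_string(s: str) -> RankedTaxonomy:
    """Parse a semicolon-delimited rank string into a RankedTaxonomy.

    SILVA-style ``d__``/``p__``.. prefixes are stripped; fewer than 7 fields
    are padded with unknowns on the right.
    """
    fields = [_SILVA_PREFIX.sub("", f.strip()) for f in s.strip().split(";")]
    if len(fields) > len(RANKS):
        raise FormatError(f"taxonomy string has more than {len(RANKS)} ranks: {s!r}")
    fields += [""] * (len(RANKS) - len(fields))
    return RankedTaxonomy(labels=tuple(fields))


# ---------------------------------------------------------------------------
# ASV tables
# ---------------------------------------------------------------------------

@dataclass
class AsvTable:
    """Samples x ASVs table of non-negative integer counts with depth layers."""

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_asvs), integer
    layer_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise FormatError("duplicate ASV ids")
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("negative count in ASV table")
        for s in self.sample_ids:
            layer = self.layer_of.get(s)
            if layer is None:
                raise FormatError(f"sample {s!r} has no layer assignment")
            if layer not in LAYERS:
                raise FormatError(f"sample {s!r} has unknown layer {layer!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    def layer_tally(self) -> dict[str, int]:
        tally = {layer: 0 for layer in LAYERS}
        for s in self.sample_ids:
            tally[self.layer_of[s]] += 1
        return tally

    def subset_asvs(self, keep: Sequence[str]) -> "AsvTable":
        keep = list(keep)
        idx = [self.asv_ids.index(a) for a in keep]
        return AsvTable(
            sample_ids=list(self.sample_ids),
            asv_ids=keep,
            counts=self.counts[:, idx].copy(),
            layer_of=dict(self.layer_of),
        )


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8", **kw)


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id -> layer TSV (header required)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"metadata {path} needs >= 2 columns (sample_id, layer)")
    layer_of: dict[str, str] = {}
    for _, row in df.iterrows():
        sid, raw = str(row.iloc[0]), str(row.iloc[1])
        layer = _LAYER_ALIASES.get(raw.strip().lower())
        if layer is None:
            raise FormatError(f"unknown layer label {raw!r} for sample {sid!r}")
        if sid in layer_of:
            raise FormatError(f"duplicate sample id {sid!r} in metadata")
        layer_of[sid] = layer
    return layer_of


def read_taxonomy(path: str | Path) -> dict[str, RankedTaxonomy]:
    """Read an asv_id -> taxonomy-string TSV (header required)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"taxonomy {path} needs >= 2 columns (asv_id, taxonomy)")
    tax: dict[str, RankedTaxonomy] = {}
    for _, row in df.iterrows():
        aid = str(row.iloc[0])
        if aid in tax:
            raise FormatError(f"duplicate ASV id {aid!r} in taxonomy")
        raw = row.iloc[1]
        tax[aid] = parse_taxonomy_string("" if pd.isna(raw) else str(raw))
    return tax


def read_asv_table(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> tuple[AsvTable, dict[str, RankedTaxonomy]]:
    """Read and join counts, taxonomy and metadata into validated structures.

    The count table's orientation (samples as rows or as columns) is detected
    by matching metadata sample ids against the header; the in-memory table is
    always samples x ASVs.
    """
    layer_of = read_metadata(metadata_path)
    taxonomy = read_taxonomy(taxonomy_path)
    raw = pd.read_csv(counts_path, sep="\t", index_col=0, encoding="utf-8")

    header = [str(c) for c in raw.columns]
    index = [str(i) for i in raw.index]
    samples = set(layer_of)
    if samples.issuperset(header):
        mat = raw.T  # samples were columns on disk
    elif samples.issuperset(index):
        mat = raw
    else:
        missing = (set(header) - samples) & (set(index) - samples)
        raise FormatError(
            "cannot orient count table: neither header nor first column is a "
            f"subset of the metadata sample ids (unmatched e.g. {sorted(missing)[:3]})"
        )

    sample_ids = [str(s) for s in mat.index]
    asv_ids = [str(a) for a in mat.columns]
    values = mat.to_numpy()
    numeric = pd.DataFrame(values).apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.any(pd.isna(numeric)):
        raise FormatError("non-numeric entry in count table")
    if np.any(numeric < 0):
        raise FormatError("negative count in count table")
    if np.any(numeric != np.floor(numeric)):
        raise FormatError("non-integer count in count table")

    for aid in asv_ids:
        if aid not in taxonomy:
            raise FormatError(f"ASV {aid!r} present in counts but absent from taxonomy")

    table = AsvTable(
        sample_ids=sample_ids,
        asv_ids=asv_ids,
        counts=numeric.astype(np.int64),
        layer_of={s: layer_of[s] for s in sample_ids},
    )
    return table, {a: taxonomy[a] for a in asv_ids}


def write_asv_table(
    table: AsvTable,
    taxonomy: Mapping[str, RankedTaxonomy],
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write counts (samples as columns, QIIME2-export orientation), taxonomy
    and metadata TSVs that :func:`read_asv_table` reads back."""
    df = table.to_frame().T  # ASVs as rows, samples as columns
    df.index.name = "asv_id"
    df.to_csv(counts_path, sep="\t", encoding="utf-8")
    with open(taxonomy_path, "w", encoding="utf-8") as fh:
        fh.write("asv_id\ttaxonomy\n")
        for aid in table.asv_ids:
            fh.write(f"{aid}\t{taxonomy[aid].to_string()}\n")
    with open(metadata_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tlayer\n")
        for sid in table.sample_ids:
            fh.write(f"{sid}\t{table.layer_of[sid]}\n")


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise dissimilarities with labels."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise FormatError("duplicate ids in distance matrix")
        if self.d.shape != (n, n):
            raise FormatError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if np.any(self.d < 0):
            raise FormatError("negative distance")
        if not np.allclose(np.diag(self.d), 0.0):
            raise FormatError("non-zero diagonal in distance matrix")
        if not np.allclose(self.d, self.d.T):
            raise FormatError("asymmetric distance matrix")

    def __len__(self) -> int:
        return len(self.ids)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.d, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", encoding="utf-8", index_label="id"
    )


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise FormatError("distance matrix rows and columns disagree")
    return DistanceMatrix(ids=ids, d=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Primer pairs
# ---------------------------------------------------------------------------

def read_primer_pairs(path: str | Path) -> list:
    """Read a primer TSV (pair_name, forward_seq, reverse_seq, min_len, max_len)."""
    from .insilico_pcr import PrimerPair  # local import avoids a module cycle

    df = _read_tsv(path)
    required = ["pair_name", "forward_seq", "reverse_seq", "min_len", "max_len"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"primer TSV missing column {col!r}")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PrimerPair(
                name=str(row["pair_name"]),
                forward=str(row["forward_seq"]),
                reverse=str(row["reverse_seq"]),
                min_len=int(row["min_len"]),
                max_len=int(row["max_len"]),
            )
        )
    return pairs


def write_primer_pairs(pairs: Iterable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pair_name\tforward_seq\treverse_seq\tmin_len\tmax_len\n")
        for p in pairs:
            fh.write(f"{p.name}\t{p.forward}\t{p.reverse}\t{p.min_len}\t{p.max_len}\n")


# ---------------------------------------------------------------------------
# Newick dendrograms
# ---------------------------------------------------------------------------

def _fmt_branch(x: float) -> str:
    s = f"{x:.6g}"
    if "." not in s and "e" not in s and "E" not in s:
        s += ".0"
    return s


def newick_string(tree) -> str:
    """Serialize a single-linkage merge tree as an ultrametric Newick string.

    Each leaf sits at height 0 and each internal node at its merge height, so
    every root-to-leaf path length equals the root's merge height.
    """
    labels = list(tree.labels)
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels in dendrogram")
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    subtree = {i: labels[i] for i in range(n)}
    for a, b, h, new in tree.merges:
        la = _fmt_branch(h - height[a])
        lb = _fmt_branch(h - height[b])
        subtree[new] = f"({subtree[a]}:{la},{subtree[b]}:{lb})"
        height[new] = h
        del subtree[a], subtree[b]
    (root,) = subtree.values()
    return root + ";"


def write_newick(tree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(newick_string(tree) + "\n")
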