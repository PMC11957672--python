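"""Readers and writers for every external artifact.

Formats
-------
structures
    PDB or mmCIF, single model, single chain; per-residue pLDDT is read
    from the B-factor column (the AlphaFold / ColabFold convention).
sequences
    FASTA.
embeddings
    HDF5, one float32 L×d dataset per protein id.
labels / splits / predictions
    Plain TSV. Residue indices are 1-based on disk and 0-based in memory.

The label format is a three-column TSV (protein_id, residue_index, class)
with one row per annotated (residue, ligand-class) pair; a residue absent
from the file is non-binding, and multi-label residues simply occupy
several rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO

#: fixed ligand-class column order used everywhere
CLASSES = ("metal", "nucleic", "small")

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")

KNOWN_EMBEDDING_DIMS = (768, 1024, 1536, 2560)


@dataclass
class ProteinRecord:
    """A protein sequence; the join key across all per-protein files."""

    id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise ValueError(f"{self.id}: invalid residue letters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CoordinateSet:
    """Cα coordinates (Å) plus per-residue pLDDT confidence in [0, 100]."""

    protein_id: str
    ca_coords: np.ndarray  # (L, 3)
    plddt: np.ndarray  # (L,)

    def __post_init__(self):
        self.ca_coords = np.asarray(self.ca_coords, dtype=np.float64)
        self.plddt = np.asarray(self.plddt, dtype=np.float64)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError(f"{self.protein_id}: coordinates must be L×3")
        if len(self.plddt) != len(self.ca_coords):
            raise ValueError(f"{self.protein_id}: pLDDT length mismatch")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError(f"{self.protein_id}: non-finite coordinates")

    @property
    def length(self) -> int:
        return len(self.ca_coords)


@dataclass
class LabelSet:
    """L×3 binary binding annotations, columns (metal, nucleic, small)."""

    protein_id: str
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2 or self.labels.shape[1] != 3:
            raise ValueError(f"{self.protein_id}: labels must be L×3")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError(f"{self.protein_id}: labels must be binary")

    @property
    def length(self) -> int:
        return len(self.labels)


@dataclass
class EmbeddingMatrix:
    """Pre-computed per-residue language-model embeddings (L×d)."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError(f"{self.protein_id}: embeddings must be L×d")

    @property
    def length(self) -> int:
        return len(self.values)

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class SplitAssignment:
    """protein_id -> fold (1..5) or the literal string "test"."""

    assignment: dict[str, int | str] = field(default_factory=dict)

    def fold_ids(self, fold: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == fold]

    @property
    def dev_ids(self) -> list[str]:
        return [p for p, f in self.assignment.items() if f != "test"]

    @property
    def test_ids(self) -> list[str]:
        return [p for p, f in self.assignment.items() if f == "test"]

    @property
    def folds(self) -> list[int]:
        return sorted({f for f in self.assignment.values() if f != "test"})


# ---------------------------------------------------------------------------
# structures


def read_structure(path) -> CoordinateSet:
    """Read one single-chain predicted structure (PDB or mmCIF).

    Returns one Cα row per residue in residue-number order with pLDDT taken
    from the B-factor field. Multi-model and multi-chain files are rejected
    as ambiguous; a residue without a Cα atom is an error.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise ValueError(f"{path}: unparseable structure file: {exc}") from exc
    st.setup_entities()
    st.remove_ligands_and_waters()
    st.remove_empty_chains()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    if len(st) > 1:
        raise ValueError(f"{path}: {len(st)} models; expected exactly one")
    model = st[0]
    if len(model) != 1:
        raise ValueError(f"{path}: {len(model)} chains; expected exactly one")
    chain = model[0]
    coords, plddt = [], []
    for residue in chain:
        ca = residue.find_atom("CA", "*")
        if ca is None:
            raise ValueError(
                f"{path}: residue {residue.seqid.num} ({residue.name}) has no Cα atom"
            )
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        plddt.append(ca.b_iso)
    # the B-factor field carries two decimals; round away float32 noise
    return CoordinateSet(path.stem, np.array(coords), np.round(plddt, 2))


_AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def write_structure(coord_set: CoordinateSet, sequence: str, path) -> None:
    """Write a Cα-only PDB with pLDDT in the B-factor column.

    Coordinates are rounded to the PDB precision of 0.001 Å, so files whose
    inputs already sit on that grid round-trip bit-identically.
    """
    if len(sequence) != coord_set.length:
        raise ValueError("sequence length does not match coordinates")
    st = gemmi.Structure()
    st.name = coord_set.protein_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (aa, xyz, b) in enumerate(
        zip(sequence, coord_set.ca_coords, coord_set.plddt), start=1
    ):
        res = gemmi.Residue()
        res.name = _AA_1TO3.get(aa, "UNK")
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.b_iso = float(b)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path) -> dict[str, ProteinRecord]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id}")
        records[rec.id] = ProteinRecord(rec.id, str(rec.seq).upper())
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records.values() if isinstance(records, dict) else records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# embeddings


def read_embeddings(path) -> dict[str, EmbeddingMatrix]:
    """Read all per-protein embedding matrices from an HDF5 container."""
    out = {}
    with h5py.File(path, "r") as fh:
        for pid in fh:
            values = np.asarray(fh[pid], dtype=np.float32)
            emb = EmbeddingMatrix(pid, values)
            if emb.dim not in KNOWN_EMBEDDING_DIMS:
                # user-declared dimensions are allowed; common pLM dims are
                # 768 (Ankh-base), 1024 (ProtT5/ProtBert), 1536 (Ankh),
                # 2560 (ESM-2 3B)
                pass
            out[pid] = emb
    return out


def write_embeddings(embeddings: dict[str, EmbeddingMatrix], path) -> None:
    with h5py.File(path, "w") as fh:
        for pid, emb in embeddings.items():
            fh.create_dataset(pid, data=emb.values.astype(np.float32))


# ---------------------------------------------------------------------------
# labels


def read_labels(path, records: dict[str, ProteinRecord]) -> dict[str, LabelSet]:
    """Read the 3-column label TSV into one L×3 matrix per protein.

    Every protein in ``records`` receives a matrix; absence from the file
    means non-binding. A label for an unknown protein or an out-of-range
    residue index is a hard error (corrupt dataset).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=["protein_id", "residue_index", "cls"],
        dtype={"protein_id": str, "residue_index": int, "cls": str},
        comment="#",
        header=None,
        skip_blank_lines=True,
    )
    if df.duplicated().any():
        dup = df[df.duplicated()].iloc[0]
        raise ValueError(
            f"duplicate label row ({dup.protein_id}, {dup.residue_index}, {dup.cls})"
        )
    out = {
        pid: LabelSet(pid, np.zeros((rec.length, 3), dtype=np.int8))
        for pid, rec in records.items()
    }
    cls_index = {c: k for k, c in enumerate(CLASSES)}
    for row in df.itertuples(index=False):
        if row.protein_id not in records:
            raise ValueError(
                f"label for unknown protein {row.protein_id!r}: corrupt dataset"
            )
        if row.cls not in cls_index:
            raise ValueError(f"unknown ligand class {row.cls!r}")
        L = records[row.protein_id].length
        if not 1 <= row.residue_index <= L:
            raise ValueError(
                f"{row.protein_id}: residue index {row.residue_index} outside 1..{L}"
            )
        out[row.protein_id].labels[row.residue_index - 1, cls_index[row.cls]] = 1
    return out


def write_labels(labels: dict[str, LabelSet], path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(labels):
            lab = labels[pid].labels
            for i, c in zip(*np.nonzero(lab)):
                fh.write(f"{pid}\t{i + 1}\t{CLASSES[c]}\n")


# ---------------------------------------------------------------------------
# splits


def read_splits(path) -> SplitAssignment:
    df = pd.read_csv(
        path, sep="\t", names=["protein_id", "fold"], dtype=str, header=None
    )
    assignment: dict[str, int | str] = {}
    for row in df.itertuples(index=False):
        if row.protein_id in assignment:
            raise ValueError(f"{row.protein_id} assigned to more than one fold")
        assignment[row.protein_id] = "test" if row.fold == "test" else int(row.fold)
    return SplitAssignment(assignment)


def write_splits(splits: SplitAssignment, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(splits.assignment):
            fh.write(f"{pid}\t{splits.assignment[pid]}\n")


# ---------------------------------------------------------------------------
# predictions


def write_predictions(
    probabilities: dict[str, np.ndarray],
    records: dict[str, ProteinRecord],
    path,
    threshold: float = 0.5,
) -> None:
    """Write per-residue class probabilities and threshold calls as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tresidue_index\tresidue_letter\t"
            "p_metal\tp_nucleic\tp_small\tcalls\n"
        )
        for pid in sorted(probabilities):
            probs = np.asarray(probabilities[pid])
            seq = records[pid].sequence
            for i, row in enumerate(probs):
                called = [c for c, p in zip(CLASSES, row) if p >= threshold]
                calls = ",".join(called) if called else "-"
                fh.write(
                    f"{pid}\t{i + 1}\t{seq[i]}\t"
                    f"{row[0]:.8f}\t{row[1]:.8f}\t{row[2]:.8f}\t{calls}\n"
                )


def read_predictions(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for pid, group in df.groupby("protein_id", sort=False):
        group = group.sort_values("residue_index")
        out[str(pid)] = group[["p_metal", "p_nucleic", "p_small"]].to_numpy()
    return out


# ---------------------------------------------------------------------------
# cross-file consistency


def validate_lengths(
    records: dict[str, ProteinRecord],
    coord_sets: dict[str, CoordinateSet] | None = None,
    embeddings: dict[str, EmbeddingMatrix] | None = None,
    labels: dict[str, LabelSet] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Keep proteins whose per-residue artifacts all agree on length.

    Returns (kept ids, excluded id -> reason). A protein is kept iff its
    sequence length equals the row count of every supplied artifact; a
    label entry for a protein with no sequence is a hard error.
    """
    if labels:
        orphans = set(labels) - set(records)
        if orphans:
            raise ValueError(
                f"labels reference proteins absent from sequences: {sorted(orphans)}"
            )
    kept, excluded = [], {}
    sources = [
        ("coordinates", coord_sets),
        ("embeddings", embeddings),
        ("labels", labels),
    ]
    for pid in sorted(records):
        L = records[pid].length
        reason = None
        for name, coll in sources:
            if coll is None:
                continue
            if pid not in coll:
                reason = f"missing {name}"
                break
            if coll[pid].length != L:
                reason = f"{name} length {coll[pid].length} != sequence length {L}"
                break
        if reason is None:
            kept.append(pid)
        else:
            excluded[pid] = reason
    return kept, excluded
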