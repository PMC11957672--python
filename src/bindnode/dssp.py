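"""DSSP per-residue records and the 20-dimensional structural feature vector.

Each residue contributes, after normalization to [0, 1]:

====================  =====  ==================================================
block                 width  normalization
====================  =====  ==================================================
relative position       1    i / L, i 1-based
secondary structure     8    one-hot over the DSSP classes (H,B,E,G,I,T,S,-)
phi                     1    (phi + 180) / 360; undefined (sentinel 360) -> 0
psi                     1    (psi + 180) / 360; undefined -> 0
RSA                     1    ACC / max-ACC (Sander), clipped to [0, 1]
H-bond rel. indices     4    min-max per column within the protein
H-bond energies         4    min-max per column within the protein
====================  =====  ==================================================

The four hydrogen-bond (relative index, energy) pairs are DSSP's
NH→O(1), O→NH(1), NH→O(2), O→NH(2) descriptors, in file order. Min-max
normalization makes the result invariant to per-column affine shifts, so
sign conventions for the relative indices do not matter. A column that is
constant within a protein normalizes to all zeros. The column order is a
package convention and is frozen by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB.DSSP import make_dssp_dict, residue_max_acc

from .io import _AA_1TO3

#: fixed one-hot order for the eight DSSP secondary-structure classes
SS_CLASSES = "HBEGITS-"

#: DSSP writes 360.0 for dihedrals undefined at chain termini
ANGLE_SENTINEL = 360.0

N_FEATURES = 20

_MAX_ACC = residue_max_acc["Sander"]
_MAX_ACC_FALLBACK = max(_MAX_ACC.values())


@dataclass
class DsspRecord:
    """One residue's raw DSSP fields (RSA already scaled to [0, 1])."""

    residue_index: int  # 1-based
    aa: str
    ss: str
    phi: float  # degrees, ANGLE_SENTINEL when undefined
    psi: float
    rsa: float
    hbond_relidx: np.ndarray  # (4,) signed ints
    hbond_energy: np.ndarray  # (4,) kcal/mol

    def __post_init__(self):
        self.hbond_relidx = np.asarray(self.hbond_relidx, dtype=np.float64)
        self.hbond_energy = np.asarray(self.hbond_energy, dtype=np.float64)
        if self.hbond_relidx.shape != (4,) or self.hbond_energy.shape != (4,):
            raise ValueError("exactly four H-bond (relidx, energy) pairs required")
        if self.ss not in SS_CLASSES:
            raise ValueError(f"unknown secondary-structure class {self.ss!r}")


def relative_accessibility(acc: float, aa: str) -> float:
    max_acc = _MAX_ACC.get(_AA_1TO3.get(aa, "UNK"), _MAX_ACC_FALLBACK)
    return float(np.clip(acc / max_acc, 0.0, 1.0))


def parse_dssp(path, length: int | None = None) -> list[DsspRecord]:
    """Parse classic DSSP text output into per-residue records.

    Tolerant of mkdssp 3.x/4.x header variants (parsing starts at the
    ``#  RESIDUE`` table header). If ``length`` is given, a record count
    that differs from it is an error.
    """
    dssp_dict, keys = make_dssp_dict(str(Path(path)))
    records = []
    for key in keys:
        (aa, ss, acc, phi, psi, _idx, r1, e1, r2, e2, r3, e3, r4, e4) = dssp_dict[key]
        records.append(
            DsspRecord(
                residue_index=key[1][1],
                aa=aa,
                ss="-" if ss in (" ", "-") else ss,
                phi=phi,
                psi=psi,
                rsa=relative_accessibility(acc, aa),
                hbond_relidx=np.array([r1, r2, r3, r4], dtype=float),
                hbond_energy=np.array([e1, e2, e3, e4], dtype=float),
            )
        )
    if length is not None and len(records) != length:
        raise ValueError(
            f"{path}: {len(records)} DSSP records but expected {length} residues"
        )
    return records


def _normalize_angle(angle: float) -> float:
    if angle == ANGLE_SENTINEL:
        return 0.0
    return float(np.clip((angle + 180.0) / 360.0, 0.0, 1.0))


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.zeros_like(col)
    return (col - lo) / (hi - lo)


def normalize_features(records: list[DsspRecord]) -> np.ndarray:
    """Build the L×20 normalized feature matrix for one protein."""
    L = len(records)
    if L == 0:
        raise ValueError("no DSSP records")
    out = np.zeros((L, N_FEATURES))
    out[:, 0] = np.arange(1, L + 1) / L
    for i, rec in enumerate(records):
        out[i, 1 + SS_CLASSES.index(rec.ss)] = 1.0
        out[i, 9] = _normalize_angle(rec.phi)
        out[i, 10] = _normalize_angle(rec.psi)
        out[i, 11] = rec.rsa
    relidx = np.array([r.hbond_relidx for r in records])
    energy = np.array([r.hbond_energy for r in records])
    for k in range(4):
        out[:, 12 + k] = _minmax(relidx[:, k])
        out[:, 16 + k] = _minmax(energy[:, k])
    return out


# ---------------------------------------------------------------------------
# classic-format writer (used by the synthetic-fixture generator)

_HEADER = (
    "==== Secondary Structure Definition; classic format ====\n"
    "REFERENCE   .\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
    "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA\n"
)


def write_dssp(records: list[DsspRecord], path) -> None:
    """Write records as classic fixed-column DSSP text.

    Emits the absolute ACC implied by each record's RSA so that a
    write→parse round trip recovers the record (up to ACC integer
    rounding). Energies must fit the file's 4-character field, i.e. lie in
    [-9.9, 9.9].
    """
    lines = [_HEADER]
    for idx, rec in enumerate(records, start=1):
        max_acc = _MAX_ACC.get(_AA_1TO3.get(rec.aa, "UNK"), _MAX_ACC_FALLBACK)
        acc = int(round(rec.rsa * max_acc))
        ss = " " if rec.ss == "-" else rec.ss
        line = f"{idx:5d}{rec.residue_index:5d} A {rec.aa}  {ss}"
        line += " " * (34 - len(line))
        line += f"{acc:4d}"
        r, e = rec.hbond_relidx.astype(int), rec.hbond_energy
        line += f"{r[0]:7d},{e[0]:4.1f}"
        line += f"{r[1]:6d},{e[1]:4.1f}"
        line += f"{r[2]:6d},{e[2]:4.1f}"
        line += f"{r[3]:6d},{e[3]:4.1f}"
        line += " " * (103 - len(line))
        line += f"{rec.phi:6.1f}{rec.psi:6.1f}"
        lines.append(line + "\n")
    Path(path).write_text("".join(lines))
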