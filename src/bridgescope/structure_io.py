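"""Read and write multi-model structure ensembles and trajectory frame tables.

The central container is :class:`FrameEnsemble`: a fixed atom topology shared
by an ordered list of coordinate frames (Å).  Multi-model PDB files (NMR
ensembles, trajectory snapshots written as MODEL/ENDMDL blocks) are parsed
with biotite; a plain-text tab-separated "frame table" dialect is provided
for lossless round trips of synthetic trajectories.

Residues are addressed exclusively by author numbering as printed in the PDB
file (1-based), so that e.g. Arg62 and Glu38 of E. coli CheW keep the numbers
used throughout the literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import ParseError, SelectionError, TopologyError

__all__ = [
    "AtomMeta",
    "FrameEnsemble",
    "IntensityTable",
    "CdTable",
    "read_multimodel_pdb",
    "read_frame_table",
    "write_frame_table",
    "read_intensity_tables",
    "read_cd_table",
    "select_atoms",
    "backbone_of",
    "residue_range",
    "is_hydrogen",
]

#: Heavy-atom names of the protein backbone.
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomMeta:
    """Identity of one atom in a topology (PDB naming, author numbering)."""

    atom_name: str
    residue_number: int
    residue_name: str
    chain_id: str


def is_hydrogen(atom_name: str) -> bool:
    """Heuristic element check from the PDB atom name (no element column)."""
    stripped = atom_name.lstrip("0123456789")
    return stripped[:1] in ("H", "D")


class FrameEnsemble:
    """An ordered set of coordinate frames over a fixed atom topology.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    atom_name, residue_number, residue_name, chain_id
        Per-atom metadata arrays of length ``n_atoms``.
    frame_labels
        Optional integer label per frame (frame index or time step).
    """

    def __init__(
        self,
        coords: np.ndarray,
        atom_name: Sequence[str],
        residue_number: Sequence[int],
        residue_name: Sequence[str],
        chain_id: Sequence[str],
        frame_labels: Sequence[int] | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise TopologyError(f"coords must be (n_frames, n_atoms, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise TopologyError("an ensemble needs at least one frame")
        if not np.all(np.isfinite(coords)):
            raise TopologyError("non-finite coordinates")
        n_atoms = coords.shape[1]
        self.coords = coords
        self.atom_name = np.asarray(atom_name, dtype=object)
        self.residue_number = np.asarray(residue_number, dtype=int)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.chain_id = np.asarray(chain_id, dtype=object)
        for arr, label in [
            (self.atom_name, "atom_name"),
            (self.residue_number, "residue_number"),
            (self.residue_name, "residue_name"),
            (self.chain_id, "chain_id"),
        ]:
            if len(arr) != n_atoms:
                raise TopologyError(f"{label} has {len(arr)} entries for {n_atoms} atoms")
        if frame_labels is None:
            frame_labels = np.arange(coords.shape[0])
        self.frame_labels = np.asarray(frame_labels, dtype=int)
        if len(self.frame_labels) != coords.shape[0]:
            raise TopologyError("frame_labels length does not match frame count")

    # -- basic introspection -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def topology(self) -> list[AtomMeta]:
        return [
            AtomMeta(str(a), int(r), str(n), str(c))
            for a, r, n, c in zip(
                self.atom_name, self.residue_number, self.residue_name, self.chain_id
            )
        ]

    def residue_numbers(self) -> np.ndarray:
        """Unique residue numbers in topology order of first appearance."""
        _, idx = np.unique(self.residue_number, return_index=True)
        return self.residue_number[np.sort(idx)].astype(int)

    # -- derived ensembles ---------------------------------------------------

    def with_coords(self, coords: np.ndarray) -> "FrameEnsemble":
        """Same topology, new coordinates (used by superposition)."""
        coords = np.asarray(coords, dtype=float)
        labels = self.frame_labels if len(coords) == self.n_frames else None
        return FrameEnsemble(
            coords, self.atom_name, self.residue_number, self.residue_name,
            self.chain_id, labels,
        )

    def take_frames(self, indices: Sequence[int]) -> "FrameEnsemble":
        indices = np.asarray(indices, dtype=int)
        return FrameEnsemble(
            self.coords[indices], self.atom_name, self.residue_number,
            self.residue_name, self.chain_id, self.frame_labels[indices],
        )

    def mask_atoms(self, mask: np.ndarray) -> "FrameEnsemble":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise SelectionError("atom mask selects no atoms")
        return FrameEnsemble(
            self.coords[:, mask], self.atom_name[mask], self.residue_number[mask],
            self.residue_name[mask], self.chain_id[mask], self.frame_labels,
        )

    def atom_index(self, residue_number: int, atom_name: str) -> int:
        """Index of a single atom; raises SelectionError if absent/ambiguous."""
        hits = np.flatnonzero(
            (self.residue_number == residue_number) & (self.atom_name == atom_name)
        )
        if len(hits) == 0:
            raise SelectionError(f"no atom {atom_name} in residue {residue_number}")
        return int(hits[0])


def select_atoms(
    ens: FrameEnsemble, predicate: Callable[[AtomMeta], bool]
) -> FrameEnsemble:
    """Restrict topology and frames to atoms for which *predicate* is true.

    Frame order is preserved; an empty selection raises
    :class:`~bridgescope.errors.SelectionError` naming the predicate.
    """
    mask = np.fromiter(
        (bool(predicate(m)) for m in ens.topology), dtype=bool, count=ens.n_atoms
    )
    if not mask.any():
        name = getattr(predicate, "__name__", repr(predicate))
        raise SelectionError(f"predicate {name} matched no atoms")
    return ens.mask_atoms(mask)


def residue_range(first: int, last: int) -> Callable[[AtomMeta], bool]:
    """Predicate: residue number in the closed interval [first, last]."""

    def pred(m: AtomMeta) -> bool:
        return first <= m.residue_number <= last

    pred.__name__ = f"residue_range({first},{last})"
    return pred


def backbone_of(first: int, last: int) -> Callable[[AtomMeta], bool]:
    """Predicate: backbone heavy atoms (N, CA, C, O) of residues first..last."""

    def pred(m: AtomMeta) -> bool:
        return first <= m.residue_number <= last and m.atom_name in BACKBONE_ATOMS

    pred.__name__ = f"backbone_of({first},{last})"
    return pred


# -- PDB ---------------------------------------------------------------------


def read_multimodel_pdb(path: str | Path) -> FrameEnsemble:
    """Parse a (multi-)model PDB file into a :class:`FrameEnsemble`.

    One frame per MODEL block (a file without MODEL records yields one
    frame).  Alternate locations are resolved to the highest-occupancy
    conformer.  Models whose atom sets disagree with the first model are
    rejected with a :class:`~bridgescope.errors.TopologyError`.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdb_file = PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises several ad-hoc types
        msg = str(exc)
        if "model" in msg.lower() or "atom" in msg.lower() and "number" in msg.lower():
            raise TopologyError(f"{path.name}: {msg}") from exc
        raise ParseError(f"{path.name}: {msg}") from exc
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:  # single model returned as AtomArray
        coords = coords[None]
    return FrameEnsemble(
        coords,
        stack.atom_name.astype(object),
        stack.res_id.astype(int),
        stack.res_name.astype(object),
        stack.chain_id.astype(object),
    )


# -- frame table -------------------------------------------------------------

_MAGIC = "# bridgescope frame table v1"


def write_frame_table(ens: FrameEnsemble, path: str | Path) -> None:
    """Write the documented tab-separated frame-table dialect.

    Line 1 is a magic comment; line 2 a header with a ``frame`` column then
    three columns per atom named ``chain|resname|resnum|atom|{x,y,z}``;
    each further line one frame.  Floats use repr precision so that a
    read-back is bitwise identical.
    """
    path = Path(path)
    cols = ["frame"]
    for m in ens.topology:
        base = f"{m.chain_id}|{m.residue_name}|{m.residue_number}|{m.atom_name}"
        cols += [f"{base}|x", f"{base}|y", f"{base}|z"]
    with path.open("w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write("\t".join(cols) + "\n")
        for i in range(ens.n_frames):
            row = [str(int(ens.frame_labels[i]))]
            row += [np.format_float_scientific(v, unique=True) for v in ens.coords[i].ravel()]
            fh.write("\t".join(row) + "\n")


def read_frame_table(path: str | Path) -> FrameEnsemble:
    """Read the frame-table dialect written by :func:`write_frame_table`."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _MAGIC:
        raise ParseError(f"{path.name}: missing frame-table magic line")
    if len(lines) < 3:
        raise ParseError(f"{path.name}: no frames in table")
    header = lines[1].split("\t")
    if header[0] != "frame" or (len(header) - 1) % 3 != 0:
        raise ParseError(f"{path.name}: malformed header")
    n_atoms = (len(header) - 1) // 3
    atom_name, res_num, res_name, chain = [], [], [], []
    for j in range(n_atoms):
        parts = header[1 + 3 * j].split("|")
        if len(parts) != 5 or parts[4] != "x":
            raise ParseError(f"{path.name}: malformed atom column {header[1 + 3 * j]!r}")
        chain.append(parts[0])
        res_name.append(parts[1])
        res_num.append(int(parts[2]))
        atom_name.append(parts[3])
    labels, frames = [], []
    for lineno, ln in enumerate(lines[2:], start=3):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 1 + 3 * n_atoms:
            raise ParseError(
                f"{path.name}:{lineno}: expected {1 + 3 * n_atoms} fields, got {len(fields)}"
            )
        labels.append(int(fields[0]))
        try:
            frames.append(np.array(fields[1:], dtype=float).reshape(n_atoms, 3))
        except ValueError as exc:
            raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
    if not frames:
        raise ParseError(f"{path.name}: no frames in table")
    return FrameEnsemble(np.array(frames), atom_name, res_num, res_name, chain, labels)


# -- tabular experiment files ------------------------------------------------


@dataclass
class IntensityTable:
    """Peak-intensity series of one residue for one relaxation modality.

    ``series`` holds (delay-or-τcp in seconds, intensity) pairs.  Modalities:
    ``R1``/``R2`` (exponential decays, ≥3 points), ``NOE_pair`` (exactly two
    intensities: saturated, unsaturated), ``CPMG`` (τcp series).
    """

    residue_number: int
    series: list[tuple[float, float]]
    modality: str = "R1"

    def __post_init__(self):
        delays = [d for d, _ in self.series]
        if self.modality in ("R1", "R2", "CPMG"):
            if any(d <= 0 for d in delays):
                raise ValueError("delays must be strictly positive")
            if len(set(delays)) != len(delays):
                raise ValueError("delays must be unique")
            if self.modality in ("R1", "R2") and len(delays) < 3:
                raise ValueError("rate fitting needs at least 3 delay points")
        elif self.modality == "NOE_pair":
            if len(self.series) != 2:
                raise ValueError("NOE_pair needs exactly two intensities")
        else:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def delays(self) -> np.ndarray:
        return np.array([d for d, _ in self.series])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.series])


@dataclass
class CdTable:
    """CD signal (220 nm) vs urea concentration for one titration."""

    points: list[tuple[float, float]]
    temperature_K: float = 298.15

    def __post_init__(self):
        urea = np.array([u for u, _ in self.points])
        if np.any(urea < 0):
            raise ValueError("urea concentrations must be non-negative")
        if np.any(np.diff(urea) <= 0):
            raise ValueError("urea concentrations must be strictly increasing")
        if len(urea) < 8:
            raise ValueError("an unfolding curve needs at least 8 points")

    @property
    def urea(self) -> np.ndarray:
        return np.array([u for u, _ in self.points])

    @property
    def signal(self) -> np.ndarray:
        return np.array([s for _, s in self.points])


def read_intensity_tables(path: str | Path, modality: str) -> list[IntensityTable]:
    """Read a TSV of (residue, delay_s or tau_cp_s, intensity) rows.

    Lines starting with ``#`` and a single header line are ignored; one
    :class:`IntensityTable` per residue, in order of first appearance.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    res_col, t_col, i_col = df.columns[:3]
    tables = []
    for res, sub in df.groupby(res_col, sort=False):
        series = list(zip(sub[t_col].astype(float), sub[i_col].astype(float)))
        tables.append(IntensityTable(int(res), series, modality=modality))
    return tables


def read_cd_table(path: str | Path, temperature_K: float = 298.15) -> CdTable:
    """Read a TSV of (urea_M, signal) rows into a :class:`CdTable`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    u_col, s_col = df.columns[:2]
    pts = sorted(zip(df[u_col].astype(float), df[s_col].astype(float)))
    return CdTable(points=pts, temperature_K=temperature_K)
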