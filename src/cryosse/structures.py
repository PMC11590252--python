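"""Atomic structures, secondary-structure class assignment, voxel labeling.

Residues are reduced to their Cα atoms.  Secondary structure follows the
standard DSSP alphabet collapsed to three classes: codes ``H``, ``G``
and ``I`` are helices, ``B`` and ``E`` are β-sheets, and every other
code — including missing annotations and all non-protein residues — is
background.  Voxels of a grid are labeled helix (or sheet) when their
center lies within 3 Å of a helix (or sheet) Cα; when a voxel is within
range of both classes the nearer Cα wins, with exact ties going to
helix.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import gemmi
from scipy.spatial import cKDTree

from .volumes import BoxSpec, DensityMap, LabelMap

logger = logging.getLogger(__name__)

#: Labeling / voting radius around a Cα atom, in Å (inclusive).
DEFAULT_RADIUS = 3.0

BACKGROUND, HELIX, SHEET = 0, 1, 2
CLASS_NAMES = {BACKGROUND: "background", HELIX: "helix", SHEET: "sheet"}

#: DSSP code -> 3-class mapping (case-sensitive; anything absent is background).
DSSP_CLASS = {
    "H": HELIX, "G": HELIX, "I": HELIX,
    "B": SHEET, "E": SHEET,
}


class EmptyStructureError(ValueError):
    """Raised when a structure contains no Cα atoms."""


@dataclass
class Residue:
    """One amino-acid residue reduced to its Cα atom."""

    chain_id: str
    seq_id: int
    ca_xyz: np.ndarray
    dssp_code: Optional[str] = None
    sse_class: int = BACKGROUND

    def __post_init__(self):
        self.ca_xyz = np.asarray(self.ca_xyz, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.ca_xyz)):
            raise ValueError("Cα coordinates must be finite")
        if self.sse_class not in (BACKGROUND, HELIX, SHEET):
            raise ValueError("invalid secondary-structure class")


@dataclass
class ChainStructure:
    """An ordered set of residues, possibly spanning several chain ids.

    A box-cropped region typically contains one complete central chain
    plus partially cropped neighboring chains; ``center_chain`` records
    which chain id is the central one (None = all residues are central).
    """

    residues: List[Residue]
    id: str = ""
    center_chain: Optional[str] = None

    def __len__(self) -> int:
        return len(self.residues)

    def ca_array(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates (empty (0, 3) when no residues)."""
        if not self.residues:
            return np.zeros((0, 3))
        return np.stack([r.ca_xyz for r in self.residues])

    def classes_array(self) -> np.ndarray:
        return np.array([r.sse_class for r in self.residues], dtype=np.int64)

    def subset(self, indices: Iterable[int]) -> "ChainStructure":
        return ChainStructure(
            [self.residues[i] for i in indices], self.id, self.center_chain
        )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_structure(path, center_chain: Optional[str] = None) -> ChainStructure:
    """Read a PDB or mmCIF file into a :class:`ChainStructure`.

    One residue per amino acid that has a Cα atom; waters, ligands and
    nucleic acids are skipped (they are background by construction and
    take no part in residue-level evaluation).  Classes are initialised
    to background; use :func:`assign_classes` to apply annotations.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    residues: List[Residue] = []
    if len(st) > 0:
        for chain in st[0]:
            for res in chain:
                info = gemmi.find_tabulated_residue(res.name)
                if info is None or not info.is_amino_acid():
                    continue
                ca = res.find_atom("CA", "*")
                if ca is None:
                    continue
                residues.append(
                    Residue(chain.name, res.seqid.num,
                            np.array([ca.pos.x, ca.pos.y, ca.pos.z]))
                )
    if not residues:
        raise EmptyStructureError(f"no amino-acid Cα atoms found in {path}")
    return ChainStructure(residues, id=path.stem, center_chain=center_chain)


def write_structure_pdb(structure: ChainStructure, path) -> None:
    """Write a Cα-trace PDB (poly-alanine) for visual inspection / round trips."""
    st = gemmi.Structure()
    st.name = structure.id or "model"
    model = gemmi.Model("1")
    chains: Dict[str, gemmi.Chain] = {}
    for r in structure.residues:
        if r.chain_id not in chains:
            chains[r.chain_id] = gemmi.Chain(r.chain_id)
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(r.seq_id), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*map(float, r.ca_xyz))
        res.add_atom(atom)
        chains[r.chain_id].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def parse_dssp(path) -> Dict[Tuple[str, int], str]:
    """Parse a classic DSSP output file into {(chain_id, seq_id): code}.

    Only the residue table is read (lines after the ``#  RESIDUE AA``
    header); chain breaks (``!`` rows) are skipped.  A blank structure
    column is returned as ``-``.
    """
    codes: Dict[Tuple[str, int], str] = {}
    in_table = False
    for line in Path(path).read_text().splitlines():
        if not in_table:
            if line.lstrip().startswith("#  RESIDUE"):
                in_table = True
            continue
        if len(line) < 17 or line[13] == "!":
            continue
        try:
            seq_id = int(line[5:10])
        except ValueError:
            continue
        chain_id = line[11].strip() or " "
        code = line[16].strip() or "-"
        codes[(chain_id, seq_id)] = code
    return codes


def read_annotation_tsv(path) -> Dict[Tuple[str, int], str]:
    """Read a per-residue annotation table: chain_id <TAB> seq_id <TAB> code."""
    codes: Dict[Tuple[str, int], str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3 or parts[0] == "chain_id":
            continue
        codes[(parts[0], int(parts[1]))] = parts[2]
    return codes


def write_annotation_tsv(structure: ChainStructure, path) -> None:
    """Write per-residue DSSP-style codes (helix -> H, sheet -> E, else -)."""
    rev = {HELIX: "H", SHEET: "E", BACKGROUND: "-"}
    lines = ["chain_id\tseq_id\tcode"]
    for r in structure.residues:
        code = r.dssp_code if r.dssp_code else rev[r.sse_class]
        lines.append(f"{r.chain_id}\t{r.seq_id}\t{code}")
    Path(path).write_text("\n".join(lines) + "\n")


def assign_classes(
    structure: ChainStructure, dssp_codes: Dict[Tuple[str, int], str]
) -> ChainStructure:
    """Apply the DSSP 3-class mapping to a structure (returns a new copy).

    H/G/I -> helix, B/E -> sheet; unknown, lowercase or missing codes ->
    background (codes are case-sensitive).
    """
    out = copy.deepcopy(structure)
    for r in out.residues:
        code = dssp_codes.get((r.chain_id, r.seq_id))
        r.dssp_code = code
        r.sse_class = DSSP_CLASS.get(code, BACKGROUND)
    return out


# ---------------------------------------------------------------------------
# Voxel labeling
# ---------------------------------------------------------------------------

def label_voxels(
    structure: ChainStructure, grid: DensityMap, radius: float = DEFAULT_RADIUS
) -> LabelMap:
    """Rasterise a structure into a per-voxel class grid.

    A voxel takes class *c* ∈ {helix, sheet} iff its center lies within
    ``radius`` Å (inclusive) of a class-*c* Cα.  Voxels within range of
    both classes take the class of the nearer Cα; exact distance ties go
    to helix.  Everything else is background.
    """
    shape = grid.shape
    classes = np.zeros(shape, dtype=np.uint8)
    ca = structure.ca_array()
    if ca.shape[0] == 0:
        return LabelMap(classes, grid.spacing, grid.origin)
    res_classes = structure.classes_array()

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    centers = (
        np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * grid.spacing
        + np.asarray(grid.origin)
    )

    dists = {}
    for cls in (HELIX, SHEET):
        pts = ca[res_classes == cls]
        if pts.shape[0] == 0:
            dists[cls] = np.full(centers.shape[0], np.inf)
        else:
            d, _ = cKDTree(pts).query(centers, k=1)
            dists[cls] = d
    dh, ds = dists[HELIX], dists[SHEET]
    flat = np.zeros(centers.shape[0], dtype=np.uint8)
    # tolerance only guards float noise; helix wins exact ties
    helix_hit = (dh <= radius + 1e-9) & (dh <= ds + 1e-9)
    sheet_hit = (ds <= radius + 1e-9) & ~helix_hit
    flat[helix_hit] = HELIX
    flat[sheet_hit] = SHEET
    classes = flat.reshape(shape)
    return LabelMap(classes, grid.spacing, grid.origin)


def residues_in_box(
    structure: ChainStructure, box: BoxSpec, grid: DensityMap | LabelMap
) -> ChainStructure:
    """Residues whose Cα lies inside the center box of a cropped grid.

    *grid* is the cropped volume the box describes.  The center-box
    extent spans voxel centers ``[origin + pad_lower * s, origin +
    (shape - pad_upper) * s)`` — closed on the lower boundary, half-open
    on the upper, so a Cα exactly on the lower boundary plane is
    included.
    """
    origin = np.asarray(grid.origin)
    s = grid.spacing
    lo = origin + np.array(box.pad_lower) * s
    hi = origin + (np.array(grid.shape) - np.array(box.pad_upper)) * s
    keep = [
        i for i, r in enumerate(structure.residues)
        if np.all(r.ca_xyz >= lo - 1e-9) and np.all(r.ca_xyz < hi - 1e-9)
    ]
    return structure.subset(keep)
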