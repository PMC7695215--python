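"""Bilayer snapshot analysis: grid-tessellation area per lipid and water insertion.

Operates on single coordinate snapshots of a planar bilayer in an
orthorhombic periodic box (read from PDB/GRO files or built by the
synthetic generator).  Two post-analysis operators are provided:

* **Area per lipid (APL)** by grid tessellation: the lateral box is
  divided into an ``Nx × Ny`` grid and every cell is assigned to the
  lipid phosphate head nearest to its center under the minimum-image
  convention; a lipid's partial area is the number of cells it owns times
  the cell area.  The tessellation is a partition, so per-leaflet areas
  sum exactly to ``Lx·Ly``.  Group means can be taken over the lipids
  near a transmembrane peptide channel versus the bulk.

* **Water insertion** at the carbonyl depth: for each lipid the center of
  mass of its four glycerol-backbone reference atoms (O21, C22, O31,
  C31) is computed, and distinct water oxygens within a 3D periodic
  cutoff (default 0.3 nm) of any such center are counted — a proxy for
  how deep water penetrates towards the membrane core.

All lengths are nanometres internally; PDB coordinates (Å) are converted
on reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import GeometryError

#: Glycerol-backbone reference atoms bounding the maximum water-insertion depth.
CARBONYL_ATOM_NAMES = ("O21", "C22", "O31", "C31")

#: Atomic masses (u) of the reference atoms, for the mass-weighted center option.
_ATOM_MASSES = {"O21": 15.999, "C22": 12.011, "O31": 15.999, "C31": 12.011}


@dataclass(frozen=True)
class ResidueSelections:
    """Residue/atom names used to pick lipids, waters and peptide from a file."""

    lipid_resnames: tuple[str, ...] = ("DOPC", "DOPE", "DOPS", "POPC", "POPE")
    head_atom: str = "P"
    water_resnames: tuple[str, ...] = ("SOL", "TIP3", "TIP", "HOH", "WAT")
    water_atom_names: tuple[str, ...] = ("OW", "OH2", "O")
    peptide_resnames: tuple[str, ...] = ("MEL", "MELT")


@dataclass(frozen=True)
class BilayerFrame:
    """One bilayer snapshot: box, lipid heads, carbonyl atoms, waters, peptide.

    ``heads`` is ``(n_lipids, 3)``, ``carbonyls`` is ``(n_lipids, 4, 3)``
    (ordered as :data:`CARBONYL_ATOM_NAMES`), ``waters`` is water-oxygen
    positions ``(n_waters, 3)`` and ``peptide`` optional channel heavy
    atoms.  Lipids are identified by ``lipid_ids`` (unique integers).
    All coordinates in nm; the box is orthorhombic ``(Lx, Ly, Lz)``.
    """

    box: np.ndarray
    lipid_ids: np.ndarray
    heads: np.ndarray
    carbonyls: np.ndarray
    waters: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    peptide: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        box = np.asarray(self.box, dtype=float)
        heads = np.asarray(self.heads, dtype=float)
        carbonyls = np.asarray(self.carbonyls, dtype=float)
        ids = np.asarray(self.lipid_ids, dtype=int)
        waters = np.asarray(self.waters, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "heads", heads)
        object.__setattr__(self, "carbonyls", carbonyls)
        object.__setattr__(self, "lipid_ids", ids)
        object.__setattr__(self, "waters", waters)
        if self.peptide is not None:
            object.__setattr__(
                self, "peptide", np.asarray(self.peptide, dtype=float).reshape(-1, 3)
            )
        if box.shape != (3,) or np.any(box <= 0):
            raise GeometryError(f"box must be 3 positive lengths, got {box}")
        n = heads.shape[0]
        if heads.shape != (n, 3):
            raise GeometryError("heads must be (n, 3)")
        if ids.shape != (n,) or len(set(ids.tolist())) != n:
            raise GeometryError("lipid_ids must be unique, one per head")
        if carbonyls.shape != (n, 4, 3):
            raise GeometryError(
                f"carbonyls must be (n_lipids, 4, 3); lipid(s) with missing "
                f"reference atoms: shape {carbonyls.shape}"
            )

    @property
    def n_lipids(self) -> int:
        return int(self.heads.shape[0])

    def translated(self, shift: Sequence[float]) -> "BilayerFrame":
        """Rigidly translate everything by ``shift`` (wrapped into the box)."""
        shift = np.asarray(shift, dtype=float)
        return replace(
            self,
            heads=(self.heads + shift) % self.box,
            carbonyls=(self.carbonyls + shift) % self.box,
            waters=(self.waters + shift) % self.box,
            peptide=None if self.peptide is None else (self.peptide + shift) % self.box,
        )


def read_frame(
    path: str | Path, selections: ResidueSelections | None = None
) -> BilayerFrame:
    """Read a bilayer snapshot from a PDB or GRO file via MDAnalysis.

    Lipids, waters and the peptide channel are selected by residue name
    (see :class:`ResidueSelections`); each lipid must provide the head
    phosphorus and the four carbonyl reference atoms.  MDAnalysis works in
    Å, so positions are divided by 10.
    """
    import MDAnalysis as mda

    sel = selections or ResidueSelections()
    u = mda.Universe(str(path))
    if u.dimensions is None or np.any(u.dimensions[:3] <= 0):
        raise GeometryError(f"{path}: no periodic box information")
    box = u.dimensions[:3] / 10.0

    lipids = u.select_atoms("resname " + " ".join(sel.lipid_resnames))
    if lipids.n_atoms == 0:
        raise GeometryError(f"{path}: no lipid residues {sel.lipid_resnames}")
    ids, heads, carbonyls = [], [], []
    for res in lipids.residues:
        names = {a.name: a.position / 10.0 for a in res.atoms}
        if sel.head_atom not in names:
            raise GeometryError(f"{path}: lipid {res.resid} lacks head atom {sel.head_atom}")
        missing = [n for n in CARBONYL_ATOM_NAMES if n not in names]
        if missing:
            raise GeometryError(f"{path}: lipid {res.resid} lacks atoms {missing}")
        ids.append(res.resid)
        heads.append(names[sel.head_atom])
        carbonyls.append([names[n] for n in CARBONYL_ATOM_NAMES])

    waters = u.select_atoms(
        "resname " + " ".join(sel.water_resnames)
        + " and name " + " ".join(sel.water_atom_names)
    )
    peptide = u.select_atoms("resname " + " ".join(sel.peptide_resnames))
    return BilayerFrame(
        box=box,
        lipid_ids=np.array(ids),
        heads=np.array(heads),
        carbonyls=np.array(carbonyls),
        waters=waters.positions / 10.0 if waters.n_atoms else np.zeros((0, 3)),
        peptide=peptide.positions / 10.0 if peptide.n_atoms else None,
    )


def write_frame_gro(frame: BilayerFrame, path: str | Path) -> None:
    """Write a frame as a GRO file (lipids as DOPC, waters as SOL, peptide as MEL)."""
    import MDAnalysis as mda

    n_lip = frame.n_lipids
    n_wat = frame.waters.shape[0]
    n_pep = 0 if frame.peptide is None else frame.peptide.shape[0]
    atoms_per_lipid = 5  # P + four carbonyl reference atoms
    n_atoms = n_lip * atoms_per_lipid + n_wat + n_pep
    n_res = n_lip + n_wat + n_pep

    resindex = np.concatenate(
        [
            np.repeat(np.arange(n_lip), atoms_per_lipid),
            np.arange(n_lip, n_lip + n_wat),
            np.arange(n_lip + n_wat, n_res),
        ]
    )
    u = mda.Universe.empty(
        n_atoms, n_residues=n_res, atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("resnames", ["DOPC"] * n_lip + ["SOL"] * n_wat + ["MEL"] * n_pep)
    u.add_TopologyAttr("resids", np.concatenate(
        [frame.lipid_ids, np.arange(n_wat) + 1, np.arange(n_pep) + 1]
    ))
    u.add_TopologyAttr(
        "names",
        (["P", *CARBONYL_ATOM_NAMES] * n_lip) + ["OW"] * n_wat + ["CA"] * n_pep,
    )
    pos = np.vstack(
        [
            np.concatenate(
                [frame.heads[:, None, :], frame.carbonyls], axis=1
            ).reshape(-1, 3),
            frame.waters,
        ]
        + ([] if frame.peptide is None else [frame.peptide])
    )
    u.atoms.positions = pos * 10.0  # nm -> Å
    u.dimensions = np.array([*(frame.box * 10.0), 90.0, 90.0, 90.0])
    u.atoms.write(str(path))


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement components for an orthorhombic box."""
    return delta - box * np.round(delta / box)


def assign_leaflets(frame: BilayerFrame) -> np.ndarray:
    """Boolean array, True where a lipid head sits in the upper leaflet.

    The midplane is the mean head z; heads with ``z >= mean`` are upper
    (the tie rule).  All-coplanar heads are rejected as degenerate.
    """
    if frame.n_lipids < 2:
        raise GeometryError("leaflet assignment needs at least 2 lipids")
    z = frame.heads[:, 2]
    if np.ptp(z) == 0:
        raise GeometryError("all lipid heads coplanar; cannot split leaflets")
    return z >= z.mean()


@dataclass(frozen=True)
class APLResult:
    """Per-lipid partial areas from one leaflet's grid tessellation."""

    lipid_ids: np.ndarray
    areas: np.ndarray
    leaflet: str
    grid: tuple[int, int]
    cell_area: float
    #: Lateral area claimed by peptide atoms (0 unless ``include_peptide``).
    peptide_area: float

    @property
    def mean(self) -> float:
        return float(self.areas.mean())

    def group_means(self, near_ids: Sequence[int]) -> dict[str, float]:
        """Mean APL over all lipids, the ``near_ids`` subset, and the rest."""
        near = np.isin(self.lipid_ids, np.asarray(list(near_ids), dtype=int))
        out = {"all": self.mean}
        out["near"] = float(self.areas[near].mean()) if near.any() else np.nan
        out["bulk"] = float(self.areas[~near].mean()) if (~near).any() else np.nan
        return out


def grid_apl(
    frame: BilayerFrame,
    leaflet: str = "upper",
    grid: tuple[int, int] = (100, 100),
    include_peptide: bool = False,
) -> APLResult:
    """Grid-tessellation area per lipid for one leaflet.

    Every cell of an ``Nx × Ny`` lateral grid (cell area
    ``Lx·Ly/(Nx·Ny)``) is assigned to the head that minimizes the periodic
    lateral distance to the cell center; ties go to the lowest lipid id.
    With ``include_peptide`` the channel atoms compete for cells too and
    the area they claim is reported separately (and excluded from lipid
    areas); by default only lipids own cells.
    """
    nx, ny = grid
    if nx < 10 or ny < 10:
        raise GeometryError(f"grid must be at least 10x10, got {grid}")
    if leaflet not in ("upper", "lower"):
        raise GeometryError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")
    upper = assign_leaflets(frame)
    mask = upper if leaflet == "upper" else ~upper
    if not mask.any():
        raise GeometryError(f"no lipids in {leaflet} leaflet")

    order = np.argsort(frame.lipid_ids[mask], kind="stable")
    ids = frame.lipid_ids[mask][order]
    heads = frame.heads[mask][:, :2][order]
    sites = heads
    n_lipid_sites = sites.shape[0]
    if include_peptide:
        if frame.peptide is None:
            raise GeometryError("include_peptide requested but frame has no peptide")
        sites = np.vstack([heads, frame.peptide[:, :2]])

    lx, ly = frame.box[0], frame.box[1]
    cell_area = lx * ly / (nx * ny)
    cx = (np.arange(nx) + 0.5) * lx / nx
    cy = (np.arange(ny) + 0.5) * ly / ny
    centers = np.stack(
        [np.repeat(cx, ny), np.tile(cy, nx)], axis=1
    )  # (nx*ny, 2)

    box2 = frame.box[:2]
    # owner of each cell: argmin of periodic lateral distance (first index
    # wins on exact ties; lipid sites are sorted by id and precede peptide)
    d = centers[:, None, :] - sites[None, :, :]
    d = _min_image(d, box2)
    owner = np.argmin(np.einsum("ijk,ijk->ij", d, d), axis=1)

    counts = np.bincount(owner, minlength=sites.shape[0])
    areas = counts[:n_lipid_sites] * cell_area
    peptide_area = float(counts[n_lipid_sites:].sum() * cell_area)
    return APLResult(
        lipid_ids=ids,
        areas=areas.astype(float),
        leaflet=leaflet,
        grid=(nx, ny),
        cell_area=cell_area,
        peptide_area=peptide_area,
    )


def near_channel_selection(
    frame: BilayerFrame,
    cutoff: float = 0.3,
    reference: str = "atoms",
) -> tuple[np.ndarray, np.ndarray]:
    """Partition lipid ids into (near-channel, bulk) by lateral distance.

    A lipid is *near* when the minimal periodic lateral (xy) distance from
    its head to any peptide atom is <= ``cutoff`` (nm) — the first lipid
    shell around the channel wall.  ``reference="com"`` instead measures
    from the lateral center of mass of the channel, for comparison.
    """
    if frame.peptide is None or frame.peptide.shape[0] == 0:
        raise GeometryError("near-channel selection needs peptide atoms")
    box2 = frame.box[:2]
    heads = frame.heads[:, :2]
    if reference == "atoms":
        ref = frame.peptide[:, :2]
    elif reference == "com":
        ref = frame.peptide[:, :2].mean(axis=0, keepdims=True)
    else:
        raise GeometryError(f"reference must be 'atoms' or 'com', got {reference!r}")
    d = _min_image(heads[:, None, :] - ref[None, :, :], box2)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d)).min(axis=1)
    near = dist <= cutoff
    return frame.lipid_ids[near], frame.lipid_ids[~near]


def carbonyl_centers(frame: BilayerFrame, mass_weighted: bool = False) -> np.ndarray:
    """Per-lipid center of the four reference atoms, ``(n_lipids, 3)``.

    Unit masses by default; ``mass_weighted`` uses atomic masses of
    O21/C22/O31/C31 (the two options differ by well under 0.02 nm for
    these atoms).  Atom positions may straddle the periodic boundary; the
    center is taken in the minimum image around the first atom.
    """
    ref = frame.carbonyls[:, :1, :]
    rel = _min_image(frame.carbonyls - ref, frame.box)
    if mass_weighted:
        m = np.array([_ATOM_MASSES[n] for n in CARBONYL_ATOM_NAMES])
        center = ref[:, 0, :] + (rel * m[None, :, None]).sum(axis=1) / m.sum()
    else:
        center = ref[:, 0, :] + rel.mean(axis=1)
    return center % frame.box


def water_insertion_count(
    frame: BilayerFrame,
    cutoff: float = 0.3,
    region: Optional[Sequence[int]] = None,
    mass_weighted: bool = False,
) -> int:
    """Count distinct waters within ``cutoff`` of any carbonyl center.

    For each lipid (restricted to ``region`` ids when given) the center of
    its four reference atoms is computed and water oxygens within the 3D
    periodic cutoff of *any* such center are counted, each water at most
    once.  Neighbor search uses a periodic k-d tree; a brute-force
    all-pairs scan gives identical counts.
    """
    if frame.waters.shape[0] == 0:
        return 0
    centers = carbonyl_centers(frame, mass_weighted=mass_weighted)
    ids = frame.lipid_ids
    if region is not None:
        mask = np.isin(ids, np.asarray(list(region), dtype=int))
        centers = centers[mask]
        if centers.shape[0] == 0:
            return 0
    waters = frame.waters % frame.box
    tree = cKDTree(waters, boxsize=frame.box)
    hits = tree.query_ball_point(centers, r=cutoff)
    distinct: set[int] = set()
    for h in hits:
        distinct.update(h)
    return len(distinct)


def frame_statistics(
    frames: Sequence[BilayerFrame],
    grid: tuple[int, int] = (100, 100),
    near_cutoff: float = 0.3,
    water_cutoff: float = 0.3,
    include_peptide: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """APL and water-insertion time series over frames, plus mean ± SD.

    Returns ``(per_frame, summary)``: one row per frame with per-leaflet
    and combined mean APL (near-channel/bulk split when a peptide is
    present) and the water-insertion count; ``summary`` aggregates each
    column as mean and standard deviation (ddof=1, NaN for a single frame).
    """
    if not frames:
        raise GeometryError("frame_statistics needs at least one frame")
    rows = []
    for i, f in enumerate(frames):
        row: dict[str, float] = {"frame": i}
        per_leaflet = {}
        for leaflet in ("upper", "lower"):
            apl = grid_apl(f, leaflet=leaflet, grid=grid, include_peptide=include_peptide)
            per_leaflet[leaflet] = apl
            row[f"apl_{leaflet}"] = apl.mean
        both = np.concatenate([per_leaflet["upper"].areas, per_leaflet["lower"].areas])
        row["apl_both"] = float(both.mean())
        if f.peptide is not None:
            near_ids, _ = near_channel_selection(f, cutoff=near_cutoff)
            for leaflet, apl in per_leaflet.items():
                g = apl.group_means(near_ids)
                row[f"apl_near_{leaflet}"] = g["near"]
                row[f"apl_bulk_{leaflet}"] = g["bulk"]
            row["water_insertions_near"] = water_insertion_count(
                f, cutoff=water_cutoff, region=near_ids
            )
        row["water_insertions"] = water_insertion_count(f, cutoff=water_cutoff)
        rows.append(row)
    per_frame = pd.DataFrame(rows).set_index("frame")
    summary = per_frame.agg(["mean", "std"]).T
    return per_frame, summary
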