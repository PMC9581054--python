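"""Structural geometry: interface residues, solvent accessibility, centrality.

Three per-residue quantities drive downstream edgotype classification:

* **interface membership** — a residue belongs to a PPI binding interface if
  its minimum heavy-atom distance to any residue of the partner chain is at
  most 5 A (configurable; 4 and 6 A are the standard robustness cutoffs);
* **relative solvent accessibility (RSA)** — Shrake-Rupley accessible
  surface area of the residue, computed over all heavy atoms of the
  assembly, normalised by a per-amino-acid maximum ASA;
* **distance-to-center ratio** — distance of the residue centroid from the
  chain's heavy-atom centroid, relative to the chain radius.

Hydrogens, waters and hetero-compounds are excluded throughout; only the
first model of a multi-model file is used.  Residues are renumbered
sequentially (1-based) per chain, so position maps are explicit and never
depend on author numbering or insertion codes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

import biotite.structure as bst

from ._tables import AA3_TO_1, DEFAULT_VDW_RADIUS, MAX_ASA_TIEN, VDW_RADII
from .errors import (
    DegenerateInputError,
    EmptyStructureError,
    MissingChainError,
    TableMissError,
)

DEFAULT_INTERFACE_CUTOFF = 5.0
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SASA_POINTS = 960
RSA_BURIAL_CUTOFF = 0.25


@dataclass
class Residue:
    """One residue: 1-based sequential index, type, heavy-atom coordinates."""

    index: int
    name: str  # three-letter code, upper case
    coords: np.ndarray  # (n_atoms, 3) float64, Angstrom
    elements: list[str] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class Structure:
    """Heavy-atom coordinates of one model, grouped by chain."""

    chains: dict[str, list[Residue]]

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise MissingChainError(chain_id) from None

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chain(chain_id))


def parse_structure(pdb_text: str) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Keeps the first MODEL only; drops waters, hetero-compounds (HETATM)
    and hydrogens.  Raises :class:`EmptyStructureError` if nothing remains.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise EmptyStructureError("no coordinate model in input")
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.is_water() or res.het_flag != "A":
                continue
            coords, elements = [], []
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(atom.element.name.upper())
            if not coords:
                continue
            residues.append(
                Residue(
                    index=len(residues) + 1,
                    name=res.name.upper(),
                    coords=np.asarray(coords, dtype=float),
                    elements=elements,
                )
            )
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise EmptyStructureError("no ATOM records after filtering")
    return Structure(chains=chains)


def _chain_atom_table(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a chain's atoms; return (coords, residue index per atom)."""
    coords = np.concatenate([r.coords for r in residues])
    owner = np.concatenate(
        [np.full(len(r.coords), r.index, dtype=int) for r in residues]
    )
    return coords, owner


def interface_residues(
    structure: Structure,
    chain_x: str,
    chain_y: str,
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
) -> tuple[set[int], set[int]]:
    """Residue index sets forming the binding interface between two chains.

    A residue is interfacial iff its minimum heavy-atom distance to any
    residue of the partner chain is <= ``cutoff`` (inter-residue distance =
    minimum over all atom pairs).  Symmetric in the chain arguments.
    """
    res_x = structure.chain(chain_x)
    res_y = structure.chain(chain_y)
    cx, ox = _chain_atom_table(res_x)
    cy, oy = _chain_atom_table(res_y)
    pairs = cKDTree(cx).query_ball_tree(cKDTree(cy), r=cutoff)
    iface_x: set[int] = set()
    iface_y: set[int] = set()
    for i, hits in enumerate(pairs):
        if hits:
            iface_x.add(int(ox[i]))
            iface_y.update(int(oy[j]) for j in hits)
    return iface_x, iface_y


def _to_atom_array(structure: Structure) -> tuple[bst.AtomArray, np.ndarray]:
    chain_ids, res_ids, res_names, elements, coords = [], [], [], [], []
    for cid, residues in structure.chains.items():
        for res in residues:
            for k in range(len(res.coords)):
                chain_ids.append(cid)
                res_ids.append(res.index)
                res_names.append(res.name)
                elements.append(res.elements[k] if res.elements else "C")
                coords.append(res.coords[k])
    n = len(coords)
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.asarray(chain_ids)
    arr.res_id = np.asarray(res_ids)
    arr.res_name = np.asarray(res_names)
    arr.atom_name = np.array(["X"] * n)
    arr.element = np.asarray(elements)
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW_RADIUS) for e in elements])
    return arr, radii


def residue_sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> dict[tuple[str, int], float]:
    """Per-residue accessible surface area (A^2), Shrake-Rupley sampling.

    The sphere-sampling quadrature runs over all heavy atoms of the full
    assembly, so partner chains occlude each other's interface residues.
    ``n_points`` controls quadrature density (relative error ~1/sqrt(n)).
    """
    arr, radii = _to_atom_array(structure)
    atom_sasa = bst.sasa(
        arr, probe_radius=probe, point_number=n_points, vdw_radii=radii
    )
    atom_sasa = np.nan_to_num(atom_sasa)
    out: dict[tuple[str, int], float] = {}
    for cid, residues in structure.chains.items():
        for res in residues:
            out[(cid, res.index)] = 0.0
    for key_cid, key_rid, s in zip(arr.chain_id, arr.res_id, atom_sasa):
        out[(str(key_cid), int(key_rid))] += float(s)
    return out


def rsa(
    asa: float,
    residue_type: str,
    max_asa_table: dict[str, float] | None = None,
) -> float:
    """Relative solvent accessibility: ASA over the residue-type maximum.

    ``residue_type`` may be a one- or three-letter code.  The ratio is not
    clipped at 1 (observed ASA may exceed the tabulated maximum).
    """
    table = max_asa_table if max_asa_table is not None else MAX_ASA_TIEN
    key = residue_type.upper()
    if len(key) == 3:
        key = AA3_TO_1.get(key, key)
    if key not in table:
        raise TableMissError(residue_type)
    return asa / table[key]


def center_distance_ratio(
    structure: Structure, chain_id: str, residue_index: int
) -> float:
    """Distance of a residue from the chain centroid, relative to chain radius.

    Radius = maximum residue-centroid distance from the all-heavy-atom
    centroid of the chain.  A single-residue chain has ratio 0.
    """
    residues = structure.chain(chain_id)
    if len(residues) == 1:
        return 0.0
    all_coords = np.concatenate([r.coords for r in residues])
    center = all_coords.mean(axis=0)
    dists = {r.index: float(np.linalg.norm(r.centroid() - center)) for r in residues}
    if residue_index not in dists:
        raise MissingChainError(f"residue {residue_index} not in chain {chain_id}")
    radius = max(dists.values())
    if radius == 0.0:
        return 0.0
    return dists[residue_index] / radius


@dataclass(frozen=True)
class RsaComparison:
    """Welch two-sample comparison of RSA distributions."""

    t: float
    p: float
    mean_group: float
    mean_background: float
    sem_group: float
    sem_background: float


def compare_rsa_distributions(group_values, background_values) -> RsaComparison:
    """Welch two-sample t-test (two-sided) between a group and the background.

    Also reports means and standard errors, the usual display quantities.
    Raises :class:`DegenerateInputError` if both samples have zero variance.
    """
    g = np.asarray(group_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    if g.size < 2 or b.size < 2:
        raise DegenerateInputError("both samples must have size >= 2")
    if np.var(g) == 0.0 and np.var(b) == 0.0:
        if g.mean() == b.mean():
            # identical constant samples: no evidence of difference
            return RsaComparison(0.0, 1.0, g.mean(), b.mean(), 0.0, 0.0)
        raise DegenerateInputError("zero variance in both groups")
    t, p = stats.ttest_ind(g, b, equal_var=False)
    return RsaComparison(
        t=float(t),
        p=float(p),
        mean_group=float(g.mean()),
        mean_background=float(b.mean()),
        sem_group=float(stats.sem(g)) if g.size > 1 else math.nan,
        sem_background=float(stats.sem(b)) if b.size > 1 else math.nan,
    )
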