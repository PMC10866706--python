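"""Per-residue geometry and region labels from KRAS complex structures.

Interface residues are those with a minimal side-chain heavy-atom distance
to any partner-chain atom below 5 A (strict); the GTP pocket is defined
analogously by distance to nucleotide/Mg atoms; the hydrophobic core by
relative accessible surface area (rASA) < 0.25, with ASA from the
Shrake-Rupley rolling-probe method on the KRAS monomer and normalization by
the Tien et al. (2013) theoretical per-residue maxima. Secondary-structure
and pocket labels follow fixed residue ranges shipped with the package.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley

logger = logging.getLogger(__name__)

INTERFACE_DISTANCE = 5.0   # A, strict '<'
GTP_POCKET_DISTANCE = 5.0  # A, strict '<'
CORE_RASA = 0.25           # strict '<'

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
DEFAULT_LIGAND_IDS = ("GTP", "GDP", "GNP", "GSP", "MG")

#: Theoretical maximum ASA per residue (A^2), Tien et al. 2013.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Secondary-structure / functional region residue ranges (inclusive).
SECONDARY_RANGES: dict[str, tuple[int, int]] = {
    "ploop": (10, 17), "switch1": (25, 40), "switch2": (58, 76),
    "alpha1": (15, 24), "alpha2": (67, 73), "alpha3": (87, 104),
    "alpha4": (127, 136), "alpha5": (148, 166),
    "beta1": (3, 9), "beta2": (38, 44), "beta3": (51, 57),
    "beta4": (77, 84), "beta5": (109, 115), "beta6": (139, 143),
}

#: Surface pockets (explicit residue sets).
POCKET_RESIDUES: dict[str, frozenset[int]] = {
    "pocket1": frozenset([5, 6, 7, 39] + list(range(54, 57))
                         + list(range(70, 76))),
    "pocket2": frozenset(list(range(61, 66)) + list(range(90, 95))),
    "pocket3": frozenset([97, 101] + list(range(107, 112))
                         + list(range(136, 141)) + list(range(161, 167))),
    "pocket4": frozenset([17, 21, 57] + list(range(24, 41))),
}


@dataclass
class StructureAnnotation:
    residue: int
    partner_distance: float = math.inf
    ligand_distance: float = math.inf
    rasa: float = math.nan
    labels: set[str] = field(default_factory=set)


def parse_structure(path: str | Path, kras_chain: str,
                    partner_chain: str | None = None,
                    ligand_ids: Sequence[str] = DEFAULT_LIGAND_IDS,
                    ) -> pd.DataFrame:
    """Parse a PDB file into an atom table.

    Returns a DataFrame with one row per heavy atom (hydrogens/deuteriums
    dropped, alternate locations resolved to the highest-occupancy
    conformer) and columns chain, resnum, resname, atom, element, x, y, z,
    is_ligand. Raises if the KRAS chain (or a requested partner chain) is
    absent.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains = {c.id for c in model.get_chains()}
    if kras_chain not in chains:
        raise ValueError(f"chain {kras_chain!r} not found in {path}")
    if partner_chain is not None and partner_chain not in chains:
        raise ValueError(f"partner chain {partner_chain!r} not found in {path}")
    ligand_ids = {l.upper() for l in ligand_ids}
    rows = []
    for chain in model.get_chains():
        for res in chain.get_residues():
            resname = res.get_resname().strip().upper()
            for atom in res.get_atoms():  # disordered -> selected (highest occ.)
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                x, y, z = atom.get_coord()
                rows.append({
                    "chain": chain.id, "resnum": res.get_id()[1],
                    "resname": resname, "atom": atom.get_name().strip(),
                    "element": element,
                    "x": float(x), "y": float(y), "z": float(z),
                    "is_ligand": resname in ligand_ids,
                })
    return pd.DataFrame(rows)


def _sidechain_coords(atoms: pd.DataFrame, glycine_ca_surrogate: bool = True,
                      all_atom: bool = False) -> np.ndarray:
    """Heavy side-chain coordinates of one residue's atom rows; glycine
    falls back to C-alpha (switchable) since it has no side chain."""
    if atoms.empty:
        raise ValueError("residue has no atoms")
    if all_atom:
        sel = atoms
    else:
        sel = atoms[~atoms["atom"].isin(BACKBONE_ATOMS)]
        if sel.empty:
            if not glycine_ca_surrogate:
                return np.empty((0, 3))
            sel = atoms[atoms["atom"] == "CA"]
            if sel.empty:
                sel = atoms
    return sel[["x", "y", "z"]].to_numpy(dtype=float)


def min_sidechain_distance(residue_atoms: pd.DataFrame,
                           target_coords: np.ndarray,
                           glycine_ca_surrogate: bool = True,
                           all_atom: bool = False) -> float:
    """Minimal Euclidean distance between a residue's side-chain heavy
    atoms and any target atom."""
    target = np.asarray(target_coords, dtype=float).reshape(-1, 3)
    if target.size == 0:
        raise ValueError("empty target atom set")
    coords = _sidechain_coords(residue_atoms, glycine_ca_surrogate, all_atom)
    if coords.size == 0:
        return math.inf
    diff = coords[:, None, :] - target[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def chain_min_distances(atoms: pd.DataFrame, kras_chain: str,
                        target_mask: pd.Series,
                        glycine_ca_surrogate: bool = True,
                        all_atom: bool = False) -> dict[int, float]:
    """Per-residue minimal side-chain heavy-atom distance from the KRAS
    chain to the atoms selected by ``target_mask``."""
    target = atoms.loc[target_mask, ["x", "y", "z"]].to_numpy(dtype=float)
    out: dict[int, float] = {}
    kras = atoms[(atoms["chain"] == kras_chain) & ~atoms["is_ligand"]]
    for resnum, group in kras.groupby("resnum"):
        if target.size == 0:
            out[int(resnum)] = math.inf
        else:
            out[int(resnum)] = min_sidechain_distance(
                group, target, glycine_ca_surrogate, all_atom)
    return out


def partner_distances(atoms: pd.DataFrame, kras_chain: str,
                      partner_chain: str, **kw) -> dict[int, float]:
    mask = (atoms["chain"] == partner_chain) & ~atoms["is_ligand"]
    return chain_min_distances(atoms, kras_chain, mask, **kw)


def ligand_distances(atoms: pd.DataFrame, kras_chain: str, **kw) -> dict[int, float]:
    return chain_min_distances(atoms, kras_chain, atoms["is_ligand"], **kw)


def relative_asa(path: str | Path, kras_chain: str,
                 probe_radius: float = 1.4, n_points: int = 100,
                 ) -> dict[int, float]:
    """Residue rASA of the isolated KRAS chain (partner and ligands
    stripped) by Shrake-Rupley, normalized by Tien et al. maxima.

    Residues of unknown type get their raw ASA with a warning.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chain = model[kras_chain]
    # strip heteroatoms (ligands/waters) and any other chains
    for other in [c for c in model.get_chains() if c.id != kras_chain]:
        model.detach_child(other.id)
    for res in [r for r in chain.get_residues() if r.get_id()[0] != " "]:
        chain.detach_child(res.get_id())
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(model, level="R")
    out = {}
    for res in chain.get_residues():
        resname = res.get_resname().strip().upper()
        asa = float(res.sasa)
        if resname in MAX_ASA:
            out[res.get_id()[1]] = asa / MAX_ASA[resname]
        else:
            logger.warning("unknown residue %s %d: reporting unnormalized ASA",
                           resname, res.get_id()[1])
            out[res.get_id()[1]] = asa
    return out


def annotate_regions(distances: Mapping[int, float] | None = None,
                     rasa: Mapping[int, float] | None = None,
                     ligand_dist: Mapping[int, float] | None = None,
                     residues: Iterable[int] | None = None,
                     secondary_ranges: Mapping[str, tuple[int, int]] | None = None,
                     pocket_residues: Mapping[str, frozenset[int]] | None = None,
                     ) -> list[StructureAnnotation]:
    """Assign region labels per residue.

    interface: partner distance < 5 A; gtp_pocket: ligand distance < 5 A;
    core: rASA < 0.25 (missing rASA -> never core); secondary structure and
    pockets from the shipped residue ranges. A residue may carry several
    labels. Idempotent: labels are a pure function of the inputs.
    """
    distances = dict(distances or {})
    rasa = dict(rasa or {})
    ligand_dist = dict(ligand_dist or {})
    secondary_ranges = dict(secondary_ranges or SECONDARY_RANGES)
    pocket_residues = dict(pocket_residues or POCKET_RESIDUES)
    if residues is None:
        residues = sorted(set(distances) | set(rasa) | set(ligand_dist))
    out = []
    for r in residues:
        if not 1 <= r <= 188:
            raise ValueError(f"residue {r} outside 1-188")
        ann = StructureAnnotation(
            residue=r,
            partner_distance=distances.get(r, math.inf),
            ligand_distance=ligand_dist.get(r, math.inf),
            rasa=rasa.get(r, math.nan))
        if ann.partner_distance < INTERFACE_DISTANCE:
            ann.labels.add("interface")
        if ann.ligand_distance < GTP_POCKET_DISTANCE:
            ann.labels.add("gtp_pocket")
        if not math.isnan(ann.rasa) and ann.rasa < CORE_RASA:
            ann.labels.add("core")
        for name, (lo, hi) in secondary_ranges.items():
            if lo <= r <= hi:
                ann.labels.add(name)
        for name, members in pocket_residues.items():
            if r in members:
                ann.labels.add(name)
        out.append(ann)
    return out


def annotate_structure(path: str | Path, kras_chain: str, partner_chain: str,
                       ligand_ids: Sequence[str] = DEFAULT_LIGAND_IDS,
                       **kw) -> list[StructureAnnotation]:
    """End-to-end: parse a complex, compute distances and rASA, and label."""
    atoms = parse_structure(path, kras_chain, partner_chain, ligand_ids)
    dist = partner_distances(atoms, kras_chain, partner_chain, **kw)
    lig = ligand_distances(atoms, kras_chain, **kw)
    rasa = relative_asa(path, kras_chain)
    return annotate_regions(dist, rasa, lig)


def write_annotation_table(annotations: Sequence[StructureAnnotation],
                           path: str | Path) -> None:
    rows = [{"residue": a.residue, "partner_distance": a.partner_distance,
             "ligand_distance": a.ligand_distance, "rasa": a.rasa,
             "labels": ";".join(sorted(a.labels))}
            for a in annotations]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> list[StructureAnnotation]:
    """Read a precomputed per-residue table (columns residue,
    partner_distance, ligand_distance, rasa and optionally labels). If the
    labels column is absent, labels are recomputed from the numeric
    columns."""
    df = pd.read_csv(path, sep="\t")
    if "labels" in df.columns:
        out = []
        for row in df.itertuples(index=False):
            labels = set(str(row.labels).split(";")) if isinstance(row.labels, str) \
                and row.labels else set()
            out.append(StructureAnnotation(
                int(row.residue), float(row.partner_distance),
                float(row.ligand_distance), float(row.rasa), labels))
        return out
    return annotate_regions(
        distances={int(r.residue): float(r.partner_distance)
                   for r in df.itertuples(index=False)},
        rasa={int(r.residue): float(r.rasa) for r in df.itertuples(index=False)},
        ligand_dist={int(r.residue): float(r.ligand_distance)
                     for r in df.itertuples(index=False)})
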