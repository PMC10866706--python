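"""Synthetic ddPCA-like data with known ground truth.

The generator emulates the study design end to end: additive per-
substitution folding and binding free-energy changes, a mutagenesis
library of all singles plus doubles built on mildly detrimental
backgrounds (split into three position blocks, each with its own
experiments and affine output maps), Boltzmann nonlinearities, and
heteroscedastic Gaussian measurement noise (or a Poisson read-count path).
Designated interface, allosteric, GTP-pocket and core positions make every
downstream mapping stage testable against a known answer.

Folding effects follow a three-component mixture — a point mass near zero,
a destabilizing gamma component (upweighted at core positions, as core
mutations dominate folding defects in real scans) and a small stabilizing
component. Binding effects are large for a random subset of substitutions
at interface positions (interfaces tolerate conservative changes, which
keeps the interface-average threshold realistic), uniformly large at
planted allosteric positions, and near zero elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import AMINO_ACIDS, KRAS_SEQUENCE, PARTNERS
from .structure_annotation import StructureAnnotation, annotate_regions
from .thermo_model import RT, fraction_bound, fraction_folded
from .variant_data import (ExperimentId, FitnessObservation, Genotype,
                           Substitution, VariantCountRecord,
                           fitness_from_counts)

AA_LIST = list(AMINO_ACIDS)


@dataclass
class EffectParams:
    """Mixture parameters for true energy draws (kcal/mol)."""

    p_zero_surface: float = 0.45      # point-mass-near-zero weight, surface
    p_zero_core: float = 0.10         # ... at core positions
    p_stabilizing: float = 0.05
    zero_sd: float = 0.05
    stabilizing_sd: float = 0.3
    destab_gamma_shape: float = 2.0
    destab_gamma_scale: float = 0.8
    interface_ddgb_loc: float = 1.5   # + gamma(2, 0.6); strong binding defects
    interface_hit_fraction: float = 0.5
    allosteric_ddgb: float = 2.0
    allosteric_ddgb_sd: float = 0.2
    binding_null_sd: float = 0.05

    def __post_init__(self):
        for w in (self.p_zero_surface, self.p_zero_core, self.p_stabilizing):
            if not 0 <= w <= 1:
                raise ValueError("mixture weights must lie in [0,1]")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated study."""

    reference: str
    positions: list[int]
    partners: tuple[str, ...]
    seed: int
    wt_dgf: float
    wt_dgb: dict[str, float]
    ddgf: dict[str, float]
    ddgb: dict[str, dict[str, float]]
    affine: dict[ExperimentId, tuple[float, float]]
    block_of: dict[int, int]
    core_positions: set[int]
    gtp_pocket_positions: set[int]
    interface_positions: dict[str, set[int]]
    allosteric_positions: dict[str, set[int]]
    effect_params: EffectParams

    def singles(self) -> list[Genotype]:
        out = []
        for sub in sorted(self.ddgf, key=lambda s: (int(s[1:-1]), s)):
            g = Substitution(int(sub[1:-1]), sub[0], sub[-1])
            out.append(Genotype((g,)))
        return out

    def abundance_effect(self, sub: str) -> float:
        """True abundance-fitness effect of a single on the wild-type-
        normalized scale (slope 1): p_f(mut) - p_f(wt)."""
        return float(fraction_folded(self.wt_dgf + self.ddgf[sub])
                     - fraction_folded(self.wt_dgf))

    def predict(self, genotype: Genotype, experiment: ExperimentId) -> float:
        a, b = self.affine[experiment]
        dgf = self.wt_dgf + sum(self.ddgf[str(s)] for s in genotype)
        if experiment.assay == "abundance":
            p = float(fraction_folded(dgf))
        else:
            coeffs = self.ddgb[experiment.partner]
            dgb = self.wt_dgb[experiment.partner] + sum(
                coeffs[str(s)] for s in genotype)
            p = float(fraction_bound(dgf, dgb))
        return a + b * p

    def energies_table(self) -> pd.DataFrame:
        rows = [{"trait": "folding", "partner": "none", "variant": s,
                 "true_ddg": v} for s, v in self.ddgf.items()]
        for p, coeffs in self.ddgb.items():
            rows += [{"trait": "binding", "partner": p, "variant": s,
                      "true_ddg": v} for s, v in coeffs.items()]
        return pd.DataFrame(rows)


def sample_truth(n_positions: int = 150,
                 partners: Sequence[str] = PARTNERS,
                 seed: int = 0,
                 effect_params: EffectParams | None = None,
                 wt_dgf: float = -2.0,
                 wt_dgb: float = -0.5,
                 n_interface: int = 8,
                 n_allosteric: int = 4,
                 n_gtp_pocket: int = 6,
                 core_fraction: float = 0.25) -> SyntheticTruth:
    """Draw a ground truth over the first ``n_positions`` mutable positions
    (2..n_positions+1) of the KRAS sequence. Deterministic in ``seed``."""
    if n_positions < 10:
        raise ValueError("n_positions must be >= 10")
    ep = effect_params or EffectParams()
    rng = np.random.default_rng(seed)
    positions = list(range(2, 2 + n_positions))
    blocks = {}
    third = math.ceil(n_positions / 3)
    for i, pos in enumerate(positions):
        blocks[pos] = min(i // third + 1, 3)

    core = set(rng.choice(positions, size=int(core_fraction * n_positions),
                          replace=False).tolist())
    surface = [p for p in positions if p not in core]
    gtp_pocket = set(rng.choice(surface, size=min(n_gtp_pocket, len(surface)),
                                replace=False).tolist())
    interface: dict[str, set[int]] = {}
    allosteric: dict[str, set[int]] = {}
    for partner in partners:
        pool = [p for p in surface if p not in gtp_pocket]
        iface = set(rng.choice(pool, size=min(n_interface, len(pool)),
                               replace=False).tolist())
        rest = [p for p in pool if p not in iface]
        allo = set(rng.choice(rest, size=min(n_allosteric, len(rest)),
                              replace=False).tolist())
        interface[partner] = iface
        allosteric[partner] = allo

    ddgf: dict[str, float] = {}
    ddgb: dict[str, dict[str, float]] = {p: {} for p in partners}
    for pos in positions:
        wt = KRAS_SEQUENCE[pos - 1]
        p_zero = ep.p_zero_core if pos in core else ep.p_zero_surface
        for mut in AA_LIST:
            if mut == wt:
                continue
            sub = f"{wt}{pos}{mut}"
            u = rng.random()
            if u < p_zero:
                ddgf[sub] = float(rng.normal(0.0, ep.zero_sd))
            elif u < p_zero + ep.p_stabilizing:
                ddgf[sub] = -abs(float(rng.normal(0.0, ep.stabilizing_sd)))
            else:
                ddgf[sub] = float(rng.gamma(ep.destab_gamma_shape,
                                            ep.destab_gamma_scale))
            for partner in partners:
                if pos in interface[partner] and rng.random() < ep.interface_hit_fraction:
                    val = ep.interface_ddgb_loc + float(rng.gamma(2.0, 0.6))
                elif pos in allosteric[partner]:
                    val = float(rng.normal(ep.allosteric_ddgb,
                                           ep.allosteric_ddgb_sd))
                else:
                    val = float(rng.normal(0.0, ep.binding_null_sd))
                ddgb[partner][sub] = val

    wt_dgb_map = {p: wt_dgb for p in partners}
    # per-experiment affine maps: slope near 1, intercept placing the
    # wild-type fitness near 0 (fitness is wild-type-normalized)
    affine: dict[ExperimentId, tuple[float, float]] = {}
    present_blocks = sorted(set(blocks.values()))
    pf_wt = float(fraction_folded(wt_dgf))
    for blk in present_blocks:
        b = float(rng.uniform(0.9, 1.1))
        affine[ExperimentId("abundance", "none", blk)] = (-b * pf_wt, b)
        for partner in partners:
            pb = float(fraction_bound(wt_dgf, wt_dgb))
            b2 = float(rng.uniform(0.9, 1.1))
            affine[ExperimentId("binding", partner, blk)] = (-b2 * pb, b2)

    return SyntheticTruth(
        reference=KRAS_SEQUENCE, positions=positions,
        partners=tuple(partners), seed=seed, wt_dgf=wt_dgf,
        wt_dgb=wt_dgb_map, ddgf=ddgf, ddgb=ddgb, affine=affine,
        block_of=blocks, core_positions=core,
        gtp_pocket_positions=gtp_pocket, interface_positions=interface,
        allosteric_positions=allosteric, effect_params=ep)


def design_library(truth: SyntheticTruth, backgrounds_per_single: int = 10,
                   background_effect_window: tuple[float, float] = (-0.5, -0.05),
                   ) -> list[Genotype]:
    """All singles plus doubles pairing each single with backgrounds drawn
    from mildly detrimental singles of the same block.

    The background pool contains singles whose true abundance-fitness
    effect (wild-type-normalized) lies in ``background_effect_window``,
    mirroring the bias toward weakly detrimental genetic backgrounds. Each
    single receives ``backgrounds_per_single`` backgrounds (sampled without
    replacement when the pool allows), so the median number of genetic
    backgrounds per single equals the requested value.
    """
    rng = np.random.default_rng(truth.seed + 1)
    singles = truth.singles()
    if backgrounds_per_single == 0:
        return singles
    lo, hi = background_effect_window
    pools: dict[int, list[Substitution]] = {}
    for g in singles:
        sub = g.substitutions[0]
        if lo <= truth.abundance_effect(str(sub)) <= hi:
            pools.setdefault(truth.block_of[sub.position], []).append(sub)
    if not any(pools.values()):
        raise ValueError("no single falls in the mild-detrimental window")
    genotypes = list(singles)
    seen: set[tuple[str, ...]] = set()
    for g in singles:
        focal = g.substitutions[0]
        pool = [s for s in pools.get(truth.block_of[focal.position], [])
                if s.position != focal.position]
        if not pool:
            raise ValueError(
                f"empty background pool for block {truth.block_of[focal.position]}")
        k = min(backgrounds_per_single, len(pool))
        picks = rng.choice(len(pool), size=k, replace=False)
        for i in picks:
            pair = tuple(sorted([focal, pool[i]]))
            key = tuple(str(s) for s in pair)
            if key not in seen:
                seen.add(key)
                genotypes.append(Genotype(pair))
    return genotypes


@dataclass
class SimulatedData:
    observations: list[FitnessObservation]
    noiseless: dict[tuple[str, ExperimentId], float]
    counts: list[VariantCountRecord] = field(default_factory=list)


def simulate_fitness(truth: SyntheticTruth, library: Sequence[Genotype],
                     noise_mode: str = "direct_sigma", seed: int = 0,
                     sigma: float = 0.1, depth: int = 2000,
                     sigma_floor: float = 1e-6) -> SimulatedData:
    """Simulate fitness tables for every (genotype, experiment) pair.

    ``direct_sigma``: per-observation sigma_n = sigma * U(0.8, 1.2) and
    y = noiseless + Normal(0, sigma_n); with sigma = 0 the emitted fitness
    equals affine(Boltzmann(truth)) exactly (sigma_floor keeps reported
    errors positive). ``counts``: input reads ~ Poisson(depth), output
    reads ~ Poisson(input * exp(noiseless fitness)), converted by the
    log-ratio estimator. The wild type is observed in every experiment.
    """
    if noise_mode not in ("direct_sigma", "counts"):
        raise ValueError(f"unsupported noise mode {noise_mode!r}")
    rng = np.random.default_rng(seed)
    experiments = sorted(truth.affine)
    wt = Genotype()
    data = SimulatedData([], {})
    for exp in experiments:
        genotypes = [wt] + [g for g in library
                            if all(truth.block_of[s.position] == exp.block
                                   for s in g)]
        wt_record = VariantCountRecord(wt, exp, 1, depth, depth)
        for g in genotypes:
            y0 = truth.predict(g, exp)
            data.noiseless[(str(g), exp)] = y0
            if noise_mode == "direct_sigma":
                s_n = sigma * float(rng.uniform(0.8, 1.2))
                y = y0 + (float(rng.normal(0.0, s_n)) if s_n > 0 else 0.0)
                data.observations.append(FitnessObservation(
                    g, exp, y, max(s_n, sigma_floor)))
            else:
                n_in = max(1, int(rng.poisson(depth)))
                n_out = int(rng.poisson(n_in * math.exp(y0)))
                rec = VariantCountRecord(g, exp, 1, n_in, n_out)
                data.counts.append(rec)
                y, s_n = fitness_from_counts(rec, wt_record, pseudocount=0.5)
                data.observations.append(FitnessObservation(g, exp, y, s_n))
    return data


def synthetic_structure(truth: SyntheticTruth, partner: str | None = None,
                        toy_pdb_path: str | Path | None = None,
                        ) -> list[StructureAnnotation]:
    """Per-residue annotations consistent with the designated positions.

    Interface positions receive partner distances < 5 A, GTP-pocket
    positions ligand distances < 5 A, core positions rASA < 0.25 (all
    others safely outside the thresholds). When ``toy_pdb_path`` is given,
    a toy coordinate file is also written — one side-chain atom per
    residue, a single partner atom and an Mg ion — whose recomputed
    distances reproduce the emitted table exactly (the table is derived
    from the written, 3-decimal coordinates).
    """
    partner = partner or truth.partners[0]
    rng = np.random.default_rng(truth.seed + 7 + truth.partners.index(partner))
    ligand_xy = np.array([0.0, 12.0])
    coords: dict[int, np.ndarray] = {}
    for pos in truth.positions:
        phi = rng.uniform(0.2, math.pi - 0.2)
        if pos in truth.interface_positions[partner]:
            r = rng.uniform(2.5, 4.5)  # near partner (origin), away from Mg
            xy = np.array([r * math.cos(phi), -r * math.sin(phi)])
        elif pos in truth.gtp_pocket_positions:
            r = rng.uniform(2.5, 4.5)  # near the Mg site
            xy = ligand_xy + np.array([r * math.cos(phi), r * math.sin(phi)])
        else:
            r = rng.uniform(6.0, 30.0)
            xy = np.array([r * math.cos(phi), -r * math.sin(phi)])
        coords[pos] = np.round(np.array([xy[0], xy[1], 0.0]), 3)

    rasa = {}
    for pos in truth.positions:
        if pos in truth.core_positions:
            rasa[pos] = float(rng.uniform(0.03, 0.2))
        else:
            rasa[pos] = float(rng.uniform(0.3, 0.95))

    dist = {p: float(np.linalg.norm(coords[p][:2])) for p in truth.positions}
    lig = {p: float(np.linalg.norm(coords[p][:2] - ligand_xy))
           for p in truth.positions}

    if toy_pdb_path is not None:
        _write_toy_pdb(toy_pdb_path, truth, coords, ligand_xy)
    return annotate_regions(distances=dist, rasa=rasa, ligand_dist=lig,
                            residues=truth.positions)


_AA3 = {"A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
        "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
        "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
        "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL"}


def _atom_line(record: str, serial: int, name: str, resname: str, chain: str,
               resseq: int, x: float, y: float, z: float, element: str) -> str:
    # PDB v3.3 fixed columns: name in 13-16 (1/2-letter elements start at
    # 14/13), resname 18-20, chain 22, resseq 23-26, coords 31-54
    name_field = f"{name:<4s}" if len(element) == 2 else f" {name:<3s}"
    return (f"{record:<6s}{serial:5d} {name_field}{'':1s}{resname:>3s} "
            f"{chain:1s}{resseq:4d}{'':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}")


def _write_toy_pdb(path, truth: SyntheticTruth, coords, ligand_xy) -> None:
    lines = []
    serial = 1
    for pos in truth.positions:
        wt = truth.reference[pos - 1]
        name = "CA" if wt == "G" else "CB"
        x, y, z = coords[pos]
        lines.append(_atom_line("ATOM", serial, name, _AA3[wt], "A", pos,
                                x, y, z, "C"))
        serial += 1
    lines.append(_atom_line("ATOM", serial, "CA", "GLY", "B", 1,
                            0.0, 0.0, 0.0, "C"))
    serial += 1
    lines.append(_atom_line("HETATM", serial, "MG", "MG", "A", 999,
                            float(ligand_xy[0]), float(ligand_xy[1]), 0.0,
                            "MG"))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
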