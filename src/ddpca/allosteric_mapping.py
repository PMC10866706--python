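"""Downstream statistics: position summaries, allosteric calls, ROC,
enrichment and beta-sheet decay.

An *allosteric mutation* is a substitution at a non-interface residue whose
binding ddG significantly exceeds the average magnitude of interface-
mutation effects (two-sided z-test against that threshold, BH-corrected).
A *major allosteric site* is a non-interface residue whose position-wise
weighted mean |ddG_b| is at least the interface average. Weighted means use
inverse-variance weights (1/sd^2) from the Monte-Carlo errors by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm, spearmanr
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

from .structure_annotation import StructureAnnotation
from .uncertainty import FreeEnergyEstimate


def variant_position(variant: str) -> int:
    """1-based residue position of a substitution string like 'G12C'."""
    return int(variant[1:-1])


def weighted_mean_abs(ddgs: Sequence[float], sds: Sequence[float],
                      weights: str = "inverse_variance") -> float:
    """Weighted mean of |ddG| with w_i = 1/sd_i^2 (or uniform)."""
    ddgs = np.asarray(ddgs, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if ddgs.size == 0:
        raise ValueError("empty input")
    if ddgs.shape != sds.shape:
        raise ValueError("ddgs and sds must have equal length")
    if weights == "inverse_variance":
        if np.any(sds <= 0):
            raise ValueError("sds must be > 0 for inverse-variance weights")
        w = 1.0 / sds ** 2
    elif weights == "uniform":
        w = np.ones_like(ddgs)
    else:
        raise ValueError(f"unknown weights {weights!r}")
    return float(np.sum(w * np.abs(ddgs)) / np.sum(w))


def _interface_residues(annotations: Sequence[StructureAnnotation]) -> set[int]:
    return {a.residue for a in annotations if "interface" in a.labels}


def _binding_estimates(estimates: Sequence[FreeEnergyEstimate], partner: str,
                       confident_only: bool) -> list[FreeEnergyEstimate]:
    return [e for e in estimates
            if e.trait == f"binding:{partner}"
            and (e.confident or not confident_only)]


def interface_threshold(estimates: Sequence[FreeEnergyEstimate],
                        annotations: Mapping[str, Sequence[StructureAnnotation]]
                        | Sequence[StructureAnnotation],
                        partners: Iterable[str],
                        confident_only: bool = False,
                        weights: str = "inverse_variance") -> float:
    """Weighted mean |ddG_b| over all mutations in interface residues,
    pooled across the requested partners (one partner for a single-partner
    map, all six for the multi-partner threshold).

    ``annotations`` is either one annotation list applied to every partner
    or a mapping partner -> annotation list (interfaces differ by
    partner)."""
    partners = list(partners)
    if not partners:
        raise ValueError("empty partner set")
    ddgs, sds = [], []
    for p in partners:
        ann = annotations[p] if isinstance(annotations, Mapping) else annotations
        iface = _interface_residues(ann)
        for e in _binding_estimates(estimates, p, confident_only):
            if variant_position(e.variant) in iface:
                ddgs.append(e.mean_ddg)
                sds.append(e.sd_ddg)
    if not ddgs:
        raise ValueError("no interface mutations with estimates")
    return weighted_mean_abs(ddgs, sds, weights)


@dataclass(frozen=True)
class AllostericCall:
    estimate: FreeEnergyEstimate
    residue: int
    z: float
    p: float
    q: float
    called: bool


def call_allosteric_mutations(estimates: Sequence[FreeEnergyEstimate],
                              annotations: Sequence[StructureAnnotation],
                              threshold: float, partner: str,
                              fdr: float = 0.05,
                              confident_only: bool = False,
                              ) -> list[AllostericCall]:
    """z-test every non-interface binding mutation against the interface
    threshold; a call requires BH q <= fdr AND mean ddG above threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    iface = _interface_residues(annotations)
    family = [e for e in _binding_estimates(estimates, partner, confident_only)
              if variant_position(e.variant) not in iface]
    if not family:
        return []
    z = np.array([(e.mean_ddg - threshold) / e.sd_ddg if e.sd_ddg > 0
                  else np.inf * np.sign(e.mean_ddg - threshold)
                  for e in family])
    z = np.nan_to_num(z, nan=0.0)
    p = np.where(np.isinf(z), 0.0, 2.0 * norm.sf(np.abs(z)))
    p = np.where(z == 0.0, 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [AllostericCall(e, variant_position(e.variant), float(zi),
                           float(pi), float(qi),
                           bool(qi <= fdr and e.mean_ddg > threshold))
            for e, zi, pi, qi in zip(family, z, p, q)]


@dataclass
class PositionSummary:
    residue: int
    trait: str
    weighted_mean_abs_ddg: float
    max_ddg: float
    n_mutations: int
    is_interface: bool
    is_major_allosteric: bool = False


def position_summaries(estimates: Sequence[FreeEnergyEstimate],
                       annotations: Sequence[StructureAnnotation],
                       trait: str, confident_only: bool = False,
                       weights: str = "inverse_variance",
                       ) -> list[PositionSummary]:
    """Per-residue weighted mean |ddG|, max ddG and mutation count for one
    trait ('folding' or 'binding:<partner>')."""
    iface = _interface_residues(annotations)
    per_pos: dict[int, list[FreeEnergyEstimate]] = {}
    for e in estimates:
        if e.trait != trait or (confident_only and not e.confident):
            continue
        per_pos.setdefault(variant_position(e.variant), []).append(e)
    out = []
    for pos in sorted(per_pos):
        group = per_pos[pos]
        out.append(PositionSummary(
            residue=pos, trait=trait,
            weighted_mean_abs_ddg=weighted_mean_abs(
                [e.mean_ddg for e in group], [e.sd_ddg for e in group], weights),
            max_ddg=max(e.mean_ddg for e in group),
            n_mutations=len(group),
            is_interface=pos in iface))
    return out


def call_major_allosteric_sites(summaries: Sequence[PositionSummary],
                                threshold: float) -> list[PositionSummary]:
    """Non-interface residues whose weighted mean |ddG_b| is >= the
    interface threshold (inclusive). Marks and returns the called sites;
    monotone in the threshold."""
    called = []
    for s in summaries:
        s.is_major_allosteric = (not s.is_interface
                                 and s.weighted_mean_abs_ddg >= threshold)
        if s.is_major_allosteric:
            called.append(s)
    return called


def roc_auc(scores: Mapping[int, float], labels: Mapping[int, bool],
            ) -> tuple[float, pd.DataFrame]:
    """ROC-AUC for predicting labelled (interface) residues from
    per-residue scores; equals the Mann-Whitney concordance probability
    with ties credited 0.5. Returns the AUC and the curve points."""
    residues = sorted(set(scores) & set(labels))
    y = np.array([bool(labels[r]) for r in residues])
    s = np.array([float(scores[r]) for r in residues])
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thresh = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
    return auc, curve


@dataclass(frozen=True)
class EnrichmentResult:
    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    haldane_corrected: bool = False


def fisher_enrichment(in_group_hits: int, in_group_misses: int,
                      out_group_hits: int, out_group_misses: int,
                      ) -> EnrichmentResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The odds ratio is the sample OR ad/bc, with a Haldane 0.5 correction of
    every cell iff any cell is zero (flagged)."""
    cells = (in_group_hits, in_group_misses, out_group_hits, out_group_misses)
    if any(c < 0 for c in cells):
        raise ValueError("negative cell")
    if sum(cells) < 1:
        raise ValueError("empty table")
    a, b, c, d = cells
    corrected = 0 in cells
    if corrected:
        oa, ob, oc, od = (x + 0.5 for x in cells)
    else:
        oa, ob, oc, od = (float(x) for x in cells)
    odds = (oa * od) / (ob * oc)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(((a, b), (c, d)), float(odds), float(p), corrected)


@dataclass
class StrandDecay:
    per_strand_mean: dict[str, float]
    spearman_rho: float
    spearman_p: float
    n_mutations: int


def beta_sheet_decay(estimates: Sequence[FreeEnergyEstimate],
                     annotations: Sequence[StructureAnnotation],
                     strand_order: Sequence[str], partner: str,
                     confident_only: bool = False,
                     weights: str = "inverse_variance") -> StrandDecay:
    """Decay of |ddG_b| across successive beta-strands.

    ``strand_order`` lists strand labels (e.g. beta2, beta3, ...) sorted by
    increasing distance to the partner. Reports the weighted mean |ddG_b|
    per strand and the mutation-level Spearman correlation between strand
    rank and |ddG_b| (negative = decay)."""
    strand_of: dict[int, str] = {}
    for ann in annotations:
        for label in strand_order:
            if label in ann.labels:
                strand_of[ann.residue] = label
    ranks, mags = [], []
    per_strand: dict[str, tuple[list[float], list[float]]] = \
        {s: ([], []) for s in strand_order}
    for e in _binding_estimates(estimates, partner, confident_only):
        pos = variant_position(e.variant)
        strand = strand_of.get(pos)
        if strand is None:
            continue
        ranks.append(strand_order.index(strand))
        mags.append(abs(e.mean_ddg))
        per_strand[strand][0].append(e.mean_ddg)
        per_strand[strand][1].append(e.sd_ddg)
    if not mags:
        raise ValueError("no strand-labelled mutations")
    covered = [s for s in strand_order if per_strand[s][0]]
    if len(covered) < 2:
        raise ValueError("need mutations in at least two strands")
    means = {s: weighted_mean_abs(*per_strand[s], weights=weights)
             for s in covered}
    if len(set(mags)) == 1 or len(set(ranks)) == 1:
        rho, pval = 0.0, 1.0
    else:
        rho, pval = spearmanr(ranks, mags)
    return StrandDecay(means, float(rho), float(pval), len(mags))


def write_position_summary(summaries: Sequence[PositionSummary],
                           path) -> None:
    pd.DataFrame([vars(s) for s in summaries]).to_csv(path, sep="\t", index=False)
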