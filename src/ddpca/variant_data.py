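"""Variant and fitness-table data model.

Genotypes are sets of amino-acid substitutions relative to wild-type KRAS
(order 0, 1 or 2 in this study), written in the usual "G12C" /
"G12C:D33E" notation. Fitness observations pair a genotype with one of the
21 selection experiments (3 AbundancePCA + 18 BindingPCA) and carry the
growth-derived fitness score and its standard error.

The module also implements the amino-acid-level high-confidence variant
filter used upstream of model fitting, and a simple log-ratio fitness
estimator for synthetic read counts.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .reference import AMINO_ACIDS, BLOCKS, KRAS_SEQUENCE, PARTNERS, STOP

logger = logging.getLogger(__name__)

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


class VariantError(ValueError):
    """Raised for malformed or invalid variant strings / records."""


@dataclass(frozen=True, order=True)
class Substitution:
    position: int  # 1-based
    wt_aa: str
    mut_aa: str

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class Genotype:
    """An ordered, validated set of substitutions (empty = wild type)."""

    substitutions: tuple[Substitution, ...] = ()

    @property
    def order(self) -> int:
        return len(self.substitutions)

    @property
    def is_wildtype(self) -> bool:
        return not self.substitutions

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.substitutions)

    def has_stop(self) -> bool:
        return any(s.mut_aa == STOP for s in self.substitutions)

    def __str__(self) -> str:
        return ":".join(str(s) for s in self.substitutions)

    def __iter__(self):
        return iter(self.substitutions)


def parse_genotype(text: str, reference: str = KRAS_SEQUENCE) -> Genotype:
    """Parse a canonical substitution string ("" = wild type).

    Validates positions against ``reference`` (1-based), rejects duplicate
    positions, identity substitutions and wild-type letter mismatches.
    Formatting the result with ``str`` reproduces the canonical
    position-sorted string.
    """
    text = (text or "").strip()
    if not text:
        return Genotype()
    subs = []
    for token in text.split(":"):
        m = _SUB_RE.match(token.strip())
        if not m:
            raise VariantError(f"malformed substitution token: {token!r}")
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
        if not 1 <= pos <= len(reference):
            raise VariantError(f"position {pos} outside 1-{len(reference)}")
        if reference[pos - 1] != wt:
            raise VariantError(
                f"wild-type letter mismatch at {pos}: reference has "
                f"{reference[pos - 1]}, token says {wt}"
            )
        if mut == wt:
            raise VariantError(f"identity substitution {token!r}")
        if mut != STOP and mut not in AMINO_ACIDS:
            raise VariantError(f"unknown amino acid {mut!r} in {token!r}")
        subs.append(Substitution(pos, wt, mut))
    positions = [s.position for s in subs]
    if len(set(positions)) != len(positions):
        raise VariantError(f"duplicate position in {text!r}")
    return Genotype(tuple(sorted(subs)))


def format_genotype(genotype: Genotype) -> str:
    return str(genotype)


@dataclass(frozen=True, order=True)
class ExperimentId:
    """One of the 21 selection experiments.

    ``assay`` is "abundance" (AbundancePCA; partner must be "none") or
    "binding" (BindingPCA against one of the six partners); ``block`` is
    the mutagenesis block (1-3).
    """

    assay: str
    partner: str
    block: int

    def __post_init__(self):
        if self.assay not in ("abundance", "binding"):
            raise VariantError(f"unknown assay {self.assay!r}")
        if self.assay == "abundance" and self.partner != "none":
            raise VariantError("abundance experiments carry partner='none'")
        if self.assay == "binding" and self.partner not in PARTNERS:
            raise VariantError(f"unknown partner {self.partner!r}")
        if self.block not in BLOCKS:
            raise VariantError(f"unknown block {self.block!r}")

    def __str__(self) -> str:
        return f"{self.assay}:{self.partner}:b{self.block}"


def all_experiments(blocks: Sequence[int] = BLOCKS,
                    partners: Sequence[str] = PARTNERS) -> list[ExperimentId]:
    """The canonical experiment grid: per block, 1 abundance + one binding
    experiment per partner (21 in the full design)."""
    out = []
    for b in blocks:
        out.append(ExperimentId("abundance", "none", b))
        for p in partners:
            out.append(ExperimentId("binding", p, b))
    return out


@dataclass(frozen=True)
class FitnessObservation:
    genotype: Genotype
    experiment: ExperimentId
    fitness: float
    sigma: float

    def __post_init__(self):
        if not math.isfinite(self.fitness):
            raise VariantError(f"non-finite fitness for {self.genotype}")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise VariantError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class VariantCountRecord:
    genotype: Genotype
    experiment: ExperimentId
    replicate: int
    input_count: int
    output_count: int

    def __post_init__(self):
        if self.input_count < 0 or self.output_count < 0:
            raise VariantError("counts must be non-negative")


FITNESS_COLUMNS = ["variant", "assay", "partner", "block", "fitness", "sigma"]
COUNT_COLUMNS = ["variant", "assay", "partner", "block", "replicate",
                 "input_count", "output_count"]


def read_fitness_table(path: str | Path,
                       reference: str = KRAS_SEQUENCE) -> list[FitnessObservation]:
    """Read a fitness TSV (columns ``variant``, ``assay``, ``partner``,
    ``block``, ``fitness``, ``sigma``; wild type = empty variant).

    Invalid rows (bad genotype, non-positive sigma, unknown partner) are
    rejected with a logged reason; a missing column raises.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant": str},
                     keep_default_na=False, na_values=[""])
    missing = [c for c in FITNESS_COLUMNS if c not in df.columns]
    if missing:
        raise VariantError(f"missing columns in {path}: {missing}")
    out: list[FitnessObservation] = []
    for row in df.itertuples(index=False):
        try:
            variant = row.variant if isinstance(row.variant, str) else ""
            geno = parse_genotype(variant, reference)
            exp = ExperimentId(str(row.assay), str(row.partner), int(row.block))
            out.append(FitnessObservation(geno, exp,
                                          float(row.fitness), float(row.sigma)))
        except (VariantError, ValueError) as exc:
            logger.warning("rejected row %r: %s", tuple(row), exc)
    return out


def write_fitness_table(observations: Iterable[FitnessObservation],
                        path: str | Path) -> None:
    rows = [
        {"variant": str(o.genotype), "assay": o.experiment.assay,
         "partner": o.experiment.partner, "block": o.experiment.block,
         "fitness": o.fitness, "sigma": o.sigma}
        for o in observations
    ]
    pd.DataFrame(rows, columns=FITNESS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path,
                     reference: str = KRAS_SEQUENCE) -> list[VariantCountRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"variant": str},
                     keep_default_na=False, na_values=[""])
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise VariantError(f"missing columns in {path}: {missing}")
    out = []
    for row in df.itertuples(index=False):
        variant = row.variant if isinstance(row.variant, str) else ""
        out.append(VariantCountRecord(
            parse_genotype(variant, reference),
            ExperimentId(str(row.assay), str(row.partner), int(row.block)),
            int(row.replicate), int(row.input_count), int(row.output_count)))
    return out


def write_count_table(records: Iterable[VariantCountRecord],
                      path: str | Path) -> None:
    rows = [
        {"variant": str(r.genotype), "assay": r.experiment.assay,
         "partner": r.experiment.partner, "block": r.experiment.block,
         "replicate": r.replicate, "input_count": r.input_count,
         "output_count": r.output_count}
        for r in records
    ]
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class FilterResult:
    retained: list[Genotype]
    background: set[Substitution]
    n_rejected_singles: int = 0
    n_rejected_doubles: int = 0


def filter_high_confidence(genotypes: Iterable[Genotype],
                           experiments_by_genotype: dict[str, set[ExperimentId]] | None = None,
                           min_obs: int = 200,
                           min_experiments: int = 5,
                           nnk_consistent: dict[str, bool] | None = None) -> FilterResult:
    """Amino-acid-level high-confidence variant filter.

    A single substitution qualifies as a *high-confidence background* if it
    is observed at least ``min_obs`` times in distinct double variants, in
    at least ``min_experiments`` experiments. Doubles are retained iff at
    least one constituent single is a background substitution; other
    doubles are discarded as likely PCR/sequencing artefacts. Singles are
    retained if flagged NNK-consistent (``nnk_consistent``, keyed by the
    substitution string; the codon-level rule is unavailable at the
    amino-acid level, so the caller supplies the flag — the synthetic
    generator sets it true) or if they qualify as backgrounds.

    ``experiments_by_genotype`` maps double-variant strings to the set of
    experiments each was observed in; if omitted it is assumed every
    genotype was seen in all experiments present in ``genotypes``'s blocks.
    """
    if min_obs < 1 or min_experiments < 1:
        raise VariantError("thresholds must be >= 1")
    genotypes = list(genotypes)
    if not genotypes:
        raise VariantError("empty input")

    doubles = [g for g in genotypes if g.order == 2]
    singles = [g for g in genotypes if g.order == 1]

    # Count distinct doubles containing each single substitution, per
    # experiment the double was observed in.
    counts: dict[Substitution, dict[ExperimentId, set[str]]] = {}
    for g in doubles:
        exps = (experiments_by_genotype or {}).get(str(g))
        if exps is None and experiments_by_genotype is not None:
            continue
        for sub in g:
            per_exp = counts.setdefault(sub, {})
            if exps is None:
                per_exp.setdefault(None, set()).add(str(g))  # type: ignore[arg-type]
            else:
                for e in exps:
                    per_exp.setdefault(e, set()).add(str(g))

    background: set[Substitution] = set()
    for sub, per_exp in counts.items():
        if None in per_exp:
            # No experiment breakdown supplied: require the count threshold
            # only (treated as seen in all experiments).
            if len(per_exp[None]) >= min_obs:  # type: ignore[index]
                background.add(sub)
        else:
            n_ok = sum(1 for doubles_seen in per_exp.values()
                       if len(doubles_seen) >= min_obs)
            if n_ok >= min_experiments:
                background.add(sub)

    retained: list[Genotype] = [g for g in genotypes if g.order == 0]
    n_rej_s = n_rej_d = 0
    for g in singles:
        sub = g.substitutions[0]
        flagged = (nnk_consistent or {}).get(str(g), nnk_consistent is None)
        if flagged or sub in background:
            retained.append(g)
        else:
            n_rej_s += 1
    for g in doubles:
        if any(sub in background for sub in g):
            retained.append(g)
        else:
            n_rej_d += 1
    if n_rej_s or n_rej_d:
        logger.info("filter_high_confidence rejected %d singles, %d doubles",
                    n_rej_s, n_rej_d)
    return FilterResult(retained, background, n_rej_s, n_rej_d)


def fitness_from_counts(record: VariantCountRecord,
                        wt_record: VariantCountRecord,
                        pseudocount: float | None = None) -> tuple[float, float]:
    """Log-ratio fitness with a Poisson-approximation standard error.

    fitness = ln(out/in) - ln(out_wt/in_wt);
    sigma   = sqrt(1/in + 1/out + 1/in_wt + 1/out_wt).

    Zero counts raise by default; pass ``pseudocount`` (e.g. 0.5) to add it
    to every count instead. This simple estimator only backs the synthetic
    counts path — real data arrive as externally estimated fitness tables.
    """
    counts = [record.input_count, record.output_count,
              wt_record.input_count, wt_record.output_count]
    if any(c == 0 for c in counts):
        if pseudocount is None:
            raise VariantError(
                "zero count; pass pseudocount=0.5 to apply a pseudocount")
        counts = [c + pseudocount for c in counts]
    ci, co, wi, wo = (float(c) for c in counts)
    fitness = math.log(co / ci) - math.log(wo / wi)
    sigma = math.sqrt(1 / ci + 1 / co + 1 / wi + 1 / wo)
    return fitness, sigma
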