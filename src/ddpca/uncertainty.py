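"""Monte-Carlo uncertainty for inferred free-energy changes.

Confidence intervals come from an ensemble of model refits, each with an
independent random train/validation/test split and an independent
resampling of the training fitness values from their error distributions.
Per-coefficient means and standard deviations across the ensemble give
normal-approximation 95% CIs; estimates with CI width < 1 kcal/mol are
flagged confident. Significance calls use a two-sided z-test with the
ensemble sd as the standard error, corrected by Benjamini-Hochberg within
each trait/partner family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .thermo_model import (DataSplit, EnergyModel, TrainingConfig, fit_model,
                           split_data)
from .variant_data import FitnessObservation

logger = logging.getLogger(__name__)

CONFIDENT_CI_WIDTH = 1.0  # kcal/mol


@dataclass(frozen=True)
class FreeEnergyEstimate:
    trait: str        # "folding" or "binding:<partner>"
    variant: str      # substitution string, e.g. "G12C"
    mean_ddg: float   # kcal/mol, ensemble mean
    sd_ddg: float     # kcal/mol, ensemble sd
    ci95_lo: float
    ci95_hi: float
    n_models: int
    confident: bool


@dataclass(frozen=True)
class SignificanceCall:
    estimate: FreeEnergyEstimate
    z: float
    p: float
    q: float
    significant_at: float

    @property
    def significant(self) -> bool:
        return self.q <= self.significant_at


def mc_ensemble(observations: Sequence[FitnessObservation],
                config: TrainingConfig, n_models: int = 10,
                master_seed: int = 0,
                partners: Sequence[str] | None = None) -> list[EnergyModel]:
    """Fit ``n_models`` models under independent splits and training-target
    resamplings; member seeds derive deterministically from
    ``master_seed``."""
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    seeds = np.random.SeedSequence(master_seed).generate_state(2 * n_models)
    seeds = (seeds % np.uint32(2 ** 31)).astype(int)
    ensemble = []
    for i in range(n_models):
        split_seed, fit_seed = seeds[2 * i], seeds[2 * i + 1]
        cfg = replace(config, seed=int(fit_seed),
                      resample_training_fitness=True)
        split = split_data(observations, replace(config, seed=int(split_seed)))
        try:
            model, _ = fit_model(observations, split, cfg, partners=partners)
        except Exception as exc:
            raise RuntimeError(f"ensemble member {i} failed: {exc}") from exc
        ensemble.append(model)
    return ensemble


def _coefficients(model: EnergyModel) -> dict[tuple[str, str], float]:
    out = {("folding", s): v for s, v in model.ddgf.items()}
    for p, coeffs in model.ddgb.items():
        for s, v in coeffs.items():
            out[(f"binding:{p}", s)] = v
    return out


def summarize_energies(ensemble: Sequence[EnergyModel],
                       ci_mode: str = "normal") -> list[FreeEnergyEstimate]:
    """Per-coefficient ensemble mean, sd and 95% CI.

    ``ci_mode="normal"`` gives mean +/- 1.96 sd (default; stable at small
    ensemble sizes); ``"percentile"`` uses the empirical 2.5/97.5
    percentiles. Coefficients missing from some members are excluded and
    logged. Permutation-invariant over members.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    maps = [_coefficients(m) for m in ensemble]
    common = set(maps[0])
    union = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
        union |= set(m)
    for key in sorted(union - common):
        logger.warning("coefficient %s missing from some members; excluded", key)
    out = []
    n = len(ensemble)
    for trait, variant in sorted(common):
        vals = np.array([m[(trait, variant)] for m in maps])
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        if ci_mode == "normal":
            lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
        elif ci_mode == "percentile":
            lo, hi = (float(np.percentile(vals, 2.5)),
                      float(np.percentile(vals, 97.5)))
        else:
            raise ValueError(f"unknown ci_mode {ci_mode!r}")
        out.append(FreeEnergyEstimate(
            trait=trait, variant=variant, mean_ddg=mean, sd_ddg=sd,
            ci95_lo=lo, ci95_hi=hi, n_models=n,
            confident=(hi - lo) < CONFIDENT_CI_WIDTH))
    return out


def ztest_calls(estimates: Sequence[FreeEnergyEstimate],
                null_value: float = 0.0, fdr: float = 0.05,
                alternative: str = "two_sided") -> list[SignificanceCall]:
    """Two-sided z-test of mean_ddg against ``null_value`` with the
    ensemble sd as standard error, BH-corrected over the given family.

    Estimates with sd = 0 get p = 0 if the mean differs from the null, 1
    otherwise.
    """
    if alternative != "two_sided":
        raise ValueError("only two_sided is supported")
    if not estimates:
        raise ValueError("empty family")
    z = np.array([
        (e.mean_ddg - null_value) / e.sd_ddg if e.sd_ddg > 0
        else (np.inf if e.mean_ddg > null_value
              else -np.inf if e.mean_ddg < null_value else 0.0)
        for e in estimates])
    p = np.where(np.isinf(z), 0.0, 2.0 * norm.sf(np.abs(z)))
    p = np.where(z == 0.0, 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [SignificanceCall(e, float(zi), float(pi), float(qi), fdr)
            for e, zi, pi, qi in zip(estimates, z, p, q)]


def detrimental_calls(estimates: Sequence[FreeEnergyEstimate],
                      fdr: float = 0.05) -> list[SignificanceCall]:
    """Calls of mutations detrimental to a trait: significantly non-zero by
    the two-sided z-test at the given FDR, with positive mean ddG."""
    calls = ztest_calls(estimates, null_value=0.0, fdr=fdr)
    return [c for c in calls if c.significant and c.estimate.mean_ddg > 0]


def write_energies_table(estimates: Sequence[FreeEnergyEstimate],
                         path: str | Path) -> None:
    rows = []
    for e in estimates:
        partner = e.trait.split(":", 1)[1] if ":" in e.trait else "none"
        rows.append({"trait": e.trait.split(":")[0], "partner": partner,
                     "variant": e.variant, "mean_ddg": e.mean_ddg,
                     "sd_ddg": e.sd_ddg, "ci95_lo": e.ci95_lo,
                     "ci95_hi": e.ci95_hi, "confident": e.confident})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_energies_table(path: str | Path) -> list[FreeEnergyEstimate]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        trait = row.trait if row.partner == "none" else f"{row.trait}:{row.partner}"
        out.append(FreeEnergyEstimate(
            trait=trait, variant=row.variant, mean_ddg=float(row.mean_ddg),
            sd_ddg=float(row.sd_ddg), ci95_lo=float(row.ci95_lo),
            ci95_hi=float(row.ci95_hi), n_models=0,
            confident=bool(row.confident)))
    return out
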