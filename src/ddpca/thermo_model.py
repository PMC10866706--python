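"""Three-state thermodynamic genotype-phenotype model and its trainer.

The model treats each KRAS-partner pair as an equilibrium between three
states — unfolded+unbound (uu), folded+unbound (fu) and folded+bound (fb);
the unfolded+bound state is assumed negligible. Free energies of folding
(dGf, shared across partners) and of binding (dGb, partner-specific, with
the unmeasured partner concentration absorbed into the wild-type term)
combine additively over substitutions in energy space. Boltzmann weights
turn total energies into a fraction folded (AbundancePCA) or fraction
folded-and-bound (BindingPCA), and a per-experiment affine layer maps that
fraction onto the observed fitness scale.

Internally all energies are dimensionless (theta = dG / RT at 303 K);
fitting minimizes a sigma-weighted mean absolute error with light L2
regularization using an Adam optimizer with the exponential
learning-rate-on-plateau schedule and wild-type-energy early-stopping rule
described in the module docstrings below. Gradients are computed
analytically: with at most two substitutions per variant the additive layer
is a gather, and its adjoint a scatter-add.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .reference import PARTNERS
from .variant_data import (ExperimentId, FitnessObservation, Genotype,
                           Substitution, parse_genotype)

logger = logging.getLogger(__name__)

#: Gas constant in kcal K^-1 mol^-1 and selection temperature in K.
R_KCAL = 0.001987
T_KELVIN = 303.0
#: Energy scale dG = theta * RT.
RT = R_KCAL * T_KELVIN  # 0.602061 kcal/mol


def fraction_folded(dgf, rt: float = RT):
    """Fraction of molecules folded, p_f = 1 / (1 + exp(dGf/RT)).

    Two-state Boltzmann: states {unfolded (weight exp(dGf/RT)), folded (1)}
    relative to the folded state. Strictly decreasing in dgf; saturates
    smoothly at the extremes. Accepts scalars or arrays.
    """
    if rt <= 0:
        raise ValueError("rt must be > 0")
    return expit(-np.asarray(dgf, dtype=float) / rt)


def fraction_bound(dgf, dgb, rt: float = RT):
    """Fraction folded and bound over the three states {uu, fu, fb}.

    p_fb = 1 / (1 + exp(dGb/RT) * (1 + exp(dGf/RT))); the unfolded-bound
    state is excluded. Strictly decreasing in each energy.
    """
    if rt <= 0:
        raise ValueError("rt must be > 0")
    tf = np.asarray(dgf, dtype=float) / rt
    tb = np.asarray(dgb, dtype=float) / rt
    # log denominator = log(1 + e^tb + e^(tb+tf)), computed stably
    log_denom = np.logaddexp(0.0, np.logaddexp(tb, tb + tf))
    return np.exp(-log_denom)


@dataclass
class EnergyModel:
    """Fitted additive free-energy coefficients plus affine output layers.

    Energies are stored in kcal/mol; the dimensionless parameters the
    optimizer works on are ``dG / rt``. ``ddgb`` maps partner ->
    {substitution string -> ddG_b}; the binding-partner concentration is
    absorbed into ``wt_dgb``.
    """

    rt: float = RT
    wt_dgf: float = 0.0
    wt_dgb: dict[str, float] = field(default_factory=dict)
    ddgf: dict[str, float] = field(default_factory=dict)
    ddgb: dict[str, dict[str, float]] = field(default_factory=dict)
    affine: dict[ExperimentId, tuple[float, float]] = field(default_factory=dict)

    def total_dgf(self, genotype: Genotype) -> float:
        total = self.wt_dgf
        for sub in genotype:
            key = str(sub)
            if key not in self.ddgf:
                raise KeyError(f"no folding coefficient for {key}")
            total += self.ddgf[key]
        return total

    def total_dgb(self, genotype: Genotype, partner: str) -> float:
        if partner not in self.wt_dgb:
            raise KeyError(f"no binding trait for partner {partner}")
        total = self.wt_dgb[partner]
        coeffs = self.ddgb.get(partner, {})
        for sub in genotype:
            key = str(sub)
            if key not in coeffs:
                raise KeyError(f"no {partner} binding coefficient for {key}")
            total += coeffs[key]
        return total


def predict_fitness(genotype: Genotype, experiment: ExperimentId,
                    model: EnergyModel) -> float:
    """Affine(Boltzmann(summed energies)) for one variant/experiment."""
    if experiment not in model.affine:
        raise KeyError(f"no affine layer for experiment {experiment}")
    a, b = model.affine[experiment]
    dgf = model.total_dgf(genotype)
    if experiment.assay == "abundance":
        p = float(fraction_folded(dgf, model.rt))
    else:
        dgb = model.total_dgb(genotype, experiment.partner)
        p = float(fraction_bound(dgf, dgb, model.rt))
    return a + b * p


def _theta_norm_sq(model: EnergyModel) -> float:
    """Sum of squared dimensionless trainable parameters (energies / RT
    plus affine intercepts and slopes)."""
    s = (model.wt_dgf / model.rt) ** 2
    s += sum((v / model.rt) ** 2 for v in model.wt_dgb.values())
    s += sum((v / model.rt) ** 2 for v in model.ddgf.values())
    for coeffs in model.ddgb.values():
        s += sum((v / model.rt) ** 2 for v in coeffs.values())
    s += sum(a * a + b * b for a, b in model.affine.values())
    return s


def loss(batch: Sequence[FitnessObservation], model: EnergyModel,
         l2_lambda: float = 0.0) -> float:
    """Sigma-weighted mean absolute error plus L2 penalty on theta.

    L = 1/N sum |y_n - yhat_n| / sigma_n + lambda2 * ||theta||^2.
    """
    if not batch:
        raise ValueError("empty batch")
    total = 0.0
    for obs in batch:
        yhat = predict_fitness(obs.genotype, obs.experiment, model)
        total += abs(obs.fitness - yhat) / obs.sigma
    return total / len(batch) + l2_lambda * _theta_norm_sq(model)


@dataclass
class TrainingConfig:
    max_epochs: int = 1000
    initial_lr: float = 0.05
    lr_decay_gamma: float = 0.98
    lr_patience_epochs: int = 10
    early_stop_wt_sd: float = 1e-3  # dimensionless theta units; <=0 disables
    l2_lambda: float = 1e-6
    batch_size: int = 1024
    holdout_fraction_val: float = 0.20
    holdout_fraction_test: float = 0.10
    resample_training_fitness: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.holdout_fraction_val < 1
                and 0 <= self.holdout_fraction_test < 1
                and self.holdout_fraction_val + self.holdout_fraction_test < 1):
            raise ValueError("holdout fractions must lie in [0,1) and sum < 1")
        if self.initial_lr <= 0 or self.lr_decay_gamma <= 0 or self.batch_size < 1:
            raise ValueError("rates and batch size must be positive")


@dataclass
class DataSplit:
    """Disjoint (variant string, experiment) key sets. Doubles are
    partitioned by genotype so no genotype straddles subsets; singles and
    the wild type always train."""

    train: set[tuple[str, ExperimentId]]
    validation: set[tuple[str, ExperimentId]]
    test: set[tuple[str, ExperimentId]]


def split_data(observations: Sequence[FitnessObservation],
               config: TrainingConfig) -> DataSplit:
    """Random 70/20/10 (by default) split of double-mutant genotypes; all
    observations of a genotype share its subset. Deterministic in
    ``config.seed``."""
    doubles = sorted({str(o.genotype) for o in observations
                      if o.genotype.order == 2})
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(doubles))
    n_val = int(round(config.holdout_fraction_val * len(doubles)))
    n_test = int(round(config.holdout_fraction_test * len(doubles)))
    val_set = {doubles[i] for i in order[:n_val]}
    test_set = {doubles[i] for i in order[n_val:n_val + n_test]}
    if doubles == [] and (config.holdout_fraction_val or config.holdout_fraction_test):
        logger.warning("no double mutants: validation/test sets are empty")
    split = DataSplit(set(), set(), set())
    for o in observations:
        key = (str(o.genotype), o.experiment)
        g = str(o.genotype)
        if g in val_set:
            split.validation.add(key)
        elif g in test_set:
            split.test.add(key)
        else:
            split.train.add(key)
    return split


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    wt_theta: list[np.ndarray] = field(default_factory=list)
    unidentifiable_traits: list[str] = field(default_factory=list)
    stopped_early: bool = False
    n_epochs: int = 0


class _Design:
    """Packed arrays for vectorized prediction/gradients.

    Each observation row holds up to two folding-coefficient indices and,
    for binding rows, up to two binding-coefficient indices into a single
    flat per-(partner, substitution) vector; sentinel indices point at a
    frozen zero slot.
    """

    def __init__(self, observations: Sequence[FitnessObservation],
                 partners: Sequence[str]):
        obs = [o for o in observations if not o.genotype.has_stop()]
        self.observations = obs
        self.experiments = sorted({o.experiment for o in obs})
        self.partners = [p for p in partners
                         if any(o.experiment.partner == p for o in obs)]
        self.missing_partners = [p for p in partners if p not in self.partners]

        self.f_subs = sorted({str(s) for o in obs for s in o.genotype},
                             key=lambda t: (int(t[1:-1]), t))
        f_index = {s: i for i, s in enumerate(self.f_subs)}
        # flat binding coefficients: (partner, substitution) pairs covered
        # by that partner's observations
        self.b_keys: list[tuple[str, str]] = []
        b_index: dict[tuple[str, str], int] = {}
        per_partner_subs: dict[str, set[str]] = {p: set() for p in self.partners}
        for o in obs:
            if o.experiment.assay == "binding":
                per_partner_subs[o.experiment.partner].update(
                    str(s) for s in o.genotype)
        for p in self.partners:
            for s in sorted(per_partner_subs[p], key=lambda t: (int(t[1:-1]), t)):
                b_index[(p, s)] = len(self.b_keys)
                self.b_keys.append((p, s))

        n = len(obs)
        self.Sf = len(self.f_subs)
        self.Sb = len(self.b_keys)
        self.y = np.array([o.fitness for o in obs])
        self.sigma = np.array([o.sigma for o in obs])
        self.f1 = np.full(n, self.Sf, dtype=np.int64)
        self.f2 = np.full(n, self.Sf, dtype=np.int64)
        self.b1 = np.full(n, self.Sb, dtype=np.int64)
        self.b2 = np.full(n, self.Sb, dtype=np.int64)
        self.exp_idx = np.empty(n, dtype=np.int64)
        self.partner_idx = np.zeros(n, dtype=np.int64)
        self.is_binding = np.zeros(n, dtype=bool)
        e_index = {e: i for i, e in enumerate(self.experiments)}
        p_index = {p: i for i, p in enumerate(self.partners)}
        for i, o in enumerate(obs):
            subs = [str(s) for s in o.genotype]
            if len(subs) >= 1:
                self.f1[i] = f_index[subs[0]]
            if len(subs) == 2:
                self.f2[i] = f_index[subs[1]]
            self.exp_idx[i] = e_index[o.experiment]
            if o.experiment.assay == "binding":
                p = o.experiment.partner
                self.is_binding[i] = True
                self.partner_idx[i] = p_index[p]
                if len(subs) >= 1:
                    self.b1[i] = b_index[(p, subs[0])]
                if len(subs) == 2:
                    self.b2[i] = b_index[(p, subs[1])]

    def membership(self, keyset: set[tuple[str, ExperimentId]]) -> np.ndarray:
        return np.array([(str(o.genotype), o.experiment) in keyset
                         for o in self.observations], dtype=bool)


class _Params:
    """Flat parameter vector layout with frozen sentinel slots."""

    def __init__(self, design: _Design):
        d = design
        self.Sf, self.Sb = d.Sf, d.Sb
        self.nP, self.nE = len(d.partners), len(d.experiments)
        self.o_wtf = d.Sf + 1 + d.Sb + 1
        self.o_wtb = self.o_wtf + 1
        self.o_a = self.o_wtb + self.nP
        self.o_b = self.o_a + self.nE
        self.size = self.o_b + self.nE
        self.sentinels = np.array([d.Sf, d.Sf + 1 + d.Sb], dtype=np.int64)

    def unpack(self, x):
        tf = x[:self.Sf]
        tb = x[self.Sf + 1:self.Sf + 1 + self.Sb]
        wtf = x[self.o_wtf]
        wtb = x[self.o_wtb:self.o_a]
        a = x[self.o_a:self.o_b]
        b = x[self.o_b:]
        return tf, tb, wtf, wtb, a, b


def _forward(x, P: _Params, d: _Design, rows: np.ndarray):
    """Predicted fitness and intermediates for the given row indices."""
    tf_all = x[:P.Sf + 1]
    tb_all = x[P.Sf + 1:P.Sf + 1 + P.Sb + 1]
    wtb = x[P.o_wtb:P.o_a]
    theta_f = x[P.o_wtf] + tf_all[d.f1[rows]] + tf_all[d.f2[rows]]
    binding = d.is_binding[rows]
    pidx = d.partner_idx[rows]
    wtb_row = wtb[pidx] if P.nP else np.zeros(rows.size)
    theta_b = np.where(binding, wtb_row, 0.0) + tb_all[d.b1[rows]] + tb_all[d.b2[rows]]
    pf = expit(-theta_f)
    log_denom = np.logaddexp(0.0, np.logaddexp(theta_b, theta_b + theta_f))
    pfb = np.exp(-log_denom)
    p_uu = np.exp(theta_b + theta_f - log_denom)
    p = np.where(binding, pfb, pf)
    a = x[P.o_a:P.o_b][d.exp_idx[rows]]
    b = x[P.o_b:][d.exp_idx[rows]]
    yhat = a + b * p
    return yhat, p, pf, pfb, p_uu, binding


def _weighted_mae(x, P, d, rows, y=None):
    yhat = _forward(x, P, d, rows)[0]
    yy = d.y[rows] if y is None else y[rows]
    return float(np.mean(np.abs(yy - yhat) / d.sigma[rows]))


def fit_model(observations: Sequence[FitnessObservation],
              split: DataSplit, config: TrainingConfig,
              partners: Sequence[str] | None = None,
              ) -> tuple[EnergyModel, TrainingLog]:
    """Fit the three-state model by minibatch Adam on the weighted MAE loss.

    Doubles in ``split.validation``/``split.test`` are excluded from
    gradient steps; the validation loss drives the learning-rate schedule
    (initial lr from ``config``, multiplied by gamma whenever the mean
    validation loss over the last ``lr_patience_epochs`` epochs has not
    improved on the preceding window). Training stops early once the
    wild-type energy parameters have stabilized (sd over the last 10 epochs
    <= ``early_stop_wt_sd`` in theta units) or at ``max_epochs``.

    If ``config.resample_training_fitness``, each training target is
    replaced once, before training, by a draw from Normal(y_n, sigma_n);
    validation and test data are left unaltered.

    Stop-codon variants are excluded (no truncation state). Partners in
    ``partners`` (default: the six canonical ones) with no covering
    observations are reported in the log as unidentifiable.
    """
    partners = list(partners) if partners is not None else list(PARTNERS)
    d = _Design(observations, partners)
    log = TrainingLog()
    log.unidentifiable_traits = [f"binding:{p}" for p in d.missing_partners]
    if not d.observations:
        log.unidentifiable_traits.insert(0, "folding")
        raise ValueError("no usable observations: traits unidentifiable: "
                         + ", ".join(log.unidentifiable_traits))
    if log.unidentifiable_traits:
        logger.warning("traits without covering data: %s",
                       ", ".join(log.unidentifiable_traits))

    P = _Params(d)
    rng = np.random.default_rng(config.seed)

    train_rows = np.flatnonzero(d.membership(split.train))
    val_rows = np.flatnonzero(d.membership(split.validation))
    if train_rows.size == 0:
        raise ValueError("empty training set")

    y_train = d.y.copy()
    if config.resample_training_fitness:
        y_train[train_rows] = rng.normal(d.y[train_rows], d.sigma[train_rows])

    # init: energies at 0; per-experiment slope = observed fitness range,
    # intercept = min observed fitness (puts the wild type near the
    # folded/bound plateau)
    x = np.zeros(P.size)
    for ei in range(P.nE):
        rows_e = train_rows[d.exp_idx[train_rows] == ei]
        ye = y_train[rows_e] if rows_e.size else np.array([0.0, 1.0])
        x[P.o_a + ei] = float(ye.min())
        x[P.o_b + ei] = float(ye.max() - ye.min()) or 1.0

    m = np.zeros_like(x)
    v = np.zeros_like(x)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.initial_lr
    t = 0
    lam = config.l2_lambda
    use_val = val_rows.size > 0
    if not use_val:
        logger.warning("empty validation set: lr schedule uses training loss")

    for epoch in range(config.max_epochs):
        perm = rng.permutation(train_rows)
        for start in range(0, perm.size, config.batch_size):
            rows = perm[start:start + config.batch_size]
            t += 1
            yhat, p, pf, pfb, p_uu, binding = _forward(x, P, d, rows)
            r = yhat - y_train[rows]
            g = np.sign(r) / (d.sigma[rows] * rows.size)
            grad = 2.0 * lam * x
            ei = d.exp_idx[rows]
            grad[P.o_a:P.o_b] += np.bincount(ei, weights=g, minlength=P.nE)
            grad[P.o_b:] += np.bincount(ei, weights=g * p, minlength=P.nE)
            gp = g * x[P.o_b:][ei]
            dtf = np.where(binding, -pfb * p_uu, -pf * (1.0 - pf)) * gp
            dtb = np.where(binding, -pfb * (1.0 - pfb), 0.0) * gp
            grad[:P.Sf + 1] += np.bincount(
                np.concatenate([d.f1[rows], d.f2[rows]]),
                weights=np.concatenate([dtf, dtf]), minlength=P.Sf + 1)
            grad[P.o_wtf] += dtf.sum()
            grad[P.Sf + 1:P.Sf + 1 + P.Sb + 1] += np.bincount(
                np.concatenate([d.b1[rows], d.b2[rows]]),
                weights=np.concatenate([dtb, dtb]), minlength=P.Sb + 1)
            if P.nP:
                grad[P.o_wtb:P.o_a] += np.bincount(
                    d.partner_idx[rows], weights=dtb, minlength=P.nP)
            grad[P.sentinels] = 0.0
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad * grad
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            x -= lr * mhat / (np.sqrt(vhat) + eps)
            x[P.sentinels] = 0.0

        reg = lam * float(np.dot(x, x))
        tl = _weighted_mae(x, P, d, train_rows, y_train) + reg
        vl = (_weighted_mae(x, P, d, val_rows) + reg) if use_val else tl
        if not (math.isfinite(tl) and math.isfinite(vl)):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        log.train_loss.append(tl)
        log.val_loss.append(vl)
        log.learning_rate.append(lr)
        wt = np.concatenate([[x[P.o_wtf]], x[P.o_wtb:P.o_a]])
        log.wt_theta.append(wt.copy())
        log.n_epochs = epoch + 1

        pat = config.lr_patience_epochs
        if len(log.val_loss) >= 2 * pat:
            recent = np.mean(log.val_loss[-pat:])
            previous = np.mean(log.val_loss[-2 * pat:-pat])
            if recent >= previous:
                lr *= config.lr_decay_gamma
        if (config.early_stop_wt_sd > 0 and len(log.wt_theta) >= 10
                and np.all(np.std(np.array(log.wt_theta[-10:]), axis=0)
                           <= config.early_stop_wt_sd)):
            log.stopped_early = True
            break

    tf, tb, wtf, wtb, a, b = P.unpack(x)
    model = EnergyModel(
        rt=RT,
        wt_dgf=float(wtf) * RT,
        wt_dgb={p: float(wtb[i]) * RT for i, p in enumerate(d.partners)},
        ddgf={s: float(tf[i]) * RT for i, s in enumerate(d.f_subs)},
        ddgb={p: {} for p in d.partners},
        affine={e: (float(a[i]), float(b[i]))
                for i, e in enumerate(d.experiments)},
    )
    for i, (p, s) in enumerate(d.b_keys):
        model.ddgb[p][s] = float(tb[i]) * RT
    return model, log


def tune_batch_size(observations: Sequence[FitnessObservation],
                    split: DataSplit, config: TrainingConfig,
                    candidate_sizes: Sequence[int]) -> int:
    """Pick the batch size minimizing the validation loss after 100 epochs
    (ties go to the smallest candidate)."""
    if not candidate_sizes:
        raise ValueError("empty candidate list")
    best_size, best_loss = None, math.inf
    for size in sorted(candidate_sizes):
        cfg = replace(config, batch_size=size, max_epochs=100,
                      early_stop_wt_sd=0.0)
        _, log = fit_model(observations, split, cfg)
        vl = log.val_loss[-1]
        logger.info("batch size %d -> validation loss %.6f", size, vl)
        if vl < best_loss:
            best_size, best_loss = size, vl
    return best_size


def evaluate_heldout(model: EnergyModel, split: DataSplit,
                     observations: Sequence[FitnessObservation],
                     subset: str = "validation") -> dict:
    """Per-experiment R^2 = 1 - SS_res/SS_tot on held-out observations,
    plus the median across abundance and across binding experiments."""
    keys = {"validation": split.validation, "test": split.test,
            "both": split.validation | split.test}[subset]
    held = [o for o in observations
            if (str(o.genotype), o.experiment) in keys
            and not o.genotype.has_stop()]
    if not held:
        raise ValueError("empty held-out set")
    per_exp: dict[ExperimentId, list[tuple[float, float]]] = {}
    for o in held:
        yhat = predict_fitness(o.genotype, o.experiment, model)
        per_exp.setdefault(o.experiment, []).append((o.fitness, yhat))
    r2 = {}
    for e, pairs in per_exp.items():
        y = np.array([p[0] for p in pairs])
        yhat = np.array([p[1] for p in pairs])
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(np.sum((y - yhat) ** 2))
        r2[e] = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    abundance = [v for e, v in r2.items() if e.assay == "abundance"]
    binding = [v for e, v in r2.items() if e.assay == "binding"]
    return {
        "per_experiment": r2,
        "median_abundance_r2": float(np.median(abundance)) if abundance else float("nan"),
        "median_binding_r2": float(np.median(binding)) if binding else float("nan"),
    }


def export_model(model: EnergyModel, coeff_path: str | Path,
                 affine_path: str | Path) -> None:
    """Write coefficients as TSV (trait/partner/variant/theta/dg_kcal_mol)
    and affine layers (+ constants) as JSON. ``import_model`` restores
    predictions bit-identically (full float repr round-trip)."""
    rows = [{"trait": "folding", "partner": "none", "variant": "WT",
             "theta": model.wt_dgf / model.rt, "dg_kcal_mol": model.wt_dgf}]
    for s, v in sorted(model.ddgf.items(), key=lambda kv: (int(kv[0][1:-1]), kv[0])):
        rows.append({"trait": "folding", "partner": "none", "variant": s,
                     "theta": v / model.rt, "dg_kcal_mol": v})
    for p in sorted(model.wt_dgb):
        rows.append({"trait": "binding", "partner": p, "variant": "WT",
                     "theta": model.wt_dgb[p] / model.rt,
                     "dg_kcal_mol": model.wt_dgb[p]})
        for s, v in sorted(model.ddgb.get(p, {}).items(),
                           key=lambda kv: (int(kv[0][1:-1]), kv[0])):
            rows.append({"trait": "binding", "partner": p, "variant": s,
                         "theta": v / model.rt, "dg_kcal_mol": v})
    pd.DataFrame(rows).to_csv(coeff_path, sep="\t", index=False,
                              float_format="%.17g")
    affine = {str(e): {"assay": e.assay, "partner": e.partner,
                       "block": e.block, "a": a, "b": b}
              for e, (a, b) in model.affine.items()}
    with open(affine_path, "w") as fh:
        json.dump({"rt": model.rt, "affine": affine}, fh, indent=1)


def import_model(coeff_path: str | Path, affine_path: str | Path) -> EnergyModel:
    df = pd.read_csv(coeff_path, sep="\t", float_precision="round_trip")
    with open(affine_path) as fh:
        meta = json.load(fh)
    model = EnergyModel(rt=float(meta["rt"]))
    for row in df.itertuples(index=False):
        v = float(row.dg_kcal_mol)
        if row.trait == "folding":
            if row.variant == "WT":
                model.wt_dgf = v
            else:
                model.ddgf[row.variant] = v
        else:
            if row.variant == "WT":
                model.wt_dgb[row.partner] = v
            else:
                model.ddgb.setdefault(row.partner, {})[row.variant] = v
    for entry in meta["affine"].values():
        e = ExperimentId(entry["assay"], entry["partner"], int(entry["block"]))
        model.affine[e] = (float(entry["a"]), float(entry["b"]))
    return model
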