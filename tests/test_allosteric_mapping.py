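"""Position summaries, allosteric calls, ROC, Fisher and strand decay."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from ddpca.allosteric_mapping import (beta_sheet_decay,
                                      call_allosteric_mutations,
                                      call_major_allosteric_sites,
                                      fisher_enrichment, interface_threshold,
                                      position_summaries, roc_auc,
                                      weighted_mean_abs)
from ddpca.structure_annotation import StructureAnnotation, annotate_regions
from ddpca.uncertainty import FreeEnergyEstimate


def _est(variant, mean, sd, trait="binding:RAF1", confident=True):
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    return FreeEnergyEstimate(trait, variant, mean, sd, lo, hi, 10, confident)


def _ann(residue, interface=False):
    labels = {"interface"} if interface else set()
    return StructureAnnotation(residue, 3.0 if interface else 20.0,
                               math.inf, 0.5, labels)


class TestWeightedMeanAbs:
    def test_equal_sds_is_mean_of_magnitudes(self):
        assert weighted_mean_abs([1.0, -3.0], [0.5, 0.5]) == pytest.approx(2.0)

    def test_inverse_variance_hand_computation(self):
        # weights 1 and 0.25: (1*1 + 0.25*2) / 1.25 = 1.2
        assert weighted_mean_abs([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.2)

    def test_single_value_absolute(self):
        assert weighted_mean_abs([-0.7], [0.1]) == pytest.approx(0.7)

    def test_uniform_mode_and_errors(self):
        assert weighted_mean_abs([1, 2], [1, 9], weights="uniform") == 1.5
        with pytest.raises(ValueError):
            weighted_mean_abs([], [])
        with pytest.raises(ValueError):
            weighted_mean_abs([1.0], [0.0])


class TestInterfaceThreshold:
    def test_single_interface_residue_symmetric_effects(self):
        ests = [_est("G12C", 1.0, 0.2), _est("G12D", -1.0, 0.2)]
        ann = [_ann(12, interface=True), _ann(13)]
        assert interface_threshold(ests, ann, ["RAF1"]) == pytest.approx(1.0)

    def test_pooled_not_mean_of_per_partner_thresholds(self):
        ests = [_est("G12C", 1.0, 0.1, "binding:RAF1"),
                _est("G12C", 3.0, 0.3, "binding:PIK3CG")]
        ann = [_ann(12, interface=True)]
        pooled = interface_threshold(ests, ann, ["RAF1", "PIK3CG"])
        w = np.array([1 / 0.01, 1 / 0.09])
        expected = float((w * [1.0, 3.0]).sum() / w.sum())
        per_partner_mean = (1.0 + 3.0) / 2
        assert pooled == pytest.approx(expected)
        assert pooled != pytest.approx(per_partner_mean)

    def test_per_partner_annotation_mapping(self):
        ests = [_est("G12C", 1.0, 0.2, "binding:RAF1"),
                _est("D33E", 2.0, 0.2, "binding:PIK3CG")]
        ann = {"RAF1": [_ann(12, True), _ann(33)],
               "PIK3CG": [_ann(12), _ann(33, True)]}
        t = interface_threshold(ests, ann, ["RAF1", "PIK3CG"])
        assert t == pytest.approx(1.5)

    def test_empty_partner_set_raises(self):
        with pytest.raises(ValueError):
            interface_threshold([_est("G12C", 1, 0.1)], [_ann(12, True)], [])

    def test_no_interface_mutations_raises(self):
        with pytest.raises(ValueError):
            interface_threshold([_est("G12C", 1, 0.1)], [_ann(13, True)],
                                ["RAF1"])


class TestAllostericMutations:
    def test_mean_at_threshold_not_called(self):
        calls = call_allosteric_mutations(
            [_est("D33E", 1.0, 0.1)], [_ann(33), _ann(12, True)],
            threshold=1.0, partner="RAF1")
        assert len(calls) == 1 and not calls[0].called

    def test_ten_sigma_above_threshold_called(self):
        calls = call_allosteric_mutations(
            [_est("D33E", 2.0, 0.1)], [_ann(33), _ann(12, True)],
            threshold=1.0, partner="RAF1")
        assert calls[0].called and calls[0].z == pytest.approx(10.0)

    def test_interface_mutations_excluded_from_family(self):
        calls = call_allosteric_mutations(
            [_est("G12C", 5.0, 0.1), _est("D33E", 0.0, 0.1)],
            [_ann(12, True), _ann(33)], threshold=1.0, partner="RAF1")
        assert [c.estimate.variant for c in calls] == ["D33E"]

    def test_planted_mutations_recovered_with_fdr_control(self):
        """20 planted allosteric mutations (ddGb = 2, sd 0.2) among 500
        nulls: recall >= 0.95 at empirical FDR <= 0.1."""
        rng = np.random.default_rng(5)
        ests, ann, planted = [], [_ann(5, interface=True)], set()
        ests.append(_est("A11C", 1.0, 0.05))  # defines threshold ~1.0
        ann.append(_ann(11))
        positions = [p for p in range(12, 181)]
        mut_codes = list("ACDEFGHIKLMNPQRSTVWY")
        k = 0
        for i in range(520):
            pos = positions[i % len(positions)]
            mut = mut_codes[(i // len(positions)) % 20]
            name = f"X{pos}{mut}"
            if i < 20:
                ests.append(_est(name, float(rng.normal(2.0, 0.05)), 0.2))
                planted.add(name)
            else:
                ests.append(_est(name, float(rng.normal(0.0, 0.05)), 0.2))
            if pos not in {a.residue for a in ann}:
                ann.append(_ann(pos))
        calls = call_allosteric_mutations(ests, [_ann(5, True)] + ann,
                                          threshold=1.0, partner="RAF1")
        called = {c.estimate.variant for c in calls if c.called}
        called -= {"A11C"}
        tp = len(called & planted)
        assert tp / len(planted) >= 0.95
        fdr = (len(called) - tp) / max(len(called), 1)
        assert fdr <= 0.1


class TestMajorAllostericSites:
    def _summaries(self):
        ests = ([_est(f"G12{m}", 2.0, 0.2) for m in "ACD"]
                + [_est(f"D33{m}", 0.9, 0.2) for m in "AC"]
                + [_est(f"I36{m}", 1.1, 0.2) for m in "AC"]
                + [_est(f"Y40{m}", 3.0, 0.2) for m in "AC"])
        ann = [_ann(12), _ann(33), _ann(36), _ann(40, interface=True),
               _ann(50)]
        return position_summaries(ests, ann, "binding:RAF1")

    def test_inclusive_threshold_and_interface_exclusion(self):
        sites = call_major_allosteric_sites(self._summaries(), threshold=1.1)
        residues = {s.residue for s in sites}
        assert residues == {12, 36}  # 36 exactly at threshold; 40 interface
        assert all(s.is_major_allosteric for s in sites)

    def test_matches_exhaustive_manual_filter(self):
        summaries = self._summaries()
        for thr in (0.5, 0.9, 1.1, 2.0, 2.5):
            got = {s.residue for s in
                   call_major_allosteric_sites(summaries, thr)}
            manual = {s.residue for s in summaries
                      if not s.is_interface
                      and s.weighted_mean_abs_ddg >= thr}
            assert got == manual

    def test_monotone_in_threshold(self):
        summaries = self._summaries()
        prev = None
        for thr in np.linspace(0, 4, 30):
            cur = {s.residue for s in
                   call_major_allosteric_sites(summaries, float(thr))}
            if prev is not None:
                assert cur <= prev
            prev = cur


def auc_bruteforce(scores, labels):
    """Pairwise concordance probability with 0.5 tie credit."""
    pos = [scores[r] for r in scores if labels[r]]
    neg = [scores[r] for r in scores if not labels[r]]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {i: float(i) for i in range(1, 11)}
        labels = {i: i > 5 for i in range(1, 11)}
        auc, curve = roc_auc(scores, labels)
        assert auc == 1.0
        assert curve.fpr.iloc[0] == 0.0 and curve.tpr.iloc[-1] == 1.0

    def test_constant_scores_half(self):
        scores = {i: 1.0 for i in range(1, 11)}
        labels = {i: i > 5 for i in range(1, 11)}
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5)

    def test_eight_point_toy_matches_concordance(self):
        scores = dict(zip(range(8), [0.1, 0.4, 0.35, 0.8, 0.8, 0.2, 0.6, 0.7]))
        labels = dict(zip(range(8), [0, 0, 1, 1, 0, 0, 1, 1]))
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_bruteforce(scores, labels), abs=1e-12)

    def test_matches_bruteforce_on_random_small_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(2, 51))
            labels = {}
            while True:
                labels = {i: bool(rng.integers(0, 2)) for i in range(n)}
                if 0 < sum(labels.values()) < n:
                    break
            # discretized scores force ties
            scores = {i: float(rng.integers(0, 6)) for i in range(n)}
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_bruteforce(scores, labels),
                                        abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc({1: 0.3, 2: 0.4}, {1: True, 2: True})


def fisher_p_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration: sum the
    probabilities of all tables (same margins) no more likely than the
    observed one."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, col1, row1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisherEnrichment:
    def test_flat_table(self):
        res = fisher_enrichment(1, 1, 1, 1)
        assert res.odds_ratio == 1.0 and res.p == pytest.approx(1.0)

    def test_2112_table_enumeration(self):
        res = fisher_enrichment(2, 1, 1, 2)
        assert res.odds_ratio == pytest.approx(4.0)
        assert res.p == pytest.approx(fisher_p_oracle(2, 1, 1, 2), abs=1e-12)

    def test_degenerate_table_haldane(self):
        res = fisher_enrichment(5, 0, 0, 5)
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx(121.0)
        assert res.p == pytest.approx(2 / 252, abs=1e-12)

    def test_matches_enumeration_on_random_small_tables(self):
        rng = np.random.default_rng(4)
        checked = 0
        while checked < 300:
            cells = rng.multinomial(int(rng.integers(1, 61)),
                                    [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            res = fisher_enrichment(a, b, c, d)
            assert res.p == pytest.approx(fisher_p_oracle(a, b, c, d),
                                          abs=1e-9)
            checked += 1

    def test_negative_cell_raises(self):
        with pytest.raises(ValueError):
            fisher_enrichment(-1, 1, 1, 1)


class TestBetaSheetDecay:
    strands = ["beta2", "beta1", "beta3"]

    def _ann(self):
        out = []
        for res, strand in [(40, "beta2"), (5, "beta1"), (53, "beta3")]:
            a = StructureAnnotation(res, 20.0, math.inf, 0.5, {strand})
            out.append(a)
        return out

    def test_strict_decay_rho_minus_one(self):
        ests = [_est("R41A", 3.0, 0.1), _est("L6A", 2.0, 0.1),
                _est("C51A", 1.0, 0.1)]
        ann = [StructureAnnotation(41, 20, math.inf, 0.5, {"beta2"}),
               StructureAnnotation(6, 20, math.inf, 0.5, {"beta1"}),
               StructureAnnotation(51, 20, math.inf, 0.5, {"beta3"})]
        decay = beta_sheet_decay(ests, ann, self.strands, "RAF1")
        assert decay.spearman_rho == pytest.approx(-1.0)
        assert decay.per_strand_mean == {
            "beta2": pytest.approx(3.0), "beta1": pytest.approx(2.0),
            "beta3": pytest.approx(1.0)}

    def test_all_equal_rho_zero(self):
        ests = [_est("R41A", 1.0, 0.1), _est("L6A", 1.0, 0.1),
                _est("C51A", 1.0, 0.1)]
        ann = [StructureAnnotation(41, 20, math.inf, 0.5, {"beta2"}),
               StructureAnnotation(6, 20, math.inf, 0.5, {"beta1"}),
               StructureAnnotation(51, 20, math.inf, 0.5, {"beta3"})]
        decay = beta_sheet_decay(ests, ann, self.strands, "RAF1")
        assert decay.spearman_rho == 0.0

    def test_matches_rank_and_correlate_by_hand(self):
        from scipy.stats import spearmanr
        mags = [2.5, 2.0, 1.4, 1.0, 0.5, 0.3]
        residues = [40, 41, 5, 6, 51, 52]
        strand_of = {40: "beta2", 41: "beta2", 5: "beta1", 6: "beta1",
                     51: "beta3", 52: "beta3"}
        ests = [_est(f"X{r}A", m, 0.1) for r, m in zip(residues, mags)]
        ann = [StructureAnnotation(r, 20, math.inf, 0.5, {strand_of[r]})
               for r in residues]
        decay = beta_sheet_decay(ests, ann, self.strands, "RAF1")
        ranks = [self.strands.index(strand_of[r]) for r in residues]
        rho, _ = spearmanr(ranks, mags)
        assert decay.spearman_rho == pytest.approx(float(rho), abs=1e-12)

    def test_no_labelled_mutations_raises(self):
        with pytest.raises(ValueError):
            beta_sheet_decay([_est("G12A", 1, 0.1)], [_ann(12)],
                             self.strands, "RAF1")


class TestRocContrastOnConfoundedData:
    def test_energy_score_beats_fitness_score_under_folding_confound(self):
        """When strongly destabilizing core mutations confound the raw
        binding fitness, the inferred binding energies still single out the
        interface while |fitness| flags folding-dead positions too."""
        import collections
        from ddpca import synthetic_data as sd
        from ddpca import thermo_model as tm
        from ddpca import uncertainty as un

        ep = sd.EffectParams(p_zero_core=0.05, destab_gamma_shape=2.5,
                             destab_gamma_scale=1.0,
                             interface_hit_fraction=0.4)
        truth = sd.sample_truth(n_positions=30, partners=("RAF1",), seed=9,
                                effect_params=ep, wt_dgf=-1.2,
                                n_allosteric=0, core_fraction=0.35)
        library = sd.design_library(truth)
        data = sd.simulate_fitness(truth, library, sigma=0.05, seed=21)
        cfg = tm.TrainingConfig(seed=5, max_epochs=400)
        ens = un.mc_ensemble(data.observations, cfg, n_models=4,
                             master_seed=91, partners=("RAF1",))
        est = un.summarize_energies(ens)
        ann = sd.synthetic_structure(truth, "RAF1")
        summ = position_summaries(est, ann, "binding:RAF1",
                                  weights="uniform")
        labels = {s.residue: s.is_interface for s in summ}
        auc_ddg, _ = roc_auc({s.residue: s.weighted_mean_abs_ddg
                              for s in summ}, labels)
        fit_by_pos = collections.defaultdict(list)
        for o in data.observations:
            if o.experiment.assay == "binding" and o.genotype.order == 1:
                fit_by_pos[o.genotype.positions[0]].append(abs(o.fitness))
        scores = {p: float(np.mean(v)) for p, v in fit_by_pos.items()
                  if p in labels}
        auc_fit, _ = roc_auc(scores, {p: labels[p] for p in scores})
        assert auc_ddg >= auc_fit
        assert auc_ddg >= 0.9
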