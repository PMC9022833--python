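"""Hierarchical family-level replication, nominal criterion, sign test."""

import numpy as np
import pandas as pd
import pytest

import pharmtx as px
from pharmtx.containers import ValidationError
from pharmtx.covariates import AdjustmentModel
from pharmtx.diffexpr import bh_adjust
from pharmtx.replication import (
    Family,
    ReplicationInput,
    build_replication_input,
    hierarchical_replication,
    nominal_replication,
    sensitivity_analysis,
    sign_test,
)

from conftest import make_expression


def _null_cohort(rng, n=400, p=200, n_substances=1, prevalence=0.3):
    """Log2-scale cohort with no true effects and a minimal annotation."""
    expr = make_expression(rng.normal(7, 1, size=(p, n)))
    annot = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n),
            "age": rng.normal(60, 10, n),
            "lymphocytes": rng.normal(30, 5, n),
            "monocytes": rng.normal(8, 2, n),
            "smoking": rng.integers(0, 2, n),
            "bmi": rng.normal(27, 4, n),
        },
        index=expr.sample_ids,
    )
    med = pd.DataFrame(
        {
            f"SUB{i}": (rng.random(n) < prevalence).astype(np.int8)
            for i in range(n_substances)
        },
        index=expr.sample_ids,
    )
    return expr, annot, med


class TestSelectionArithmetic:
    def test_family_selection_and_adjusted_threshold(self, rng, monkeypatch):
        """Three families with min q (0.001, 0.5, 0.9): BH selects only the
        first; probes there are re-thresholded at 0.05 * 1/3."""
        expr, annot, med = _null_cohort(rng, n_substances=3)
        fams = [
            Family(f"SUB{i}", list(expr.probe_ids[:30]),
                   pd.Series(1, index=expr.probe_ids[:30]))
            for i in range(3)
        ]
        # intercept the per-family q-values to fix the min-q vector
        import pharmtx.replication as repl

        real_bh = repl.bh_adjust
        target_min = {"SUB0": 0.001, "SUB1": 0.5, "SUB2": 0.9}
        calls = {"family": []}

        def fake_bh(p):
            q = real_bh(p)
            if len(p) == 30:  # within-family adjustment
                fam = fams[len(calls["family"])].substance
                calls["family"].append(fam)
                q = np.maximum(q, target_min[fam])
                q[np.argmin(q)] = target_min[fam]
            return q

        monkeypatch.setattr(repl, "bh_adjust", fake_bh)
        result = hierarchical_replication(
            ReplicationInput(families=fams), expr, annot, med,
            AdjustmentModel(), q_level=0.05, min_users=5,
        )
        # BH over (0.001, 0.5, 0.9): adjusted = (0.003, 0.75, 0.9) -> 1 selected
        assert result.family_table["selected"].tolist() == [True, False, False]
        assert result.n_selected == 1
        sub0 = result.probe_table[result.probe_table.substance == "SUB0"]
        # selective threshold 0.05 * 1/3
        assert set(sub0[sub0.significant].index) == set(
            sub0[sub0.q <= 0.05 / 3].index
        )

    def test_unselected_family_has_no_replicated_probes(self, rng):
        expr, annot, med = _null_cohort(rng, n_substances=2)
        fams = [
            Family(f"SUB{i}", list(expr.probe_ids[:20]),
                   pd.Series(1, index=expr.probe_ids[:20]))
            for i in range(2)
        ]
        result = hierarchical_replication(
            ReplicationInput(families=fams), expr, annot, med,
            AdjustmentModel(), min_users=5,
        )
        unselected = result.family_table[~result.family_table.selected]
        assert (unselected["n_replicated"] == 0).all()


class TestDirectionRule:
    def test_opposite_direction_never_replicates(self, rng):
        expr, annot, med = _null_cohort(rng)
        # plant a strong effect, then claim the discovery direction was opposite
        probe = expr.probe_ids[0]
        expr.values.loc[probe] += 3.0 * med["SUB0"].to_numpy()
        fam = Family("SUB0", [probe], pd.Series({probe: -1}))
        result = hierarchical_replication(
            ReplicationInput(families=[fam]), expr, annot, med,
            AdjustmentModel(), min_users=5,
        )
        row = result.probe_table.iloc[0]
        assert row.significant and not row.replicated

    def test_flipping_intake_coding_flips_directions(self, rng):
        expr, annot, med = _null_cohort(rng)
        probe = expr.probe_ids[0]
        expr.values.loc[probe] += 3.0 * med["SUB0"].to_numpy()
        fam = Family("SUB0", [probe], pd.Series({probe: 1}))
        res1 = hierarchical_replication(
            ReplicationInput(families=[fam]), expr, annot, med,
            AdjustmentModel(), min_users=5,
        )
        med_flipped = 1 - med
        res2 = hierarchical_replication(
            ReplicationInput(families=[fam]), expr, annot, med_flipped,
            AdjustmentModel(), min_users=5,
        )
        assert res1.probe_table.iloc[0].replicated
        assert res2.probe_table.iloc[0].direction == -res1.probe_table.iloc[0].direction
        assert not res2.probe_table.iloc[0].replicated


class TestMonotonicity:
    def test_adding_null_probe_keeps_other_calls(self, rng):
        expr, annot, med = _null_cohort(rng)
        probes = list(expr.probe_ids[:10])
        for pr in probes[:3]:
            expr.values.loc[pr] += 2.0 * med["SUB0"].to_numpy()
        fam_small = Family("SUB0", probes, pd.Series(1, index=probes))
        # add one more probe that is pure noise (q will be ~1)
        probes_big = probes + [expr.probe_ids[150]]
        fam_big = Family("SUB0", probes_big, pd.Series(1, index=probes_big))
        r1 = hierarchical_replication(
            ReplicationInput(families=[fam_small]), expr, annot, med,
            AdjustmentModel(), min_users=5,
        )
        r2 = hierarchical_replication(
            ReplicationInput(families=[fam_big]), expr, annot, med,
            AdjustmentModel(), min_users=5,
        )
        rep1 = set(r1.probe_table.loc[r1.probe_table.replicated, "probe"])
        rep2 = set(r2.probe_table.loc[r2.probe_table.replicated, "probe"])
        # strongly separated effects: the extra noise probe does not change calls
        assert rep2 - {str(expr.probe_ids[150])} == rep1


class TestNominal:
    @pytest.mark.parametrize(
        "p,d_disc,d_rep,expected",
        [
            (0.049, 1, 1, True),
            (0.049, 1, -1, False),
            (0.051, 1, 1, False),
        ],
    )
    def test_nominal_rule(self, p, d_disc, d_rep, expected):
        table = pd.DataFrame(
            {"p": [p], "direction": [d_rep], "direction_discovery": [d_disc]}
        )
        assert nominal_replication(table).iloc[0] == expected


class TestSignTest:
    def test_all_concordant(self):
        p = sign_test([1] * 8, [1] * 8)
        assert p == pytest.approx(2 * 0.5**8)

    def test_half_concordant_is_null_center(self):
        signs = [1] * 5 + [-1] * 5
        assert sign_test([1] * 10, signs) == pytest.approx(1.0)

    def test_fully_discordant_symmetric_tail(self):
        assert sign_test([1] * 6, [-1] * 6) == pytest.approx(2 * 0.5**6)

    def test_matches_binomial_enumeration(self, rng):
        from math import comb

        for n in [1, 5, 12, 20]:
            a = rng.choice([-1, 1], size=n)
            b = rng.choice([-1, 1], size=n)
            k = int((a == b).sum())
            pmf = [comb(n, i) * 0.5**n for i in range(n + 1)]
            expected = sum(pr for i, pr in enumerate(pmf) if pr <= pmf[k] + 1e-12)
            assert sign_test(a, b) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            sign_test([1, 1], [1])


class TestBuildInput:
    def test_platform_and_medication_intersection(self, cohort_pair):
        cfg, disc_data, rep_data = cohort_pair
        expr, annot, med, probes, truth = disc_data
        out = px.discovery_pipeline(expr, annot, med, probes)
        # replication platform misses some probes and one substance
        rexpr, rannot, rmed, rprobes, rtruth = rep_data
        rep_in = build_replication_input(
            out.de_results,
            replication_probes=rexpr.probe_ids,
            replication_substances=[c for c in rmed.columns if c != "H02AB06"],
        )
        assert "H02AB06" in rep_in.excluded
        assert rep_in.excluded["H02AB06"] == "not recorded in replication cohort"
        assert all(f.substance != "H02AB06" for f in rep_in.families)

    def test_no_families_is_error(self, rng):
        expr, annot, med = _null_cohort(rng)
        with pytest.raises(ValidationError):
            hierarchical_replication(
                ReplicationInput(families=[]), expr, annot, med, AdjustmentModel()
            )


class TestTwoCohort:
    def test_shared_effects_replicate(self, cohort_pair):
        cfg, disc_data, rep_data = cohort_pair
        expr, annot, med, probes, truth = disc_data
        disc = px.discovery_pipeline(expr, annot, med, probes)
        rexpr, rannot, rmed, rprobes, _ = rep_data
        rep = px.replication_pipeline(disc, rexpr, rannot, rmed, rprobes)
        fam = rep.replication.family_table
        # the two effect-carrying substances are selected and replicate probes
        assert fam.loc["H02AB06", "selected"]
        assert fam.loc["H02AB06", "n_replicated"] >= 0.5 * fam.loc["H02AB06", "n_probes_available"]
        sens = rep.sensitivity
        assert sens.loc["H02AB06", "sign_test_p"] < 0.05

    def test_sensitivity_counts_bounded(self, cohort_pair):
        cfg, disc_data, rep_data = cohort_pair
        expr, annot, med, probes, truth = disc_data
        disc = px.discovery_pipeline(expr, annot, med, probes)
        rexpr, rannot, rmed, rprobes, _ = rep_data
        rep = px.replication_pipeline(disc, rexpr, rannot, rmed, rprobes)
        sens = rep.sensitivity
        assert (sens["n_nominal_same_direction"] <= sens["n_probes"]).all()
        assert (sens["n_concordant"] <= sens["n_probes"]).all()
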