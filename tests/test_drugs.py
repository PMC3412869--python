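"""State-dependent block: scheme augmentation, analytic oracles, and the
mechanistic signatures of closed- vs open-state blockers."""

import numpy as np
import pytest

from mouseap.channels import build_iktof_scheme
from mouseap.drugs import DrugSpec, augment_scheme, fraction_blocked
from mouseap.markov import (
    MarkovScheme,
    SchemeError,
    Transition,
    simulate_piecewise_clamp,
    steady_state_occupancy,
)
from mouseap.protocols import BLOCK_CLAMP, clamp_channel


@pytest.fixture(scope="module")
def control_trace():
    return clamp_channel("iktof", BLOCK_CLAMP)


def drugged_trace(mech, dose, **over):
    return clamp_channel("iktof", BLOCK_CLAMP,
                         drug=DrugSpec.from_name(mech, dose, **over))


class TestDrugSpec:
    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError, match="mechanism"):
            DrugSpec(mechanism="allosteric", concentration=1.0, kon=1.0, koff=1.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            DrugSpec.drug_o(-0.1)

    def test_named_loaders(self):
        c = DrugSpec.drug_c(1.0)
        o = DrugSpec.drug_o(0.1)
        assert c.mechanism == "closed_state" and o.mechanism == "open_state"
        assert c.koff_b3 > c.koff     # block relieved on depolarization
        assert o.koff_b3 == o.koff


class TestAugmentScheme:
    def test_closed_state_adds_three_bound_states(self):
        aug = augment_scheme(build_iktof_scheme(), DrugSpec.drug_c(1.0))
        assert aug.states[-3:] == ("B1", "B2", "B3")
        assert aug.conducting_states == frozenset({"O"})

    def test_open_state_adds_single_bound_state(self):
        aug = augment_scheme(build_iktof_scheme(), DrugSpec.drug_o(0.1))
        assert aug.states[-1] == "BO"

    def test_base_transitions_preserved(self):
        base = build_iktof_scheme()
        aug = augment_scheme(base, DrugSpec.drug_c(1.0))
        base_edges = {(t.src, t.dst) for t in base.transitions}
        aug_edges = {(t.src, t.dst) for t in aug.transitions}
        assert base_edges <= aug_edges

    def test_closed_block_needs_three_closed_states(self):
        toy = MarkovScheme(
            name="toy", states=("C1", "O"),
            transitions=(Transition("C1", "O", lambda V, c: 1.0),
                         Transition("O", "C1", lambda V, c: 1.0)),
            conducting_states=frozenset({"O"}),
        )
        with pytest.raises(SchemeError, match="three closed states"):
            augment_scheme(toy, DrugSpec.drug_c(1.0))

    def test_association_scales_linearly_with_dose(self):
        aug = augment_scheme(build_iktof_scheme(), DrugSpec.drug_o(1.0))
        bind = [t for t in aug.transitions if t.label == "bind"][0]
        assert bind.rate(0.0, 2.0) == pytest.approx(2 * bind.rate(0.0, 1.0))

    def test_open_block_steady_state_matches_analytic_three_state(self):
        """C<->O plus open block: stationary occupancy of the linear
        three-state chain solved in closed form (detailed balance)."""
        alpha, beta, kon, koff, dose = 0.8, 0.3, 2.0, 0.05, 0.4
        toy = MarkovScheme(
            name="toy", states=("C", "O"),
            transitions=(Transition("C", "O", lambda V, c: alpha),
                         Transition("O", "C", lambda V, c: beta)),
            conducting_states=frozenset({"O"}),
        )
        aug = augment_scheme(
            toy, DrugSpec(mechanism="open_state", concentration=dose,
                          kon=kon, koff=koff)
        )
        p = steady_state_occupancy(aug, 0.0, drug_conc=dose)
        # chain C <-> O <-> B: p_O/p_C = alpha/beta, p_B/p_O = kon*dose/koff
        w = np.array([1.0, alpha / beta, (alpha / beta) * kon * dose / koff])
        assert np.allclose(p, w / w.sum(), atol=1e-9)


class TestZeroDoseEquivalence:
    @pytest.mark.parametrize("mech", ["c", "o"])
    def test_zero_concentration_reduces_to_unblocked(self, mech, control_trace):
        tr = drugged_trace(mech, 0.0)
        peak = control_trace.current.max()
        assert np.abs(tr.current - control_trace.current).max() < 1e-9 * peak


class TestBlockSignatures:
    def test_fraction_blocked_identity_and_errors(self, control_trace):
        assert fraction_blocked(control_trace, control_trace, "peak") == 0.0
        assert fraction_blocked(control_trace, control_trace, "area") == 0.0
        with pytest.raises(ValueError, match="mode"):
            fraction_blocked(control_trace, control_trace, "charge")
        silent = drugged_trace("o", 0.0)
        silent.current = np.zeros_like(silent.current)
        with pytest.raises(ValueError, match="undefined"):
            fraction_blocked(silent, control_trace, "peak")

    def test_low_dose_closed_blocker_has_no_detectable_effect(self, control_trace):
        tr = drugged_trace("c", 0.001)   # 1 uM
        assert fraction_blocked(control_trace, tr, "peak") < 0.01
        assert fraction_blocked(control_trace, tr, "area") < 0.01

    @pytest.mark.parametrize("mech,mode", [("c", "peak"), ("c", "area"),
                                           ("o", "peak"), ("o", "area")])
    def test_block_monotone_in_dose(self, mech, mode, control_trace):
        doses = np.logspace(-3, 1, 7)
        fb = [fraction_blocked(control_trace, drugged_trace(mech, d), mode)
              for d in doses]
        assert np.all(np.diff(fb) >= -1e-6)

    def test_decay_kinetics_signature_at_1mM(self, control_trace):
        """Closed-state block slows apparent current decay; open-state block
        accelerates it (time-to-half-decay ordering)."""

        def t_half(tr):
            cur = tr.current
            i = cur.argmax()
            below = np.nonzero(cur[i:] <= cur[i] / 2)[0]
            return tr.time_ms[i:][below[0]] - tr.time_ms[i]

        th_ctrl = t_half(control_trace)
        assert t_half(drugged_trace("o", 1.0)) < th_ctrl < t_half(drugged_trace("c", 1.0))

    def test_open_block_area_exceeds_peak_block_at_1mM(self, control_trace):
        tr = drugged_trace("o", 1.0)
        area = fraction_blocked(control_trace, tr, "area")
        peak = fraction_blocked(control_trace, tr, "peak")
        assert area >= peak
        assert area > 0.9

    def test_occupancy_conserved_in_augmented_schemes(self):
        for mech, dose in (("c", 10.0), ("o", 1.0)):
            tr = drugged_trace(mech, dose)
            assert np.abs(tr.occupancy.sum(axis=1) - 1).max() < 1e-6
            assert tr.occupancy.min() >= -1e-9
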