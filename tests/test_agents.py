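"""Single-cell behavioural rules: walks, contacts, differentiation, arrest."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppsim import (
    LTI,
    LTIN,
    CellState,
    MotileCell,
    adhesion_arrest_probability,
    handle_contact,
    step_lti,
    step_ltin,
)

from conftest import make_environment

STEP = dict(speed=5.0, dt=1.0, r_adh=50.0)


def cell(kind, x, y, state=CellState.MIGRATING):
    return MotileCell(
        kind=kind, position=np.array([x, y], dtype=float), radius=5.0, state=state
    )


class TestArrestProbability:
    @pytest.mark.parametrize(
        "expr,d,expected",
        [
            (0.0, 10.0, 0.0),
            (1.0, 0.0, 1.0),
            (0.5, 25.0, 0.25),  # r_adh/2 at r_adh=50
            (1.0, 50.0, 0.0),  # at the cutoff
            (0.7, 80.0, 0.0),  # beyond the cutoff
        ],
    )
    def test_closed_form(self, expr, d, expected):
        assert adhesion_arrest_probability(expr, d, 50.0) == pytest.approx(expected)

    @pytest.mark.parametrize("expr", [-0.1, 1.1])
    def test_expression_domain_error(self, expr):
        with pytest.raises(ValueError):
            adhesion_arrest_probability(expr, 10.0, 50.0)

    @given(
        e1=st.floats(0.0, 1.0),
        e2=st.floats(0.0, 1.0),
        d=st.floats(0.0, 100.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_monotone_in_expression(self, e1, e2, d):
        lo, hi = sorted([e1, e2])
        assert adhesion_arrest_probability(
            lo, d, 50.0
        ) <= adhesion_arrest_probability(hi, d, 50.0)


class TestHandleContact:
    def test_ltin_differentiates_virgin_lto(self):
        env = make_environment(lto_positions=[(100.0, 100.0)])
        handle_contact(env, 0, LTIN, l0=0.2, dl=0.05)
        assert env.lto_differentiated[0]
        assert env.lto_expression[0] == pytest.approx(0.2)

    def test_lti_matures_differentiated_lto(self):
        env = make_environment(lto_positions=[(100.0, 100.0)], expressions=[0.4])
        handle_contact(env, 0, LTI, l0=0.2, dl=0.05)
        assert env.lto_expression[0] == pytest.approx(0.45)
        assert env.lto_lti_contacts[0] == 1

    def test_expression_caps_at_one(self):
        env = make_environment(lto_positions=[(100.0, 100.0)], expressions=[0.98])
        handle_contact(env, 0, LTI, l0=0.2, dl=0.05)
        assert env.lto_expression[0] == 1.0

    def test_lti_cannot_initiate(self):
        env = make_environment(lto_positions=[(100.0, 100.0)])
        handle_contact(env, 0, LTI, l0=0.2, dl=0.05)
        assert not env.lto_differentiated[0]
        assert env.lto_expression[0] == 0.0

    def test_repeat_ltin_contact_is_inert(self):
        env = make_environment(lto_positions=[(100.0, 100.0)], expressions=[0.5])
        handle_contact(env, 0, LTIN, l0=0.2, dl=0.05)
        assert env.lto_expression[0] == pytest.approx(0.5)


class TestStepLTin:
    def test_arrested_cell_is_inert(self, bare_environment, rng):
        c = cell(LTIN, 100.0, 100.0, state=CellState.ARRESTED)
        out, events = step_ltin(c, bare_environment, rng, **STEP)
        assert out is c
        assert events == []

    def test_free_walk_moves_exactly_one_step_length(self, bare_environment, rng):
        c = cell(LTIN, 500.0, 200.0)
        out, events = step_ltin(c, bare_environment, rng, **STEP)
        d = bare_environment.distance(out.position, c.position)
        assert d == pytest.approx(5.0)
        assert out.state is CellState.MIGRATING
        assert events == []

    def test_contact_event_differentiates_lto(self, rng):
        env = make_environment(lto_positions=[(500.0, 200.0)])
        c = cell(LTIN, 500.0, 200.0)  # overlapping the LTo wherever it steps
        out, events = step_ltin(c, env, rng, **STEP)
        assert len(events) == 1
        for ev in events:
            handle_contact(env, ev.lto_index, ev.cell_kind, l0=0.2, dl=0.05)
        assert env.lto_differentiated[0]

    def test_wrong_kind_rejected(self, bare_environment, rng):
        with pytest.raises(ValueError):
            step_ltin(cell(LTI, 0.0, 0.0), bare_environment, rng, **STEP)

    def test_random_walk_diagnostic(self, bare_environment):
        """Free LTin walks: mean displacement ~0, MSD ~ linear in steps."""
        rng = np.random.default_rng(42)
        n_cells, n_steps, step_len = 150, 64, 5.0
        disp = np.zeros((n_cells, 2))
        msd_half = msd_full = 0.0
        for i in range(n_cells):
            c = cell(LTIN, 500.0, 200.0)
            for s in range(n_steps):
                c, _ = step_ltin(c, bare_environment, rng, **STEP)
                if s == n_steps // 2 - 1:
                    msd_half += np.sum(
                        bare_environment.delta(c.position, [500.0, 200.0]) ** 2
                    )
            disp[i] = bare_environment.delta(c.position, [500.0, 200.0])
            msd_full += np.sum(disp[i] ** 2)
        msd_half /= n_cells
        msd_full /= n_cells
        # isotropy: mean displacement small relative to single-walk RMS
        rms = np.sqrt(msd_full)
        assert np.linalg.norm(disp.mean(axis=0)) < 0.5 * rms
        # diffusive scaling: doubling steps ~doubles MSD (within 35 %)
        assert msd_full / msd_half == pytest.approx(2.0, rel=0.35)


class TestStepLTi:
    def test_arrested_cell_is_inert(self, bare_environment, rng):
        c = cell(LTI, 100.0, 100.0, state=CellState.ARRESTED)
        out, events = step_lti(c, bare_environment, rng, **STEP)
        assert out is c
        assert events == []

    def test_zero_field_walk_is_unbiased_unit_step(self, bare_environment, rng):
        c = cell(LTI, 500.0, 200.0)
        out, _ = step_lti(c, bare_environment, rng, **STEP)
        assert bare_environment.distance(out.position, c.position) == pytest.approx(5.0)

    def test_saturated_field_steps_straight_up_gradient(self, rng):
        # two coincident saturated sources: level >= 1 within 75 um
        env = make_environment(
            lto_positions=[(500.0, 100.0), (500.0, 100.0)], expressions=[1.0, 1.0]
        )
        c = cell(LTI, 500.0, 160.0)  # 60 um "north" of the sources
        out, _ = step_lti(c, env, rng, **STEP)
        move = env.delta(out.position, c.position)
        assert move[1] == pytest.approx(-5.0, abs=1e-6)  # straight toward source
        assert abs(move[0]) < 1e-6

    def test_saturated_field_distance_strictly_decreases(self, rng):
        env = make_environment(
            lto_positions=[(500.0, 100.0), (500.0, 100.0)],
            expressions=[1.0, 1.0],
            lto_radius=0.5,  # keep contact radius small: observe pure approach
        )
        c = cell(LTI, 500.0, 170.0)
        src = np.array([500.0, 100.0])
        d_prev = env.distance(c.position, src)
        for _ in range(10):
            c, _ = step_lti(c, env, rng, speed=5.0, dt=1.0, r_adh=50.0)
            if c.state is CellState.ARRESTED or d_prev <= 5.0:
                break
            d = env.distance(c.position, src)
            assert d < d_prev
            d_prev = d

    def test_wrong_kind_rejected(self, bare_environment, rng):
        with pytest.raises(ValueError):
            step_lti(cell(LTIN, 0.0, 0.0), bare_environment, rng, **STEP)
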