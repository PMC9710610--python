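import numpy as np
import pytest

from screpsim.dynamics import (
    ISOTYPES,
    RepertoireState,
    SimulationParams,
    class_switch,
    replay_event_log,
    replication_probability,
    run_simulation,
    select_variants,
    step,
)
from screpsim.germline import RecombinationSettings, simulate_initial_repertoire
from screpsim.metrics import gini_coefficient
from screpsim.shm import ShmModel


def small_run(settings, rng_seed=0, shm=None, **overrides):
    params = SimulationParams(seed=rng_seed, **overrides)
    return run_simulation(params, shm_model=shm, settings=settings)


class TestReplicationProbability:
    def test_no_feedback(self):
        p = SimulationParams(p_div0=0.1, beta_div=0.0)
        assert replication_probability(1, p) == replication_probability(500, p) == 0.1

    def test_linear_feedback(self):
        p = SimulationParams(p_div0=0.1, beta_div=0.01, p_max=0.5)
        assert replication_probability(11, p) == pytest.approx(0.20)

    def test_clamped_at_pmax(self):
        p = SimulationParams(p_div0=0.1, beta_div=0.01, p_max=0.5)
        assert replication_probability(10_000, p) == 0.5


class TestClassSwitch:
    def test_identity_matrix_never_switches(self, rng):
        eye = np.eye(5)
        for iso in ISOTYPES:
            assert all(class_switch(iso, eye, rng) == iso for _ in range(20))

    def test_deterministic_row(self, rng):
        m = np.eye(5)
        m[0] = [0, 0, 1, 0, 0]
        assert all(class_switch("IGHM", m, rng) == "IGHG" for _ in range(20))

    def test_invalid_matrix_rejected(self):
        bad = np.eye(5)
        bad[0, 0] = -1.0
        with pytest.raises(ValueError):
            SimulationParams(isotype_T=bad)
        bad2 = np.eye(5)
        bad2[1, 1] = 0.5
        with pytest.raises(ValueError, match="sum"):
            SimulationParams(isotype_T=bad2)


class TestStep:
    def test_static_params_leave_state_unchanged(self, fast_settings, rng):
        params = SimulationParams(
            init_clones=5, p_div0=0.0, p_death=0.0, p_new_clone=0.0, seed=3
        )
        state = run_simulation(params, shm_model=None, settings=fast_settings)
        assert state.step_index == params.n_steps
        alive = state.alive_cells()
        assert len(alive) == 5
        assert all(c.birth_step == 0 for c in alive)

    def test_certain_death(self, fast_settings):
        params = SimulationParams(
            init_clones=8, n_steps=1, p_div0=0.0, p_death=1.0, p_new_clone=0.0, seed=4
        )
        state = run_simulation(params, shm_model=None, settings=fast_settings)
        assert all(not c.alive and c.death_step == 0 for c in state.cells)

    def test_branching_process_mean(self, fast_settings):
        """beta=0, no death: E[N_n] = (1+p)^n; mean over 1,000 replicates
        within 3 standard errors."""
        p, n_steps, reps = 0.3, 5, 1000
        finals = np.empty(reps)
        for r in range(reps):
            params = SimulationParams(
                init_clones=1, n_steps=n_steps, p_div0=p, beta_div=0.0,
                p_death=0.0, p_new_clone=0.0, seed=10_000 + r,
            )
            state = run_simulation(params, shm_model=None, settings=fast_settings)
            finals[r] = len(state.alive_cells())
        expected = (1 + p) ** n_steps
        se = finals.std(ddof=1) / np.sqrt(reps)
        assert abs(finals.mean() - expected) < 3 * se

    def test_conservation_every_step(self, fast_settings):
        params = SimulationParams(
            init_clones=10, n_steps=10, p_death=0.1, p_new_clone=0.2, seed=5
        )
        rng = np.random.default_rng(params.seed)
        state = RepertoireState(settings=fast_settings, params=params)
        for f in simulate_initial_repertoire(params.init_clones, fast_settings, rng):
            state.found_clone(f, rng)
        shm = ShmModel()
        for _ in range(params.n_steps):
            step(state, params, shm, rng)
            created = sum(
                1 for e in state.event_log if e[1] in ("found_clone", "division")
            )
            n_alive = sum(c.alive for c in state.cells)
            n_dead = sum(not c.alive for c in state.cells)
            assert created == n_alive + n_dead == len(state.cells)

    def test_isotype_monotone_under_default_matrix(self, fast_settings):
        """No cell ever moves left in (IGHM, IGHD, IGHG, IGHA, IGHE)."""
        params = SimulationParams(init_clones=30, n_steps=12, seed=6)
        state = run_simulation(params, shm_model=None, settings=fast_settings)
        rank = {iso: i for i, iso in enumerate(ISOTYPES)}
        history: dict[str, int] = {}
        for _, event, _, bc, _, payload in state.event_log:
            if event == "found_clone":
                history[bc] = rank[payload["isotype"]]
            elif event == "division":
                history[bc] = history[payload["mother"]]
            elif event == "isotype_switch":
                assert rank[payload["to"]] >= history[bc]
                history[bc] = rank[payload["to"]]

    def test_event_log_replay_reproduces_cell_table(self, fast_settings):
        params = SimulationParams(init_clones=10, n_steps=10, p_new_clone=0.3, seed=7)
        state = run_simulation(params, shm_model=ShmModel(), settings=fast_settings)
        replayed = replay_event_log(state.event_log)
        assert len(replayed) == len(state.cells)
        for cell in state.cells:
            assert replayed[cell.barcode] == (
                cell.clone_id, cell.variant_id, cell.isotype, cell.phenotype,
                cell.alive, cell.birth_step, cell.death_step,
            )

    def test_seeded_run_bit_reproducible(self, fast_settings):
        runs = [
            run_simulation(
                SimulationParams(init_clones=10, n_steps=8, seed=42),
                shm_model=ShmModel(), settings=fast_settings,
            )
            for _ in range(2)
        ]
        assert runs[0].event_log == runs[1].event_log


class TestSelection:
    def make_state(self, settings, n_clones=10, seed=8):
        params = SimulationParams(init_clones=n_clones, n_steps=0, seed=seed)
        return run_simulation(params, shm_model=None, settings=settings), params

    def test_mode_none_empty(self, fast_settings, rng):
        state, _ = self.make_state(fast_settings)
        assert select_variants(state, 0, "none", None, rng) == set()

    def test_germline_mode_filter_oracle(self, fast_settings, rng):
        """Selection by V gene matches a direct filter over the founder table."""
        state, _ = self.make_state(fast_settings, n_clones=10)
        v_id = state.clones[0].founder.heavy.v_id
        expected_clones = {
            cid for cid, info in state.clones.items() if info.founder.heavy.v_id == v_id
        }
        for cid in state.clones:
            got = select_variants(state, cid, "germline", v_id, rng)
            assert bool(got) == (cid in expected_clones)

    def test_germline_mode_unknown_v_errors(self, fast_settings, rng):
        state, _ = self.make_state(fast_settings)
        with pytest.raises(ValueError, match="unknown V segment"):
            select_variants(state, 0, "germline", "IGHV99-99", rng)

    def test_cdr3_threshold_zero_selects_all(self, fast_settings, rng):
        state, _ = self.make_state(fast_settings)
        for cid in state.clones:
            assert select_variants(state, cid, "cdr3_length", 0, rng) == set(
                state.networks[cid].nodes
            )

    def test_selected_inheritance_by_sequence(self, fast_settings):
        """Every cell carrying a selected variant's sequence is flagged."""
        params = SimulationParams(
            init_clones=5, n_steps=10, selection_mode="cdr3_length",
            selection_param=0, sel_multiplier=2.0, seed=9,
        )
        state = run_simulation(params, shm_model=ShmModel(), settings=fast_settings)
        for cell in state.alive_cells():
            info = state.clones[cell.clone_id]
            if state.variant_seq(cell) in info.selected_seqs:
                from screpsim.dynamics import _is_selected

                assert _is_selected(state, cell)

    def test_selection_boosts_expansion(self, fast_settings):
        """sel_multiplier > 1 yields more cells than the unselected run."""
        sizes = {}
        for mult in (1.0, 3.0):
            params = SimulationParams(
                init_clones=10, n_steps=10, selection_mode="cdr3_length",
                selection_param=0, sel_multiplier=mult, p_new_clone=0.0, seed=10,
            )
            state = run_simulation(params, shm_model=None, settings=fast_settings)
            sizes[mult] = len(state.alive_cells())
        assert sizes[3.0] > sizes[1.0]


class TestRepertoirePresets:
    def test_expanded_repertoire_more_unequal_than_naive(self, fast_settings):
        """Clone-size Gini: expanded preset > naive preset on >= 3 seeds."""
        wins = 0
        for seed in range(3):
            naive = SimulationParams(
                init_clones=30, n_steps=10, p_div0=0.02, beta_div=0.0,
                p_new_clone=0.5, p_death=0.0, seed=seed,
            )
            expanded = SimulationParams(
                init_clones=30, n_steps=10, p_div0=0.25, beta_div=0.01,
                p_new_clone=0.05, p_death=0.0, seed=seed,
            )
            ginis = {}
            for name, params in (("naive", naive), ("expanded", expanded)):
                state = run_simulation(params, shm_model=None, settings=fast_settings)
                sizes = list(state.clone_sizes().values())
                ginis[name] = gini_coefficient(sizes)
            wins += ginis["expanded"] > ginis["naive"]
        assert wins == 3

    def test_n_steps_zero_initial_state(self, fast_settings):
        params = SimulationParams(init_clones=7, n_steps=0, seed=11)
        state = run_simulation(params, shm_model=None, settings=fast_settings)
        assert len(state.alive_cells()) == 7
        assert all(c.isotype == "IGHM" and c.alive for c in state.cells)
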