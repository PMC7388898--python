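"""Grid-world transition semantics, maze generation and the ASCII format."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ovarlap as ov
from ovarlap.gridworld import ACTIONS, MazeFormatError, _canonical_signature


def open_room(wall_penalty=0.0, goals=None):
    passable = np.zeros((20, 20), dtype=bool)
    passable[1:19, 1:19] = True
    return ov.GridWorld(passable, (10, 10), goals or {(15, 15): 1.0},
                        wall_penalty)


class TestStep:
    def test_wall_hit_painful_vs_painless(self):
        """An ineffective action costs -1 in the painful world and 0 in the
        painless one; either way the agent stays put."""
        for penalty, expected in [(-1.0, -1.0), (0.0, 0.0)]:
            world = open_room(penalty)
            tr = world.step((2, 2), 1)  # west into the border
            assert tr.reward == expected
            assert tr.next_state == (2, 2)
            assert tr.wall_hit and not tr.terminal
            assert tr.intended_target == (1, 2)

    def test_goal_entry_terminates_with_goal_reward(self):
        world = open_room(goals={(15, 15): 2.0})
        tr = world.step((14, 15), 0)  # east into the reward-2 goal
        assert tr.reward == 2.0 and tr.terminal
        assert tr.next_state == (15, 15)

    def test_plain_move(self):
        world = open_room()
        tr = world.step((10, 10), 3)  # north
        assert tr.reward == 0.0 and tr.next_state == (10, 11)
        assert not tr.terminal and not tr.wall_hit

    def test_step_rejects_impassable_and_goal_states(self):
        world = open_room()
        with pytest.raises(ValueError):
            world.step((1, 1), 0)
        with pytest.raises(ValueError):
            world.step((15, 15), 0)

    def test_step_is_pure(self):
        world = open_room(-1.0)
        first = world.step((2, 2), 1)
        assert world.step((2, 2), 1) == first


class TestCandidateTargets:
    def test_open_surroundings(self):
        assert open_room().candidate_targets((10, 10)) == [
            (11, 10), (9, 10), (10, 9), (10, 11)]

    def test_four_targets_even_next_to_walls(self):
        targets = open_room().candidate_targets((2, 2))
        assert len(targets) == 4
        assert (1, 2) in targets  # impassable target still listed

    def test_fully_walled_pocket(self):
        passable = np.zeros((20, 20), dtype=bool)
        passable[1, 1] = True  # (2, 2) alone
        passable[1:19, 4:19] = True
        world = ov.GridWorld(passable, (10, 10), {(15, 15): 1.0},
                             validate=False)
        targets = world.candidate_targets((2, 2))
        assert all(not world.is_passable(*t) for t in targets)


class TestInvariants:
    def test_border_must_be_impassable(self):
        passable = np.ones((20, 20), dtype=bool)
        with pytest.raises(ValueError):
            ov.GridWorld(passable, (10, 10), {(15, 15): 1.0})

    def test_unreachable_goal_rejected(self):
        passable = np.zeros((20, 20), dtype=bool)
        passable[1:5, 1:5] = True
        passable[10:15, 10:15] = True  # disconnected pocket
        with pytest.raises(ValueError):
            ov.GridWorld(passable, (2, 2), {(12, 12): 1.0})

    def test_positive_wall_penalty_rejected(self):
        passable = np.zeros((20, 20), dtype=bool)
        passable[1:19, 1:19] = True
        with pytest.raises(ValueError):
            ov.GridWorld(passable, (10, 10), {(15, 15): 1.0}, wall_penalty=0.5)

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=200))
    def test_wall_hit_accounting_and_painless_reward(self, actions):
        """Along any trajectory, accumulated wall_hit flags equal the count
        of ineffective actions, and a completed painless episode's reward
        equals exactly the entered goal's reward."""
        world = open_room(0.0, goals={(15, 15): 2.0})
        s = world.start
        hits = stays = 0
        total = 0.0
        for a in actions:
            tr = world.step(s, a)
            hits += tr.wall_hit
            stays += tr.next_state == s
            total += tr.reward
            if tr.terminal:
                assert total == 2.0
                break
            s = tr.next_state
        assert hits == stays


class TestGenerator:
    def test_deterministic_under_fixed_seed(self):
        w1 = ov.generate_painful_maze(np.random.default_rng(7))
        w2 = ov.generate_painful_maze(np.random.default_rng(7))
        assert w1 == w2

    @pytest.mark.parametrize("seed", range(8))
    def test_structure_and_reachability(self, seed):
        world = ov.generate_painful_maze(np.random.default_rng(seed))
        assert sorted(world.goals.values()) == [1.0, 2.0]
        assert world.wall_penalty == -1.0
        # reachability re-checked by an independent flood fill
        frontier = [world.start]
        seen = {world.start}
        while frontier:
            x, y = frontier.pop()
            for dx, dy in ACTIONS:
                nxt = (x + dx, y + dy)
                if nxt not in seen and world.is_passable(*nxt):
                    seen.add(nxt)
                    if nxt not in world.goals:
                        frontier.append(nxt)
        assert all(g in seen for g in world.goals)

    def test_batch_rejects_symmetric_duplicates(self):
        worlds = ov.generate_painful_mazes(np.random.default_rng(3), 5)
        sigs = {_canonical_signature(w) for w in worlds}
        assert len(sigs) == 5

    def test_infeasible_params_raise(self):
        with pytest.raises(ValueError):
            ov.generate_painful_maze(np.random.default_rng(0), min_length=30)


class TestAsciiFormat:
    @pytest.mark.parametrize("maker", [ov.two_goal_corridor, ov.four_goal_arena])
    def test_round_trip(self, maker):
        world = maker()
        assert ov.load_maze(ov.save_maze(world)) == world

    def test_generated_maze_round_trip(self):
        world = ov.generate_painful_maze(np.random.default_rng(11))
        assert ov.load_maze(ov.save_maze(world)) == world

    def test_ragged_row_is_format_error(self):
        text = ov.save_maze(ov.two_goal_corridor())
        lines = text.splitlines()
        lines[3] = lines[3][:-1]
        with pytest.raises(MazeFormatError):
            ov.load_maze("\n".join(lines))

    def test_missing_start_is_format_error(self):
        text = ov.save_maze(ov.two_goal_corridor()).replace("S", ".")
        with pytest.raises(MazeFormatError, match="start"):
            ov.load_maze(text)

    def test_unknown_glyph_names_line_and_column(self):
        text = ov.save_maze(ov.two_goal_corridor())
        lines = text.splitlines()
        lines[10] = lines[10][:5] + "?" + lines[10][6:]
        with pytest.raises(MazeFormatError, match="line 11, column 6"):
            ov.load_maze("\n".join(lines))
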