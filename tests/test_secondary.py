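import numpy as np
import pytest

from nsalign.core import CoordinateChain, Residue
from nsalign import fixtures as fx
from nsalign.secondary import (
    PAIR_DIST_MAX,
    PAIR_DIST_MIN,
    assign_protein_ss,
    assign_rna_basepairs,
    ca_distance_profile,
    classify_profile,
)


def chain_from_points(points, names=None, mtype="protein", atom="CA"):
    names = names or ["ALA"] * len(points)
    residues = [
        Residue(index=i, name=names[i], author_id=str(i + 1), coords={atom: np.asarray(p, float)})
        for i, p in enumerate(points)
    ]
    return CoordinateChain(
        molecule_type=mtype,
        residues=residues,
        points=np.asarray(points, float),
        unit_labels=[f"{i + 1}:{names[i]}:{atom}" for i in range(len(points))],
        unit_names=list(names),
        unit_residue=list(range(len(points))),
    )


class TestProteinStates:
    def test_ideal_helix_interior_is_helix(self):
        chain = chain_from_points(fx.helix_points(12))
        states = assign_protein_ss(chain).states
        assert all(s == "H" for s in states[2:-2])
        assert states[0] == states[1] == states[-1] == states[-2] == "C"

    def test_ideal_strand_interior_is_strand(self):
        chain = chain_from_points(fx.strand_points(12))
        states = assign_protein_ss(chain).states
        assert all(s == "E" for s in states[2:-2])

    def test_straight_line_is_coil(self, line_chain):
        # d15 = 15.2: |15.2 - 13| = 2.2 >= 1.42 and d15 >= 8
        states = assign_protein_ss(line_chain).states
        assert all(s == "C" for s in states)

    def test_turn_profile(self):
        prof = {"d13": 9.0, "d14": 9.0, "d15": 7.0, "d24": 9.0, "d25": 9.0, "d35": 9.0}
        assert classify_profile(prof) == "T"

    def test_profile_distance_definitions(self):
        chain = chain_from_points(fx.helix_points(7))
        prof = ca_distance_profile(chain.points, 3)
        p = chain.points
        assert prof["d13"] == pytest.approx(np.linalg.norm(p[1] - p[3]))
        assert prof["d15"] == pytest.approx(np.linalg.norm(p[1] - p[5]))
        assert prof["d35"] == pytest.approx(np.linalg.norm(p[3] - p[5]))

    def test_helix_precedence_on_random_profiles(self):
        """Helix is tested before strand; any profile satisfying both
        threshold sets must come out helix."""
        rng = np.random.default_rng(0)
        keys = ["d13", "d14", "d15", "d24", "d25", "d35"]
        both = 0
        for _ in range(10000):
            prof = dict(zip(keys, rng.uniform(3.0, 16.0, 6)))
            helix_ok = max(
                abs(prof["d15"] - 6.37), abs(prof["d14"] - 5.18), abs(prof["d25"] - 5.18),
                abs(prof["d13"] - 5.45), abs(prof["d24"] - 5.45), abs(prof["d35"] - 5.45),
            ) < 2.1
            strand_ok = max(
                abs(prof["d15"] - 13.0), abs(prof["d14"] - 10.4), abs(prof["d25"] - 10.4),
                abs(prof["d13"] - 6.1), abs(prof["d24"] - 6.1), abs(prof["d35"] - 6.1),
            ) < 1.42
            if helix_ok and strand_ok:
                both += 1
                assert classify_profile(prof) == "H"
            elif helix_ok:
                assert classify_profile(prof) == "H"
            elif strand_ok:
                assert classify_profile(prof) == "E"

    def test_rigid_invariance(self, two_helix):
        moved, _ = fx.rigid_copy(two_helix, seed=4)
        assert assign_protein_ss(two_helix).states == assign_protein_ss(moved).states

    def test_elements_are_sse_runs(self, two_helix):
        ann = assign_protein_ss(two_helix)
        for start, end in ann.elements:
            run = set(ann.states[start:end])
            assert len(run) == 1 and run <= {"H", "E"}
            assert end - start >= 3

    def test_rejects_nucleic_chain(self):
        chain = chain_from_points(np.zeros((6, 3)) + np.arange(6)[:, None],
                                  names=["A"] * 6, mtype="rna", atom="C3'")
        with pytest.raises(ValueError):
            assign_protein_ss(chain)


def brute_force_pairs(points, names):
    """Naive restatement of the pairing rules, used as an oracle."""
    L = len(points)
    allowed = {("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")}

    def cand(i, j):
        if not (0 <= i < j < L):
            return False
        d = np.linalg.norm(points[i] - points[j])
        return PAIR_DIST_MIN <= d <= PAIR_DIST_MAX and (names[i], names[j]) in allowed

    out = set()
    for i in range(L):
        for j in range(i + 1, L):
            if cand(i, j) and (cand(i - 1, j + 1) or cand(i + 1, j - 1)):
                out.add((i, j))
    return out


class TestRnaPairing:
    def test_isolated_pair_is_excluded(self):
        # one A:U contact at 13 A with no stacked neighbour candidates
        pts = [[0, 0, 0], [100, 0, 0], [200, 0, 0], [200, 13, 0], [300, 0, 0], [0, 13, 0]]
        names = ["A", "C", "A", "U", "C", "U"]
        ann = assign_rna_basepairs(chain_from_points(pts, names, "rna", "C3'"))
        assert all(s == "." for s in ann.states)

    def test_non_complementary_pair_rejected(self):
        chain, _ = fx.make_chain(fx.FixtureSpec([("na_duplex", 6)], seed=0))
        names = ["A"] * chain.L  # same geometry, all-purine sequence
        bad = chain_from_points(chain.points, names, "rna", "C3'")
        ann = assign_rna_basepairs(bad)
        assert all(s == "." for s in ann.states)

    def test_duplex_interior_paired_with_correct_polarity(self):
        chain, truth = fx.make_chain(fx.FixtureSpec([("na_duplex", 8)], seed=1))
        ann = assign_rna_basepairs(chain)
        n = chain.L // 2
        # interior of the 5' strand pairs downstream, 3' strand upstream
        assert all(s == "(" for s in ann.states[1 : n - 1])
        assert all(s == ")" for s in ann.states[n + 1 : -1])

    def test_matches_brute_force_rules(self):
        chain, _ = fx.make_chain(fx.FixtureSpec([("na_duplex", 10)], noise_sigma=0.3, seed=5))
        ann = assign_rna_basepairs(chain)
        oracle = brute_force_pairs(chain.points, chain.unit_names)
        paired = {i for i, s in enumerate(ann.states) if s != "."}
        allowed_members = {i for p in oracle for i in p}
        assert paired <= allowed_members  # never pairs outside the rule set

    def test_up_down_counts_balance(self):
        chain, _ = fx.make_chain(fx.FixtureSpec([("na_duplex", 9)], noise_sigma=0.2, seed=2))
        states = assign_rna_basepairs(chain).states
        assert states.count("(") == states.count(")")

    def test_rigid_invariance(self):
        chain, _ = fx.make_chain(fx.FixtureSpec([("na_duplex", 7)], seed=3))
        moved, _ = fx.rigid_copy(chain, seed=8)
        assert assign_rna_basepairs(chain).states == assign_rna_basepairs(moved).states

    def test_rejects_protein_chain(self, two_helix):
        with pytest.raises(ValueError):
            assign_rna_basepairs(two_helix)
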