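import numpy as np
import pytest

from circsponge import mre
from circsponge.mre import MatureMiRNA, MRESite


def _random_rna(rng, n):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=n)])


def _rotation_oracle(seq, mirna):
    """Brute-force circular seed scan: linear scan of every rotation.

    Independent reimplementation: for each rotation, check each fully
    interior window against the seed rules, then map positions back.
    """
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    core = "".join(comp[b] for b in reversed(mirna.sequence[1:7]))
    m8 = comp[mirna.sequence[7]]
    L = len(seq)
    found = {}
    for r in range(L):
        rot = seq[r:] + seq[:r]
        for i in range(1, L - 6):       # need i-1 and i+6 interior
            if rot[i:i + 6] != core:
                continue
            has_m8 = rot[i - 1] == m8
            has_a1 = rot[i + 6] == "A"
            t = ("8mer" if has_m8 and has_a1 else
                 "7mer-m8" if has_m8 else "7mer-A1" if has_a1 else "6mer")
            found[(i + r) % L] = t
    return found


def _reference_sw(target, mirna):
    """Plain O(n*m) Smith-Waterman with the module's duplex scoring."""
    m = mirna.sequence[::-1]
    seed = {len(mirna.sequence) - 1 - i for i in range(1, 8)}
    best = 0.0
    n, k = len(target), len(m)
    H = [[0.0] * (k + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, k + 1):
            w = mre.SEED_WEIGHT if (j - 1) in seed else 1.0
            s = w * mre._pair_score(target[i - 1], m[j - 1])
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, H[i - 1][j] + mre.GAP, H[i][j - 1] + mre.GAP)
            best = max(best, H[i][j])
    return best


class TestSeedScan:
    def test_planted_8mer_found_at_position(self, rng):
        m = MatureMiRNA("m1", _random_rna(rng, 21))
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        site = "".join(comp[b] for b in reversed(m.sequence[1:8])) + "A"
        background = _random_rna(rng, 60).replace(site[1:7], "ACGUAC")
        seq = background[:30] + site + background[30:]
        hits = mre.scan_seed_sites("c", seq, m)
        assert any(s.start == 31 and s.site_type == "8mer" for s in hits)

    def test_junction_spanning_site_found_once(self):
        m = MatureMiRNA("m1", "UAGCUUAUCAGACUGAUGUUG")  # seed AGCUUAU
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        core = "".join(comp[b] for b in reversed(m.sequence[1:7]))  # 6 nt
        # split the core across the circular junction: 3 nt at the end, 3 at start
        filler = "CCCCCCCCCCCCCCCCCCCC"
        seq = core[3:] + "A" + filler + comp[m.sequence[7]] + core[:3]
        hits = mre.scan_seed_sites("c", seq, m)
        starts = [s.start for s in hits]
        assert starts.count(len(seq) - 3) == 1

    def test_scrambled_sequence_reports_nothing(self, rng):
        m = MatureMiRNA("m1", _random_rna(rng, 21))
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        core = "".join(comp[b] for b in reversed(m.sequence[1:7]))
        while True:
            seq = _random_rna(rng, 120)
            if core not in (seq + seq):
                break
        assert mre.scan_seed_sites("c", seq, m) == []

    @pytest.mark.parametrize("trial", range(10))
    def test_equals_rotation_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        seq = _random_rna(rng, int(rng.integers(40, 200)))
        m = MatureMiRNA("m", _random_rna(rng, 21))
        ours = {s.start: s.site_type for s in mre.scan_seed_sites("c", seq, m)}
        assert ours == _rotation_oracle(seq, m)

    def test_every_reported_site_passes_seed_check(self, pipeline_result):
        bundle = pipeline_result.bundle
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for circ_id, seq in bundle["circ_seqs"].items():
            rna = seq.replace("T", "U")
            for mid, ms in list(bundle["mirnas"].items())[:40]:
                m = MatureMiRNA(mid, ms)
                core = "".join(comp[b] for b in reversed(m.sequence[1:7]))
                for s in mre.scan_seed_sites(circ_id, rna, m):
                    window = (rna + rna)[s.start:s.start + 6]
                    assert window == core

    def test_alphabet_violation_raises(self):
        m = MatureMiRNA("m1", "ACGUACGUACGUACGUACGU")
        with pytest.raises(ValueError):
            mre.scan_seed_sites("c", "ACGTNNNNACGT", m)


class TestComplementarityAligner:
    def test_perfect_complement_hand_score(self, rng):
        m = MatureMiRNA("m1", _random_rna(rng, 21))
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        full = "".join(comp[b] for b in reversed(m.sequence))
        # flanks of the same repeated base cannot extend the alignment by pairing
        seq = "AAAA" + full + "AAAA" if m.sequence[0] != "U" else "CCCC" + full + "CCCC"
        hits = mre.align_complementarity("c", seq, m, score_threshold=50)
        # 21 Watson-Crick pairs at +5, positions 2-8 doubled: 5*21 + 5*7 = 140
        assert max(h.score for h in hits) >= 140.0

    def test_dp_matches_reference_smith_waterman(self):
        for trial in range(6):
            rng = np.random.default_rng(200 + trial)
            seq = _random_rna(rng, 60)
            m = MatureMiRNA("m", _random_rna(rng, 16))
            hits = mre.align_complementarity("c", seq, m, score_threshold=1.0)
            ours = max((h.score for h in hits), default=0.0)
            ref = _reference_sw(seq + seq, m)
            assert ours == pytest.approx(ref)

    def test_random_sequences_empty_at_stringent_threshold(self):
        rng = np.random.default_rng(3)
        fired = 0
        for _ in range(20):
            seq = _random_rna(rng, 300)
            m = MatureMiRNA("m", _random_rna(rng, 21))
            fired += bool(mre.align_complementarity("c", seq, m, score_threshold=120))
        assert fired == 0

    def test_nonpositive_threshold_rejected(self):
        m = MatureMiRNA("m", "ACGUACGUACGUACGUACGU")
        with pytest.raises(ValueError):
            mre.align_complementarity("c", "ACGU" * 10, m, score_threshold=0)


class TestIngest:
    def test_three_rows_tagged(self, tmp_path):
        p = tmp_path / "pita.tsv"
        p.write_text("c1\tm1\t10\t-12.5\nc1\tm2\t44\t-9.1\nc2\tm1\t3\t-20.0\n")
        sites = mre.ingest_predictor_output(p, "pita")
        assert len(sites) == 3
        assert {s.predictor for s in sites} == {"pita"}

    def test_unknown_mirna_rejected_with_row(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("c1\tmX\t10\t1.0\n")
        with pytest.raises(Exception, match="row 1"):
            mre.ingest_predictor_output(p, "pita", known_circ={"c1"}, known_mirna={"m1"})

    def test_duplicates_collapsed_with_warning(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("c1\tm1\t10\t1.0\nc1\tm1\t10\t1.0\n")
        with pytest.warns(UserWarning, match="duplicate"):
            sites = mre.ingest_predictor_output(p, "pita")
        assert len(sites) == 1

    def test_same_file_under_two_names_gives_two_votes(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("c1\tm1\t10\t1.0\n")
        lists = {
            "pita": mre.ingest_predictor_output(p, "pita"),
            "rnahybrid": mre.ingest_predictor_output(p, "rnahybrid"),
        }
        (target,) = mre.consensus_vote(lists, min_votes=2)
        assert target.votes == 2


class TestConsensus:
    def _site(self, circ, mirna, predictor):
        return MRESite(circ, mirna, 0, "6mer", predictor)

    def test_pair_in_two_predictors_kept(self):
        lists = {"A": [self._site("c", "m", "A")], "B": [self._site("c", "m", "B")]}
        (t,) = mre.consensus_vote(lists)
        assert (t.circ_id, t.mirna_id, t.votes) == ("c", "m", 2)

    def test_single_predictor_pair_dropped(self):
        lists = {"A": [self._site("c", "m", "A")], "B": []}
        assert mre.consensus_vote(lists) == []

    def test_min_votes_above_predictors_errors(self):
        with pytest.raises(ValueError):
            mre.consensus_vote({"A": []}, min_votes=2)

    def test_matches_set_intersection_oracle(self, rng):
        predictors = ["A", "B", "C", "D"]
        lists = {p: [] for p in predictors}
        pair_sets = {p: set() for p in predictors}
        for _ in range(100):
            p = predictors[rng.integers(0, 4)]
            pair = (f"c{rng.integers(0, 3)}", f"m{rng.integers(0, 12)}")
            lists[p].append(self._site(*pair, p))
            pair_sets[p].add(pair)
        for k in (2, 3, 4):
            expected = {
                pair
                for pair in set().union(*pair_sets.values())
                if sum(pair in s for s in pair_sets.values()) >= k
            }
            got = {(t.circ_id, t.mirna_id) for t in mre.consensus_vote(lists, k)}
            assert got == expected

    def test_vote_tiers_nest_monotonically(self, rng):
        predictors = ["A", "B", "C", "D"]
        lists = {p: [] for p in predictors}
        for _ in range(150):
            p = predictors[rng.integers(0, 4)]
            lists[p].append(self._site(f"c{rng.integers(0, 3)}", f"m{rng.integers(0, 15)}", p))
        tiers = {
            k: {(t.circ_id, t.mirna_id) for t in mre.consensus_vote(lists, k)}
            for k in (2, 3, 4)
        }
        assert tiers[4] <= tiers[3] <= tiers[2]


class TestNetwork:
    def test_edges_match_consensus(self, tmp_path):
        targets = [
            mre.ConsensusTarget("c1", "m1", 2, frozenset({"A", "B"})),
            mre.ConsensusTarget("c1", "m2", 3, frozenset({"A", "B", "C"})),
        ]
        df = mre.build_network(targets, tmp_path / "net.edgelist")
        assert len(df) == 2
        assert sorted(df["votes"]) == [2, 3]
        text = (tmp_path / "net.edgelist").read_text().splitlines()
        assert text[0].startswith("circ_id")

    def test_empty_consensus_writes_header_only(self, tmp_path):
        mre.build_network([], tmp_path / "net.edgelist")
        lines = (tmp_path / "net.edgelist").read_text().splitlines()
        assert len(lines) == 1
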