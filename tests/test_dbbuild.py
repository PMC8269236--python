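"""Seed/core/full database construction and deduplication."""

import numpy as np
import pytest

from cobpath.align import ScoringScheme, align_global
from cobpath.dbbuild import (
    BuildConfig,
    BuildError,
    attach_homolog_groups,
    build_seed,
    dedup_exact,
    merge_refseq_like,
    recruit_core,
)
from cobpath.model import HomologGroup, ReferenceDatabase, SequenceRecord
from cobpath.simulate import AA20, SimulationConfig, simulate_reference_set

SCHEME = ScoringScheme()


def _random_protein(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


def _mutant(rng, seq, n_subs):
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        alternatives = [a for a in AA20 if a != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


@pytest.fixture
def toy_seed(toy_registry):
    """Seeds for two homologous families derived from a common ancestor."""
    rng = np.random.default_rng(41)
    ancestor = _random_protein(rng, 150)
    records = []
    for fam, offset in (("cysG", 15), ("cobA", 30)):
        for j in range(3):
            seq = _mutant(rng, ancestor, offset + 3 * j)
            records.append(SequenceRecord(f"{fam}_s{j}", seq, ("target", fam)))
    return build_seed(records, toy_registry), ancestor, rng


class TestBuildSeed:
    def test_counts_per_family(self, toy_registry):
        rng = np.random.default_rng(1)
        records = [
            SequenceRecord(f"s{i}", _random_protein(rng, 50), ("target", fam))
            for i, fam in enumerate(["cysG"] * 5 + ["cobA"] * 3)
        ]
        db = build_seed(records, toy_registry)
        assert db.tier == "seed"
        assert {f: len(v) for f, v in db.targets.items()} == {"cysG": 5, "cobA": 3}

    def test_unknown_family_rejected(self, toy_registry):
        rec = SequenceRecord("s1", "MKVLH", ("target", "nosuch"))
        with pytest.raises(BuildError, match="nosuch"):
            build_seed([rec], toy_registry)

    def test_simulated_families_all_registered(self, small_sim):
        config, db, _ = small_sim
        assert len(db.targets) == config.n_families


class TestRecruitCore:
    def test_high_identity_candidate_recruited(self, toy_seed, toy_registry):
        seed_db, _, rng = toy_seed
        source = seed_db.targets["cobA"][0]
        cand = SequenceRecord(
            "c1", _mutant(rng, source.residues, 7), ("target", "cobA")
        )
        core, report = recruit_core([cand], seed_db, toy_registry)
        row = report.iloc[0]
        assert row.decision == "recruited" and row.family == "cobA"
        assert row.identity > 0.9
        assert "c1" in core.target_ids()

    def test_low_identity_candidate_rejected(self, toy_seed, toy_registry):
        seed_db, _, _ = toy_seed
        rng = np.random.default_rng(77)
        cand = SequenceRecord("c1", _random_protein(rng, 150), ("target", "cobA"))
        core, report = recruit_core([cand], seed_db, toy_registry)
        row = report.iloc[0]
        assert row.decision == "rejected"
        assert "below 0.30" in row.reason
        assert "c1" not in core.target_ids()

    def test_unknown_nominal_family_is_an_error(self, toy_seed, toy_registry):
        seed_db, _, _ = toy_seed
        cand = SequenceRecord("c1", "MKVLH", ("target", "nosuch"))
        with pytest.raises(BuildError, match="nosuch"):
            recruit_core([cand], seed_db, toy_registry)

    def test_report_partitions_candidates(self, toy_seed, toy_registry):
        seed_db, ancestor, rng = toy_seed
        candidates = []
        for i in range(8):
            if i % 2:
                seq = _mutant(rng, ancestor, 20)
            else:
                seq = _random_protein(rng, 150)
            candidates.append(SequenceRecord(f"c{i}", seq, ("target", "cysG")))
        core, report = recruit_core(candidates, seed_db, toy_registry)
        assert len(report) == 8
        n_rec = (report.decision == "recruited").sum()
        n_rej = (report.decision == "rejected").sum()
        assert n_rec + n_rej == 8
        assert core.n_targets == seed_db.n_targets + n_rec

    def test_assignment_matches_argmax_with_majority_oracle(self, toy_seed, toy_registry):
        """Homologous-family mixtures recruit to the family of the best seed,
        exactly as an exhaustive per-seed argmax predicts."""
        seed_db, ancestor, rng = toy_seed
        candidates = []
        for i in range(10):
            fam = "cysG" if i % 2 else "cobA"
            source = seed_db.targets[fam][int(rng.integers(3))]
            candidates.append(
                SequenceRecord(f"c{i}", _mutant(rng, source.residues, 6), ("target", fam))
            )
        core, report = recruit_core(candidates, seed_db, toy_registry)
        pool = [s for fam in ("cobA", "cysG") for s in seed_db.targets[fam]]
        for cand in candidates:
            scored = sorted(
                (
                    (-align_global(cand.residues, s.residues, SCHEME).score, s.seq_id, s.family_id)
                    for s in pool
                ),
            )
            top_score = scored[0][0]
            tied = [t for t in scored if t[0] == top_score]
            votes = {}
            for _, _, fam in tied:
                votes[fam] = votes.get(fam, 0) + 1
            expected = min(votes, key=lambda f: (-votes[f], f))
            got = report.set_index("candidate_id").loc[cand.seq_id]
            assert got.decision == "recruited"
            assert got.family == expected

    def test_tier_monotonicity(self, toy_seed, toy_registry):
        seed_db, ancestor, rng = toy_seed
        cand = SequenceRecord("c1", _mutant(rng, ancestor, 15), ("target", "cysG"))
        core, _ = recruit_core([cand], seed_db, toy_registry)
        assert seed_db.target_ids() <= core.target_ids()


class TestAttachHomologGroups:
    @pytest.fixture
    def core_db(self, toy_registry):
        rng = np.random.default_rng(53)
        ancestor = _random_protein(rng, 150)
        records = [
            SequenceRecord(f"cobB_s{j}", _mutant(rng, ancestor, 8 + j), ("target", "cysG"))
            for j in range(4)
        ]
        db = build_seed(records, toy_registry).copy(tier="core")
        return db, ancestor, rng

    def _group(self, name, rng, ancestor, n_hitting, n_total=5):
        """A group with exactly n_hitting members similar to the core family."""
        seqs = {}
        members = []
        for j in range(n_total):
            sid = f"{name}_m{j}"
            if j < n_hitting:
                seqs[sid] = _mutant(rng, ancestor, 60)  # ~60% identity: hits
            else:
                seqs[sid] = _random_protein(rng, 150)   # unrelated: no hit
            members.append(sid)
        return HomologGroup(name, "eggNOG", tuple(members)), seqs

    def test_planted_hit_fractions_drive_decisions(self, core_db):
        db, ancestor, rng = core_db
        groups, seqs = [], {}
        for name, n_hit in (("g0", 0), ("g20", 1), ("g60", 3), ("g100", 5)):
            g, s = self._group(name, rng, ancestor, n_hit)
            groups.append(g)
            seqs.update(s)
        full, report = attach_homolog_groups(db, groups, seqs, None)
        decisions = report.set_index("group_id")["decision"].to_dict()
        assert decisions == {
            "g0": "dropped",
            "g20": "decoy",
            "g60": "merged",
            "g100": "merged",
        }
        assert full.tier == "full"
        assert set(full.decoys) == {"g20"}
        # merged members landed in the target family
        assert any(r.seq_id == "g60_m0" for r in full.targets["cysG"])

    def test_unresolvable_member_is_an_error(self, core_db):
        db, _, _ = core_db
        group = HomologGroup("gx", "COG", ("missing1",))
        with pytest.raises(BuildError, match="missing1"):
            attach_homolog_groups(db, [group], {}, None)


class TestMergeRefseqLike:
    @pytest.fixture
    def full_db(self, small_sim):
        _, db, _ = small_sim
        return db

    def test_routing_by_best_hit_label(self, full_db):
        rng = np.random.default_rng(67)
        target_src = full_db.targets[sorted(full_db.targets)[0]][0]
        decoy_src = full_db.decoys[sorted(full_db.decoys)[0]][0]
        lineage = ("Bacteria", "Firmicutes", "c", "o", "f", "g", "s")
        proteins = [
            SequenceRecord("gp_t", _mutant(rng, target_src.residues, 3),
                           ("unrelated", None), taxonomy=lineage),
            SequenceRecord("gp_d", _mutant(rng, decoy_src.residues, 3),
                           ("unrelated", None), taxonomy=lineage),
            SequenceRecord("gp_n", _random_protein(rng, 140), ("unrelated", None)),
        ]
        merged, report = merge_refseq_like(full_db, proteins)
        routes = report.set_index("seq_id")["route"].to_dict()
        assert routes == {"gp_t": "target", "gp_d": "decoy", "gp_n": "discarded"}
        assert merged.get("gp_t").family_id == target_src.family_id
        assert merged.get("gp_t").taxonomy == lineage
        assert merged.get("gp_d").group_id == decoy_src.group_id
        with pytest.raises(KeyError):
            merged.get("gp_n")


class TestDedupExact:
    def _db_with(self, seqs_by_family):
        db = ReferenceDatabase("full")
        i = 0
        for fam, seqs in seqs_by_family.items():
            for seq in seqs:
                db.add(SequenceRecord(f"s{i}", seq, ("target", fam)))
                i += 1
        return db

    def test_identical_pair_collapsed_with_log(self):
        db = self._db_with({"cobA": ["MKVLH", "MKVLH"]})
        deduped, report = dedup_exact(db)
        assert deduped.n_targets == 1
        rep = deduped.targets["cobA"][0]
        assert rep.seq_id == "s0" and rep.duplicate_ids == ("s1",)
        assert (report.kind == "within").sum() == 1

    def test_all_unique_unchanged(self):
        db = self._db_with({"cobA": ["MKVLH", "MKVLW"], "cysG": ["AAAA"]})
        deduped, report = dedup_exact(db)
        assert deduped.n_targets == 3
        assert (report.kind == "within").sum() == 0

    def test_kfold_duplicates_reduce_by_k_minus_one(self):
        rng = np.random.default_rng(3)
        folds = {"cobA": 3, "cysG": 5, "hemB": 1}
        seqs = {
            fam: [_random_protein(rng, 30)] * k for fam, k in folds.items()
        }
        db = self._db_with(seqs)
        deduped, _ = dedup_exact(db)
        expected_removed = sum(k - 1 for k in folds.values())
        assert db.n_targets - deduped.n_targets == expected_removed

    def test_idempotent(self):
        db = self._db_with({"cobA": ["MKVLH", "MKVLH", "WWWW"]})
        once, _ = dedup_exact(db)
        twice, report2 = dedup_exact(once)
        assert {r.seq_id for r in twice.records()} == {r.seq_id for r in once.records()}
        assert (report2.kind == "within").sum() == 0

    def test_cross_family_identical_flagged_not_collapsed(self):
        db = self._db_with({"cobA": ["MKVLH"], "cysG": ["MKVLH"]})
        deduped, report = dedup_exact(db)
        assert deduped.n_targets == 2
        assert (report.kind == "cross_bucket_flag").sum() == 1


def test_full_pipeline_separable_simulation_recovers_all_labels(toy_registry):
    """Recruitment recovers every true family label when member and decoy
    identity tiers are well separated."""
    rng = np.random.default_rng(97)
    ancestors = {
        "cysG": _random_protein(rng, 140),
        "cobA": _random_protein(rng, 140),
    }
    seeds = []
    for fam, anc in ancestors.items():
        for j in range(2):
            seeds.append(SequenceRecord(f"{fam}_s{j}", _mutant(rng, anc, 7), ("target", fam)))
    seed_db = build_seed(seeds, toy_registry)
    candidates, truth = [], {}
    for i in range(20):
        fam = "cysG" if i % 2 else "cobA"
        candidates.append(
            SequenceRecord(f"c{i}", _mutant(rng, ancestors[fam], 10), ("target", fam))
        )
        truth[f"c{i}"] = fam
    core, report = recruit_core(candidates, seed_db, toy_registry)
    recruited = report[report.decision == "recruited"].set_index("candidate_id")
    assert len(recruited) == 20
    for cid, fam in truth.items():
        assert recruited.loc[cid, "family"] == fam
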