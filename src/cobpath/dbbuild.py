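"""Tiered reference-database construction.

Stages mirror the curated-database workflow: a manually verified seed tier;
a core tier recruited from less-trusted candidate sequences by global best-hit
against pooled seeds at a 30% identity floor; and a full tier that merges
orthology-group members (into target families or homolog-decoy groups by a
majority rule) and routes genome proteins by best hit, followed by exact
100%-identity deduplication.

The homolog-decoy groups are the remedy for the "small database issue": reads
genuinely derived from homologs of the target families would otherwise have no
better place to land than the targets themselves and would inflate false
positives.  Group-level decisions that a curator would make by inspection are
automated here by an auditable majority-fraction rule, with every decision and
its evidence logged in the returned reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import ScoringScheme, SearchConfig, best_hit
from .model import (
    FamilyRegistry,
    HomologGroup,
    ReferenceDatabase,
    SequenceRecord,
)


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class BuildConfig:
    min_global_identity: float = 0.30
    decoy_majority_fraction: float = 0.50
    min_members_hitting: int = 1
    tie_tolerance: float = 0.0  # score units within which hits count as tied

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_global_identity <= 1.0:
            raise ValueError("min_global_identity must lie in [0, 1]")
        if not 0.0 <= self.decoy_majority_fraction <= 1.0:
            raise ValueError("decoy_majority_fraction must lie in [0, 1]")


def build_seed(
    curated: Iterable[SequenceRecord], registry: FamilyRegistry
) -> ReferenceDatabase:
    """Store curated, family-labelled sequences as the seed tier."""
    db = ReferenceDatabase("seed")
    for rec in curated:
        if rec.kind != "target":
            raise BuildError(f"seed record {rec.seq_id!r} is not family-labelled")
        if rec.family_id not in registry.families:
            raise BuildError(
                f"seed record {rec.seq_id!r} names unknown family {rec.family_id!r}"
            )
        db.add(rec)
    return db


def _seed_pool(
    seed_db: ReferenceDatabase, registry: FamilyRegistry, family_id: str
) -> list[SequenceRecord]:
    pool: list[SequenceRecord] = []
    for fid in sorted(registry.homolog_pool(family_id)):
        pool.extend(seed_db.targets.get(fid, []))
    return pool


def recruit_core(
    candidates: Iterable[SequenceRecord],
    seed_db: ReferenceDatabase,
    registry: FamilyRegistry,
    config: BuildConfig = BuildConfig(),
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Recruit candidate sequences into the core tier by global best hit.

    Each candidate is aligned globally against the pooled seeds of its nominal
    family and all declared homolog families, and recruited to the best-hit
    seed's family when identity reaches the floor.  When the top score is tied
    across seeds of different families, the candidate goes to the family
    holding the majority of the tied seeds (final ties to the
    lexicographically smallest family id).  Failing candidates are reported as
    rejected with a reason; recruited + rejected partition the input exactly.
    """
    if seed_db.n_targets == 0:
        raise BuildError("seed database is empty")
    core = seed_db.copy(tier="core")
    rows = []
    for cand in candidates:
        if cand.kind != "target":
            raise BuildError(f"candidate {cand.seq_id!r} has no nominal family")
        if cand.family_id not in registry.families:
            raise BuildError(
                f"candidate {cand.seq_id!r} names unknown family {cand.family_id!r}"
            )
        pool = _seed_pool(seed_db, registry, cand.family_id)
        if not pool:
            rows.append(
                dict(
                    candidate_id=cand.seq_id,
                    nominal_family=cand.family_id,
                    decision="rejected",
                    family="",
                    identity=float("nan"),
                    reason="no seeds for family pool",
                )
            )
            continue
        from .align import _aligner, _from_biopython

        al = _aligner(scheme, "global")
        scored = []
        for seed in pool:
            s = float(al.score(cand.residues, seed.residues))
            scored.append((s, seed))
        top = max(s for s, _ in scored)
        tied = [seed for s, seed in scored if top - s <= config.tie_tolerance]
        # majority rule over families of the tied seeds
        fam_votes: dict[str, int] = {}
        for seed in tied:
            fam_votes[seed.family_id] = fam_votes.get(seed.family_id, 0) + 1
        winner = min(fam_votes, key=lambda f: (-fam_votes[f], f))
        best_seed = min(
            (s for s in tied if s.family_id == winner), key=lambda s: s.seq_id
        )
        aln = _from_biopython(
            al.align(cand.residues, best_seed.residues), cand.residues, "global"
        )
        if aln.identity >= config.min_global_identity:
            core.add(
                SequenceRecord(
                    seq_id=cand.seq_id,
                    residues=cand.residues,
                    label=("target", winner),
                    taxonomy=cand.taxonomy,
                    tier="core",
                )
            )
            rows.append(
                dict(
                    candidate_id=cand.seq_id,
                    nominal_family=cand.family_id,
                    decision="recruited",
                    family=winner,
                    identity=aln.identity,
                    reason="",
                )
            )
        else:
            rows.append(
                dict(
                    candidate_id=cand.seq_id,
                    nominal_family=cand.family_id,
                    decision="rejected",
                    family="",
                    identity=aln.identity,
                    reason=f"best identity {aln.identity:.3f} below "
                    f"{config.min_global_identity:.2f}",
                )
            )
    report = pd.DataFrame(
        rows,
        columns=[
            "candidate_id",
            "nominal_family",
            "decision",
            "family",
            "identity",
            "reason",
        ],
    )
    return core, report


def attach_homolog_groups(
    core_db: ReferenceDatabase,
    groups: Sequence[HomologGroup],
    sequences: Mapping[str, str],
    registry: FamilyRegistry,
    config: BuildConfig = BuildConfig(),
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Classify orthology groups against core targets and attach them.

    Per group, every member is best-hit searched (globally) against the core
    targets.  A group whose members majority-hit a single family at the
    identity floor is merged into that family; a group with at least
    ``min_members_hitting`` members hitting any target becomes a homolog-decoy
    group; anything else is dropped.  The report carries the per-group decision
    with its evidence so a curator can audit the calls.
    """
    full = core_db.copy(tier="full")
    core_targets = core_db.without_decoys("core")
    search = SearchConfig(mode="global", min_identity=config.min_global_identity)
    rows = []
    for group in groups:
        members = [
            (sid, sequences[sid]) for sid in group.member_seq_ids if sid in sequences
        ]
        missing = [sid for sid in group.member_seq_ids if sid not in sequences]
        if missing:
            raise BuildError(
                f"group {group.group_id!r}: unresolvable members {missing}"
            )
        if not members:
            rows.append(
                dict(
                    group_id=group.group_id,
                    source_db=group.source_db,
                    n_members=0,
                    n_hitting=0,
                    top_family="",
                    top_fraction=0.0,
                    decision="dropped",
                )
            )
            continue
        fam_hits: dict[str, int] = {}
        n_hitting = 0
        per_member_family: dict[str, Optional[str]] = {}
        for sid, seq in members:
            hit = best_hit(seq, core_targets, search, scheme, query_id=sid)
            if hit is not None:
                n_hitting += 1
                fam = hit.ref_label[1]
                fam_hits[fam] = fam_hits.get(fam, 0) + 1
                per_member_family[sid] = fam
            else:
                per_member_family[sid] = None
        if fam_hits:
            top_family = min(fam_hits, key=lambda f: (-fam_hits[f], f))
            top_fraction = fam_hits[top_family] / len(members)
        else:
            top_family, top_fraction = "", 0.0
        if top_family and top_fraction >= config.decoy_majority_fraction:
            decision = "merged"
            for sid, seq in members:
                full.add(
                    SequenceRecord(
                        seq_id=sid, residues=seq, label=("target", top_family)
                    )
                )
        elif n_hitting >= config.min_members_hitting:
            decision = "decoy"
            for sid, seq in members:
                full.add(
                    SequenceRecord(
                        seq_id=sid, residues=seq, label=("decoy", group.group_id)
                    )
                )
        else:
            decision = "dropped"
        rows.append(
            dict(
                group_id=group.group_id,
                source_db=group.source_db,
                n_members=len(members),
                n_hitting=n_hitting,
                top_family=top_family,
                top_fraction=top_fraction,
                decision=decision,
            )
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "source_db",
            "n_members",
            "n_hitting",
            "top_family",
            "top_fraction",
            "decision",
        ],
    )
    return full, report


def merge_refseq_like(
    full_db: ReferenceDatabase,
    genome_proteins: Iterable[SequenceRecord],
    config: BuildConfig = BuildConfig(),
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Route genome proteins into the full database by best hit.

    A protein whose best hit is a target joins that family; one whose best hit
    is a decoy joins that decoy group (carrying its taxonomy either way); one
    with no passing hit is discarded.
    """
    out = full_db.copy()
    search = SearchConfig(mode="global", min_identity=config.min_global_identity)
    rows = []
    for prot in genome_proteins:
        hit = best_hit(prot.residues, full_db, search, scheme, query_id=prot.seq_id)
        if hit is None:
            rows.append(
                dict(seq_id=prot.seq_id, route="discarded", destination="", identity=float("nan"))
            )
            continue
        kind, key = hit.ref_label
        out.add(
            SequenceRecord(
                seq_id=prot.seq_id,
                residues=prot.residues,
                label=(kind, key),
                taxonomy=prot.taxonomy,
            )
        )
        rows.append(
            dict(
                seq_id=prot.seq_id,
                route="target" if kind == "target" else "decoy",
                destination=key,
                identity=hit.identity,
            )
        )
    report = pd.DataFrame(rows, columns=["seq_id", "route", "destination", "identity"])
    return out, report


def dedup_exact(db: ReferenceDatabase) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Collapse byte-identical residue strings within each family/group.

    The earliest-inserted record becomes the representative and accumulates
    the duplicate ids; the operation is idempotent.  Identical sequences in
    *different* families or groups are deliberately not collapsed — that would
    silently delete a family's only evidence — but they are flagged in the
    report for curation.
    """
    out = ReferenceDatabase(db.tier)
    rows = []
    seen_across: dict[str, list[str]] = {}
    for key, records in list(db.targets.items()) + list(db.decoys.items()):
        by_seq: dict[str, SequenceRecord] = {}
        for rec in records:
            if rec.residues in by_seq:
                rep = by_seq[rec.residues]
                by_seq[rec.residues] = SequenceRecord(
                    seq_id=rep.seq_id,
                    residues=rep.residues,
                    label=rep.label,
                    taxonomy=rep.taxonomy,
                    tier=rep.tier,
                    duplicate_ids=rep.duplicate_ids + (rec.seq_id,) + rec.duplicate_ids,
                )
                rows.append(
                    dict(
                        representative=rep.seq_id,
                        duplicate=rec.seq_id,
                        bucket=key,
                        kind="within",
                    )
                )
            else:
                by_seq[rec.residues] = rec
        for seq, rec in by_seq.items():
            out.add(rec)
            seen_across.setdefault(seq, []).append(key)
    for seq, buckets in seen_across.items():
        if len(buckets) > 1:
            rows.append(
                dict(
                    representative="",
                    duplicate="",
                    bucket=";".join(sorted(buckets)),
                    kind="cross_bucket_flag",
                )
            )
    report = pd.DataFrame(rows, columns=["representative", "duplicate", "bucket", "kind"])
    return out, report
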