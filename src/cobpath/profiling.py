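"""Homolog-aware read assignment and profile generation.

Every read receives exactly one of three fates: ``assigned`` (best hit is a
target-family sequence), ``homolog_absorbed`` (best hit is a homolog-decoy
sequence — the read is similar to the targets but more similar to a known
homolog, so counting it would be a false positive), or ``unassigned``.  The
three statuses always partition the input read set.

Functional profiles count assigned reads per family; relative abundance is
normalised by the number of assigned reads (an optional gene-length
normalisation is available but off by default, and the choice is recorded in
the profile metadata).  Taxonomic profiles default to best-hit transfer — each
assigned read inherits the lineage of its best-hit reference — with an adapter
slot for an external classifier.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import (
    Hit,
    ScoringScheme,
    SearchConfig,
    best_hit,
    looks_nucleotide,
)
from .model import (
    TAXONOMIC_RANKS,
    FamilyRegistry,
    ReferenceDatabase,
)
from . import model


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str  # {assigned, homolog_absorbed, unassigned}
    family_id: Optional[str] = None
    ref_id: Optional[str] = None
    score: Optional[float] = None
    identity: Optional[float] = None
    frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.status not in ("assigned", "homolog_absorbed", "unassigned"):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.family_id is not None) != (self.status == "assigned"):
            raise ValueError("family_id must be present iff status is 'assigned'")


def _assign_one(
    read_id: str,
    seq: str,
    db: ReferenceDatabase,
    config: SearchConfig,
    scheme: ScoringScheme,
) -> ReadAssignment:
    cfg = config
    if looks_nucleotide(seq) and config.mode != "translated_local":
        cfg = SearchConfig(
            mode="translated_local",
            min_identity=config.min_identity,
            min_score=config.min_score,
            evalue_threshold=config.evalue_threshold,
        )
    hit = best_hit(seq, db, cfg, scheme, query_id=read_id)
    if hit is None:
        return ReadAssignment(read_id=read_id, status="unassigned")
    kind, key = hit.ref_label
    if kind == "target":
        return ReadAssignment(
            read_id=read_id,
            status="assigned",
            family_id=key,
            ref_id=hit.ref_id,
            score=hit.score,
            identity=hit.identity,
            frame=hit.frame,
        )
    return ReadAssignment(
        read_id=read_id,
        status="homolog_absorbed",
        ref_id=hit.ref_id,
        score=hit.score,
        identity=hit.identity,
        frame=hit.frame,
    )


def _assign_chunk(args) -> list[ReadAssignment]:
    reads, db, config, scheme = args
    return [_assign_one(rid, seq, db, config, scheme) for rid, seq in reads]


def assign_reads(
    reads: Sequence[tuple[str, str]],
    db: ReferenceDatabase,
    config: SearchConfig = SearchConfig(),
    scheme: ScoringScheme = ScoringScheme(),
    threads: int = 1,
) -> list[ReadAssignment]:
    """Best-hit assignment of reads against a reference database.

    Nucleotide reads (detected by alphabet) are translated in six frames and
    the best frame's best hit is used.  Results are deterministic given the
    configuration and independent of thread count and database record order.
    """
    if not reads:
        return []
    if threads <= 1 or len(reads) < 4 * threads:
        return [_assign_one(rid, seq, db, config, scheme) for rid, seq in reads]
    chunk = (len(reads) + threads - 1) // threads
    chunks = [reads[i : i + chunk] for i in range(0, len(reads), chunk)]
    with ProcessPoolExecutor(max_workers=threads) as pool:
        parts = pool.map(_assign_chunk, [(c, db, config, scheme) for c in chunks])
        return [a for part in parts for a in part]


@dataclass
class FunctionalProfile:
    sample_id: str
    family_counts: dict[str, int]
    n_reads: int
    n_assigned: int
    n_absorbed: int
    n_unassigned: int
    relative_abundance: dict[str, float]
    pathway_counts_replicate: dict[str, float]
    pathway_counts_fractional: dict[str, float]
    normalization: str = "assigned_reads"
    zero_assigned: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                family_id=fid,
                count=self.family_counts[fid],
                rel_abundance=self.relative_abundance[fid],
            )
            for fid in sorted(self.family_counts)
        ]
        return pd.DataFrame(rows, columns=["family_id", "count", "rel_abundance"])

    def pathway_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                pathway_id=pid,
                count_replicate=self.pathway_counts_replicate.get(pid, 0.0),
                count_fractional=self.pathway_counts_fractional.get(pid, 0.0),
            )
            for pid in sorted(self.pathway_counts_replicate)
        ]
        return pd.DataFrame(
            rows, columns=["pathway_id", "count_replicate", "count_fractional"]
        )


def functional_profile(
    assignments: Sequence[ReadAssignment],
    registry: FamilyRegistry,
    sample_id: str = "sample",
    gene_lengths: Optional[Mapping[str, float]] = None,
) -> FunctionalProfile:
    """Per-family counts and relative abundances for one sample.

    Relative abundance divides by the number of assigned reads; with zero
    assigned reads all abundances are reported as zero and flagged.  Pathway
    rollups are emitted in both share modes (see rollup_counts_by_pathway).
    """
    counts: dict[str, int] = {}
    n_assigned = n_absorbed = n_unassigned = 0
    for a in assignments:
        if a.status == "assigned":
            n_assigned += 1
            counts[a.family_id] = counts.get(a.family_id, 0) + 1
        elif a.status == "homolog_absorbed":
            n_absorbed += 1
        else:
            n_unassigned += 1
    weighted: dict[str, float] = dict(counts)
    if gene_lengths is not None:
        weighted = {f: c / gene_lengths[f] for f, c in counts.items()}
    total = sum(weighted.values())
    zero = total == 0
    rel = {f: (0.0 if zero else w / total) for f, w in weighted.items()}
    return FunctionalProfile(
        sample_id=sample_id,
        family_counts=counts,
        n_reads=len(assignments),
        n_assigned=n_assigned,
        n_absorbed=n_absorbed,
        n_unassigned=n_unassigned,
        relative_abundance=rel,
        pathway_counts_replicate=model.rollup_counts_by_pathway(
            registry, counts, "replicate"
        ),
        pathway_counts_fractional=model.rollup_counts_by_pathway(
            registry, counts, "fractional"
        ),
        normalization="per_gene_length" if gene_lengths is not None else "assigned_reads",
        zero_assigned=zero,
    )


def extract_assigned_reads(
    assignments: Sequence[ReadAssignment],
    reads: Sequence[tuple[str, str]],
) -> list[tuple[str, str]]:
    """The reads with status 'assigned', original residues, input order."""
    by_id = dict(reads)
    assigned = {a.read_id for a in assignments if a.status == "assigned"}
    missing = sorted(
        a.read_id for a in assignments if a.status == "assigned" and a.read_id not in by_id
    )
    if missing:
        raise KeyError(f"assigned read ids missing from the read set: {missing}")
    return [(rid, seq) for rid, seq in reads if rid in assigned]


@dataclass
class TaxonomicProfile:
    sample_id: str
    rank: str
    taxon_counts: dict[str, int]
    relative_abundance: dict[str, float]
    n_classified: int
    n_unclassified: int
    provenance: str = "besthit_transfer"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                taxon=t,
                count=self.taxon_counts[t],
                rel_abundance=self.relative_abundance[t],
            )
            for t in sorted(self.taxon_counts)
        ]
        return pd.DataFrame(rows, columns=["taxon", "count", "rel_abundance"])


def taxonomic_profile(
    assignments: Sequence[ReadAssignment],
    db: ReferenceDatabase,
    rank: str = "phylum",
    classifier: str | Callable[[str], Optional[str]] = "besthit_transfer",
    sample_id: str = "sample",
) -> TaxonomicProfile:
    """Taxon counts at a rank for the assigned reads.

    The default classifier transfers the lineage of each assigned read's
    best-hit reference; references lacking a lineage at the requested rank
    count as unclassified.  A callable classifier (read_id -> taxon or None)
    can replace the transfer, e.g. to adapt an external k-mer classifier.
    """
    if rank not in TAXONOMIC_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {TAXONOMIC_RANKS}")
    rank_idx = TAXONOMIC_RANKS.index(rank)
    lineages = {rec.seq_id: rec.taxonomy for rec in db.records()}
    counts: dict[str, int] = {}
    n_unclassified = 0
    for a in assignments:
        if a.status != "assigned":
            continue
        if callable(classifier):
            taxon = classifier(a.read_id)
        else:
            lineage = lineages.get(a.ref_id)
            taxon = lineage[rank_idx] if lineage and lineage[rank_idx] else None
        if taxon is None:
            n_unclassified += 1
        else:
            counts[taxon] = counts.get(taxon, 0) + 1
    n_classified = sum(counts.values())
    rel = {t: c / n_classified for t, c in counts.items()} if n_classified else {}
    return TaxonomicProfile(
        sample_id=sample_id,
        rank=rank,
        taxon_counts=counts,
        relative_abundance=rel,
        n_classified=n_classified,
        n_unclassified=n_unclassified,
        provenance="external" if callable(classifier) else "besthit_transfer",
    )


def assignments_frame(assignments: Sequence[ReadAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                read_id=a.read_id,
                status=a.status,
                family_id=a.family_id or "",
                ref_id=a.ref_id or "",
                score=a.score,
                identity=a.identity,
                frame=a.frame,
            )
            for a in assignments
        ],
        columns=["read_id", "status", "family_id", "ref_id", "score", "identity", "frame"],
    )


def wide_matrix(profiles: Sequence[FunctionalProfile]) -> pd.DataFrame:
    """Families x samples matrix of relative abundances."""
    data = {p.sample_id: p.relative_abundance for p in profiles}
    return pd.DataFrame(data).fillna(0.0).sort_index()
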