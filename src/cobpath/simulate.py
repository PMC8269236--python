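"""Seeded synthetic data: reference families, homolog decoys, evaluation sets,
and fragmented metagenomic reads with ground-truth provenance.

The generator plants a random ancestor protein per family and derives family
members by point substitution to a sampled target identity (0.90-0.99 by
default).  Homolog-decoy groups are derived from the *same* ancestors at a
lower identity (0.40-0.60 by default): they genuinely attract hits from
homolog-derived reads, which reproduces the mechanism behind the small
database issue, while remaining clearly separated from the members' identity
tier.  Unrelated sequences are i.i.d. draws from the residue background.
Substitution-only mutation keeps identity exactly controllable and makes
ground-truth audits alignment-free; an indel mode exists but is off by
default.

Everything is driven by one integer seed; outputs are byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ReferenceDatabase, SequenceRecord, TAXONOMIC_RANKS

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_PHYLA = (
    "Proteobacteria",
    "Firmicutes",
    "Bacteroidetes",
    "Actinobacteria",
    "Cyanobacteria",
)

# default evaluation-set composition: target-derived / homolog-derived /
# unrelated full-length query proteins
EVAL_SET_COUNTS = (143, 57, 70)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_families: int = 10
    members_per_family: int = 8
    length_range: tuple[int, int] = (180, 240)
    member_identity: tuple[float, float] = (0.90, 0.99)
    decoy_identity: tuple[float, float] = (0.40, 0.60)
    n_decoy_groups: int = 10
    decoy_members_per_group: int = 3
    n_unrelated: int = 20
    background: Optional[Sequence[float]] = None  # over AA20; uniform if None
    read_length_range: tuple[int, int] = (40, 80)
    reads_per_sample: int = 5000
    proportions: Optional[Mapping[str, float]] = None
    indel_rate: float = 0.0  # substitution-only by default

    def __post_init__(self) -> None:
        for lo, hi in (self.member_identity, self.decoy_identity):
            if not (0.0 < lo <= hi <= 1.0):
                raise SimulationError("identity ranges must lie in (0, 1]")
        if self.member_identity[0] <= self.decoy_identity[1]:
            import warnings

            warnings.warn(
                "member and decoy identity ranges overlap; hit separability "
                "is not guaranteed",
                stacklevel=2,
            )


@dataclass
class LabeledDataset:
    """Sequences with truth labels and a provenance map back to their sources."""

    sequences: list[SequenceRecord]
    provenance: pd.DataFrame  # seq_id, label_kind, label_key, source_seq_id, identity_to_source
    config: SimulationConfig

    def truth(self) -> dict[str, tuple[str, Optional[str]]]:
        return {rec.seq_id: rec.label for rec in self.sequences}


def _random_protein(rng: np.random.Generator, length: int, probs) -> str:
    return "".join(rng.choice(list(AA20), size=length, p=probs))


def _mutate(
    rng: np.random.Generator,
    seq: str,
    target_identity: float,
    lo: float,
    hi: float = 1.0,
) -> tuple[str, float]:
    """Substitute residues to the target identity, clamped into [lo, hi]."""
    L = len(seq)
    d_min = max(1, int(math.ceil((1.0 - hi) * L - 1e-9)))
    d_max = int(math.floor((1.0 - lo) * L + 1e-9))
    if d_min > d_max:
        raise SimulationError(
            f"sequence of length {L} cannot resolve an identity in [{lo}, {hi}]"
        )
    d = int(round((1.0 - target_identity) * L))
    d = max(d_min, min(d, d_max))
    positions = rng.choice(L, size=d, replace=False)
    chars = list(seq)
    for pos in positions:
        current = chars[pos]
        alternatives = [a for a in AA20 if a != current]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars), 1.0 - d / L


def _lineage(family_idx: int, phylum: str) -> tuple[str, ...]:
    return (
        "Bacteria",
        phylum,
        f"Class_{family_idx}",
        f"Order_{family_idx}",
        f"Family_{family_idx}",
        f"Genus_{family_idx}",
        f"Species_{family_idx}",
    )


def simulate_reference_set(
    config: SimulationConfig,
) -> tuple[ReferenceDatabase, LabeledDataset]:
    """A full-tier reference database with planted truth.

    Families get one ancestor each; members are substitution mutants at the
    member identity tier and carry a planted 7-rank lineage (one lineage per
    family).  Decoy groups mutate a randomly chosen family ancestor down to
    the decoy identity tier and then add within-group members near that decoy
    ancestor.
    """
    rng = np.random.default_rng(config.seed)
    probs = None
    if config.background is not None:
        probs = np.asarray(config.background, dtype=float)
        probs = probs / probs.sum()
    db = ReferenceDatabase("full")
    records: list[SequenceRecord] = []
    prov_rows = []

    ancestors: dict[str, str] = {}
    for i in range(config.n_families):
        fid = f"fam{i:02d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        ancestor = _random_protein(rng, length, probs)
        ancestors[fid] = ancestor
        lineage = _lineage(i, _PHYLA[int(rng.integers(len(_PHYLA)))])
        for j in range(config.members_per_family):
            target = rng.uniform(*config.member_identity)
            seq, realized = _mutate(rng, ancestor, target, *config.member_identity)
            rec = SequenceRecord(
                seq_id=f"{fid}_m{j:02d}",
                residues=seq,
                label=("target", fid),
                taxonomy=lineage,
                tier="full",
            )
            db.add(rec)
            records.append(rec)
            prov_rows.append(
                dict(
                    seq_id=rec.seq_id,
                    label_kind="target",
                    label_key=fid,
                    source_seq_id=f"{fid}_ancestor",
                    identity_to_source=realized,
                )
            )

    family_ids = sorted(ancestors)
    for g in range(config.n_decoy_groups):
        gid = f"hg{g:02d}"
        src_family = family_ids[int(rng.integers(len(family_ids)))]
        target = rng.uniform(*config.decoy_identity)
        decoy_ancestor, realized = _mutate(
            rng, ancestors[src_family], target, *config.decoy_identity
        )
        lineage = _lineage(config.n_families + g, _PHYLA[int(rng.integers(len(_PHYLA)))])
        for j in range(config.decoy_members_per_group):
            if j == 0:
                seq, ident = decoy_ancestor, realized
            else:
                t = rng.uniform(*config.member_identity)
                seq, ident = _mutate(rng, decoy_ancestor, t, *config.member_identity)
            rec = SequenceRecord(
                seq_id=f"{gid}_m{j:02d}",
                residues=seq,
                label=("decoy", gid),
                taxonomy=lineage,
                tier="full",
            )
            db.add(rec)
            records.append(rec)
            prov_rows.append(
                dict(
                    seq_id=rec.seq_id,
                    label_kind="decoy",
                    label_key=gid,
                    source_seq_id=f"{src_family}_ancestor",
                    identity_to_source=ident,
                )
            )

    dataset = LabeledDataset(
        sequences=records,
        provenance=pd.DataFrame(
            prov_rows,
            columns=[
                "seq_id",
                "label_kind",
                "label_key",
                "source_seq_id",
                "identity_to_source",
            ],
        ),
        config=config,
    )
    return db, dataset


def make_artificial_eval_set(
    db: ReferenceDatabase,
    config: SimulationConfig,
    counts: tuple[int, int, int] = EVAL_SET_COUNTS,
    rng: Optional[np.random.Generator] = None,
) -> LabeledDataset:
    """Full-length query proteins mirroring the artificial evaluation design:
    mutated copies of target members, mutated copies of decoy members, and
    unrelated random sequences, with truth labels attached."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_target, n_decoy, n_unrelated = counts
    targets = sorted(db.records(include_decoys=False), key=lambda r: r.seq_id)
    decoys = sorted(
        (r for r in db.records() if r.kind == "decoy"), key=lambda r: r.seq_id
    )
    if n_target > 0 and not targets:
        raise SimulationError("no target sequences available for evaluation queries")
    if n_decoy > 0 and not decoys:
        raise SimulationError("no decoy sequences available for evaluation queries")
    probs = None
    if config.background is not None:
        probs = np.asarray(config.background, dtype=float)
        probs = probs / probs.sum()

    records: list[SequenceRecord] = []
    prov_rows = []

    def _queries(pool, n, prefix, kind):
        for i in range(n):
            src = pool[int(rng.integers(len(pool)))]
            t = rng.uniform(*config.member_identity)
            seq, ident = _mutate(rng, src.residues, t, *config.member_identity)
            rec = SequenceRecord(
                seq_id=f"{prefix}{i:03d}",
                residues=seq,
                label=(kind, src.label[1]),
            )
            records.append(rec)
            prov_rows.append(
                dict(
                    seq_id=rec.seq_id,
                    label_kind=kind,
                    label_key=src.label[1],
                    source_seq_id=src.seq_id,
                    identity_to_source=ident,
                )
            )

    _queries(targets, n_target, "qt", "target")
    _queries(decoys, n_decoy, "qh", "decoy")
    for i in range(n_unrelated):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        rec = SequenceRecord(
            seq_id=f"qu{i:03d}",
            residues=_random_protein(rng, length, probs),
            label=("unrelated", None),
        )
        records.append(rec)
        prov_rows.append(
            dict(
                seq_id=rec.seq_id,
                label_kind="unrelated",
                label_key=None,
                source_seq_id="",
                identity_to_source=float("nan"),
            )
        )
    return LabeledDataset(
        sequences=records,
        provenance=pd.DataFrame(
            prov_rows,
            columns=[
                "seq_id",
                "label_kind",
                "label_key",
                "source_seq_id",
                "identity_to_source",
            ],
        ),
        config=config,
    )


_REVERSE_CODONS: dict[str, list[str]] = {}


def _reverse_codon_table() -> dict[str, list[str]]:
    if not _REVERSE_CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _REVERSE_CODONS.setdefault(aa, []).append(codon)
        for aa in _REVERSE_CODONS:
            _REVERSE_CODONS[aa].sort()
    return _REVERSE_CODONS


def reverse_translate(
    peptide: str, rng: np.random.Generator
) -> str:
    """A random nucleotide coding sequence for a peptide (uniform codon choice)."""
    table = _reverse_codon_table()
    return "".join(
        table[aa][int(rng.integers(len(table[aa])))] for aa in peptide
    )


def fragment_reads(
    db: ReferenceDatabase,
    config: SimulationConfig,
    proportions: Optional[Mapping[str, float]] = None,
    n_reads: Optional[int] = None,
    nucleotide: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample fragment reads from database sequences by community proportion.

    ``proportions`` is keyed by family id and/or decoy group id and must sum
    to 1.  Within the chosen family/group a member is picked uniformly, the
    start position uniformly, and the read length uniformly from the
    configured range (clipped, with a warning, when a source is shorter).
    With ``nucleotide=True`` each peptide fragment is reverse-translated with
    uniform codon choice, for translated-search testing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if proportions is None:
        proportions = config.proportions
    if proportions is None:
        keys = sorted(db.targets)
        proportions = {k: 1.0 / len(keys) for k in keys}
    if n_reads is None:
        n_reads = config.reads_per_sample
    keys = sorted(proportions)
    p = np.array([proportions[k] for k in keys], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise SimulationError(f"community proportions sum to {p.sum():.6f}, not 1")
    pools: dict[str, list[SequenceRecord]] = {}
    for k in keys:
        pool = db.targets.get(k) or db.decoys.get(k)
        if not pool:
            raise SimulationError(f"unknown family/group id {k!r} in proportions")
        pools[k] = sorted(pool, key=lambda r: r.seq_id)
    lo, hi = config.read_length_range
    reads: list[tuple[str, str]] = []
    prov_rows = []
    choices = rng.choice(len(keys), size=n_reads, p=p)
    clipped = False
    for i, ki in enumerate(choices):
        key = keys[int(ki)]
        src = pools[key][int(rng.integers(len(pools[key])))]
        length = int(rng.integers(lo, hi + 1))
        if length > len(src.residues):
            length = len(src.residues)
            clipped = True
        start = int(rng.integers(0, len(src.residues) - length + 1))
        fragment = src.residues[start : start + length]
        read_id = f"read{i:06d}"
        seq = reverse_translate(fragment, rng) if nucleotide else fragment
        reads.append((read_id, seq))
        prov_rows.append(
            dict(
                read_id=read_id,
                label_kind=src.kind,
                label_key=src.label[1],
                source_seq_id=src.seq_id,
                start=start,
                length=length,
            )
        )
    if clipped:
        import warnings

        warnings.warn("some reads were clipped to their source length", stacklevel=2)
    provenance = pd.DataFrame(
        prov_rows,
        columns=["read_id", "label_kind", "label_key", "source_seq_id", "start", "length"],
    )
    return reads, provenance
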