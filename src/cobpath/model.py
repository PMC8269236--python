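"""Domain model: gene families, pathways, the packaged count fixture, and the
tiered reference database.

The registry describes a set of curated gene (sub)families organised into
pathways.  A family may belong to several pathways (e.g. *cobA* participates in
precorrin-2 synthesis, the anaerobic branch, and salvage/remodeling); such
shared families are stored once, with the set of member pathways, and the
packaged per-pathway count table is validated to carry identical rows for each
of the family's pathways before being collapsed.  This makes the deduplicated
sequence totals (each shared family counted once) a first-class operation
rather than spreadsheet arithmetic.

Declared homology between families (e.g. *cysG* / *cobA*) is a symmetric
relation used during candidate recruitment: candidates for a family are scored
against the pooled seeds of the family and all of its declared homologs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Optional, Sequence

import pandas as pd

PATHWAY_IDS = (
    "precorrin2",
    "aerobic",
    "anaerobic",
    "salvage_remodeling",
    "post_adocbip",
)

HOMOLOG_SOURCES = ("arCOG", "COG", "eggNOG", "KEGG")

TAXONOMIC_RANKS = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

Tier = Literal["seed", "core", "full"]


class RegistryError(ValueError):
    """Raised for malformed or internally inconsistent registry inputs."""


@dataclass(frozen=True)
class GeneFamily:
    """One curated gene (sub)family.

    Sub-family suffixes (``cobC-beta`` vs ``cobC-ado``) are distinct family
    ids: same gene symbol, different enzymatic role.
    """

    family_id: str
    annotation: str
    pathways: frozenset[str]
    homolog_family_ids: frozenset[str] = frozenset()

    @property
    def shared(self) -> bool:
        return len(self.pathways) > 1


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    member_family_ids: tuple[str, ...]


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with its role in the reference database.

    ``label`` is a tagged union encoded as a pair: ``("target", family_id)``,
    ``("decoy", group_id)`` or ``("unrelated", None)``.
    """

    seq_id: str
    residues: str
    label: tuple[str, Optional[str]] = ("unrelated", None)
    taxonomy: Optional[tuple[str, ...]] = None
    tier: Tier = "full"
    duplicate_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty residue string for {self.seq_id!r}")
        kind = self.label[0]
        if kind not in ("target", "decoy", "unrelated"):
            raise ValueError(f"unknown label kind {kind!r}")
        if self.taxonomy is not None and len(self.taxonomy) != len(TAXONOMIC_RANKS):
            raise ValueError(
                f"taxonomy for {self.seq_id!r} must have {len(TAXONOMIC_RANKS)} ranks"
            )

    @property
    def kind(self) -> str:
        return self.label[0]

    @property
    def family_id(self) -> Optional[str]:
        return self.label[1] if self.label[0] == "target" else None

    @property
    def group_id(self) -> Optional[str]:
        return self.label[1] if self.label[0] == "decoy" else None


@dataclass(frozen=True)
class HomologGroup:
    """An orthology-group cluster from a public database (arCOG/COG/eggNOG/KEGG)."""

    group_id: str
    source_db: str
    member_seq_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.source_db not in HOMOLOG_SOURCES + ("other",):
            raise ValueError(f"unknown source db {self.source_db!r}")


class FamilyRegistry:
    """Families, pathways and (optionally) the packaged per-pathway count fixture."""

    def __init__(
        self,
        families: Mapping[str, GeneFamily],
        pathways: Mapping[str, Pathway],
        counts: Optional[pd.DataFrame] = None,
    ) -> None:
        self.families = dict(families)
        self.pathways = dict(pathways)
        self.counts = counts
        self._validate()

    def _validate(self) -> None:
        for fam in self.families.values():
            unknown = fam.pathways - set(self.pathways)
            if unknown:
                raise RegistryError(
                    f"family {fam.family_id!r} references unknown pathways {sorted(unknown)}"
                )
            for hid in fam.homolog_family_ids:
                if hid not in self.families:
                    raise RegistryError(
                        f"family {fam.family_id!r} declares unknown homolog {hid!r}"
                    )
                if fam.family_id not in self.families[hid].homolog_family_ids:
                    raise RegistryError(
                        f"homology not symmetric: {fam.family_id!r} -> {hid!r}"
                    )
        for pw in self.pathways.values():
            for fid in pw.member_family_ids:
                if fid not in self.families:
                    raise RegistryError(
                        f"pathway {pw.pathway_id!r} lists unknown family {fid!r}"
                    )

    # -- convenience views ------------------------------------------------

    @property
    def family_ids(self) -> list[str]:
        return list(self.families)

    @property
    def shared_family_ids(self) -> set[str]:
        return {f.family_id for f in self.families.values() if f.shared}

    def homolog_pool(self, family_id: str) -> set[str]:
        """The family itself plus all declared homolog families."""
        fam = self.families[family_id]
        return {family_id, *fam.homolog_family_ids}

    # -- fixture arithmetic ----------------------------------------------

    def _require_counts(self) -> pd.DataFrame:
        if self.counts is None:
            raise RegistryError("no count fixture attached to this registry")
        return self.counts

    def unique_family_total(self, fixture_field: str) -> int:
        """Sum a count column over *distinct* families.

        Shared families appear once per member pathway in the printed fixture
        with identical values; they contribute that value once here.  This is
        the deduplication that turns the printed per-pathway column sums into
        the database-wide sequence totals.
        """
        counts = self._require_counts()
        if fixture_field not in ("core_count", "full_count"):
            raise RegistryError(f"unknown fixture field {fixture_field!r}")
        per_family = counts.groupby("family_id")[fixture_field]
        if (per_family.nunique() > 1).any():
            bad = per_family.nunique()
            offenders = sorted(bad[bad > 1].index)
            raise RegistryError(
                f"conflicting duplicate {fixture_field} values for shared families {offenders}"
            )
        return int(per_family.first().sum())

    def unique_homolog_group_total(self, source: Optional[str] = None) -> int:
        """Deduplicated homolog-group total, optionally restricted to one source."""
        counts = self._require_counts()
        sources = [source] if source is not None else list(HOMOLOG_SOURCES)
        total = 0
        for src in sources:
            if src not in HOMOLOG_SOURCES:
                raise RegistryError(f"unknown homolog source {src!r}")
            per_family = counts.groupby("family_id")[src].first()
            total += int(per_family.fillna(0).sum())
        return total

    def pathway_homolog_group_total(self, pathway_id: str) -> int:
        """Sum of the four per-source homolog-group counts over a pathway's
        families, as printed (missing cells count as zero)."""
        counts = self._require_counts()
        if pathway_id not in self.pathways:
            raise RegistryError(f"unknown pathway {pathway_id!r}")
        rows = counts[counts["pathway_id"] == pathway_id]
        return int(rows[list(HOMOLOG_SOURCES)].fillna(0).to_numpy().sum())

    def pathway_column_sum(self, pathway_id: str, column: str) -> int:
        """Straight per-pathway column sum, matching the printed "Sum" rows."""
        counts = self._require_counts()
        if pathway_id not in self.pathways:
            raise RegistryError(f"unknown pathway {pathway_id!r}")
        rows = counts[counts["pathway_id"] == pathway_id]
        return int(rows[column].fillna(0).sum())

    def grand_column_sum(self, column: str) -> int:
        """Straight column sum over all printed rows (shared families repeated)."""
        counts = self._require_counts()
        return int(counts[column].fillna(0).sum())


def rollup_counts_by_pathway(
    registry: FamilyRegistry,
    per_family_counts: Mapping[str, float],
    share_mode: str = "replicate",
) -> dict[str, float]:
    """Aggregate per-family counts to per-pathway totals.

    ``replicate``: a family shared by k pathways contributes its full count to
    each of them (pathway totals then over-count relative to the family total).
    ``fractional``: the count is split equally across the k member pathways, so
    the pathway totals conserve the overall mass exactly.
    """
    if share_mode not in ("replicate", "fractional"):
        raise ValueError(f"unknown share_mode {share_mode!r}")
    unknown = sorted(set(per_family_counts) - set(registry.families))
    if unknown:
        raise RegistryError(f"unknown family ids in counts: {unknown}")
    totals: dict[str, float] = {pid: 0.0 for pid in registry.pathways}
    for fid, count in per_family_counts.items():
        pathways = sorted(registry.families[fid].pathways)
        share = count if share_mode == "replicate" else count / len(pathways)
        for pid in pathways:
            totals[pid] += share
    return totals


def _split_field(value: str) -> list[str]:
    value = value.strip()
    return [v for v in (s.strip() for s in value.split(";")) if v] if value else []


def load_registry(
    registry_tsv: Optional[str | Path] = None,
    fixture_tsv: Optional[str | Path] = None,
) -> FamilyRegistry:
    """Load a registry (and optional count fixture) from TSV.

    With no arguments, loads the packaged cobalamin-biosynthesis registry:
    60 gene (sub)families across five pathway processes, with the published
    per-pathway sequence and homolog-group counts attached.
    """
    if registry_tsv is None:
        registry_tsv = importlib.resources.files("cobpath.data") / "registry.tsv"
        if fixture_tsv is None:
            fixture_tsv = importlib.resources.files("cobpath.data") / "family_counts.tsv"
    reg = pd.read_csv(registry_tsv, sep="\t", dtype=str).fillna("")
    required = {"family_id", "annotation", "pathways"}
    if not required <= set(reg.columns):
        raise RegistryError(f"registry TSV must have columns {sorted(required)}")

    families: dict[str, GeneFamily] = {}
    pathway_members: dict[str, list[str]] = {}
    for _, row in reg.iterrows():
        fid = row["family_id"].strip()
        if fid in families:
            raise RegistryError(f"duplicate family row {fid!r}")
        pathways = _split_field(row["pathways"])
        if not pathways:
            raise RegistryError(f"family {fid!r} has no pathways")
        for pid in pathways:
            if pid not in PATHWAY_IDS:
                raise RegistryError(f"family {fid!r}: unknown pathway id {pid!r}")
            pathway_members.setdefault(pid, []).append(fid)
        homologs = _split_field(row.get("homolog_family_ids", ""))
        families[fid] = GeneFamily(
            family_id=fid,
            annotation=row["annotation"].strip(),
            pathways=frozenset(pathways),
            homolog_family_ids=frozenset(homologs),
        )
    pathways = {
        pid: Pathway(pid, tuple(members)) for pid, members in pathway_members.items()
    }

    counts = None
    if fixture_tsv is not None:
        counts = pd.read_csv(
            fixture_tsv,
            sep="\t",
            dtype={"pathway_id": str, "family_id": str},
            na_values=["NA"],
        )
        for col in ("core_count", "full_count"):
            if (counts[col].dropna() < 0).any():
                raise RegistryError(f"negative values in fixture column {col!r}")
        dup = counts.duplicated(subset=["pathway_id", "family_id"], keep=False)
        if dup.any():
            rows = counts[dup][["pathway_id", "family_id"]].drop_duplicates()
            raise RegistryError(
                "duplicate fixture rows for "
                + ", ".join(f"{r.family_id}/{r.pathway_id}" for r in rows.itertuples())
            )
        # shared-family rows must be identical across pathways before collapsing
        value_cols = ["core_count", "full_count", *HOMOLOG_SOURCES]
        for fid, grp in counts.groupby("family_id"):
            deduped = grp[value_cols].drop_duplicates()
            if len(deduped) > 1:
                raise RegistryError(
                    f"shared family {fid!r} has conflicting per-pathway fixture rows"
                )
            if fid not in families:
                raise RegistryError(f"fixture references unknown family {fid!r}")
            fixture_pw = set(grp["pathway_id"])
            if fixture_pw != set(families[fid].pathways):
                raise RegistryError(
                    f"fixture pathways for {fid!r} ({sorted(fixture_pw)}) do not match "
                    f"registry ({sorted(families[fid].pathways)})"
                )

    return FamilyRegistry(families, pathways, counts)


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------


class ReferenceDatabase:
    """A tiered sequence store: target sequences by family, decoy sequences by
    homolog group.  Decoys exist only at the ``full`` tier."""

    def __init__(self, tier: Tier) -> None:
        self.tier: Tier = tier
        self.targets: dict[str, list[SequenceRecord]] = {}
        self.decoys: dict[str, list[SequenceRecord]] = {}
        self._ids: set[str] = set()

    def __len__(self) -> int:
        return len(self._ids)

    @property
    def n_targets(self) -> int:
        return sum(len(v) for v in self.targets.values())

    @property
    def n_decoys(self) -> int:
        return sum(len(v) for v in self.decoys.values())

    def add(self, record: SequenceRecord) -> None:
        if record.seq_id in self._ids:
            raise ValueError(f"duplicate sequence id {record.seq_id!r}")
        kind, key = record.label
        if kind == "target":
            self.targets.setdefault(key, []).append(replace(record, tier=self.tier))
        elif kind == "decoy":
            if self.tier != "full":
                raise ValueError("decoy sequences are only allowed at the full tier")
            self.decoys.setdefault(key, []).append(replace(record, tier=self.tier))
        else:
            raise ValueError(f"cannot store unrelated sequence {record.seq_id!r}")
        self._ids.add(record.seq_id)

    def records(self, include_decoys: bool = True) -> Iterator[SequenceRecord]:
        for fam in self.targets.values():
            yield from fam
        if include_decoys:
            for grp in self.decoys.values():
                yield from grp

    def get(self, seq_id: str) -> SequenceRecord:
        for rec in self.records():
            if rec.seq_id == seq_id:
                return rec
        raise KeyError(seq_id)

    def target_ids(self) -> set[str]:
        return {r.seq_id for r in self.records(include_decoys=False)}

    def label_of(self, ref_id: str) -> tuple[str, Optional[str]]:
        return self.get(ref_id).label

    def copy(self, tier: Optional[Tier] = None) -> "ReferenceDatabase":
        out = ReferenceDatabase(tier or self.tier)
        for rec in self.records():
            if rec.kind == "decoy" and out.tier != "full":
                continue
            out.add(rec)
        return out

    def without_decoys(self, tier: Tier = "core") -> "ReferenceDatabase":
        """The same targets with all decoy groups removed (a 'small database')."""
        out = ReferenceDatabase(tier)
        for rec in self.records(include_decoys=False):
            out.add(rec)
        return out

    def stage_counts(self) -> dict[str, int]:
        return {
            "tier": 0 if self.tier == "seed" else (1 if self.tier == "core" else 2),
            "n_families": len(self.targets),
            "n_targets": self.n_targets,
            "n_decoy_groups": len(self.decoys),
            "n_decoys": self.n_decoys,
        }


# ---------------------------------------------------------------------------
# FASTA header convention
# ---------------------------------------------------------------------------

def format_header(record: SequenceRecord) -> str:
    kind, key = record.label
    parts = [record.seq_id, f"fam={key}", f"kind={kind}"]
    if record.taxonomy is not None:
        parts.append("tax=" + ";".join(record.taxonomy))
    return " ".join(parts)


def parse_header(header: str) -> tuple[str, dict[str, str]]:
    fields = header.split()
    seq_id = fields[0]
    attrs = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
    return seq_id, attrs


def write_reference_fasta(db: ReferenceDatabase, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in db.records():
            fh.write(f">{format_header(rec)}\n{rec.residues}\n")


def read_reference_fasta(path: str | Path, tier: Tier = "full") -> ReferenceDatabase:
    from Bio import SeqIO

    db = ReferenceDatabase(tier)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, attrs = parse_header(rec.description)
        kind = attrs.get("kind", "target")
        tax = tuple(attrs["tax"].split(";")) if "tax" in attrs else None
        db.add(
            SequenceRecord(
                seq_id=seq_id,
                residues=str(rec.seq),
                label=(kind, attrs.get("fam")),
                taxonomy=tax,
                tier=tier,
            )
        )
    return db


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read reads/queries as (id, sequence) pairs from FASTA or FASTQ."""
    from Bio import SeqIO

    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n{seq}\n")
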