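"""Protein alignment and best-hit search.

The pipeline's search contract is "single best hit, identity >= 30%", the
configuration used throughout database construction and profiling.  The
built-in searcher implements that contract with optimal pairwise alignment
(Needleman-Wunsch / Smith-Waterman with affine gaps, BLOSUM62 by default) via
Bio.Align.PairwiseAligner, so the whole pipeline is testable without an
external search engine.  An adapter is provided for external engines that emit
BLAST-style 12-column tabular output; adapter hits are interchangeable with
built-in hits downstream.

Conventions (documented once, applied everywhere):

* a gap of length k costs ``gap_open + k * gap_extend``;
* global alignments penalize end gaps;
* identity = identical columns / all alignment columns, including gap columns
  (for local alignments, columns of the local span only);
* the built-in searcher thresholds on raw score and identity.  E-values belong
  to the external-engine contract and are honored only in adapter mode: at
  desk-scale database sizes an e-value adds no information beyond the raw
  score threshold.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import Align as _bioalign
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .model import ReferenceDatabase, SequenceRecord

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = frozenset("ACGTN")

# raw-score floor for local (fragment) search: comfortably above the maximal
# local score expected between unrelated sequences at desk-scale database
# sizes (Karlin-Altschul estimate ~45 raw units for ~100 x 200-residue
# references), far below any true fragment hit.
DEFAULT_LOCAL_MIN_SCORE = 60.0


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (positive costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)

    def substitution(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    def gap_cost(self, length: int) -> float:
        return 0.0 if length == 0 else self.gap_open + length * self.gap_extend


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment with gapped strings and summary statistics."""

    query_aln: str
    ref_aln: str
    score: float
    query_start: int = 0
    query_end: int = 0

    def __post_init__(self) -> None:
        if len(self.query_aln) != len(self.ref_aln):
            raise AlignmentError("aligned strings must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.query_aln)

    @property
    def n_identical(self) -> int:
        return sum(
            1 for a, b in zip(self.query_aln, self.ref_aln) if a == b and a != "-"
        )

    @property
    def identity(self) -> float:
        return self.n_identical / self.n_columns if self.n_columns else 0.0

    def query_coverage(self, query_length: int) -> float:
        if query_length == 0:
            return 0.0
        span = self.query_end - self.query_start
        return span / query_length


@dataclass(frozen=True)
class Hit:
    query_id: str
    ref_id: str
    ref_label: tuple[str, Optional[str]]
    score: float
    identity: float
    evalue: Optional[float] = None
    frame: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")


@dataclass(frozen=True)
class SearchConfig:
    """Best-hit search settings (one hit per query, thresholds >= 0)."""

    mode: str = "local"  # {global, local, translated_local}
    min_identity: float = 0.30
    min_score: Optional[float] = None  # resolved per mode; see resolved_min_score
    evalue_threshold: float = 1e-4  # external adapters only
    max_hits: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local", "translated_local"):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if self.min_identity < 0 or self.evalue_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.max_hits != 1:
            raise ValueError("the search contract is single best hit")

    @property
    def resolved_min_score(self) -> float:
        if self.min_score is not None:
            return self.min_score
        return 0.0 if self.mode == "global" else DEFAULT_LOCAL_MIN_SCORE


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise AlignmentError(f"{name}: empty sequence")
    for i, ch in enumerate(seq):
        if ch not in AA_ALPHABET:
            raise AlignmentError(f"{name}: non-alphabet residue {ch!r} at position {i}")


def _aligner(scheme: ScoringScheme, mode: str) -> _bioalign.PairwiseAligner:
    al = _bioalign.PairwiseAligner()
    al.substitution_matrix = scheme.matrix
    # engine convention: opening a gap immediately pays open + one extension
    al.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    al.extend_gap_score = -scheme.gap_extend
    al.mode = mode
    return al


def _from_biopython(alns, query: str, mode: str) -> Alignment:
    if len(alns) == 0 or (mode == "local" and alns.score <= 0):
        return Alignment("", "", 0.0, 0, 0)
    best = alns[0]
    q, r = str(best[0]), str(best[1])
    qcoords = best.coordinates[0]
    return Alignment(
        query_aln=q,
        ref_aln=r,
        score=float(alns.score),
        query_start=int(qcoords[0]),
        query_end=int(qcoords[-1]),
    )


def align_global(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> Alignment:
    """Optimal global (Needleman-Wunsch) alignment, end gaps penalized."""
    _check_protein(a, "query")
    _check_protein(b, "reference")
    al = _aligner(scheme, "global")
    return _from_biopython(al.align(a, b), a, "global")


def align_local(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> Alignment:
    """Optimal local (Smith-Waterman) alignment; empty when no positive score."""
    _check_protein(a, "query")
    _check_protein(b, "reference")
    al = _aligner(scheme, "local")
    return _from_biopython(al.align(a, b), a, "local")


# ---------------------------------------------------------------------------
# Six-frame translation
# ---------------------------------------------------------------------------

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAMES = (1, 2, 3, -1, -2, -3)


def _translate_frame(seq: str, offset: int) -> str:
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


def translate_six_frames(seq: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six frames (standard code).

    Stops are emitted as '*', codons containing N as 'X', and trailing partial
    codons are dropped.  Frames are keyed +1..+3 (forward) and -1..-3
    (reverse complement).
    """
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in NT_ALPHABET:
            raise AlignmentError(f"non-nucleotide character {ch!r} at position {i}")
    rc = seq.translate(_COMPLEMENT)[::-1]
    return {
        1: _translate_frame(seq, 0),
        2: _translate_frame(seq, 1),
        3: _translate_frame(seq, 2),
        -1: _translate_frame(rc, 0),
        -2: _translate_frame(rc, 1),
        -3: _translate_frame(rc, 2),
    }


def looks_nucleotide(seq: str) -> bool:
    letters = set(seq.upper())
    return bool(letters) and letters <= NT_ALPHABET


# ---------------------------------------------------------------------------
# Best-hit search
# ---------------------------------------------------------------------------

ReferenceSet = Union[ReferenceDatabase, Mapping[str, str], Sequence[SequenceRecord]]


def _iter_refs(db: ReferenceSet):
    if isinstance(db, ReferenceDatabase):
        for rec in db.records():
            yield rec.seq_id, rec.residues, rec.label
    elif isinstance(db, Mapping):
        for ref_id, seq in db.items():
            yield ref_id, seq, ("target", None)
    else:
        for rec in db:
            yield rec.seq_id, rec.residues, rec.label


def _best_hit_protein(
    query_id: str,
    query: str,
    refs: list[tuple[str, str, tuple]],
    config: SearchConfig,
    scheme: ScoringScheme,
    frame: Optional[int] = None,
) -> Optional[Hit]:
    mode = "global" if config.mode == "global" else "local"
    al = _aligner(scheme, mode)
    min_score = config.resolved_min_score
    scores = []
    for ref_id, ref_seq, label in refs:
        s = float(al.score(query, ref_seq))
        if s >= min_score:
            scores.append((s, ref_id, ref_seq, label))
    # walk score tiers from the top; within a tier prefer higher identity,
    # then the lexicographically smallest reference id
    scores.sort(key=lambda t: (-t[0], t[1]))
    i = 0
    while i < len(scores):
        tier_score = scores[i][0]
        tier = []
        while i < len(scores) and scores[i][0] == tier_score:
            tier.append(scores[i])
            i += 1
        candidates = []
        for s, ref_id, ref_seq, label in tier:
            aln = _from_biopython(al.align(query, ref_seq), query, mode)
            if aln.identity >= config.min_identity:
                candidates.append((aln.identity, ref_id, label, s))
        if candidates:
            candidates.sort(key=lambda t: (-t[0], t[1]))
            identity, ref_id, label, s = candidates[0]
            return Hit(
                query_id=query_id,
                ref_id=ref_id,
                ref_label=label,
                score=s,
                identity=identity,
                frame=frame,
            )
    return None


def best_hit(
    query: str,
    db: ReferenceSet,
    config: SearchConfig = SearchConfig(),
    scheme: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
) -> Optional[Hit]:
    """The single best reference for a query, or None when nothing passes.

    The winner is the highest-scoring reference that passes the identity and
    score thresholds; score ties are broken by higher identity, then by the
    lexicographically smallest reference id.  In translated mode the query is
    nucleotide: all six reading frames are searched and the best frame's best
    hit is returned.  Absence of a hit is a value, not an error.
    """
    refs = list(_iter_refs(db))
    if not refs:
        raise AlignmentError("reference set is empty")
    if config.mode == "translated_local":
        best: Optional[Hit] = None
        for frame, peptide in translate_six_frames(query).items():
            peptide = peptide.replace("*", "X")
            if not peptide:
                continue
            hit = _best_hit_protein(query_id, peptide, refs, config, scheme, frame)
            if hit is None:
                continue
            if (
                best is None
                or hit.score > best.score
                or (hit.score == best.score and hit.identity > best.identity)
            ):
                best = hit
        return best
    _check_protein(query, query_id)
    return _best_hit_protein(query_id, query, refs, config, scheme)


# ---------------------------------------------------------------------------
# External search adapter (BLAST-style 12-column tabular interchange)
# ---------------------------------------------------------------------------

TABULAR_COLUMNS = (
    "query",
    "ref",
    "pident",
    "length",
    "mismatches",
    "gapopens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


class EngineMissingError(RuntimeError):
    pass


def parse_tabular_hits(
    path: str | Path,
    config: SearchConfig = SearchConfig(),
    label_of=None,
) -> list[Hit]:
    """Parse 12-column tabular search output into best-hit records.

    Applies the external-engine contract: one best hit per query, e-value at
    most the configured threshold, identity at least the configured minimum.
    ``label_of`` maps a reference id to its (kind, key) label; unresolved
    references are labelled targets with no family.
    """
    best: dict[str, Hit] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(TABULAR_COLUMNS):
                raise AlignmentError(
                    f"{path}: line {lineno}: expected {len(TABULAR_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            try:
                pident = float(parts[2])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise AlignmentError(f"{path}: line {lineno}: {exc}") from exc
            if evalue > config.evalue_threshold:
                continue
            if pident / 100.0 < config.min_identity:
                continue
            label = label_of(parts[1]) if label_of else ("target", None)
            hit = Hit(
                query_id=parts[0],
                ref_id=parts[1],
                ref_label=label,
                score=bitscore,
                identity=pident / 100.0,
                evalue=evalue,
            )
            prev = best.get(hit.query_id)
            if prev is None:
                best[hit.query_id] = hit
                order.append(hit.query_id)
            elif (hit.score, hit.identity, prev.ref_id) > (
                prev.score,
                prev.identity,
                hit.ref_id,
            ):
                best[hit.query_id] = hit
    return [best[q] for q in order]


def external_search_adapter(
    query_fasta: str | Path,
    db_fasta: str | Path,
    config: SearchConfig = SearchConfig(),
    engine: str = "blastp",
    label_of=None,
    workdir: Optional[str | Path] = None,
) -> list[Hit]:
    """Run an external protein search engine and parse its tabular output.

    Requires the engine binaries on PATH; raises EngineMissingError otherwise.
    Currently wired for NCBI blastp (`-outfmt 6`); other engines emitting the
    same 12-column format can be parsed directly with parse_tabular_hits.
    """
    import tempfile

    if shutil.which(engine) is None:
        raise EngineMissingError(f"search engine {engine!r} not found on PATH")
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        out = Path(tmp) / "hits.tsv"
        cmd = [
            engine,
            "-query",
            str(query_fasta),
            "-subject",
            str(db_fasta),
            "-outfmt",
            "6",
            "-evalue",
            str(config.evalue_threshold),
            "-max_target_seqs",
            "1",
            "-out",
            str(out),
        ]
        subprocess.run(cmd, check=True, capture_output=True)
        return parse_tabular_hits(out, config, label_of)
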