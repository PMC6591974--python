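"""Tabular input/output with strict validation.

All inputs are plain TSV (tab- or whitespace-separated) with ``#``-prefixed
comment lines. Loading deduplicates records and reports what was dropped via
the module logger; malformed lines raise :class:`FormatError` naming the line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_KINDS = ("domain", "localization")


class FormatError(ValueError):
    """A malformed input line or table."""


@dataclass(frozen=True)
class InteractionTable:
    """Undirected protein-protein interactions, free of self-pairs and
    duplicate unordered pairs."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.records:
            if not a or not b:
                raise FormatError("empty protein ID in interaction record")
            if a == b:
                raise FormatError(f"self-interaction {a!r} in interaction table")
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                raise FormatError(f"duplicate interaction {key!r}")
            seen.add(key)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for rec in self.records for p in rec)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class AnnotationTable:
    """(protein, term) pairs; ``kind`` is 'domain' or 'localization'."""

    kind: str
    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise FormatError(f"unknown annotation kind {self.kind!r}")
        if len(set(self.records)) != len(self.records):
            raise FormatError("duplicate (protein, term) pair in annotation table")
        for p, t in self.records:
            if not p or not t:
                raise FormatError("empty field in annotation record")

    def terms_by_protein(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for p, t in self.records:
            out.setdefault(p, set()).add(t)
        return {p: frozenset(ts) for p, ts in out.items()}

    def proteins_by_term(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for p, t in self.records:
            out.setdefault(t, set()).add(p)
        return {t: frozenset(ps) for t, ps in out.items()}


@dataclass(frozen=True)
class OrthologyTable:
    """Per-protein count of reference organisms with an ortholog."""

    records: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p, c in self.records.items():
            if not p:
                raise FormatError("empty protein ID in orthology table")
            if not isinstance(c, int) or c < 0:
                raise FormatError(f"orthology count for {p!r} must be a non-negative integer")

    def count(self, protein: str) -> int:
        return self.records.get(protein, 0)


@dataclass(frozen=True)
class RankedOutput:
    """An ordered ranking: (1-based rank, protein ID, score) rows with
    non-increasing scores."""

    rows: tuple[tuple[int, str, float], ...]

    def __post_init__(self) -> None:
        prev = None
        for i, (rank, pid, score) in enumerate(self.rows, start=1):
            if rank != i:
                raise FormatError(f"ranks must be consecutive from 1; got {rank} at row {i}")
            if prev is not None and score > prev + 1e-15:
                raise FormatError("scores must be non-increasing down the ranking")
            prev = score
            if not pid:
                raise FormatError("empty protein ID in ranking")

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(pid for _, pid, _ in self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split()


def read_ppi_edgelist(path: str | Path) -> InteractionTable:
    """Load a two-column PPI edge list; self-interactions and repeated
    interactions are filtered out, with the dropped count logged."""
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    total = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected ≥2 fields, got {len(fields)}")
        a, b = fields[0], fields[1]
        total += 1
        if a == b:
            dropped += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if key in pairs:
            dropped += 1
            continue
        pairs.add(key)
    if total == 0:
        logger.warning("PPI edge list %s contains no interaction records", path)
    if dropped:
        logger.info("dropped %d self/duplicate interactions from %s", dropped, path)
    return InteractionTable(records=tuple(sorted(pairs)))


def read_annotation(path: str | Path, kind: str) -> AnnotationTable:
    """Load a two-column (protein, term) table of the given kind
    ('domain' or 'localization'); duplicate pairs collapse to one."""
    if kind not in ANNOTATION_KINDS:
        raise FormatError(f"unknown annotation kind {kind!r}")
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        rec = (fields[0], fields[1])
        if rec in pairs:
            dropped += 1
        pairs.add(rec)
    if dropped:
        logger.info("collapsed %d duplicate annotation rows in %s", dropped, path)
    return AnnotationTable(kind=kind, records=tuple(sorted(pairs)))


def read_orthology(path: str | Path) -> OrthologyTable:
    """Load protein → ortholog-count pairs; duplicates and negative or
    non-integer counts are errors."""
    counts: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        pid, raw = fields[0], fields[1]
        if pid in counts:
            raise FormatError(f"{path}:{lineno}: duplicate protein {pid!r}")
        try:
            value = int(raw)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer count {raw!r}") from exc
        if value < 0:
            raise FormatError(f"{path}:{lineno}: negative count {value} for {pid!r}")
        counts[pid] = value
    return OrthologyTable(records=counts)


def read_essential_list(path: str | Path) -> frozenset[str]:
    """Load a benchmark essential-protein list (one ID per line)."""
    ids = set()
    for _, fields in _data_lines(path):
        ids.add(fields[0])
    return frozenset(ids)


def write_ranking(result: RankedOutput, path: str | Path) -> None:
    """Write a ranking as TSV with header rank/protein/score; scores are
    rendered with 12 significant digits so a round trip is faithful."""
    df = pd.DataFrame(list(result.rows), columns=["rank", "protein", "score"])
    df["score"] = df["score"].map(lambda s: format(float(s), ".12g"))
    df.to_csv(path, sep="\t", index=False)


def read_ranking(path: str | Path) -> RankedOutput:
    """Inverse of :func:`write_ranking`."""
    df = pd.read_csv(path, sep="\t", dtype={"rank": int, "protein": str, "score": float})
    rows = tuple(
        (int(r), str(p), float(s)) for r, p, s in df.itertuples(index=False, name=None)
    )
    return RankedOutput(rows=rows)
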