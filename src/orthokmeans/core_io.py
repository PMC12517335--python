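"""Domain containers and on-disk formats.

The pipeline revolves around three in-memory objects:

* :class:`ProteinRecord` / :class:`ProteinRegistry` — the proteins under
  study, each carrying a species code and (optionally) a reference
  orthologous-group label, in a fixed row order;
* :class:`EmbeddingMatrix` — an ``n x p`` real matrix of per-protein
  language-model embeddings, row-aligned to the registry.

On disk everything is plain text: FASTA with species-coded headers
(``>pfal|PF3D7_1449200 description``, the OrthoMCL-DB style), a
tab-separated group map (``protein_id  species  group_id``), a
tab-separated embedding table (``protein_id  v1 .. vp``), and TSV/JSON
outputs for predicted pairs, predicted groups and metric reports.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DimensionMismatchError,
    DuplicateRecordError,
    EmptyInputError,
    MalformedHeaderError,
    ParseError,
    UnknownIdError,
)

#: Residues accepted in protein sequences: the 20 standard amino acids plus
#: the common ambiguity/extension codes and the stop symbol.
AMINO_ACID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" "XBZU*")

#: Prefix used for the private singleton groups assigned to proteins that
#: carry no reference group (every protein must belong to exactly one
#: reference group for the group-level metrics to be well defined).
SINGLETON_PREFIX = "__singleton__"


# ---------------------------------------------------------------------------
# header dialect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeaderDialect:
    """How a FASTA header encodes species and protein id.

    The default matches OrthoMCL-DB-style exports: the species code is the
    token before the first ``|``, the protein id runs up to the first
    whitespace, and anything after that is free-text description.
    """

    separator: str = "|"

    def format(self, species: str, protein_id: str, description: str = "") -> str:
        head = f"{species}{self.separator}{protein_id}"
        return f"{head} {description}" if description else head


DEFAULT_DIALECT = HeaderDialect()


def parse_header(
    header_line: str, dialect: HeaderDialect = DEFAULT_DIALECT
) -> tuple[str, str, str]:
    """Split a FASTA header line into ``(species, protein_id, description)``.

    Raises :class:`MalformedHeaderError` if the separator is absent or the
    species/id token is empty.
    """
    if not header_line.startswith(">"):
        raise MalformedHeaderError(f"not a FASTA header line: {header_line!r}")
    body = header_line[1:].rstrip("\n")
    if dialect.separator not in body:
        raise MalformedHeaderError(
            f"missing species separator {dialect.separator!r} in header {header_line!r}"
        )
    species, _, rest = body.partition(dialect.separator)
    # the id runs to the first whitespace; a leading space means an empty id
    match = re.match(r"(\S*)\s*(.*)$", rest, re.S)
    protein_id, description = match.group(1), match.group(2).strip()
    if not species:
        raise MalformedHeaderError(f"empty species code in header {header_line!r}")
    if not protein_id:
        raise MalformedHeaderError(f"empty protein id in header {header_line!r}")
    return species, protein_id, description


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: id, species code, optional sequence / reference group."""

    id: str
    species: str
    sequence: str | None = None
    group: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.species:
            raise ValueError(f"species code for {self.id!r} must be non-empty")
        if self.sequence is not None:
            bad = set(self.sequence) - AMINO_ACID_ALPHABET
            if bad:
                raise ValueError(
                    f"sequence of {self.id!r} contains invalid residues: "
                    f"{''.join(sorted(bad))}"
                )


class ProteinRegistry:
    """Ordered collection of :class:`ProteinRecord` with unique ids.

    The row order is the canonical order for everything downstream: the
    embedding matrix, cluster labels and partitions are all aligned to it.
    """

    def __init__(self, records: Iterable[ProteinRecord]):
        self.records: list[ProteinRecord] = list(records)
        index: dict[str, int] = {}
        for pos, rec in enumerate(self.records):
            if rec.id in index:
                raise DuplicateRecordError(f"duplicate protein id {rec.id!r}")
            index[rec.id] = pos
        self.index = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> ProteinRecord:
        if isinstance(key, str):
            return self.records[self.index[key]]
        return self.records[key]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(r.species for r in self.records)

    @property
    def n_species(self) -> int:
        return len(self.species_set)

    def with_groups(self, mapping: Mapping[str, tuple[str, str]]) -> "ProteinRegistry":
        """Return a copy with reference groups set from a group map.

        ``mapping`` is ``protein_id -> (species, group_label)`` as returned
        by :func:`read_group_map`. Ids absent from the registry are an error;
        registry proteins absent from the map keep their current group.
        An empty group label leaves the protein ungrouped.
        """
        unknown = sorted(set(mapping) - set(self.index))
        if unknown:
            raise UnknownIdError(
                f"group map names {len(unknown)} unknown protein id(s): "
                + ", ".join(unknown[:10])
                + ("..." if len(unknown) > 10 else "")
            )
        new_records = []
        for rec in self.records:
            if rec.id in mapping:
                species, group = mapping[rec.id]
                new_records.append(
                    dataclasses.replace(
                        rec, species=species or rec.species, group=group or None
                    )
                )
            else:
                new_records.append(rec)
        return ProteinRegistry(new_records)

    def with_singleton_groups(self) -> tuple["ProteinRegistry", list[str]]:
        """Assign each ungrouped protein a private singleton group.

        Returns the completed registry and the list of protein ids that were
        flagged as singletons, so reports can disclose them.
        """
        flagged = [r.id for r in self.records if r.group is None]
        new_records = [
            dataclasses.replace(r, group=f"{SINGLETON_PREFIX}{r.id}")
            if r.group is None
            else r
            for r in self.records
        ]
        return ProteinRegistry(new_records), flagged

    def partition(self) -> dict[str, str]:
        """Reference partition ``protein_id -> group label``.

        Raises :class:`EmptyInputError` on an empty registry and
        :class:`UnknownIdError` if any protein is still ungrouped (use
        :meth:`with_singleton_groups` first).
        """
        if not self.records:
            raise EmptyInputError("registry is empty")
        ungrouped = [r.id for r in self.records if r.group is None]
        if ungrouped:
            raise UnknownIdError(
                f"{len(ungrouped)} protein(s) have no reference group "
                f"(e.g. {ungrouped[0]!r}); assign singleton groups first"
            )
        return {r.id: r.group for r in self.records}  # type: ignore[misc]

    def groups(self) -> dict[str, list[str]]:
        """Reference groups as ``group label -> member ids`` (registry order)."""
        part = self.partition()
        out: dict[str, list[str]] = {}
        for pid, grp in part.items():
            out.setdefault(grp, []).append(pid)
        return out


@dataclass
class EmbeddingMatrix:
    """``n x p`` real matrix of per-protein embeddings, one row per id."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionMismatchError(
                f"embedding matrix must be 2-D, got shape {self.values.shape}"
            )
        if len(self.ids) != self.values.shape[0]:
            raise DimensionMismatchError(
                f"{len(self.ids)} ids but {self.values.shape[0]} matrix rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateRecordError("duplicate protein ids in embedding matrix")
        if not np.all(np.isfinite(self.values)):
            raise ParseError("embedding matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def align_to(self, registry: ProteinRegistry) -> "EmbeddingMatrix":
        """Reorder rows to the registry's row order.

        The id sets must match exactly; the symmetric difference is reported
        otherwise.
        """
        mine, theirs = set(self.ids), set(registry.index)
        if mine != theirs:
            missing = sorted(theirs - mine)[:5]
            extra = sorted(mine - theirs)[:5]
            raise UnknownIdError(
                "embedding ids do not match registry; "
                f"missing from embeddings: {missing}; not in registry: {extra}"
            )
        pos = {pid: i for i, pid in enumerate(self.ids)}
        order = [pos[pid] for pid in registry.ids]
        return EmbeddingMatrix(list(registry.ids), self.values[order])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(
    path: str | Path, dialect: HeaderDialect = DEFAULT_DIALECT
) -> ProteinRegistry:
    """Read a species-coded FASTA file into a registry (file order kept)."""
    records = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        species, pid, desc = parse_header(">" + seq_rec.description, dialect)
        records.append(
            ProteinRecord(
                id=pid, species=species, sequence=str(seq_rec.seq), description=desc
            )
        )
    if not records:
        raise EmptyInputError(f"no FASTA entries in {path}")
    return ProteinRegistry(records)


def write_fasta(
    registry: ProteinRegistry,
    path: str | Path,
    dialect: HeaderDialect = DEFAULT_DIALECT,
    width: int = 60,
) -> None:
    seq_records = [
        SeqRecord(
            Seq(rec.sequence or ""),
            id=dialect.format(rec.species, rec.id),
            description=rec.description,
        )
        for rec in registry
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# group map TSV
# ---------------------------------------------------------------------------


def read_group_map(
    path: str | Path, has_header: bool = False
) -> dict[str, tuple[str, str]]:
    """Read ``protein_id<TAB>species<TAB>group_id`` into a mapping.

    An empty group field marks the protein as ungrouped (it will receive a
    private singleton group at evaluation time). Rows with a wrong column
    count raise :class:`ParseError` with the line number.
    """
    mapping: dict[str, tuple[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and has_header:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            pid, species, group = fields
            if pid in mapping:
                raise DuplicateRecordError(f"{path}:{lineno}: duplicate id {pid!r}")
            mapping[pid] = (species, group)
    if not mapping:
        raise EmptyInputError(f"no rows in group map {path}")
    return mapping


def write_group_map(registry: ProteinRegistry, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in registry:
            fh.write(f"{rec.id}\t{rec.species}\t{rec.group or ''}\n")


def registry_from_group_map(mapping: Mapping[str, tuple[str, str]]) -> ProteinRegistry:
    """Build a registry (no sequences) directly from a group map."""
    return ProteinRegistry(
        ProteinRecord(id=pid, species=species, group=group or None)
        for pid, (species, group) in mapping.items()
    )


# ---------------------------------------------------------------------------
# embedding table TSV
# ---------------------------------------------------------------------------


def read_embedding_table(path: str | Path, delimiter: str = "\t") -> EmbeddingMatrix:
    """Read a delimited table ``protein_id v1 .. vp`` into a matrix.

    All rows must have the same dimension; every value must be finite.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    p: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected an id and at least one value"
                )
            pid, values = fields[0], fields[1:]
            if p is None:
                p = len(values)
            elif len(values) != p:
                raise DimensionMismatchError(
                    f"{path}:{lineno}: row has {len(values)} values, expected {p}"
                )
            parsed = []
            for col, tok in enumerate(values, start=2):
                try:
                    x = float(tok)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: column {col}: not a number: {tok!r}"
                    ) from exc
                if not math.isfinite(x):
                    raise ParseError(
                        f"{path}:{lineno}: column {col}: non-finite value {tok!r}"
                    )
                parsed.append(x)
            ids.append(pid)
            rows.append(np.asarray(parsed))
    if not rows:
        raise EmptyInputError(f"no rows in embedding table {path}")
    return EmbeddingMatrix(ids, np.vstack(rows))


def write_embedding_table(
    matrix: EmbeddingMatrix, path: str | Path, delimiter: str = "\t", fmt: str = "%.10g"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, row in zip(matrix.ids, matrix.values):
            fh.write(pid + delimiter + delimiter.join(fmt % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# prediction outputs
# ---------------------------------------------------------------------------


def write_pairs_tsv(pairs, path: str | Path) -> None:
    """Write a PairSet as ``id_a id_b cluster_label mode`` (sorted rows)."""
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), (label, mode) in sorted(pairs.items()):
            fh.write(f"{a}\t{b}\t{label}\t{mode}\n")


def read_pairs_tsv(path: str | Path):
    from .pairing import PairSet  # local import to avoid a cycle

    ps = PairSet()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            a, b, label, mode = fields
            ps.add(a, b, label, mode)
    return ps


def write_groups_tsv(groups: Sequence[Sequence[str]], path: str | Path) -> None:
    """Write predicted groups as ``cluster_label<TAB>protein_id`` rows."""
    with open(path, "w", encoding="utf-8") as fh:
        for label, members in enumerate(groups):
            for pid in sorted(members):
                fh.write(f"{label}\t{pid}\n")


def read_groups_tsv(path: str | Path) -> list[frozenset[str]]:
    by_label: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            label, pid = fields
            by_label.setdefault(label, set()).add(pid)
    if not by_label:
        raise EmptyInputError(f"no rows in groups file {path}")
    return [frozenset(v) for _, v in sorted(by_label.items())]


def write_json_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
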