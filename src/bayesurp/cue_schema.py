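"""Cue inventory, clause data model, and corpus I/O.

A *clause record* describes one transitive clause by the linguistic cues of
its two NP arguments (animacy, givenness, definiteness, number, person,
pronominality, case, text deixis, length), of its verb (volitionality,
experiencer semantics, causativity, possessivity, presence of auxiliaries),
and of the clause itself (embedding, verb-before-arguments order), together
with the observed constituent order: SO (subject before object, the
actor-initial interpretation) or OS (object before subject, undergoer-initial).

Corpora are delimited tables with one clause per row and columns named
``np1_<cue>``, ``verb_<cue>``, ``np2_<cue>``, ``clause_<cue>``, ``order`` and
``genre``.  Swedish marks case only on pronouns, so any record with a
case-marked lexical NP is rejected as inconsistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("bayesurp.cue_schema")

ORDER_COLUMN = "order"
GENRE_COLUMN = "genre"
ORDER_LEVELS = ("SO", "OS")


class SchemaError(ValueError):
    """A corpus file does not have the expected column set."""


class CorpusValidationError(ValueError):
    """One or more rows violate the cue inventory or clause invariants."""

    def __init__(self, diagnostics: Sequence["RowDiagnostic"]):
        self.diagnostics = list(diagnostics)
        lines = "\n".join(f"  row {d.row}: {d.reason}" for d in self.diagnostics[:20])
        more = "" if len(self.diagnostics) <= 20 else f"\n  ... {len(self.diagnostics) - 20} more"
        super().__init__(f"{len(self.diagnostics)} invalid corpus row(s):\n{lines}{more}")


@dataclass(frozen=True)
class RowDiagnostic:
    row: int
    column: str
    reason: str


@dataclass(frozen=True)
class CueDescriptor:
    """One cue: its name, measurement role, and level set.

    ``kind`` is ``"binary"`` (two levels, first one is coded +0.5),
    ``"three_level"`` (case: unmarked / subject / object) or ``"continuous"``
    (length in words, a non-negative integer).
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "three_level", "continuous"):
            raise ValueError(f"unknown cue kind {self.kind!r}")
        if self.kind == "binary" and len(self.levels) != 2:
            raise ValueError(f"binary cue {self.name!r} needs exactly 2 levels")
        if self.kind == "three_level" and len(self.levels) != 3:
            raise ValueError(f"three-level cue {self.name!r} needs exactly 3 levels")


def _np_cues() -> tuple[CueDescriptor, ...]:
    return (
        CueDescriptor("animacy", "binary", ("animate", "inanimate")),
        CueDescriptor("givenness", "binary", ("given", "new")),
        CueDescriptor("definiteness", "binary", ("definite", "indefinite")),
        CueDescriptor("number", "binary", ("singular", "plural")),
        # person/egophoricity: 1st and 2nd ("local") vs. 3rd person
        CueDescriptor("person", "binary", ("local", "third")),
        CueDescriptor("pronominality", "binary", ("pronominal", "lexical")),
        CueDescriptor("case", "three_level", ("unmarked", "subject", "object")),
        CueDescriptor("deixis", "binary", ("deictic", "other")),
        CueDescriptor("length", "continuous"),
    )


def _verb_cues() -> tuple[CueDescriptor, ...]:
    return tuple(
        CueDescriptor(name, "binary", ("yes", "no"))
        for name in ("volitional", "experiencer", "causative", "possessive", "auxiliary")
    )


def _clause_cues() -> tuple[CueDescriptor, ...]:
    return (
        CueDescriptor("embedded", "binary", ("embedded", "main")),
        CueDescriptor("verb_initial", "binary", ("verb_initial", "verb_medial")),
    )


@dataclass(frozen=True)
class CueInventory:
    """The full cue inventory: NP cues (applied to NP1 and NP2), verb cues
    and clause-level cues."""

    np_cues: tuple[CueDescriptor, ...] = field(default_factory=_np_cues)
    verb_cues: tuple[CueDescriptor, ...] = field(default_factory=_verb_cues)
    clause_cues: tuple[CueDescriptor, ...] = field(default_factory=_clause_cues)

    def __post_init__(self) -> None:
        for scope_cues in (self.np_cues, self.verb_cues, self.clause_cues):
            names = [c.name for c in scope_cues]
            if len(names) != len(set(names)):
                raise ValueError("duplicate cue name within a scope")

    def columns(self) -> list[str]:
        """Canonical column order for a corpus table."""
        cols = ["clause_id"]
        for prefix, cues in (("np1", self.np_cues), ("verb", self.verb_cues),
                             ("np2", self.np_cues), ("clause", self.clause_cues)):
            cols += [f"{prefix}_{c.name}" for c in cues]
        cols += [ORDER_COLUMN, GENRE_COLUMN]
        return cols

    def descriptor(self, column: str) -> CueDescriptor:
        prefix, _, name = column.partition("_")
        scope = {"np1": self.np_cues, "np2": self.np_cues,
                 "verb": self.verb_cues, "clause": self.clause_cues}.get(prefix)
        if scope is None:
            raise KeyError(column)
        for cue in scope:
            if cue.name == name:
                return cue
        raise KeyError(column)


DEFAULT_INVENTORY = CueInventory()


@dataclass
class ClauseRecord:
    """One transitive clause.  ``order_label`` may be ``None`` for
    prediction-only records, in which case NP2 cues may also be absent."""

    clause_id: str
    np1: dict[str, object]
    verb: dict[str, object]
    clause: dict[str, object]
    np2: dict[str, object] | None = None
    order_label: str | None = None
    genre: str | None = None

    def to_row(self, inventory: CueInventory = DEFAULT_INVENTORY) -> dict[str, object]:
        row: dict[str, object] = {"clause_id": self.clause_id}
        for prefix, cues, values in (("np1", inventory.np_cues, self.np1),
                                     ("verb", inventory.verb_cues, self.verb),
                                     ("np2", inventory.np_cues, self.np2 or {}),
                                     ("clause", inventory.clause_cues, self.clause)):
            for cue in cues:
                row[f"{prefix}_{cue.name}"] = values.get(cue.name)
        row[ORDER_COLUMN] = self.order_label
        row[GENRE_COLUMN] = self.genre
        return row


@dataclass
class CorpusTable:
    """A validated collection of clause records, backed by a DataFrame in
    canonical column order."""

    frame: pd.DataFrame
    inventory: CueInventory = field(default_factory=CueInventory)
    provenance: str = "<memory>"

    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> Iterator[ClauseRecord]:
        np_names = [c.name for c in self.inventory.np_cues]
        verb_names = [c.name for c in self.inventory.verb_cues]
        clause_names = [c.name for c in self.inventory.clause_cues]
        for _, row in self.frame.iterrows():
            np2 = {n: row[f"np2_{n}"] for n in np_names}
            if all(pd.isna(v) for v in np2.values()):
                np2 = None
            yield ClauseRecord(
                clause_id=str(row["clause_id"]),
                np1={n: row[f"np1_{n}"] for n in np_names},
                verb={n: row[f"verb_{n}"] for n in verb_names},
                np2=np2,
                clause={n: row[f"clause_{n}"] for n in clause_names},
                order_label=None if pd.isna(row[ORDER_COLUMN]) else str(row[ORDER_COLUMN]),
                genre=None if pd.isna(row[GENRE_COLUMN]) else str(row[GENRE_COLUMN]),
            )


def table_from_records(records: Sequence[ClauseRecord],
                       inventory: CueInventory = DEFAULT_INVENTORY,
                       validate: bool = True) -> CorpusTable:
    cols = inventory.columns()
    frame = pd.DataFrame([r.to_row(inventory) for r in records], columns=cols)
    table = CorpusTable(frame=frame, inventory=inventory, provenance="<records>")
    if validate:
        diags = validate_table(table)
        if diags:
            raise CorpusValidationError(diags)
    return table


# ---------------------------------------------------------------------------
# validation

def validate_table(table: CorpusTable) -> list[RowDiagnostic]:
    """Check every row against the inventory; one diagnostic per bad row.

    Invariants: categorical cells must be in the cue's level set; lengths are
    non-negative integers; case-marking other than 'unmarked' requires a
    pronominal NP (Swedish nouns are caseless); NP2 cues may be missing only
    when the order label is also missing (prediction-only prefix records);
    clause_ids are unique.
    """
    inv = table.inventory
    frame = table.frame
    expected = set(inv.columns())
    missing_cols = expected - set(frame.columns)
    if missing_cols:
        raise SchemaError(f"missing required column(s): {sorted(missing_cols)}")

    diags: list[RowDiagnostic] = []
    seen: dict[str, int] = {}
    np_names = [c.name for c in inv.np_cues]
    for idx, row in frame.iterrows():
        reason = _row_problem(row, inv, np_names)
        if reason is not None:
            diags.append(RowDiagnostic(row=int(idx), column=reason[0], reason=reason[1]))
            continue
        cid = str(row["clause_id"])
        if cid in seen:
            diags.append(RowDiagnostic(int(idx), "clause_id",
                                       f"duplicate clause_id {cid!r} (first at row {seen[cid]})"))
        else:
            seen[cid] = int(idx)
    return diags


def _row_problem(row: pd.Series, inv: CueInventory,
                 np_names: list[str]) -> tuple[str, str] | None:
    order = row[ORDER_COLUMN]
    has_order = not pd.isna(order)
    if has_order and order not in ORDER_LEVELS:
        return ORDER_COLUMN, f"unknown order label {order!r}"
    np2_cols = [f"np2_{n}" for n in np_names]
    np2_missing = [c for c in np2_cols if pd.isna(row[c])]
    if np2_missing and has_order:
        return np2_missing[0], "missing NP2 cue on a training record"
    if np2_missing and len(np2_missing) != len(np2_cols):
        return np2_missing[0], "partially missing NP2 cues"
    np2_absent = len(np2_missing) == len(np2_cols)

    for prefix in ("np1", "verb", "np2", "clause"):
        cues = {"np1": inv.np_cues, "np2": inv.np_cues,
                "verb": inv.verb_cues, "clause": inv.clause_cues}[prefix]
        if prefix == "np2" and np2_absent:
            continue
        for cue in cues:
            col = f"{prefix}_{cue.name}"
            value = row[col]
            if pd.isna(value):
                return col, "missing value"
            if cue.kind == "continuous":
                try:
                    length = int(value)
                except (TypeError, ValueError):
                    return col, f"length {value!r} is not an integer"
                if length < 0 or length != float(value):
                    return col, f"length {value!r} is not a non-negative integer"
            elif value not in cue.levels:
                return col, f"unknown level {value!r} (expected one of {cue.levels})"
        if prefix in ("np1", "np2") and not (prefix == "np2" and np2_absent):
            case = row[f"{prefix}_case"]
            pron = row[f"{prefix}_pronominality"]
            if case in ("subject", "object") and pron == "lexical":
                return (f"{prefix}_case",
                        f"case-marked lexical NP ({prefix}_case={case!r}); "
                        "Swedish marks case only on pronouns")
    return None


# ---------------------------------------------------------------------------
# I/O

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_corpus(path: str | Path,
                inventory: CueInventory = DEFAULT_INVENTORY,
                column_map: Mapping[str, str] | None = None,
                level_map: Mapping[str, Mapping[str, str]] | None = None,
                on_invalid: str = "raise") -> CorpusTable:
    """Read and validate a corpus table.

    Parameters
    ----------
    column_map
        Optional mapping from canonical column names to the names used in the
        file, so externally deposited tables can be ingested without editing.
    level_map
        Optional per-column mapping from file level spellings to canonical
        level names.
    on_invalid
        ``"raise"`` (default) raises :class:`CorpusValidationError` listing
        every bad row; ``"drop"`` logs each diagnostic and keeps valid rows.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=object,
                        keep_default_na=False, na_values=[""])
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    expected = inventory.columns()
    missing = set(expected) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {sorted(missing)}")
    frame = frame[expected]
    if level_map:
        for col, mapping in level_map.items():
            frame[col] = frame[col].map(lambda v: mapping.get(v, v))
    for col in frame.columns:
        if col.endswith("_length"):
            frame[col] = pd.to_numeric(frame[col], errors="coerce")

    table = CorpusTable(frame=frame.reset_index(drop=True), inventory=inventory,
                        provenance=str(path))
    diags = validate_table(table)
    if diags:
        if on_invalid == "raise":
            raise CorpusValidationError(diags)
        if on_invalid != "drop":
            raise ValueError(f"unknown on_invalid mode {on_invalid!r}")
        for d in diags:
            logger.warning("%s: dropping row %d (%s: %s)", path, d.row, d.column, d.reason)
        bad = {d.row for d in diags}
        table.frame = table.frame.drop(index=list(bad)).reset_index(drop=True)
    # normalize length dtypes to nullable integers after validation
    for col in table.frame.columns:
        if col.endswith("_length"):
            table.frame[col] = table.frame[col].astype("Int64")
    return table


def write_corpus(table: CorpusTable, path: str | Path) -> None:
    """Write a corpus table; ``read_corpus(write_corpus(t))`` is the identity."""
    path = Path(path)
    table.frame.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# summaries

def summarize_corpus(table: CorpusTable) -> dict:
    """Per-cue level frequencies plus OS proportion overall and per genre.

    Requires every record to carry an order label.
    """
    frame = table.frame
    if frame[ORDER_COLUMN].isna().any():
        raise ValueError("summarize_corpus requires order labels on all records")
    n = len(frame)
    os_overall = float((frame[ORDER_COLUMN] == "OS").mean()) if n else float("nan")
    by_genre = {
        str(genre): float((sub[ORDER_COLUMN] == "OS").mean())
        for genre, sub in frame.groupby(GENRE_COLUMN, dropna=False)
    }
    level_freqs: dict[str, dict[str, float]] = {}
    for col in table.inventory.columns():
        if col in ("clause_id", ORDER_COLUMN, GENRE_COLUMN) or col.endswith("_length"):
            continue
        counts = frame[col].value_counts(normalize=True, dropna=True)
        level_freqs[col] = {str(k): float(v) for k, v in counts.items()}
    return {
        "n_clauses": n,
        "os_proportion": os_overall,
        "os_proportion_by_genre": by_genre,
        "level_frequencies": level_freqs,
    }
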