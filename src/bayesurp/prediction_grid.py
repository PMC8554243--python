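"""Model predictions over arbitrary cue combinations.

The staged models make predictions for any combination of cue values,
attested or not, without refitting: a grid query holds some cues fixed and
enumerates others over their level sets, and each combination is pushed
through the belief-trajectory machinery.  Combinations that violate clause
invariants (e.g., a case-marked lexical NP) are skipped with a log entry so
that factorial queries remain usable.

``design_predictions`` evaluates the 2x2x2 reading-experiment design
(constituent order x object animacy x verb class) and returns the predicted
per-region Bayesian surprise that drives the SPR simulation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .cue_schema import CorpusTable, CueInventory, DEFAULT_INVENTORY, validate_table
from .stage_models import PosteriorFit
from .surprise_engine import OUTPUT_COLUMNS, REGIONS, batch_trajectories
from .synthetic_data import FixtureItem, fixture_item

logger = logging.getLogger("bayesurp.grid")

DEFAULT_CAP = 1_000_000


class GridSizeError(ValueError):
    """Raised when an in-memory enumeration would exceed the row cap."""


@dataclass
class GridQuery:
    """A grid of cue combinations.

    ``fixed`` maps corpus-format columns (``np1_animacy`` ...) to constant
    values; ``varying`` is either a list of columns (levels taken from the
    inventory) or a mapping column -> explicit candidate values (required
    for continuous cues).  ``regions`` selects which surprise regions to
    report.
    """

    fixed: dict[str, object]
    varying: Mapping[str, Sequence[object]] | Sequence[str] = ()
    regions: tuple[str, ...] = REGIONS
    cap: int = DEFAULT_CAP

    def resolved_varying(self, inventory: CueInventory) -> dict[str, list[object]]:
        if isinstance(self.varying, Mapping):
            items = {k: list(v) for k, v in self.varying.items()}
        else:
            items = {}
            for col in self.varying:
                cue = inventory.descriptor(col)
                if cue.kind == "continuous":
                    raise ValueError(
                        f"continuous cue {col!r} needs explicit candidate values")
                items[col] = list(cue.levels)
        for col in items:
            inventory.descriptor(col)  # raises KeyError on unknown cues
        return items

    def n_combinations(self, inventory: CueInventory) -> int:
        sizes = [len(v) for v in self.resolved_varying(inventory).values()]
        return int(np.prod(sizes)) if sizes else 1


def _combo_frames(query: GridQuery, inventory: CueInventory,
                  chunk_size: int) -> Iterator[pd.DataFrame]:
    varying = query.resolved_varying(inventory)
    names = list(varying)
    combos = itertools.product(*varying.values()) if names else iter([()])
    counter = itertools.count()
    columns = inventory.columns()
    while True:
        chunk = list(itertools.islice(combos, chunk_size))
        if not chunk:
            return
        rows = []
        for combo in chunk:
            row = {c: None for c in columns}
            row.update(query.fixed)
            row.update(dict(zip(names, combo)))
            row["clause_id"] = f"grid{next(counter):08d}"
            rows.append(row)
        yield pd.DataFrame(rows, columns=columns)


def _predict_chunk(frame: pd.DataFrame, query: GridQuery,
                   fits: Mapping[str, PosteriorFit],
                   inventory: CueInventory) -> pd.DataFrame:
    table = CorpusTable(frame=frame.reset_index(drop=True), inventory=inventory)
    diags = validate_table(table)
    if diags:
        for d in diags[:5]:
            logger.info("grid: skipping combination (%s: %s)", d.column, d.reason)
        if len(diags) > 5:
            logger.info("grid: ... %d further combinations skipped", len(diags) - 5)
        bad = {d.row for d in diags}
        table.frame = table.frame.drop(index=list(bad)).reset_index(drop=True)
    if not len(table.frame):
        varying_cols = list(query.resolved_varying(inventory))
        return pd.DataFrame(columns=varying_cols + OUTPUT_COLUMNS)
    traj = batch_trajectories(table, fits)
    traj = traj[traj["region"].isin(query.regions)]
    varying_cols = list(query.resolved_varying(inventory))
    meta = table.frame[["clause_id"] + varying_cols]
    return meta.merge(traj, on="clause_id", how="inner")


def enumerate_grid(query: GridQuery, fits: Mapping[str, PosteriorFit],
                   inventory: CueInventory = DEFAULT_INVENTORY,
                   chunk_size: int = 256) -> pd.DataFrame:
    """Materialize predictions for every combination of the query.

    One output row per valid combination x region, with the varying cue
    columns alongside the trajectory schema.  Raises :class:`GridSizeError`
    above the row cap — use :func:`stream_grid` for larger enumerations.
    """
    n = query.n_combinations(inventory)
    if n > query.cap:
        raise GridSizeError(
            f"{n} combinations exceed the cap of {query.cap}; "
            "use stream_grid() for lazy enumeration")
    pieces = [_predict_chunk(frame, query, fits, inventory)
              for frame in _combo_frames(query, inventory, chunk_size)]
    pieces = [p for p in pieces if len(p)]
    if not pieces:
        return pd.DataFrame(
            columns=list(query.resolved_varying(inventory)) + OUTPUT_COLUMNS)
    return pd.concat(pieces, ignore_index=True)


def stream_grid(query: GridQuery, fits: Mapping[str, PosteriorFit],
                path: str | Path,
                inventory: CueInventory = DEFAULT_INVENTORY,
                chunk_size: int = 256) -> int:
    """Stream predictions to a delimited file without materializing the grid;
    returns the number of rows written.  Produces exactly the rows
    :func:`enumerate_grid` would."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    written = 0
    header = True
    with open(path, "w") as fh:
        for frame in _combo_frames(query, inventory, chunk_size):
            out = _predict_chunk(frame, query, fits, inventory)
            out.to_csv(fh, sep=sep, index=False, header=header)
            header = False
            written += len(out)
    return written


# ---------------------------------------------------------------------------
# the 2x2x2 experimental design

def design_predictions(fits: Mapping[str, PosteriorFit],
                       item: FixtureItem | None = None) -> pd.DataFrame:
    """Predicted Bayesian surprise for the 8 design conditions x 3 regions.

    Returns a tidy frame with columns (order, object_animacy, verb_class,
    region, dkl, dkl_lo, dkl_hi, p_os) — the input both for qualitative
    design checks and for the SPR simulator.
    """
    item = item or fixture_item()
    records = list(item.records.values())
    table_frame = pd.DataFrame([r.to_row(fits["np1"].inventory) for r in records])
    table = CorpusTable(frame=table_frame, inventory=fits["np1"].inventory)
    traj = batch_trajectories(table, fits)
    cond = pd.DataFrame(
        [{"clause_id": rec.clause_id, "order": key[0], "object_animacy": key[1],
          "verb_class": key[2]} for key, rec in item.records.items()])
    out = cond.merge(traj, on="clause_id")
    out = out.rename(columns={"dkl_mean": "dkl", "p_os_mean": "p_os"})
    return out[["order", "object_animacy", "verb_class", "region",
                "dkl", "dkl_lo", "dkl_hi", "p_os"]]
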