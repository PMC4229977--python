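"""Motif libraries and batch searches over many structures.

A library is a directory (or several) of motif files, filterable by
template-set label (P = developer-provided, U = user-made, J/N reserved).
Batch mode runs the cross product of structures × motifs and flattens
every scored match into one CSV record, with per-structure error
isolation so a single malformed input cannot abort a long run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .finder import SearchOptions, find_matches
from .motif import Motif, MotifError, load_motif, validate_motif
from .scoring import rank_matches, score_match
from .structure import Structure

__all__ = [
    "MotifLibrary",
    "ResultRecord",
    "load_library",
    "batch_search",
    "write_results",
    "ec_match_level",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

MOTIF_SUFFIXES = (".yaml", ".yml", ".motif")

RESULT_COLUMNS = [
    "query_id", "motif_id", "motif_ec", "levenshtein",
    "rmsd_all", "rmsd_ca", "rmsd_ca_cb",
    "n_substitutions", "n_unmatched", "assignment",
]


class LibraryError(ValueError):
    """Raised when a motif library cannot be assembled."""


@dataclass
class MotifLibrary:
    motifs: list[Motif] = field(default_factory=list)
    sources: dict[str, Path] = field(default_factory=dict)

    @property
    def set_labels(self) -> set[str]:
        return {m.set_label for m in self.motifs}

    def __len__(self) -> int:
        return len(self.motifs)


@dataclass
class ResultRecord:
    query_id: str
    motif_id: str
    motif_ec: str
    levenshtein: int
    rmsd_all: float
    rmsd_ca: float
    rmsd_ca_cb: float
    n_substitutions: int
    n_unmatched: int
    assignment: str


def load_library(
    directories: list[str | Path] | str | Path,
    set_filter: set[str] | None = None,
) -> MotifLibrary:
    """Load every valid motif file under the given directories.

    Files that fail to parse or validate are skipped with a warning;
    duplicate motif ids across files are a hard error.  An empty result
    after filtering raises :class:`LibraryError`.
    """
    if isinstance(directories, (str, Path)):
        directories = [directories]
    lib = MotifLibrary()
    n_files = 0
    for d in directories:
        d = Path(d)
        if not d.is_dir():
            raise LibraryError(f"motif directory {d} does not exist")
        for path in sorted(p for p in d.iterdir()
                           if p.is_file() and p.suffix in MOTIF_SUFFIXES):
            n_files += 1
            try:
                motif = load_motif(path)
            except MotifError as exc:
                logger.warning("skipping unreadable motif file %s: %s", path, exc)
                continue
            if set_filter is not None and motif.set_label not in set_filter:
                continue
            if motif.motif_id in lib.sources:
                raise LibraryError(
                    f"duplicate motif_id {motif.motif_id!r} in "
                    f"{lib.sources[motif.motif_id]} and {path}"
                )
            lib.motifs.append(motif)
            lib.sources[motif.motif_id] = path
    if not lib.motifs:
        raise LibraryError(
            f"no usable motif files found ({n_files} candidate files, "
            f"set filter {sorted(set_filter) if set_filter else 'none'})"
        )
    return lib


def _format_assignment(motif: Motif, match) -> str:
    parts = []
    for res in match.assignment:
        parts.append("-" if res is None else f"{res.chain}:{res.seq_id}{res.icode}:{res.res_name}")
    return ";".join(parts)


def batch_search(
    structures: list[Structure],
    library: MotifLibrary,
    options: SearchOptions | None = None,
    compute_rmsd: bool = True,
) -> list[ResultRecord]:
    """Search every structure against every library motif.

    Records come out ordered by (query_id, motif_id, rank).  A failure on
    one structure is logged and skipped; the rest of the run proceeds.
    """
    options = options or SearchOptions()
    records: list[ResultRecord] = []
    for structure in structures:
        try:
            for motif in sorted(library.motifs, key=lambda m: m.motif_id):
                matches = find_matches(motif, structure, options)
                scored = rank_matches(
                    [score_match(motif, m, structure, compute_rmsd=compute_rmsd)
                     for m in matches]
                )
                for s in scored:
                    records.append(ResultRecord(
                        query_id=structure.struct_id,
                        motif_id=motif.motif_id,
                        motif_ec=motif.ec_number,
                        levenshtein=s.levenshtein,
                        rmsd_all=s.rmsd_all,
                        rmsd_ca=s.rmsd_ca,
                        rmsd_ca_cb=s.rmsd_ca_cb,
                        n_substitutions=s.match.n_substitutions,
                        n_unmatched=s.match.n_unmatched,
                        assignment=_format_assignment(motif, s.match),
                    ))
            if not any(r.query_id == structure.struct_id for r in records):
                logger.info("no matches for structure %s", structure.struct_id)
        except Exception:
            logger.exception("structure %s failed; continuing batch", structure.struct_id)
    records.sort(key=lambda r: (r.query_id, r.motif_id))
    return records


def results_frame(records: list[ResultRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [[getattr(r, c) for c in RESULT_COLUMNS] for r in records],
        columns=RESULT_COLUMNS,
    )
    return df


def write_results(records: list[ResultRecord], path: str | Path) -> Path:
    """Write records as CSV: fixed header, 3-decimal floats, NaN → empty."""
    path = Path(path)
    df = results_frame(records)
    df.to_csv(path, index=False, float_format="%.3f", na_rep="")
    return path


def ec_match_level(motif_ec: str, query_ec: str) -> int:
    """Number of leading EC components (0–4) on which two dotted EC
    classifications agree; a wildcard or missing component stops the count."""
    a = [p for p in str(motif_ec).split(".") if p != ""]
    b = [p for p in str(query_ec).split(".") if p != ""]
    level = 0
    for x, y in zip(a[:4], b[:4]):
        if x == "-" or y == "-" or x != y:
            break
        level += 1
    return level
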