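"""Core data container and import / target-setting operations.

A free-association study is represented as three linked tables:

``participants``
    one row per participant, with demographic covariates;
``cues``
    one row per distinct cue word or phrase;
``responses``
    one row per produced response token, in original production order,
    with a 1-based ``response_position`` within each (participant, cue)
    block and any response-level covariates (e.g. snowball ``level``).

After :func:`set_targets` the container additionally carries a ``targets``
table — the unit of analysis that every downstream stage (counting,
characterization, embedding, clustering, comparison) is restricted to —
and, after embedding, an :class:`~freeassoc.embedding.EmbeddingMatrix`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from .errors import IntegrityError, SchemaError, UsageError

if TYPE_CHECKING:  # pragma: no cover
    from .embedding import EmbeddingMatrix

logger = logging.getLogger(__name__)

TARGET_SOURCES = ("cues", "responses", "both")

MANIFEST_NAME = "manifest.json"
SCHEMA_VERSION = 1


@dataclass
class AssociationStudy:
    """Container threading a free-association study through the pipeline.

    Attributes
    ----------
    participants, cues, responses : pandas.DataFrame
        The three linked tables (see module docstring).
    targets : pandas.DataFrame or None
        Unit-of-analysis table, absent until :func:`set_targets`.
        Characterization stages append columns to it.
    embedding : EmbeddingMatrix or None
        Target embedding, absent until :func:`freeassoc.embedding.embed_targets`.
    meta : dict
        Provenance: targets source, normalization applied, seeds.
    """

    participants: pd.DataFrame
    cues: pd.DataFrame
    responses: pd.DataFrame
    targets: pd.DataFrame | None = None
    embedding: "EmbeddingMatrix | None" = None
    meta: dict = field(default_factory=dict)

    # -- convenience ---------------------------------------------------
    @property
    def has_targets(self) -> bool:
        return self.targets is not None

    def target_list(self) -> list[str]:
        if self.targets is None:
            raise UsageError("targets have not been set; call set_targets first")
        return self.targets["target"].tolist()

    def copy(self) -> "AssociationStudy":
        return AssociationStudy(
            participants=self.participants.copy(),
            cues=self.cues.copy(),
            responses=self.responses.copy(),
            targets=None if self.targets is None else self.targets.copy(),
            embedding=self.embedding,
            meta=dict(self.meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationStudy):
            return NotImplemented
        for a, b in (
            (self.participants, other.participants),
            (self.cues, other.cues),
            (self.responses, other.responses),
        ):
            if not a.reset_index(drop=True).equals(b.reset_index(drop=True)):
                return False
        if (self.targets is None) != (other.targets is None):
            return False
        if self.targets is not None and not self.targets.reset_index(
            drop=True
        ).equals(other.targets.reset_index(drop=True)):
            return False
        return True


def _require_columns(frame: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"input table is missing required column(s): {', '.join(missing)}"
        )


def _dedupe_covariates(
    frame: pd.DataFrame, key: str, covariates: Sequence[str], what: str
) -> pd.DataFrame:
    """One row per key; conflicting covariate values are a hard error.

    Silent first-wins resolution would corrupt group comparisons, so any
    key carrying two distinct values for a covariate aborts the import.
    """
    sub = frame[[key, *covariates]].drop_duplicates()
    counts = sub.groupby(key, sort=False).size()
    conflicting = counts[counts > 1].index.tolist()
    if conflicting:
        shown = ", ".join(map(str, conflicting[:10]))
        raise IntegrityError(
            f"conflicting covariate values for {what}(s): {shown}"
        )
    return sub.reset_index(drop=True)


def import_study(
    raw: pd.DataFrame,
    participant_col: str = "participant_id",
    cue_col: str = "cue",
    response_col: str = "response",
    participant_vars: Sequence[str] = (),
    cue_vars: Sequence[str] = (),
    response_vars: Sequence[str] = (),
) -> AssociationStudy:
    """Import long-format response data into an :class:`AssociationStudy`.

    ``raw`` must contain one row per response token.  The three key
    columns are renamed to the canonical ``participant_id`` / ``cue`` /
    ``response``.  Rows whose response is empty after trimming are
    dropped (with a logged count).  If no ``response_position`` column is
    supplied, positions are assigned 1..n within each (participant, cue)
    block in file order.

    Raises
    ------
    SchemaError
        A named column is missing from ``raw``.
    IntegrityError
        A participant (or cue) carries conflicting covariate values.
    """
    _require_columns(raw, [participant_col, cue_col, response_col])
    _require_columns(raw, list(participant_vars) + list(cue_vars) + list(response_vars))

    frame = raw.rename(
        columns={
            participant_col: "participant_id",
            cue_col: "cue",
            response_col: "response",
        }
    ).copy()
    for col in ("participant_id", "cue", "response"):
        frame[col] = frame[col].astype(str)

    trimmed = frame["response"].str.strip()
    empty = (trimmed == "") | frame["response"].isna()
    if empty.any():
        logger.info("dropping %d rows with empty responses", int(empty.sum()))
        frame = frame.loc[~empty].reset_index(drop=True)

    response_cols = ["participant_id", "cue", "response", *response_vars]
    responses = frame[response_cols].copy()
    if "response_position" not in responses.columns:
        responses["response_position"] = (
            responses.groupby(["participant_id", "cue"], sort=False).cumcount() + 1
        )

    participants = _dedupe_covariates(
        frame, "participant_id", list(participant_vars), "participant"
    )
    cues = _dedupe_covariates(frame, "cue", list(cue_vars), "cue")

    return AssociationStudy(
        participants=participants,
        cues=cues,
        responses=responses,
        meta={"schema_version": SCHEMA_VERSION},
    )


def set_targets(study: AssociationStudy, source: str = "cues") -> AssociationStudy:
    """Fix the unit of analysis: unique strings from cues, responses or both.

    Ordering is first-occurrence order (cues first when ``source='both'``).
    All downstream analyses are restricted to this set; the source is
    recorded in ``study.meta['targets_source']`` because response-based
    embeddings are only feasible when targets are drawn from cues alone.
    """
    if source not in TARGET_SOURCES:
        raise UsageError(
            f"unknown targets source {source!r}; expected one of {TARGET_SOURCES}"
        )
    out = study.copy()
    parts: list[pd.Series] = []
    if source in ("cues", "both"):
        parts.append(out.cues["cue"])
    if source in ("responses", "both"):
        parts.append(out.responses["response"])
    seen: dict[str, None] = {}
    for series in parts:
        for value in series:
            seen.setdefault(value, None)
    out.targets = pd.DataFrame({"target": list(seen)})
    out.meta["targets_source"] = source
    out.embedding = None
    return out


# -- serialization -----------------------------------------------------

_TABLES = ("participants", "cues", "responses", "targets")


def save_study(study: AssociationStudy, directory: str | Path) -> Path:
    """Serialize a study as a directory of CSVs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        table = getattr(study, name)
        if table is not None:
            table.to_csv(directory / f"{name}.csv", index=False)
    if study.embedding is not None:
        study.embedding.to_csv(
            directory / "embedding.csv", directory / "embedding.json"
        )
    manifest = {"schema_version": SCHEMA_VERSION, **study.meta}
    manifest["tables"] = [
        name for name in _TABLES if getattr(study, name) is not None
    ]
    manifest["has_embedding"] = study.embedding is not None
    (directory / MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return directory


def load_study(directory: str | Path) -> AssociationStudy:
    """Load a study saved by :func:`save_study` (string-for-string)."""
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise SchemaError(f"no study manifest found in {directory}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))

    def _read(name: str) -> pd.DataFrame:
        return pd.read_csv(
            directory / f"{name}.csv", dtype=str, keep_default_na=False
        )

    tables = {}
    for name in _TABLES:
        if name in manifest.get("tables", []):
            tables[name] = _read(name)
        else:
            tables[name] = None
    responses = tables["responses"]
    if responses is not None and "response_position" in responses.columns:
        responses["response_position"] = responses["response_position"].astype(int)
    targets = tables["targets"]
    if targets is not None:
        # re-infer numeric characterization columns saved as text
        for col in targets.columns:
            if col in ("target", "cluster"):
                continue
            nonblank = targets[col] != ""
            converted = pd.to_numeric(targets[col].where(nonblank), errors="coerce")
            if converted[nonblank].notna().all():
                targets[col] = converted
    embedding = None
    if manifest.get("has_embedding"):
        from .embedding import EmbeddingMatrix

        embedding = EmbeddingMatrix.from_csv(
            directory / "embedding.csv", directory / "embedding.json"
        )
    meta = {
        k: v
        for k, v in manifest.items()
        if k not in ("tables", "has_embedding")
    }
    return AssociationStudy(
        participants=tables["participants"],
        cues=tables["cues"],
        responses=responses,
        targets=targets,
        embedding=embedding,
        meta=meta,
    )
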