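"""Group comparison of mental representations.

Three levels of contrast between participant groups:

* cluster level — :func:`cross_targets` counts response tokens per
  (group, target category) and optionally normalizes rows to proportions;
* target-characteristic level — :func:`compare_targets` aggregates a
  continuous target characteristic over each group's response tokens,
  so frequent targets weigh in proportionally;
* representation level — :func:`compare_embeddings` rebuilds a
  response-based embedding per group and correlates the groups'
  cosine-similarity matrices (Spearman), i.e. representational
  similarity analysis.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .clustering import cosine_similarity_matrix
from .embedding import _count_matrix, default_n_dim, ppmi, svd_embed
from .errors import SchemaError, StateError, UsageError
from .study import AssociationStudy

logger = logging.getLogger(__name__)

RSA_TYPES = ("lower_triangle", "row_wise")


def _require_targets_column(study: AssociationStudy, column: str) -> pd.Series:
    if study.targets is None:
        raise StateError("targets have not been set")
    if column not in study.targets.columns:
        raise SchemaError(f"targets table has no column {column!r}")
    return study.targets.set_index("target")[column]


def _tokens_with_groups(
    study: AssociationStudy, participant_var: str
) -> pd.DataFrame:
    if participant_var not in study.participants.columns:
        raise SchemaError(f"participants table has no column {participant_var!r}")
    groups = study.participants.set_index("participant_id")[participant_var]
    tokens = study.responses[["participant_id", "response"]].copy()
    tokens["group"] = tokens["participant_id"].map(groups)
    return tokens


def cross_targets(
    study: AssociationStudy,
    participant_var: str,
    target_var: str = "cluster",
    normalize: bool = False,
) -> pd.DataFrame:
    """Cross-tabulate response tokens by participant group x target category.

    Cell (g, c) counts the response tokens produced by participants in
    group g whose response is a target in category c (tokens whose
    response is not a target, or whose target lacks a category, are out
    of scope).  With ``normalize=True`` rows are divided by their totals;
    a group with zero in-scope tokens gets a NaN row.
    """
    category = _require_targets_column(study, target_var)
    if pd.api.types.is_float_dtype(category) and category.nunique() > 20:
        raise UsageError(
            f"target variable {target_var!r} looks continuous; use "
            "compare_targets for frequency-weighted summaries"
        )
    tokens = _tokens_with_groups(study, participant_var)
    tokens["category"] = tokens["response"].map(category)
    tokens = tokens.dropna(subset=["category"])
    table = pd.crosstab(tokens["group"], tokens["category"])
    # keep every group level, including ones with zero in-scope tokens
    all_groups = pd.unique(study.participants[participant_var])
    table = table.reindex(sorted(all_groups), fill_value=0)
    table.index.name = participant_var
    table.columns.name = target_var
    if normalize:
        totals = table.sum(axis=1)
        table = table.div(totals, axis=0)
        table[totals == 0] = np.nan
    return table


def compare_targets(
    study: AssociationStudy,
    participant_var: str,
    target_var: str,
    fun: Callable | str = "mean",
) -> pd.DataFrame:
    """Frequency-weighted group summary of a continuous target characteristic.

    Every response token contributes its target's characteristic value
    once, so the aggregate reflects what each group actually retrieved.
    Tokens whose target lacks the characteristic are excluded and counted
    in the ``n_missing`` coverage column.
    """
    values = _require_targets_column(study, target_var)
    if not pd.api.types.is_numeric_dtype(values):
        raise UsageError(f"target variable {target_var!r} must be numeric")
    tokens = _tokens_with_groups(study, participant_var)
    tokens["value"] = tokens["response"].map(values)
    in_target = tokens["response"].isin(values.index)
    tokens = tokens[in_target]
    rows = []
    for group, chunk in tokens.groupby("group", sort=True):
        present = chunk["value"].dropna()
        n_missing = int(chunk["value"].isna().sum())
        if present.empty:
            warnings.warn(
                f"group {group!r}: no tokens with a {target_var!r} value",
                stacklevel=2,
            )
            summary = np.nan
        else:
            summary = float(present.agg(fun))
        rows.append((group, summary, len(present), n_missing))
    return pd.DataFrame(
        rows, columns=[participant_var, target_var, "n_tokens", "n_missing"]
    )


@dataclass
class RSAResult:
    """Representational similarity between two participant groups."""

    variable: str
    group_a: str
    group_b: str
    rho: float
    type: str
    shared_target_count: int


def _group_embedding_vectors(
    study: AssociationStudy,
    participant_ids: set[str],
    n_dim: int,
    smoothing: float | None,
) -> pd.DataFrame:
    """Response-based embedding built from one group's responses only."""
    responses = study.responses[
        study.responses["participant_id"].isin(participant_ids)
    ]
    targets = study.target_list()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-response targets drop silently here
        counts = _count_matrix(responses, targets)
    weighted = ppmi(counts, smoothing=smoothing)
    k = min(n_dim, min(weighted.shape))
    emb = svd_embed(weighted, k, labels=counts.row_labels)
    return emb.to_frame()


def _rsa_rho(
    frame_a: pd.DataFrame, frame_b: pd.DataFrame, rsa_type: str
) -> tuple[float, int]:
    shared = [t for t in frame_a.index if t in set(frame_b.index)]
    if len(shared) < 3:
        raise UsageError(
            f"only {len(shared)} shared embeddable targets; representational "
            "comparison needs at least 3"
        )
    sims_a = cosine_similarity_matrix(shared, frame_a.loc[shared].to_numpy()).values
    sims_b = cosine_similarity_matrix(shared, frame_b.loc[shared].to_numpy()).values
    n = len(shared)
    if rsa_type == "lower_triangle":
        tri = np.tril_indices(n, k=-1)
        rho = spearmanr(sims_a[tri], sims_b[tri]).statistic
    else:  # row_wise: mean over targets of per-row rank correlation
        off = ~np.eye(n, dtype=bool)
        rhos = [
            spearmanr(sims_a[i, off[i]], sims_b[i, off[i]]).statistic
            for i in range(n)
        ]
        rho = float(np.nanmean(rhos))
    return float(rho), n


def compare_embeddings(
    study: AssociationStudy,
    participant_vars: Sequence[str] | str,
    type: str = "lower_triangle",
    n_dim: int | None = None,
    smoothing: float | None = None,
) -> list[RSAResult]:
    """Representational similarity analysis between participant groups.

    For every level of each variable (and, with several variables, every
    level combination) a group-specific PPMI-SVD embedding is rebuilt
    from that group's responses alone; each pair of groups is then
    compared via the Spearman correlation of their cosine-similarity
    matrices, restricted to targets embeddable in both groups
    (``shared_target_count`` records the comparison basis).

    ``n_dim`` and ``smoothing`` default to the pooled embedding's
    settings when one is present.
    """
    if type not in RSA_TYPES:
        raise UsageError(f"type must be one of {RSA_TYPES}")
    if isinstance(participant_vars, str):
        participant_vars = [participant_vars]
    if study.targets is None:
        raise StateError("targets must be set before comparing embeddings")
    if study.meta.get("targets_source", "cues") != "cues":
        raise UsageError(
            "representational comparison requires response-based embeddings, "
            "hence targets drawn from cues only"
        )
    if n_dim is None:
        if study.embedding is not None and study.embedding.method == "ppmi-svd":
            n_dim = study.embedding.n_dim
        else:
            n_targets = len(study.target_list())
            n_dim = default_n_dim(n_targets, n_targets)

    groupings: list[tuple[str, pd.Series]] = []
    for var in participant_vars:
        if var not in study.participants.columns:
            raise SchemaError(f"participants table has no column {var!r}")
        groupings.append((var, study.participants[var].astype(str)))
    if len(participant_vars) > 1:
        combo = study.participants[list(participant_vars)].astype(str).agg(
            " x ".join, axis=1
        )
        groupings.append((" x ".join(participant_vars), combo))

    results: list[RSAResult] = []
    for var, series in groupings:
        frames: dict[str, pd.DataFrame] = {}
        for level in sorted(series.unique()):
            ids = set(study.participants.loc[series == level, "participant_id"])
            frames[level] = _group_embedding_vectors(study, ids, n_dim, smoothing)
        for a, b in itertools.combinations(sorted(frames), 2):
            rho, shared = _rsa_rho(frames[a], frames[b], type)
            results.append(
                RSAResult(
                    variable=var,
                    group_a=a,
                    group_b=b,
                    rho=rho,
                    type=type,
                    shared_target_count=shared,
                )
            )
    return results


def rsa_frame(results: Sequence[RSAResult]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of RSA results."""
    return pd.DataFrame(
        [
            (r.variable, r.group_a, r.group_b, r.rho, r.type, r.shared_target_count)
            for r in results
        ],
        columns=["variable", "group_a", "group_b", "rho", "type", "shared_targets"],
    )


def rsa_self(study: AssociationStudy, participant_var: str, level: str,
             type: str = "lower_triangle", n_dim: int | None = None) -> RSAResult:
    """Compare a group's representation with itself (a sanity identity)."""
    series = study.participants[participant_var].astype(str)
    ids = set(study.participants.loc[series == level, "participant_id"])
    if n_dim is None:
        n_targets = len(study.target_list())
        n_dim = default_n_dim(n_targets, n_targets)
    frame = _group_embedding_vectors(study, ids, n_dim, None)
    rho, shared = _rsa_rho(frame, frame, type)
    return RSAResult(
        variable=participant_var,
        group_a=level,
        group_b=level,
        rho=rho,
        type=type,
        shared_target_count=shared,
    )
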