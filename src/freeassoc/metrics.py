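"""Target characterization: frequencies, norms, summaries, correlations.

Each operation appends (or replaces) its own column(s) on the study's
``targets`` table and leaves every other column untouched, so
characterizations can be layered and re-run independently.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, StateError, UsageError
from .study import AssociationStudy

logger = logging.getLogger(__name__)

COUNT_SCOPES = ("first", "all")


def _require_targets(study: AssociationStudy) -> pd.DataFrame:
    if study.targets is None:
        raise StateError("targets have not been set; call set_targets first")
    return study.targets


def _first_level_mask(responses: pd.DataFrame, level_col: str) -> pd.Series:
    """Rows belonging to the first response level.

    The first level is identified as the smallest value of ``level_col``
    (works for 1/2 integer coding and for "first"/"second" labels).
    """
    levels = responses[level_col]
    return levels == levels.min()


def count_targets(
    study: AssociationStudy,
    scope: str = "first",
    level_col: str = "level",
) -> AssociationStudy:
    """Attach ``frequency``: how often each target occurs among responses.

    ``scope='first'`` (default) counts only first-level response tokens —
    the count that determines how many second-level responses are
    available to embed the target, hence its embedding reliability.
    ``scope='all'`` counts across every level.  If the responses table has
    no ``level_col`` column, all rows are counted.
    """
    targets = _require_targets(study)
    if scope not in COUNT_SCOPES:
        raise UsageError(f"scope must be one of {COUNT_SCOPES}")
    responses = study.responses
    if scope == "first" and level_col in responses.columns:
        responses = responses.loc[_first_level_mask(responses, level_col)]
    counts = responses["response"].value_counts()
    out = study.copy()
    out.targets = targets.copy()
    out.targets["frequency"] = (
        out.targets["target"].map(counts).fillna(0).astype(int)
    )
    return out


def characterize_targets(
    study: AssociationStudy,
    characteristics: Sequence[str] | None = None,
    lookup: pd.DataFrame | str | Path | None = None,
    word_col: str = "word",
) -> AssociationStudy:
    """Left-join psycholinguistic characteristics onto the targets table.

    ``lookup`` is a norms table with one text key column (``word_col``)
    and one numeric column per characteristic (valence, arousal,
    dominance, concreteness, word_frequency, or user-defined).  Matching
    is on the exact (already-normalized) string; unmatched targets get
    NaN.  No norm tables are bundled: supply your own lookup, e.g. loaded
    from the published affective-ratings or word-frequency databases.
    """
    targets = _require_targets(study)
    if lookup is None:
        raise UsageError(
            "characterize_targets requires a lookup table (no norm tables "
            "are bundled); pass lookup=<DataFrame or CSV path>"
        )
    if not isinstance(lookup, pd.DataFrame):
        lookup = pd.read_csv(lookup)
    if word_col not in lookup.columns:
        raise SchemaError(f"lookup table has no {word_col!r} column")
    available = [c for c in lookup.columns if c != word_col]
    if characteristics is None:
        characteristics = available
    else:
        unknown = [c for c in characteristics if c not in available]
        if unknown:
            raise UsageError(
                f"characteristic(s) not in lookup: {', '.join(unknown)}"
            )
    keyed = lookup.drop_duplicates(subset=word_col).set_index(word_col)
    out = study.copy()
    out.targets = targets.copy()
    for name in characteristics:
        out.targets[name] = out.targets["target"].map(keyed[name])
    return out


def summarize_targets(
    study: AssociationStudy,
    response_var: str = "response_position",
    fun: Callable | str = "mean",
    name: str | None = None,
) -> AssociationStudy:
    """Aggregate a response covariate per target (e.g. mean position)."""
    targets = _require_targets(study)
    if response_var not in study.responses.columns:
        raise SchemaError(f"responses table has no column {response_var!r}")
    values = study.responses[response_var]
    fun_name = fun if isinstance(fun, str) else getattr(fun, "__name__", "agg")
    if not pd.api.types.is_numeric_dtype(values):
        numeric = pd.to_numeric(values, errors="coerce")
        if numeric.isna().any():
            raise SchemaError(
                f"response variable {response_var!r} is not numeric; cannot "
                f"aggregate with {fun_name}"
            )
        values = numeric
    grouped = values.groupby(study.responses["response"]).agg(fun)
    out = study.copy()
    out.targets = targets.copy()
    out.targets[name or f"{response_var}_{fun_name}"] = out.targets["target"].map(
        grouped
    )
    return out


def phi_coefficient(n11: int, n10: int, n01: int, n00: int) -> float:
    """Phi coefficient of a 2x2 contingency table.

    phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0), the Pearson
    correlation of the two underlying 0/1 variables.  Returns NaN when a
    margin is zero (one variable is constant).
    """
    n1_, n0_ = n11 + n10, n01 + n00
    n_1, n_0 = n11 + n01, n10 + n00
    denom = float(n1_) * n0_ * n_1 * n_0
    if denom == 0:
        return float("nan")
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


def _retrieval_indicator(study: AssociationStudy, target: str) -> pd.Series:
    """Per-participant 0/1: produced the target at least once."""
    producers = set(
        study.responses.loc[study.responses["response"] == target, "participant_id"]
    )
    return study.participants["participant_id"].isin(producers).astype(float)


def correlate_targets(
    study: AssociationStudy,
    participant_vars: Sequence[str],
    metric: str = "auto",
    top_n: int | None = 50,
    scope: str = "first",
) -> AssociationStudy:
    """Correlate target retrieval with participant characteristics.

    For each target a per-participant 0/1 retrieval indicator is built
    (produced at least once).  Binary covariates use the phi coefficient;
    numeric covariates use the point-biserial (Pearson on the indicator).
    Because low-frequency targets yield unreliable correlations, the
    computation is restricted to the ``top_n`` most frequent targets by
    default (ties at the cutoff frequency are all included); pass
    ``top_n=None`` to correlate every target.

    One column per covariate is appended, named ``{var}_phi`` or
    ``{var}_r``; targets outside the top-``n`` set get NaN.
    """
    targets = _require_targets(study)
    if metric not in ("auto", "phi", "pearson"):
        raise UsageError("metric must be 'auto', 'phi' or 'pearson'")
    missing = [v for v in participant_vars if v not in study.participants.columns]
    if missing:
        raise SchemaError(
            f"participants table has no column(s): {', '.join(missing)}"
        )

    if "frequency" in targets.columns:
        freq = targets.set_index("target")["frequency"]
    else:
        freq = (
            count_targets(study, scope=scope).targets.set_index("target")["frequency"]
        )
    if top_n is not None and top_n < len(freq):
        cutoff = freq.sort_values(ascending=False).iloc[top_n - 1]
        selected = freq[freq >= cutoff].index
    else:
        selected = freq.index

    out = study.copy()
    out.targets = targets.copy()
    for var in participant_vars:
        covariate = study.participants[var]
        numeric = pd.api.types.is_numeric_dtype(covariate)
        levels = covariate.dropna().unique()
        if len(levels) < 2:
            warnings.warn(
                f"participant variable {var!r} is constant; correlations "
                "undefined, reporting NaN",
                stacklevel=2,
            )
            out.targets[f"{var}_phi" if not numeric else f"{var}_r"] = np.nan
            continue
        use_phi = (metric == "phi") or (
            metric == "auto" and not numeric and len(levels) == 2
        )
        if metric == "phi" and (numeric or len(levels) != 2):
            raise UsageError(
                f"metric='phi' requires a binary covariate; {var!r} is not"
            )
        if use_phi:
            # code the alphabetically-first level as 1 for a fixed sign
            pos = sorted(map(str, levels))[0]
            x = (covariate.astype(str) == pos).astype(float).to_numpy()
            col = f"{var}_phi"
            coding = f"1 = {pos}"
        else:
            if not numeric:
                raise UsageError(
                    f"covariate {var!r} is non-numeric with >2 levels; phi/"
                    "point-biserial undefined — recode or use cross_targets"
                )
            x = covariate.astype(float).to_numpy()
            col = f"{var}_r"
            coding = "numeric"
        values = {}
        for target in selected:
            y = _retrieval_indicator(study, target).to_numpy()
            if y.std() == 0 or x.std() == 0:
                values[target] = np.nan
            else:
                values[target] = float(np.corrcoef(x, y)[0, 1])
        out.targets[col] = out.targets["target"].map(values)
        out.targets.attrs.setdefault("correlation_coding", {})[var] = coding
    return out


def correlations_frame(study: AssociationStudy) -> pd.DataFrame:
    """Tidy (target, variable, metric, value) view of correlation columns."""
    targets = _require_targets(study)
    rows = []
    for col in targets.columns:
        if col.endswith("_phi") or col.endswith("_r"):
            metric = "phi" if col.endswith("_phi") else "point_biserial"
            var = col.rsplit("_", 1)[0]
            for target, value in zip(targets["target"], targets[col]):
                rows.append((target, var, metric, value))
    return pd.DataFrame(rows, columns=["target", "variable", "metric", "value"])
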