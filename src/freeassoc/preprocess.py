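"""Word-form normalization and the manual spelling-correction round trip.

Free-association responses arrive with arbitrary casing, stray whitespace
and punctuation ("banana", " Banana!", "BANANA") that proliferate word
forms without carrying meaning.  :func:`normalize` unifies them with a
fixed rule order (whitespace -> punctuation -> case) so that modal-casing
counts are computed on already-cleaned strings.  Automatic spellchecking
is deliberately not offered — correcting isolated words without context
is error-prone — but :func:`export_wordlist` / :func:`import_wordlist`
support a manual correction pass over the unique response forms, using
frequency as a rough misspelling indicator.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .errors import ProcessingError, SchemaError, StateError, UsageError
from .study import AssociationStudy

logger = logging.getLogger(__name__)

CASE_OPTIONS = ("lower", "upper", "sentence", "most_frequent", "none")
PUNCT_OPTIONS = ("all", "end", "none")
WHITESPACE_OPTIONS = ("trim", "squish", "none")
APPLY_TO_OPTIONS = ("responses", "all")

# Hyphens and apostrophes between word characters are legitimate parts of
# association responses ("problem-solving", "don't") and are kept.
_KEEP_INTERNAL = {"-", "'", "’"}


@dataclass(frozen=True)
class NormalizationConfig:
    case: str = "lower"
    punct: str = "all"
    whitespace: str = "trim"
    process_cues: bool = True
    extra_punct: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.case not in CASE_OPTIONS:
            raise UsageError(f"case must be one of {CASE_OPTIONS}, got {self.case!r}")
        if self.punct not in PUNCT_OPTIONS:
            raise UsageError(f"punct must be one of {PUNCT_OPTIONS}, got {self.punct!r}")
        if self.whitespace not in WHITESPACE_OPTIONS:
            raise UsageError(
                f"whitespace must be one of {WHITESPACE_OPTIONS}, got {self.whitespace!r}"
            )


def _is_punct(char: str) -> bool:
    return unicodedata.category(char).startswith("P")


def _strip_punct_all(text: str, extra: frozenset[str]) -> str:
    out = []
    n = len(text)
    for i, ch in enumerate(text):
        if ch in extra:
            continue
        if _is_punct(ch):
            internal = (
                ch in _KEEP_INTERNAL
                and 0 < i < n - 1
                and text[i - 1].isalnum()
                and text[i + 1].isalnum()
            )
            if not internal:
                continue
        out.append(ch)
    return "".join(out)


def _strip_punct_end(text: str, extra: frozenset[str]) -> str:
    # strips the full trailing run of punctuation, not just one mark
    end = len(text)
    while end > 0 and (_is_punct(text[end - 1]) or text[end - 1] in extra):
        end -= 1
    return text[:end]


def _apply_whitespace(text: str, mode: str) -> str:
    if mode == "trim":
        return text.strip()
    if mode == "squish":
        return re.sub(r"\s+", " ", text.strip())
    return text


def _apply_case_simple(text: str, mode: str) -> str:
    if mode == "lower":
        return text.lower()
    if mode == "upper":
        return text.upper()
    if mode == "sentence":
        return text[:1].upper() + text[1:].lower() if text else text
    return text


def normalize(
    study: AssociationStudy,
    case: str = "lower",
    punct: str = "all",
    whitespace: str = "trim",
    process_cues: bool = True,
    config: NormalizationConfig | None = None,
) -> AssociationStudy:
    """Normalize response (and optionally cue) word forms.

    Rules are applied in the fixed order whitespace -> punctuation -> case.
    ``case='most_frequent'`` maps every case-insensitive form group to its
    modal original casing (ties broken alphabetically), with counts taken
    over the cleaned strings of all processed columns.

    Must be called before :func:`freeassoc.study.set_targets`: targets fix
    the analysis vocabulary, and rewriting word forms afterwards would
    silently desynchronize it.
    """
    if study.has_targets:
        raise StateError(
            "normalize must be called before set_targets; re-import or "
            "re-derive targets after changing word forms"
        )
    cfg = config or NormalizationConfig(
        case=case, punct=punct, whitespace=whitespace, process_cues=process_cues
    )

    def clean(text: str) -> str:
        text = _apply_whitespace(text, cfg.whitespace)
        if cfg.punct == "all":
            text = _strip_punct_all(text, cfg.extra_punct)
        elif cfg.punct == "end":
            text = _strip_punct_end(text, cfg.extra_punct)
        # punctuation removal can expose new edge whitespace
        return _apply_whitespace(text, cfg.whitespace)

    out = study.copy()
    columns: list[tuple[pd.DataFrame, str]] = [(out.responses, "response")]
    if cfg.process_cues:
        columns.append((out.responses, "cue"))
        columns.append((out.cues, "cue"))

    cleaned: dict[tuple[int, str], pd.Series] = {}
    for frame, col in columns:
        cleaned[(id(frame), col)] = frame[col].map(clean)

    if cfg.case == "most_frequent":
        counts: Counter[str] = Counter()
        for series in cleaned.values():
            counts.update(series)
        modal: dict[str, str] = {}
        for group in {form.lower() for form in counts}:
            variants = [f for f in counts if f.lower() == group]
            # highest count wins; ties broken alphabetically
            modal[group] = min(variants, key=lambda f: (-counts[f], f))
        recase: Callable[[str], str] = lambda t: modal[t.lower()]
    else:
        recase = lambda t: _apply_case_simple(t, cfg.case)

    for frame, col in columns:
        frame[col] = cleaned[(id(frame), col)].map(recase)
    out.cues = out.cues.drop_duplicates(subset="cue").reset_index(drop=True)
    out.meta["normalized"] = {
        "case": cfg.case,
        "punct": cfg.punct,
        "whitespace": cfg.whitespace,
        "process_cues": cfg.process_cues,
    }
    return out


def apply_custom_normalizer(
    study: AssociationStudy,
    transform: Callable[[str], str],
    apply_to: str = "responses",
) -> AssociationStudy:
    """Apply a user-supplied text->text function element-wise.

    This is the hook for external text processing (stemmers, lemmatizers,
    transliteration) that the package itself does not bundle.
    """
    if apply_to not in APPLY_TO_OPTIONS:
        raise UsageError(f"apply_to must be one of {APPLY_TO_OPTIONS}")

    def safe(text: str) -> str:
        try:
            result = transform(text)
        except Exception as exc:  # noqa: BLE001 - re-raise with input context
            raise ProcessingError(
                f"custom normalizer raised on input {text!r}: {exc}"
            ) from exc
        if not isinstance(result, str):
            raise ProcessingError(
                f"custom normalizer returned non-text for input {text!r}: "
                f"{type(result).__name__}"
            )
        return result

    out = study.copy()
    out.responses["response"] = out.responses["response"].map(safe)
    if apply_to == "all":
        out.responses["cue"] = out.responses["cue"].map(safe)
        out.cues["cue"] = out.cues["cue"].map(safe)
        out.cues = out.cues.drop_duplicates(subset="cue").reset_index(drop=True)
    if out.has_targets:
        out.targets["target"] = out.targets["target"].map(safe)
        out.targets = out.targets.drop_duplicates(subset="target").reset_index(
            drop=True
        )
    return out


WORDLIST_COLUMNS = ("response", "response_correct", "response_frequency")


def make_wordlist(study: AssociationStudy, sort: str = "alphabetical") -> pd.DataFrame:
    """Unique response forms with blank correction slots and frequencies."""
    if sort not in ("alphabetical", "frequency"):
        raise UsageError("sort must be 'alphabetical' or 'frequency'")
    counts = Counter(study.responses["response"])
    rows = [(form, "", freq) for form, freq in counts.items()]
    if sort == "alphabetical":
        rows.sort(key=lambda r: r[0])
    else:  # descending by count, ties alphabetical
        rows.sort(key=lambda r: (-r[2], r[0]))
    return pd.DataFrame(rows, columns=list(WORDLIST_COLUMNS))


def export_wordlist(
    study: AssociationStudy, path: str | Path, sort: str = "alphabetical"
) -> pd.DataFrame:
    """Write the wordlist CSV for a manual spelling-correction pass."""
    wordlist = make_wordlist(study, sort=sort)
    wordlist.to_csv(path, index=False, encoding="utf-8")
    return wordlist


def import_wordlist(
    study: AssociationStudy,
    wordlist: str | Path | pd.DataFrame,
    apply_to: str = "responses",
) -> AssociationStudy:
    """Apply corrections from a completed wordlist in a single pass.

    Wherever ``response_correct`` is non-blank, that form replaces the
    original in the selected columns.  Replacement is one-pass: a pair of
    corrections mapping two forms to each other swaps them rather than
    chaining.
    """
    if apply_to not in APPLY_TO_OPTIONS:
        raise UsageError(f"apply_to must be one of {APPLY_TO_OPTIONS}")
    if not isinstance(wordlist, pd.DataFrame):
        wordlist = pd.read_csv(wordlist, dtype=str, keep_default_na=False)
    missing = [c for c in WORDLIST_COLUMNS[:2] if c not in wordlist.columns]
    if missing:
        raise SchemaError(
            f"wordlist is missing column(s): {', '.join(missing)}; expected "
            f"schema {WORDLIST_COLUMNS}"
        )
    corrections = {
        row.response: row.response_correct
        for row in wordlist.itertuples()
        if isinstance(row.response_correct, str) and row.response_correct != ""
    }
    if not corrections:
        return study.copy()
    logger.info("applying %d wordlist corrections", len(corrections))

    def fix(text: str) -> str:
        return corrections.get(text, text)

    out = study.copy()
    out.responses["response"] = out.responses["response"].map(fix)
    if apply_to == "all":
        out.responses["cue"] = out.responses["cue"].map(fix)
        out.cues["cue"] = out.cues["cue"].map(fix)
        out.cues = out.cues.drop_duplicates(subset="cue").reset_index(drop=True)
    return out
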