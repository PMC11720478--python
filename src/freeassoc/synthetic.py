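"""Mini-snowball free-association study generator with known latent structure.

Emulates the structure of a two-level ("mini-snowball") free-association
study: every participant gives ``n_first`` first-level responses to one
top-level cue, then ``n_second`` second-level responses to each of their
first-level responses (so 5 + 5x5 = 30 tokens per participant under the
defaults).  Responses are drawn from a mixture of latent topics with
disjoint vocabularies; participant groups (e.g. gender x education)
modulate topic retrieval probabilities multiplicatively, and word choice
within a topic is Zipf-distributed.  Because the topic of every word and
the exact group-wise topic weights are known, every pipeline stage —
normalization, embedding, clustering, stability, group comparison — can
be validated against ground truth without any external data.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .study import AssociationStudy, import_study

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Topic:
    label: str
    vocabulary: tuple[str, ...]
    weight: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the generator.

    ``group_effects`` maps variable -> level -> topic label -> positive
    multiplier on that topic's base retrieval weight; absent entries
    default to 1 (no effect).  ``topic_fidelity`` is the probability that
    a second-level response stays in its cue's topic; the remainder is
    drawn from the participant's (group-adjusted) topic mixture.
    ``typo_rate`` perturbs a fraction of response strings at the
    character level to exercise the wordlist-correction round trip.
    """

    n_participants: int = 1000
    top_cue: str = "intelligence"
    topics: tuple[Topic, ...] = ()
    group_vars: dict[str, tuple[str, ...]] = field(default_factory=dict)
    group_effects: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=dict
    )
    n_first: int = 5
    n_second: int = 5
    zipf_exponent: float = 1.0
    topic_fidelity: float = 0.8
    typo_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not self.topics:
            raise ConfigurationError("at least one topic is required")
        seen: set[str] = set()
        for topic in self.topics:
            overlap = seen & set(topic.vocabulary)
            if overlap:
                raise ConfigurationError(
                    f"topic vocabularies must be disjoint; duplicated: "
                    f"{sorted(overlap)[:5]}"
                )
            seen |= set(topic.vocabulary)
            if topic.weight <= 0:
                raise ConfigurationError("topic weights must be positive")
            if len(topic.vocabulary) < self.n_first:
                raise ConfigurationError(
                    f"topic {topic.label!r} vocabulary ({len(topic.vocabulary)} "
                    f"words) is smaller than n_first={self.n_first}"
                )
            if len(topic.vocabulary) < self.n_second:
                raise ConfigurationError(
                    f"topic {topic.label!r} vocabulary ({len(topic.vocabulary)} "
                    f"words) is smaller than n_second={self.n_second}"
                )
        for var, levels in self.group_effects.items():
            if var not in self.group_vars:
                raise ConfigurationError(f"group effect on unknown variable {var!r}")
            labels = {t.label for t in self.topics}
            for level, effects in levels.items():
                if level not in self.group_vars[var]:
                    raise ConfigurationError(
                        f"group effect on unknown level {var}={level!r}"
                    )
                for topic_label, mult in effects.items():
                    if topic_label not in labels:
                        raise ConfigurationError(
                            f"group effect on unknown topic {topic_label!r}"
                        )
                    if mult <= 0:
                        raise ConfigurationError("effect multipliers must be positive")
        if not 0.0 <= self.topic_fidelity <= 1.0:
            raise ConfigurationError("topic_fidelity must be in [0, 1]")
        if not 0.0 <= self.typo_rate <= 1.0:
            raise ConfigurationError("typo_rate must be in [0, 1]")
        if self.zipf_exponent < 0:
            raise ConfigurationError("zipf_exponent must be >= 0")


def _pseudo_words(prefix: str, n: int, rng: np.random.Generator) -> tuple[str, ...]:
    """Pronounceable-ish pseudo-words, unique, prefixed by topic."""
    consonants = "bcdfgklmnprstvz"
    vowels = "aeiou"
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < n:
        stem = "".join(
            rng.choice(list(consonants)) + rng.choice(list(vowels))
            for _ in range(3)
        )
        word = f"{prefix}{stem}"
        if word not in seen:
            seen.add(word)
            words.append(word)
    return tuple(words)


def default_config(
    n_participants: int = 1000,
    n_topics: int = 6,
    vocab_size: int = 60,
    seed: int = 0,
) -> GeneratorConfig:
    """Configuration emulating the working-example study design.

    1,000 participants, one top-level cue, 5 first- and 5 second-level
    responses, gender x education groups, six latent topics with
    moderate group-dependent retrieval effects.
    """
    rng = np.random.default_rng(seed + 7919)
    labels = [f"topic{string.ascii_lowercase[i]}" for i in range(n_topics)]
    # hyphenated prefix: survives word-form normalization intact
    topics = tuple(
        Topic(label=lab, vocabulary=_pseudo_words(f"{lab}-", vocab_size, rng))
        for lab in labels
    )
    # alternating moderate push/pull effects across topics per level
    effects_gender = {
        "male": {labels[i]: (1.5 if i % 2 == 0 else 1 / 1.5) for i in range(n_topics)},
    }
    effects_edu = {
        "university": {
            labels[i]: (1.4 if i < n_topics // 2 else 1 / 1.4) for i in range(n_topics)
        },
    }
    return GeneratorConfig(
        n_participants=n_participants,
        topics=topics,
        group_vars={
            "gender": ("male", "female"),
            "education": ("high_school", "university"),
        },
        group_effects={"gender": effects_gender, "education": effects_edu},
        seed=seed,
    )


from functools import lru_cache


@lru_cache(maxsize=64)
def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    weights = ranks**-exponent
    return weights / weights.sum()


def adjusted_topic_weights(
    config: GeneratorConfig, levels: dict[str, str]
) -> np.ndarray:
    """Normalized topic probabilities for a participant with these levels."""
    weights = np.array([t.weight for t in config.topics], dtype=float)
    for var, level in levels.items():
        effects = config.group_effects.get(var, {}).get(level, {})
        for i, topic in enumerate(config.topics):
            weights[i] *= effects.get(topic.label, 1.0)
    return weights / weights.sum()


def ground_truth(config: GeneratorConfig) -> dict:
    """Latent labels and analytic expectations implied by a configuration.

    Returns ``word_topic`` (word -> topic label), ``group_proportions``
    (DataFrame: one row per level combination, expected first-level topic
    probabilities), and ``effect_signs`` (variable, level, topic, sign of
    the injected multiplier relative to 1).
    """
    config.validate()
    word_topic = {
        word: topic.label for topic in config.topics for word in topic.vocabulary
    }
    labels = [t.label for t in config.topics]
    combos = (
        list(itertools.product(*config.group_vars.values()))
        if config.group_vars
        else [()]
    )
    rows = []
    for combo in combos:
        levels = dict(zip(config.group_vars, combo))
        probs = adjusted_topic_weights(config, levels)
        rows.append({**levels, **dict(zip(labels, probs))})
    signs = [
        (var, level, topic, int(np.sign(np.log(mult))))
        for var, per_level in config.group_effects.items()
        for level, effects in per_level.items()
        for topic, mult in effects.items()
        if mult != 1.0
    ]
    return {
        "word_topic": word_topic,
        "group_proportions": pd.DataFrame(rows),
        "effect_signs": pd.DataFrame(
            signs, columns=["variable", "level", "topic", "sign"]
        ),
    }


def _sample_without_replacement(
    rng: np.random.Generator,
    config: GeneratorConfig,
    topic_probs: np.ndarray,
    n_draws: int,
    fixed_topic: int | None = None,
) -> list[str]:
    """Draw distinct responses: topic per draw, Zipfian word within topic."""
    chosen: list[str] = []
    used: set[str] = set()
    n_topics = len(config.topics)
    while len(chosen) < n_draws:
        if fixed_topic is not None and rng.random() < config.topic_fidelity:
            t = fixed_topic
        else:
            t = int(rng.choice(n_topics, p=topic_probs))
        vocab = config.topics[t].vocabulary
        probs = _zipf_probs(len(vocab), config.zipf_exponent)
        word = vocab[int(rng.choice(len(vocab), p=probs))]
        if word not in used:
            used.add(word)
            chosen.append(word)
    return chosen


def _inject_typo(word: str, rng: np.random.Generator) -> str:
    if len(word) < 2:
        return word + "x"
    i = int(rng.integers(0, len(word) - 1))
    return word[:i] + word[i + 1] + word[i] + word[i + 2 :]  # adjacent swap


def generate_frame(config: GeneratorConfig) -> pd.DataFrame:
    """Long-format response table (one row per token), deterministic in seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    word_topic_index = {
        word: i
        for i, topic in enumerate(config.topics)
        for word in topic.vocabulary
    }
    rows: list[tuple] = []
    group_vars = list(config.group_vars)
    for p in range(config.n_participants):
        pid = f"p{p + 1:04d}"
        levels = {
            var: config.group_vars[var][int(rng.integers(0, len(config.group_vars[var])))]
            for var in group_vars
        }
        topic_probs = adjusted_topic_weights(config, levels)
        first = _sample_without_replacement(
            rng, config, topic_probs, config.n_first
        )
        for pos, word in enumerate(first, start=1):
            rows.append(
                (pid, *[levels[v] for v in group_vars], config.top_cue, word, pos, "first")
            )
        for cue_word in first:
            second = _sample_without_replacement(
                rng,
                config,
                topic_probs,
                config.n_second,
                fixed_topic=word_topic_index[cue_word],
            )
            for pos, word in enumerate(second, start=1):
                rows.append(
                    (pid, *[levels[v] for v in group_vars], cue_word, word, pos, "second")
                )
    frame = pd.DataFrame(
        rows,
        columns=["participant_id", *group_vars, "cue", "response",
                 "response_position", "level"],
    )
    if config.typo_rate > 0:
        mask = rng.random(len(frame)) < config.typo_rate
        frame.loc[mask, "response"] = frame.loc[mask, "response"].map(
            lambda w: _inject_typo(w, rng)
        )
    return frame


def generate_study(config: GeneratorConfig) -> AssociationStudy:
    """Generate a study and import it through the standard validation path."""
    frame = generate_frame(config)
    study = import_study(
        frame,
        participant_vars=list(config.group_vars),
        response_vars=["response_position", "level"],
    )
    study.meta["generator_seed"] = config.seed
    return study


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    return replace(config, seed=seed)
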