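"""Artificial-language stimulus streams.

A stream is a sequence of syllable tokens presented isochronously (300 ms
per syllable by default) in which trisyllabic nonsense words repeat in a
pseudorandom order without immediate repetition.  Because presentation is
isochronous, syllables arrive at 1/syllable_duration Hz (3.33 Hz) and the
hidden words at one third of that (1.11 Hz) — the two tagged frequencies
every downstream analysis is locked to.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: The four trisyllabic nonsense words of the exposure stream.
DEFAULT_WORDS = {
    "tafuko": ("ta", "fu", "ko"),
    "rugeme": ("ru", "ge", "me"),
    "repuni": ("re", "pu", "ni"),
    "fetisu": ("fe", "ti", "su"),
}

DEFAULT_SYLLABLE_DURATION = 0.300  # seconds


class StreamConstraintError(ValueError):
    """Raised when the no-immediate-repeat word order is unsatisfiable."""


@dataclass(frozen=True)
class Lexicon:
    """A set of trisyllabic words sharing no syllables.

    Parameters
    ----------
    words
        Mapping from word label to its ordered syllable triple.
    syllable_duration
        Presentation duration of one syllable, in seconds.
    """

    words: dict[str, tuple[str, str, str]] = field(
        default_factory=lambda: dict(DEFAULT_WORDS)
    )
    syllable_duration: float = DEFAULT_SYLLABLE_DURATION

    def __post_init__(self) -> None:
        if self.syllable_duration <= 0:
            raise ValueError("syllable_duration must be positive")
        if not self.words:
            raise ValueError("lexicon must contain at least one word")
        seen: set[str] = set()
        for label, sylls in self.words.items():
            if len(sylls) != 3:
                raise ValueError(f"word {label!r} must have exactly 3 syllables")
            for s in sylls:
                if s in seen:
                    raise ValueError(f"syllable {s!r} appears in more than one word")
                seen.add(s)

    @property
    def word_duration(self) -> float:
        return 3.0 * self.syllable_duration

    @property
    def syllable_rate(self) -> float:
        """Syllable presentation rate in Hz."""
        return 1.0 / self.syllable_duration

    @property
    def word_rate(self) -> float:
        """Word presentation rate in Hz (one third of the syllable rate)."""
        return 1.0 / self.word_duration


@dataclass(frozen=True)
class Token:
    syllable: str
    onset: float
    word: str
    position: int  # 1..3 within the word


@dataclass(frozen=True)
class StreamSpec:
    """Realized stimulus stream: ordered syllable tokens with onset times."""

    tokens: tuple[Token, ...]
    syllable_duration: float
    seed: int

    def __post_init__(self) -> None:
        onsets = np.array([t.onset for t in self.tokens])
        if len(onsets) > 1:
            steps = np.diff(onsets)
            if not np.allclose(steps, self.syllable_duration, atol=1e-9):
                raise ValueError("token onsets must be isochronous")

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def n_words(self) -> int:
        return len(self.tokens) // 3

    @property
    def duration(self) -> float:
        return self.n_tokens * self.syllable_duration

    @property
    def word_sequence(self) -> list[str]:
        return [t.word for t in self.tokens if t.position == 1]

    @property
    def word_duration(self) -> float:
        return 3.0 * self.syllable_duration

    @property
    def word_rate(self) -> float:
        return 1.0 / self.word_duration

    @property
    def syllable_rate(self) -> float:
        return 1.0 / self.syllable_duration

    def all_word_onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.tokens if t.position == 1])


def generate_stream(
    lexicon: Lexicon, repetitions_per_word: int, seed: int
) -> StreamSpec:
    """Generate a pseudorandom stream with per-word quotas and no repeats.

    Words are drawn uniformly among those with remaining quota, excluding
    the previously emitted word and any choice that would strand the
    remaining quotas in an unsatisfiable state: counts c with total T can
    follow previous word p without adjacent repetition iff
    max(c) <= ceil(T/2) and not (T odd and c[p] = ceil(T/2)).  The result
    is deterministic given ``seed`` and always completes for feasible
    inputs.
    """
    if repetitions_per_word < 1:
        raise ValueError("repetitions_per_word must be >= 1")
    labels = list(lexicon.words)
    if len(labels) == 1 and repetitions_per_word > 1:
        raise StreamConstraintError(
            "a single-word lexicon cannot repeat without adjacent repetition"
        )

    def feasible(quota: dict[str, int], prev: str | None) -> bool:
        total = sum(quota.values())
        if total == 0:
            return True
        half = (total + 1) // 2
        if max(quota.values()) > half:
            return False
        if total % 2 == 1 and prev is not None and quota.get(prev, 0) == half:
            return False
        return True

    rng = np.random.default_rng(seed)
    quota = {w: repetitions_per_word for w in labels}
    order: list[str] = []
    n_total = len(labels) * repetitions_per_word
    while len(order) < n_total:
        prev = order[-1] if order else None
        choices = []
        for w in labels:
            if quota[w] == 0 or w == prev:
                continue
            quota[w] -= 1
            if feasible(quota, w):
                choices.append(w)
            quota[w] += 1
        if not choices:
            raise StreamConstraintError("no-repeat ordering unsatisfiable")
        pick = choices[int(rng.integers(len(choices)))]
        order.append(pick)
        quota[pick] -= 1

    tokens: list[Token] = []
    for i, word in enumerate(order):
        for pos, syll in enumerate(lexicon.words[word], start=1):
            idx = 3 * i + (pos - 1)
            tokens.append(
                Token(
                    syllable=syll,
                    onset=idx * lexicon.syllable_duration,
                    word=word,
                    position=pos,
                )
            )
    return StreamSpec(
        tokens=tuple(tokens), syllable_duration=lexicon.syllable_duration, seed=seed
    )


def word_onsets(stream: StreamSpec, every_k: int = 1) -> np.ndarray:
    """Onset times of every ``every_k``-th word (0-based: words 0, k, 2k, ...)."""
    if every_k < 1:
        raise ValueError("every_k must be >= 1")
    return stream.all_word_onsets()[::every_k]


def write_events(stream: StreamSpec, path: str | Path) -> Path:
    """Write the stream as a BIDS-style tab-separated event file."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["onset", "duration", "trial_type", "syllable", "word", "word_onset_flag"]
        )
        for t in stream.tokens:
            writer.writerow(
                [
                    f"{t.onset:.6f}",
                    f"{stream.syllable_duration:.6f}",
                    "syllable",
                    t.syllable,
                    t.word,
                    int(t.position == 1),
                ]
            )
    return path


def read_events(path: str | Path, seed: int = 0) -> StreamSpec:
    """Read an event file written by :func:`write_events`.

    The syllable duration is recovered from the duration column; ``seed``
    is carried as metadata only (the token order is fully specified by the
    file).
    """
    path = Path(path)
    tokens: list[Token] = []
    durations: list[float] = []
    rows: list[dict] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = list(reader)
    if not rows:
        raise ValueError("event file contains no tokens")
    syllable_duration = float(rows[0]["duration"])
    pos = 0
    for i, row in enumerate(rows):
        pos = 1 if int(row["word_onset_flag"]) else pos + 1
        # Onsets are reconstructed from the isochronous grid rather than
        # parsed, so the round trip is exact despite text formatting.
        tokens.append(
            Token(
                syllable=row["syllable"],
                onset=i * syllable_duration,
                word=row["word"],
                position=pos,
            )
        )
        durations.append(float(row["duration"]))
    return StreamSpec(
        tokens=tuple(tokens), syllable_duration=syllable_duration, seed=seed
    )
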