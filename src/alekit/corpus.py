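"""Foci corpora: experiments, Sleuth text I/O and metadata filtering.

A *corpus* is the result set of one literature search: a list of experiments,
each contributing a subject count and the peak activation coordinates (foci,
in mm) it reported, plus free-form metadata labels (gender, diagnosis,
behavioral domain, paradigm ...) that the filtering step selects on.

The text dialect is the Sleuth foci export: ``//``-prefixed comment lines
carrying the reference space, study name, subject count and metadata,
followed by whitespace-separated ``x y z`` rows; blank lines separate
experiments.  We are liberal in what we accept: any ``// key=value`` comment
becomes metadata, other comments name the experiment.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Focus",
    "Experiment",
    "Corpus",
    "SleuthParseError",
    "parse_sleuth",
    "write_sleuth",
    "filter_corpus",
    "corpus_summary",
]


class SleuthParseError(ValueError):
    """Malformed Sleuth foci text."""


@dataclass(frozen=True)
class Focus:
    """One reported peak activation coordinate, in world mm."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not np.isfinite(v):
                raise ValueError(f"focus coordinates must be finite, got {self!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_xyz(cls, arr) -> "Focus":
        x, y, z = (float(v) for v in arr)
        return cls(x, y, z)


@dataclass
class Experiment:
    """One published contrast: its foci, subject count and metadata labels."""

    id: str
    n_subjects: int
    foci: list[Focus]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("experiment id must be nonempty")
        self.n_subjects = int(self.n_subjects)
        if self.n_subjects < 1:
            raise ValueError(f"{self.id}: n_subjects must be >= 1")
        if len(self.foci) < 1:
            raise ValueError(f"{self.id}: an experiment needs at least one focus")

    @property
    def foci_mm(self) -> np.ndarray:
        """(n_foci, 3) array of focus coordinates in mm."""
        return np.array([f.xyz for f in self.foci])

    def matches(self, predicate: dict[str, str]) -> bool:
        return all(self.metadata.get(k) == v for k, v in predicate.items())


@dataclass
class Corpus:
    """The experiments returned by one search, in one reference space."""

    experiments: list[Experiment]
    space_label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if not self.space_label:
            raise ValueError("space_label must be nonempty")
        ids = [e.id for e in self.experiments]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate experiment ids in corpus: {dup}")

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.experiments]

    @property
    def n_subjects_total(self) -> int:
        return sum(e.n_subjects for e in self.experiments)

    def subset(self, ids) -> "Corpus":
        wanted = set(ids)
        return Corpus(
            experiments=[e for e in self.experiments if e.id in wanted],
            space_label=self.space_label,
        )


# -- Sleuth dialect -------------------------------------------------------


def parse_sleuth(source) -> Corpus:
    """Parse Sleuth foci text from a string, path-like or text stream.

    One experiment per block; blocks are separated by blank lines.  Comment
    lines start with ``//``: ``// Reference=<space>`` declares the space,
    ``// Subjects=<n>`` the subject count (required per block), other
    ``// key=value`` comments become metadata and any other comment names
    the experiment.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".txt", ".tsv"))
    ):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = str(source)

    space_label: str | None = None
    experiments: list[Experiment] = []
    seen_ids: set[str] = set()

    block_name: str | None = None
    block_subjects: int | None = None
    block_meta: dict[str, str] = {}
    block_foci: list[Focus] = []
    block_start_line = 0

    def flush(line_no: int) -> None:
        nonlocal block_name, block_subjects, block_meta, block_foci
        if block_name is None and block_subjects is None and not block_foci and not block_meta:
            return
        if block_subjects is None:
            raise SleuthParseError(
                f"block starting near line {block_start_line}: missing '// Subjects=<n>' line"
            )
        if not block_foci:
            raise SleuthParseError(
                f"block starting near line {block_start_line}: no coordinate rows"
            )
        exp_id = block_name if block_name else f"experiment-{len(experiments) + 1}"
        if exp_id in seen_ids:
            raise SleuthParseError(f"duplicate experiment id {exp_id!r}")
        seen_ids.add(exp_id)
        experiments.append(
            Experiment(id=exp_id, n_subjects=block_subjects, foci=block_foci, metadata=block_meta)
        )
        block_name, block_subjects, block_meta, block_foci = None, None, {}, []

    in_block = False
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            flush(line_no)
            in_block = False
            continue
        if not in_block:
            block_start_line = line_no
            in_block = True
        if line.startswith("//"):
            body = line[2:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key, value = key.strip(), value.strip()
                if key.lower() == "reference":
                    if space_label is None:
                        space_label = value
                    in_block = bool(block_foci or block_meta or block_name)
                elif key.lower() == "subjects":
                    try:
                        block_subjects = int(value)
                    except ValueError:
                        raise SleuthParseError(
                            f"line {line_no}: non-integer subject count {value!r}"
                        ) from None
                else:
                    block_meta[key] = value
            elif body:
                if block_name is None:
                    block_name = body
            continue
        tokens = line.split()
        if len(tokens) != 3:
            raise SleuthParseError(
                f"line {line_no}: expected 3 coordinate columns, got {len(tokens)}"
            )
        try:
            x, y, z = (float(t) for t in tokens)
        except ValueError:
            raise SleuthParseError(f"line {line_no}: non-numeric coordinate in {line!r}") from None
        block_foci.append(Focus(x, y, z))
    flush(line_no=len(text.splitlines()) + 1)

    if not experiments:
        raise SleuthParseError("empty corpus")
    return Corpus(experiments=experiments, space_label=space_label or "UNKNOWN")


def _fmt(v: float) -> str:
    """Shortest decimal that round-trips the float exactly."""
    return repr(float(v))


def write_sleuth(corpus: Corpus, stream=None) -> str:
    """Emit the Sleuth dialect accepted by :func:`parse_sleuth`.

    ``parse_sleuth(write_sleuth(c))`` preserves ids, subject counts, foci
    (order and exact values) and metadata.
    """
    buf = io.StringIO()
    buf.write(f"// Reference={corpus.space_label}\n")
    for exp in corpus.experiments:
        buf.write("\n")
        buf.write(f"// {exp.id}\n")
        buf.write(f"// Subjects={exp.n_subjects}\n")
        for key in sorted(exp.metadata):
            buf.write(f"// {key}={exp.metadata[key]}\n")
        for f in exp.foci:
            buf.write(f"{_fmt(f.x)}\t{_fmt(f.y)}\t{_fmt(f.z)}\n")
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def filter_corpus(corpus: Corpus, predicate: dict[str, str]) -> Corpus:
    """Sub-corpus of experiments whose metadata satisfies every term.

    The predicate is a conjunction of exact ``key=value`` matches, mirroring
    a database search with multiple criteria (e.g. ``gender=males`` and
    ``diagnosis=depression``); a missing key leaves a term unsatisfied.  An
    empty predicate is the identity; an empty result is legal.
    """
    return Corpus(
        experiments=[e for e in corpus.experiments if e.matches(predicate)],
        space_label=corpus.space_label,
    )


def corpus_summary(corpus: Corpus) -> pd.DataFrame:
    """One row per experiment: id, n_subjects, n_foci and metadata columns."""
    rows = []
    for e in corpus.experiments:
        row = {"id": e.id, "n_subjects": e.n_subjects, "n_foci": len(e.foci)}
        row.update(e.metadata)
        rows.append(row)
    return pd.DataFrame(rows)
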